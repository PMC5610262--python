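import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import isletq as q

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def default_protocol():
    return q.default_protocol()


def make_cell(cell_id, means, sds=(2.0, 2.0, 2.0), n_pixels=50, islet="islet_0",
              xyz=(0.0, 0.0, 0.0)):
    """One row of the per-cell color-measurement schema as a Series."""
    r, g, b = means
    sr, sg, sb = sds
    return pd.Series(
        {
            "cell_id": cell_id, "islet_id": islet, "stage_dpf": 3.5,
            "r_mean": float(r), "g_mean": float(g), "b_mean": float(b),
            "r_sd": float(sr), "g_sd": float(sg), "b_sd": float(sb),
            "n_pixels": int(n_pixels),
            "x": xyz[0], "y": xyz[1], "z": xyz[2],
        }
    )


def make_cells(rows):
    return pd.DataFrame([make_cell(*r) if not isinstance(r, pd.Series) else r
                         for r in rows]).reset_index(drop=True)


@pytest.fixture
def small_islet():
    """A small simulated islet with measurements and truth."""
    return q.simulate_islet(
        q.GrowthConfig(n_founders=25, quiescent_fraction=0.5, division_rate=0.6),
        q.RecombinationConfig(p_recomb=0.35),
        q.NoiseConfig(),
        seed=11,
    )


@pytest.fixture
def truth_factory():
    """Build a hand-specified SyntheticIsletTruth from (position, volume, levels)."""

    def _make(cells_spec, noise=None):
        noise = noise or q.NoiseConfig(
            pixel_sd_per_channel=(0.0, 0.0, 0.0),
            background_mean_per_channel=(10.0, 10.0, 10.0),
        )
        rows = []
        for i, (pos, volume, levels) in enumerate(cells_spec):
            rows.append(
                {
                    "cell_id": f"c{i}", "clone_id": i, "lineage": "embryonic",
                    "birth_stage_dpf": 3.5, "n_divisions": 0,
                    "h2b_retained": True, "responder": False,
                    "region": "posterior",
                    "x": pos[0], "y": pos[1], "z": pos[2],
                    "volume_um3": float(volume),
                    "cassette_states": "0,0,0", "color_class": "red_only",
                    "r_level": levels[0], "g_level": levels[1],
                    "b_level": levels[2],
                }
            )
        cells = pd.DataFrame(
            rows,
            columns=["cell_id", "clone_id", "lineage", "birth_stage_dpf",
                     "n_divisions", "h2b_retained", "responder", "region",
                     "x", "y", "z", "volume_um3", "cassette_states",
                     "color_class", "r_level", "g_level", "b_level"],
        )
        return q.SyntheticIsletTruth(
            cells=cells, recomb=q.RecombinationConfig(),
            growth=q.GrowthConfig(), noise=noise, seed=0,
        )

    return _make
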