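"""Synthetic islet generator with full ground truth.

Emulates the data-generating process the downstream analyses assume:

* a multicassette Cre-lox color transgene — each cassette independently keeps
  its default red state or recombines to green or blue, so a trichromatic
  cell needs at least two independent recombination events;
* clonal proliferation of founders as a discrete-generation branching
  process, with a quiescent fraction that never divides and daughters
  inheriting the mother's cassette states exactly;
* per-founder cassette expression levels (lognormal variegation) inherited
  by the clone, giving each clone a continuous, heritable RGB barcode;
* post-embryonic neogenesis adding unlabeled cells at the anterior tip of a
  prolate-ellipsoid islet whose long axis is the A/P axis;
* voxelized cell bodies rendered into per-channel 3D stacks with Gaussian
  intensity noise;
* phenomenological GCaMP traces with basal / glucose / KCl phases, known
  responder status, and a quality-control-failure fraction.

Every stochastic step flows through one ``numpy.random.Generator`` seeded by
the caller, so identical configs + seed reproduce outputs exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calcium import CalciumTrace, StimulusProtocol
from .errors import InvalidConfigError

# Cassette states
RED, GREEN, BLUE = 0, 1, 2
_STATE_CHANNEL = {RED: "r", GREEN: "g", BLUE: "b"}

#: Base fluorescence contributed by one expressed cassette (a.u.).
BASE_CASSETTE_INTENSITY = 120.0
#: Lognormal sigma of per-founder cassette expression variegation.
EXPRESSION_SIGMA = 0.35


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise InvalidConfigError(f"{name} must be in [0, 1], got {p}")


@dataclass(frozen=True)
class RecombinationConfig:
    """Cassette-level recombination probabilities.

    n_cassettes
        Independent lox cassettes per cell (default 3).
    p_recomb
        Per-cassette recombination probability during tamoxifen induction.
    p_green_given_recomb
        Probability a recombined cassette switches to green (else blue).
    p_leaky
        Per-cassette spontaneous recombination probability without induction.
    """

    n_cassettes: int = 3
    p_recomb: float = 0.25
    p_green_given_recomb: float = 0.5
    p_leaky: float = 0.0005

    def __post_init__(self):
        if self.n_cassettes < 1:
            raise InvalidConfigError("n_cassettes must be >= 1")
        _check_prob("p_recomb", self.p_recomb)
        _check_prob("p_green_given_recomb", self.p_green_given_recomb)
        _check_prob("p_leaky", self.p_leaky)


@dataclass(frozen=True)
class GrowthConfig:
    """Clonal growth and islet geometry settings.

    division_rate is the probability a proliferative cell divides in one
    inter-stage interval (discrete-generation branching); neogenesis_rate is
    the expected number of new unlabeled anterior cells per interval.
    """

    n_founders: int = 60
    quiescent_fraction: float = 0.5
    division_rate: float = 0.5
    stages: Sequence[float] = (3.5, 15.0, 30.0)
    neogenesis_rate: float = 8.0
    mean_cell_volume: float = 185.0
    sd_cell_volume: float = 28.0

    def __post_init__(self):
        if self.n_founders < 0:
            raise InvalidConfigError("n_founders must be >= 0")
        _check_prob("quiescent_fraction", self.quiescent_fraction)
        if self.division_rate < 0 or self.neogenesis_rate < 0:
            raise InvalidConfigError("rates must be >= 0")
        if self.mean_cell_volume <= 0 or self.sd_cell_volume < 0:
            raise InvalidConfigError("volumes must be positive")
        if len(self.stages) < 1 or list(self.stages) != sorted(self.stages):
            raise InvalidConfigError("stages must be a nonempty increasing sequence")


@dataclass(frozen=True)
class NoiseConfig:
    """Measurement-noise model for per-cell ROI statistics."""

    pixel_sd_per_channel: tuple[float, float, float] = (6.0, 6.0, 6.0)
    background_mean_per_channel: tuple[float, float, float] = (12.0, 10.0, 10.0)
    pixels_per_cell_range: tuple[int, int] = (30, 80)

    def __post_init__(self):
        if any(s < 0 for s in self.pixel_sd_per_channel):
            raise InvalidConfigError("pixel sds must be >= 0")
        if any(b < 0 for b in self.background_mean_per_channel):
            raise InvalidConfigError("background means must be >= 0")
        lo, hi = self.pixels_per_cell_range
        if lo < 3 or hi < lo:
            raise InvalidConfigError("pixel range must be nonempty with min >= 3")


@dataclass
class SyntheticIsletTruth:
    """Ground truth for one simulated islet.

    ``cells`` has one row per cell: cell_id, clone_id, lineage
    (embryonic|post_embryonic), birth_stage_dpf, n_divisions, h2b_retained,
    responder, region, x/y/z (µm), volume_um3, cassette_states, and the true
    per-channel signal levels r/g/b_level (a.u. above background).
    """

    cells: pd.DataFrame
    recomb: RecombinationConfig
    growth: GrowthConfig
    noise: NoiseConfig
    seed: int
    semi_axes: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def clone_labels(self) -> pd.Series:
        return self.cells.set_index("cell_id")["clone_id"]

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def color_class_from_states(states: np.ndarray) -> np.ndarray:
    """Classify cells by the set of colors their cassettes express.

    trichromatic iff the expressed set is exactly {red, green, blue};
    red_only iff it is {red}; anything else (including the rare fully
    switched single-color cell) is reported dichromatic.
    """
    states = np.asarray(states)
    has = [np.any(states == s, axis=1) for s in (RED, GREEN, BLUE)]
    tri = has[0] & has[1] & has[2]
    red_only = has[0] & ~has[1] & ~has[2]
    out = np.full(states.shape[0], "dichromatic", dtype=object)
    out[tri] = "trichromatic"
    out[red_only] = "red_only"
    return out


def simulate_recombination(
    cfg: RecombinationConfig, n_cells: int, seed: int, induced: bool = True
) -> pd.DataFrame:
    """Draw cassette states for ``n_cells`` independent cells.

    Each cassette recombines with probability p_recomb (induction) or
    p_leaky (no induction); recombined cassettes switch to green with
    p_green_given_recomb, else blue.  Returns a frame with cell_id, one
    column per cassette, and the derived color class.
    """
    if n_cells < 0:
        raise InvalidConfigError("n_cells must be >= 0")
    rng = np.random.default_rng(seed)
    states = _draw_states(cfg, n_cells, rng, induced)
    df = pd.DataFrame(
        states, columns=[f"cassette_{i}" for i in range(cfg.n_cassettes)]
    )
    df.insert(0, "cell_id", [f"cell_{i}" for i in range(n_cells)])
    df["color_class"] = color_class_from_states(states) if n_cells else []
    return df


def _draw_states(
    cfg: RecombinationConfig, n: int, rng: np.random.Generator, induced: bool
) -> np.ndarray:
    p = cfg.p_recomb if induced else 0.0
    p_switch = 1.0 - (1.0 - p) * (1.0 - cfg.p_leaky)
    recombined = rng.random((n, cfg.n_cassettes)) < p_switch
    to_green = rng.random((n, cfg.n_cassettes)) < cfg.p_green_given_recomb
    states = np.full((n, cfg.n_cassettes), RED, dtype=np.int8)
    states[recombined & to_green] = GREEN
    states[recombined & ~to_green] = BLUE
    return states


def _founder_levels(
    states: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Per-founder true (r, g, b) signal levels from cassette states.

    Each cassette contributes a lognormally variegated copy of the base
    intensity to the channel of its state; the draw is per founder and is
    inherited unchanged by every descendant.
    """
    n, k = states.shape
    levels = np.zeros((n, 3))
    cassette_intensity = BASE_CASSETTE_INTENSITY * rng.lognormal(
        mean=0.0, sigma=EXPRESSION_SIGMA, size=(n, k)
    )
    for ch in (RED, GREEN, BLUE):
        levels[:, ch] = np.where(states == ch, cassette_intensity, 0.0).sum(axis=1)
    return levels


def _signature(levels: np.ndarray) -> np.ndarray:
    return levels / levels.sum() * 100.0


def _sample_positions(
    n: int,
    semi_axes: np.ndarray,
    sides: np.ndarray,
    min_sep: float,
    ap_bias: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Dart-throw points in a prolate ellipsoid with a minimum separation.

    ``sides`` gives each cell's preferred A/P half (+1 anterior x > 0,
    -1 posterior, 0 no preference); the preference is honored with
    probability ``ap_bias``.  If packing fails the separation relaxes
    geometrically, so the sampler always terminates.
    """
    pts = np.empty((n, 3))
    placed = 0
    sep = min_sep
    attempts = 0
    while placed < n:
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        r = rng.random() ** (1.0 / 3.0)
        cand = u * r * semi_axes
        want = sides[placed]
        if want != 0 and rng.random() < ap_bias and np.sign(cand[0]) != want:
            cand[0] = -cand[0]
        if placed and np.min(np.linalg.norm(pts[:placed] - cand, axis=1)) < sep:
            attempts += 1
            if attempts > 200:
                sep *= 0.8
                attempts = 0
            continue
        pts[placed] = cand
        placed += 1
        attempts = 0
    return pts


def simulate_islet(
    growth: GrowthConfig,
    recomb: RecombinationConfig,
    noise: NoiseConfig,
    seed: int,
    *,
    islet_id: str = "islet_0",
    induced: bool = True,
    responder_p: tuple[float, float] = (0.34, 0.67),
    ap_bias: float = 0.9,
    min_signature_separation_pct: Optional[float] = None,
    packing_fraction: float = 0.08,
) -> tuple[pd.DataFrame, SyntheticIsletTruth]:
    """Simulate one islet end to end: lineage, geometry, and measurements.

    Returns the per-cell color-measurement table (the CSV schema consumed by
    the clonal analysis) and the ground truth.  ``responder_p`` gives the
    (anterior, posterior) glucose-responder probabilities; ``ap_bias`` the
    strength of the age polarity (1.0 = embryonic cells strictly posterior,
    post-embryonic strictly anterior).  ``min_signature_separation_pct``
    optionally enforces a minimum pairwise L∞ distance (percentage points)
    between the normalized barcodes of trichromatic founders — the
    well-separated regime used for clone-recovery benchmarks.
    """
    _check_prob("ap_bias", ap_bias)
    for p in responder_p:
        _check_prob("responder_p", p)
    rng = np.random.default_rng(seed)

    # --- founders: cassette states + clone-heritable expression levels
    founder_states = _draw_states(recomb, growth.n_founders, rng, induced)
    founder_levels = _founder_levels(founder_states, rng)
    if min_signature_separation_pct is not None:
        founder_levels = _separate_barcodes(
            founder_states, founder_levels, min_signature_separation_pct, rng
        )
    quiescent = rng.random(growth.n_founders) < growth.quiescent_fraction

    # --- growth: discrete-generation branching across stage intervals
    # cells: (clone_id, lineage, birth_stage, n_divisions, quiescent)
    cells: list[list] = [
        [f, "embryonic", growth.stages[0], 0, bool(quiescent[f])]
        for f in range(growth.n_founders)
    ]
    states_by_clone: dict[int, np.ndarray] = {
        f: founder_states[f] for f in range(growth.n_founders)
    }
    levels_by_clone: dict[int, np.ndarray] = {
        f: founder_levels[f] for f in range(growth.n_founders)
    }
    next_clone = growth.n_founders
    p_div = min(1.0, growth.division_rate)
    for stage_end in growth.stages[1:]:
        newborn: list[list] = []
        for cell in cells:
            if not cell[4] and rng.random() < p_div:
                cell[3] += 1
                sister = [cell[0], cell[1], stage_end, cell[3], cell[4]]
                newborn.append(sister)
        cells.extend(newborn)
        n_new = rng.poisson(growth.neogenesis_rate)
        if n_new:
            new_states = _draw_states(recomb, n_new, rng, induced=False)
            new_levels = _founder_levels(new_states, rng)
            for j in range(n_new):
                states_by_clone[next_clone] = new_states[j]
                levels_by_clone[next_clone] = new_levels[j]
                q = rng.random() < growth.quiescent_fraction
                cells.append([next_clone, "post_embryonic", stage_end, 0, q])
                next_clone += 1

    n_cells = len(cells)
    clone_ids = np.array([c[0] for c in cells])
    lineages = np.array([c[1] for c in cells], dtype=object)
    birth_stage = np.array([c[2] for c in cells])
    n_div = np.array([c[3] for c in cells])

    # --- geometry: prolate ellipsoid scaled to hold the cells without overlap
    volumes = np.clip(
        rng.normal(growth.mean_cell_volume, growth.sd_cell_volume, n_cells),
        0.25 * growth.mean_cell_volume,
        None,
    )
    r_cell = (3.0 * growth.mean_cell_volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    ell_volume = max(volumes.sum(), growth.mean_cell_volume) / packing_fraction
    b_ax = (ell_volume * 3.0 / (4.0 * np.pi * 2.5)) ** (1.0 / 3.0)
    semi_axes = np.array([2.5 * b_ax, b_ax, b_ax])
    sides = np.where(lineages == "post_embryonic", 1, -1)
    pts = _sample_positions(n_cells, semi_axes, sides, 1.9 * r_cell, ap_bias, rng)
    region = np.where(pts[:, 0] >= 0, "anterior", "posterior")

    # --- functional truth
    p_ant, p_post = responder_p
    p_resp = np.where(region == "anterior", p_ant, p_post)
    responder = rng.random(n_cells) < p_resp
    h2b_retained = n_div == 0

    levels = np.array([levels_by_clone[c] for c in clone_ids]) if n_cells else np.zeros((0, 3))
    truth_cells = pd.DataFrame(
        {
            "cell_id": [f"{islet_id}_c{i}" for i in range(n_cells)],
            "clone_id": clone_ids,
            "lineage": lineages,
            "birth_stage_dpf": birth_stage,
            "n_divisions": n_div,
            "h2b_retained": h2b_retained,
            "responder": responder,
            "region": region,
            "x": pts[:, 0],
            "y": pts[:, 1],
            "z": pts[:, 2],
            "volume_um3": volumes,
            "cassette_states": [
                ",".join(map(str, states_by_clone[c])) for c in clone_ids
            ],
            "color_class": color_class_from_states(
                np.array([states_by_clone[c] for c in clone_ids])
            ) if n_cells else [],
            "r_level": levels[:, 0],
            "g_level": levels[:, 1],
            "b_level": levels[:, 2],
        }
    )

    # --- noisy ROI measurements
    lo, hi = noise.pixels_per_cell_range
    n_pix = rng.integers(lo, hi + 1, size=n_cells)
    meas = {c: np.empty(n_cells) for c in ("r_mean", "g_mean", "b_mean",
                                           "r_sd", "g_sd", "b_sd")}
    for i in range(n_cells):
        for ch, name in enumerate("rgb"):
            true = levels[i, ch] + noise.background_mean_per_channel[ch]
            sd = noise.pixel_sd_per_channel[ch]
            if sd == 0.0:  # exact degenerate ROI: no float drift across n
                meas[f"{name}_mean"][i] = true
                meas[f"{name}_sd"][i] = 0.0
                continue
            px = rng.normal(true, sd, size=n_pix[i])
            meas[f"{name}_mean"][i] = max(0.0, px.mean())
            meas[f"{name}_sd"][i] = px.std(ddof=1)
    measurements = pd.DataFrame(
        {
            "cell_id": truth_cells["cell_id"],
            "islet_id": islet_id,
            "stage_dpf": growth.stages[-1],
            **meas,
            "n_pixels": n_pix,
            "x": pts[:, 0],
            "y": pts[:, 1],
            "z": pts[:, 2],
        }
    )
    truth = SyntheticIsletTruth(
        cells=truth_cells, recomb=recomb, growth=growth, noise=noise,
        seed=seed, semi_axes=tuple(semi_axes),
    )
    return measurements, truth


def _separate_barcodes(
    states: np.ndarray,
    levels: np.ndarray,
    min_sep_pct: float,
    rng: np.random.Generator,
    max_tries: int = 500,
) -> np.ndarray:
    """Redraw trichromatic founders' expression until barcodes are separated."""
    levels = levels.copy()
    tri = np.flatnonzero(color_class_from_states(states) == "trichromatic")
    accepted: list[np.ndarray] = []
    for idx in tri:
        k = states.shape[1]
        for _ in range(max_tries):
            sig = _signature(levels[idx])
            if all(np.max(np.abs(sig - a)) >= min_sep_pct for a in accepted):
                break
            cassette_intensity = BASE_CASSETTE_INTENSITY * rng.lognormal(
                0.0, EXPRESSION_SIGMA, size=k
            )
            lv = np.zeros(3)
            for ch in (RED, GREEN, BLUE):
                lv[ch] = cassette_intensity[states[idx] == ch].sum()
            levels[idx] = lv
        else:
            warnings.warn("could not separate all trichromatic barcodes")
        accepted.append(_signature(levels[idx]))
    return levels


def render_stack(
    truth: SyntheticIsletTruth,
    voxel_size: float = 1.0,
    seed: int = 0,
    overlap_tolerance: float = 0.05,
) -> dict[str, np.ndarray]:
    """Voxelize the islet into per-channel 16-bit 3D stacks.

    Each cell becomes a compact blob of ``round(volume / voxel_volume)``
    voxels (nearest voxels to its centroid), so the rendered volume matches
    truth to within one voxel.  Channel intensity inside a blob is the cell's
    true level; background voxels sit at the configured background mean, and
    Gaussian pixel noise is added everywhere.  Overlapping blobs beyond
    ``overlap_tolerance`` (fraction of foreground voxels) trigger a warning.
    """
    if voxel_size <= 0:
        raise InvalidConfigError("voxel size must be positive")
    rng = np.random.default_rng(seed)
    vv = voxel_size**3
    cells = truth.cells
    noise = truth.noise
    if len(cells) == 0:
        shape = (8, 8, 8)
        return {
            name: _finalize_channel(np.zeros(shape), noise, ch, rng)
            for ch, name in enumerate("rgb")
        }

    pos = cells[["z", "y", "x"]].to_numpy(float) / voxel_size
    r_vox = ((3.0 * cells["volume_um3"].to_numpy(float) / (4 * np.pi)) ** (1 / 3)
             / voxel_size)
    margin = int(np.ceil(r_vox.max())) + 3
    origin = np.floor(pos.min(axis=0)).astype(int) - margin
    top = np.ceil(pos.max(axis=0)).astype(int) + margin + 1
    shape = tuple((top - origin).astype(int))
    signal = {ch: np.zeros(shape) for ch in range(3)}
    occupied = np.zeros(shape, dtype=bool)
    overlap_voxels = 0
    total_voxels = 0

    levels = cells[["r_level", "g_level", "b_level"]].to_numpy(float)
    for i in range(len(cells)):
        k = max(1, int(round(cells["volume_um3"].iat[i] / vv)))
        center = pos[i] - origin
        rad = int(np.ceil((3.0 * k / (4 * np.pi)) ** (1 / 3))) + 2
        base = np.floor(center).astype(int)
        lo = np.maximum(base - rad, 0)
        hi = np.minimum(base + rad + 1, shape)
        zz, yy, xx = np.meshgrid(
            *(np.arange(lo[d], hi[d]) for d in range(3)), indexing="ij"
        )
        coords = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
        d2 = ((coords + 0.5 - center) ** 2).sum(axis=1)
        order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0], d2))
        chosen = coords[order[: min(k, len(order))]]
        idx = tuple(chosen.T)
        overlap_voxels += int(occupied[idx].sum())
        occupied[idx] = True
        total_voxels += len(chosen)
        for ch in range(3):
            if levels[i, ch] > 0:
                signal[ch][idx] = np.maximum(signal[ch][idx], levels[i, ch])
    if total_voxels and overlap_voxels / total_voxels > overlap_tolerance:
        warnings.warn(
            f"{overlap_voxels}/{total_voxels} foreground voxels overlap "
            f"(> {overlap_tolerance:.0%} tolerance)"
        )
    return {
        name: _finalize_channel(signal[ch], noise, ch, rng)
        for ch, name in enumerate("rgb")
    }


def _finalize_channel(
    signal: np.ndarray, noise: NoiseConfig, ch: int, rng: np.random.Generator
) -> np.ndarray:
    img = signal + noise.background_mean_per_channel[ch]
    if noise.pixel_sd_per_channel[ch] > 0:
        img = img + rng.normal(0.0, noise.pixel_sd_per_channel[ch], signal.shape)
    return np.clip(np.rint(img), 0, 65535).astype(np.uint16)


@dataclass
class CalciumSimResult:
    traces: list[CalciumTrace]
    qc_fail_ids: frozenset = field(default_factory=frozenset)


def simulate_calcium_traces(
    truth: SyntheticIsletTruth,
    protocol: StimulusProtocol,
    noise_sd: float = 3.0,
    seed: int = 0,
    qc_fail_fraction: float = 0.05,
    dt: float = 2.0,
) -> CalciumSimResult:
    """Phenomenological GCaMP traces for every cell in the truth table.

    Non-responders stay at baseline through the glucose phases; true
    responders step up during every glucose phase; all cells except a
    ``qc_fail_fraction`` (flat, excluded by KCl quality control) peak during
    the KCl phase.  Baseline, glucose and KCl amplitudes scale with a
    per-cell baseline drawn around 100 a.u.
    """
    if noise_sd < 0:
        raise InvalidConfigError("noise_sd must be >= 0")
    _check_prob("qc_fail_fraction", qc_fail_fraction)
    rng = np.random.default_rng(seed)
    t = np.arange(protocol.phases[0].t_start, protocol.kcl.t_end, dt)
    traces = []
    qc_fail = []
    cells = truth.cells
    for _, row in cells.iterrows():
        base = rng.normal(100.0, 8.0)
        f = np.full_like(t, base, dtype=float)
        fail = rng.random() < qc_fail_fraction
        if fail:
            qc_fail.append(row["cell_id"])
        else:
            if row["responder"]:
                for ph in protocol.glucose_phases:
                    f[ph.contains(t)] = base * (1.0 + 0.02 * ph.concentration_mm)
            f[protocol.kcl.contains(t)] = base * 2.5
        if noise_sd > 0:
            f = f + rng.normal(0.0, noise_sd, size=t.shape)
        traces.append(
            CalciumTrace(
                cell_id=row["cell_id"],
                t=t.copy(),
                f=f,
                region=row["region"],
                label_status=(
                    "h2b_positive" if row["h2b_retained"] else "h2b_negative"
                ),
            )
        )
    return CalciumSimResult(traces=traces, qc_fail_ids=frozenset(qc_fail))
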