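"""File I/O: CSV table schemas, TIFF stacks, configs and run manifests.

All tables are UTF-8 CSV with a header row; image stacks are multi-page
16-bit grayscale TIFF, one file per channel; stimulus protocols and run
manifests are JSON; run configuration is YAML (JSON accepted).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .calcium import CalciumTrace
from .errors import ParseError, SchemaError

#: Per-cell color-measurement schema shared by the simulator and the clonal
#: analysis.
CELL_COLUMNS = [
    "cell_id", "islet_id", "stage_dpf",
    "r_mean", "g_mean", "b_mean", "r_sd", "g_sd", "b_sd",
    "n_pixels", "x", "y", "z",
]

TRACE_COLUMNS = ["cell_id", "t_seconds", "fluorescence"]


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises many flavors; name the file
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(path, missing)
    return df


def read_cells(path) -> pd.DataFrame:
    """Read a per-cell color-measurement table, validating the schema."""
    return _read_csv(path, CELL_COLUMNS)


def write_cells(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, index=False)


def read_traces(path, meta: pd.DataFrame | None = None) -> list[CalciumTrace]:
    """Read long-format traces; optional meta maps cell_id to region/label."""
    df = _read_csv(path, TRACE_COLUMNS)
    lookup = {}
    if meta is not None:
        lookup = meta.set_index("cell_id").to_dict("index")
    traces = []
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("t_seconds")
        info = lookup.get(cid, {})
        traces.append(
            CalciumTrace(
                cell_id=cid,
                t=grp["t_seconds"].to_numpy(float),
                f=grp["fluorescence"].to_numpy(float),
                region=info.get("region", "unassigned"),
                label_status=info.get("label_status", "none"),
            )
        )
    return traces


def write_traces(traces, path) -> None:
    frames = [
        pd.DataFrame(
            {"cell_id": tr.cell_id, "t_seconds": tr.t, "fluorescence": tr.f}
        )
        for tr in traces
    ]
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=TRACE_COLUMNS)
    )
    out.to_csv(path, index=False)


def read_stack(path) -> np.ndarray:
    path = Path(path)
    try:
        return tifffile.imread(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_stack(stack: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.uint16))


def load_config(path) -> dict:
    """Load a YAML (or JSON — valid YAML) run configuration."""
    path = Path(path)
    try:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return cfg


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, *, config: dict, seed, inputs=(), outputs=()) -> dict:
    """Record the full provenance of one run: config, seed, file checksums."""
    from . import __version__

    manifest = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "inputs": {str(p): sha256_file(p) for p in inputs},
        "outputs": {str(p): sha256_file(p) for p in outputs},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
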