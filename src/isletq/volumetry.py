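"""Threshold-and-label 3D volumetry and cell-number estimation.

An islet's beta-cell number is estimated without segmenting individual nuclei:
threshold the composite stack, sum the volume of every labeled region (total
beta-cell volume), divide by the mean volume of isolated single cells taken
from the green+blue composite (where sparse recombined cells sit apart from
their neighbors).  The same machinery supports the arithmetic for the leaky
(background) recombination probability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure
from skimage.filters import threshold_otsu

from .errors import InsufficientDataError, InvalidConfigError


def _voxel_volume(voxel_size) -> float:
    vs = np.atleast_1d(np.asarray(voxel_size, dtype=float))
    if (vs <= 0).any():
        raise InvalidConfigError("voxel size must be positive")
    if vs.size == 1:
        return float(vs[0] ** 3)
    if vs.size == 3:
        return float(np.prod(vs))
    raise InvalidConfigError("voxel_size must be a scalar or (z, y, x) triple")


def to_8bit(stack: np.ndarray) -> np.ndarray:
    """Min–max rescale a grayscale stack to uint8, as done before counting."""
    stack = np.asarray(stack, dtype=float)
    lo, hi = stack.min(), stack.max()
    if hi == lo:
        return np.zeros(stack.shape, dtype=np.uint8)
    return ((stack - lo) / (hi - lo) * 255).astype(np.uint8)


def label_objects_3d(
    stack: np.ndarray,
    threshold="otsu",
    voxel_size=1.0,
    connectivity: int = 26,
) -> pd.DataFrame:
    """Threshold a 3D stack and label connected foreground regions.

    Parameters
    ----------
    stack : (z, y, x) grayscale array
    threshold : "otsu" or a numeric cutoff applied to the 8-bit-converted
        stack; voxels strictly above the cutoff are foreground.
    voxel_size : scalar edge length in µm, or (z, y, x) triple.
    connectivity : 26 (voxels touching at faces, edges or corners are
        neighbors; the default of the classic 3D object counter) or 6.

    Returns
    -------
    DataFrame with one row per object: object_id, voxel_count, volume_um3,
    half-open 0-based bounding box (z0,y0,x0,z1,y1,x1) and centroid
    (cz, cy, cx) in voxel units.  An all-background stack yields an empty
    table, not an error.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.size == 0:
        raise InvalidConfigError("expected a nonempty 3D stack")
    if connectivity not in (6, 26):
        raise InvalidConfigError("connectivity must be 6 or 26")
    vv = _voxel_volume(voxel_size)

    img8 = to_8bit(stack)
    if threshold == "otsu":
        if img8.min() == img8.max():
            return _empty_object_table()
        cut = threshold_otsu(img8)
    else:
        cut = float(threshold)
    mask = img8 > cut
    if not mask.any():
        return _empty_object_table()

    conn = 3 if connectivity == 26 else 1
    labels = measure.label(mask, connectivity=conn)
    rows = []
    for rp in measure.regionprops(labels):
        z0, y0, x0, z1, y1, x1 = rp.bbox
        rows.append(
            {
                "object_id": int(rp.label),
                "voxel_count": int(rp.area),
                "volume_um3": float(rp.area) * vv,
                "z0": z0, "y0": y0, "x0": x0, "z1": z1, "y1": y1, "x1": x1,
                "cz": rp.centroid[0], "cy": rp.centroid[1], "cx": rp.centroid[2],
            }
        )
    return pd.DataFrame(rows).sort_values("object_id", ignore_index=True)


def _empty_object_table() -> pd.DataFrame:
    cols = ["object_id", "voxel_count", "volume_um3",
            "z0", "y0", "x0", "z1", "y1", "x1", "cz", "cy", "cx"]
    return pd.DataFrame(columns=cols)


def total_beta_volume(objects: pd.DataFrame) -> float:
    """Sum of all object volumes: the whole beta-cell mass (µm³)."""
    if len(objects) == 0:
        return 0.0
    return float(objects["volume_um3"].sum())


def single_cell_volumes(
    objects: pd.DataFrame, window: tuple[float, float] = (50.0, 500.0)
) -> pd.Series:
    """Volumes of objects plausibly representing one isolated cell.

    Objects from the green+blue composite whose volume falls inside the
    window are retained; fused neighbors (too big) and debris (too small) are
    excluded, mirroring the exclusion of adjacent cells with similar color
    profiles that cannot be separated.  Returns an empty Series with a
    warning if nothing passes.
    """
    lo, hi = window
    if not 0 < lo < hi:
        raise InvalidConfigError("window must satisfy 0 < lo < hi")
    if len(objects) == 0:
        kept = objects
    else:
        kept = objects[(objects["volume_um3"] >= lo) & (objects["volume_um3"] <= hi)]
    if len(kept) == 0:
        warnings.warn("no objects passed the single-cell isolation window")
        return pd.Series([], dtype=float, name="volume_um3")
    return kept["volume_um3"].reset_index(drop=True)


@dataclass(frozen=True)
class CellCountEstimate:
    """Cell number as total volume over mean single-cell volume."""

    raw: float

    @property
    def rounded(self) -> int:
        return int(round(self.raw))

    @property
    def to_nearest_ten(self) -> int:
        return int(round(self.raw, -1))


def estimate_cell_number(
    total_volume: float, mean_single_cell_volume: float
) -> CellCountEstimate:
    """Estimate beta-cell number by the volume ratio.

    E.g. a 151337.80 µm³ islet with 184.70 µm³ mean single-cell volume gives
    819.4 cells, quoted as ≈ 820.
    """
    if mean_single_cell_volume <= 0:
        raise InvalidConfigError("mean single-cell volume must be > 0")
    if total_volume < 0:
        raise InvalidConfigError("total volume must be >= 0")
    return CellCountEstimate(raw=total_volume / mean_single_cell_volume)


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median: smallest value whose cumulative weight reaches half."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0 or weights.sum() <= 0:
        raise InsufficientDataError("weighted median of an empty sample")
    order = np.argsort(values)
    cum = np.cumsum(weights[order])
    return float(values[order][np.searchsorted(cum, 0.5 * cum[-1])])


def cell_count_from_stacks(
    stacks: dict,
    voxel_size=1.0,
    threshold="otsu",
    window="auto",
    connectivity: int = 26,
) -> tuple[CellCountEstimate, dict]:
    """Estimate beta-cell number from per-channel stacks, end to end.

    The total beta-cell volume comes from the all-channel composite
    (pixelwise maximum of r, g, b); the mean single-cell volume from
    isolated objects of the green+blue composite.  ``window="auto"``
    derives the isolation window from the G+B objects themselves as
    [0.5, 1.5] x their volume-weighted median volume: when isolated single
    cells dominate the labeled mass that median is a single-cell volume,
    fused pairs (about twice the single volume) fall outside, and noise
    speckles — often numerous but holding negligible total volume — cannot
    drag it down, all regardless of absolute scale.  Pass an explicit
    (lo, hi) to override.  Returns the estimate and a details dict
    (total volume, per-object single-cell volumes).
    """
    r, g, b = (np.asarray(stacks[c], dtype=float) for c in "rgb")
    composite_all = np.maximum(np.maximum(r, g), b)
    composite_gb = np.maximum(g, b)
    objs_all = label_objects_3d(composite_all, threshold=threshold,
                                voxel_size=voxel_size, connectivity=connectivity)
    objs_gb = label_objects_3d(composite_gb, threshold=threshold,
                               voxel_size=voxel_size, connectivity=connectivity)
    total = total_beta_volume(objs_all)
    if window == "auto":
        if len(objs_gb) == 0:
            raise InsufficientDataError("no objects in the green+blue composite")
        med = weighted_median(objs_gb["volume_um3"].to_numpy(),
                              objs_gb["volume_um3"].to_numpy())
        window = (0.5 * med, 1.5 * med)
    singles = single_cell_volumes(objs_gb, window=window)
    if len(singles) == 0:
        raise InsufficientDataError(
            "no isolated single cells in the green+blue composite"
        )
    est = estimate_cell_number(total, float(singles.mean()))
    return est, {
        "total_volume_um3": total,
        "single_cell_volumes": singles,
        "n_objects_all": len(objs_all),
        "n_objects_gb": len(objs_gb),
    }


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


@dataclass(frozen=True)
class RecombinationStats:
    """Leaky-recombination probabilities from untreated-sample counts.

    p_single is the per-cell chance of one spontaneous recombination event;
    a trichromatic cell needs two independent events, so its probability is
    the square.  By reporting convention p_single is first rounded to
    ``sig_figs`` significant figures and then squared; the unrounded product
    is kept alongside.
    """

    n_leaky_events: int
    n_cells_per_islet: int
    n_islets: int
    p_single_raw: float
    p_single: float
    p_trichromatic: float
    p_trichromatic_raw: float


def background_recombination(
    n_events: int, n_cells_per_islet: int, n_islets: int, sig_figs: int = 1
) -> RecombinationStats:
    """Estimate spontaneous recombination probabilities from event counts.

    With 4 leaky events over 10 islets of ~820 cells each:
    p_single = 4/8200 ≈ 0.0005 and p_trichromatic = 0.0005² = 2.5e-7.
    """
    if n_events < 0:
        raise InvalidConfigError("event count must be >= 0")
    if n_cells_per_islet < 1 or n_islets < 1:
        raise InvalidConfigError("need >= 1 cell per islet and >= 1 islet")
    p_raw = n_events / (n_cells_per_islet * n_islets)
    p_rounded = round_sig(p_raw, sig_figs)
    return RecombinationStats(
        n_leaky_events=n_events,
        n_cells_per_islet=n_cells_per_islet,
        n_islets=n_islets,
        p_single_raw=p_raw,
        p_single=p_rounded,
        p_trichromatic=p_rounded**2,
        p_trichromatic_raw=p_raw**2,
    )
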