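"""Anterior/posterior half-splitting and regional islet statistics.

The primary islet is elongated; its age and function are polarized along the
anterior–posterior (A/P) axis.  Comparisons split the islet into two halves:
the A/P segment joins the anterior and posterior tips on the (x, y)
maximum-intensity projection, and the divider is the perpendicular through
the segment midpoint.  A cell is anterior iff the signed projection of its
centroid onto the tip axis falls on the anterior side of the midpoint; cells
exactly on the divider count as anterior (fixed tie-break).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull, QhullError

from .errors import InsufficientDataError, InvalidConfigError


@dataclass
class ApPartition:
    anterior_tip: np.ndarray
    posterior_tip: np.ndarray
    midpoint: np.ndarray
    assignment: pd.Series  # cell_id -> "anterior" | "posterior"
    signed_projection: pd.Series  # cell_id -> µm along the A/P axis from midpoint

    @property
    def n_anterior(self) -> int:
        return int((self.assignment == "anterior").sum())

    @property
    def n_posterior(self) -> int:
        return int((self.assignment == "posterior").sum())


def estimate_tips(cells: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Most distant pair of (x, y) centroids, via the projection convex hull.

    Returns the pair ordered so the first tip has the larger x (the
    simulator's anterior convention); when tips are supplied manually the
    caller controls orientation instead.
    """
    pts = cells[["x", "y"]].to_numpy(dtype=float)
    if len(pts) < 2:
        raise InsufficientDataError("need >= 2 cells to estimate tips")
    uniq = np.unique(pts, axis=0)
    if len(uniq) > 3:
        try:
            uniq = uniq[ConvexHull(uniq).vertices]
        except QhullError:
            pass  # degenerate (collinear) clouds: brute-force all points
    best, pair = -1.0, None
    for i in range(len(uniq)):
        d = np.linalg.norm(uniq[i + 1:] - uniq[i], axis=1)
        if len(d) and d.max() > best:
            best = float(d.max())
            pair = (uniq[i], uniq[i + 1 + int(d.argmax())])
    if best <= 0:
        raise InvalidConfigError("all cells coincide; tips undefined")
    a, b = pair
    return (a, b) if a[0] >= b[0] else (b, a)


def split_ap(
    cells: pd.DataFrame,
    anterior_tip=None,
    posterior_tip=None,
) -> ApPartition:
    """Assign every cell to the anterior or posterior half.

    Tips may be given as (x, y) pairs; if omitted, both are estimated as the
    two most distant cell centroids with the larger-x one taken as anterior.
    """
    if (anterior_tip is None) != (posterior_tip is None):
        raise InvalidConfigError("provide both tips or neither")
    if anterior_tip is None:
        anterior_tip, posterior_tip = estimate_tips(cells)
    a = np.asarray(anterior_tip, dtype=float)
    p = np.asarray(posterior_tip, dtype=float)
    if np.allclose(a, p):
        raise InvalidConfigError("anterior and posterior tips coincide")
    mid = (a + p) / 2.0
    axis = (a - p) / np.linalg.norm(a - p)
    pts = cells[["x", "y"]].to_numpy(dtype=float)
    s = (pts - mid) @ axis
    assign = np.where(s >= 0, "anterior", "posterior")
    idx = cells["cell_id"] if "cell_id" in cells else cells.index
    return ApPartition(
        anterior_tip=a,
        posterior_tip=p,
        midpoint=mid,
        assignment=pd.Series(assign, index=pd.Index(idx, name="cell_id")),
        signed_projection=pd.Series(s, index=pd.Index(idx, name="cell_id")),
    )


def labeling_ratio(partition: ApPartition, cells: pd.DataFrame) -> float:
    """Posterior/anterior ratio of summed green+blue label intensity.

    Intensity is aggregated per cell (mean × ROI pixel count when n_pixels is
    present, else the mean alone).  A label-free anterior half makes the
    ratio infinite; it is returned as ``inf`` for the caller to flag.
    """
    gb = cells["g_mean"].to_numpy(float) + cells["b_mean"].to_numpy(float)
    if "n_pixels" in cells:
        gb = gb * cells["n_pixels"].to_numpy(float)
    side = partition.assignment.to_numpy()
    post = float(gb[side == "posterior"].sum())
    ant = float(gb[side == "anterior"].sum())
    if ant == 0.0:
        return float("inf")
    return post / ant


def regional_counts(
    partition: ApPartition, cells: pd.DataFrame, predicate=None
) -> tuple[int, int]:
    """(n_anterior, n_posterior) cells satisfying a predicate.

    ``predicate`` is a boolean mask aligned with ``cells`` or a callable
    applied to the frame; None counts every cell.
    """
    if predicate is None:
        mask = np.ones(len(cells), dtype=bool)
    elif callable(predicate):
        mask = np.asarray(predicate(cells), dtype=bool)
    else:
        mask = np.asarray(predicate, dtype=bool)
    side = partition.assignment.to_numpy()
    return int((mask & (side == "anterior")).sum()), int((mask & (side == "posterior")).sum())


def paired_half_test(anterior_values, posterior_values) -> float:
    """Paired two-tailed t-test across islets for anterior-vs-posterior values."""
    a = np.asarray(anterior_values, dtype=float)
    b = np.asarray(posterior_values, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise InsufficientDataError("need paired 1D samples of length >= 2")
    return float(stats.ttest_rel(a, b).pvalue)
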