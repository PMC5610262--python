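"""Clonal analysis of multicolor (RGB) cell barcodes.

Beta-cells carrying a stochastically recombined multicassette transgene express
a heritable mix of red, green and blue fluorophores.  Cells of one clone share
the mix; clonal analysis therefore proceeds by

1. subtracting green/blue background measured on unlabeled cells,
2. normalizing each cell's (R, G, B) channel means to percentages summing to
   100 (the *color signature*),
3. keeping only *triple-positive* cells, i.e. cells whose mean is more than
   2.58 sd above zero in every channel (a two-sided 1% normal criterion),
4. declaring two cells equivalent when a per-channel TOST (two one-sided
   tests) confidently bounds the difference of their normalized signatures
   inside a pre-set margin, and
5. merging equivalent pairs transitively into clones.

Note the asymmetry in step 1: only the green and blue channels are
background-subtracted; the red channel is used as measured.  This mirrors the
original acquisition protocol, where background references were taken for the
two recombination-derived colors only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateSignalError, InsufficientDataError, InvalidConfigError

#: Two-sided standard-normal critical distance for p = 0.01; a channel mean
#: further than this many sds from zero is called confidently positive.
TRIPLE_POSITIVE_Z = 2.58

_CHANNELS = ("r", "g", "b")


@dataclass(frozen=True)
class BackgroundEstimate:
    """Mean green/blue intensity of unlabeled reference cells (a.u.)."""

    g_background: float
    b_background: float
    n_reference_cells: int = 3

    def __post_init__(self):
        if self.g_background < 0 or self.b_background < 0:
            raise InvalidConfigError("background intensities must be >= 0")
        if self.n_reference_cells < 3:
            raise InvalidConfigError(
                "background must be estimated from at least 3 unlabeled cells"
            )


@dataclass(frozen=True)
class TostParams:
    """Equivalence-test settings.

    margin_pct
        Equivalence half-width per channel, in percentage points of the
        normalized signature.  The original procedure does not state its
        margin, so it is a mandatory, reported parameter here.
    alpha
        Significance level of each one-sided test.
    """

    margin_pct: float = 10.0
    alpha: float = 0.05

    def __post_init__(self):
        if not self.margin_pct > 0:
            raise InvalidConfigError("margin_pct must be > 0")
        if not 0 < self.alpha < 1:
            raise InvalidConfigError("alpha must be in (0, 1)")


@dataclass
class CloneSet:
    """Partition of the triple-positive cells of one islet into clones."""

    islet_id: object
    clones: list[frozenset]
    excluded: frozenset = field(default_factory=frozenset)

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.clones]

    @property
    def n_single(self) -> int:
        return sum(1 for c in self.clones if len(c) == 1)

    @property
    def n_multi(self) -> int:
        return sum(1 for c in self.clones if len(c) >= 2)

    def size_histogram(self) -> dict[int, int]:
        hist: dict[int, int] = {}
        for s in self.sizes:
            hist[s] = hist.get(s, 0) + 1
        return dict(sorted(hist.items()))


def estimate_background(unlabeled: pd.DataFrame) -> BackgroundEstimate:
    """Average green/blue means over >= 3 unlabeled reference cells."""
    if len(unlabeled) < 3:
        raise InsufficientDataError(
            f"need >= 3 unlabeled cells for background, got {len(unlabeled)}"
        )
    return BackgroundEstimate(
        g_background=float(unlabeled["g_mean"].mean()),
        b_background=float(unlabeled["b_mean"].mean()),
        n_reference_cells=len(unlabeled),
    )


def subtract_background(cells: pd.DataFrame, bg: BackgroundEstimate) -> pd.DataFrame:
    """Subtract green/blue background from channel means, clamping at zero.

    Red is deliberately left untouched; sds are unchanged.
    """
    out = cells.copy()
    out["g_mean"] = np.maximum(0.0, out["g_mean"] - bg.g_background)
    out["b_mean"] = np.maximum(0.0, out["b_mean"] - bg.b_background)
    return out


def normalize_signature(cells: pd.DataFrame) -> pd.DataFrame:
    """Add normalized-signature columns r_pct/g_pct/b_pct.

    Each channel mean is expressed as a percentage of the channel sum,
    C_normalized = C_mean / (R_mean + G_mean + B_mean) * 100, so the three
    percentages sum to 100 exactly.
    """
    total = cells["r_mean"] + cells["g_mean"] + cells["b_mean"]
    if (total <= 0).any():
        bad = cells.loc[total <= 0, "cell_id"].tolist()
        raise DegenerateSignalError(f"zero channel sum for cell(s) {bad}")
    out = cells.copy()
    for c in _CHANNELS:
        out[f"{c}_pct"] = cells[f"{c}_mean"] / total * 100.0
    return out


def is_triple_positive(cells: pd.DataFrame, z: float = TRIPLE_POSITIVE_Z) -> pd.Series:
    """True where C_mean - z * C_sd > 0 in all three channels (strict)."""
    ok = pd.Series(True, index=cells.index)
    for c in _CHANNELS:
        ok &= cells[f"{c}_mean"] - z * cells[f"{c}_sd"] > 0
    return ok


def _normalized_variances(row: Mapping) -> np.ndarray:
    """Delta-method variance of each normalized channel mean.

    The signature p_C = 100 * C / (R + G + B) is a ratio of channel means,
    whose sds are recorded on the raw scale.  With independent channel means
    of variance s_C^2 / n, the gradient of p_C propagates these to the
    percentage scale.
    """
    m = np.array([row[f"{c}_mean"] for c in _CHANNELS], dtype=float)
    s = np.array([row[f"{c}_sd"] for c in _CHANNELS], dtype=float)
    n = float(row["n_pixels"])
    if n < 2:
        raise InsufficientDataError(f"n_pixels must be >= 2, got {n}")
    total = m.sum()
    if total <= 0:
        raise DegenerateSignalError("zero channel sum")
    var_mean = s**2 / n
    out = np.empty(3)
    for i in range(3):
        grad = -100.0 * m[i] / total**2 * np.ones(3)
        grad[i] = 100.0 * (total - m[i]) / total**2
        out[i] = float(grad**2 @ var_mean)
    return out


def tost_pair(a: Mapping, b: Mapping, params: TostParams) -> bool:
    """Equivalence of two cells' normalized signatures by per-channel TOST.

    For every channel, both one-sided Welch t-tests of the normalized-mean
    difference against +/- margin must reject non-equivalence at alpha.
    Degrees of freedom follow Welch–Satterthwaite with per-cell n_pixels - 1;
    when both propagated variances vanish the decision reduces to
    |difference| < margin.  Symmetric in its arguments.
    """
    pa = np.array([_pct(a, c) for c in _CHANNELS])
    pb = np.array([_pct(b, c) for c in _CHANNELS])
    va = _normalized_variances(a)
    vb = _normalized_variances(b)
    na, nb = float(a["n_pixels"]), float(b["n_pixels"])
    for i in range(3):
        diff = pa[i] - pb[i]
        se2 = va[i] + vb[i]
        if se2 == 0.0:
            if abs(diff) >= params.margin_pct:
                return False
            continue
        se = np.sqrt(se2)
        df = se2**2 / (va[i] ** 2 / (na - 1) + vb[i] ** 2 / (nb - 1))
        # H0a: diff <= -margin  vs  diff > -margin
        p_lower = stats.t.sf((diff + params.margin_pct) / se, df)
        # H0b: diff >= +margin  vs  diff < +margin
        p_upper = stats.t.cdf((diff - params.margin_pct) / se, df)
        if max(p_lower, p_upper) >= params.alpha:
            return False
    return True


def _pct(row: Mapping, c: str) -> float:
    if f"{c}_pct" in row:
        return float(row[f"{c}_pct"])
    total = sum(float(row[f"{x}_mean"]) for x in _CHANNELS)
    if total <= 0:
        raise DegenerateSignalError("zero channel sum")
    return float(row[f"{c}_mean"]) / total * 100.0


class _UnionFind:
    def __init__(self, items: Iterable):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def cluster_clones(cells: pd.DataFrame, params: TostParams) -> CloneSet:
    """Cluster one islet's triple-positive cells into clones.

    Clones are the connected components of the graph whose edges join
    TOST-equivalent pairs: if a cell is equivalent to members of two groups,
    the groups merge.  Non-triple-positive cells are excluded and reported in
    ``CloneSet.excluded``.
    """
    islet_ids = cells["islet_id"].unique() if len(cells) else []
    if len(islet_ids) > 1:
        raise InvalidConfigError(
            f"cluster_clones expects cells from one islet, got {list(islet_ids)}"
        )
    islet_id = islet_ids[0] if len(islet_ids) else None
    if len(cells) == 0:
        return CloneSet(islet_id=islet_id, clones=[])

    tp = is_triple_positive(cells)
    kept = cells.loc[tp]
    excluded = frozenset(cells.loc[~tp, "cell_id"])
    ids = list(kept["cell_id"])
    uf = _UnionFind(ids)
    rows = [row for _, row in kept.iterrows()]
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            if tost_pair(rows[i], rows[j], params):
                uf.union(ids[i], ids[j])
    groups: dict[object, set] = {}
    for cid in ids:
        groups.setdefault(uf.find(cid), set()).add(cid)
    clones = sorted(
        (frozenset(g) for g in groups.values()), key=lambda s: sorted(map(str, s))
    )
    return CloneSet(islet_id=islet_id, clones=list(clones), excluded=excluded)


def clonality_summary(cs: CloneSet) -> dict:
    """Percentages of clones that stayed single cells vs. grew multicellular.

    The denominator is the number of clones — each clone is one tracked
    recombination event, whether or not it divided.
    """
    n = len(cs.clones)
    if n == 0:
        raise InsufficientDataError("no clones: percentages undefined")
    return {
        "n_clones": n,
        "pct_single": 100.0 * cs.n_single / n,
        "pct_multi": 100.0 * cs.n_multi / n,
        "size_histogram": cs.size_histogram(),
    }


def compare_clonality(counts_a: Sequence[int], counts_b: Sequence[int]) -> float:
    """Two-sided Fisher exact p-value for a 2x2 (single, multi) x stage table.

    An all-zero table returns p = 1.0 by convention (no evidence either way).
    """
    table = np.asarray([counts_a, counts_b], dtype=object)
    if table.shape != (2, 2):
        raise InvalidConfigError("expected a 2x2 table")
    arr = np.asarray(table, dtype=float)
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise InvalidConfigError("counts must be nonnegative integers")
    if arr.sum() == 0:
        return 1.0
    return float(stats.fisher_exact(arr.astype(int), alternative="two-sided")[1])


#: Ternary-plot vertices for the pure-color signatures, in the unit
#: equilateral triangle: red at the origin, green at (1, 0), blue at the apex.
TERNARY_VERTICES = {
    "r": np.array([0.0, 0.0]),
    "g": np.array([1.0, 0.0]),
    "b": np.array([0.5, np.sqrt(3.0) / 2.0]),
}


def ternary_coordinates(r_pct: float, g_pct: float, b_pct: float) -> tuple[float, float]:
    """Barycentric map of a normalized signature into the unit triangle."""
    w = np.array([r_pct, g_pct, b_pct], dtype=float) / 100.0
    uv = (
        w[0] * TERNARY_VERTICES["r"]
        + w[1] * TERNARY_VERTICES["g"]
        + w[2] * TERNARY_VERTICES["b"]
    )
    return float(uv[0]), float(uv[1])


def ternary_plot(cells: pd.DataFrame, path=None, ax=None, color_by_clone=None):
    """Scatter normalized signatures on a ternary plot; optionally save."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.5))
    tri = np.array(
        [TERNARY_VERTICES["r"], TERNARY_VERTICES["g"], TERNARY_VERTICES["b"],
         TERNARY_VERTICES["r"]]
    )
    ax.plot(tri[:, 0], tri[:, 1], color="0.4", lw=1)
    uv = np.array(
        [ternary_coordinates(row["r_pct"], row["g_pct"], row["b_pct"])
         for _, row in cells.iterrows()]
    )
    if len(uv):
        c = None
        if color_by_clone is not None:
            c = [color_by_clone.get(cid, -1) for cid in cells["cell_id"]]
        ax.scatter(uv[:, 0], uv[:, 1], c=c, cmap="tab20", s=22, edgecolor="k",
                   linewidth=0.3)
    for name, v in TERNARY_VERTICES.items():
        ax.annotate(name.upper(), v, textcoords="offset points",
                    xytext=(0, -12 if v[1] == 0 else 6), ha="center")
    ax.set_aspect("equal")
    ax.axis("off")
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
    return ax
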