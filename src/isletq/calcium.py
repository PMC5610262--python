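"""GCaMP calcium-trace normalization and glucose-responder classification.

Islets are imaged through a stimulus ramp: basal glucose (5 mM), one or more
elevated-glucose phases, and a terminal KCl depolarization that forces calcium
influx in every viable beta-cell.  Per cell:

* F0 is the mean raw fluorescence over the basal phase; traces are reported
  as (F - F0) / (Fmax - F0) so the global peak maps to 1.
* Cells whose KCl response does not rise above basal are quality-control
  failures and are dropped from all quantification.
* A QC-passed cell is a *glucose responder* if its raw trace spends at least
  a dwell fraction of some glucose phase above basal mean + k_sd * basal sd,
  while not doing so within the basal phase itself.

Classification happens against basal statistics of the raw trace, so the
calls are invariant to affine rescaling (detector gain/offset).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, InvalidConfigError

PHASE_LABELS = ("basal", "glucose_7.5", "glucose_10", "glucose_20", "kcl")


@dataclass(frozen=True)
class Phase:
    label: str
    concentration_mm: float
    t_start: float
    t_end: float

    def __post_init__(self):
        if self.t_end <= self.t_start:
            raise InvalidConfigError(f"phase {self.label}: t_end must exceed t_start")

    def contains(self, t: np.ndarray) -> np.ndarray:
        return (t >= self.t_start) & (t < self.t_end)


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered, non-overlapping stimulus phases: basal first, KCl last."""

    phases: tuple[Phase, ...]

    def __post_init__(self):
        if len(self.phases) < 2:
            raise InvalidConfigError("protocol needs at least basal and kcl phases")
        if self.phases[0].label != "basal":
            raise InvalidConfigError("first phase must be basal")
        if self.phases[-1].label != "kcl":
            raise InvalidConfigError("last phase must be kcl")
        if sum(p.label == "basal" for p in self.phases) != 1:
            raise InvalidConfigError("exactly one basal phase")
        if sum(p.label == "kcl" for p in self.phases) != 1:
            raise InvalidConfigError("exactly one kcl phase")
        for a, b in zip(self.phases, self.phases[1:]):
            if b.t_start < a.t_end:
                raise InvalidConfigError(
                    f"phases {a.label} and {b.label} overlap or are out of order"
                )

    @property
    def basal(self) -> Phase:
        return self.phases[0]

    @property
    def kcl(self) -> Phase:
        return self.phases[-1]

    @property
    def glucose_phases(self) -> tuple[Phase, ...]:
        return tuple(p for p in self.phases if p.label.startswith("glucose"))

    def to_json(self, path):
        payload = [vars(p) for p in self.phases]
        with open(path, "w") as fh:
            json.dump({"phases": payload}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "StimulusProtocol":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(tuple(Phase(**p) for p in payload["phases"]))


def default_protocol() -> StimulusProtocol:
    """Basal 5 mM, 10 mM and 20 mM glucose steps, then 30 mM KCl."""
    return StimulusProtocol(
        (
            Phase("basal", 5.0, 0.0, 120.0),
            Phase("glucose_10", 10.0, 120.0, 240.0),
            Phase("glucose_20", 20.0, 240.0, 360.0),
            Phase("kcl", 30.0, 360.0, 420.0),
        )
    )


@dataclass
class CalciumTrace:
    """One cell's raw fluorescence time series."""

    cell_id: object
    t: np.ndarray
    f: np.ndarray
    region: str = "unassigned"  # anterior | posterior | unassigned
    label_status: str = "none"  # h2b_positive | h2b_negative | none

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.t.shape != self.f.shape or self.t.ndim != 1:
            raise InvalidConfigError("t and f must be 1D arrays of equal length")
        if not np.all(np.diff(self.t) > 0):
            raise InvalidConfigError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.f)):
            raise InvalidConfigError("fluorescence must be finite")


@dataclass
class NormalizedTrace:
    """(F - F0) / (Fmax - F0) trace plus the raw basal statistics."""

    cell_id: object
    t: np.ndarray
    f_raw: np.ndarray
    f_norm: np.ndarray
    f0: float
    f_max: float
    basal_sd: float
    flat: bool
    region: str = "unassigned"
    label_status: str = "none"


def normalize_trace(trace: CalciumTrace, protocol: StimulusProtocol) -> NormalizedTrace:
    """Anchor a trace to its basal mean (0) and global maximum (1).

    A trace whose maximum equals its basal mean carries no signal; it is
    flagged flat (f_norm all-zero) rather than raising, so cohorts with dead
    cells still process.
    """
    in_basal = protocol.basal.contains(trace.t)
    if in_basal.sum() < 3:
        raise InsufficientDataError(
            f"cell {trace.cell_id}: basal phase has {int(in_basal.sum())} samples, need >= 3"
        )
    f0 = float(trace.f[in_basal].mean())
    basal_sd = float(trace.f[in_basal].std(ddof=1))
    f_max = float(trace.f.max())
    if f_max <= f0:
        return NormalizedTrace(
            trace.cell_id, trace.t, trace.f, np.zeros_like(trace.f),
            f0, f_max, basal_sd, flat=True,
            region=trace.region, label_status=trace.label_status,
        )
    f_norm = (trace.f - f0) / (f_max - f0)
    return NormalizedTrace(
        trace.cell_id, trace.t, trace.f, f_norm, f0, f_max, basal_sd, flat=False,
        region=trace.region, label_status=trace.label_status,
    )


def qc_kcl(ntrace: NormalizedTrace, protocol: StimulusProtocol, k_sd: float = 3.0) -> bool:
    """Positive-control gate: the KCl phase must rise above basal.

    Pass iff the mean raw fluorescence during the KCl phase exceeds the basal
    mean by more than k_sd basal standard deviations.
    """
    if ntrace.flat:
        return False
    in_kcl = protocol.kcl.contains(ntrace.t)
    if not in_kcl.any():
        return False
    kcl_mean = float(ntrace.f_raw[in_kcl].mean())
    return kcl_mean > ntrace.f0 + k_sd * ntrace.basal_sd


def classify_responder(
    ntrace: NormalizedTrace,
    protocol: StimulusProtocol,
    k_sd: float = 3.0,
    dwell_fraction: float = 0.10,
    basal_k_sd: float = 3.0,
) -> bool:
    """Call a QC-passed cell a glucose responder.

    Responder iff the raw trace exceeds basal mean + k_sd * basal sd for at
    least ``dwell_fraction`` of the samples of some glucose phase, and is not
    already active within the basal phase itself (cells responding at 5 mM
    are not glucose-ramp responders).  Basal activity is judged against the
    fixed ``basal_k_sd`` multiplier, not ``k_sd``, so that lowering the
    responder sensitivity dial never disqualifies cells through their own
    baseline noise: the responder call is monotone in ``k_sd``.
    """
    in_basal = protocol.basal.contains(ntrace.t)
    basal_thresh = ntrace.f0 + basal_k_sd * ntrace.basal_sd
    if float((ntrace.f_raw[in_basal] > basal_thresh).mean()) >= dwell_fraction:
        return False
    thresh = ntrace.f0 + k_sd * ntrace.basal_sd
    for phase in protocol.glucose_phases:
        sel = phase.contains(ntrace.t)
        if not sel.any():
            continue
        if float((ntrace.f_raw[sel] > thresh).mean()) >= dwell_fraction:
            return True
    return False


def classify_cohort(
    traces: Sequence[CalciumTrace],
    protocol: StimulusProtocol,
    k_sd_qc: float = 3.0,
    k_sd_responder: float = 3.0,
    dwell_fraction: float = 0.10,
) -> pd.DataFrame:
    """Normalize, QC and classify a list of traces; one row per cell."""
    rows = []
    for tr in traces:
        nt = normalize_trace(tr, protocol)
        ok = qc_kcl(nt, protocol, k_sd=k_sd_qc)
        rows.append(
            {
                "cell_id": tr.cell_id,
                "region": tr.region,
                "label_status": tr.label_status,
                "qc_pass": ok,
                "responder": (
                    classify_responder(nt, protocol, k_sd=k_sd_responder,
                                       dwell_fraction=dwell_fraction)
                    if ok else False
                ),
                "f0": nt.f0,
                "f_max": nt.f_max,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RegionalResponderStats:
    """Per-islet regional responder percentages and posterior/anterior ratio."""

    per_islet: pd.DataFrame
    pct_anterior_mean: float
    pct_anterior_sem: float
    pct_posterior_mean: float
    pct_posterior_sem: float
    ratio_mean: float
    ratio_sem: float
    n_infinite_ratios: int = 0


def regional_responder_stats(calls: pd.DataFrame) -> RegionalResponderStats:
    """Aggregate responder calls by islet and region.

    ``calls`` needs columns islet_id, region (anterior|posterior), qc_pass,
    responder.  Percentages use QC-passed cells as denominator.  Islets with
    zero anterior responders get an infinite ratio; these are flagged,
    excluded from the ratio mean/SEM, and counted.
    """
    df = calls[calls["qc_pass"]]
    if len(df) == 0:
        raise InsufficientDataError("no QC-passed cells")
    rows = []
    for islet, grp in df.groupby("islet_id"):
        rec = {"islet_id": islet}
        for region in ("anterior", "posterior"):
            sub = grp[grp["region"] == region]
            if len(sub) == 0:
                raise InsufficientDataError(
                    f"islet {islet}: no QC-passed {region} cells"
                )
            rec[f"pct_{region}"] = 100.0 * sub["responder"].mean()
        rec["ratio_post_over_ant"] = (
            rec["pct_posterior"] / rec["pct_anterior"]
            if rec["pct_anterior"] > 0 else np.inf
        )
        rows.append(rec)
    per_islet = pd.DataFrame(rows)
    finite = per_islet.loc[np.isfinite(per_islet["ratio_post_over_ant"]),
                           "ratio_post_over_ant"]
    n_inf = int(len(per_islet) - len(finite))
    if n_inf:
        warnings.warn(
            f"{n_inf} islet(s) had zero anterior responders; "
            "their ratios are infinite and excluded from aggregation"
        )

    def _sem(x):
        return float(stats.sem(x)) if len(x) > 1 else float("nan")

    return RegionalResponderStats(
        per_islet=per_islet,
        pct_anterior_mean=float(per_islet["pct_anterior"].mean()),
        pct_anterior_sem=_sem(per_islet["pct_anterior"]),
        pct_posterior_mean=float(per_islet["pct_posterior"].mean()),
        pct_posterior_sem=_sem(per_islet["pct_posterior"]),
        ratio_mean=float(finite.mean()) if len(finite) else float("nan"),
        ratio_sem=_sem(finite),
        n_infinite_ratios=n_inf,
    )


def compare_ratios_across_stages(ratios_by_stage: dict) -> dict:
    """Kruskal–Wallis across stages, then pairwise two-sided rank tests.

    Infinite ratios are dropped with a warning before testing.
    """
    clean = {}
    for stage, vals in ratios_by_stage.items():
        arr = np.asarray(list(vals), dtype=float)
        finite = arr[np.isfinite(arr)]
        if len(finite) < len(arr):
            warnings.warn(f"stage {stage}: dropped {len(arr) - len(finite)} "
                          "infinite ratio(s) before rank tests")
        if len(finite) == 0:
            raise InsufficientDataError(f"stage {stage}: no finite ratios")
        clean[stage] = finite
    if len(clean) < 2:
        raise InsufficientDataError("need >= 2 stages to compare")
    kw_stat, kw_p = stats.kruskal(*clean.values())
    stages = list(clean)
    pairwise = {}
    for i in range(len(stages)):
        for j in range(i + 1, len(stages)):
            a, b = stages[i], stages[j]
            pairwise[(a, b)] = float(
                stats.mannwhitneyu(clean[a], clean[b], alternative="two-sided")[1]
            )
    return {"kruskal_p": float(kw_p), "pairwise_p": pairwise}


def classify_h2b_status(
    mean_intensity: float,
    background_mean: float,
    background_sd: float,
    k: float = 2.0,
) -> str:
    """Call histone-label retention from nuclear mCherry intensity.

    A cell is h2b_negative when its mean intensity is similar to background:
    at or below background mean + k background sds.
    """
    if background_sd < 0:
        raise InvalidConfigError("background sd must be >= 0")
    if mean_intensity <= background_mean + k * background_sd:
        return "h2b_negative"
    return "h2b_positive"
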