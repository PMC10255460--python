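"""Condition-level aggregation, exclusion criteria and quadrant summaries.

Per-session synchronization scores (R²) are aggregated to condition means
within each (eye feature, channel, band, quadrant) cell, empathic vs
non-empathic means are compared with a two-tailed Welch t-test, and two
exclusion rules remove triples where empathy confers no advantage:

1. the non-empathic mean R² is at least as high as the empathic one, or
2. the mean ± 1 std intervals of the two conditions overlap.

Retained triples are grouped by valence-arousal quadrant and tagged by
hemisphere: 10-20 channels with odd site numbers are left, even right,
"z" midline; pupil features carry an eye side, so pupil-channel pairs are
labelled same/crossed hemisphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .eye_features import FEATURE_SIDE
from .montage import hemisphere

QUADRANTS = ("pleasant-aroused", "pleasant-relaxed",
             "unpleasant-relaxed", "unpleasant-aroused")


@dataclass
class ConditionComparison:
    """Empathic vs non-empathic R² comparison for one triple in one quadrant."""

    eye_feature: str
    channel: str
    band: str
    quadrant: str
    mean_emp: float
    std_emp: float
    n_emp: int
    mean_non: float
    std_non: float
    n_non: int
    t_stat: float = np.nan
    p_value: float = np.nan
    retained: bool = False
    retention_reason: str = "kept"
    hemisphere_tag: str = ""


@dataclass
class QuadrantSummary:
    """Retained triples of one valence-arousal quadrant."""

    quadrant: str
    triples: list[ConditionComparison] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return len(self.triples)


def aggregate(results: pd.DataFrame,
              by: tuple[str, ...] = ("eye_feature", "channel", "band",
                                     "condition", "quadrant"),
              ) -> pd.DataFrame:
    """Mean / sample-std / count of R² per group.

    Groups of size 1 report their mean with std NaN (flagged downstream).
    Undefined (NaN) R² rows are dropped before aggregation.
    """
    if results.empty:
        raise ValueError("no results to aggregate")
    df = results.dropna(subset=["r2"])
    out = (df.groupby(list(by))["r2"]
             .agg(mean="mean", std=lambda v: v.std(ddof=1), n="count")
             .reset_index())
    return out


def compare_conditions(emp: np.ndarray, non: np.ndarray,
                       ) -> tuple[float, float]:
    """Two-tailed Welch t-test on per-session R² values.

    Degenerate case: both groups constant with equal means gives
    (t, p) = (0, 1) by convention.
    """
    emp = np.asarray(emp, dtype=float)
    non = np.asarray(non, dtype=float)
    if len(emp) < 2 or len(non) < 2:
        raise ValueError("both groups need >= 2 sessions for a t-test")
    if emp.std() == 0 and non.std() == 0:
        if emp.mean() == non.mean():
            return 0.0, 1.0
        return (np.inf if emp.mean() > non.mean() else -np.inf), 0.0
    t, p = stats.ttest_ind(emp, non, equal_var=False)
    return float(t), float(p)


def apply_exclusion(comp: ConditionComparison,
                    use_standard_error: bool = False) -> ConditionComparison:
    """Apply the two exclusion rules, setting ``retained`` and the reason.

    Rule 1 fires when the non-empathic mean is at least the empathic mean;
    rule 2 when the mean ± std intervals intersect
    (``use_standard_error`` shrinks the intervals to mean ± std/sqrt(n)).
    A missing std makes rule 2 unevaluable, which excludes conservatively.
    """
    if comp.mean_non >= comp.mean_emp:
        comp.retained = False
        comp.retention_reason = "non_empathic_higher"
        return comp
    if not (np.isfinite(comp.std_emp) and np.isfinite(comp.std_non)):
        comp.retained = False
        comp.retention_reason = "std_overlap"  # unevaluable -> conservative
        return comp
    half_emp = comp.std_emp
    half_non = comp.std_non
    if use_standard_error:
        half_emp /= np.sqrt(comp.n_emp)
        half_non /= np.sqrt(comp.n_non)
    lo_emp, hi_emp = comp.mean_emp - half_emp, comp.mean_emp + half_emp
    lo_non, hi_non = comp.mean_non - half_non, comp.mean_non + half_non
    if lo_emp <= hi_non and lo_non <= hi_emp:
        comp.retained = False
        comp.retention_reason = "std_overlap"
        return comp
    comp.retained = True
    comp.retention_reason = "kept"
    return comp


def hemisphere_tag(eye_feature: str, channel: str) -> str:
    """same | crossed | midline | unsided, from 10-20 parity and eye side."""
    side = FEATURE_SIDE[eye_feature]
    ch_side = hemisphere(channel)
    if ch_side == "midline":
        return "midline"
    if side is None:
        return "unsided"
    return "same" if side == ch_side else "crossed"


def build_comparisons(results: pd.DataFrame,
                      adjust: str | None = None,
                      use_standard_error: bool = False,
                      ) -> list[ConditionComparison]:
    """Full comparison table: one entry per (feature, channel, band, quadrant).

    ``results`` is a per-session SyncResult frame (one R² per subject x
    video x triple).  ``adjust="bh"`` additionally Benjamini-Hochberg
    corrects the p-values across comparisons (off by default; reported in
    ``p_value`` in place of the raw value).
    """
    df = results.dropna(subset=["r2"])
    comps: list[ConditionComparison] = []
    keys = ["eye_feature", "channel", "band", "quadrant"]
    for (feature, channel, band, quadrant), g in df.groupby(keys):
        emp = g.loc[g["condition"] == "empathic", "r2"].to_numpy()
        non = g.loc[g["condition"] == "non_empathic", "r2"].to_numpy()
        if len(emp) == 0 or len(non) == 0:
            continue
        comp = ConditionComparison(
            eye_feature=feature, channel=channel, band=band,
            quadrant=quadrant,
            mean_emp=float(emp.mean()),
            std_emp=float(emp.std(ddof=1)) if len(emp) > 1 else np.nan,
            n_emp=len(emp),
            mean_non=float(non.mean()),
            std_non=float(non.std(ddof=1)) if len(non) > 1 else np.nan,
            n_non=len(non),
            hemisphere_tag=hemisphere_tag(feature, channel))
        if len(emp) >= 2 and len(non) >= 2:
            comp.t_stat, comp.p_value = compare_conditions(emp, non)
        comps.append(apply_exclusion(comp,
                                     use_standard_error=use_standard_error))
    if adjust == "bh":
        pvals = np.array([c.p_value for c in comps])
        ok = np.isfinite(pvals)
        if ok.any():
            adj = stats.false_discovery_control(pvals[ok], method="bh")
            for c, p in zip(np.array(comps, dtype=object)[ok], adj):
                c.p_value = float(p)
    return comps


def quadrant_report(comparisons: list[ConditionComparison],
                    ) -> dict[str, QuadrantSummary]:
    """Group the retained triples by quadrant (every quadrant present)."""
    report = {q: QuadrantSummary(quadrant=q) for q in QUADRANTS}
    for comp in comparisons:
        if comp.quadrant not in report:
            raise ValueError(f"unknown quadrant {comp.quadrant!r}")
        if comp.retained:
            report[comp.quadrant].triples.append(comp)
    return report


def comparisons_to_frame(comps: list[ConditionComparison]) -> pd.DataFrame:
    cols = ["eye_feature", "channel", "band", "quadrant", "mean_emp",
            "std_emp", "n_emp", "mean_non", "std_non", "n_non", "t_stat",
            "p_value", "retained", "retention_reason", "hemisphere_tag"]
    return pd.DataFrame([[getattr(c, a) for a in cols] for c in comps],
                        columns=cols)
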