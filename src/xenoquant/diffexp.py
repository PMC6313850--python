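"""Differential-expression statistics and the three identification criteria.

A protein is called differentially expressed between experimental groups
when all three criteria hold (thresholds inclusive):

(i)   ANOVA p-value <= 0.05 between the compared groups — a one-way
      fixed-effects ANOVA for independent groups, or a within-subject
      (repeated-measures) ANOVA for patient-matched samples;
(ii)  at least 2 unique peptides contributing to the identification;
(iii) at least a 1.5-fold change in relative abundance.

Statistics are computed on natural-log abundances (variance
stabilization for label-free intensities); fold changes are reported on
the linear scale. No multiple-testing correction is applied by default —
the raw-p rule above is the published convention this pipeline mirrors —
but Benjamini–Hochberg adjustment is available behind a flag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import Condition, FixtureRow
from .quant import ProteinQuantResult

#: Smallest reportable p-value; degenerate zero-variance perfect effects
#: are reported at this floor rather than exactly 0.
P_FLOOR = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class DECriteria:
    """The three differential-expression criteria (inclusive thresholds)."""

    p_threshold: float = 0.05
    min_unique_peptides: int = 2
    min_fold_change: float = 1.5
    paired: bool = False
    fdr_adjust: bool = False

    def passes(self, p_value: float, unique_peptides: int, fold: float) -> bool:
        return (
            p_value <= self.p_threshold
            and unique_peptides >= self.min_unique_peptides
            and fold >= self.min_fold_change
        )


def anova_oneway(
    values_by_condition: Mapping[Condition, Sequence[float]],
) -> float:
    """One-way fixed-effects ANOVA p-value across >= 2 groups.

    Degenerate inputs: all groups constant with equal means -> p = 1
    (no effect, no noise); constant groups with differing means -> p at
    the machine floor (a perfect effect with zero residual variance).
    """
    groups = [np.asarray(v, dtype=float) for v in values_by_condition.values()]
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least 2 values")
    if all(np.ptp(g) == 0 for g in groups):
        means = [g.mean() for g in groups]
        return 1.0 if np.ptp(means) == 0 else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = stats.f_oneway(*groups).pvalue
    if not np.isfinite(p):
        return 1.0
    return float(p)


@dataclass
class RMAnovaResult:
    """Full repeated-measures ANOVA output for paired designs."""

    f_statistic: float
    p_value: float
    df_condition: int
    df_error: int
    n_subjects: int
    n_dropped: int
    floored: bool = False


def anova_repeated_full(
    values_by_subject: Mapping[str, Sequence[Optional[float]]],
) -> RMAnovaResult:
    """Within-subject one-way ANOVA over k conditions.

    ``values_by_subject`` maps each subject to its k condition values in
    a fixed condition order; subjects with any missing value (None/NaN)
    are dropped and counted. For two conditions the F statistic equals
    the squared paired-t statistic.
    """
    complete: list[np.ndarray] = []
    n_dropped = 0
    width = None
    for subj, vals in values_by_subject.items():
        arr = np.asarray(
            [math.nan if v is None else float(v) for v in vals], dtype=float
        )
        if width is None:
            width = arr.size
        elif arr.size != width:
            raise ValueError(f"subject {subj!r} has {arr.size} values, expected {width}")
        if np.isnan(arr).any():
            n_dropped += 1
        else:
            complete.append(arr)
    if len(complete) < 2:
        raise ValueError(
            f"repeated-measures ANOVA needs >= 2 complete subjects, "
            f"got {len(complete)}"
        )
    data = np.vstack(complete)  # subjects x conditions
    n, k = data.shape
    if k < 2:
        raise ValueError("need >= 2 conditions")
    grand = data.mean()
    ss_cond = n * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = max(ss_total - ss_cond - ss_subj, 0.0)
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    floored = False
    if ss_err <= 0:
        if ss_cond <= 0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p, floored = math.inf, P_FLOOR, True
    else:
        f_stat = (ss_cond / df_cond) / (ss_err / df_err)
        p = float(stats.f.sf(f_stat, df_cond, df_err)) if ss_cond > 0 else 1.0
        if p < P_FLOOR:
            p, floored = P_FLOOR, True
    return RMAnovaResult(
        f_statistic=float(f_stat),
        p_value=float(p),
        df_condition=df_cond,
        df_error=df_err,
        n_subjects=n,
        n_dropped=n_dropped,
        floored=floored,
    )


def anova_repeated(
    pairs_by_subject: Mapping[str, Sequence[Optional[float]]],
) -> float:
    """Repeated-measures ANOVA p-value (see :func:`anova_repeated_full`)."""
    return anova_repeated_full(pairs_by_subject).p_value


@dataclass
class DifferentialResult:
    """One protein's differential test outcome against the criteria."""

    accession: str
    unique_peptides: int
    p_value: float
    fold_change: float
    direction: Optional[Condition]
    passes: bool = False
    protein: Optional[ProteinQuantResult] = None
    p_adjusted: Optional[float] = None
    gene: str = ""

    @classmethod
    def from_fixture_row(cls, row: FixtureRow) -> "DifferentialResult":
        return cls(
            accession=row.accession,
            unique_peptides=row.peptides,
            p_value=row.p_value,
            fold_change=row.fold_change,
            direction=row.highest_in,
            gene=row.gene,
        )


def apply_de_filters(
    results: Iterable[DifferentialResult],
    criteria: DECriteria = DECriteria(),
    baseline: Optional[Condition] = None,
) -> tuple[list[DifferentialResult], dict[str, int]]:
    """Apply the three criteria; return passing list and up/down counts.

    The passing list is sorted by descending fold change. Directions are
    counted relative to ``baseline``: a passing protein whose higher
    condition is *not* the baseline counts as "up" (over-expressed in
    the comparison arm), one higher in the baseline as "down". Without a
    baseline, counts are keyed by the higher condition's name.

    With ``criteria.fdr_adjust`` the p criterion is applied to
    Benjamini–Hochberg adjusted p-values instead of raw ones.
    """
    results = list(results)
    pvals = [r.p_value for r in results]
    if criteria.fdr_adjust and results:
        adjusted = multipletests(pvals, method="fdr_bh")[1]
        for r, q in zip(results, adjusted):
            r.p_adjusted = float(q)
    for r in results:
        p_for_rule = r.p_adjusted if criteria.fdr_adjust else r.p_value
        r.passes = criteria.passes(p_for_rule, r.unique_peptides, r.fold_change)
    passing = sorted(
        (r for r in results if r.passes),
        key=lambda r: -r.fold_change,
    )
    summary: dict[str, int] = {"up": 0, "down": 0}
    if baseline is not None:
        for r in passing:
            if r.direction == baseline:
                summary["down"] += 1
            else:
                summary["up"] += 1
    else:
        summary = {}
        for r in passing:
            key = str(r.direction) if r.direction is not None else "unknown"
            summary[key] = summary.get(key, 0) + 1
    return passing, summary


@dataclass
class StabilityReport:
    """Cross-generation (F1 vs F2) stability summary of passing proteins.

    The xenograft proteome is judged stable across generations when no
    protein that rose in the later (F2) generation exceeded a 2-fold
    change.
    """

    n_higher_f2: int
    n_higher_f1: int
    max_fold_f2_higher: float
    max_fold_f1_higher: float
    over_twofold: list[str] = field(default_factory=list)
    over_twofold_f2: list[str] = field(default_factory=list)
    stable: bool = True


def stability_report(
    passing: Sequence[DifferentialResult],
    later_generation: Condition = Condition.PDX_F2,
) -> StabilityReport:
    """Summarise an F1-vs-F2 passing list by direction and 2-fold flags."""
    higher_later = [r for r in passing if r.direction == later_generation]
    higher_earlier = [r for r in passing if r.direction != later_generation]
    over2 = [r.accession for r in passing if r.fold_change > 2.0]
    over2_later = [
        r.accession for r in higher_later if r.fold_change > 2.0
    ]
    return StabilityReport(
        n_higher_f2=len(higher_later),
        n_higher_f1=len(higher_earlier),
        max_fold_f2_higher=max(
            (r.fold_change for r in higher_later), default=float("nan")
        ),
        max_fold_f1_higher=max(
            (r.fold_change for r in higher_earlier), default=float("nan")
        ),
        over_twofold=over2,
        over_twofold_f2=over2_later,
        stable=not over2_later,
    )
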