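"""Cohort tallies, group comparisons and qPCR relative quantification.

Tallies count neurons per activity class; percentages are rounded half-up
to integers for report parity with how such censuses are usually printed
(raw proportions are always retained alongside).  Group comparisons are
generic routines: a two-sided unpaired t-test (Welch by default) for two
groups, one-way ANOVA with Tukey's post-hoc test for more, always
reporting mean ± SEM per group.  qPCR fold changes use 2^−ΔΔCt against a
reference gene and a control condition.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .current_clamp import ActivityClass, INDUCED_CLASSES
from .errors import ValidationError

__all__ = [
    "CohortTally",
    "DdCtResult",
    "GroupComparison",
    "tally",
    "genuine_ap_share",
    "compare_groups",
    "ddct",
    "build_report",
]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class CohortTally:
    """Counts of activity classes in one group of neurons."""

    group_label: str
    counts: dict[ActivityClass, int]

    def __post_init__(self):
        if any(c < 0 for c in self.counts.values()):
            raise ValidationError("counts must be non-negative")
        if self.n == 0:
            raise ValidationError("tally must contain at least one neuron")

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def proportions(self) -> dict[ActivityClass, float]:
        """Exact fractions; sum to 1."""
        return {cls: c / self.n for cls, c in self.counts.items()}

    def percentages(self) -> dict[ActivityClass, int]:
        """Integer percentages, rounded half-up (report parity)."""
        return {cls: _round_half_up(100.0 * c / self.n) for cls, c in self.counts.items()}


@dataclass(frozen=True)
class DdCtResult:
    """2^−ΔΔCt relative quantification of one target gene."""

    target_gene: str
    reference_gene: str
    delta_ct_sample: float
    delta_ct_control: float
    fold_change: float


@dataclass
class GroupComparison:
    """Result of a two-group t-test or one-way ANOVA with Tukey post-hoc."""

    design: str
    statistic: float
    pvalue: float
    means: list[float]
    sems: list[float]
    posthoc: Optional[pd.DataFrame] = field(default=None, repr=False)


def tally(
    classes: Sequence[tuple[str, ActivityClass]],
    group_label: str = "",
    coding: str = "induced",
) -> CohortTally:
    """Count neurons per activity class.

    ``classes`` is a sequence of (neuron id, ActivityClass).  ``coding``
    selects which classes appear (with zero counts when absent):
    ``"induced"`` (five levels) or ``"noninduced"`` (Quiet/Spontaneous).
    """
    if not classes:
        raise ValidationError("tally needs at least one classified neuron")
    if coding == "induced":
        universe = list(INDUCED_CLASSES)
    elif coding == "noninduced":
        universe = [ActivityClass.QUIET, ActivityClass.SPONTANEOUS]
    else:
        raise ValidationError(f"unknown coding {coding!r}")
    counts = {cls: 0 for cls in universe}
    for _, cls in classes:
        if cls not in counts:
            raise ValidationError(f"class {cls.value} not valid under {coding} coding")
        counts[cls] += 1
    return CohortTally(group_label=group_label, counts=counts)


def genuine_ap_share(t: CohortTally) -> float:
    """Percentage of neurons with genuine action potentials:
    100·(Single + AttemptingTrain + Train)/n."""
    if t.n == 0:
        raise ValidationError("empty tally")
    if ActivityClass.SPONTANEOUS in t.counts:
        raise ValidationError("genuine-AP share is defined for induced-coding tallies")
    good = sum(
        t.counts.get(cls, 0)
        for cls in (ActivityClass.SINGLE, ActivityClass.ATTEMPTING_TRAIN, ActivityClass.TRAIN)
    )
    return 100.0 * good / t.n


def _mean_sem(sample: np.ndarray) -> tuple[float, float]:
    return float(np.mean(sample)), float(np.std(sample, ddof=1) / np.sqrt(sample.size))


def compare_groups(
    *samples: Sequence[float],
    design: Optional[str] = None,
    equal_var: bool = False,
) -> GroupComparison:
    """Compare group means.

    Two samples: two-sided unpaired t-test (Welch unless
    ``equal_var=True``).  Three or more: one-way ANOVA followed by
    Tukey's pairwise post-hoc test.  Each sample needs n >= 2.
    """
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if len(arrays) < 2:
        raise ValidationError("need at least two groups")
    for a in arrays:
        if a.size < 2:
            raise ValidationError("each group needs at least two observations")
    if design is None:
        design = "two_group" if len(arrays) == 2 else "multi_group"
    if design == "two_group" and len(arrays) != 2:
        raise ValidationError("two_group design needs exactly two samples")

    means, sems = zip(*(_mean_sem(a) for a in arrays))
    if all(np.ptp(a) == 0 for a in arrays) and len({float(a[0]) for a in arrays}) == 1:
        warnings.warn("all groups constant and equal; p = 1 by convention")
        return GroupComparison(design, 0.0, 1.0, list(means), list(sems))

    if design == "two_group":
        res = stats.ttest_ind(arrays[0], arrays[1], equal_var=equal_var)
        return GroupComparison(design, float(res.statistic), float(res.pvalue), list(means), list(sems))
    if design != "multi_group":
        raise ValidationError(f"unknown design {design!r}")
    res = stats.f_oneway(*arrays)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(arrays)
    labels = np.concatenate([np.full(a.size, f"g{i}") for i, a in enumerate(arrays)])
    tukey = pairwise_tukeyhsd(values, labels)
    posthoc = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return GroupComparison(
        "multi_group", float(res.statistic), float(res.pvalue), list(means), list(sems), posthoc
    )


def ddct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_control: float,
    ct_ref_control: float,
    target_gene: str = "target",
    reference_gene: str = "reference",
) -> DdCtResult:
    """Relative expression by the 2^−ΔΔCt method.

    ΔCt = Ct(target) − Ct(reference) per condition;
    fold change = 2^−(ΔCt_sample − ΔCt_control).
    """
    cts = (ct_target_sample, ct_ref_sample, ct_target_control, ct_ref_control)
    if not all(np.isfinite(cts)) or any(c <= 0 for c in cts):
        raise ValidationError(f"all Ct values must be finite and positive, got {cts}")
    d_sample = ct_target_sample - ct_ref_sample
    d_control = ct_target_control - ct_ref_control
    return DdCtResult(
        target_gene=target_gene,
        reference_gene=reference_gene,
        delta_ct_sample=d_sample,
        delta_ct_control=d_control,
        fold_change=float(2.0 ** -(d_sample - d_control)),
    )


# ---------------------------------------------------------------------------
# structured report


def build_report(
    cohorts: Sequence[CohortTally],
    feature_tables: Optional[dict[str, pd.DataFrame]] = None,
    calcium_tables: Optional[dict[str, pd.DataFrame]] = None,
) -> dict:
    """Assemble a structured (JSON-serializable) report.

    Per group: class counts, integer percentages, exact proportions and
    the genuine-AP share; feature and calcium tables contribute
    mean ± SEM summaries; with two or more feature tables, Welch t-test
    comparisons per numeric column are included.  Render with
    :func:`report_to_markdown` or ``json.dumps``.
    """
    if not cohorts:
        raise ValidationError("report needs at least one cohort tally")
    out: dict = {"groups": [], "comparisons": {}}
    for t in cohorts:
        entry = {
            "label": t.group_label,
            "n": t.n,
            "counts": {cls.value: c for cls, c in t.counts.items()},
            "percentages": {cls.value: p for cls, p in t.percentages().items()},
            "proportions": {cls.value: p for cls, p in t.proportions().items()},
        }
        try:
            entry["genuine_ap_pct"] = genuine_ap_share(t)
        except ValidationError:
            pass
        out["groups"].append(entry)

    def summarize(tables: dict[str, pd.DataFrame]) -> dict:
        summary = {}
        for label, table in tables.items():
            num = table.select_dtypes("number")
            summary[label] = {
                col: {
                    "mean": float(np.nanmean(num[col])) if num[col].notna().any() else None,
                    "sem": float(
                        np.nanstd(num[col], ddof=1) / np.sqrt(num[col].notna().sum())
                    )
                    if num[col].notna().sum() > 1
                    else None,
                    "n": int(num[col].notna().sum()),
                }
                for col in num.columns
            }
        return summary

    if feature_tables:
        out["features"] = summarize(feature_tables)
        out["comparisons"]["features"] = _pairwise_feature_tests(feature_tables)
    if calcium_tables:
        out["calcium"] = summarize(calcium_tables)
        out["comparisons"]["calcium"] = _pairwise_feature_tests(calcium_tables)
    return out


def _pairwise_feature_tests(tables: dict[str, pd.DataFrame]) -> dict:
    labels = list(tables)
    tests: dict = {}
    if len(labels) < 2:
        return tests
    a_label, b_label = labels[0], labels[1]
    a_tab, b_tab = tables[a_label], tables[b_label]
    for col in a_tab.select_dtypes("number").columns:
        if col not in b_tab.columns:
            continue
        a = a_tab[col].dropna().to_numpy()
        b = b_tab[col].dropna().to_numpy()
        if a.size < 2 or b.size < 2:
            continue
        cmp = compare_groups(a, b)
        tests[col] = {"t": cmp.statistic, "p": cmp.pvalue, "groups": [a_label, b_label]}
    return tests


def report_to_markdown(report: dict) -> str:
    """Render a report dict as Markdown."""
    lines = ["# Cohort report", ""]
    for g in report["groups"]:
        lines.append(f"## {g['label'] or 'group'} (n = {g['n']})")
        lines.append("")
        lines.append("| class | count | percent | proportion |")
        lines.append("|---|---|---|---|")
        for cls, c in g["counts"].items():
            lines.append(
                f"| {cls} | {c} | {g['percentages'][cls]}% | {g['proportions'][cls]:.3f} |"
            )
        if "genuine_ap_pct" in g:
            lines.append("")
            lines.append(f"Genuine-AP share: {g['genuine_ap_pct']:.1f}%")
        lines.append("")
    for section in ("features", "calcium"):
        if section in report:
            lines.append(f"## {section} summaries")
            lines.append("")
            lines.append("```json")
            lines.append(json.dumps(report[section], indent=1))
            lines.append("```")
            lines.append("")
    if report.get("comparisons"):
        lines.append("## comparisons")
        lines.append("")
        lines.append("```json")
        lines.append(json.dumps(report["comparisons"], indent=1))
        lines.append("```")
    return "\n".join(lines)
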