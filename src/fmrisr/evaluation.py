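"""Functional-resolution metrics and paired cohort statistics.

Functional resolution — the ability to tell two spatially adjacent
responses apart — is operationalised as the Dice coefficient between
the activation-related regions of the two tasks: *lower* Dice means
better separation.  Arms (native vs super-resolved) are compared per
subject with the two-sided Wilcoxon signed-rank test; summaries are
reported as median (IQR) with linear-interpolation quantiles.

Dice is computed on each arm's native grid — it is scale-free, so no
resampling between grids is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DiceResult",
    "GroupComparison",
    "dice",
    "wilcoxon_signed_rank",
    "summarize",
    "compare_arms",
    "render_table",
]


@dataclass(frozen=True)
class DiceResult:
    """Overlap of two binary regions: 2|A∩B| / (|A|+|B|)."""

    dice: float
    region_a_count: int
    region_b_count: int
    overlap_count: int
    subject_id: str | None = None
    arm_label: str | None = None


@dataclass(frozen=True)
class GroupComparison:
    """Paired two-sample comparison across subjects."""

    values_first: tuple[float, ...]
    values_second: tuple[float, ...]
    statistic: float | None
    p_value: float | None
    exact: bool | None
    median_iqr_first: tuple[float, float, float]
    median_iqr_second: tuple[float, float, float]
    n_pairs: int
    note: str = ""


def dice(mask_a: np.ndarray, mask_b: np.ndarray, subject_id=None, arm_label=None) -> DiceResult:
    """Dice coefficient of two binary masks on the same grid."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask grids differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise ValueError("both masks are empty; Dice is undefined")
    overlap = int((a & b).sum())
    return DiceResult(
        dice=2.0 * overlap / (na + nb),
        region_a_count=na,
        region_b_count=nb,
        overlap_count=overlap,
        subject_id=subject_id,
        arm_label=arm_label,
    )


_EXACT_MAX_N = 25


def wilcoxon_signed_rank(
    first: Sequence[float], second: Sequence[float]
) -> GroupComparison:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Zero differences are dropped (Wilcoxon's convention).  The exact
    null distribution is used for n <= 25 without rank ties; otherwise
    the normal approximation with tie correction.  Raises if every
    pair is tied.
    """
    x = np.asarray(first, dtype=float)
    y = np.asarray(second, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValueError("need two equal-length nonempty 1D value sequences")
    diffs = x - y
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        raise ValueError("all paired differences are zero; test undefined")
    has_ties = np.unique(np.abs(nonzero)).size < nonzero.size
    exact = nonzero.size <= _EXACT_MAX_N and not has_ties
    res = stats.wilcoxon(
        x,
        y,
        zero_method="wilcox",
        alternative="two-sided",
        method="exact" if exact else "approx",
    )
    return GroupComparison(
        values_first=tuple(x),
        values_second=tuple(y),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        exact=exact,
        median_iqr_first=summarize(x),
        median_iqr_second=summarize(y),
        n_pairs=int(x.size),
    )


def summarize(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, Q1, Q3) with the linear-interpolation quantile convention."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarise an empty sequence")
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)


def _paired_metric(
    cohort: Mapping[str, Mapping[str, Mapping[str, float]]],
    arm_first: str,
    arm_second: str,
    metric: str,
) -> tuple[list[float], list[float]]:
    firsts, seconds = [], []
    for subject, arms in cohort.items():
        if arm_first not in arms or arm_second not in arms:
            raise ValueError(f"subject {subject!r} is missing an arm")
        firsts.append(float(arms[arm_first][metric]))
        seconds.append(float(arms[arm_second][metric]))
    return firsts, seconds


def compare_arms(
    cohort: Mapping[str, Mapping[str, Mapping[str, float]]],
    arm_first: str = "raw",
    arm_second: str = "stss",
) -> dict:
    """Paired arm-vs-arm comparison of every metric present in the cohort.

    ``cohort`` maps subject -> arm -> {metric: value}; every subject
    must carry both arms.  Each metric gets median (IQR) per arm and a
    Wilcoxon p.  With a single subject the test is skipped with a
    notice.  Returns a JSON-serialisable report.
    """
    if not cohort:
        raise ValueError("empty cohort")
    subjects = sorted(cohort)
    metrics = sorted(cohort[subjects[0]][arm_first].keys())
    report: dict = {
        "arms": [arm_first, arm_second],
        "n_subjects": len(subjects),
        "subjects": subjects,
        "metrics": {},
        "significance_level": 0.05,
    }
    for metric in metrics:
        firsts, seconds = _paired_metric(cohort, arm_first, arm_second, metric)
        entry: dict = {
            arm_first: {"median": None, "iqr": None, "values": firsts},
            arm_second: {"median": None, "iqr": None, "values": seconds},
        }
        med1, q1a, q3a = summarize(firsts)
        med2, q1b, q3b = summarize(seconds)
        entry[arm_first].update(median=med1, iqr=[q1a, q3a])
        entry[arm_second].update(median=med2, iqr=[q1b, q3b])
        if len(subjects) < 2:
            entry.update(p_value=None, note="single subject: test skipped")
        else:
            try:
                comp = wilcoxon_signed_rank(firsts, seconds)
                entry.update(
                    p_value=comp.p_value,
                    statistic=comp.statistic,
                    exact=comp.exact,
                    note="",
                )
            except ValueError as err:  # all ties
                entry.update(p_value=None, note=str(err))
        report["metrics"][metric] = entry
    return report


def render_table(report: dict) -> str:
    """Human-readable 'median (IQR), p' table for a compare_arms report."""
    arm1, arm2 = report["arms"]
    lines = [
        f"| metric | {arm1} median (IQR) | {arm2} median (IQR) | p |",
        "|---|---|---|---|",
    ]
    for metric, entry in report["metrics"].items():
        def fmt(arm):
            m = entry[arm]["median"]
            lo, hi = entry[arm]["iqr"]
            return f"{m:.3f} ({lo:.3f}-{hi:.3f})"

        p = entry.get("p_value")
        p_str = f"{p:.5g}" if p is not None else entry.get("note", "n/a")
        lines.append(f"| {metric} | {fmt(arm1)} | {fmt(arm2)} | {p_str} |")
    return "\n".join(lines)
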