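"""Cohort summary statistics and the exact paired Wilcoxon signed-rank test.

Small ECMO cohorts (n = 7 animals here) put the signed-rank statistic deep
in its discrete regime, where the commonly used normal approximation is
misleading and exact p-values are required: with seven distinct-magnitude
pairs the smallest achievable two-sided p is 2/2^7 = 0.015625.  The exact
null distribution is computed by dynamic programming over all 2^m sign
assignments, with mid-ranks for tied magnitudes (doubled ranks keep the
arithmetic integral) and a configurable zero-difference policy.

Cohort cells are reported as median (min-max), the convention for small
nonparametric samples, with per-subject percent change used for the
relative vibration metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "PairedSample",
    "SummaryCell",
    "PhaseBlock",
    "CohortSummary",
    "median_min_max",
    "percent_change",
    "wilcoxon_signed_rank_exact",
    "summarize_cohort",
    "SIGNIFICANCE_LEVEL",
    "EXACT_ENUMERATION_LIMIT",
]

#: Two-sided significance threshold used to flag cells.
SIGNIFICANCE_LEVEL = 0.05

#: Largest number of nonzero differences for which the exact null
#: distribution is enumerated; beyond this a normal approximation with
#: continuity correction is used.  Kept generous so that every plausible
#: cohort size in this setting is exact.
EXACT_ENUMERATION_LIMIT = 25


@dataclass
class PairedSample:
    """Paired measurements of one metric under two conditions."""

    baseline: np.ndarray
    condition: np.ndarray
    metric_name: str = ""

    def __post_init__(self) -> None:
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.condition = np.asarray(self.condition, dtype=float)
        if self.baseline.size != self.condition.size:
            raise ValueError("baseline and condition must have equal length")
        if self.baseline.size < 1:
            raise ValueError("need at least one pair")

    @property
    def n(self) -> int:
        return int(self.baseline.size)

    @property
    def differences(self) -> np.ndarray:
        return self.condition - self.baseline


def median_min_max(x) -> tuple[float, float, float]:
    """Median (mean of the two middle order statistics for even n), min, max."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    return float(np.median(x)), float(np.min(x)), float(np.max(x))


def percent_change(baseline: float, value: float) -> float:
    """Relative change ``100 * (value - baseline) / baseline`` in percent."""
    if baseline == 0:
        raise ZeroDivisionError("percent change undefined for zero baseline")
    return 100.0 * (value - baseline) / baseline


# ---------------------------------------------------------------------------
# Exact Wilcoxon signed-rank test


def _signed_rank_setup(d: np.ndarray, zero_policy: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (doubled mid-ranks of nonzero |d|, signs of nonzero d).

    Under ``drop`` zeros are discarded before ranking; under ``pratt`` they
    participate in the ranking but carry no sign.  Doubling the mid-ranks
    makes every rank an exact integer even with ties.
    """
    if zero_policy == "drop":
        d = d[d != 0]
        if d.size == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        ranks = rankdata(np.abs(d), method="average")
    elif zero_policy == "pratt":
        nz = d != 0
        ranks_all = rankdata(np.abs(d), method="average")
        ranks = ranks_all[nz]
        d = d[nz]
    else:
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    doubled = np.rint(2 * ranks).astype(np.int64)
    return doubled, np.sign(d).astype(np.int64)


def _exact_tail_probs(doubled: np.ndarray, w_doubled: int) -> tuple[float, float]:
    """P(W <= w) and P(W >= w) by DP over all 2^m sign assignments.

    ``counts[s]`` accumulates the number of sign assignments whose positive
    doubled-rank sum equals ``s``; integer arithmetic throughout, so the
    tail probabilities are exact up to the final float division.
    """
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=object)
    counts[0] = 1
    for r in doubled:
        r = int(r)
        counts[r:] = counts[r:] + counts[:-r]
    denom = 1 << len(doubled)
    p_le = int(sum(counts[: w_doubled + 1])) / denom
    p_ge = int(sum(counts[w_doubled:])) / denom
    return p_le, p_ge


def _normal_tail_probs(doubled: np.ndarray, w_doubled: int) -> tuple[float, float]:
    """Normal approximation with continuity correction (large m fallback).

    Mean and variance of W follow directly from the symmetric +/- assignment
    of each rank; mid-rank ties are handled by using the actual rank values
    in the variance.
    """
    mu = doubled.sum() / 2.0
    sigma = math.sqrt(float((doubled.astype(float) ** 2).sum()) / 4.0)
    # half a (doubled) rank unit of continuity correction
    z_le = (w_doubled - mu + 1.0) / sigma
    z_ge = (w_doubled - mu - 1.0) / sigma
    from scipy.stats import norm

    return float(norm.cdf(z_le)), float(norm.sf(z_ge))


def wilcoxon_signed_rank_exact(
    sample: PairedSample,
    zero_policy: str = "drop",
    alternative: str = "two_sided",
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test with an exact small-sample p-value.

    Differences ``d_i = condition - baseline`` are ranked by magnitude with
    mid-ranks for ties; ``W`` is the sum of ranks of positive differences.
    For up to :data:`EXACT_ENUMERATION_LIMIT` nonzero differences the null
    distribution of ``W`` is enumerated exactly; the two-sided p-value is
    ``min(1, 2 * min(P(W <= w), P(W >= w)))``.  If every difference is zero
    under the ``drop`` policy the test is vacuous and ``(W, p) = (0, 1.0)``.

    Returns
    -------
    (W, p)
        ``W`` in ordinary rank units (may be half-integral with ties).
    """
    if alternative not in {"two_sided", "greater", "less"}:
        raise ValueError(f"unknown alternative {alternative!r}")
    doubled, signs = _signed_rank_setup(sample.differences, zero_policy)
    if doubled.size == 0:
        return 0.0, 1.0
    w_doubled = int(doubled[signs > 0].sum())
    if doubled.size <= EXACT_ENUMERATION_LIMIT:
        p_le, p_ge = _exact_tail_probs(doubled, w_doubled)
    else:
        p_le, p_ge = _normal_tail_probs(doubled, w_doubled)
    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_le, p_ge))
    return w_doubled / 2.0, float(p)


# ---------------------------------------------------------------------------
# Cohort summaries


@dataclass
class SummaryCell:
    """One Table-style cell: median (min-max) with an optional paired p."""

    median: float
    min: float
    max: float
    n: int
    p_vs_baseline: float | None = None

    def __post_init__(self) -> None:
        if not (self.min <= self.median <= self.max):
            raise ValueError("require min <= median <= max")

    @property
    def significant(self) -> bool:
        return self.p_vs_baseline is not None and self.p_vs_baseline <= SIGNIFICANCE_LEVEL


@dataclass(frozen=True)
class PhaseBlock:
    """A baseline column and the condition columns tested against it."""

    name: str
    baseline: str
    conditions: tuple[str, ...]


@dataclass
class CohortSummary:
    """Grid of summary cells indexed by (block, metric, timepoint)."""

    cells: dict[tuple[str, str, str], SummaryCell]
    blocks: list[PhaseBlock]
    metrics: list[str]

    def to_frame(self) -> pd.DataFrame:
        """Tidy machine-readable table with unrounded values."""
        rows = []
        for block in self.blocks:
            for metric in self.metrics:
                for tp in (block.baseline, *block.conditions):
                    cell = self.cells.get((block.name, metric, tp))
                    if cell is None:
                        continue
                    rows.append(
                        {
                            "block": block.name,
                            "metric": metric,
                            "timepoint": tp,
                            "n": cell.n,
                            "median": cell.median,
                            "min": cell.min,
                            "max": cell.max,
                            "p": cell.p_vs_baseline,
                            "p_rounded": None
                            if cell.p_vs_baseline is None
                            else round(cell.p_vs_baseline, 2),
                            "significant": cell.significant,
                        }
                    )
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        """Aligned human-readable table, one block at a time.

        Values are printed to three significant figures as
        ``median (min - max)``; p-values to two decimals with ``*`` marking
        significance at p <= 0.05.
        """

        def sig3(v: float) -> str:
            if v == 0 or not np.isfinite(v):
                return f"{v:g}"
            return f"{v:.3g}"

        lines = []
        for block in self.blocks:
            cols = [block.baseline, *block.conditions]
            header = [f"{block.name} metric"] + [
                c if c == block.baseline else f"{c} | p" for c in cols
            ]
            table_rows = [header]
            for metric in self.metrics:
                row = [metric]
                for tp in cols:
                    cell = self.cells.get((block.name, metric, tp))
                    if cell is None:
                        row.append("N/A")
                        continue
                    txt = f"{sig3(cell.median)} ({sig3(cell.min)} - {sig3(cell.max)})"
                    if cell.p_vs_baseline is not None:
                        mark = "*" if cell.significant else ""
                        txt += f" | {cell.p_vs_baseline:.2f}{mark}"
                    row.append(txt)
                table_rows.append(row)
            widths = [max(len(r[i]) for r in table_rows) for i in range(len(header))]
            for r in table_rows:
                lines.append("  ".join(c.ljust(w) for c, w in zip(r, widths)))
            lines.append("")
        lines.append("Data as median (min - max); * p <= 0.05 (exact Wilcoxon signed-rank)")
        return "\n".join(lines)


def _paired(
    df: pd.DataFrame, metric: str, baseline: str, condition: str
) -> tuple[np.ndarray, np.ndarray]:
    """Align per-subject values at two timepoints; subjects missing either
    timepoint are dropped from the pairing (cells stay annotated with n)."""
    sub = df[df["metric"] == metric]
    base = sub[sub["timepoint"] == baseline].set_index("subject")["value"]
    cond = sub[sub["timepoint"] == condition].set_index("subject")["value"]
    common = base.index.intersection(cond.index)
    return base.loc[common].to_numpy(), cond.loc[common].to_numpy()


def summarize_cohort(
    metric_table: pd.DataFrame,
    blocks: list[PhaseBlock],
    relative_metrics: dict[str, str] | None = None,
    zero_policy: str = "drop",
) -> CohortSummary:
    """Build the Table-style cohort summary from a tidy metric table.

    Parameters
    ----------
    metric_table
        Columns ``subject, metric, timepoint, value`` — one value per
        subject x metric x timepoint.
    blocks
        Phase blocks, each naming its baseline timepoint and the condition
        timepoints tested against it with the exact signed-rank test.
    relative_metrics
        Mapping ``source metric -> derived metric name``; for each entry a
        per-subject percent change from the block baseline is computed and
        summarized, with its p from a signed-rank test of the changes
        against zero (equivalently, of the source pairs).

    Cells with a single available pair carry no p-value.
    """
    if relative_metrics is None:
        relative_metrics = {"rms_oxy": "delta_rms_oxy_pct"}
    required = {"subject", "metric", "timepoint", "value"}
    if not required.issubset(metric_table.columns):
        raise ValueError(f"metric table must have columns {sorted(required)}")

    cells: dict[tuple[str, str, str], SummaryCell] = {}
    base_metrics = list(dict.fromkeys(metric_table["metric"]))
    metrics = list(base_metrics)
    for src, derived in relative_metrics.items():
        if src in base_metrics:
            metrics.insert(metrics.index(src) + 1, derived)

    for block in blocks:
        for metric in base_metrics:
            sub = metric_table[metric_table["metric"] == metric]
            for tp in (block.baseline, *block.conditions):
                vals = sub[sub["timepoint"] == tp]["value"].to_numpy()
                if vals.size == 0:
                    continue
                med, lo, hi = median_min_max(vals)
                p = None
                if tp != block.baseline:
                    b, c = _paired(metric_table, metric, block.baseline, tp)
                    if b.size >= 2:
                        _, p = wilcoxon_signed_rank_exact(
                            PairedSample(b, c, metric), zero_policy=zero_policy
                        )
                cells[(block.name, metric, tp)] = SummaryCell(
                    median=med, min=lo, max=hi, n=int(vals.size), p_vs_baseline=p
                )
            derived = relative_metrics.get(metric)
            if derived is None:
                continue
            for tp in block.conditions:
                b, c = _paired(metric_table, metric, block.baseline, tp)
                if b.size == 0:
                    continue
                changes = np.array(
                    [percent_change(bi, ci) for bi, ci in zip(b, c)]
                )
                med, lo, hi = median_min_max(changes)
                p = None
                if changes.size >= 2:
                    _, p = wilcoxon_signed_rank_exact(
                        PairedSample(np.zeros_like(changes), changes, derived),
                        zero_policy=zero_policy,
                    )
                cells[(block.name, derived, tp)] = SummaryCell(
                    median=med, min=lo, max=hi, n=int(changes.size), p_vs_baseline=p
                )
    return CohortSummary(cells=cells, blocks=list(blocks), metrics=metrics)
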