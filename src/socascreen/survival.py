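"""Virtual double-knockdown survival screen.

For every gene pair in the knockout library, a patient cohort is stratified
by the mean normalised expression of the two genes: samples in the bottom
quartile (cutoff-low, 0-25) versus the top quartile (cutoff-high, 75-100).
Survival of the two strata is compared with a Kaplan-Meier / log-rank test,
giving a pair p-value, and likewise for each gene alone.  The pair score
against gene X is

    score_X = log1p(p_pair / p_X)            (literal orientation)
    score_X = log1p(p_X / p_pair)            (reciprocal orientation)

and a pair is classified non-neutral only when both scores exceed 1:
*favourable* when the low-expression stratum survives longer (joint loss is
protective — the virtual analogue of a beneficial double knockdown),
*unfavourable* when it survives worse.  The reciprocal orientation highlights
pairs whose joint stratification separates survival more strongly than either
single gene; the literal orientation is the ratio as written.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

__all__ = [
    "ExpressionCohort",
    "LogrankResult",
    "pair_mean_expression",
    "percentile_groups",
    "km_curve",
    "logrank_p",
    "pair_scores",
    "survival_direction",
    "VirtualScreen",
    "VirtualScreenResults",
]


@dataclass
class ExpressionCohort:
    """Expression-by-sample table with overall-survival follow-up.

    ``expression`` is samples x genes of non-negative normalised values
    (upper-quartile FPKM semantics); ``time`` is survival time in days;
    ``event`` is 1 for death, 0 for censoring; ``exclude`` optionally marks
    samples to drop (e.g. viral-aetiology exclusions) before screening.
    """

    expression: pd.DataFrame
    time: pd.Series
    event: pd.Series
    exclude: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.expression.columns.duplicated().any():
            raise ValueError("gene names must be unique")
        for series, what in ((self.time, "time"), (self.event, "event")):
            if not series.index.equals(self.expression.index):
                raise ValueError(f"{what} index must match expression samples")
            if series.isna().any():
                raise ValueError(f"missing values in {what}")
        if (self.time <= 0).any():
            raise ValueError("survival times must be positive")
        if not self.event.isin([0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")
        if (self.expression.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def samples(self) -> pd.Index:
        return self.expression.index

    @property
    def genes(self) -> pd.Index:
        return self.expression.columns

    def filtered(self) -> "ExpressionCohort":
        """Cohort with excluded samples removed."""
        if self.exclude is None:
            return self
        keep = self.samples[~self.exclude.reindex(self.samples).fillna(False).astype(bool)]
        return ExpressionCohort(
            expression=self.expression.loc[keep],
            time=self.time.loc[keep],
            event=self.event.loc[keep],
        )

    @classmethod
    def from_tables(
        cls, expression_tsv: str | Path, survival_tsv: str | Path
    ) -> "ExpressionCohort":
        """Load from an expression TSV (samples x genes, first column = sample)
        and a survival TSV with columns sample, time, event[, exclude]."""
        expr = pd.read_csv(expression_tsv, sep="\t", index_col=0)
        surv = pd.read_csv(survival_tsv, sep="\t", index_col=0)
        surv = surv.reindex(expr.index)
        exclude = surv["exclude"].astype(bool) if "exclude" in surv else None
        return cls(
            expression=expr,
            time=surv["time"].astype(float),
            event=surv["event"].astype(int),
            exclude=exclude,
        )


def pair_mean_expression(cohort: ExpressionCohort, gene_a: str, gene_b: str) -> pd.Series:
    """Per-sample arithmetic mean of the two genes' normalised expression."""
    for gene in (gene_a, gene_b):
        if gene not in cohort.genes:
            raise KeyError(f"gene {gene!r} not in cohort expression table")
    return cohort.expression[[gene_a, gene_b]].mean(axis=1)


def percentile_groups(
    values: pd.Series, low_pct: float = 25.0, high_pct: float = 75.0
) -> pd.Series:
    """Quartile stratification labels: 'low', 'high' or 'excluded'.

    low = values at or below the ``low_pct`` percentile, high = values at or
    above the ``high_pct`` percentile (linear-interpolation percentiles;
    boundary-equal samples are included in their group); everything between
    is excluded.
    """
    if len(values) < 8:
        raise ValueError("need at least 8 samples to stratify")
    arr = values.to_numpy(dtype=float)
    if np.ptp(arr) == 0:
        raise ValueError("constant values cannot be stratified")
    lo, hi = np.percentile(arr, [low_pct, high_pct])
    labels = np.where(arr <= lo, "low", np.where(arr >= hi, "high", "excluded"))
    return pd.Series(labels, index=values.index, name="group")


def km_curve(
    time: Sequence[float] | pd.Series, event: Sequence[int] | pd.Series
) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan-Meier product-limit estimate: (times, survival probabilities).

    Right-continuous step function starting at S(0) = 1; drops only at event
    times.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("empty survival data")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


@dataclass(frozen=True)
class LogrankResult:
    chi2: float
    p: float
    degenerate: bool = False


def logrank_p(
    group1: tuple[Sequence[float], Sequence[int]],
    group2: tuple[Sequence[float], Sequence[int]],
) -> LogrankResult:
    """Mantel-Cox log-rank test between two survival groups (1 df).

    When neither group has any event the test is undefined and
    (chi2 = 0, p = 1, degenerate) is returned.
    """
    t1, e1 = (np.asarray(v, dtype=float) for v in group1)
    t2, e2 = (np.asarray(v, dtype=float) for v in group2)
    if t1.size == 0 or t2.size == 0:
        raise ValueError("both groups must be non-empty")
    if e1.sum() + e2.sum() == 0:
        return LogrankResult(chi2=0.0, p=1.0, degenerate=True)
    res = logrank_test(t1, t2, event_observed_A=e1, event_observed_B=e2)
    return LogrankResult(chi2=float(res.test_statistic), p=float(res.p_value))


def pair_scores(
    p_pair: float, p_gene_a: float, p_gene_b: float, orientation: str = "literal"
) -> tuple[float, float]:
    """log1p p-ratio scores of a pair against each of its genes.

    literal: log1p(p_pair / p_X); reciprocal: log1p(p_X / p_pair).  Natural
    logarithm; a score crosses the classification threshold 1 when the ratio
    exceeds e - 1.
    """
    for name, p in (("p_pair", p_pair), ("p_gene_a", p_gene_a), ("p_gene_b", p_gene_b)):
        if not 0 < p <= 1:
            raise ValueError(f"{name} must lie in (0, 1], got {p}")
    if orientation == "literal":
        return math.log1p(p_pair / p_gene_a), math.log1p(p_pair / p_gene_b)
    if orientation == "reciprocal":
        return math.log1p(p_gene_a / p_pair), math.log1p(p_gene_b / p_pair)
    raise ValueError("orientation must be 'literal' or 'reciprocal'")


def survival_direction(
    time: pd.Series, event: pd.Series, labels: pd.Series
) -> str:
    """'low_better' if the low-expression stratum survives longer, else
    'high_better'.  Compares KM median survival; if neither median is reached,
    falls back to the final KM survival probability."""
    stats = {}
    for group in ("low", "high"):
        mask = labels == group
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event_observed=event[mask])
        stats[group] = (
            float(kmf.median_survival_time_),
            float(kmf.survival_function_.iloc[-1, 0]),
        )
    med_low, final_low = stats["low"]
    med_high, final_high = stats["high"]
    if math.isfinite(med_low) or math.isfinite(med_high):
        if not math.isfinite(med_low):
            return "low_better"
        if not math.isfinite(med_high):
            return "high_better"
        return "low_better" if med_low > med_high else "high_better"
    return "low_better" if final_low >= final_high else "high_better"


class VirtualScreen:
    """Virtual double-knockdown screen over a cohort and a pair list.

    Parameters
    ----------
    cohort :
        expression + survival cohort; excluded samples are dropped first.
    pairs :
        iterable of (gene_a, gene_b) tuples — typically the library's DKO pairs.
    orientation :
        'literal' (p_pair / p_single, the ratio as defined) or 'reciprocal'
        (p_single / p_pair, highlighting stronger joint stratification).
    """

    def __init__(
        self,
        cohort: ExpressionCohort,
        pairs: Sequence[tuple[str, str]],
        orientation: str = "literal",
        low_pct: float = 25.0,
        high_pct: float = 75.0,
    ) -> None:
        if orientation not in {"literal", "reciprocal"}:
            raise ValueError("orientation must be 'literal' or 'reciprocal'")
        self.cohort = cohort.filtered()
        if len(self.cohort.samples) < 8:
            raise ValueError("need at least 8 usable samples")
        self.pairs = [tuple(p) for p in pairs]
        self.orientation = orientation
        self.low_pct = low_pct
        self.high_pct = high_pct
        self._gene_cache: dict[str, tuple[float, pd.Series]] = {}

    def _stratified_p(self, values: pd.Series) -> tuple[float, pd.Series]:
        labels = percentile_groups(values, self.low_pct, self.high_pct)
        time, event = self.cohort.time, self.cohort.event
        low, high = labels == "low", labels == "high"
        res = logrank_p(
            (time[low], event[low]), (time[high], event[high])
        )
        return res.p, labels

    def _gene_p(self, gene: str) -> float:
        if gene not in self._gene_cache:
            self._gene_cache[gene] = self._stratified_p(self.cohort.expression[gene])
        return self._gene_cache[gene][0]

    def fit(self) -> "VirtualScreenResults":
        rows = []
        skipped: dict[str, str] = {}
        for gene_a, gene_b in self.pairs:
            label = f"{gene_a}__{gene_b}"
            try:
                p_a = self._gene_p(gene_a)
                p_b = self._gene_p(gene_b)
                mean_expr = pair_mean_expression(self.cohort, gene_a, gene_b)
                p_pair, labels = self._stratified_p(mean_expr)
                score_a, score_b = pair_scores(p_pair, p_a, p_b, self.orientation)
            except (KeyError, ValueError) as err:
                skipped[label] = str(err)
                continue
            if not (math.isfinite(score_a) and math.isfinite(score_b)):
                skipped[label] = "removing outlier value (non-finite score)"
                continue
            direction = survival_direction(self.cohort.time, self.cohort.event, labels)
            if score_a > 1 and score_b > 1:
                classification = "favourable" if direction == "low_better" else "unfavourable"
            else:
                classification = "neutral"
            rows.append(
                {
                    "pair": label,
                    "gene_a": gene_a,
                    "gene_b": gene_b,
                    "p_pair": p_pair,
                    "p_gene_a": p_a,
                    "p_gene_b": p_b,
                    "score_a": score_a,
                    "score_b": score_b,
                    "direction": direction,
                    "classification": classification,
                }
            )
        table = pd.DataFrame(rows).set_index("pair") if rows else pd.DataFrame()
        return VirtualScreenResults(self, table, skipped)


class VirtualScreenResults:
    """Per-pair survival-screen scores and classifications."""

    def __init__(
        self, screen: VirtualScreen, table: pd.DataFrame, skipped: dict[str, str]
    ) -> None:
        self.screen = screen
        self.table = table
        self.skipped = skipped

    def classified(self, classification: str) -> pd.DataFrame:
        return self.table[self.table["classification"] == classification]

    def summary(self) -> str:
        n = len(self.table)
        fav = len(self.classified("favourable"))
        unfav = len(self.classified("unfavourable"))
        lines = [
            "Virtual double-knockdown survival screen",
            f"  cohort: {len(self.screen.cohort.samples)} samples, "
            f"{int(self.screen.cohort.event.sum())} events",
            f"  orientation: {self.screen.orientation}",
            f"  pairs tested: {n} (skipped: {len(self.skipped)})",
            f"  favourable: {fav}   unfavourable: {unfav}   neutral: {n - fav - unfav}",
        ]
        for label, row in self.table[self.table["classification"] != "neutral"].iterrows():
            lines.append(
                f"      {label}  {row['classification']}  p_pair={row['p_pair']:.3g}"
            )
        return "\n".join(lines)

    def plot_scores(self, ax=None):
        """Score_A vs score_B scatter coloured by classification."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        colours = {"favourable": "royalblue", "unfavourable": "crimson", "neutral": "grey"}
        for cls, colour in colours.items():
            sub = self.classified(cls)
            if len(sub):
                ax.scatter(sub["score_a"], sub["score_b"], s=14, c=colour, label=cls)
        ax.axvline(1.0, ls="--", lw=0.8, c="k")
        ax.axhline(1.0, ls="--", lw=0.8, c="k")
        ax.set_xlabel("score vs gene A")
        ax.set_ylabel("score vs gene B")
        ax.legend(frameon=False, fontsize=8)
        return ax
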