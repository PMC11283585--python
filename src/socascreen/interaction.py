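"""Genetic-interaction calling for dual-crRNA double-knockout screens.

Two complementary models flag synergistic gene pairs, both operating on
reads-per-million (rpm) abundances of the crRNA arrays:

1. **Enrichment outlier model.**  For each gene pair the control-normalised
   observed double-knockout enrichment

       observed = (D_t / D_c) * (N_c / N_t)

   is regressed on the additive expectation from the two single knockouts

       expected = (A_t / A_c) * (N_c / N_t) + (B_t / B_c) * (N_c / N_t)

   where D, A, B, N are median abundances of the pair's DKO array, gene A's
   SKO arrays, gene B's SKO arrays and the NTC-NTC arrays, in the tumour (_t)
   and cell (_c) screens.  Pairs whose observed enrichment is an outlier of
   the linear fit (externally studentized residual, two-sided t test,
   Benjamini-Hochberg adjusted p < alpha) are called; negative residuals mean
   depletion beyond the additive expectation — synergy under negative
   selection.

2. **Rank-sum model.**  Per pair, the DKO array's per-sample log2 fold-changes
   are compared with the pooled LFCs of both genes' SKO arrays by a two-sided
   Wilcoxon rank-sum test, BH-adjusted across pairs.

A third screen regresses per-entity tumour abundance on cell abundance
(DKO arrays plus per-gene collapsed SKOs, log2 rpm scale) and flags outliers
the same way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.outliers_influence import OLSInfluence

from .library import Category, LibraryDesign
from .quantify import SampleInfo, collapse_sko_per_gene, compute_lfc

__all__ = [
    "MedianAbundanceSummary",
    "bh_adjust",
    "studentized_outlier_test",
    "wilcoxon_rank_sum",
    "observed_dko_enrichment",
    "expected_dko_enrichment",
    "median_abundance_summaries",
    "synergy_by_enrichment",
    "synergy_by_rank_test",
    "regression_cell_vs_tumour",
    "InteractionModel",
    "InteractionResults",
]


def bh_adjust(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved, <= 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def studentized_outlier_test(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    labels: Sequence | None = None,
) -> pd.DataFrame:
    """Regression outlier test: externally studentized residuals of y ~ x.

    Fits ordinary least squares, computes the externally studentized residual
    t_i of every point, its two-sided p from a t distribution with n - 3
    degrees of freedom (n points minus two regression parameters minus the
    deleted observation), and BH-adjusted p over all n points.  Rows are
    sorted by |t_i| descending.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = x.size
    if n < 4:
        raise ValueError("outlier test needs at least 4 points")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance; regression is degenerate")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    scale = max(float(np.sum((y - y.mean()) ** 2)), float(np.sum(y**2)), 1.0)
    if fit.ssr <= 1e-12 * scale:
        # numerically perfect fit: no point is an outlier
        t = np.zeros(n)
    else:
        t = OLSInfluence(fit).resid_studentized_external
        t = np.where(np.isnan(t), 0.0, t)
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 3)
    out = pd.DataFrame(
        {
            "studentized_residual": t,
            "p": p,
            "p_adj": bh_adjust(p),
        },
        index=pd.Index(labels if labels is not None else np.arange(n), name="point_id"),
    )
    return out.reindex(out["studentized_residual"].abs().sort_values(ascending=False).index)


def wilcoxon_rank_sum(
    xs: Sequence[float] | np.ndarray, ys: Sequence[float] | np.ndarray
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U of xs) and its p-value.

    Uses the exact null distribution for small tie-free samples (both at most
    8 observations, or at most 10 in total), otherwise the normal
    approximation with tie and continuity corrections.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([xs, ys])
    no_ties = np.unique(pooled).size == pooled.size
    small = (xs.size <= 8 and ys.size <= 8) or (xs.size + ys.size <= 10)
    method = "exact" if (small and no_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(
        xs, ys, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class MedianAbundanceSummary:
    """The eight median abundances feeding the enrichment formulas for one pair."""

    pair: tuple[str, str]
    D_t: float
    D_c: float
    A_t: float
    A_c: float
    B_t: float
    B_c: float
    N_t: float
    N_c: float

    def __post_init__(self) -> None:
        for name in ("D_t", "D_c", "A_t", "A_c", "B_t", "B_c", "N_t", "N_c"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _require_positive(summary: MedianAbundanceSummary, names: tuple[str, ...]) -> None:
    for name in names:
        if getattr(summary, name) <= 0:
            raise ZeroDivisionError(
                f"pair {summary.pair}: median {name} is zero; enrichment undefined"
            )


def observed_dko_enrichment(s: MedianAbundanceSummary) -> float:
    """(D_t/D_c) * (N_c/N_t): NTC-normalised double-knockout abundance change."""
    _require_positive(s, ("D_c", "N_t"))
    return (s.D_t / s.D_c) * (s.N_c / s.N_t)


def expected_dko_enrichment(s: MedianAbundanceSummary) -> float:
    """Additive single-gene expectation: gene A enrichment + gene B enrichment."""
    _require_positive(s, ("A_c", "B_c", "N_t"))
    return (s.A_t / s.A_c) * (s.N_c / s.N_t) + (s.B_t / s.B_c) * (s.N_c / s.N_t)


def median_abundance_summaries(
    rpm: pd.DataFrame,
    design: LibraryDesign,
    cell_samples: Sequence[str],
    tumour_samples: Sequence[str],
) -> list[MedianAbundanceSummary]:
    """Median rpm summaries per DKO pair.

    D medians are taken across the condition's replicate samples of the pair's
    DKO array; A/B medians across all array x sample values of the gene's SKO
    arrays; N across all NTC-NTC array x sample values.
    """
    cell_samples = list(cell_samples)
    tumour_samples = list(tumour_samples)
    ntc_ids = [a.array_id for a in design.by_category(Category.NTC_NTC)]
    if not ntc_ids:
        raise ValueError("design has no NTC-NTC arrays")
    N_t = float(np.median(rpm.loc[ntc_ids, tumour_samples].to_numpy()))
    N_c = float(np.median(rpm.loc[ntc_ids, cell_samples].to_numpy()))

    def sko_median(gene: str, cols: list[str]) -> float:
        ids = [a.array_id for a in design.sko_arrays_for(gene)]
        if not ids:
            raise ValueError(f"gene {gene!r} has no SKO arrays")
        return float(np.median(rpm.loc[ids, cols].to_numpy()))

    out = []
    for a in design.by_category(Category.DKO):
        gene_a, gene_b = a.pos1.name, a.pos2.name
        out.append(
            MedianAbundanceSummary(
                pair=(gene_a, gene_b),
                D_t=float(rpm.loc[a.array_id, tumour_samples].median()),
                D_c=float(rpm.loc[a.array_id, cell_samples].median()),
                A_t=sko_median(gene_a, tumour_samples),
                A_c=sko_median(gene_a, cell_samples),
                B_t=sko_median(gene_b, tumour_samples),
                B_c=sko_median(gene_b, cell_samples),
                N_t=N_t,
                N_c=N_c,
            )
        )
    return out


def _pair_label(pair: tuple[str, str]) -> str:
    return f"{pair[0]}__{pair[1]}"


def synergy_by_enrichment(
    summaries: Sequence[MedianAbundanceSummary],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Observed-vs-expected enrichment outlier calls.

    Returns a DataFrame (index = pair label, sorted by |residual| descending)
    and a dict of skipped pairs with reasons.  ``significant`` is BH-adjusted
    p < alpha; a negative residual means the double knockout is depleted
    beyond the additive expectation.
    """
    labels, obs, exp = [], [], []
    skipped: dict[str, str] = {}
    for s in summaries:
        try:
            o = observed_dko_enrichment(s)
            e = expected_dko_enrichment(s)
        except ZeroDivisionError as err:
            skipped[_pair_label(s.pair)] = str(err)
            continue
        labels.append(_pair_label(s.pair))
        obs.append(o)
        exp.append(e)
    if len(labels) < 4:
        raise ValueError("need at least 4 computable pairs for the outlier test")
    table = studentized_outlier_test(exp, obs, labels=labels)
    table.insert(0, "expected", pd.Series(exp, index=labels).reindex(table.index))
    table.insert(0, "observed", pd.Series(obs, index=labels).reindex(table.index))
    table["significant"] = table["p_adj"] < alpha
    table.index.name = "pair"
    return table, skipped


def synergy_by_rank_test(
    lfc: pd.DataFrame,
    design: LibraryDesign,
    alpha: float = 0.05,
    strategy: str = "pooled",
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Per-pair Wilcoxon rank-sum of DKO LFCs versus SKO LFCs.

    ``lfc`` is an arrays x samples table of log2 fold-changes.  For each DKO
    pair, xs are the DKO array's per-sample LFCs; ys are the per-sample LFCs
    of the two genes' SKO arrays, pooled (``strategy='pooled'``) or the more
    conservative of the two per-gene tests (``strategy='per_gene_max'``).
    BH adjustment across all tested pairs.
    """
    if strategy not in {"pooled", "per_gene_max"}:
        raise ValueError("strategy must be 'pooled' or 'per_gene_max'")
    rows = []
    skipped: dict[str, str] = {}
    for a in design.by_category(Category.DKO):
        label = a.array_id
        gene_a, gene_b = a.pos1.name, a.pos2.name
        if a.array_id not in lfc.index:
            skipped[label] = "DKO array missing from LFC table"
            continue
        xs = lfc.loc[a.array_id].to_numpy(dtype=float)
        sko_a = [s.array_id for s in design.sko_arrays_for(gene_a) if s.array_id in lfc.index]
        sko_b = [s.array_id for s in design.sko_arrays_for(gene_b) if s.array_id in lfc.index]
        if not sko_a or not sko_b:
            skipped[label] = "missing SKO arrays for one or both genes"
            continue
        if strategy == "pooled":
            ys = lfc.loc[sko_a + sko_b].to_numpy(dtype=float).ravel()
            w, p = wilcoxon_rank_sum(xs, ys)
        else:
            results = [
                wilcoxon_rank_sum(xs, lfc.loc[ids].to_numpy(dtype=float).ravel())
                for ids in (sko_a, sko_b)
            ]
            w, p = max(results, key=lambda wp: wp[1])
        rows.append(
            {
                "pair": label,
                "gene_a": gene_a,
                "gene_b": gene_b,
                "median_dko_lfc": float(np.median(xs)),
                "W": w,
                "p": p,
            }
        )
    if not rows:
        raise ValueError("no testable DKO pairs")
    table = pd.DataFrame(rows).set_index("pair")
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["p_adj"] < alpha
    return table.sort_values("p_adj"), skipped


def regression_cell_vs_tumour(
    cell: pd.Series,
    tumour: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Outlier screen on the tumour ~ cell abundance regression.

    ``cell`` and ``tumour`` are per-entity abundances (DKO arrays plus
    per-gene collapsed SKOs, log2 rpm scale) sharing an index.  Entities whose
    tumour abundance falls off the fitted line (BH-adjusted two-sided
    studentized-residual p < alpha) are flagged.
    """
    if set(cell.index) != set(tumour.index):
        raise ValueError("cell and tumour abundances must cover the same entities")
    tumour = tumour.reindex(cell.index)
    table = studentized_outlier_test(
        cell.to_numpy(dtype=float), tumour.to_numpy(dtype=float), labels=cell.index
    )
    table.insert(0, "tumour", tumour.reindex(table.index))
    table.insert(0, "cell", cell.reindex(table.index))
    table["significant"] = table["p_adj"] < alpha
    table.index.name = "entity"
    return table


class InteractionModel:
    """Genetic-interaction model over a screen's rpm abundance matrix.

    Parameters
    ----------
    rpm :
        arrays x samples reads-per-million table (all library arrays present).
    design :
        the library the screen used.
    sample_info :
        one :class:`~socascreen.quantify.SampleInfo` per rpm column, in column
        order.  Sample roles are derived from it: the *initial* and *cell
        screen* samples both default to the earliest cell timepoint — the
        injected cell pool is the comparator the tumour screens are measured
        against — and the *tumour screen* samples to all tumour columns; each
        can be overridden explicitly (e.g. ``cell_samples`` set to the day-14
        columns to contrast tumours with the in-vitro endpoint instead).
    pseudocount_rpm :
        pseudocount used for fold-changes and log2 abundances (default 1 rpm).
    """

    def __init__(
        self,
        rpm: pd.DataFrame,
        design: LibraryDesign,
        sample_info: Sequence[SampleInfo],
        *,
        initial_samples: Sequence[str] | None = None,
        cell_samples: Sequence[str] | None = None,
        tumour_samples: Sequence[str] | None = None,
        pseudocount_rpm: float = 1.0,
        rank_strategy: str = "pooled",
        sko_statistic: str = "mean",
    ) -> None:
        if list(rpm.columns) != [s.sample_id for s in sample_info]:
            raise ValueError("sample_info must match rpm columns in order")
        missing = set(design.array_ids) - set(rpm.index)
        if missing:
            raise ValueError(f"rpm table is missing {len(missing)} design arrays")
        self.rpm = rpm.loc[design.array_ids]
        self.design = design
        self.sample_info = list(sample_info)
        self.pseudocount_rpm = pseudocount_rpm
        self.rank_strategy = rank_strategy
        self.sko_statistic = sko_statistic

        by_cond: dict[str, list[SampleInfo]] = {"plasmid": [], "cell": [], "tumour": []}
        for s in self.sample_info:
            by_cond[s.condition].append(s)
        cells = by_cond["cell"]
        if initial_samples is None:
            if not cells:
                raise ValueError("no cell samples; pass initial_samples explicitly")
            t0 = min(s.timepoint_days for s in cells)
            initial_samples = [s.sample_id for s in cells if s.timepoint_days == t0]
        if cell_samples is None:
            cell_samples = list(initial_samples)
        if tumour_samples is None:
            tumour_samples = [s.sample_id for s in by_cond["tumour"]]
        if not tumour_samples:
            raise ValueError("no tumour samples; pass tumour_samples explicitly")
        self.initial_samples = list(initial_samples)
        self.cell_samples = list(cell_samples)
        self.tumour_samples = list(tumour_samples)

    # -- derived inputs ----------------------------------------------------

    def tumour_lfc(self) -> pd.DataFrame:
        """Per-tumour-sample LFC versus the mean initial-cell abundance."""
        initial = self.rpm[self.initial_samples].mean(axis=1)
        cols = {
            col: compute_lfc(self.rpm[col], initial, self.pseudocount_rpm)["lfc"]
            for col in self.tumour_samples
        }
        return pd.DataFrame(cols)

    def _log2_entity_abundance(self, columns: list[str]) -> pd.Series:
        log2 = np.log2(self.rpm[columns] + self.pseudocount_rpm)
        mean_log2 = log2.mean(axis=1)
        dko_ids = [a.array_id for a in self.design.by_category(Category.DKO)]
        dko = mean_log2.loc[dko_ids]
        sko = collapse_sko_per_gene(mean_log2, self.design, statistic=self.sko_statistic)
        return pd.concat([dko, sko])

    # -- fitting -----------------------------------------------------------

    def fit(self, model: str = "all", alpha: float = 0.05) -> "InteractionResults":
        """Run the requested interaction model(s) and return results.

        ``model`` is ``'enrichment'``, ``'ranksum'``, ``'regression'`` or
        ``'all'``; ``alpha`` is the threshold on BH-adjusted p-values.
        """
        if model not in {"enrichment", "ranksum", "regression", "all"}:
            raise ValueError(f"unknown model {model!r}")
        enrichment = ranksum = regression = None
        skipped: dict[str, dict[str, str]] = {}
        if model in {"enrichment", "all"}:
            summaries = median_abundance_summaries(
                self.rpm, self.design, self.cell_samples, self.tumour_samples
            )
            enrichment, skip = synergy_by_enrichment(summaries, alpha=alpha)
            skipped["enrichment"] = skip
        if model in {"ranksum", "all"}:
            ranksum, skip = synergy_by_rank_test(
                self.tumour_lfc(), self.design, alpha=alpha, strategy=self.rank_strategy
            )
            skipped["ranksum"] = skip
        if model in {"regression", "all"}:
            cell = self._log2_entity_abundance(self.cell_samples)
            tumour = self._log2_entity_abundance(self.tumour_samples)
            regression = regression_cell_vs_tumour(cell, tumour, alpha=alpha)
        return InteractionResults(
            model=self,
            alpha=alpha,
            enrichment=enrichment,
            ranksum=ranksum,
            regression=regression,
            skipped=skipped,
        )


class InteractionResults:
    """Fitted interaction calls; one DataFrame per model that was run."""

    def __init__(
        self,
        model: InteractionModel,
        alpha: float,
        enrichment: pd.DataFrame | None,
        ranksum: pd.DataFrame | None,
        regression: pd.DataFrame | None,
        skipped: dict[str, dict[str, str]],
    ) -> None:
        self.model = model
        self.alpha = alpha
        self.enrichment = enrichment
        self.ranksum = ranksum
        self.regression = regression
        self.skipped = skipped

    def significant_pairs(self, which: str = "enrichment") -> list[str]:
        table = getattr(self, which)
        if table is None:
            raise ValueError(f"model {which!r} was not fitted")
        return list(table.index[table["significant"]])

    def summary(self) -> str:
        lines = [
            "Dual-crRNA screen interaction calls",
            f"  arrays: {len(self.model.design)}  "
            f"DKO pairs: {len(self.model.design.by_category(Category.DKO))}",
            f"  cell samples: {len(self.model.cell_samples)}  "
            f"tumour samples: {len(self.model.tumour_samples)}",
            f"  alpha (BH-adjusted): {self.alpha}",
        ]
        for name in ("enrichment", "ranksum", "regression"):
            table = getattr(self, name)
            if table is None:
                continue
            sig = table.index[table["significant"]]
            lines.append(f"  [{name}] {len(sig)}/{len(table)} significant")
            for label in list(sig[:10]):
                row = table.loc[label]
                if "p_adj" in row:
                    lines.append(f"      {label}  p_adj={row['p_adj']:.3g}")
        return "\n".join(lines)

    def plot_enrichment(self, ax=None):
        """Observed vs expected enrichment scatter with significant pairs marked."""
        if self.enrichment is None:
            raise ValueError("enrichment model was not fitted")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.enrichment
        sig = t["significant"]
        ax.scatter(t.loc[~sig, "expected"], t.loc[~sig, "observed"], s=12, c="grey")
        ax.scatter(t.loc[sig, "expected"], t.loc[sig, "observed"], s=24, c="crimson")
        for label in t.index[sig]:
            ax.annotate(label, (t.loc[label, "expected"], t.loc[label, "observed"]),
                        fontsize=7)
        ax.set_xlabel("expected DKO enrichment")
        ax.set_ylabel("observed DKO enrichment")
        return ax
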