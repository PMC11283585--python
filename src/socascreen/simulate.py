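"""Synthetic screens, reads and cohorts with the structure the analysis assumes.

The screen generator plants a simple fitness model on the library: every
array's terminal relative abundance is its baseline times
``2**(f_g1 + f_g2 + eps)`` where f_g is the per-gene log2 fitness (controls
contribute 0) and eps the pairwise interaction term of its DKO pair.  Counts
are drawn with negative-binomial noise around the expected sequencing depth;
tumour samples first pass the library through a transplantation bottleneck
(multinomial resample of a fixed number of cells).  The cohort generator
plants proportional-hazard effects of standardized log expression, with an
interaction covariate that is non-zero only when both genes of a pair are
lowly expressed — a joint-loss effect the quartile survival screen can see.

Everything is bit-reproducible from its seed.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .library import Category, CrRNAArray, GeneEntry, GeneSet, LibraryDesign, enumerate_arrays
from .quantify import SampleInfo, reverse_complement
from .survival import ExpressionCohort

__all__ = [
    "FitnessModel",
    "SimulatedScreen",
    "CohortParams",
    "synthetic_gene_entries",
    "synthetic_library",
    "default_fitness_model",
    "expected_rpm",
    "simulate_screen",
    "simulate_fastq",
    "simulate_cohort",
    "truth_report",
]


# --- library synthesis -----------------------------------------------------

def _random_spacer(rng: np.random.Generator) -> str:
    # GC fraction kept inside the 30-70% design band
    while True:
        spacer = "".join(rng.choice(list("ACGT"), size=20))
        gc = sum(1 for b in spacer if b in "GC") / 20
        if 0.30 <= gc <= 0.70:
            return spacer


def synthetic_gene_entries(
    n_kinase: int = 15,
    n_metabolism: int = 12,
    n_controls: int = 5,
    seed: int = 0,
) -> tuple[list[GeneEntry], list[GeneEntry], list[GeneEntry]]:
    """Generic gene panels with random valid spacers (synthetic stand-ins for
    the bench panels, whose spacer sequences are not part of the analysis)."""
    rng = np.random.default_rng(seed)
    pams = ["TTTA", "TTTC", "TTTG"]
    seen: set[str] = set()

    def spacer() -> str:
        while True:
            s = _random_spacer(rng)
            if s not in seen:
                seen.add(s)
                return s

    kinase = [
        GeneEntry(f"KIN{i+1:02d}", GeneSet.KINASE, spacer(), pams[i % 3])
        for i in range(n_kinase)
    ]
    metabolism = [
        GeneEntry(f"MET{i+1:02d}", GeneSet.METABOLISM, spacer(), pams[i % 3])
        for i in range(n_metabolism)
    ]
    controls = [
        GeneEntry(f"NTC{i+1:02d}", GeneSet.CONTROL, spacer()) for i in range(n_controls)
    ]
    return kinase, metabolism, controls


def synthetic_library(
    n_kinase: int = 15, n_metabolism: int = 12, n_controls: int = 5, seed: int = 0
) -> LibraryDesign:
    """The default 340-array study design (15 kinase x 12 metabolism genes,
    5 non-targeting controls)."""
    kin, met, ctrl = synthetic_gene_entries(n_kinase, n_metabolism, n_controls, seed)
    return enumerate_arrays(kin, met, ctrl)


# --- screen simulation -----------------------------------------------------

@dataclass
class FitnessModel:
    """Per-gene fitness, pairwise interactions and count-noise parameters.

    fitness : per-gene log2 fitness (negative = depleting); controls are 0.
    interactions : eps per (gene1, gene2) DKO pair; 0 when absent.
    dispersion : NB overdispersion alpha (variance mu + alpha mu^2).
    depth : expected reads per array per sample.
    bottleneck : cells sampled at transplantation (None = no bottleneck).
    baseline_sigma : lognormal sigma of the initial plasmid abundance.
    """

    fitness: dict[str, float]
    interactions: dict[tuple[str, str], float] = field(default_factory=dict)
    dispersion: float = 0.1
    depth: float = 1000.0
    bottleneck: int | None = 100_000
    baseline_sigma: float = 0.5

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def default_fitness_model(
    design: LibraryDesign,
    seed: int = 0,
    fitness_sd: float = 0.4,
    interactions: dict[tuple[str, str], float] | None = None,
    **kwargs,
) -> FitnessModel:
    """Heterogeneous per-gene fitness drawn N(0, fitness_sd^2) — most genes
    near-neutral, some depleting/enriching, which is what spreads the
    expected-enrichment axis of the outlier model."""
    rng = np.random.default_rng(seed)
    genes = design.targeting_genes()
    fitness = {g: float(rng.normal(0.0, fitness_sd)) for g in genes}
    return FitnessModel(fitness=fitness, interactions=dict(interactions or {}), **kwargs)


@dataclass
class SimulatedScreen:
    """A simulated count matrix plus the ground truth that generated it."""

    design: LibraryDesign
    counts: pd.DataFrame
    sample_info: list[SampleInfo]
    truth: dict[tuple[str, str], float]

    @property
    def truth_labels(self) -> set[str]:
        return {f"{a}__{b}" for (a, b) in self.truth}


def _selection_factors(design: LibraryDesign, model: FitnessModel) -> np.ndarray:
    factors = np.empty(len(design))
    for i, a in enumerate(design.arrays):
        total = 0.0
        for entry in (a.pos1, a.pos2):
            if not entry.is_control:
                if entry.name not in model.fitness:
                    raise ValueError(f"no fitness entry for gene {entry.name!r}")
                total += model.fitness[entry.name]
        if a.category is Category.DKO:
            total += model.interactions.get((a.pos1.name, a.pos2.name), 0.0)
        factors[i] = 2.0 ** total
    return factors


def expected_rpm(
    design: LibraryDesign,
    model: FitnessModel,
    baseline: np.ndarray | None = None,
) -> pd.DataFrame:
    """Noise-free expected rpm per array: columns ``initial`` (baseline pool)
    and ``selected`` (after one screen interval of selection).  With a uniform
    baseline the control-normalised enrichment formulas reduce to their
    closed forms in the planted parameters."""
    n = len(design)
    base = np.full(n, 1.0 / n) if baseline is None else np.asarray(baseline, float)
    base = base / base.sum()
    sel = base * _selection_factors(design, model)
    sel = sel / sel.sum()
    return pd.DataFrame(
        {"initial": base * 1e6, "selected": sel * 1e6}, index=design.array_ids
    )


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.clip(mean, 1e-12, None)
    if dispersion == 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def simulate_screen(
    design: LibraryDesign,
    model: FitnessModel,
    n_cell_reps: int = 3,
    n_tumours: int = 6,
    seed: int = 0,
) -> SimulatedScreen:
    """Simulate the full screen count matrix.

    Columns: one plasmid sample; ``n_cell_reps`` cell replicates at day 4
    (pre-selection pool, the tumour comparator) and day 14 (after one interval
    of selection); ``n_tumours`` tumours at day 10 and day 18, each from an
    independent transplantation bottleneck followed by selection.
    """
    rng = np.random.default_rng(seed)
    n = len(design)
    baseline = rng.lognormal(mean=0.0, sigma=model.baseline_sigma, size=n)
    p0 = baseline / baseline.sum()
    sel = _selection_factors(design, model)
    p_sel = p0 * sel
    p_sel = p_sel / p_sel.sum()
    total_reads = model.depth * n

    columns: dict[str, np.ndarray] = {}
    info: list[SampleInfo] = []

    def add(sample: SampleInfo, probs: np.ndarray, dispersion: float) -> None:
        columns[sample.sample_id] = _nb_counts(rng, total_reads * probs, dispersion)
        info.append(sample)

    # pre-expansion pools carry sequencing (Poisson) noise only; the NB
    # overdispersion models clonal-outgrowth stochasticity in grown samples
    add(SampleInfo("plasmid", "plasmid", 0, 1), p0, 0.0)
    for r in range(1, n_cell_reps + 1):
        add(SampleInfo(f"cell_d4_r{r}", "cell", 4, r), p0, 0.0)
    for r in range(1, n_cell_reps + 1):
        add(SampleInfo(f"cell_d14_r{r}", "cell", 14, r), p_sel, model.dispersion)
    for day in (10, 18):
        for m in range(1, n_tumours + 1):
            if model.bottleneck:
                founder = rng.multinomial(model.bottleneck, p0).astype(float)
                if founder.sum() == 0:
                    raise ValueError("bottleneck produced an empty founder pool")
                p_t = founder * sel
            else:
                p_t = p0 * sel
            p_t = p_t / p_t.sum()
            add(SampleInfo(f"tumour_d{day}_m{m}", "tumour", day, m), p_t, model.dispersion)

    counts = pd.DataFrame(columns, index=design.array_ids)
    return SimulatedScreen(
        design=design, counts=counts, sample_info=info, truth=dict(model.interactions)
    )


# --- FASTQ simulation ------------------------------------------------------

def simulate_fastq(
    counts: pd.Series,
    design: LibraryDesign,
    out1: str | Path,
    out2: str | Path,
    read_length: int = 150,
    seed: int = 0,
) -> tuple[Path, Path]:
    """Emit paired-end reads for one sample column of planted counts.

    Each array contributes ``count`` read pairs spanning its reference
    cassette: read 1 from the 5' end, read 2 the reverse complement of the 3'
    end, guaranteed to overlap by more than 30 nt.  Read order is shuffled
    deterministically by the seed; qualities are constant.
    """
    rng = np.random.default_rng(seed)
    out1, out2 = Path(out1), Path(out2)
    pairs: list[tuple[str, str, str]] = []
    for a in design.arrays:
        c = int(counts.get(a.array_id, 0))
        if c == 0:
            continue
        ref = design.reference(a)
        if len(ref) > 2 * read_length - 31:
            raise ValueError(
                f"cassette length {len(ref)} unmergeable at read length {read_length}"
            )
        r1 = ref[:read_length]
        r2 = reverse_complement(ref[-read_length:])
        for k in range(c):
            pairs.append((f"{a.array_id}:{k}", r1, r2))
    order = rng.permutation(len(pairs))

    def opener(path: Path):
        return gzip.open(path, "wt") if path.suffix == ".gz" else open(path, "w")

    with opener(out1) as f1, opener(out2) as f2:
        for i in order:
            name, r1, r2 = pairs[i]
            f1.write(f"@{name}/1\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{name}/2\n{r2}\n+\n{'I' * len(r2)}\n")
    return out1, out2


# --- cohort simulation -----------------------------------------------------

@dataclass
class CohortParams:
    """Planted-hazard cohort parameters.

    n_samples : cohort size.
    gene_effects : per-gene log-hazard slope on standardized log expression.
    interaction_effects : per-pair log-hazard coefficient on the joint-low
        covariate max(-z_A, 0) * max(-z_B, 0) (negative = joint low expression
        is protective).
    baseline_hazard : events per day at covariate zero.
    censor_fraction : expected fraction of samples censored.
    """

    n_samples: int = 400
    gene_effects: dict[str, float] = field(default_factory=dict)
    interaction_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    baseline_hazard: float = 1.0 / 1000.0
    censor_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 8:
            raise ValueError("n_samples must be >= 8")
        if not 0 <= self.censor_fraction < 1:
            raise ValueError("censor_fraction must lie in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")


def simulate_cohort(params: CohortParams, genes: Sequence[str]) -> ExpressionCohort:
    """Log-normal expression with planted proportional-hazard effects.

    Per-gene log expression is normal with a gene-specific mean; z-scores are
    the standardized log expression.  The per-sample hazard is

        h = baseline * exp( sum_g beta_g z_g
                            + sum_{(A,B)} beta_int * max(-z_A,0) * max(-z_B,0) )

    so a negative interaction coefficient lowers the hazard only for samples
    in which *both* genes are lowly expressed.  Event times are exponential at
    that hazard; censoring replaces the time of a ``censor_fraction`` of
    samples by an independent uniform draw on (0, t).
    """
    genes = list(genes)
    rng = np.random.default_rng(params.seed)
    n = params.n_samples
    mu = rng.uniform(3.0, 7.0, size=len(genes))
    log_expr = rng.normal(loc=mu, scale=1.0, size=(n, len(genes)))
    expression = pd.DataFrame(
        np.exp(log_expr),
        index=[f"S{i+1:04d}" for i in range(n)],
        columns=genes,
    )
    z = (log_expr - log_expr.mean(axis=0)) / log_expr.std(axis=0)
    zmap = {g: z[:, j] for j, g in enumerate(genes)}

    log_hazard = np.full(n, np.log(params.baseline_hazard))
    for gene, beta in params.gene_effects.items():
        log_hazard += beta * zmap[gene]
    for (a, b), beta in params.interaction_effects.items():
        joint_low = np.maximum(-zmap[a], 0.0) * np.maximum(-zmap[b], 0.0)
        log_hazard += beta * joint_low

    times = rng.exponential(scale=np.exp(-log_hazard))
    event = np.ones(n, dtype=int)
    censored = rng.random(n) < params.censor_fraction
    times = np.where(censored, times * rng.random(n), times)
    event[censored] = 0
    times = np.maximum(times, 1e-6)
    return ExpressionCohort(
        expression=expression,
        time=pd.Series(times, index=expression.index, name="time"),
        event=pd.Series(event, index=expression.index, name="event"),
    )


# --- recovery metrics ------------------------------------------------------

def truth_report(
    screen: SimulatedScreen, flagged: Iterable[str] | pd.DataFrame
) -> dict[str, float]:
    """Sensitivity and observed FDR of interaction calls against the planted truth.

    ``flagged`` is either an iterable of pair labels (``gene1__gene2``) or an
    interaction-results DataFrame with a boolean ``significant`` column.
    """
    if isinstance(flagged, pd.DataFrame):
        flagged_set = set(flagged.index[flagged["significant"]])
    else:
        flagged_set = set(flagged)
    dko_labels = {a.array_id for a in screen.design.by_category(Category.DKO)}
    unknown = flagged_set - dko_labels
    if unknown:
        raise ValueError(f"flagged pairs not in this design: {sorted(unknown)[:5]}")
    truth = screen.truth_labels
    tp = len(flagged_set & truth)
    sensitivity = tp / len(truth) if truth else 0.0
    fdr = (len(flagged_set) - tp) / len(flagged_set) if flagged_set else 0.0
    return {
        "sensitivity": sensitivity,
        "fdr": fdr,
        "n_truth": len(truth),
        "n_flagged": len(flagged_set),
    }
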