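"""Dual-crRNA (SOCA) library model.

A SOCA library is a pool of single-transcript crRNA arrays, each encoding two
Cas12a guides.  Each array pairs a position-1 spacer with a position-2 spacer
inside the cassette ``DR-spacer1-DR-overlap-DR-spacer2-DR``, where DR is the
Cas12a direct repeat and the overlap is the complementary end used to splice
the two halves during SOE PCR.  Arrays fall into three categories:

* ``DKO``     — kinase gene in position 1, metabolism gene in position 2
                (double knockout);
* ``SKO``     — one targeting spacer plus one non-targeting control
                (single knockout);
* ``NTC_NTC`` — two non-targeting controls (neutral reference).

The canonical screen enumerates every kinase x metabolism pair, every
targeting gene against every control, and every ordered control x control
pair: with k kinase, m metabolism and c control spacers that is
``k*m + (k+m)*c + c**2`` arrays (15/12/5 gives the 340-array design).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

import pandas as pd

__all__ = [
    "GeneSet",
    "Category",
    "GeneEntry",
    "CrRNAArray",
    "LibraryDesign",
    "DEFAULT_DR",
    "DEFAULT_OVERLAP",
    "enumerate_arrays",
    "build_reference_sequence",
    "check_spacer_rules",
    "write_library",
    "read_library",
]

#: Canonical Cas12a-style direct repeat. The bench sequence is vendor/ortholog
#: specific and not part of the analysis; this placeholder is what the
#: simulator uses when no DR is supplied.
DEFAULT_DR = "AATTTCTACTAAGTGTAGAT"

#: Synthetic complementary-end (overlap) placeholder, GC-balanced 20-mer.
DEFAULT_OVERLAP = "GTCACGTCAAGTCCTAGCAG"

SPACER_LENGTH = 20
_PAM_RE = re.compile(r"^TTT[ACG]$")
_DNA_RE = re.compile(r"^[ACGT]+$")


class GeneSet(str, enum.Enum):
    KINASE = "kinase"
    METABOLISM = "metabolism"
    CONTROL = "control"


class Category(str, enum.Enum):
    DKO = "DKO"
    SKO = "SKO"
    NTC_NTC = "NTC_NTC"


def _require_dna(seq: str, what: str) -> None:
    if not seq or not _DNA_RE.match(seq):
        raise ValueError(f"{what} must be a non-empty A/C/G/T string, got {seq!r}")


@dataclass(frozen=True)
class GeneEntry:
    """A single spacer entry: a gene (or non-targeting control) and its guide."""

    name: str
    gene_set: GeneSet
    spacer: str
    pam_context: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_set", GeneSet(self.gene_set))
        _require_dna(self.spacer, f"spacer of {self.name!r}")
        if len(self.spacer) != SPACER_LENGTH:
            raise ValueError(
                f"spacer of {self.name!r} must be {SPACER_LENGTH} nt, "
                f"got {len(self.spacer)}"
            )
        if self.gene_set is not GeneSet.CONTROL:
            if self.pam_context is None:
                raise ValueError(f"targeting entry {self.name!r} requires a PAM context")
            if not _PAM_RE.match(self.pam_context):
                raise ValueError(
                    f"PAM context of {self.name!r} must match TTTV, got {self.pam_context!r}"
                )

    @property
    def is_control(self) -> bool:
        return self.gene_set is GeneSet.CONTROL


@dataclass(frozen=True)
class CrRNAArray:
    """One dual-guide cassette: two spacer entries and their category."""

    array_id: str
    pos1: GeneEntry
    pos2: GeneEntry
    category: Category

    def __post_init__(self) -> None:
        object.__setattr__(self, "category", Category(self.category))
        expected = _category_of(self.pos1, self.pos2)
        if self.category is not expected:
            raise ValueError(
                f"array {self.array_id!r}: category {self.category.value} inconsistent "
                f"with gene sets ({self.pos1.gene_set.value}, {self.pos2.gene_set.value})"
            )


def _category_of(pos1: GeneEntry, pos2: GeneEntry) -> Category:
    if pos1.is_control and pos2.is_control:
        return Category.NTC_NTC
    if pos1.is_control or pos2.is_control:
        return Category.SKO
    return Category.DKO


def build_reference_sequence(array: CrRNAArray, dr: str, overlap: str) -> str:
    """Reference amplicon of one array: DR-spacer1-DR-overlap-DR-spacer2-DR."""
    _require_dna(dr, "direct repeat")
    _require_dna(overlap, "overlap")
    return dr + array.pos1.spacer + dr + overlap + dr + array.pos2.spacer + dr


@dataclass
class LibraryDesign:
    """An ordered collection of crRNA arrays plus the shared cassette context."""

    arrays: list[CrRNAArray]
    dr_sequence: str = DEFAULT_DR
    overlap_sequence: str = DEFAULT_OVERLAP

    def __post_init__(self) -> None:
        _require_dna(self.dr_sequence, "direct repeat")
        _require_dna(self.overlap_sequence, "overlap")
        ids = [a.array_id for a in self.arrays]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate array_id in library design")
        pairs = [(a.pos1.spacer, a.pos2.spacer) for a in self.arrays]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (spacer1, spacer2) pair in library design")
        refs = [self.reference(a) for a in self.arrays]
        if len(set(refs)) != len(refs):
            raise ValueError("reference sequences are not all distinct")

    def __len__(self) -> int:
        return len(self.arrays)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LibraryDesign):
            return NotImplemented
        return (
            self.arrays == other.arrays
            and self.dr_sequence == other.dr_sequence
            and self.overlap_sequence == other.overlap_sequence
        )

    @property
    def array_ids(self) -> list[str]:
        return [a.array_id for a in self.arrays]

    def reference(self, array: CrRNAArray) -> str:
        return build_reference_sequence(array, self.dr_sequence, self.overlap_sequence)

    def signature(self, array: CrRNAArray) -> str:
        """Counting signature: the full inter-spacer cassette
        spacer1 + DR + overlap + DR + spacer2 (unique per array)."""
        core = self.dr_sequence + self.overlap_sequence + self.dr_sequence
        return array.pos1.spacer + core + array.pos2.spacer

    def by_category(self, category: Category | str) -> list[CrRNAArray]:
        category = Category(category)
        return [a for a in self.arrays if a.category is category]

    def sko_arrays_for(self, gene: str) -> list[CrRNAArray]:
        """SKO arrays whose targeting spacer hits ``gene``."""
        out = [
            a
            for a in self.by_category(Category.SKO)
            if (a.pos1.name == gene and not a.pos1.is_control)
            or (a.pos2.name == gene and not a.pos2.is_control)
        ]
        return out

    def targeting_genes(self) -> list[str]:
        names: list[str] = []
        for a in self.arrays:
            for entry in (a.pos1, a.pos2):
                if not entry.is_control and entry.name not in names:
                    names.append(entry.name)
        return names

    def dko_pairs(self) -> list[tuple[str, str]]:
        return [(a.pos1.name, a.pos2.name) for a in self.by_category(Category.DKO)]

    def category_counts(self) -> dict[str, int]:
        return {c.value: len(self.by_category(c)) for c in Category}


def enumerate_arrays(
    kinase_genes: Sequence[GeneEntry],
    metabolism_genes: Sequence[GeneEntry],
    control_spacers: Sequence[GeneEntry],
    dr: str = DEFAULT_DR,
    overlap: str = DEFAULT_OVERLAP,
) -> LibraryDesign:
    """Enumerate the full combinatorial library.

    Every kinase x metabolism pair becomes a DKO array (kinase in position 1);
    every targeting gene paired with every control becomes an SKO array
    (gene in position 1, control in position 2); every ordered control x
    control pair becomes an NTC_NTC array.  Output order is deterministic:
    arrays sorted lexicographically by array_id within each category block
    (DKO, then SKO, then NTC_NTC), with array_id ``<gene1>__<gene2>``.
    """
    if not kinase_genes or not metabolism_genes or not control_spacers:
        raise ValueError("kinase, metabolism and control entry lists must be non-empty")
    for entries, expected in (
        (kinase_genes, GeneSet.KINASE),
        (metabolism_genes, GeneSet.METABOLISM),
        (control_spacers, GeneSet.CONTROL),
    ):
        for e in entries:
            if e.gene_set is not expected:
                raise ValueError(f"entry {e.name!r} is not in gene set {expected.value}")
    names = [e.name for e in (*kinase_genes, *metabolism_genes, *control_spacers)]
    if len(set(names)) != len(names):
        raise ValueError("duplicate entry names across the library")

    def make(p1: GeneEntry, p2: GeneEntry) -> CrRNAArray:
        return CrRNAArray(
            array_id=f"{p1.name}__{p2.name}",
            pos1=p1,
            pos2=p2,
            category=_category_of(p1, p2),
        )

    targeting = list(kinase_genes) + list(metabolism_genes)
    dko = sorted(
        (make(k, m) for k in kinase_genes for m in metabolism_genes),
        key=lambda a: a.array_id,
    )
    sko = sorted(
        (make(g, c) for g in targeting for c in control_spacers),
        key=lambda a: a.array_id,
    )
    ntc = sorted(
        (make(c1, c2) for c1 in control_spacers for c2 in control_spacers),
        key=lambda a: a.array_id,
    )
    return LibraryDesign(arrays=dko + sko + ntc, dr_sequence=dr, overlap_sequence=overlap)


def check_spacer_rules(spacer: str, pam_context: str) -> list[str]:
    """Validate one spacer against the library design rules.

    Returns a list of violation codes (empty when the spacer passes):
    ``length`` (not 20 nt), ``alphabet`` (non-ACGT characters),
    ``pam_mismatch`` (PAM context not TTTV) and ``gc_out_of_range``
    (GC fraction outside the inclusive 30-70% band).
    """
    violations: list[str] = []
    if len(spacer) != SPACER_LENGTH:
        violations.append("length")
    if not _DNA_RE.match(spacer or ""):
        violations.append("alphabet")
    if not _PAM_RE.match(pam_context or ""):
        violations.append("pam_mismatch")
    if spacer and "alphabet" not in violations:
        gc = sum(1 for b in spacer if b in "GC") / len(spacer)
        if not 0.30 <= gc <= 0.70:
            violations.append("gc_out_of_range")
    return violations


# --- persistence: FASTA of reference sequences + TSV of metadata -----------

_TSV_COLUMNS = [
    "array_id",
    "gene1",
    "gene2",
    "set1",
    "set2",
    "category",
    "spacer1",
    "spacer2",
    "pam1",
    "pam2",
]


def write_library(design: LibraryDesign, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.fasta`` (reference sequences) and ``<prefix>.tsv``
    (array metadata; the header also carries the DR/overlap sequences so the
    files round-trip to an equal design)."""
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    fasta_path = out_prefix.with_suffix(".fasta")
    tsv_path = out_prefix.with_suffix(".tsv")

    records = [
        SeqRecord(Seq(design.reference(a)), id=a.array_id, description="")
        for a in design.arrays
    ]
    SeqIO.write(records, str(fasta_path), "fasta")

    rows = []
    for a in design.arrays:
        rows.append(
            {
                "array_id": a.array_id,
                "gene1": a.pos1.name,
                "gene2": a.pos2.name,
                "set1": a.pos1.gene_set.value,
                "set2": a.pos2.gene_set.value,
                "category": a.category.value,
                "spacer1": a.pos1.spacer,
                "spacer2": a.pos2.spacer,
                "pam1": a.pos1.pam_context or "",
                "pam2": a.pos2.pam_context or "",
            }
        )
    table = pd.DataFrame(rows, columns=_TSV_COLUMNS)
    with open(tsv_path, "w") as fh:
        fh.write(f"#dr={design.dr_sequence}\n#overlap={design.overlap_sequence}\n")
        table.to_csv(fh, sep="\t", index=False)
    return fasta_path, tsv_path


def read_library(prefix_or_tsv: str | Path) -> LibraryDesign:
    """Read a design back from the TSV written by :func:`write_library`."""
    path = Path(prefix_or_tsv)
    if path.suffix != ".tsv":
        path = path.with_suffix(".tsv")
    dr = overlap = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            if key == "dr":
                dr = value
            elif key == "overlap":
                overlap = value
    if dr is None or overlap is None:
        raise ValueError(f"{path}: missing #dr= / #overlap= header lines")
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")

    entries: dict[str, GeneEntry] = {}

    def entry(name: str, gene_set: str, spacer: str, pam: str) -> GeneEntry:
        if name not in entries:
            entries[name] = GeneEntry(
                name=name, gene_set=GeneSet(gene_set), spacer=spacer,
                pam_context=pam or None,
            )
        return entries[name]

    arrays = []
    for row in table.itertuples(index=False):
        p1 = entry(row.gene1, row.set1, row.spacer1, row.pam1)
        p2 = entry(row.gene2, row.set2, row.spacer2, row.pam2)
        arrays.append(
            CrRNAArray(array_id=row.array_id, pos1=p1, pos2=p2, category=Category(row.category))
        )
    return LibraryDesign(arrays=arrays, dr_sequence=dr, overlap_sequence=overlap)


def read_gene_entries(path: str | Path, gene_set: GeneSet | str) -> list[GeneEntry]:
    """Read gene entries from a TSV with columns name, spacer[, pam_context]."""
    gene_set = GeneSet(gene_set)
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for row in table.itertuples(index=False):
        pam = getattr(row, "pam_context", "") or None
        out.append(GeneEntry(name=row.name, gene_set=gene_set, spacer=row.spacer, pam_context=pam))
    return out
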