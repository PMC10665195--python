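"""Searchable normal-peptidome index.

Windows a gene-annotated proteome into fixed-length peptides and annotates
each unique window with

* its parent gene set (a peptide occurring in several proteins carries the
  union of parent genes),
* the predicted binding affinity ``b`` (nM IC50) and percentile rank on a
  named HLA allele, via a pluggable :class:`BindingPredictor`, and
* ``E_max``, the maximum expression of any parent gene across normal
  tissues (RPKM/FPKM).

The resulting :class:`ProteomeIndex` is the search space for the
cross-reactivity scan.  At full scale the same structure holds tens of
millions of normal peptides per allele panel; the builder is scale-agnostic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Protocol

import pandas as pd
from Bio import SeqIO

from .peptide_core import (_CANONICAL_SET, MIN_LENGTH, MAX_LENGTH, PeptideError)

__all__ = [
    "ProteinRecord",
    "BindingPredictor",
    "TablePredictor",
    "ProteomeIndex",
    "read_fasta",
    "write_fasta",
    "window_peptides",
    "annotate_expression",
    "build_index",
    "DEFAULT_EMAX_FLOOR",
]

#: expression assigned to genes absent from the matrix; keeps the
#: overall-score division finite while leaving "unexpressed" peptides
#: high-scoring under the printed formula
DEFAULT_EMAX_FLOOR = 0.01

_HEADER_RE = re.compile(r"^(?P<pid>[^|\s]+)\|(?P<gene>[^|\s]+)")


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    gene: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for protein {self.protein_id}")


class BindingPredictor(Protocol):
    """Contract for pMHC binding engines (NetMHC-class tools or stand-ins).

    ``predict`` must be deterministic for fixed inputs and return a strictly
    positive IC50 in nM together with a percentile rank in [0, 100].
    """

    def predict(self, peptide: str, allele: str) -> tuple[float, float]: ...


class TablePredictor:
    """Replay predictor backed by a precomputed (peptide, allele) table.

    Lets external engines be run once, cached to TSV (columns: peptide,
    allele, ic50_nm, rank_pct) and replayed deterministically.
    """

    def __init__(self, table: dict[tuple[str, str], tuple[float, float]]):
        self._table = dict(table)

    def predict(self, peptide: str, allele: str) -> tuple[float, float]:
        try:
            return self._table[(peptide, allele)]
        except KeyError:
            raise KeyError(f"no prediction for ({peptide}, {allele})") from None

    def to_tsv(self, path) -> None:
        rows = [{"peptide": p, "allele": a, "ic50_nm": b, "rank_pct": r}
                for (p, a), (b, r) in sorted(self._table.items())]
        pd.DataFrame(rows, columns=["peptide", "allele", "ic50_nm", "rank_pct"]
                     ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TablePredictor":
        df = pd.read_csv(path, sep="\t")
        return cls({(row.peptide, row.allele): (float(row.ic50_nm), float(row.rank_pct))
                    for row in df.itertuples()})


def read_fasta(path, gene_regex: str | re.Pattern = _HEADER_RE) -> list[ProteinRecord]:
    """Read a proteome FASTA with ``ID|GENE description`` headers.

    ``gene_regex`` must expose named groups ``pid`` and ``gene``; the
    default matches the ``ID|GENE`` dialect.
    """
    pattern = re.compile(gene_regex) if isinstance(gene_regex, str) else gene_regex
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        m = pattern.match(rec.id)
        if m is None:
            raise ValueError(f"cannot extract gene from FASTA header {rec.id!r}")
        pid = m.group("pid")
        if pid in seen:
            raise ValueError(f"duplicate protein id {pid!r} in {path}")
        seen.add(pid)
        records.append(ProteinRecord(pid, m.group("gene"), str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id}|{rec.gene}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def window_peptides(proteome: Iterable[ProteinRecord], length: int
                    ) -> tuple[dict[str, frozenset[str]], int]:
    """Enumerate unique fixed-length windows with parent-gene sets.

    Returns ``(mapping, n_skipped)`` where ``mapping`` sends each unique
    window to the frozenset of parent genes and ``n_skipped`` counts windows
    dropped for containing non-canonical residues.  Proteins shorter than
    ``length`` contribute nothing.
    """
    if not (MIN_LENGTH <= length <= MAX_LENGTH):
        raise PeptideError(f"window length {length} outside {MIN_LENGTH}-{MAX_LENGTH}")
    acc: dict[str, set[str]] = {}
    skipped = 0
    for rec in proteome:
        seq = rec.sequence
        for i in range(len(seq) - length + 1):
            window = seq[i:i + length]
            if not _CANONICAL_SET.issuperset(window):
                skipped += 1
                continue
            acc.setdefault(window, set()).add(rec.gene)
    return {p: frozenset(g) for p, g in acc.items()}, skipped


def annotate_expression(peptide_genes: dict[str, frozenset[str]],
                        expression: pd.DataFrame,
                        missing_floor: float = DEFAULT_EMAX_FLOOR,
                        ) -> tuple[dict[str, float], list[str]]:
    """Per-peptide E_max: maximum expression of any parent gene in any tissue.

    ``expression`` is a genes x tissues matrix of non-negative RPKM/FPKM.
    Genes absent from the matrix contribute ``missing_floor`` and are
    returned in the missing-gene log.
    """
    if (expression.to_numpy() < 0).any():
        raise ValueError("expression matrix contains negative values")
    gene_max = expression.max(axis=1)
    missing: set[str] = set()
    emax: dict[str, float] = {}
    for peptide, genes in peptide_genes.items():
        best = 0.0
        for g in genes:
            if g in gene_max.index:
                best = max(best, float(gene_max[g]))
            else:
                missing.add(g)
                best = max(best, missing_floor)
        emax[peptide] = best
    return emax, sorted(missing)


@dataclass
class ProteomeIndex:
    """Gene-annotated normal-peptidome for one HLA allele and one length.

    ``table`` columns: peptide, genes (frozenset), b_nm, rank_pct, e_max.
    No duplicate peptide sequences; annotations are merged at build time.
    """

    allele: str
    length: int
    table: pd.DataFrame
    n_skipped_windows: int = 0
    n_predictor_failures: int = 0
    missing_genes: list[str] = field(default_factory=list)

    COLUMNS = ["peptide", "genes", "b_nm", "rank_pct", "e_max"]

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["genes"] = out["genes"].map(lambda gs: ";".join(sorted(gs)))
        out.insert(0, "allele", self.allele)
        out.insert(1, "length", self.length)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ProteomeIndex":
        df = pd.read_csv(path, sep="\t")
        if df.empty:
            raise ValueError(f"empty index file {path}")
        allele = df["allele"].iloc[0]
        length = int(df["length"].iloc[0])
        table = df[cls.COLUMNS[:1] + ["genes", "b_nm", "rank_pct", "e_max"]].copy()
        table["genes"] = table["genes"].map(
            lambda s: frozenset(str(s).split(";")))
        return cls(allele=allele, length=length,
                   table=table.reset_index(drop=True))


def build_index(proteome: Iterable[ProteinRecord], length: int, allele: str,
                predictor: BindingPredictor, expression: pd.DataFrame,
                missing_floor: float = DEFAULT_EMAX_FLOOR) -> ProteomeIndex:
    """Window -> predict -> annotate; one row per unique retained window.

    Peptides the predictor fails on are skipped and counted, never silently
    dropped.  Output rows are sorted by peptide sequence so the build is
    independent of protein input order.
    """
    peptide_genes, n_skipped = window_peptides(proteome, length)
    emax, missing = annotate_expression(peptide_genes, expression, missing_floor)
    rows = []
    failures = 0
    for peptide in sorted(peptide_genes):
        try:
            b, rank = predictor.predict(peptide, allele)
        except Exception:
            failures += 1
            continue
        if b <= 0:
            failures += 1
            continue
        rows.append((peptide, peptide_genes[peptide], float(b), float(rank),
                     emax[peptide]))
    table = pd.DataFrame(rows, columns=ProteomeIndex.COLUMNS)
    return ProteomeIndex(allele=allele, length=length, table=table,
                         n_skipped_windows=n_skipped,
                         n_predictor_failures=failures,
                         missing_genes=missing)
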