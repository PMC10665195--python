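"""Cross-reactivity scan engine.

Given a query tumour pMHC (peptide + HLA allele), score every normal
peptide of matching length in a :class:`~scrapseek.proteome_index.ProteomeIndex`
and rank by the overall cross-reactivity score

    overall = sum_p / (b * E_max)            (printed orientation)

where ``sum_p`` is the positional similarity score summed over the scored
(non-anchor) positions, ``b`` the predicted binding affinity of the normal
peptide in nM, and ``E_max`` its maximum normal-tissue expression.  An
alternative ``expression_weighted`` orientation, sum_p * E_max / b, is
provided because under the printed formula high normal expression *lowers*
the risk score; the orientation used is always recorded in the report
metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peptide_core import (AminoAcidTable, CANONICAL_RESIDUES, PeptideError,
                           classify_pair, default_table, scored_positions,
                           validate_peptide)
from .proteome_index import DEFAULT_EMAX_FLOOR, ProteomeIndex

__all__ = [
    "similarity_score",
    "overall_score",
    "pair_score_matrix",
    "scan",
    "ScanResult",
    "write_report",
    "read_report",
    "REPORT_COLUMNS",
]

REPORT_COLUMNS = ["rank", "peptide", "genes", "sum_p", "b_nM", "E_max",
                  "overall_score", "in_normal_ligandome", "self"]

_RESIDUE_CODE = {r: i for i, r in enumerate(CANONICAL_RESIDUES)}


def similarity_score(query: str, candidate: str,
                     table: AminoAcidTable | None = None,
                     positions: tuple[int, ...] | None = None,
                     ) -> tuple[int, list[int]]:
    """Positional similarity between equal-length peptides.

    Applies the 5/2/-2 residue-pair rule at the given 1-based ``positions``
    (default: the anchor-excluding text convention) and returns
    ``(sum_p, per_position_scores)``.  No alignment or gapping: a length
    mismatch is an error.
    """
    query = validate_peptide(query)
    candidate = validate_peptide(candidate)
    if len(query) != len(candidate):
        raise PeptideError(
            f"length mismatch: query {len(query)} vs candidate {len(candidate)}")
    if positions is None:
        positions = scored_positions(len(query))
    if any(p < 1 or p > len(query) for p in positions):
        raise PeptideError(f"scored positions {positions} outside 1..{len(query)}")
    table = table or default_table()
    scores = [classify_pair(query[p - 1], candidate[p - 1], table)
              for p in positions]
    return sum(scores), scores


def overall_score(sum_p: float, b: float, e_max: float,
                  mode: str = "printed",
                  floor: float = DEFAULT_EMAX_FLOOR) -> float:
    """Combine similarity, binding and expression into one risk score.

    ``printed``: sum_p / (b * max(e_max, floor)).
    ``expression_weighted``: sum_p * max(e_max, floor) / b.
    """
    if b <= 0:
        raise ValueError(f"binding affinity must be positive, got {b}")
    if e_max < 0:
        raise ValueError(f"E_max must be non-negative, got {e_max}")
    e = max(e_max, floor)
    if mode == "printed":
        return sum_p / (b * e)
    if mode == "expression_weighted":
        return sum_p * e / b
    raise ValueError(f"unknown score mode {mode!r}")


def pair_score_matrix(table: AminoAcidTable | None = None) -> np.ndarray:
    """20x20 residue-pair score matrix in canonical residue order."""
    table = table or default_table()
    n = len(CANONICAL_RESIDUES)
    mat = np.empty((n, n), dtype=np.int64)
    for i, a in enumerate(CANONICAL_RESIDUES):
        for j, b in enumerate(CANONICAL_RESIDUES):
            mat[i, j] = classify_pair(a, b, table)
    return mat


def _encode(peptides: "pd.Series | list[str]", length: int) -> np.ndarray:
    arr = np.frombuffer("".join(peptides).encode("ascii"), dtype=np.uint8)
    codes = np.full(128, -1, dtype=np.int64)
    for r, i in _RESIDUE_CODE.items():
        codes[ord(r)] = i
    return codes[arr].reshape(-1, length)


@dataclass
class ScanResult:
    """Ranked cross-reactivity report plus run metadata."""

    report: pd.DataFrame
    query: str
    allele: str
    mode: str
    convention: str
    total_candidates: int
    metadata: dict = field(default_factory=dict)


def scan(query: str, index: ProteomeIndex,
         normal_ligandome: "pd.DataFrame | None" = None,
         top_k: int | None = None,
         allele: str | None = None,
         mode: str = "printed",
         convention: str = "text",
         table: AminoAcidTable | None = None,
         floor: float = DEFAULT_EMAX_FLOOR) -> ScanResult:
    """Score every index peptide against ``query`` and rank by risk.

    Ties in ``overall_score`` break by (sum_p desc, b asc, peptide
    lexicographic) so the ranking is reproducible under any input row
    order.  Exact self-matches are kept and flagged rather than removed.
    ``normal_ligandome`` (columns ``peptide``, ``gene``, optionally
    ``tissue``) drives the T/F reported-in-normal-immunopeptidome flag.
    """
    query = validate_peptide(query)
    if allele is not None and allele != index.allele:
        raise ValueError(f"query allele {allele} does not match index allele "
                         f"{index.allele}")
    if len(query) != index.length:
        raise PeptideError(f"query length {len(query)} does not match index "
                           f"length {index.length}")
    tab = index.table
    n = len(tab)
    if n == 0:
        report = pd.DataFrame(columns=REPORT_COLUMNS)
        return ScanResult(report, query, index.allele, mode, convention, 0)

    positions = scored_positions(index.length, convention)
    pos0 = np.asarray(positions, dtype=np.int64) - 1
    mat = pair_score_matrix(table)
    cand = _encode(list(tab["peptide"]), index.length)
    qcodes = _encode([query], index.length)[0]
    sum_p = mat[qcodes[pos0][None, :], cand[:, pos0]].sum(axis=1)

    b = tab["b_nm"].to_numpy(dtype=float)
    e = np.maximum(tab["e_max"].to_numpy(dtype=float), floor)
    if mode == "printed":
        overall = sum_p / (b * e)
    elif mode == "expression_weighted":
        overall = sum_p * e / b
    else:
        raise ValueError(f"unknown score mode {mode!r}")

    ligandome_peptides: frozenset[str] = frozenset()
    if normal_ligandome is not None and len(normal_ligandome):
        ligandome_peptides = frozenset(normal_ligandome["peptide"].astype(str))

    report = pd.DataFrame({
        "peptide": tab["peptide"].to_numpy(),
        "genes": tab["genes"].to_numpy(),
        "sum_p": sum_p,
        "b_nM": b,
        "E_max": tab["e_max"].to_numpy(dtype=float),
        "overall_score": overall,
        "in_normal_ligandome": tab["peptide"].isin(ligandome_peptides).to_numpy(),
        "self": (tab["peptide"] == query).to_numpy(),
    })
    report = report.sort_values(
        by=["overall_score", "sum_p", "b_nM", "peptide"],
        ascending=[False, False, True, True],
        kind="mergesort").reset_index(drop=True)
    report.insert(0, "rank", np.arange(1, len(report) + 1))
    if top_k is not None:
        report = report.head(top_k).copy()
    return ScanResult(report=report, query=query, allele=index.allele,
                      mode=mode, convention=convention, total_candidates=n)


def write_report(result: "ScanResult | pd.DataFrame", path) -> None:
    """Write a ranked report as TSV with a fixed column order.

    The ligandome and self flags render as literal ``T``/``F``.
    """
    report = result.report if isinstance(result, ScanResult) else result
    out = report.copy()
    if len(out):
        out["genes"] = out["genes"].map(
            lambda gs: ";".join(sorted(gs)) if isinstance(gs, frozenset) else gs)
        for col in ("in_normal_ligandome", "self"):
            out[col] = np.where(out[col].astype(bool), "T", "F")
    out = out.reindex(columns=REPORT_COLUMNS)
    out.to_csv(path, sep="\t", index=False)


def read_report(path) -> pd.DataFrame:
    """Read back a report written by :func:`write_report`."""
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str})
    if len(df):
        df["genes"] = df["genes"].map(lambda s: frozenset(str(s).split(";")))
        for col in ("in_normal_ligandome", "self"):
            df[col] = df[col].map({"T": True, "F": False})
    return df
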