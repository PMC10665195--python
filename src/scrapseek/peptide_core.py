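"""Peptide primitives: validation, residue chemistry tables, positional
similarity scoring and monoisotopic mass / m/z arithmetic.

Everything downstream (the proteome index, the cross-reactivity scan, the
MS1 matcher) is built on the functions in this module.  The unit of work is
an MHC class I peptide: an upper-case string of 8-14 canonical residues.

The per-position similarity rule is the three-outcome scheme used for
receptor-facing cross-reactivity scoring: identical residues score 5,
different residues of the same chemical class score 2, and everything else
scores -2.  MHC anchor positions (P2 and the C terminus) are buried in the
binding groove and are excluded from scoring by default.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

__all__ = [
    "CANONICAL_RESIDUES",
    "WATER_MONO",
    "PROTON_MASS",
    "PeptideError",
    "Peptide",
    "AminoAcidTable",
    "validate_peptide",
    "classify_pair",
    "scored_positions",
    "monoisotopic_mass",
    "mz",
]

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_RESIDUES)

MIN_LENGTH = 8
MAX_LENGTH = 14

# monoisotopic residue masses in Da (standard values, CODATA-consistent)
_RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

WATER_MONO = 18.010565
PROTON_MASS = 1.007276

# default chemical classes; the polar flag marks residues with polar side
# chains (everything outside the aliphatic set and F/W; Y counts as polar)
_DEFAULT_CLASSES = {
    "aliphatic-nonpolar": "GAVLIPM",
    "aromatic": "FWY",
    "polar-uncharged": "STCNQ",
    "positive": "KRH",
    "negative": "DE",
}
_NONPOLAR = frozenset("GAVLIPMFW")


class PeptideError(ValueError):
    """Raised when a peptide string fails validation."""


def validate_peptide(sequence: str, min_length: int = MIN_LENGTH,
                     max_length: int = MAX_LENGTH) -> str:
    """Validate and normalise a peptide string.

    Returns the upper-cased sequence. Rejects non-canonical residues
    (including the ambiguity codes B/J/O/U/X/Z) and lengths outside the
    class I window of ``min_length``-``max_length`` residues.
    """
    if not isinstance(sequence, str):
        raise PeptideError(f"peptide must be a string, got {type(sequence).__name__}")
    seq = sequence.upper()
    for ch in seq:
        if ch not in _CANONICAL_SET:
            raise PeptideError(
                f"non-canonical residue {ch!r} in peptide {sequence!r}")
    if not (min_length <= len(seq) <= max_length):
        raise PeptideError(
            f"peptide length {len(seq)} outside allowed range "
            f"{min_length}-{max_length}: {sequence!r}")
    return seq


@dataclass(frozen=True)
class Peptide:
    """A validated MHC class I peptide (8-14 canonical residues)."""

    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_peptide(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)

    def __str__(self) -> str:
        return self.sequence


@dataclass(frozen=True)
class AminoAcidTable:
    """Residue chemistry lookup: chemical class, polarity and mass.

    The table is deliberately data-driven (loadable from TSV) so alternative
    classification schemes can be dropped in without code changes.
    """

    class_of: dict[str, str]
    polar: dict[str, bool]
    monoisotopic_mass: dict[str, float]

    def __post_init__(self) -> None:
        for name, mapping in (("class_of", self.class_of),
                              ("polar", self.polar),
                              ("monoisotopic_mass", self.monoisotopic_mass)):
            missing = _CANONICAL_SET - set(mapping)
            if missing:
                raise ValueError(
                    f"amino-acid table {name} missing residues {sorted(missing)}")
        for r, m in self.monoisotopic_mass.items():
            if m <= 0:
                raise ValueError(f"non-positive mass for residue {r}: {m}")

    @classmethod
    def default(cls) -> "AminoAcidTable":
        class_of = {r: cname for cname, members in _DEFAULT_CLASSES.items()
                    for r in members}
        polar = {r: r not in _NONPOLAR for r in CANONICAL_RESIDUES}
        return cls(class_of=class_of, polar=polar,
                   monoisotopic_mass=dict(_RESIDUE_MASS))

    # --- TSV round trip: columns residue, class, polar(0/1), monoisotopic_mass
    def to_tsv(self, path_or_buf) -> None:
        rows = ["residue\tclass\tpolar\tmonoisotopic_mass"]
        for r in CANONICAL_RESIDUES:
            rows.append(f"{r}\t{self.class_of[r]}\t{int(self.polar[r])}\t"
                        f"{self.monoisotopic_mass[r]:.5f}")
        text = "\n".join(rows) + "\n"
        if isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__"):
            with open(path_or_buf, "w") as fh:
                fh.write(text)
        else:
            path_or_buf.write(text)

    @classmethod
    def from_tsv(cls, path_or_buf) -> "AminoAcidTable":
        if isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__"):
            fh = open(path_or_buf)
            close = True
        else:
            fh, close = path_or_buf, False
        try:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {c: i for i, c in enumerate(header)}
            class_of, polar, mass = {}, {}, {}
            for line in fh:
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                r = parts[idx["residue"]]
                class_of[r] = parts[idx["class"]]
                polar[r] = bool(int(parts[idx["polar"]]))
                mass[r] = float(parts[idx["monoisotopic_mass"]])
        finally:
            if close:
                fh.close()
        return cls(class_of=class_of, polar=polar, monoisotopic_mass=mass)


_DEFAULT_TABLE: AminoAcidTable | None = None


def default_table() -> AminoAcidTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = AminoAcidTable.default()
    return _DEFAULT_TABLE


def _check_residue(r: str) -> None:
    if r not in _CANONICAL_SET:
        raise PeptideError(f"non-canonical residue {r!r}")


def classify_pair(a: str, b: str, table: AminoAcidTable | None = None) -> int:
    """Three-outcome positional similarity score between two residues.

    Returns 5 for an identical pair, 2 for distinct residues sharing a
    chemical class, and -2 otherwise (different class, regardless of
    polarity).  Symmetric and total over the canonical 20x20 grid.
    """
    _check_residue(a)
    _check_residue(b)
    if a == b:
        return 5
    table = table or default_table()
    if table.class_of[a] == table.class_of[b]:
        return 2
    return -2


def scored_positions(length: int, convention: str = "text") -> tuple[int, ...]:
    """1-based peptide positions included in the similarity sum.

    ``text`` (default) excludes the MHC anchor positions: position 1 plus
    positions 3..length-1 (P2 and the C terminus are anchors).  ``equation``
    is the literal displayed-sum reading: positions 3..length.
    """
    if not (MIN_LENGTH <= length <= MAX_LENGTH):
        raise PeptideError(
            f"length {length} outside allowed range {MIN_LENGTH}-{MAX_LENGTH}")
    if convention == "text":
        return (1,) + tuple(range(3, length))
    if convention == "equation":
        return tuple(range(3, length + 1))
    raise ValueError(f"unknown scoring convention {convention!r}")


def monoisotopic_mass(peptide: str | Peptide,
                      table: AminoAcidTable | None = None) -> float:
    """Monoisotopic mass of the neutral peptide in Da (residues + water)."""
    seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
    table = table or default_table()
    total = WATER_MONO
    for r in seq:
        _check_residue(r)
        total += table.monoisotopic_mass[r]
    return total


def mz(peptide: str | Peptide, charge: int,
       table: AminoAcidTable | None = None) -> float:
    """Theoretical m/z of ``peptide`` at positive integer ``charge``."""
    if not isinstance(charge, int) or charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge!r}")
    return (monoisotopic_mass(peptide, table) + charge * PROTON_MASS) / charge
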