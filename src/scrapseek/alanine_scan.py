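"""Alanine-scan analysis: call receptor contact residues from binding data.

A single-position alanine walk across a peptide, read out as tetramer or
dextramer staining of receptor-bearing cells, localises the residues the
receptor contacts: substituting a contact residue abrogates binding.  This
module normalises the raw signals against wild type and thresholds the
relative binding loss, excluding MHC anchor positions (which face the
groove, not the receptor).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "AlanineScanResult",
    "relative_binding",
    "contact_residues",
    "analyze_scan_table",
    "DEFAULT_CONTACT_THRESHOLD",
]

#: relative binding below which a substitution counts as abrogating
DEFAULT_CONTACT_THRESHOLD = 0.5


@dataclass(frozen=True)
class AlanineScanResult:
    """Outcome at one scanned position.

    ``substituted_residue`` is normally A; when the wild-type residue is
    already alanine a configured alternative (e.g. G) is used.
    """

    position: int
    substituted_residue: str
    relative_binding: float
    is_contact: bool = False

    def __post_init__(self) -> None:
        if self.relative_binding < 0:
            raise ValueError("relative_binding must be >= 0")


def relative_binding(signal_mut: float, signal_wt: float,
                     signal_background: float = 0.0) -> float:
    """Background-subtracted binding of a mutant as a fraction of wild type.

    (mut - background) / (wt - background), clipped below at zero.
    """
    if signal_wt <= signal_background:
        raise ValueError(
            f"wild-type signal ({signal_wt}) must exceed background "
            f"({signal_background})")
    return max(0.0, (signal_mut - signal_background)
               / (signal_wt - signal_background))


def contact_residues(scan: list[AlanineScanResult],
                     threshold: float = DEFAULT_CONTACT_THRESHOLD,
                     anchors: frozenset[int] | set[int] = frozenset(),
                     ) -> list[int]:
    """Positions whose substitution drops binding below ``threshold``.

    Anchor positions are excluded; the result is sorted ascending.
    Duplicate positions in the scan are an error.
    """
    positions = [r.position for r in scan]
    if len(positions) != len(set(positions)):
        dupes = sorted({p for p in positions if positions.count(p) > 1})
        raise ValueError(f"duplicate scan positions {dupes}")
    return sorted(r.position for r in scan
                  if r.position not in anchors
                  and r.relative_binding < threshold)


def analyze_scan_table(table: pd.DataFrame,
                       threshold: float = DEFAULT_CONTACT_THRESHOLD,
                       anchors: frozenset[int] | set[int] = frozenset(),
                       ) -> tuple[list[AlanineScanResult], list[int]]:
    """Normalise a raw scan table and call contacts.

    ``table`` columns: position, substitution, mean_signal, background.
    The wild-type row is identified by substitution ``WT`` (position 0 or
    blank is also accepted); every other row is normalised against it.
    """
    for col in ("position", "substitution", "mean_signal", "background"):
        if col not in table.columns:
            raise ValueError(f"scan table missing column {col!r}")
    is_wt = table["substitution"].astype(str).str.upper() == "WT"
    if is_wt.sum() != 1:
        raise ValueError("scan table must contain exactly one WT row")
    wt = table[is_wt].iloc[0]
    results = []
    for row in table[~is_wt].itertuples():
        rb = relative_binding(float(row.mean_signal), float(wt.mean_signal),
                              float(row.background))
        results.append(AlanineScanResult(
            position=int(row.position),
            substituted_residue=str(row.substitution),
            relative_binding=rb,
            is_contact=(rb < threshold and int(row.position) not in anchors)))
    contacts = contact_residues(results, threshold=threshold, anchors=anchors)
    return results, contacts
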