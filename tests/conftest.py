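import numpy as np
import pandas as pd
import pytest

from scrapseek.peptide_core import (AminoAcidTable, classify_pair,
                                    scored_positions)
from scrapseek.proteome_index import ProteomeIndex


@pytest.fixture(scope="session")
def aatable() -> AminoAcidTable:
    return AminoAcidTable.default()


def naive_scan(query: str, index: ProteomeIndex, mode: str = "printed",
               convention: str = "text", floor: float = 0.01) -> pd.DataFrame:
    """Reference double-loop scan, independent of the vectorised engine.

    Scores every index peptide position by position with pure-python
    loops, then sorts with the same deterministic tie-break.
    """
    positions = scored_positions(len(query), convention)
    rows = []
    for row in index.table.itertuples():
        sum_p = 0
        for p in positions:
            sum_p += classify_pair(query[p - 1], row.peptide[p - 1])
        e = max(row.e_max, floor)
        if mode == "printed":
            overall = sum_p / (row.b_nm * e)
        else:
            overall = sum_p * e / row.b_nm
        rows.append((row.peptide, sum_p, row.b_nm, row.e_max, overall))
    rows.sort(key=lambda r: (-r[4], -r[1], r[2], r[0]))
    out = pd.DataFrame(rows, columns=["peptide", "sum_p", "b_nM", "E_max",
                                      "overall_score"])
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


def random_index(rng: np.random.Generator, n: int, length: int = 9,
                 allele: str = "HLA-A24:02") -> ProteomeIndex:
    """Random proteome index with log-uniform affinities and expressions."""
    residues = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    peptides = set()
    while len(peptides) < n:
        peptides.update("".join(rng.choice(residues, size=length))
                        for _ in range(n - len(peptides)))
    peptides = sorted(peptides)
    table = pd.DataFrame({
        "peptide": peptides,
        "genes": [frozenset({f"G{i % 50:03d}"}) for i in range(n)],
        "b_nm": np.exp(rng.uniform(0, np.log(50000), size=n)),
        "rank_pct": rng.uniform(0, 100, size=n),
        "e_max": np.exp(rng.uniform(np.log(0.01), np.log(1000), size=n)),
    })
    return ProteomeIndex(allele=allele, length=length, table=table)
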