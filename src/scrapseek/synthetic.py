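"""Deterministic synthetic-data generators with planted ground truth.

Every input the rest of the package consumes — a gene-annotated proteome,
a tumour-vs-normal expression matrix, immunopeptidomics hit tables, a
normal-tissue ligandome, MS1 feature tables and a binding predictor — can
be generated here from a seed, together with the ground truth needed to
score the downstream result (planted cross-reactive peptides with expected
similarity scores and ranks, planted tumour-specific genes, per-record
funnel stage labels, feature-to-peptide provenance).

All generators are pure functions of (parameters, seed): a single root
seed fans out to fixed named substreams, so each fixture regenerates
byte-identically and independently of the others.

Design notes: residue composition is near-uniform over the 20 canonical
amino acids (tests need coverage of every chemical class, not human
composition); the toy binding predictor is an anchor-dominated
position-weight scheme mapped monotonically onto IC50 in [1, 50000] nM,
standing in for an external pMHC binding engine behind the same contract.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peptide_core import (CANONICAL_RESIDUES, classify_pair, default_table,
                           mz as peptide_mz, scored_positions)
from .proteome_index import ProteinRecord, window_peptides

__all__ = [
    "substream",
    "make_proteome",
    "ToyPredictor",
    "OverlayPredictor",
    "plant_cross_reactor",
    "PlantedCrossReactor",
    "make_expression",
    "ExpressionTruth",
    "make_immunopeptidome",
    "make_normal_ligandome",
    "make_ms1_features",
    "make_funnel_fixture",
    "FunnelFixture",
]

# fixed substream keys so fixtures are independently regenerable
_STREAM_KEYS = {
    "proteome": 11, "plant": 13, "expression": 17, "immunopeptidome": 19,
    "ligandome": 23, "ms1": 29, "funnel": 31,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child RNG of a root seed; stable across calls and call order."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAM_KEYS[name],)))


_RESIDUES = np.array(list(CANONICAL_RESIDUES))


def make_proteome(n_genes: int, length_range: tuple[int, int] = (50, 100),
                  seed: int = 0) -> list[ProteinRecord]:
    """Random gene-annotated proteome, one protein per gene."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = substream(seed, "proteome")
    lo, hi = length_range
    records = []
    for i in range(n_genes):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(_RESIDUES, size=length))
        records.append(ProteinRecord(f"P{i + 1:04d}", f"G{i + 1:04d}", seq))
    return records


class ToyPredictor:
    """Deterministic stand-in for an external pMHC binding engine.

    Per allele, anchor positions (P2 and the C terminus) carry dominant
    residue weights with one preferred residue at weight 1; non-anchor
    residues contribute a small mean term.  The summed energy is mapped
    monotonically onto IC50 in [1, 50000] nM and percentile rank in
    [0, 100]; the rank is a monotone transform of the IC50 within an
    allele.  Allele weight tables derive from (seed, crc32(allele)), so
    predictions are independent of call order.
    """

    IC50_MAX = 50000.0

    def __init__(self, seed: int = 0):
        self.seed = seed
        self._weights: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def _allele_weights(self, allele: str):
        if allele not in self._weights:
            rng = np.random.default_rng(
                np.random.SeedSequence(self.seed,
                                       spawn_key=(zlib.crc32(allele.encode()),)))
            w2 = rng.uniform(0, 0.8, size=20)
            wc = rng.uniform(0, 0.8, size=20)
            w2[rng.integers(20)] = 1.0   # preferred P2 residue
            wc[rng.integers(20)] = 1.0   # preferred C-terminal residue
            wother = rng.uniform(0, 1, size=20)
            self._weights[allele] = (w2, wc, wother)
        return self._weights[allele]

    def preferred_anchors(self, allele: str) -> tuple[str, str]:
        w2, wc, _ = self._allele_weights(allele)
        return CANONICAL_RESIDUES[int(np.argmax(w2))], \
            CANONICAL_RESIDUES[int(np.argmax(wc))]

    def _energy(self, peptide: str, allele: str) -> float:
        w2, wc, wother = self._allele_weights(allele)
        idx = [CANONICAL_RESIDUES.index(r) for r in peptide]
        other = [idx[i] for i in range(len(idx)) if i not in (1, len(idx) - 1)]
        return (w2[idx[1]] + wc[idx[-1]]
                + 0.1 * float(np.mean(wother[other])))

    def predict(self, peptide: str, allele: str) -> tuple[float, float]:
        e = self._energy(peptide, allele) / 2.1  # max energy 1 + 1 + 0.1
        e = min(max(e, 0.0), 1.0)
        ic50 = self.IC50_MAX ** (1.0 - e)
        rank = 100.0 * (1.0 - e)
        return float(ic50), float(rank)


class OverlayPredictor:
    """Base predictor with explicit (peptide, allele) overrides.

    Used to pin planted peptides to exact affinities while every other
    peptide keeps its base prediction.
    """

    def __init__(self, base, overrides: dict[tuple[str, str], tuple[float, float]]):
        self.base = base
        self.overrides = dict(overrides)

    def predict(self, peptide: str, allele: str) -> tuple[float, float]:
        key = (peptide, allele)
        if key in self.overrides:
            return self.overrides[key]
        return self.base.predict(peptide, allele)


@dataclass(frozen=True)
class PlantedCrossReactor:
    """Ground truth for one planted near-identical peptide."""

    peptide: str
    gene: str
    query: str
    substituted_positions: tuple[int, ...]
    expected_sum_p: int
    ic50_nm: float
    rank_pct: float
    expression_level: float
    expected_rank: int | None = None


def plant_cross_reactor(proteome: list[ProteinRecord], query: str,
                        n_substitutions: int = 0,
                        at_positions: tuple[int, ...] | None = None,
                        expression_level: float = 0.0,
                        ic50_nm: float = 1.0, rank_pct: float = 0.01,
                        seed: int = 0, convention: str = "text",
                        gene: str = "PLANTED",
                        ) -> tuple[list[ProteinRecord], PlantedCrossReactor]:
    """Insert a controlled near-copy of ``query`` into the proteome.

    The planted peptide differs from the query at exactly the requested
    1-based positions; each substitution picks a residue from a different
    chemical class, so it scores -2 wherever the position is scored.  With
    zero substitutions, minimum IC50 and expression at the E_max floor the
    planted peptide dominates a printed-mode scan (expected rank 1).
    Returns the extended proteome and the ground-truth record; the caller
    wires ``ic50_nm``/``rank_pct`` in via :class:`OverlayPredictor` and
    ``expression_level`` via the expression matrix.
    """
    rng = substream(seed, "plant")
    table = default_table()
    if at_positions is None:
        scored = scored_positions(len(query), convention)
        at_positions = tuple(scored[:n_substitutions])
    elif n_substitutions and len(at_positions) != n_substitutions:
        raise ValueError("n_substitutions disagrees with at_positions")
    if any(p < 1 or p > len(query) for p in at_positions):
        raise ValueError(f"positions {at_positions} outside 1..{len(query)}")
    planted = list(query)
    for p in at_positions:
        orig = query[p - 1]
        candidates = [r for r in CANONICAL_RESIDUES
                      if table.class_of[r] != table.class_of[orig]]
        planted[p - 1] = str(rng.choice(candidates))
    planted_seq = "".join(planted)
    scored = scored_positions(len(query), convention)
    expected = sum(classify_pair(query[p - 1], planted_seq[p - 1], table)
                   for p in scored)
    dominant = (not at_positions and ic50_nm <= 1.0 and expression_level <= 0.0)
    truth = PlantedCrossReactor(
        peptide=planted_seq, gene=gene, query=query,
        substituted_positions=tuple(at_positions), expected_sum_p=expected,
        ic50_nm=ic50_nm, rank_pct=rank_pct,
        expression_level=expression_level,
        expected_rank=1 if dominant else None)
    extended = proteome + [ProteinRecord(f"P_{gene}", gene, planted_seq)]
    return extended, truth


@dataclass(frozen=True)
class ExpressionTruth:
    planted_genes: frozenset[str]
    effect_log2: float
    tumour_samples: tuple[str, ...]
    tissues: tuple[str, ...]


def make_expression(genes: list[str], n_tumour: int = 20,
                    n_normal_tissues: int = 5, samples_per_tissue: int = 20,
                    planted_genes: tuple[str, ...] = (),
                    effect_log2: float = 3.0, seed: int = 0,
                    fixed_levels: dict[str, float] | None = None,
                    baseline_log2_range: tuple[float, float] = (1.0, 4.0),
                    sigma_log2: float = 1.0,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, ExpressionTruth]:
    """Tumour cohort vs multi-tissue normal expression with planted effects.

    Per gene, log2 expression is Normal(mu_g, sigma) with mu_g uniform in
    ``baseline_log2_range``; planted genes gain ``effect_log2`` log2 units
    in tumour samples only.  ``fixed_levels`` pins a gene to a constant
    FPKM across all samples (e.g. 0 for an unexpressed planted gene).
    Returns (genes x samples matrix, sample->tissue/cohort map, truth).
    """
    if effect_log2 < 0:
        raise ValueError("effect_log2 must be >= 0")
    unknown = set(planted_genes) - set(genes)
    if unknown:
        raise ValueError(f"planted genes not in gene list: {sorted(unknown)}")
    rng = substream(seed, "expression")
    tumour_samples = [f"T{i + 1:03d}" for i in range(n_tumour)]
    tissue_names = [f"tissue{t + 1:02d}" for t in range(n_normal_tissues)]
    normal_samples = [(f"N_{t}_{i + 1:02d}", t) for t in tissue_names
                      for i in range(samples_per_tissue)]
    samples = tumour_samples + [s for s, _ in normal_samples]

    lo, hi = baseline_log2_range
    mu = rng.uniform(lo, hi, size=len(genes))
    log2x = rng.normal(mu[:, None], sigma_log2, size=(len(genes), len(samples)))
    planted_set = frozenset(planted_genes)
    gidx = {g: i for i, g in enumerate(genes)}
    for g in planted_set:
        log2x[gidx[g], :n_tumour] += effect_log2
    x = np.power(2.0, log2x)
    expr = pd.DataFrame(x, index=pd.Index(genes, name="gene"), columns=samples)
    for g, level in (fixed_levels or {}).items():
        if g in gidx:
            expr.iloc[gidx[g], :] = level
    cohorts = pd.DataFrame(
        [{"sample": s, "tissue": "tumour", "cohort": "tumour"}
         for s in tumour_samples]
        + [{"sample": s, "tissue": t, "cohort": "normal"}
           for s, t in normal_samples])
    truth = ExpressionTruth(planted_genes=planted_set, effect_log2=effect_log2,
                            tumour_samples=tuple(tumour_samples),
                            tissues=tuple(tissue_names))
    return expr, cohorts, truth


def make_immunopeptidome(proteome: list[ProteinRecord], predictor,
                         allele: str, n_records: int, seed: int = 0,
                         length: int = 9,
                         samples: tuple[str, ...] = ("T001", "T002", "T003"),
                         ) -> pd.DataFrame:
    """Sample immunopeptidomics hits from proteome windows, biased to binders.

    Window selection weight is proportional to 1/IC50, mimicking the
    enrichment of strong binders among eluted ligands.  One row per record:
    sample, peptide, gene, allele, ic50_nm, rank_pct.
    """
    windows, _ = window_peptides(proteome, length)
    peptides = sorted(windows)
    if n_records > len(peptides):
        raise ValueError(f"requested {n_records} records but only "
                         f"{len(peptides)} unique windows available")
    rng = substream(seed, "immunopeptidome")
    preds = {p: predictor.predict(p, allele) for p in peptides}
    w = np.array([1.0 / preds[p][0] for p in peptides])
    chosen = rng.choice(len(peptides), size=n_records, replace=False,
                        p=w / w.sum())
    rows = []
    for j, ci in enumerate(chosen):
        p = peptides[ci]
        ic50, rank = preds[p]
        gene = sorted(windows[p])[0]
        rows.append({"sample": samples[j % len(samples)], "peptide": p,
                     "gene": gene, "allele": allele,
                     "ic50_nm": ic50, "rank_pct": rank})
    return pd.DataFrame(rows)


def make_normal_ligandome(proteome: list[ProteinRecord], n_peptides: int,
                          tissues: tuple[str, ...] = ("liver", "heart", "lung"),
                          seed: int = 0, length: int = 9) -> pd.DataFrame:
    """Benign-tissue immunopeptidome: peptide, parent gene, tissue."""
    windows, _ = window_peptides(proteome, length)
    peptides = sorted(windows)
    n = min(n_peptides, len(peptides))
    rng = substream(seed, "ligandome")
    chosen = rng.choice(len(peptides), size=n, replace=False)
    rows = []
    for ci in chosen:
        p = peptides[ci]
        rows.append({"peptide": p, "gene": sorted(windows[p])[0],
                     "tissue": str(rng.choice(list(tissues)))})
    return pd.DataFrame(rows, columns=["peptide", "gene", "tissue"])


def make_ms1_features(peptides: list[str], jitter_ppm: float = 0.0,
                      jitter_rt: float = 0.0, seed: int = 0,
                      reference_rt: float = 30.0,
                      samples: tuple[str, ...] = ("S1",),
                      charges: tuple[int, ...] = (1, 2, 3),
                      n_decoys_per_sample: int = 0,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """MS1 feature tables with known peptide provenance.

    Each (sample, peptide) emits one feature at the theoretical m/z of a
    randomly chosen charge offset by exactly ``jitter_ppm`` ppm (random
    sign) and at ``reference_rt`` offset by exactly ``jitter_rt`` minutes
    (random sign); decoy features land far from any planted m/z.  Returns
    (features, truth) where truth maps feature ids to source peptides.
    """
    rng = substream(seed, "ms1")
    feat_rows, truth_rows = [], []
    fid = 0
    for sample in samples:
        for pep in peptides:
            z = int(rng.choice(list(charges)))
            theo = peptide_mz(pep, z)
            sign_mz = rng.choice([-1.0, 1.0])
            sign_rt = rng.choice([-1.0, 1.0])
            obs_mz = theo * (1.0 + sign_mz * jitter_ppm * 1e-6)
            obs_rt = reference_rt + sign_rt * jitter_rt
            feat_rows.append({"feature_id": f"F{fid:05d}", "sample": sample,
                              "mz": obs_mz, "rt_min": obs_rt, "charge": z})
            truth_rows.append({"feature_id": f"F{fid:05d}", "sample": sample,
                               "peptide": pep, "charge": z,
                               "offset_ppm": sign_mz * jitter_ppm,
                               "offset_rt": sign_rt * jitter_rt})
            fid += 1
        for _ in range(n_decoys_per_sample):
            feat_rows.append({"feature_id": f"F{fid:05d}", "sample": sample,
                              "mz": float(rng.uniform(2000.0, 3000.0)),
                              "rt_min": float(rng.uniform(0.0, 120.0)),
                              "charge": int(rng.choice(list(charges)))})
            fid += 1
    features = pd.DataFrame(
        feat_rows, columns=["feature_id", "sample", "mz", "rt_min", "charge"])
    truth = pd.DataFrame(
        truth_rows, columns=["feature_id", "sample", "peptide", "charge",
                             "offset_ppm", "offset_rt"])
    return features, truth


@dataclass
class FunnelFixture:
    """A complete funnel input set with per-record stage labels.

    ``labels`` has one row per record with boolean columns
    ``pass_binding``, ``pass_de`` and ``pass_ligandome`` (each conditional
    on surviving the previous stage), computed from the planted
    construction, not by running the funnel.
    """

    records: pd.DataFrame
    expr: pd.DataFrame
    cohorts: pd.DataFrame
    ligandome: pd.DataFrame
    labels: pd.DataFrame
    tumour_genes: frozenset[str]
    benign_genes: frozenset[str]
    params: dict = field(default_factory=dict)


def make_funnel_fixture(seed: int = 0, n_genes: int = 30, n_records: int = 60,
                        n_tissues: int = 3, n_tumour: int = 20,
                        samples_per_tissue: int = 5,
                        frac_tumour_specific: float = 0.3,
                        frac_benign_ligandome: float = 0.3,
                        threshold_nm: float = 500.0) -> FunnelFixture:
    """Generate records + expression + ligandome with known stage labels.

    Tumour-specific genes get fully separated expression (tumour FPKM
    uniform in [64, 128] vs normal in [0, 1], a >= 6 log2-unit shift), so
    the rank-sum differential-expression call matches the planted label;
    the benign ligandome contains peptides from a random gene subset, so
    the gene-level exclusion label is exact.
    """
    rng = substream(seed, "funnel")
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    n_spec = max(1, int(round(frac_tumour_specific * n_genes)))
    tumour_genes = frozenset(rng.choice(genes, size=n_spec, replace=False))

    tumour_samples = [f"T{i + 1:03d}" for i in range(n_tumour)]
    tissue_names = [f"tissue{t + 1:02d}" for t in range(n_tissues)]
    normal_samples = [(f"N_{t}_{i + 1:02d}", t) for t in tissue_names
                      for i in range(samples_per_tissue)]
    samples = tumour_samples + [s for s, _ in normal_samples]
    mu = rng.uniform(1.0, 4.0, size=n_genes)
    x = np.power(2.0, rng.normal(mu[:, None], 1.0,
                                 size=(n_genes, len(samples))))
    for gi, g in enumerate(genes):
        if g in tumour_genes:
            x[gi, :n_tumour] = rng.uniform(64.0, 128.0, size=n_tumour)
            x[gi, n_tumour:] = rng.uniform(0.0, 1.0, size=len(normal_samples))
    expr = pd.DataFrame(x, index=pd.Index(genes, name="gene"), columns=samples)
    cohorts = pd.DataFrame(
        [{"sample": s, "tissue": "tumour", "cohort": "tumour"}
         for s in tumour_samples]
        + [{"sample": s, "tissue": t, "cohort": "normal"}
           for s, t in normal_samples])

    n_benign = int(round(frac_benign_ligandome * n_genes))
    benign_genes = frozenset(rng.choice(genes, size=n_benign, replace=False)) \
        if n_benign else frozenset()
    lig_rows = [{"peptide": "".join(rng.choice(_RESIDUES, size=9)),
                 "gene": g, "tissue": f"normal{j % 5}"}
                for j, g in enumerate(sorted(benign_genes))]
    ligandome = pd.DataFrame(lig_rows, columns=["peptide", "gene", "tissue"])

    rec_rows, label_rows = [], []
    for i in range(n_records):
        gene = str(rng.choice(genes))
        peptide = "".join(rng.choice(_RESIDUES, size=9))
        log_ic50 = rng.uniform(0.0, np.log(50000.0))
        ic50 = float(np.exp(log_ic50))
        rank = 100.0 * log_ic50 / np.log(50000.0)
        rec_rows.append({"sample": tumour_samples[i % n_tumour],
                         "peptide": peptide, "gene": gene,
                         "allele": "HLA-A24:02", "ic50_nm": ic50,
                         "rank_pct": rank})
        pb = ic50 <= threshold_nm
        pde = pb and gene in tumour_genes
        plig = pde and gene not in benign_genes
        label_rows.append({"pass_binding": pb, "pass_de": pde,
                           "pass_ligandome": plig})
    records = pd.DataFrame(rec_rows)
    labels = pd.DataFrame(label_rows)
    return FunnelFixture(records=records, expr=expr, cohorts=cohorts,
                         ligandome=ligandome, labels=labels,
                         tumour_genes=tumour_genes, benign_genes=benign_genes,
                         params={"seed": seed, "threshold_nm": threshold_nm})
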