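"""Antigen-discovery funnel and prioritization.

Immunopeptidomics hits (one row per sample x peptide x allele, with a
predicted IC50 and percentile rank) are filtered in three stages:

1. **binding** — keep predicted binders at or below an IC50 threshold
   (default 500 nM);
2. **differential expression** — keep peptides whose parent gene is
   over-expressed in the tumour cohort versus *every* normal tissue
   (default: log2 fold change >= 1 on log2(FPKM+1) and rank-sum P < 0.01
   per tissue);
3. **normal ligandome** — drop any peptide whose parent gene appears
   anywhere in an empirical normal-tissue immunopeptidome (gene-level
   exclusion: a single benign presentation of the gene disqualifies all of
   its peptides).

Survivors can then be ranked by a composite of differential expression,
HLA allele population frequency, relative peptide abundance, predicted
binding and recurrence across tumours — a decision-support ranking, since
the final shortlist in practice also weighs biological context.

The module also provides the cross-HLA presentation scan (which additional
alleles are predicted to present an identical peptide) and the MS1
matched-peptide search (m/z within ppm tolerance at some charge, retention
time within a window of a reference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .peptide_core import mz as peptide_mz
from .peptide_core import validate_peptide
from .proteome_index import BindingPredictor

__all__ = [
    "PMHC_COLUMNS",
    "DifferentialExpressionResult",
    "FunnelReport",
    "validate_pmhc_records",
    "filter_binding",
    "differential_expression",
    "de_pass_genes",
    "filter_normal_ligandome",
    "run_funnel",
    "prioritize",
    "cross_hla_scan",
    "CrossHlaResult",
    "match_ms1_features",
]

PMHC_COLUMNS = ["sample", "peptide", "gene", "allele", "ic50_nm", "rank_pct"]

FUNNEL_STAGES = ("input", "binding", "differential_expression", "normal_ligandome")


def validate_pmhc_records(records: pd.DataFrame) -> pd.DataFrame:
    """Check a peptide-table for required columns and valid peptides.

    Returns the frame unchanged; raises with row-level detail otherwise.
    """
    missing = [c for c in PMHC_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"peptide table missing columns {missing}")
    bad = []
    for i, p in records["peptide"].items():
        try:
            validate_peptide(str(p))
        except Exception as exc:
            bad.append(f"row {i}: {exc}")
    if bad:
        raise ValueError("invalid peptides:\n" + "\n".join(bad))
    return records


def filter_binding(records: pd.DataFrame, threshold_nm: float = 500.0
                   ) -> pd.DataFrame:
    """Keep predicted binders with IC50 <= ``threshold_nm`` (inclusive)."""
    if "ic50_nm" not in records.columns:
        raise ValueError("records lack an ic50_nm column")
    na = records.index[records["ic50_nm"].isna()].tolist()
    if na:
        raise ValueError(f"missing ic50_nm in rows {na}")
    return records[records["ic50_nm"] <= threshold_nm].copy()


@dataclass
class DifferentialExpressionResult:
    """Tumour-vs-each-normal-tissue test outcome for one gene.

    ``passes`` is the conjunction over every normal tissue of
    (lfc >= min_lfc AND p < alpha).
    """

    gene: str
    lfc: dict[str, float]
    p_value: dict[str, float]
    passes: bool


def differential_expression(expr: pd.DataFrame, cohorts: pd.DataFrame,
                            min_lfc: float = 1.0, alpha: float = 0.01,
                            test: str = "mannwhitney",
                            log_base: float = 2.0,
                            tumour_cohort: str = "tumour",
                            ) -> dict[str, DifferentialExpressionResult]:
    """Per-gene tumour-specificity calls against every normal tissue.

    ``expr`` is genes x samples (FPKM/RPKM); ``cohorts`` maps samples to a
    tissue and a cohort label, with the tumour cohort named by
    ``tumour_cohort`` and everything else treated as normal tissue grouped
    by its ``tissue`` value.  Fold changes are computed on
    log(x+1)/log(log_base) means; p-values from a two-sided Mann-Whitney
    rank-sum test (``test="welch"`` switches to Welch's t).  Tissues with
    fewer than two samples are excluded with a warning.  No
    multiple-testing correction is applied: the rule is a raw per-tissue
    P < alpha conjunction.
    """
    cohorts = cohorts.set_index("sample") if "sample" in cohorts.columns else cohorts
    samples = [s for s in expr.columns if s in cohorts.index]
    if len(samples) < len(expr.columns):
        dropped = set(expr.columns) - set(samples)
        warnings.warn(f"samples without cohort annotation dropped: {sorted(dropped)}")
    tumour_samples = [s for s in samples
                     if cohorts.loc[s, "cohort"] == tumour_cohort]
    if len(tumour_samples) < 2:
        raise ValueError(f"need >= 2 samples in cohort {tumour_cohort!r}, "
                         f"got {len(tumour_samples)}")
    normal = cohorts.loc[[s for s in samples if s not in set(tumour_samples)]]
    tissues: dict[str, list[str]] = {}
    for tissue, grp in normal.groupby("tissue"):
        if len(grp) < 2:
            warnings.warn(f"tissue {tissue!r} has < 2 samples; excluded")
            continue
        tissues[str(tissue)] = list(grp.index)
    if not tissues:
        raise ValueError("no normal tissue with >= 2 samples")

    logx = np.log1p(expr[samples].to_numpy(dtype=float)) / np.log(log_base)
    logx = pd.DataFrame(logx, index=expr.index, columns=samples)
    tum = logx[tumour_samples].to_numpy()
    tum_mean = tum.mean(axis=1)

    lfc_by_tissue: dict[str, np.ndarray] = {}
    p_by_tissue: dict[str, np.ndarray] = {}
    for tissue, cols in tissues.items():
        norm = logx[cols].to_numpy()
        lfc_by_tissue[tissue] = tum_mean - norm.mean(axis=1)
        if test == "mannwhitney":
            res = stats.mannwhitneyu(tum, norm, axis=1,
                                     alternative="two-sided")
        elif test == "welch":
            res = stats.ttest_ind(tum, norm, axis=1, equal_var=False)
        else:
            raise ValueError(f"unknown test {test!r}")
        p_by_tissue[tissue] = np.asarray(res.pvalue)

    results: dict[str, DifferentialExpressionResult] = {}
    for gi, gene in enumerate(expr.index):
        lfc = {t: float(lfc_by_tissue[t][gi]) for t in tissues}
        pv = {t: float(p_by_tissue[t][gi]) for t in tissues}
        passes = all(lfc[t] >= min_lfc and pv[t] < alpha for t in tissues)
        results[str(gene)] = DifferentialExpressionResult(
            gene=str(gene), lfc=lfc, p_value=pv, passes=passes)
    return results


def de_pass_genes(results: dict[str, DifferentialExpressionResult]) -> frozenset[str]:
    return frozenset(g for g, r in results.items() if r.passes)


def filter_normal_ligandome(records: pd.DataFrame,
                            normal_ligandome: pd.DataFrame) -> pd.DataFrame:
    """Drop records whose parent gene has any benign presentation.

    Exclusion is gene-level: one normal-tissue peptide from a gene removes
    every record of that gene, even for different peptide sequences.
    """
    if normal_ligandome is None or len(normal_ligandome) == 0:
        return records.copy()
    benign_genes = set(normal_ligandome["gene"].astype(str))
    return records[~records["gene"].astype(str).isin(benign_genes)].copy()


@dataclass
class FunnelReport:
    """Per-stage surviving record sets and counts for one funnel run."""

    stages: tuple[str, ...]
    surviving: dict[str, pd.DataFrame]
    params: dict = field(default_factory=dict)

    @property
    def counts(self) -> pd.DataFrame:
        rows = []
        for stage in self.stages:
            df = self.surviving[stage]
            rows.append({
                "stage": stage,
                "n_records": len(df),
                "n_unique_peptides": df["peptide"].nunique(),
                "n_unique_genes": df["gene"].nunique(),
            })
        return pd.DataFrame(rows)

    def survivors(self) -> pd.DataFrame:
        return self.surviving[self.stages[-1]]


def run_funnel(records: pd.DataFrame, expr: pd.DataFrame,
               cohorts: pd.DataFrame, normal_ligandome: pd.DataFrame,
               threshold_nm: float = 500.0, min_lfc: float = 1.0,
               alpha: float = 0.01, test: str = "mannwhitney") -> FunnelReport:
    """Run the three-stage funnel: binding -> DE -> benign-ligandome."""
    validate_pmhc_records(records)
    surviving = {"input": records.copy()}
    surviving["binding"] = filter_binding(surviving["input"], threshold_nm)
    de = differential_expression(expr, cohorts, min_lfc=min_lfc, alpha=alpha,
                                 test=test)
    passing = de_pass_genes(de)
    s = surviving["binding"]
    surviving["differential_expression"] = s[
        s["gene"].astype(str).isin(passing)].copy()
    surviving["normal_ligandome"] = filter_normal_ligandome(
        surviving["differential_expression"], normal_ligandome)
    return FunnelReport(
        stages=FUNNEL_STAGES, surviving=surviving,
        params={"threshold_nm": threshold_nm, "min_lfc": min_lfc,
                "alpha": alpha, "test": test})


_PRIOR_FACTORS = ("de_lfc", "allele_freq", "abundance", "binding", "recurrence")


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0 or not np.isfinite(sd):
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def prioritize(survivors: pd.DataFrame,
               allele_freq: dict[str, float] | None = None,
               recurrence: dict[str, int] | None = None,
               de_lfc: dict[str, float] | None = None,
               weights: dict[str, float] | None = None) -> pd.DataFrame:
    """Composite decision-support ranking of funnel survivors.

    One output row per unique (peptide, allele).  Factors, each z-scored
    and oriented so larger means a better target: minimum tumour log-fold
    change of the parent gene, HLA allele population frequency, relative
    peptide abundance (negated percentile rank), binding strength (negated
    log10 IC50) and recurrence (number of distinct tumours presenting the
    identical peptide).  Missing factors are imputed to the cohort median
    and flagged.  Weights default to equal.
    """
    if len(survivors) == 0:
        return pd.DataFrame(columns=["rank", "peptide", "gene", "allele",
                                     "composite"])
    agg = survivors.groupby(["peptide", "allele"], as_index=False).agg(
        gene=("gene", "first"),
        ic50_nm=("ic50_nm", "median"),
        rank_pct=("rank_pct", "median"),
        n_samples=("sample", "nunique"),
    )
    if recurrence is None:
        recurrence = agg.set_index("peptide")["n_samples"].to_dict()

    def lookup(mapping, keys):
        if mapping is None:
            return np.full(len(keys), np.nan)
        return np.array([mapping.get(k, np.nan) for k in keys], dtype=float)

    raw = pd.DataFrame({
        "de_lfc": lookup(de_lfc, agg["gene"]),
        "allele_freq": lookup(allele_freq, agg["allele"]),
        "abundance": -agg["rank_pct"].to_numpy(dtype=float),
        "binding": -np.log10(agg["ic50_nm"].to_numpy(dtype=float)),
        "recurrence": lookup(recurrence, agg["peptide"]),
    })
    imputed_cols = []
    for col in raw.columns:
        x = raw[col]
        if x.isna().all():
            raw[col] = 0.0
            imputed_cols.append(col)
        elif x.isna().any():
            raw[col] = x.fillna(x.median())
            imputed_cols.append(col)
    weights = dict(weights or {})
    w = np.array([weights.get(f, 1.0) for f in _PRIOR_FACTORS], dtype=float)
    z = np.column_stack([_zscore(raw[f].to_numpy()) for f in _PRIOR_FACTORS])
    composite = z @ (w / w.sum())

    out = agg[["peptide", "gene", "allele", "ic50_nm", "rank_pct"]].copy()
    for i, f in enumerate(_PRIOR_FACTORS):
        out[f"factor_{f}"] = raw[f].to_numpy()
        out[f"z_{f}"] = z[:, i]
    out["composite"] = composite
    out["imputed_factors"] = ";".join(imputed_cols) if imputed_cols else ""
    out = out.sort_values(by=["composite", "peptide", "allele"],
                          ascending=[False, True, True],
                          kind="mergesort").reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out


@dataclass
class CrossHlaResult:
    """Alleles predicted to present a peptide, plus unscorable alleles."""

    peptide: str
    presented: pd.DataFrame  # columns: allele, ic50_nm, rank_pct
    unscored: list[str]
    discovery_allele: str | None = None


def cross_hla_scan(peptide: str, alleles: list[str],
                   predictor: BindingPredictor,
                   rank_threshold_pct: float = 2.0,
                   discovery_allele: str | None = None) -> CrossHlaResult:
    """Which additional HLA alleles are predicted to present ``peptide``?

    An allele presents if its percentile rank is <= the threshold.  The
    discovery allele is excluded from the additional set; alleles the
    predictor cannot score are reported separately, never silently dropped.
    """
    peptide = validate_peptide(peptide)
    rows, unscored = [], []
    for allele in alleles:
        if discovery_allele is not None and allele == discovery_allele:
            continue
        try:
            ic50, rank = predictor.predict(peptide, allele)
        except Exception:
            unscored.append(allele)
            continue
        if rank <= rank_threshold_pct:
            rows.append({"allele": allele, "ic50_nm": ic50, "rank_pct": rank})
    presented = pd.DataFrame(rows, columns=["allele", "ic50_nm", "rank_pct"])
    presented = presented.sort_values(
        by=["rank_pct", "allele"], kind="mergesort").reset_index(drop=True)
    return CrossHlaResult(peptide=peptide, presented=presented,
                          unscored=unscored, discovery_allele=discovery_allele)


def match_ms1_features(peptide: str, features: pd.DataFrame,
                       reference_rt: float,
                       ppm_tol: float = 10.0, rt_window_min: float = 1.0,
                       charges: tuple[int, ...] = (1, 2, 3)) -> pd.DataFrame:
    """MS1 matched-peptide search for an unfragmented precursor.

    A feature (columns ``sample``, ``mz``, ``rt_min``) matches if its m/z is
    within ``ppm_tol`` of the theoretical m/z of ``peptide`` at some charge
    in ``charges`` AND its retention time is within ``rt_window_min``
    minutes of ``reference_rt``.  Matches are returned grouped by sample
    with the matched charge and the ppm error.  No retention-time
    prediction is attempted: the reference RT is required.
    """
    peptide = validate_peptide(peptide)
    if reference_rt is None:
        raise ValueError("reference_rt is required (no RT prediction is done)")
    for col in ("sample", "mz", "rt_min"):
        if col not in features.columns:
            raise ValueError(f"features table missing column {col!r}")
    theo = {z: peptide_mz(peptide, z) for z in charges}
    obs_mz = features["mz"].to_numpy(dtype=float)
    rt_ok = np.abs(features["rt_min"].to_numpy(dtype=float) - reference_rt) \
        <= rt_window_min
    best_z = np.zeros(len(features), dtype=int)
    best_ppm = np.full(len(features), np.inf)
    for z, t in theo.items():
        ppm = np.abs(obs_mz - t) / t * 1e6
        better = ppm < best_ppm
        best_ppm = np.where(better, ppm, best_ppm)
        best_z = np.where(better, z, best_z)
    hit = rt_ok & (best_ppm <= ppm_tol)
    out = features.loc[hit].copy()
    out["charge_matched"] = best_z[hit]
    out["ppm_error"] = best_ppm[hit]
    out["peptide"] = peptide
    return out.sort_values(by=["sample", "rt_min"],
                           kind="mergesort").reset_index(drop=True)
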