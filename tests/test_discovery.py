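"""Discovery funnel, prioritization, cross-HLA scan and MS1 matching."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from scrapseek.discovery import (cross_hla_scan, de_pass_genes,
                                 differential_expression, filter_binding,
                                 filter_normal_ligandome, match_ms1_features,
                                 prioritize, run_funnel)
from scrapseek.peptide_core import mz
from scrapseek.proteome_index import TablePredictor
from scrapseek.synthetic import make_funnel_fixture


def _records(ic50s, genes=None, peptides=None):
    n = len(ic50s)
    return pd.DataFrame({
        "sample": [f"T{i}" for i in range(n)],
        "peptide": peptides or ["ACDEFGHIK"] * n,
        "gene": genes or [f"g{i}" for i in range(n)],
        "allele": ["HLA-A24:02"] * n,
        "ic50_nm": ic50s,
        "rank_pct": np.linspace(0.1, 5, n),
    })


class TestFilterBinding:
    def test_boundary_inclusive_at_500(self):
        out = filter_binding(_records([100.0, 500.0, 501.0]))
        assert list(out["ic50_nm"]) == [100.0, 500.0]

    def test_infinite_threshold_is_identity(self):
        rec = _records([1.0, 49999.0])
        assert len(filter_binding(rec, np.inf)) == len(rec)

    def test_threshold_monotone(self):
        rec = _records(list(np.linspace(10, 5000, 20)))
        loose = set(filter_binding(rec, 1000).index)
        tight = set(filter_binding(rec, 200).index)
        assert tight <= loose

    def test_missing_ic50_errors_with_rows(self):
        rec = _records([100.0, np.nan, 200.0])
        with pytest.raises(ValueError, match="1"):
            filter_binding(rec)


def _separated_expression(n=10):
    """One gene: tumour FPKM 8 everywhere, every normal 0."""
    tum = {f"T{i}": 8.0 for i in range(n)}
    norm = {f"N_a_{i}": 0.0 for i in range(n)}
    norm.update({f"N_b_{i}": 0.0 for i in range(n)})
    expr = pd.DataFrame({**tum, **norm}, index=["g1"])
    cohorts = pd.DataFrame(
        [{"sample": s, "tissue": "tumour", "cohort": "tumour"} for s in tum]
        + [{"sample": s, "tissue": s.split("_")[1], "cohort": "normal"}
           for s in norm])
    return expr, cohorts


class TestDifferentialExpression:
    def test_fully_separated_gene_passes_with_closed_form_lfc(self):
        expr, cohorts = _separated_expression()
        res = differential_expression(expr, cohorts)["g1"]
        # lfc = log2(8+1) - log2(0+1) = 3.1699 per tissue
        # exact two-sided rank-sum p for complete 10-vs-10 separation is
        # 2/C(20,10); the tie-corrected asymptotic p is of the same order
        # and far below alpha either way
        for t in ("a", "b"):
            assert res.lfc[t] == pytest.approx(np.log2(9.0), abs=1e-9)
            assert res.p_value[t] < 0.01
        assert res.passes

    def test_identity_in_one_tissue_fails_conjunction(self):
        expr, cohorts = _separated_expression()
        # make tissue b identical to tumour
        for c in expr.columns:
            if c.startswith("N_b"):
                expr[c] = 8.0
        res = differential_expression(expr, cohorts)["g1"]
        assert not res.passes
        assert res.lfc["a"] >= 1.0  # still tumour-specific vs tissue a

    def test_invariant_to_sample_column_order(self):
        expr, cohorts = _separated_expression()
        rng = np.random.default_rng(0)
        expr.iloc[0] = rng.uniform(0, 10, size=expr.shape[1])
        shuffled = expr[list(rng.permutation(expr.columns))]
        a = differential_expression(expr, cohorts)["g1"]
        b = differential_expression(shuffled, cohorts)["g1"]
        assert a.passes == b.passes
        assert a.lfc == pytest.approx(b.lfc)

    def test_small_tissue_excluded_with_warning(self):
        expr, cohorts = _separated_expression()
        expr["N_c_0"] = 0.0
        cohorts = pd.concat([cohorts, pd.DataFrame(
            [{"sample": "N_c_0", "tissue": "c", "cohort": "normal"}])],
            ignore_index=True)
        with pytest.warns(UserWarning, match="c"):
            res = differential_expression(expr, cohorts)["g1"]
        assert set(res.lfc) == {"a", "b"}

    def test_welch_option(self):
        expr, cohorts = _separated_expression()
        rng = np.random.default_rng(1)
        expr.iloc[0, :10] = 64 + rng.uniform(0, 1, 10)
        assert differential_expression(expr, cohorts, test="welch")["g1"].passes


class TestLigandomeFilter:
    def test_gene_level_exclusion_drops_different_peptide(self):
        rec = _records([10.0], genes=["g1"], peptides=["ACDEFGHIK"])
        lig = pd.DataFrame({"peptide": ["WWWWWWWWK"], "gene": ["g1"],
                            "tissue": ["liver"]})
        assert len(filter_normal_ligandome(rec, lig)) == 0

    def test_empty_or_unrelated_ligandome_is_identity(self):
        rec = _records([10.0, 20.0])
        empty = pd.DataFrame(columns=["peptide", "gene", "tissue"])
        assert len(filter_normal_ligandome(rec, empty)) == 2
        unrelated = pd.DataFrame({"peptide": ["WWWWWWWWK"], "gene": ["gZ"],
                                  "tissue": ["liver"]})
        assert len(filter_normal_ligandome(rec, unrelated)) == 2


class TestFunnel:
    @pytest.mark.parametrize("seed", [0, 7, 23])
    def test_stage_sets_equal_planted_labels(self, seed):
        fx = make_funnel_fixture(seed=seed)
        report = run_funnel(fx.records, fx.expr, fx.cohorts, fx.ligandome)
        lbl = fx.labels
        assert set(report.surviving["binding"].index) == \
            set(lbl.index[lbl.pass_binding])
        assert set(report.surviving["differential_expression"].index) == \
            set(lbl.index[lbl.pass_de])
        assert set(report.surviving["normal_ligandome"].index) == \
            set(lbl.index[lbl.pass_ligandome])

    def test_counts_monotone_and_subset_chain(self):
        fx = make_funnel_fixture(seed=1)
        report = run_funnel(fx.records, fx.expr, fx.cohorts, fx.ligandome)
        counts = report.counts["n_records"].tolist()
        assert counts == sorted(counts, reverse=True)
        prev = None
        for stage in report.stages:
            idx = set(report.surviving[stage].index)
            if prev is not None:
                assert idx <= prev
            prev = idx

    def test_all_failing_input_gives_empty_final_stage(self):
        fx = make_funnel_fixture(seed=2)
        records = fx.records.assign(ic50_nm=10000.0)
        report = run_funnel(records, fx.expr, fx.cohorts, fx.ligandome)
        assert len(report.survivors()) == 0


class TestPrioritize:
    def test_single_candidate_is_rank_1(self):
        out = prioritize(_records([10.0]))
        assert len(out) == 1 and out.iloc[0]["rank"] == 1

    def test_recurrence_breaks_otherwise_identical_candidates(self):
        rec = pd.DataFrame({
            "sample": ["T1", "T2"],
            "peptide": ["ACDEFGHIK", "CDEFGHIKL"],
            "gene": ["g1", "g2"],
            "allele": ["A"] * 2,
            "ic50_nm": [100.0] * 2,
            "rank_pct": [1.0] * 2,
        })
        out = prioritize(rec, recurrence={"ACDEFGHIK": 8, "CDEFGHIKL": 1})
        assert out.iloc[0]["peptide"] == "ACDEFGHIK"

    def test_missing_factors_imputed_and_flagged(self):
        out = prioritize(_records([10.0, 20.0]), allele_freq=None)
        assert "allele_freq" in out["imputed_factors"].iloc[0]


class TestCrossHla:
    def _predictor(self):
        alleles = [f"A{i:02d}" for i in range(10)]
        ranks = [0.1, 0.5, 1.9, 2.5, 3.0, 10, 20, 40, 60, 90]
        return alleles, TablePredictor(
            {("ACDEFGHIK", a): (50.0 * (i + 1), r)
             for i, (a, r) in enumerate(zip(alleles, ranks))})

    def test_exactly_the_passing_alleles_sorted_by_rank(self):
        alleles, pred = self._predictor()
        res = cross_hla_scan("ACDEFGHIK", alleles, pred, rank_threshold_pct=2.0)
        assert list(res.presented["allele"]) == ["A00", "A01", "A02"]
        assert res.presented["rank_pct"].is_monotonic_increasing

    def test_threshold_extremes(self):
        alleles, pred = self._predictor()
        assert len(cross_hla_scan("ACDEFGHIK", alleles, pred, 0.0).presented) == 0
        assert len(cross_hla_scan("ACDEFGHIK", alleles, pred, 100.0).presented) == 10

    def test_discovery_allele_excluded_and_unknown_reported(self):
        alleles, pred = self._predictor()
        res = cross_hla_scan("ACDEFGHIK", alleles + ["B99"], pred,
                             rank_threshold_pct=2.0, discovery_allele="A00")
        assert "A00" not in set(res.presented["allele"])
        assert res.unscored == ["B99"]


class TestMs1Matching:
    PEP = "QYNPIRTTF"

    def _features(self, mz_vals, rts, sample="S1"):
        return pd.DataFrame({"sample": [sample] * len(mz_vals),
                             "mz": mz_vals, "rt_min": rts})

    def test_exact_mz_within_rt_window_matches(self):
        feats = self._features([mz(self.PEP, 2)], [30.5])
        out = match_ms1_features(self.PEP, feats, reference_rt=30.0)
        assert len(out) == 1
        assert out.iloc[0]["charge_matched"] == 2

    def test_rt_offset_beyond_window_never_matches(self):
        feats = self._features([mz(self.PEP, 2)], [31.5])
        assert len(match_ms1_features(self.PEP, feats, reference_rt=30.0)) == 0

    def test_mz_offset_beyond_tolerance_never_matches(self):
        off = mz(self.PEP, 2) * (1 + 50e-6)
        feats = self._features([off], [30.0])
        assert len(match_ms1_features(self.PEP, feats, reference_rt=30.0,
                                      ppm_tol=10.0)) == 0

    def test_reference_rt_required(self):
        feats = self._features([mz(self.PEP, 2)], [30.0])
        with pytest.raises(ValueError):
            match_ms1_features(self.PEP, feats, reference_rt=None)
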