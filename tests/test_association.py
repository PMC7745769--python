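import numpy as np
import pandas as pd
import pytest
from _oracles import oracle_conditional_mle_or, oracle_fisher_p
from scipy import stats

from xhybscan.association import (
    AssociationTable,
    PhenotypeTable,
    bonferroni_threshold,
    conditional_mle_or,
    correlation_check,
    enrichment_test,
    ewas,
    format_threshold,
    red_flag_report,
    regional_effect_check,
    shared_suffix_check,
)
from xhybscan.manifest import ProbeSequenceVariant
from xhybscan.mapping import FlagSet


def _phenotype(n, rng, carrier_fraction=0.5):
    ids = [f"s{i}" for i in range(n)]
    return PhenotypeTable(
        pd.DataFrame(
            {
                "status": (rng.random(n) < carrier_fraction).astype(int),
                "sex": rng.choice(["M", "F"], n),
                "batch": rng.choice(["b1", "b2"], n),
                "age": rng.normal(60, 8, n),
                "smoking_score": rng.normal(0, 1, n),
            },
            index=pd.Index(ids, name="sample_id"),
        )
    )


def _response(values, samples):
    return pd.DataFrame(
        np.atleast_2d(values),
        index=pd.Index([f"p{i}" for i in range(np.atleast_2d(values).shape[0])], name="probe_id"),
        columns=samples,
    )


class TestEwas:
    def test_status_must_be_binary(self, rng):
        frame = _phenotype(10, rng).frame.copy()
        frame["status"] = 2
        with pytest.raises(ValueError, match="binary"):
            PhenotypeTable(frame)

    def test_zero_variance_is_na_with_reason(self, rng):
        pheno = _phenotype(30, rng)
        resp = _response(np.ones((1, 30)), pheno.frame.index)
        table = ewas(resp, pheno)
        assert np.isnan(table.frame.loc["p0", "p"])
        assert table.frame.loc["p0", "reason"] == "zero variance"

    def test_agrees_with_statsmodels(self, rng):
        import statsmodels.api as sm

        pheno = _phenotype(80, rng)
        resp = _response(rng.normal(0, 1, size=(5, 80)), pheno.frame.index)
        resp.iloc[0] += pheno.frame["status"].to_numpy() * 0.8
        table = ewas(resp, pheno)
        X = pd.get_dummies(
            pheno.frame[["status", "sex", "batch", "age", "smoking_score"]],
            columns=["sex", "batch"],
            drop_first=True,
            dtype=float,
        )
        X = sm.add_constant(X.astype(float))
        for i, pid in enumerate(resp.index):
            fit = sm.OLS(resp.iloc[i].to_numpy(), X.to_numpy()).fit()
            assert table.frame.loc[pid, "effect"] == pytest.approx(fit.params[1])
            assert table.frame.loc[pid, "se"] == pytest.approx(fit.bse[1])
            assert table.frame.loc[pid, "p"] == pytest.approx(fit.pvalues[1])

    def test_null_pvalues_uniform(self, rng):
        pheno = _phenotype(200, rng)
        resp = _response(rng.normal(0.5, 0.1, size=(1000, 200)), pheno.frame.index)
        table = ewas(resp, pheno)
        ks = stats.kstest(table.frame["p"].dropna(), "uniform")
        # 1% critical value of the KS statistic for n=1000
        assert ks.statistic < 1.63 / np.sqrt(1000)

    def test_injected_effects_rank_first(self, rng):
        pheno = _phenotype(400, rng)
        resp = _response(rng.normal(0.5, 0.05, size=(500, 400)), pheno.frame.index)
        hit = rng.choice(500, size=20, replace=False)
        resp.iloc[hit] += 0.1 * pheno.frame["status"].to_numpy()
        table = ewas(resp, pheno)
        top20 = set(table.frame["p"].nsmallest(20).index)
        assert top20 == {f"p{i}" for i in hit}

    def test_location_invariance(self, rng):
        pheno = _phenotype(60, rng)
        resp = _response(rng.normal(0, 1, size=(3, 60)), pheno.frame.index)
        t1 = ewas(resp, pheno).frame["t"]
        t2 = ewas(resp + 7.5, pheno).frame["t"]
        np.testing.assert_allclose(t1, t2, rtol=1e-8)

    def test_missing_values_complete_case(self, rng):
        pheno = _phenotype(60, rng)
        values = rng.normal(0, 1, size=(2, 60))
        values[0, :5] = np.nan
        table = ewas(_response(values, pheno.frame.index), pheno)
        assert table.frame.loc["p0", "n"] == 55
        assert table.frame.loc["p1", "n"] == 60

    def test_collinear_covariates_named(self, rng):
        pheno_frame = _phenotype(50, rng).frame.copy()
        cells = rng.dirichlet([5, 5, 5], size=50)
        pheno_frame[["cellA", "cellB", "cellC"]] = cells  # sums to one
        pheno = PhenotypeTable(pheno_frame)
        resp = _response(rng.normal(0, 1, size=(2, 50)), pheno_frame.index)
        with pytest.raises(ValueError, match="rank-deficient"):
            ewas(resp, pheno, covariates=("age", "cellA", "cellB", "cellC"))
        # dropping one fraction restores estimability
        ewas(resp, pheno, covariates=("age", "cellA", "cellB"))


class TestBonferroni:
    def test_paper_scale_thresholds(self):
        assert bonferroni_threshold(0.05, 467303) == pytest.approx(1.07e-7, rel=1e-2)
        assert format_threshold(bonferroni_threshold(0.05, 467303)) == pytest.approx(1.1e-7)
        assert bonferroni_threshold(0.05, 16) == pytest.approx(0.003125)
        assert format_threshold(bonferroni_threshold(0.05, 16), sig_digits=1) == pytest.approx(0.003)
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)


class TestEnrichment:
    @staticmethod
    def _run(sig, flagged, universe_size):
        universe = {f"p{i}" for i in range(universe_size)}
        flags = FlagSet(threshold_bp=14, flagged_probe_ids=frozenset(flagged))
        return enrichment_test(flags, set(sig), universe)

    def test_balanced_table_is_null(self):
        res = self._run(
            sig={"p0", "p1"}, flagged={"p0", "p2"}, universe_size=4
        )
        assert res.table.tolist() == [[1, 1], [1, 1]]
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table",
        [
            [[2, 1], [1, 2]],
            [[5, 2], [3, 11]],
            [[1, 9], [8, 4]],
            [[6, 0], [3, 12]],
            [[0, 4], [7, 9]],
        ],
    )
    def test_small_tables_match_exhaustive_enumeration(self, table):
        p = float(stats.fisher_exact(table)[1])
        assert p == pytest.approx(oracle_fisher_p(table), rel=1e-6)
        mle = conditional_mle_or(table)
        oracle = oracle_conditional_mle_or(table)
        if np.isinf(oracle) or oracle == 0:
            assert mle == oracle
        else:
            assert mle == pytest.approx(oracle, rel=1e-3)

    def test_agrees_with_scipy_conditional_mle(self):
        from scipy.stats.contingency import odds_ratio

        for table in ([[2, 1], [1, 2]], [[7, 3], [2, 9]], [[11, 7], [126, 4672]]):
            assert conditional_mle_or(table) == pytest.approx(
                odds_ratio(table).statistic, rel=1e-6
            )

    def test_degenerate_margin(self):
        res = self._run(sig=set(), flagged={"p0"}, universe_size=3)
        assert res.status == "degenerate"

    def test_significant_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            self._run(sig={"q"}, flagged=set(), universe_size=2)


class TestChecks:
    def test_identical_rows_correlate_perfectly(self, rng):
        base = rng.normal(0.5, 0.1, 50)
        beta = pd.DataFrame(
            [base, base, rng.normal(0.5, 0.1, 50)],
            index=pd.Index(["a", "b", "c"], name="probe_id"),
        )
        out = correlation_check(beta, ["a", "b"])
        assert out["matrix"].loc["a", "b"] == pytest.approx(1.0)
        assert out["status"] == "warn"

    def test_independent_noise_uncorrelated(self, rng):
        beta = pd.DataFrame(
            rng.normal(0.5, 0.1, size=(10, 500)),
            index=pd.Index([f"p{i}" for i in range(10)], name="probe_id"),
        )
        out = correlation_check(beta, list(beta.index))
        assert out["mean_abs_r"] < 0.1
        assert out["status"] == "pass"

    def test_constant_probe_gives_na(self, rng):
        beta = pd.DataFrame(
            [np.ones(20), rng.normal(0.5, 0.1, 20)],
            index=pd.Index(["const", "var"], name="probe_id"),
        )
        out = correlation_check(beta, ["const", "var"])
        assert np.isnan(out["matrix"].loc["const", "var"])

    def test_shared_suffix_groups(self):
        variants = [
            ProbeSequenceVariant("a", 0, "A" * 40 + "GGGGTCGGGG", "NA", "II"),
            ProbeSequenceVariant("b", 0, "C" * 40 + "GGGGTCGGGG", "NA", "II"),
            ProbeSequenceVariant("c", 0, "C" * 40 + "TTTTTTTTTT", "NA", "II"),
        ]
        out = shared_suffix_check(variants, {"a", "b", "c"}, k=10)
        assert out["groups"] == {"GGGGTCGGGG": ["a", "b"]}
        assert out["status"] == "warn"
        by_base = shared_suffix_check(variants, {"a", "b", "c"}, k=1)
        assert by_base["groups"] == {"G": ["a", "b"]}
        with pytest.raises(ValueError):
            shared_suffix_check(variants, {"a"}, k=0)

    def test_regional_classification(self):
        assoc = AssociationTable(
            pd.DataFrame(
                {"p": [1e-9, 0.5, 0.5, 1e-9, 1e-5, 1e-9]},
                index=pd.Index(["sig1", "n1", "n2", "sig2", "n3", "lone"], name="probe_id"),
            ),
            "BETA",
        )
        positions = {
            "sig1": ("chr1", 1_000_000),
            "n1": ("chr1", 1_010_000),
            "n2": ("chr1", 990_000),
            "sig2": ("chr2", 5_000_000),
            "n3": ("chr2", 5_050_000),
            "lone": ("chr3", 1),
        }
        out = regional_effect_check(assoc, positions, ["sig1", "sig2", "lone"])
        assert out == {"sig1": "isolated", "sig2": "supported", "lone": "no_neighbors"}

    def test_report_with_no_significant_probes(self):
        report = red_flag_report(significant=set())
        assert all(c["status"] == "not_run" for c in report.checks.values())

    def test_report_marks_missing_components(self):
        report = red_flag_report(significant={"p1"})
        assert report.checks["correlation"]["status"] == "not_run"
        assert report.checks["oob_association"]["status"] == "not_run"
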