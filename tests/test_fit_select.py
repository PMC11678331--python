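import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from floralfit.core_data import BLOCKS
from floralfit.fit_select import (
    OptimizerConfig,
    aicc,
    block_diagnostics,
    compare_structures,
    design_matrix,
    fit_ensemble,
    fit_one,
    param_names,
    summarize_parameters,
    test_hypotheses,
    wls_oracle,
)
from floralfit.preprocess import interpolate, resample
from floralfit.reg_models import (
    ModelSpec,
    ParameterVector,
    cost,
    count_parameters,
)
from floralfit.synthetic_data import make_dataset, make_scenario

WLS = OptimizerConfig(method="wls")


def _replicates(scenario="Pal_like_SD", n=10, seed=3, n_intermediate=3):
    cfg = make_scenario(scenario, seed=seed)
    dense = interpolate(make_dataset(cfg), n_intermediate)
    return cfg, dense, resample(dense, n, seed=seed + 100)


class TestWlsOracle:
    def test_centered_regressor_gives_block_means_as_intercepts(self, toy_dataset):
        # when the regressor sums to zero within every block and sigmas are
        # equal, the weighted normal equations put c0 at the block AGL8 mean
        spec = ModelSpec.hypothesis("H5", c1_varies_by="none")
        for block in BLOCKS:
            s = toy_dataset.get(block, "FTc1")
            s.mean = s.mean - s.mean.mean()
        params, _ = wls_oracle(spec, toy_dataset)
        for block in BLOCKS:
            agl8 = toy_dataset.get(block, "AGL8").mean
            assert params.c0[block] == pytest.approx(agl8.mean())

    def test_agrees_with_brute_force_grid_on_two_parameter_toy(self, toy_dataset):
        # all blocks identical -> the optimum has equal c0 everywhere, so the
        # effective problem is 2-D and a grid refinement is an oracle
        for block in BLOCKS:
            for gene in ("FTc1", "AGL8"):
                ref = toy_dataset.get(BLOCKS[0], gene)
                s = toy_dataset.get(block, gene)
                s.mean = ref.mean.copy()
        spec = ModelSpec.hypothesis("H5", c1_varies_by="none")

        def f2(v):
            c0, c1 = v
            p = ParameterVector.from_array(spec, np.array([c0, c0, c0, c0, c1]))
            return cost(spec, p, toy_dataset)

        (gc0, gc1), gf, *_ = optimize.brute(
            f2, ((-5, 5), (-5, 5)), Ns=41, full_output=True, finish=optimize.fmin
        )
        params, f_min = wls_oracle(spec, toy_dataset)
        assert f_min == pytest.approx(gf, abs=1e-4)
        assert params.c0[BLOCKS[0]] == pytest.approx(gc0, abs=1e-3)
        assert params.c[(0, "all")] == pytest.approx(gc1, abs=1e-3)

    def test_residuals_orthogonal_to_weighted_design(self):
        _, _, reps = _replicates(n=3)
        for spec in [ModelSpec.model("M3"), ModelSpec.hypothesis("H2")]:
            for rep in reps:
                params, _ = wls_oracle(spec, rep)
                X, y, w = design_matrix(spec, rep)
                r = y - X @ params.to_array(spec)
                assert np.max(np.abs(X.T @ (w * r))) < 1e-8

    def test_rank_deficient_design_warns(self, toy_dataset):
        for block in BLOCKS:
            s = toy_dataset.get(block, "FTa2")
            s.mean = np.zeros_like(s.mean)
        spec = ModelSpec(
            family="M3",
            included_genes=("FTa2",),
            regulator_groups=(("FTa2",),),
        )
        with pytest.warns(RuntimeWarning, match="rank-deficient"):
            wls_oracle(spec, toy_dataset)


class TestFitOne:
    def test_noise_free_truth_recovered_exactly(self, toy_dataset):
        # toy AGL8 = 1 + 2*FTc1 exactly; the quadratic has a zero-residual
        # minimum at the generating parameters
        spec = ModelSpec.hypothesis("H5")
        fit = fit_one(spec, toy_dataset)
        assert fit.f_min == pytest.approx(0.0, abs=1e-10)
        arr = fit.params.to_array(spec)
        np.testing.assert_allclose(arr, [1, 1, 1, 1, 2, 2], atol=1e-6)

    def test_minimization_contract_beats_truth_params(self):
        cfg, _, reps = _replicates(n=5)
        for rep in reps:
            fit = fit_one(cfg.spec, rep)
            assert fit.f_min <= cost(cfg.spec, cfg.params, rep) + 1e-10

    def test_nelder_mead_matches_oracle(self):
        _, _, reps = _replicates(n=5)
        for spec in [ModelSpec.hypothesis("H0"), ModelSpec.model("M7")]:
            for rep in reps:
                nm = fit_one(spec, rep)
                _, f_wls = wls_oracle(spec, rep)
                assert nm.f_min == pytest.approx(f_wls, rel=1e-6, abs=1e-9)

    def test_explicit_init_and_unknown_method(self, toy_dataset):
        spec = ModelSpec.hypothesis("H5")
        init = ParameterVector.from_array(spec, np.ones(6))
        fit = fit_one(spec, toy_dataset, init=init)
        assert fit.f_min == pytest.approx(0.0, abs=1e-8)
        with pytest.raises(ValueError):
            fit_one(spec, toy_dataset, optimizer_cfg=OptimizerConfig(method="bfgs"))

    def test_random_restarts_do_not_worsen_the_minimum(self, toy_dataset):
        spec = ModelSpec.hypothesis("H5")
        base = fit_one(spec, toy_dataset)
        rst = fit_one(
            spec, toy_dataset, optimizer_cfg=OptimizerConfig(restarts=2, restart_seed=7)
        )
        assert rst.f_min <= base.f_min + 1e-9


class TestFitEnsemble:
    def test_zero_noise_ensemble_has_zero_parameter_spread(self):
        cfg = make_scenario("Pal_like_SD", seed=1, noise_cv=0.0)
        ds = make_dataset(cfg)
        for s in ds.series.values():
            s.sd = np.zeros_like(s.sd)
        dense = interpolate(ds, 2)
        reps = resample(dense, 5, seed=2)
        fr = fit_ensemble(cfg.spec, reps, WLS)
        assert np.all(fr.summary()["sd"] < 1e-9)
        assert fr.f_sd == pytest.approx(0.0, abs=1e-12)

    def test_summaries_invariant_to_replicate_order(self):
        cfg, _, reps = _replicates(n=8)
        a = fit_ensemble(cfg.spec, reps, WLS)
        rng = np.random.default_rng(0)
        shuffled = list(reps)
        rng.shuffle(shuffled)
        b = fit_ensemble(cfg.spec, shuffled, WLS)
        pd.testing.assert_frame_equal(a.summary(), b.summary())
        np.testing.assert_array_equal(a.f_values, b.f_values)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            fit_ensemble(ModelSpec.hypothesis("H0"), [], WLS)


class TestAicc:
    def test_printed_formula_on_a_grid(self):
        assert aicc(6, 61, 10.0) == pytest.approx(12 + 10 + 84 / 54)
        assert aicc(0, 10, 0.0) == 0.0
        for k, m, f in [(5, 52, 3.7), (12, 52, 8.1), (6, 41, 0.0)]:
            assert aicc(k, m, f) == pytest.approx(
                2 * k + f + (2 * k**2 + 2 * k) / (m - k - 1)
            )

    def test_domain_error_when_m_too_small(self):
        with pytest.raises(ValueError):
            aicc(6, 7, 1.0)
        with pytest.raises(ValueError):
            aicc(6, 6, 1.0)

    def test_penalty_strictly_increasing_in_k(self):
        vals = [aicc(k, 61, 5.0) for k in range(0, 20)]
        assert np.all(np.diff(vals) > 0)


class TestCompareStructures:
    def test_identical_fits_get_identical_aicc(self):
        _, dense, reps = _replicates(n=6)
        f1 = fit_ensemble(ModelSpec.model("M1"), reps, WLS)
        f1b = fit_ensemble(ModelSpec.model("M1"), reps, WLS)
        rep = compare_structures([f1, f1b], m=dense.n_points_total)
        assert rep["aicc"].nunique() == 1

    def test_nested_model_never_fits_worse(self):
        # M3 nests M1: oracle F_min(M3) <= F_min(M1) on every replicate
        _, _, reps = _replicates(n=20)
        for rep in reps:
            _, f1 = wls_oracle(ModelSpec.model("M1"), rep)
            _, f3 = wls_oracle(ModelSpec.model("M3"), rep)
            assert f3 <= f1 + 1e-9

    def test_mismatched_ensembles_rejected(self):
        _, dense, reps = _replicates(n=4)
        _, _, reps2 = _replicates(n=6)
        fa = fit_ensemble(ModelSpec.model("M1"), reps, WLS)
        fb = fit_ensemble(ModelSpec.model("M2"), reps2, WLS)
        with pytest.raises(ValueError, match="different datasets"):
            compare_structures([fa, fb], m=dense.n_points_total)


class TestHypothesisTests:
    def test_h0_against_itself_is_the_exact_null(self):
        _, _, reps = _replicates(n=6)
        f0 = fit_ensemble(ModelSpec.hypothesis("H0"), reps, WLS)
        rep = test_hypotheses({"H0": f0}).set_index("hypothesis")
        assert rep.loc["H0", "p_value"] == 1.0
        assert rep.loc["H0", "f_ratio_vs_h0"] == 1.0

    def test_identical_ensembles_give_p_one(self):
        _, _, reps = _replicates(n=6)
        f0 = fit_ensemble(ModelSpec.hypothesis("H0"), reps, WLS)
        for method in ("wilcoxon", "paired_t", "welch"):
            rep = test_hypotheses({"H0": f0, "H1": f0}, method=method)
            assert rep.set_index("hypothesis").loc["H1", "p_value"] == 1.0

    def test_unequal_ensemble_lengths_rejected(self):
        _, _, reps = _replicates(n=6)
        f0 = fit_ensemble(ModelSpec.hypothesis("H0"), reps, WLS)
        f1 = fit_ensemble(ModelSpec.hypothesis("H1"), reps[:4], WLS)
        with pytest.raises(ValueError, match="ensemble length"):
            test_hypotheses({"H0": f0, "H1": f1})

    def test_requires_h0_and_known_method(self):
        _, _, reps = _replicates(n=4)
        f1 = fit_ensemble(ModelSpec.hypothesis("H1"), reps, WLS)
        with pytest.raises(ValueError, match="H0"):
            test_hypotheses({"H1": f1})
        f0 = fit_ensemble(ModelSpec.hypothesis("H0"), reps, WLS)
        with pytest.raises(ValueError, match="unknown test method"):
            test_hypotheses({"H0": f0, "H1": f1}, method="anova")

    def test_holm_correction_only_increases_p(self):
        _, _, reps = _replicates("Ku_like_SD", n=30, seed=9)
        fits = {
            h: fit_ensemble(ModelSpec.hypothesis(h), reps, WLS)
            for h in ("H0", "H2", "H4", "H5")
        }
        raw = test_hypotheses(fits, holm=False).set_index("hypothesis")["p_value"]
        adj = test_hypotheses(fits, holm=True).set_index("hypothesis")["p_value"]
        assert np.all(adj.drop("H0") >= raw.drop("H0") - 1e-15)

    def test_star_coding_thresholds(self):
        from floralfit.fit_select import _stars

        assert _stars(0.005) == "**"
        assert _stars(0.03) == "*"
        assert _stars(0.2) == ""


class TestBlockDiagnostics:
    def test_contributions_sum_to_the_cost(self):
        cfg, dense, reps = _replicates(n=3)
        spec = ModelSpec.hypothesis("H4")
        for rep in reps:
            params, f_min = wls_oracle(spec, rep)
            diag = block_diagnostics(spec, params, rep)
            assert diag.total == pytest.approx(f_min, abs=1e-10)
            assert diag.total == pytest.approx(cost(spec, params, rep), abs=1e-10)

    def test_h0_diagnosed_against_itself_flags_nothing(self):
        cfg, dense, _ = _replicates(n=2)
        spec = ModelSpec.hypothesis("H0")
        params, _ = wls_oracle(spec, dense)
        ref = block_diagnostics(spec, params, dense)
        diag = block_diagnostics(spec, params, dense, reference=ref)
        assert not any(diag.flags.values())

    def test_frame_has_one_row_per_block(self):
        cfg, dense, _ = _replicates(n=2)
        params, _ = wls_oracle(cfg.spec, dense)
        df = block_diagnostics(cfg.spec, params, dense).to_frame()
        assert len(df) == 4
        assert set(zip(df.vernalization, df.daytime)) == set(BLOCKS)


class TestSummarizeParameters:
    def test_row_count_is_total_parameter_count(self):
        _, _, reps = _replicates(n=4)
        specs = [ModelSpec.model("M1"), ModelSpec.model("M3"), ModelSpec.hypothesis("H5")]
        fits = [fit_ensemble(s, reps, WLS) for s in specs]
        table = summarize_parameters(fits)
        assert len(table) == sum(count_parameters(s) for s in specs)

    def test_names_align_with_canonical_order(self):
        spec = ModelSpec.model("M2", c1_varies_by="daytime")
        names = param_names(spec)
        assert names[0] == ("c0", "V:morning")
        assert names[4:] == [
            ("c1", "morning"),
            ("c1", "evening"),
            ("c2", "morning"),
            ("c2", "evening"),
        ]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_parameters([])
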