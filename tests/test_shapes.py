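import itertools

import numpy as np
import pytest

from senkit import shapes, syndata
from senkit.shapes import (FAMILIES, ShapeFit, SwitchRecord, assign_shape,
                           classify_switch, fit_family, ks_gof, ks_statistic,
                           shape_census, switch_census)

from oracles import ks_d_naive


class TestFitFamily:
    def test_poisson_pmf_example(self):
        # lnL of [2,2,2,2] under lambda=2: 4*log pmf(2;2); BIC = ln4 - 2 lnL
        fit = fit_family([2, 2, 2, 2], family="P")
        assert fit.mu[0] == pytest.approx(2.0)
        assert fit.loglik == pytest.approx(-5.2274, abs=1e-4)
        assert fit.bic == pytest.approx(11.841, abs=1e-3)
        assert fit.k == 1

    @pytest.mark.parametrize("family", FAMILIES)
    def test_all_zero_input_is_degenerate(self, family):
        fit = fit_family(np.zeros(50, dtype=int), family=family)
        assert not fit.converged

    def test_non_integer_input_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            fit_family([1.5, 2.0], family="P")
        with pytest.raises(ValueError, match="negative|integer"):
            fit_family([-1, 2], family="P")

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            fit_family([1, 2], family="gaussian")

    def test_zinb_parameter_recovery(self):
        spec = syndata.ShapeSpec("g", families=["ZINB"], mu=[5.0],
                                 theta=[2.0], pi=[0.3], cells_per_group=5000)
        adata, _ = syndata.gen_shape_counts([spec], seed=17,
                                            timepoints=("T0",),
                                            replicates=("R1",))
        y = np.asarray(adata.X.todense()).ravel()
        fit = fit_family(y, family="ZINB")
        assert fit.pi == pytest.approx(0.3, abs=0.05)
        assert fit.mu[0] == pytest.approx(5.0, rel=0.05)

    def test_replicate_means_are_adjusted(self):
        spec = syndata.ShapeSpec("g", families=["NB"], mu=[8.0], theta=[3.0],
                                 replicate_effects=(1.0, 2.0, 0.5),
                                 cells_per_group=2000)
        adata, _ = syndata.gen_shape_counts([spec], seed=21,
                                            timepoints=("T0",))
        y = np.asarray(adata.X.todense()).ravel()
        fit = fit_family(y, adata.obs["replicate"], family="NB")
        assert fit.k == 3 + 1
        np.testing.assert_allclose(fit.mu, [8.0, 16.0, 4.0], rtol=0.07)
        # log-link coefficients: intercept + contrasts
        assert fit.beta[1] == pytest.approx(np.log(2.0), abs=0.1)

    @pytest.mark.parametrize("seed", range(6))
    def test_inflated_families_nest_their_base(self, seed):
        rng = np.random.default_rng(seed)
        y = np.where(rng.random(400) < 0.25, 0,
                     rng.negative_binomial(1.5, 1.5 / 5.5, 400))
        reps = np.repeat(["R1", "R2"], 200)
        eps = 1e-4
        fits = {f: fit_family(y, reps, f) for f in FAMILIES}
        assert fits["ZIP"].loglik >= fits["P"].loglik - eps
        assert fits["ZINB"].loglik >= fits["NB"].loglik - eps
        assert fits["NB"].loglik >= fits["P"].loglik - eps

    def test_poisson_limit_flagged_for_underdispersed_nb(self):
        # variance < mean drives the NB size parameter to its upper bound
        rng = np.random.default_rng(3)
        fit = fit_family(rng.binomial(10, 0.5, 2000), family="NB")
        assert fit.poisson_limit
        assert fit.converged


class TestKs:
    def test_statistic_matches_naive_scan(self, rng):
        y = rng.negative_binomial(2, 0.3, 300)
        fit = fit_family(y, family="NB")
        naive = ks_d_naive(y, lambda x: float(
            shapes._model_cdf(fit, np.array([x]), fit._rep_codes)[0]))
        assert ks_statistic(fit, y, fit._rep_codes) == pytest.approx(naive)

    def test_point_mass_vs_wide_nb_has_large_d(self):
        y = np.full(100, 5)
        fit = ShapeFit(gene="g", timepoint="T0", family="NB",
                       mu=np.array([5.0]), rep_levels=np.array(["R1"]),
                       theta=0.1, pi=None, loglik=-1.0, k=2, n=100,
                       converged=True,
                       _rep_codes=np.zeros(100, dtype=np.intp))
        d = ks_statistic(fit, y, fit._rep_codes)
        from scipy.stats import nbinom
        assert d >= 1.0 - nbinom.cdf(5, 0.1, 0.1 / 5.1) - 1e-12

    def test_p_value_bounds_and_resolution_guard(self, rng):
        y = rng.poisson(4, 200)
        fit = fit_family(y, family="P")
        p = ks_gof(fit, y, n_boot=19, seed=1)
        assert 1 / 20 <= p <= 1.0
        with pytest.raises(ValueError, match="n_boot"):
            ks_gof(fit, y, n_boot=10, seed=1)

    def test_calibration_under_the_null(self):
        # data drawn from the fitted model itself should rarely be rejected
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng([99, seed])
            y = rng.poisson(3.0, 1000)
            fit = fit_family(y, family="P")
            if ks_gof(fit, y, n_boot=99, seed=seed) > 0.05:
                hits += 1
        assert hits >= 0.9 * n_seeds

    def test_requires_converged_fit(self):
        fit = fit_family(np.zeros(30, dtype=int), family="P")
        with pytest.raises(ValueError, match="converged"):
            ks_gof(fit, np.zeros(30, dtype=int), seed=0)


class TestAssignShape:
    @pytest.mark.parametrize("planted,spec_kwargs", [
        ("P", dict(families=["P"], mu=[3.0])),
        ("NB", dict(families=["NB"], mu=[5.0], theta=[0.5])),
        ("ZINB", dict(families=["ZINB"], mu=[8.0], theta=[2.0], pi=[0.4])),
    ])
    def test_identifies_planted_family(self, planted, spec_kwargs):
        spec = syndata.ShapeSpec("g", cells_per_group=2000, **spec_kwargs)
        adata, _ = syndata.gen_shape_counts([spec], seed=31,
                                            timepoints=("T0",),
                                            replicates=("R1",))
        y = np.asarray(adata.X.todense()).ravel()
        a = assign_shape(y, alpha=0.05, n_boot=100, seed=5)
        assert a.family == planted

    def test_selection_is_permutation_invariant(self, rng):
        y = rng.negative_binomial(1.0, 0.2, 600)
        reps = np.repeat(["R1", "R2", "R3"], 200)
        a1 = assign_shape(y, reps, n_boot=49, seed=2)
        perm = rng.permutation(600)
        a2 = assign_shape(y[perm], reps[perm], n_boot=49, seed=2)
        assert a1.family == a2.family

    def test_unassigned_when_nothing_passes(self, rng):
        # bimodal far from every family at both modes
        y = np.concatenate([np.full(300, 1), np.full(300, 60)])
        a = assign_shape(y, alpha=0.05, n_boot=49, seed=3)
        assert a.family is None


class TestClassifySwitch:
    @pytest.mark.parametrize("triple,expected", [
        (("P", "NB", "ZIP"), "distinct_triple"),
        (("P", "NB", "P"), "reverting"),
        (("P", "P", "P"), "stable"),
        (("P", "P", "NB"), "single_transition"),
        (("NB", "ZIP", "ZIP"), "single_transition"),
        (("NONE", "P", "P"), "unassigned"),
        ((None, "P", "P"), "unassigned"),
    ])
    def test_examples(self, triple, expected):
        assert classify_switch(*triple) == expected

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            classify_switch("P", "gaussian", "NB")

    def test_partitions_all_64_triples(self):
        # independent brute-force categorisation of every triple
        counts = {c: 0 for c in shapes.SWITCH_CATEGORIES}
        for t in itertools.product(FAMILIES, repeat=3):
            counts[classify_switch(*t)] += 1
            a, b, c = t
            changes = (a != b) + (b != c)
            if changes == 0:
                expected = "stable"
            elif changes == 1:
                expected = "single_transition"
            else:
                expected = "reverting" if a == c else "distinct_triple"
            assert classify_switch(*t) == expected
        assert sum(counts.values()) == 64
        assert counts["unassigned"] == 0


class TestCensuses:
    def test_single_gene_census_is_total(self):
        df = shape_census([shapes.ShapeAssignment("g", t, "P")
                           for t in ("T0", "T1", "T2")])
        p_rows = df[df["family"] == "P"]
        assert (p_rows["pct"] == 100.0).all()

    def test_duplicate_assignment_rejected(self):
        a = [shapes.ShapeAssignment("g", "T0", "P"),
             shapes.ShapeAssignment("g", "T0", "NB")]
        with pytest.raises(ValueError, match="duplicate"):
            shape_census(a)

    def test_census_tracks_planted_proportions(self):
        # 60 genes: 30 P, 20 NB, 10 ZIP planted at one timepoint
        specs = ([syndata.ShapeSpec(f"p{i}", families=["P"], mu=[3.0],
                                    cells_per_group=1000) for i in range(30)]
                 + [syndata.ShapeSpec(f"n{i}", families=["NB"], mu=[5.0],
                                      theta=[0.5], cells_per_group=1000)
                    for i in range(20)]
                 + [syndata.ShapeSpec(f"z{i}", families=["ZIP"], mu=[6.0],
                                      pi=[0.5], cells_per_group=1000)
                    for i in range(10)])
        adata, _ = syndata.gen_shape_counts(specs, seed=41,
                                            timepoints=("T0",),
                                            replicates=("R1",))
        X = np.asarray(adata.X.todense())
        assigns = [assign_shape(X[:, j], n_boot=49, seed=j, gene=g,
                                timepoint="T0")
                   for j, g in enumerate(adata.var_names)]
        df = shape_census(assigns)
        pct = df.set_index("family")["pct"]
        assert pct["P"] == pytest.approx(50.0, abs=10)
        assert pct["NB"] == pytest.approx(33.3, abs=10)
        assert pct["ZIP"] == pytest.approx(16.7, abs=10)

    def test_empty_switch_census(self):
        patterns, totals = switch_census([])
        assert patterns.empty
        assert totals["differentially_distributed"] == 0

    def test_all_stable_switch_census(self):
        recs = [SwitchRecord(f"g{i}", ("P", "P", "P"), "stable")
                for i in range(5)]
        _, totals = switch_census(recs)
        assert totals["stable"] == 5
        assert totals["differentially_distributed"] == 0

    def test_duplicate_gene_rejected(self):
        recs = [SwitchRecord("g", ("P", "P", "P"), "stable")] * 2
        with pytest.raises(ValueError, match="duplicate"):
            switch_census(recs)
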