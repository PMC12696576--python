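"""Multinomial marginal fitting, copula calibration, sampling and fidelity."""

import warnings

import numpy as np
import pytest
from scipy import stats

import rcads_ml as r
from rcads_ml import copula
from rcads_ml.augment import gof_multinomial
from rcads_ml.itembank import item_column

from conftest import make_cohort


@pytest.fixture(scope="module")
def fitted(complete_cohort, bank):
    cohort, truth = complete_cohort
    model = r.fit_marginals(cohort, bank).calibrate(bank)
    return cohort, truth, model


class TestFitMarginals:
    def test_frequency_definition(self, bank):
        items = np.zeros((100, 47))
        items[:, 0] = np.repeat([0, 1, 2, 3], [10, 20, 30, 40])
        model = r.fit_marginals(make_cohort(items), bank)
        assert np.allclose(model.item_probs[1], [0.1, 0.2, 0.3, 0.4])

    def test_single_record_one_hot_with_warning(self, bank):
        items = np.full((1, 47), 2.0)
        with pytest.warns(UserWarning, match="single-record"):
            model = r.fit_marginals(make_cohort(items), bank)
        assert np.allclose(model.item_probs[1], [0, 0, 1, 0])

    def test_empty_cohort_rejected(self, bank):
        with pytest.raises(ValueError, match="empty"):
            r.fit_marginals(make_cohort(np.zeros((0, 47))), bank)

    def test_recovery_against_generator_truth(self, bank):
        """Fitted category probabilities close to generator truth at n=1780."""
        cfg = r.GeneratorConfig(n=1780, seed=21, missing_sex=0, missing_grade=0,
                                missing_both=0)
        cohort, truth = r.generate_cohort(cfg, bank, with_correlations=False)
        model = r.fit_marginals(cohort, bank)
        gap = max(
            np.max(np.abs(model.item_probs[i] - truth.item_probs[i]))
            for i in bank.item_ids
        )
        assert gap < 0.05

    def test_item_total_mode(self, complete_cohort, bank):
        cohort, _ = complete_cohort
        m = r.fit_marginals(cohort, bank, rho_mode="item_total")
        assert all(0 <= v <= 0.99 for v in m.subscale_rho.values())

    def test_json_round_trip(self, fitted, tmp_path, bank):
        _, _, model = fitted
        path = tmp_path / "model.json"
        model.to_json(path)
        back = r.AugmentationModel.from_json(path)
        assert back.fitted_n == model.fitted_n
        for i in bank.item_ids:
            assert np.allclose(back.item_probs[i], model.item_probs[i])
        assert back.latent_rho == pytest.approx(model.latent_rho)


class TestGofMultinomial:
    def test_exactly_proportional_counts(self):
        chi2, p = gof_multinomial([10, 20, 30, 40], [0.1, 0.2, 0.3, 0.4])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_uniform_counts_vs_uniform_reference(self):
        _, p = gof_multinomial([25, 25, 25, 25], [0.25] * 4)
        assert p == pytest.approx(1.0)

    def test_calibration_under_the_null(self):
        """Counts drawn from the reference: ~5% rejections."""
        rng = np.random.default_rng(5)
        ref = np.array([0.4, 0.3, 0.2, 0.1])
        rej = 0
        reps = 500
        for _ in range(reps):
            counts = rng.multinomial(200, ref)
            _, p = gof_multinomial(counts, ref)
            rej += p < 0.05
        assert 0.03 <= rej / reps <= 0.075

    def test_zero_reference_nonzero_count_rejected(self):
        with pytest.raises(ValueError, match="zero-probability"):
            gof_multinomial([10, 10, 5, 1], [0.5, 0.3, 0.2, 0.0])

    def test_zero_reference_categories_reduce_df(self):
        chi2, p = gof_multinomial([30, 70, 0, 0], [0.3, 0.7, 0.0, 0.0])
        assert p == pytest.approx(1.0)


class TestCalibration:
    def test_target_zero_maps_to_latent_zero(self):
        probs = [np.array([0.4, 0.3, 0.2, 0.1])] * 3
        assert copula.calibrate_latent_rho(0.0, probs) == 0.0

    def test_near_maximum_target_clamps(self):
        probs = [np.array([0.4, 0.3, 0.2, 0.1])] * 2
        with pytest.warns(UserWarning, match="clamping"):
            rho = copula.calibrate_latent_rho(0.99, probs)
        assert rho >= 0.99

    def test_monotone_induced_correlation(self):
        probs = [np.array([0.5, 0.3, 0.15, 0.05]), np.array([0.25] * 4)]
        grid = [copula.mean_induced_spearman(x, probs)
                for x in (0.0, 0.2, 0.4, 0.6, 0.8, 0.95)]
        assert all(a < b for a, b in zip(grid, grid[1:]))
        assert abs(grid[0]) < 1e-9

    @pytest.mark.parametrize(
        "probs_pair,target",
        [
            (([0.5, 0.5, 0.0, 0.0], [0.5, 0.5, 0.0, 0.0]), 0.35),
            (([0.55, 0.25, 0.15, 0.05], [0.55, 0.25, 0.15, 0.05]), 0.4),
            (([0.25, 0.25, 0.25, 0.25], [0.7, 0.2, 0.08, 0.02]), 0.3),
        ],
    )
    def test_calibration_matches_monte_carlo_oracle(self, probs_pair, target):
        """Induced Spearman within 0.01 of target vs a brute-force sample."""
        probs = [np.asarray(p, dtype=float) for p in probs_pair]
        latent = copula.calibrate_latent_rho(target, probs)
        rng = np.random.default_rng(123)
        X = copula.sample_discretized(latent, probs, 10**6, rng)
        induced = stats.spearmanr(X[:, 0], X[:, 1])[0]
        assert induced == pytest.approx(target, abs=0.01)

    def test_binary_case_matches_closed_form_quadrature(self):
        """Symmetric binary marginals: analytic check of the induced value."""
        probs = [np.array([0.5, 0.5, 0.0, 0.0])] * 2
        # P(both high) = 1/4 + arcsin(rho)/(2 pi); Spearman = phi coefficient
        rho = 0.5
        p11 = 0.25 + np.arcsin(rho) / (2 * np.pi)
        phi = (p11 - 0.25) / 0.25
        assert copula.induced_spearman(rho, probs[0], probs[1]) == pytest.approx(
            phi, abs=1e-6
        )


class TestSampling:
    def test_zero_latent_rho_gives_uncorrelated_items(self):
        probs = [np.array([0.4, 0.3, 0.2, 0.1])] * 4
        X = copula.sample_discretized(0.0, probs, 10_000, np.random.default_rng(1))
        corr = np.corrcoef(X, rowvar=False)
        assert np.max(np.abs(corr[np.triu_indices(4, 1)])) < 0.05

    def test_marginals_preserved(self, fitted, bank):
        _, _, model = fitted
        n = 100_000
        X = r.augment.sample_items(model, "MDD", n, bank, 7)
        for col, i in enumerate(bank.items_of("MDD")):
            p = model.item_probs[i]
            emp = np.bincount(X[:, col], minlength=4)[:4] / n
            tol = 3 * np.sqrt(np.maximum(p * (1 - p), 1e-12) / n)
            assert (np.abs(emp - p) <= np.maximum(tol, 5e-4)).all()

    def test_degenerate_marginal_constant_column(self, bank):
        probs = [np.array([1.0, 0.0, 0.0, 0.0])] * 2
        X = copula.sample_discretized(0.3, probs, 500, np.random.default_rng(2))
        assert (X == 0).all()


class TestGenerateSynthetic:
    def test_ratio_sizes(self, fitted, norms, bank):
        _, _, model = fitted
        synth = r.generate_synthetic(model, 4, 11, bank, norms)
        assert synth.n == 4 * 89 == 356
        assert synth.provenance == "synthetic"
        assert synth.ratio == 4
        assert synth.labels is not None and len(synth.labels) == 356

    def test_seed_determinism(self, fitted, norms, bank):
        _, _, model = fitted
        a = r.generate_synthetic(model, 4, 5, bank, norms)
        b = r.generate_synthetic(model, 4, 5, bank, norms)
        assert a.df.equals(b.df)
        assert np.array_equal(a.labels, b.labels)

    def test_nonstandard_ratio_warns(self, fitted, norms, bank):
        _, _, model = fitted
        with pytest.warns(UserWarning, match="non-standard"):
            synth = r.generate_synthetic(model, 2, 1, bank, norms)
        assert synth.n == 178

    def test_missing_norms_rejected(self, fitted, bank):
        _, _, model = fitted
        with pytest.raises(ValueError, match="norms"):
            r.generate_synthetic(model, 4, 1, bank, None)


class TestMakeHybrid:
    def test_sizes_and_order(self, fitted, norms, bank):
        cohort, _, model = fitted
        cohort.labels = r.score_cohort(cohort, bank, norms)["label"].to_numpy()
        synth = r.generate_synthetic(model, 4, 13, bank, norms)
        hybrid = r.make_hybrid(cohort, synth)
        assert hybrid.n == 89 + 356 == 445
        assert hybrid.provenance == "hybrid"
        assert hybrid.ratio == 4
        assert hybrid.df.iloc[:89].equals(cohort.df)
        # class counts conserved
        combined = np.concatenate([cohort.labels, synth.labels])
        assert np.array_equal(np.bincount(hybrid.labels, minlength=3),
                              np.bincount(combined, minlength=3))

    def test_ratio_twenty_arithmetic(self, fitted, norms, bank):
        _, _, model = fitted
        synth = r.generate_synthetic(model, 20, 3, bank, norms)
        assert synth.n == 1780
        hybrid = r.make_hybrid(fitted[0], synth)
        assert hybrid.n == 1869

    def test_empty_synthetic_is_identity_with_hybrid_provenance(self, fitted, bank):
        cohort, _, _ = fitted
        empty = r.Cohort(cohort.df.iloc[:0].copy(), provenance="synthetic")
        hybrid = r.make_hybrid(cohort, empty)
        assert hybrid.n == cohort.n
        assert hybrid.provenance == "hybrid"


class TestFidelity:
    def test_copy_is_perfectly_faithful(self, fitted, bank):
        cohort, _, model = fitted
        rep = r.fidelity(cohort, cohort, bank, model)
        assert all(v == 0 for v in rep.marginal_tv.values())
        assert all(p == pytest.approx(1.0) for p in rep.mw_p.values())

    def test_planted_shift_detected(self, fitted, norms, bank):
        """Moving 0.3 probability mass on one item trips its MW test."""
        _, _, model = fitted
        import copy

        shifted = copy.deepcopy(model)
        p = shifted.item_probs[7].copy()
        moved = min(0.3, p[0])
        p[0] -= moved
        p[3] += moved
        shifted.item_probs[7] = p
        synth = r.generate_synthetic(shifted, 4, 19, bank, norms)
        rep = r.fidelity(fitted[0], synth, bank, model)
        assert rep.mw_p[7] < 0.01

    def test_tv_shrinks_at_large_ratio(self, fitted, norms, bank):
        cohort, _, model = fitted
        synth = r.generate_synthetic(model, 20, 23, bank, norms)
        rep = r.fidelity(cohort, synth, bank, model)
        assert max(rep.marginal_tv.values()) < 0.06

    def test_correlation_preserved_at_large_n(self, fitted, norms, bank):
        _, _, model = fitted
        synth = r.generate_synthetic(model, 20, 29, bank, norms)
        rep = r.fidelity(fitted[0], synth, bank, model)
        assert max(rep.corr_gap.values()) < 0.05
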