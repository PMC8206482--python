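import numpy as np
import pytest

from wordingsim.contamination import contaminate
from wordingsim.datagen import (
    DesignCell,
    PopulationSpec,
    build_population_matrix,
    draw_loadings,
    generate_sample,
    make_rng,
)
from wordingsim.polycorr import MixedCorrMatrix, build_mixed_matrix
from wordingsim.sem import (
    ModelSpec,
    WordingFactorModel,
    factor_scores,
    fit_indices,
    implied_correlations,
)

from conftest import make_sample


def population_mixed_matrix(spec: PopulationSpec) -> MixedCorrMatrix:
    """Exact population matrix packaged as an estimated one (unit weights)."""
    k = spec.n_items
    n_moments = k * (k - 1) // 2 + k
    return MixedCorrMatrix(
        corr=build_population_matrix(spec),
        thresholds_hat=np.tile(np.asarray(spec.thresholds), (k, 1)),
        asym_var=np.ones(n_moments),
        n=1000,
    )


class TestImpliedCorrelations:
    def test_onefactor_reduces_to_loading_products(self):
        spec = ModelSpec("onefactor", 2, criterion_included=False)
        r = implied_correlations([0.7, -0.7], spec)
        assert r[0, 1] == pytest.approx(-0.49)
        assert np.allclose(np.diag(r), 1.0)

    def test_riifa_adds_wording_variance(self):
        spec = ModelSpec("riifa", 2, criterion_included=False)
        # parameter vector: loadings then sqrt(omega)
        r = implied_correlations([0.7, -0.7, np.sqrt(0.1)], spec)
        assert r[0, 1] == pytest.approx(-0.49 + 0.1)

    def test_criterion_column(self):
        spec = ModelSpec("riifa", 2, criterion_included=True)
        s = np.sqrt(0.1)
        r = implied_correlations([0.7, -0.7, 0.4, 0.2, s], spec)
        assert r[0, 2] == pytest.approx(0.7 * 0.4 + s * 0.2)
        assert np.allclose(np.diag(r), 1.0)


class TestZeroResidualRecovery:
    def test_onefactor_recovers_generating_parameters(self, rng):
        spec = PopulationSpec(n_items=12, loadings=draw_loadings(12, rng))
        fit = WordingFactorModel(population_mixed_matrix(spec), "onefactor").fit(
            compute_scores=False
        )
        assert fit.converged
        assert np.abs(fit.loadings_hat - spec.loadings).max() < 1e-6
        assert fit.beta_sf == pytest.approx(0.50, abs=1e-6)  # path product 0.50 * 1.0
        assert fit.chi2 == pytest.approx(0.0, abs=1e-6)
        assert fit.cfi == 1.0
        assert fit.rmsea == 0.0

    def test_riifa_hits_omega_boundary_on_clean_population(self, rng):
        spec = PopulationSpec(n_items=12, loadings=draw_loadings(12, rng))
        fit = WordingFactorModel(population_mixed_matrix(spec), "riifa").fit(
            compute_scores=False
        )
        assert fit.omega_hat < 1e-5
        assert not fit.converged
        assert "boundary" in fit.reason


class TestDegreesOfFreedom:
    @pytest.mark.parametrize("k", [10, 12, 24, 60])
    def test_riifa_costs_two_parameters_with_criterion(self, k):
        """With the criterion regressed on both factors, RIIFA frees omega and
        beta_wf, so df drops by 2 — the accounting that reproduces the
        accounting standard SEM software reports (df = 44 vs 42 for a
        10-item scale plus criterion)."""
        d1 = ModelSpec("onefactor", k, criterion_included=True)
        d2 = ModelSpec("riifa", k, criterion_included=True)
        assert d1.df - d2.df == 2
        if k == 10:
            assert d1.df == 44
            assert d2.df == 42

    @pytest.mark.parametrize("k", [10, 24])
    def test_riifa_costs_one_df_without_criterion(self, k):
        d1 = ModelSpec("onefactor", k, criterion_included=False)
        d2 = ModelSpec("riifa", k, criterion_included=False)
        assert d1.df - d2.df == 1


class TestFitIndices:
    def test_cfi_formula_by_hand(self):
        cfi, _, _ = fit_indices(100, 10, 1000, 45, 101)
        assert cfi == pytest.approx(1 - 90 / 955)

    def test_rmsea_formula_by_hand(self):
        _, _, rmsea = fit_indices(100, 10, 1000, 45, 101)
        assert rmsea == pytest.approx(np.sqrt(90 / (10 * 100)))

    def test_perfect_fit_clamps(self):
        cfi, tli, rmsea = fit_indices(8, 10, 1000, 45, 101)
        assert cfi == 1.0
        assert tli == 1.0
        assert rmsea == 0.0

    def test_degenerate_baseline_clamps_cfi(self):
        cfi, _, _ = fit_indices(12, 10, 9, 45, 101)
        assert cfi == 1.0


class TestFactorScores:
    def test_eap_matches_dense_grid_oracle(self, rng):
        spec = PopulationSpec(n_items=6, loadings=draw_loadings(6, rng))
        fit = WordingFactorModel(population_mixed_matrix(spec), "onefactor").fit(
            compute_scores=False
        )
        resp = rng.integers(1, 5, size=(40, 6))
        data = make_sample(resp, polarity=spec.item_polarity)
        eap, _ = factor_scores(data, fit)
        # brute-force posterior mean on a dense Riemann grid
        grid = np.linspace(-6, 6, 201)
        lam, tau = fit.loadings_hat, fit.thresholds_hat
        sd = np.sqrt(np.maximum(1 - lam**2, 5e-3))
        from scipy.special import ndtr

        edges = np.concatenate([np.full((6, 1), -np.inf), tau, np.full((6, 1), np.inf)], axis=1)
        probs = np.diff(ndtr((edges[:, None, :] - lam[:, None, None] * grid[None, :, None]) / sd[:, None, None]), axis=2)
        prior = np.exp(-grid**2 / 2)
        oracle = np.empty(40)
        for r in range(40):
            like = prior.copy()
            for i in range(6):
                like *= probs[i, :, resp[r, i] - 1]
            oracle[r] = np.sum(grid * like) / np.sum(like)
        assert np.abs(eap - oracle).max() < 1e-4

    def test_extreme_consistent_pattern_scores_highest(self, rng):
        cell = DesignCell("none", 0, 300, 12, custom=True)
        spec, data = generate_sample(cell, 41, 42)
        fit = WordingFactorModel.from_sample(data, "onefactor").fit(compute_scores=False)
        resp = data.responses.copy()
        resp[0] = np.where(np.asarray(data.item_polarity) == "PW", 4, 1)
        top = make_sample(resp, polarity=data.item_polarity, criterion=data.criterion)
        sf, _ = factor_scores(top, fit)
        assert sf[0] == pytest.approx(sf.max())

    def test_refuses_nonconverged_fit(self, rng):
        spec = PopulationSpec(n_items=12, loadings=draw_loadings(12, rng))
        fit = WordingFactorModel(population_mixed_matrix(spec), "riifa").fit(
            compute_scores=False
        )
        data = make_sample(rng.integers(1, 5, size=(10, 12)))
        with pytest.raises(ValueError):
            factor_scores(data, fit)


class TestOnSampleData:
    def test_nesting_riifa_never_fits_worse(self):
        cell = DesignCell("carelessness", 40, 500, 12)
        _, clean = generate_sample(cell, 51, 52)
        cont, _ = contaminate(clean, "carelessness", 40, make_rng(53))
        M = build_mixed_matrix(cont)
        f1 = WordingFactorModel(M, "onefactor").fit(compute_scores=False)
        f2 = WordingFactorModel(M, "riifa").fit(compute_scores=False)
        assert f2.fmin <= f1.fmin + 1e-10

    def test_models_agree_on_clean_data(self):
        """Without wording contamination the RIIFA reduces to the 1F model
        (omega at the boundary), so both models' EAP scores coincide."""
        cell = DesignCell("none", 0, 1000, 24)
        _, data = generate_sample(cell, 61, 62)
        m = WordingFactorModel.from_sample(data, "riifa")
        fit2 = m.fit(compute_scores=False)
        assert not fit2.converged  # omega boundary
        fit2.converged = True  # score the boundary solution anyway
        sf2, _ = factor_scores(data, fit2)
        fit1 = WordingFactorModel(m.corr, "onefactor", data=data).fit(compute_scores=False)
        sf1, _ = factor_scores(data, fit1)
        assert np.corrcoef(sf1, sf2)[0, 1] > 0.99

    def test_parameter_recovery_over_replicates(self):
        """Mean loading and structural-coefficient bias on clean data."""
        lam_bias, beta = [], []
        for rep in range(12):
            cell = DesignCell("none", 0, 1000, 24)
            spec, data = generate_sample(cell, 100 + rep, 200 + rep)
            fit = WordingFactorModel(build_mixed_matrix(data), "onefactor").fit(
                compute_scores=False
            )
            assert fit.converged
            lam_bias.append(np.mean(fit.loadings_hat - spec.loadings))
            beta.append(fit.beta_sf)
        assert abs(np.mean(lam_bias)) < 0.02
        assert np.mean(beta) == pytest.approx(0.50, abs=0.02)

    def test_summary_mentions_key_quantities(self):
        cell = DesignCell("none", 0, 300, 12, custom=True)
        _, data = generate_sample(cell, 71, 72)
        fit = WordingFactorModel.from_sample(data, "onefactor").fit(compute_scores=False)
        text = fit.summary()
        assert "CFI" in text and "RMSEA" in text and "beta_sf" in text
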