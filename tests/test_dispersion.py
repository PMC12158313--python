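"""Multi-logistic dispersion model: identities, fitting, extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from esospec import (
    DispersionParams,
    DispersionTerm,
    PermittivitySpectrum,
    conductivity_at_frequency,
    evaluate_model,
    fit_dispersions,
    initial_guess,
    relaxation_summary,
)
from esospec.dispersion import (
    DispersionError,
    ExtrapolationError,
    FittedDispersionModel,
)

TWO_TERM = DispersionParams(
    log_eps_inf=1.0,
    terms=(
        DispersionTerm(step=1.0, log_w2_tau=6.0, slope=1.0),   # α
        DispersionTerm(step=0.5, log_w2_tau=14.0, slope=1.2),  # β
    ),
)


def spectrum_from_params(params, f_lo=1.0, f_hi=1e8, n=64):
    f = np.logspace(np.log10(f_lo), np.log10(f_hi), n)
    lw = np.log10(2 * np.pi * f)
    eps_real = 10.0 ** evaluate_model(params, lw)
    return PermittivitySpectrum(frequencies=f, eps_real=eps_real,
                                eps_imag=np.ones(n))


@st.composite
def random_params(draw):
    n_terms = draw(st.integers(1, 3))
    lei = draw(st.floats(-1, 2))
    locs = sorted(
        draw(st.lists(st.floats(2, 18), min_size=n_terms, max_size=n_terms,
                      unique=True))
    )
    # enforce strict separation so ordering is meaningful
    for i in range(1, len(locs)):
        locs[i] = max(locs[i], locs[i - 1] + 0.2)
    terms = tuple(
        DispersionTerm(step=draw(st.floats(0.1, 3)), log_w2_tau=loc,
                       slope=draw(st.floats(0.2, 5)))
        for loc in locs
    )
    return DispersionParams(log_eps_inf=lei, terms=terms)


class TestEvaluateModel:
    def test_high_frequency_limit(self):
        lw = np.array([TWO_TERM.terms[-1].log_w2_tau / 2 + 100.0])
        assert evaluate_model(TWO_TERM, lw)[0] == pytest.approx(
            TWO_TERM.log_eps_inf, abs=1e-12
        )

    def test_low_frequency_plateau_sums_steps(self):
        # two-term model with lε′∞=1 and steps 1.0 + 0.5 plateaus at 2.5
        lw = np.array([-100.0])
        assert evaluate_model(TWO_TERM, lw)[0] == pytest.approx(2.5, abs=1e-12)

    def test_single_term_midpoint(self):
        p = DispersionParams(log_eps_inf=0.7,
                             terms=(DispersionTerm(step=1.4, log_w2_tau=8.0, slope=2.0),))
        lw = np.array([4.0])  # 2·lω = 8 = location
        assert evaluate_model(p, lw)[0] == pytest.approx(0.7 + 1.4 / 2, abs=1e-14)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(params=random_params(), seed=st.integers(0, 10_000))
    def test_monotone_non_increasing(self, params, seed):
        rng = np.random.default_rng(seed)
        lw = np.sort(rng.uniform(-5, 15, size=40))
        y = evaluate_model(params, lw)
        assert np.all(np.diff(y) <= 1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(params=random_params())
    def test_plateau_limits(self, params):
        # 10 slope-widths beyond every transition reaches the plateaus to 1e-6
        widths = [10.0 / t.slope for t in params.terms]
        lo = min(t.log_w2_tau for t in params.terms) / 2 - max(widths)
        hi = max(t.log_w2_tau for t in params.terms) / 2 + max(widths)
        y_lo = evaluate_model(params, np.array([lo]))[0]
        y_hi = evaluate_model(params, np.array([hi]))[0]
        assert y_lo == pytest.approx(params.log_eps_inf + params.total_step, abs=1e-6)
        assert y_hi == pytest.approx(params.log_eps_inf, abs=1e-6)

    def test_params_validation(self):
        with pytest.raises(DispersionError):
            DispersionTerm(step=-1.0, log_w2_tau=5.0, slope=1.0)
        with pytest.raises(DispersionError):
            DispersionParams(log_eps_inf=1.0, terms=(
                DispersionTerm(1.0, 8.0, 1.0), DispersionTerm(1.0, 6.0, 1.0)))


class TestInitialGuess:
    def test_locations_near_truth_noiseless(self):
        perm = spectrum_from_params(TWO_TERM)
        guess = initial_guess(perm, n_terms=2)
        for got, want in zip(guess.terms, TWO_TERM.terms):
            assert abs(got.log_w2_tau - want.log_w2_tau) < 2 * 0.5  # 0.5 in lω units

    def test_flat_spectrum_falls_back(self):
        f = np.logspace(1, 7, 32)
        perm = PermittivitySpectrum(frequencies=f, eps_real=np.full(32, 50.0),
                                    eps_imag=np.ones(32))
        with pytest.warns(UserWarning, match="falling back"):
            guess = initial_guess(perm, n_terms=2)
        assert guess.n_terms == 2
        assert all(t.step <= 0.05 for t in guess.terms)  # near-zero steps

    @pytest.mark.parametrize("n_terms", [2, 3])
    def test_guess_satisfies_invariants(self, n_terms):
        import warnings
        perm = spectrum_from_params(TWO_TERM)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            guess = initial_guess(perm, n_terms=n_terms)
        locs = [t.log_w2_tau for t in guess.terms]
        assert locs == sorted(locs)
        assert all(t.step > 0 and t.slope > 0 for t in guess.terms)


class TestFit:
    def test_noiseless_recovery(self):
        perm = spectrum_from_params(TWO_TERM)
        fit = fit_dispersions(perm, n_terms=2, seed=0)
        assert fit.converged
        assert fit.residual_sse < 1e-10
        for got, want in zip(fit.params.terms, TWO_TERM.terms):
            assert got.log_w2_tau == pytest.approx(want.log_w2_tau, rel=0.01)
            assert got.step == pytest.approx(want.step, rel=0.01)

    def test_refit_from_optimum_is_fixed_point(self):
        perm = spectrum_from_params(TWO_TERM)
        fit1 = fit_dispersions(perm, n_terms=2, seed=0)
        fit2 = fit_dispersions(perm, n_terms=2, init=fit1.params, seed=1)
        assert fit2.residual_sse <= fit1.residual_sse + 1e-12

    def test_invariant_under_initial_term_permutation(self):
        perm = spectrum_from_params(TWO_TERM)
        init_fwd = initial_guess(perm, n_terms=2)
        # swap the initial terms (locations must stay ordered in the type, so
        # build the swapped start by exchanging step/slope between terms)
        a, b = init_fwd.terms
        init_swapped = DispersionParams(
            log_eps_inf=init_fwd.log_eps_inf,
            terms=(DispersionTerm(b.step, a.log_w2_tau, b.slope),
                   DispersionTerm(a.step, b.log_w2_tau, a.slope)),
        )
        f1 = fit_dispersions(perm, n_terms=2, init=init_fwd, seed=0)
        f2 = fit_dispersions(perm, n_terms=2, init=init_swapped, seed=0)
        assert abs(f1.residual_sse - f2.residual_sse) < 1e-8

    def test_coincident_locations_merged_and_flagged(self):
        perm = spectrum_from_params(TWO_TERM)
        near = DispersionParams(
            log_eps_inf=1.0,
            terms=(DispersionTerm(0.5, 9.00, 1.0), DispersionTerm(0.5, 9.05, 1.0)),
        )
        from esospec.dispersion import _sorted_params
        merged, was_merged = _sorted_params(
            np.array([1.0, 0.5, 9.00, 1.0, 0.5, 9.05, 1.0])
        )
        assert was_merged
        assert merged.n_terms == 1
        assert merged.terms[0].step == pytest.approx(1.0)
        del perm, near

    def test_invalid_n_terms(self, simulated_perm):
        perm, _ = simulated_perm
        with pytest.raises(DispersionError):
            fit_dispersions(perm, n_terms=4)


class TestRelaxationSummary:
    def test_hand_evaluated_example(self):
        # lε′∞=1, Δβ=2, Δα=3, locations 6 and 14
        params = DispersionParams(
            log_eps_inf=1.0,
            terms=(DispersionTerm(step=3.0, log_w2_tau=6.0, slope=1.0),
                   DispersionTerm(step=2.0, log_w2_tau=14.0, slope=1.0)),
        )
        fit = FittedDispersionModel(params=params, residual_sse=0.0, converged=True,
                                    n_iterations=0)
        perm = spectrum_from_params(params)
        s = relaxation_summary(fit, perm)
        assert s.f_alpha == pytest.approx(10**3 / (2 * np.pi), rel=1e-12)
        assert s.f_beta == pytest.approx(10**7 / (2 * np.pi), rel=1e-12)
        assert s.f_alpha == pytest.approx(159.15, rel=1e-4)
        assert s.f_beta == pytest.approx(1.5915e6, rel=1e-4)
        assert s.eps_beta == pytest.approx(100.0, rel=1e-12)
        assert s.eps_alpha == pytest.approx(10**4.5, rel=1e-12)

    def test_midpoint_identity_for_well_separated_terms(self):
        # ε′ evaluated at 2·lω = lϖτ²_β equals the closed-form ε′β when the
        # α sigmoid is fully saturated there
        params = DispersionParams(
            log_eps_inf=0.8,
            terms=(DispersionTerm(step=2.0, log_w2_tau=4.0, slope=2.0),
                   DispersionTerm(step=1.0, log_w2_tau=16.0, slope=2.0)),
        )
        leps = evaluate_model(params, np.array([16.0 / 2]))[0]
        assert 10**leps == pytest.approx(10 ** (0.8 + 1.0 / 2), rel=1e-9)

    def test_ordering_invariant(self, simulated_perm):
        perm, _ = simulated_perm
        fit = fit_dispersions(perm, n_terms=2, seed=0)
        s = relaxation_summary(fit, perm)
        assert s.f_alpha < s.f_beta
        assert s.eps_alpha > s.eps_beta

    def test_refuses_non_converged(self, simulated_perm):
        perm, _ = simulated_perm
        fit = FittedDispersionModel(params=TWO_TERM, residual_sse=np.inf,
                                    converged=False, n_iterations=0)
        with pytest.raises(DispersionError, match="non-converged"):
            relaxation_summary(fit, perm)


class TestConductivityAtFrequency:
    def test_exact_at_grid_points(self, simulated_perm):
        perm, _ = simulated_perm
        for i in (0, len(perm) // 2, len(perm) - 1):
            sigma, loss = conductivity_at_frequency(perm, float(perm.frequencies[i]))
            assert sigma == pytest.approx(perm.conductivity[i], rel=1e-12)
            assert loss == pytest.approx(perm.eps_imag[i], rel=1e-12)

    def test_power_law_interpolation_is_exact(self):
        f = np.logspace(1, 7, 16)
        # σ ∝ f^0.7 → exactly log-log linear
        eps_imag = 3.0 * f**-0.3  # gives σ = ε0·2π·3·f^0.7
        perm = PermittivitySpectrum(frequencies=f, eps_real=np.ones(16),
                                    eps_imag=eps_imag)
        f_q = 10 ** 3.37
        sigma, _ = conductivity_at_frequency(perm, f_q)
        import esospec
        expected = esospec.EPSILON_0 * 2 * np.pi * 3.0 * f_q**0.7
        assert sigma == pytest.approx(expected, rel=1e-9)

    def test_out_of_range_refused(self, simulated_perm):
        perm, _ = simulated_perm
        with pytest.raises(ExtrapolationError):
            conductivity_at_frequency(perm, perm.frequencies[0] / 2)
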