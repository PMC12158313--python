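"""Multi-logistic dispersion decomposition of log-permittivity spectra.

The dielectric constant of biological media drops in discrete steps across
the radiofrequency range, one step per dispersion (α at Hz–kHz from mobile
ions, β at tens of kHz–tens of MHz from fixed macromolecular charges).  In
decimal-log coordinates each step is well described by a logistic sigmoid in
the log of the squared angular velocity, so the whole spectrum is a sum of
sigmoids (the Traffano–Schiffo model):

    lε′(ω) = lε′∞ + Σₙ Δlε′ₙ / (1 + exp((2·lω − lϖτ²ₙ)·αₙ))

with ``lω = log10(2πf)``, ``lε′∞`` the high-frequency plateau, ``Δlε′ₙ`` the
magnitude of dispersion *n*, ``lϖτ²ₙ`` its location (the decimal log of the
squared relaxation angular velocity) and ``αₙ`` its slope.  The relaxation
frequency of each dispersion follows from its location parameter,

    fₙ = 10^(lϖτ²ₙ / 2) / (2π),

and the dielectric constants at the α and β relaxations are the sigmoid
midpoints sitting on top of the remaining steps:

    ε′β = 10^(lε′∞ + Δlε′β/2),    ε′α = 10^(lε′∞ + Δlε′β + Δlε′α/2).

Fitting is performed on log10 ε′ only.  The loss factor is not fitted: at
high ionicity it is dominated (masked) by the dc conduction term, so σ and
ε″ at the relaxation frequencies are read off the raw spectrum by log-log
interpolation instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .spectra import PermittivitySpectrum

__all__ = [
    "DispersionTerm",
    "DispersionParams",
    "FittedDispersionModel",
    "RelaxationSummary",
    "DispersionError",
    "ExtrapolationError",
    "evaluate_model",
    "initial_guess",
    "fit_dispersions",
    "relaxation_summary",
    "conductivity_at_frequency",
]

#: fitted locations closer than this (in lϖτ² units) are merged into one term
MERGE_TOLERANCE = 0.1

STEP_MAX = 10.0
SLOPE_MAX = 20.0
_EPS = 1e-8


class DispersionError(ValueError):
    """Invalid dispersion parameters or an unusable fit."""


class ExtrapolationError(ValueError):
    """Requested frequency lies outside the measured grid."""


@dataclass(frozen=True)
class DispersionTerm:
    """One logistic dispersion term.

    Attributes
    ----------
    step : float
        Δlε′ₙ — magnitude of the dispersion in decimal-log units (> 0).
    log_w2_tau : float
        lϖτ²ₙ — decimal log of the squared relaxation angular velocity.
    slope : float
        αₙ — dimensionless sigmoid steepness (> 0).
    """

    step: float
    log_w2_tau: float
    slope: float

    def __post_init__(self) -> None:
        if not (self.step > 0):
            raise DispersionError(f"dispersion step must be > 0, got {self.step}")
        if not (self.slope > 0):
            raise DispersionError(f"dispersion slope must be > 0, got {self.slope}")

    @property
    def relaxation_frequency(self) -> float:
        """fₙ = 10^(lϖτ²ₙ/2) / (2π), Hz."""
        return 10.0 ** (self.log_w2_tau / 2.0) / (2.0 * np.pi)


@dataclass(frozen=True)
class DispersionParams:
    """Full parameter vector: high-frequency plateau plus 1–3 ordered terms."""

    log_eps_inf: float
    terms: tuple[DispersionTerm, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.terms) <= 3:
            raise DispersionError(f"need 1–3 terms, got {len(self.terms)}")
        locs = [t.log_w2_tau for t in self.terms]
        if any(b <= a for a, b in zip(locs, locs[1:])):
            raise DispersionError("terms must be strictly ordered by ascending log_w2_tau")

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    @property
    def total_step(self) -> float:
        return float(sum(t.step for t in self.terms))


@dataclass(frozen=True)
class FittedDispersionModel:
    """A fitted model with diagnostics.

    ``covariance_ok`` is lowered when two fitted locations collapsed onto
    each other and were merged, which makes the per-term parameters
    unidentifiable.
    """

    params: DispersionParams
    residual_sse: float
    converged: bool
    n_iterations: int
    covariance_ok: bool = True


@dataclass(frozen=True)
class RelaxationSummary:
    """Per-spectrum α/β relaxation summary.

    Frequencies in Hz; ``eps_alpha``/``eps_beta`` are the dielectric
    constants at the two relaxations; ``sigma_alpha``/``sigma_beta`` the
    ionic conductivity (S/m) and ``loss_alpha`` the loss factor read off the
    measured spectrum at those frequencies.
    """

    f_alpha: float
    f_beta: float
    eps_alpha: float
    eps_beta: float
    sigma_alpha: float
    sigma_beta: float
    loss_alpha: float

    def __post_init__(self) -> None:
        if not (0 < self.f_alpha < self.f_beta):
            raise DispersionError("relaxation ordering requires 0 < f_alpha < f_beta")


def evaluate_model(params: DispersionParams, log_omega) -> np.ndarray:
    """Evaluate lε′ at the decimal-log angular velocities *log_omega*.

    Monotonically non-increasing in lω; tends to ``lε′∞ + Σ Δlε′ₙ`` as
    lω → −∞ and to ``lε′∞`` as lω → +∞.
    """
    lw = np.asarray(log_omega, dtype=float)
    out = np.full_like(lw, params.log_eps_inf, dtype=float)
    for t in params.terms:
        z = (2.0 * lw - t.log_w2_tau) * t.slope
        # exp overflow is harmless (sigmoid → 0); silence the warning
        with np.errstate(over="ignore"):
            out = out + t.step / (1.0 + np.exp(z))
    return out


def _pack(params: DispersionParams) -> np.ndarray:
    theta = [params.log_eps_inf]
    for t in params.terms:
        theta.extend((t.step, t.log_w2_tau, t.slope))
    return np.array(theta)


def _unpack(theta: np.ndarray) -> tuple[float, list[tuple[float, float, float]]]:
    lei = float(theta[0])
    triples = [
        (float(theta[i]), float(theta[i + 1]), float(theta[i + 2]))
        for i in range(1, len(theta), 3)
    ]
    return lei, triples


def _theta_model(theta: np.ndarray, lw: np.ndarray) -> np.ndarray:
    out = np.full_like(lw, theta[0])
    for i in range(1, len(theta), 3):
        step, loc, slope = theta[i], theta[i + 1], theta[i + 2]
        with np.errstate(over="ignore"):
            out = out + step / (1.0 + np.exp((2.0 * lw - loc) * slope))
    return out


def _log_omega(perm: PermittivitySpectrum) -> np.ndarray:
    return np.log10(2.0 * np.pi * perm.frequencies)


def initial_guess(perm: PermittivitySpectrum, n_terms: int = 2) -> DispersionParams:
    """Data-driven starting point for :func:`fit_dispersions`.

    The high-frequency plateau comes from the top half-decade of log ε′;
    term locations from the *n_terms* deepest local minima of the smoothed
    derivative d(log ε′)/d(lω); steps from plateau differences between
    transitions.  Slopes start at 1.  When fewer transitions are detectable
    than requested, locations fall back to an equally spaced layout across
    the observed range (with a warning, not an error).
    """
    if not 1 <= n_terms <= 3:
        raise DispersionError(f"n_terms must be 1–3, got {n_terms}")
    lw = _log_omega(perm)
    if lw[-1] - lw[0] < 3.0:
        raise DispersionError("spectrum must span at least 3 decades of frequency")
    if np.any(perm.eps_real <= 0):
        raise DispersionError("dielectric constant must be positive to take its log")
    y = np.log10(perm.eps_real)

    log_eps_inf = float(np.mean(y[lw >= lw[-1] - 0.5]))

    dy = np.gradient(y, lw)
    win = max(3, min(7, (len(y) // 8) * 2 + 1))
    kernel = np.ones(win) / win
    smooth = np.convolve(dy, kernel, mode="same")

    # interior local minima of the smoothed derivative, deepest first
    interior = np.arange(1, len(smooth) - 1)
    is_min = (smooth[interior] <= smooth[interior - 1]) & (
        smooth[interior] <= smooth[interior + 1]
    )
    cand = interior[is_min & (smooth[interior] < -0.05)]
    cand = cand[np.argsort(smooth[cand])]

    # enforce minimum spacing of 0.5 lω units between detected transitions
    chosen: list[int] = []
    for idx in cand:
        if all(abs(lw[idx] - lw[j]) >= 0.5 for j in chosen):
            chosen.append(int(idx))
        if len(chosen) == n_terms:
            break

    if len(chosen) < n_terms:
        warnings.warn(
            f"detected {len(chosen)} transitions but {n_terms} terms requested; "
            "falling back to equally spaced locations",
            stacklevel=2,
        )
        qs = np.linspace(0.25, 0.75, n_terms)
        locs = 2.0 * (lw[0] + qs * (lw[-1] - lw[0]))
    else:
        locs = np.sort(2.0 * lw[np.array(chosen)])

    # plateau levels between consecutive transitions → step sizes
    trans_lw = locs / 2.0
    bounds = np.concatenate(([lw[0] - 1], trans_lw, [lw[-1] + 1]))
    plateaus = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        mid_mask = (lw > lo) & (lw < hi)
        # favour bins away from the transitions themselves
        if np.any(mid_mask):
            plateaus.append(float(np.median(y[mid_mask])))
        else:
            plateaus.append(plateaus[-1] if plateaus else log_eps_inf)
    steps = [max(plateaus[i] - plateaus[i + 1], 0.01) for i in range(n_terms)]

    # strict ascending order for locations (perturb ties)
    locs = np.asarray(locs, dtype=float)
    for i in range(1, len(locs)):
        if locs[i] <= locs[i - 1]:
            locs[i] = locs[i - 1] + 1e-6

    terms = tuple(
        DispersionTerm(step=s, log_w2_tau=float(l), slope=1.0)
        for s, l in zip(steps, locs)
    )
    return DispersionParams(log_eps_inf=log_eps_inf, terms=terms)


def fit_dispersions(
    perm: PermittivitySpectrum,
    n_terms: int = 2,
    init: DispersionParams | None = None,
    seed: int = 0,
    n_restarts: int = 5,
) -> FittedDispersionModel:
    """Fit the multi-logistic model to log10 ε′ by bounded least squares.

    Minimizes Σ (log10 ε′_obs − lε′_model)² with trust-region reflective
    least squares under box bounds (steps in (0, 10], slopes in (0, 20],
    locations within the observed 2·lω range ± 2).  Multi-modality is
    handled by *n_restarts* seeded jittered restarts (sd 0.25 per
    parameter); the lowest-SSE solution wins.  Terms are re-sorted by
    ascending location before return; locations closer than 0.1 are merged
    (summed steps) and flagged via ``covariance_ok=False``.

    Never raises on a valid spectrum: if no restart converges the
    best-effort parameters are returned with ``converged=False``.
    """
    if not 2 <= n_terms <= 3:
        raise DispersionError(f"n_terms must be 2 or 3, got {n_terms}")
    lw = _log_omega(perm)
    y = np.log10(perm.eps_real)
    theta0 = _pack(init if init is not None else initial_guess(perm, n_terms))

    lo = [y.min() - 2.0]
    hi = [y.max() + 2.0]
    loc_lo, loc_hi = 2.0 * lw[0] - 2.0, 2.0 * lw[-1] + 2.0
    for _ in range(n_terms):
        lo.extend((_EPS, loc_lo, _EPS))
        hi.extend((STEP_MAX, loc_hi, SLOPE_MAX))
    lo_arr, hi_arr = np.array(lo), np.array(hi)
    theta0 = np.clip(theta0, lo_arr + _EPS, hi_arr - _EPS)

    def residuals(theta: np.ndarray) -> np.ndarray:
        return _theta_model(theta, lw) - y

    rng = np.random.default_rng(seed)
    best = None
    best_sse = np.inf
    n_iter = 0
    any_success = False
    for k in range(max(1, n_restarts)):
        start = theta0 if k == 0 else np.clip(
            theta0 + rng.normal(0.0, 0.25, size=theta0.size), lo_arr + _EPS, hi_arr - _EPS
        )
        try:
            res = least_squares(
                residuals,
                start,
                bounds=(lo_arr, hi_arr),
                method="trf",
                ftol=1e-14,
                xtol=1e-14,
                gtol=1e-14,
            )
        except Exception:  # pragma: no cover - defensive
            continue
        sse = float(np.sum(res.fun**2))
        n_iter += int(res.nfev)
        any_success = any_success or bool(res.success)
        if sse < best_sse:
            best, best_sse = res, sse

    if best is None:  # pragma: no cover - least_squares essentially never throws
        params = _theta_to_params(theta0)
        return FittedDispersionModel(params, np.inf, False, n_iter, False)

    params, merged = _sorted_params(best.x)
    converged = bool(best.success) and np.isfinite(best_sse)
    if not converged:
        warnings.warn("dispersion fit did not converge; returning best-effort parameters",
                      stacklevel=2)
    return FittedDispersionModel(
        params=params,
        residual_sse=best_sse,
        converged=converged,
        n_iterations=n_iter,
        covariance_ok=not merged,
    )


def _theta_to_params(theta: np.ndarray) -> DispersionParams:
    params, _ = _sorted_params(theta)
    return params


def _sorted_params(theta: np.ndarray) -> tuple[DispersionParams, bool]:
    lei, triples = _unpack(theta)
    triples.sort(key=lambda t: t[1])
    merged = False
    out: list[tuple[float, float, float]] = []
    for step, loc, slope in triples:
        if out and abs(loc - out[-1][1]) < MERGE_TOLERANCE:
            pstep, ploc, pslope = out[-1]
            w = pstep + step
            out[-1] = (w, (pstep * ploc + step * loc) / w, 0.5 * (pslope + slope))
            merged = True
        else:
            out.append((step, loc, slope))
    terms = tuple(
        DispersionTerm(step=max(s, _EPS), log_w2_tau=l, slope=max(a, _EPS))
        for s, l, a in out
    )
    return DispersionParams(log_eps_inf=lei, terms=terms), merged


def conductivity_at_frequency(
    perm: PermittivitySpectrum, f: float
) -> tuple[float, float]:
    """σ (S/m) and ε″ at frequency *f* by log-log interpolation on the grid.

    Exact at grid points; refuses to extrapolate outside the measured range.
    """
    freqs = perm.frequencies
    if not (freqs[0] <= f <= freqs[-1]):
        raise ExtrapolationError(
            f"{f} Hz outside measured range [{freqs[0]}, {freqs[-1]}] Hz"
        )
    lf = np.log10(f)
    lgrid = np.log10(freqs)

    def _interp(values: np.ndarray) -> float:
        if np.all(values > 0):
            return float(10.0 ** np.interp(lf, lgrid, np.log10(values)))
        return float(np.interp(lf, lgrid, values))

    return _interp(perm.conductivity), _interp(perm.eps_imag)


def relaxation_summary(
    fit: FittedDispersionModel, perm: PermittivitySpectrum
) -> RelaxationSummary:
    """Extract α/β relaxation frequencies and dielectric properties.

    The fitted term with the lowest location is taken as the α dispersion
    and the next as β (any further term is kept in the fit result but
    excluded here).  Frequencies follow fᵢ = 10^(lϖτ²ᵢ/2)/(2π); the
    dielectric constants are the sigmoid midpoints ε′β = 10^(lε′∞+Δlε′β/2)
    and ε′α = 10^(lε′∞+Δlε′β+Δlε′α/2).  σ and ε″ at those frequencies are
    interpolated from the measured spectrum.
    """
    if not fit.converged:
        raise DispersionError("refusing to summarize a non-converged fit")
    params = fit.params
    if params.n_terms < 2:
        raise DispersionError("need at least two fitted terms for an α/β summary")
    alpha, beta = params.terms[0], params.terms[1]
    f_alpha = alpha.relaxation_frequency
    f_beta = beta.relaxation_frequency
    eps_beta = 10.0 ** (params.log_eps_inf + beta.step / 2.0)
    eps_alpha = 10.0 ** (params.log_eps_inf + beta.step + alpha.step / 2.0)
    sigma_alpha, loss_alpha = conductivity_at_frequency(perm, f_alpha)
    sigma_beta, _ = conductivity_at_frequency(perm, f_beta)
    return RelaxationSummary(
        f_alpha=f_alpha,
        f_beta=f_beta,
        eps_alpha=eps_alpha,
        eps_beta=eps_beta,
        sigma_alpha=sigma_alpha,
        sigma_beta=sigma_beta,
        loss_alpha=loss_alpha,
    )
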