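"""Fitting dispersion data to the two-state exchange models.

The analysis is two-stage, matching standard relaxation-dispersion
practice: peak-intensity decays are first fitted per spin-lock setting
to a mono-exponential, then the resulting R1rho values (weighted by
their errors) are fitted to the Laguerre closed form -- per residue, or
globally with kex and pES shared across probes.  Parameter uncertainties
come from Monte-Carlo resampling (parametric bootstrap around the
best-fit model, 50 iterations by default).  CEST profiles are fitted
with the exchange parameters frozen to the R1rho-derived values, which
pins down the excited-state 1H shift.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .exchange import (
    ExchangeParams,
    RelaxationRates,
    laguerre_rate,
    simulate_cest,
)
from .profiles import CESTProfile, R1rhoProfile

__all__ = [
    "FitResult",
    "ProbeFit",
    "CESTFitResult",
    "fit_decay_to_r1rho",
    "fit_r1rho_single",
    "fit_r1rho_global",
    "mc_errors",
    "normalize_cest",
    "difference_cest",
    "fit_cest",
    "reconstruct_es_shift",
]

# loose physical bounds for the dispersion fit
PES_BOUNDS = (1e-6, 0.5)
LOG10_KEX_BOUNDS = (0.5, 6.0)
DW_PPM_BOUNDS = (-20.0, 20.0)
R1_BOUNDS = (0.1, 10.0)
R2_BOUNDS = (1.0, 100.0)


# --------------------------------------------------------------------------
# stage 1: mono-exponential decays
# --------------------------------------------------------------------------


def _monoexp_rates(t, Y, sigma=None, n_iter: int = 12):
    """Vectorised weighted least-squares I(t) = I0 exp(-R t) over rows
    of Y (weights 1/sigma when measurement errors are given).

    Log-linear initialisation followed by Gauss-Newton refinement of
    (I0, R) in intensity space.  Returns (I0, R) arrays.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    t = np.asarray(t, dtype=float)
    w = np.ones_like(t) if sigma is None else 1.0 / np.asarray(sigma, dtype=float)
    pos = np.clip(Y, 1e-12, None)
    logs = np.log(pos)
    tc = t - t.mean()
    denom = np.sum(tc**2)
    R = -(logs @ tc) / denom
    I0 = np.exp(logs.mean(axis=1) + R * t.mean())
    for _ in range(n_iter):
        e = np.exp(-R[:, None] * t[None, :])
        f = I0[:, None] * e
        r = (Y - f) * w[None, :]
        j1 = e * w[None, :]  # d f / d I0, weighted
        j2 = -I0[:, None] * t[None, :] * e * w[None, :]  # d f / d R, weighted
        a11 = np.einsum("ij,ij->i", j1, j1)
        a12 = np.einsum("ij,ij->i", j1, j2)
        a22 = np.einsum("ij,ij->i", j2, j2)
        b1 = np.einsum("ij,ij->i", j1, r)
        b2 = np.einsum("ij,ij->i", j2, r)
        det = a11 * a22 - a12**2
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        dI0 = (a22 * b1 - a12 * b2) / det
        dR = (a11 * b2 - a12 * b1) / det
        I0 = I0 + dI0
        R = R + dR
    return I0, R


def fit_decay_to_r1rho(
    delays,
    intensities,
    errors,
    n_mc: int = 50,
    seed: int | None = None,
):
    """Fit one peak-intensity decay to a mono-exponential and estimate the
    R1rho uncertainty by Monte-Carlo resampling.

    The standard deviation is that of the rate over ``n_mc`` refits of
    Gaussian-perturbed intensities (perturbations centred on the best-fit
    model curve, with the stated measurement errors).  Deterministic under
    a fixed seed.  Returns ``(R1rho, SD)``.
    """
    t = np.asarray(delays, dtype=float)
    y = np.asarray(intensities, dtype=float)
    err = np.asarray(errors, dtype=float)
    if t.size < 3 or np.unique(t).size < 3:
        raise ValueError("need >= 3 distinct delays")
    if np.any(err <= 0):
        raise ValueError("errors must be positive")

    I0, R = _monoexp_rates(t, y[None, :])
    rate = float(R[0])
    if not np.isfinite(rate) or not np.isfinite(I0[0]):
        raise RuntimeError(
            f"mono-exponential fit did not converge (I0={I0[0]}, R={rate}) "
            f"for delays {t}"
        )
    if rate < -1e-6 * max(abs(rate), 1.0):
        warnings.warn(
            f"fitted decay rate is negative ({rate:.4g} s^-1): intensity "
            "grows with delay",
            RuntimeWarning,
            stacklevel=2,
        )
    if n_mc <= 0:
        return rate, float("nan")
    rng = np.random.default_rng(seed)
    model = I0[0] * np.exp(-rate * t)
    perturbed = model[None, :] + rng.normal(0.0, 1.0, (n_mc, t.size)) * err[None, :]
    _, Rmc = _monoexp_rates(t, perturbed)
    return rate, float(np.std(Rmc, ddof=1))


# --------------------------------------------------------------------------
# stage 2: dispersion fits
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ProbeFit:
    """Per-probe parameters of a dispersion fit."""

    delta_omega_ppm: float
    R1: float
    R2: float


@dataclass
class FitResult:
    """Exchange parameters, per-probe parameters and fit diagnostics."""

    params: ExchangeParams
    probe_fits: dict
    chi2: float
    dof: int
    errors: dict | None = None
    flags: list = field(default_factory=list)
    alternatives: list = field(default_factory=list)

    @property
    def chi2_reduced(self) -> float:
        return self.chi2 / self.dof if self.dof > 0 else math.nan


class _Dataset:
    """Flattened per-probe arrays consumed by the dispersion residuals."""

    def __init__(self, profiles, n_mc_decay=50, seed=None):
        rng = np.random.default_rng(seed)
        self.probes = []
        self.w_sl = []
        self.w_rf = []
        self.y = []
        self.err = []
        for prof in profiles:
            if len(prof.settings) < 2:
                raise ValueError(
                    f"probe {prof.probe.residue_id}: need >= 2 spin-lock settings"
                )
            if prof.r1rho is not None:
                y = np.asarray(prof.r1rho, dtype=float)
                err = (
                    np.asarray(prof.r1rho_err, dtype=float)
                    if prof.r1rho_err is not None
                    else np.full(y.size, 0.02 * np.abs(y).mean())
                )
            else:
                vals, sds = [], []
                for d, inten, e in zip(prof.delays, prof.intensities, prof.errors):
                    r, sd = fit_decay_to_r1rho(
                        d, inten, e, n_mc=n_mc_decay,
                        seed=int(rng.integers(2**31 - 1)),
                    )
                    vals.append(r)
                    sds.append(sd if np.isfinite(sd) and sd > 0 else 0.02 * abs(r))
                y, err = np.asarray(vals), np.asarray(sds)
            self.probes.append(prof.probe)
            self.w_sl.append(np.array([s.omega_SL for s in prof.settings]))
            self.w_rf.append(np.array([s.omega_rf for s in prof.settings]))
            self.y.append(y)
            self.err.append(err)
        self.n_points = int(sum(v.size for v in self.y))
        self.n_probes = len(self.probes)

    def model(self, pES, kex, probe_params):
        """Per-probe Laguerre predictions for (dw_ppm, R1, R2) triples."""
        out = []
        for probe, (dw_ppm, R1, R2), wsl, wrf in zip(
            self.probes, probe_params, self.w_sl, self.w_rf
        ):
            dw = dw_ppm * 2.0 * math.pi * probe.larmor_MHz
            rate, den = laguerre_rate(
                pES, kex, dw, R1, R2, wsl, wrf, probe.omega_GS, check=False
            )
            rate = np.where(den > 0, rate, 1e6)  # steer the optimiser away
            out.append(rate)
        return out

    def residuals(self, x):
        pES = x[0]
        kex = 10.0 ** x[1]
        triples = x[2:].reshape(self.n_probes, 3)
        res = []
        for m, y, err in zip(self.model(pES, kex, triples), self.y, self.err):
            res.append((m - y) / err)
        return np.concatenate(res)


def _pack(pES, kex, probe_params):
    return np.concatenate([[pES, math.log10(kex)], np.ravel(probe_params)])


def _bounds(n_probes):
    lo = [PES_BOUNDS[0], LOG10_KEX_BOUNDS[0]]
    hi = [PES_BOUNDS[1], LOG10_KEX_BOUNDS[1]]
    for _ in range(n_probes):
        lo += [DW_PPM_BOUNDS[0], R1_BOUNDS[0], R2_BOUNDS[0]]
        hi += [DW_PPM_BOUNDS[1], R1_BOUNDS[1], R2_BOUNDS[1]]
    return np.array(lo), np.array(hi)


def _minimize(ds: _Dataset, x0s, **ls_kwargs):
    lo, hi = _bounds(ds.n_probes)
    best = None
    for x0 in x0s:
        x0 = np.clip(x0, lo + 1e-12, hi - 1e-12)
        try:
            sol = least_squares(
                ds.residuals, x0, bounds=(lo, hi), method="trf",
                ftol=1e-12, xtol=1e-12, gtol=1e-12, **ls_kwargs,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all dispersion fit starts failed")
    return best


def _default_starts(ds: _Dataset, init: FitResult | None):
    """Multistart grid over the sign/magnitude of dw and kex decades,
    guarding the +-dw and fast/slow exchange degeneracies."""
    r1_0 = [max(R1_BOUNDS[0], min(v.min() * 0.8, R1_BOUNDS[1])) for v in ds.y]
    r2_0 = [min(max(np.median(v), R2_BOUNDS[0] + 1), R2_BOUNDS[1] - 1) for v in ds.y]
    starts = []
    for dw0 in (0.8, -0.8, 2.0, -2.0):
        for kex0 in (300.0, 1200.0):
            triples = [(dw0, 2.0, r2) for r2 in r2_0]
            starts.append(_pack(0.03, kex0, triples))
    if init is not None:
        triples = [
            (
                init.probe_fits[p.residue_id].delta_omega_ppm,
                init.probe_fits[p.residue_id].R1,
                init.probe_fits[p.residue_id].R2,
            )
            for p in ds.probes
        ]
        starts.insert(0, _pack(init.params.pES, init.params.kex, triples))
    return starts


def _result_from_solution(ds: _Dataset, sol) -> FitResult:
    pES = float(sol.x[0])
    kex = float(10.0 ** sol.x[1])
    triples = sol.x[2:].reshape(ds.n_probes, 3)
    probe_fits = {
        p.residue_id: ProbeFit(float(dw), float(r1), float(r2))
        for p, (dw, r1, r2) in zip(ds.probes, triples)
    }
    chi2 = float(2.0 * sol.cost)
    dof = ds.n_points - sol.x.size
    return FitResult(
        params=ExchangeParams.from_populations(pES, kex),
        probe_fits=probe_fits,
        chi2=chi2,
        dof=dof,
    )


def _diagnose(ds: _Dataset, sol, result: FitResult):
    """Flag exchange-free data and the +-dw sign degeneracy."""
    # null model: no exchange amplitude
    x_null = sol.x.copy()
    triples = x_null[2:].reshape(ds.n_probes, 3).copy()
    triples[:, 0] = 0.0
    x_null[2:] = triples.ravel()
    sol_null = least_squares(
        lambda x: ds.residuals(
            np.concatenate([x[:2], _with_fixed_dw(x[2:], 0.0, ds.n_probes)])
        ),
        x_null,
        bounds=_bounds(ds.n_probes),
        method="trf",
    )
    chi2_null = float(2.0 * sol_null.cost)
    if chi2_null - result.chi2 < 2.0:
        result.flags.append("no_exchange_information")

    # sign-flipped minimum
    x_flip = sol.x.copy()
    triples = x_flip[2:].reshape(ds.n_probes, 3).copy()
    triples[:, 0] *= -1.0
    x_flip[2:] = triples.ravel()
    sol_flip = _minimize(ds, [x_flip])
    chi2_flip = float(2.0 * sol_flip.cost)
    if chi2_flip - result.chi2 < 1.0:
        flipped = _result_from_solution(ds, sol_flip)
        signs_differ = any(
            np.sign(flipped.probe_fits[r].delta_omega_ppm)
            != np.sign(result.probe_fits[r].delta_omega_ppm)
            for r in result.probe_fits
            if abs(result.probe_fits[r].delta_omega_ppm) > 1e-6
        )
        if signs_differ:
            result.flags.append("ambiguous_dw_sign")
            result.alternatives.append(flipped)


def _with_fixed_dw(triples_flat, dw, n_probes):
    t = np.asarray(triples_flat).reshape(n_probes, 3).copy()
    t[:, 0] = dw
    return t.ravel()


def fit_r1rho_global(
    profiles,
    init: FitResult | None = None,
    n_mc_decay: int = 50,
    seed: int | None = None,
    diagnose: bool = True,
) -> FitResult:
    """Global dispersion fit: one shared (pES, kex), per-probe
    (delta_omega, R1, R2), minimising error-weighted squared residuals of
    the Laguerre model.  The global chi^2 is the sum over probes.

    Raw intensity profiles are first reduced to R1rho values via
    :func:`fit_decay_to_r1rho` (errors from Monte-Carlo, ``n_mc_decay``
    iterations).  With ``diagnose`` the fit is checked for absent
    exchange information and for the +-delta_omega degeneracy; a
    sign-degenerate minimum within Delta-chi^2 < 1 is reported in
    ``alternatives`` (the sign is ultimately resolved by external
    chemical-shift prediction, not by the dispersion data).
    """
    ds = _Dataset(profiles, n_mc_decay=n_mc_decay, seed=seed)
    sol = _minimize(ds, _default_starts(ds, init))
    result = _result_from_solution(ds, sol)
    if diagnose:
        _diagnose(ds, sol, result)
    return result


def fit_r1rho_single(
    profile: R1rhoProfile,
    init: FitResult | None = None,
    n_mc_decay: int = 50,
    seed: int | None = None,
    diagnose: bool = True,
) -> FitResult:
    """Two-state fit of a single probe's dispersion profile over
    (pES, kex, delta_omega, R1, R2).  See :func:`fit_r1rho_global`."""
    return fit_r1rho_global(
        [profile], init=init, n_mc_decay=n_mc_decay, seed=seed, diagnose=diagnose
    )


def mc_errors(
    fit: FitResult,
    profiles,
    n_mc: int = 50,
    seed: int | None = None,
    max_failure_frac: float = 0.2,
) -> dict:
    """Monte-Carlo (parametric bootstrap) parameter uncertainties.

    Each replicate resamples every R1rho value from a Gaussian centred on
    the best-fit model prediction with the measured error as SD, refits
    from the best-fit starting point, and the per-parameter standard
    deviations over replicates are reported.  Deterministic under a fixed
    seed.  More than ``max_failure_frac`` failed refits invalidates the
    estimate (raises).
    """
    ds = _Dataset(profiles, n_mc_decay=0)
    triples = [
        (
            fit.probe_fits[p.residue_id].delta_omega_ppm,
            fit.probe_fits[p.residue_id].R1,
            fit.probe_fits[p.residue_id].R2,
        )
        for p in ds.probes
    ]
    x_best = _pack(fit.params.pES, fit.params.kex, triples)
    model = ds.model(fit.params.pES, fit.params.kex, np.asarray(triples))

    rng = np.random.default_rng(seed)
    samples = []
    failures = 0
    y_orig = [v.copy() for v in ds.y]
    try:
        for _ in range(n_mc):
            for j, (m, err) in enumerate(zip(model, ds.err)):
                ds.y[j] = m + rng.normal(0.0, 1.0, m.size) * err
            try:
                sol = _minimize(ds, [x_best])
                samples.append(sol.x)
            except RuntimeError:
                failures += 1
    finally:
        for j, v in enumerate(y_orig):
            ds.y[j] = v
    if n_mc > 0 and failures / n_mc > max_failure_frac:
        raise RuntimeError(
            f"{failures}/{n_mc} Monte-Carlo refits failed; error estimate invalid"
        )
    X = np.asarray(samples)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(x_best.size)
    kex_samples = 10.0 ** X[:, 1]
    out = {
        "pES": float(sd[0]),
        "kex": float(np.std(kex_samples, ddof=1)) if X.shape[0] > 1 else 0.0,
        "n_failures": failures,
        "probes": {},
    }
    for j, p in enumerate(ds.probes):
        s = sd[2 + 3 * j : 5 + 3 * j]
        out["probes"][p.residue_id] = {
            "delta_omega_ppm": float(s[0]),
            "R1": float(s[1]),
            "R2": float(s[2]),
        }
    return out


# --------------------------------------------------------------------------
# CEST
# --------------------------------------------------------------------------


def normalize_cest(raw: CESTProfile, reference_intensity: float) -> CESTProfile:
    """Scale a profile by its far-off-resonance reference so the baseline
    is 1.0."""
    if reference_intensity <= 0:
        raise ValueError("reference intensity must be positive")
    return CESTProfile(
        probe=raw.probe,
        setting=raw.setting,
        component=raw.component,
        intensity=raw.intensity / reference_intensity,
        reference_intensity=float(reference_intensity),
        construct=raw.construct,
    )


def difference_cest(alpha: CESTProfile, beta: CESTProfile) -> CESTProfile:
    """Difference profile beta - alpha isolating the exchange dips.

    Requires identical carrier grids.
    """
    ga, gb = alpha.setting.grid, beta.setting.grid
    if ga.size != gb.size or not np.allclose(ga, gb):
        raise ValueError("carrier grids of alpha and beta components differ")
    return CESTProfile(
        probe=alpha.probe,
        setting=alpha.setting,
        component="difference",
        intensity=beta.intensity - alpha.intensity,
        reference_intensity=alpha.reference_intensity,
        construct=alpha.construct,
    )


def reconstruct_es_shift(gs_shift: float, delta_omega: float) -> float:
    """Excited-state chemical shift (ppm): GS shift plus delta_omega.

    With the downfield-positive convention, a G.U -> G-C type transition
    (delta_omega > 0) yields an ES resonance downfield of the GS.
    """
    return gs_shift + delta_omega


@dataclass(frozen=True)
class CESTFitResult:
    es_shift_ppm: float
    es_shift_sd: float
    delta_omega_ppm: float
    rates: RelaxationRates
    chi2: float
    dof: int
    flags: tuple = ()


def _cest_model(profile: CESTProfile, fixed: ExchangeParams, dw_ppm, R1, R2):
    probe = profile.probe.with_delta_omega_ppm(float(dw_ppm))
    rates = RelaxationRates(R1=float(R1), R2=float(R2))
    two = simulate_cest(fixed, probe, profile.setting, rates).intensity
    if profile.component == "difference":
        one = simulate_cest(
            ExchangeParams.from_populations(0.0, 0.0), probe, profile.setting, rates
        ).intensity
        return one - two
    return two


def fit_cest(
    profile: CESTProfile,
    fixed: ExchangeParams,
    rates_init: RelaxationRates | None = None,
) -> CESTFitResult:
    """Fit a normalised CEST profile for the excited-state shift with the
    exchange parameters held fixed (taken from the 15N dispersion
    analysis); R1 and R2 of the observed coherence are refit as nuisance
    parameters.

    Raises when the fixed ES population is at or below 0.2% -- the minor
    dip is then unidentifiable.  A fitted delta_omega collapsing onto the
    main dip is flagged ``dw_collapsed``.
    """
    if fixed.pES <= 0.002:
        raise ValueError(
            f"fixed pES = {fixed.pES:.4f} <= 0.002: ES shift unidentifiable"
        )
    r0 = rates_init or RelaxationRates(R1=2.0, R2=20.0)
    grid = profile.setting.grid
    y = profile.intensity

    # candidate dips: local minima away from the GS resonance
    dev = -y if profile.component != "difference" else y
    gs_ppm = profile.probe.gs_ppm
    starts_dw = []
    interior = np.arange(1, grid.size - 1)
    is_min = (dev[interior] > dev[interior - 1]) & (dev[interior] >= dev[interior + 1])
    cand = interior[is_min]
    cand = cand[np.abs(grid[cand] - gs_ppm) > 0.1]
    for i in cand[np.argsort(dev[cand])[::-1][:3]]:
        starts_dw.append(grid[i] - gs_ppm)
    starts_dw += [0.3, -0.3, 0.6]

    lo = np.array([-5.0, R1_BOUNDS[0], R2_BOUNDS[0]])
    hi = np.array([5.0, R1_BOUNDS[1], R2_BOUNDS[1]])

    def resid(x):
        return _cest_model(profile, fixed, *x) - y

    best = None
    for dw0 in starts_dw:
        x0 = np.clip([dw0, r0.R1, r0.R2], lo + 1e-9, hi - 1e-9)
        try:
            sol = least_squares(resid, x0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all CEST fit starts failed")

    dof = grid.size - 3
    s_sq = 2.0 * best.cost / dof if dof > 0 else np.nan
    J = best.jac
    try:
        cov = s_sq * np.linalg.inv(J.T @ J)
        dw_sd = float(math.sqrt(max(cov[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        dw_sd = float("nan")
    dw = float(best.x[0])
    flags = []
    if abs(dw) < 2.5 * (grid[1] - grid[0]):
        flags.append("dw_collapsed")
    return CESTFitResult(
        es_shift_ppm=reconstruct_es_shift(gs_ppm, dw),
        es_shift_sd=dw_sd,
        delta_omega_ppm=dw,
        rates=RelaxationRates(R1=float(best.x[1]), R2=float(best.x[2])),
        chi2=float(2.0 * best.cost),
        dof=dof,
        flags=tuple(flags),
    )
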