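"""Gating-spring model fitting of receiver stiffness and CAP response curves.

Direct gating of mechanotransducer channels carves localized compliance dips
into the sound receiver's slope stiffness. With two channel populations — a
*sensitive* one (hearing, larger single-channel gating force z) and an
*insensitive* one (wind/gravity sensing, smaller z) — the stiffness reads

    K(X) = K_steady + K_GS - sum_j N_j z_j^2 / (k_B T) p_j(X) (1 - p_j(X)),
    p_j(X) = 1 / (1 + exp(-z_j (X - X0_j) / (k_B T))),

so each population contributes a dip of depth N_j z_j^2 / (4 k_B T) at its set
point X0_j. Fitting N_j and z_j across individuals and ages exposes the
homeostatic compensation law in which falling channel numbers are balanced by
rising gating forces, holding the nonlinearity depth N z^2 roughly constant.

K_steady (antennal joint) and K_GS (gating springs) act in parallel here and
are not separately identifiable from a single stiffness curve; fits report
their sum ``k_total``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal, stats

from .constants import ROOM_TEMPERATURE, kbt
from .synthdata import CAPCurve, GatingPopulation, StiffnessCurve, cap_response, gating_stiffness

__all__ = [
    "PopulationFit",
    "GatingSpringFit",
    "CAPFit",
    "HomeostasisCorrelation",
    "fit_gating_spring",
    "fit_cap",
    "nz_homeostasis",
]


@dataclass
class PopulationFit:
    """Fitted parameters of one transducer channel population."""

    N: float
    z: float  # single-channel gating force, N
    X0: float  # set point, m
    N_sd: float = np.inf
    z_sd: float = np.inf

    @property
    def dip_depth(self) -> float:
        """Stiffness deficit N z^2 / (4 k_B T) at the set point (at 294.15 K
        unless recomputed by the caller)."""
        return self.N * self.z**2 / (4.0 * kbt(ROOM_TEMPERATURE))


@dataclass
class GatingSpringFit:
    """Two-population gating-spring fit of one stiffness curve.

    ``sensitive`` is the population with the larger gating force z (labelling
    convention); ``k_total`` estimates K_steady + K_GS. ``K_steady`` and
    ``K_GS`` are filled only when ``series_compliance_ratio`` was supplied to
    the fit, otherwise they stay None.
    """

    k_total: float
    sensitive: PopulationFit | None
    insensitive: PopulationFit | None
    T: float
    residual: float
    converged: bool
    identifiable: bool = True
    K_steady: float | None = None
    K_GS: float | None = None
    covariance: np.ndarray | None = None
    n_points: int = 0

    def predict(self, X: np.ndarray) -> np.ndarray:
        pops = [
            GatingPopulation(N=p.N, z=p.z, X0=p.X0)
            for p in (self.sensitive, self.insensitive)
            if p is not None and p.N > 0
        ]
        return gating_stiffness(X, self.k_total, tuple(pops), self.T)


@dataclass
class CAPFit:
    """Double-sigmoid fit of compound-action-potential medians vs |X|."""

    A_s: float
    A_i: float
    X50_s: float
    X50_i: float
    w_s: float
    w_i: float
    residual: float
    converged: bool
    monotone_warning: bool = False
    level_medians: np.ndarray | None = None


@dataclass
class HomeostasisCorrelation:
    """log N vs log z correlation and the N z^2 nonlinearity statistic."""

    n_pairs: int
    r_log: float
    p_value: float
    nz2_mean: float
    nz2_cv: float  # coefficient of variation of N z^2 across individuals


# ---------------------------------------------------------------------------
# stiffness-curve fitting


def _detect_dips(X: np.ndarray, K: np.ndarray, T: float, max_dips: int):
    """Locate compliance dips by smoothing + local-minimum search.

    Returns a list of (X0, depth, z_init) ordered by depth, and the estimated
    constant level. Returns an empty list when no dip rises above noise
    (model-selection guard against fitting spurious populations).
    """
    n = len(K)
    win = max(5, (n // 10) | 1)
    K_s = signal.savgol_filter(K, window_length=min(win, n - (1 - n % 2)), polyorder=2)
    noise = np.median(np.abs(np.diff(K - K_s))) / np.sqrt(2) / 0.6745 + 1e-30
    level = np.percentile(K_s, 90)
    prominence = max(3.0 * noise, 1e-4 * level)
    peaks, props = signal.find_peaks(-K_s, prominence=prominence, width=1, rel_height=0.5)
    dips = []
    dx = np.median(np.diff(X))
    for i, pk in enumerate(peaks):
        depth = level - K_s[pk]
        width_x = props["widths"][i] * dx
        # two-state dip FWHM = 3.525 k_B T / z
        z0 = 3.525 * kbt(T) / max(width_x, dx)
        dips.append((X[pk], depth, z0))
    dips.sort(key=lambda d: -d[1])
    return dips[:max_dips], level


def fit_gating_spring(
    curve: StiffnessCurve,
    T: float = ROOM_TEMPERATURE,
    n_populations: int = 2,
    series_compliance_ratio: float | None = None,
) -> GatingSpringFit:
    """Bounded nonlinear least-squares fit of the gating-spring model.

    Populations are initialized from dips found by smoothing + local-minimum
    search (z from the dip width via z ~ 4 k_B T / width, N from the dip
    depth). The fit runs in non-dimensionalized variables, then labels
    populations by the |z| convention: sensitive = larger gating force.

    If no dip rises above the noise the gating populations are dropped and the
    constant level is returned with N = 0 (no spurious dips). If the grid does
    not cover a detected dip's Boltzmann flanks the fit is flagged
    unidentifiable and the population's variances are set to infinity.

    ``series_compliance_ratio`` = K_GS / (K_steady + K_GS), when known from an
    independent series-spring analysis, splits ``k_total`` into the reported
    K_steady and K_GS; otherwise both stay None.
    """
    if n_populations not in (1, 2):
        raise ValueError("n_populations must be 1 or 2")
    X = np.asarray(curve.displacement, dtype=float)
    K = np.asarray(curve.stiffness, dtype=float)
    if X.size < 15:
        raise ValueError("need >= 15 stiffness points")
    order = np.argsort(X)
    X, K = X[order], K[order]

    dips, level = _detect_dips(X, K, T, n_populations)
    kT = kbt(T)

    if not dips:
        k_tot = float(np.mean(K))
        resid = float(np.sqrt(np.mean((K - k_tot) ** 2)))
        fit = GatingSpringFit(
            k_total=k_tot,
            sensitive=None,
            insensitive=None,
            T=T,
            residual=resid,
            converged=True,
            n_points=X.size,
        )
        _split_k(fit, series_compliance_ratio)
        return fit

    # non-dimensionalize: X' = X / xs, K' = K / ks; each population is fitted
    # as (scaled dip depth d, scaled gating force z', scaled set point x0')
    xs = (X.max() - X.min()) / 2.0
    ks = level

    def unpack(theta):
        k_tot = theta[0] * ks
        pops = []
        for j in range((len(theta) - 1) // 3):
            d, zp, x0p = theta[1 + 3 * j : 4 + 3 * j]
            z = zp * kT / xs
            N = d * ks * 4.0 * kT / z**2
            pops.append((N, z, x0p * xs))
        return k_tot, pops

    def model(theta):
        k_tot, pops = unpack(theta)
        Km = np.full_like(X, k_tot)
        for N, z, x0 in pops:
            arg = np.clip(z * (X - x0) / kT, -500, 500)
            p = 1.0 / (1.0 + np.exp(-arg))
            Km = Km - N * z**2 / kT * p * (1.0 - p)
        return Km

    def solve(inits):
        theta0 = [level / ks]
        lb, ub = [1e-3], [1e3]
        for X0, depth, z0 in inits:
            theta0 += [max(depth, 1e-3 * level) / ks, z0 * xs / kT, X0 / xs]
            lb += [0.0, 1e-3, X.min() / xs - 1.0]
            ub += [1e3, 1e4, X.max() / xs + 1.0]
        return optimize.least_squares(
            lambda th: model(th) - K,
            x0=theta0,
            bounds=(lb, ub),
            method="trf",
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
        )

    inits = list(dips)
    sol = solve(inits)
    noise = np.median(np.abs(np.diff(K))) / np.sqrt(2) / 0.6745 + 1e-30

    # overlapping dips can merge into one broad minimum; seed further
    # populations from the residual of the current fit and refit jointly
    while len(inits) < n_populations:
        r = model(sol.x) - K  # positive where data dips below the model
        win = max(5, (X.size // 10) | 1)
        r_s = signal.savgol_filter(r, window_length=min(win, X.size - (1 - X.size % 2)), polyorder=2)
        i_min = int(np.argmax(r_s))
        depth = float(r_s[i_min])
        if depth <= 0:
            break
        half = depth / 2.0
        left = i_min
        while left > 0 and r_s[left] > half:
            left -= 1
        right = i_min
        while right < X.size - 1 and r_s[right] > half:
            right += 1
        width_x = max(X[right] - X[left], np.median(np.diff(X)))
        z0 = 3.525 * kT / width_x
        inits.append((X[i_min], depth, z0))
        sol = solve(inits)

    k_tot, pops = unpack(sol.x)
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    converged = bool(sol.success)

    # identifiability: every fitted dip needs +-4 k_B T / z coverage
    identifiable = True
    for _N, z, x0 in pops:
        span = 4.0 * kT / z
        if X.min() > x0 - span or X.max() < x0 + span:
            identifiable = False

    # covariance of the scaled parameters from the Gauss-Newton approximation
    dof = max(X.size - len(sol.x), 1)
    s2 = float(np.sum(sol.fun**2)) / dof
    try:
        cov_scaled = s2 * np.linalg.inv(sol.jac.T @ sol.jac)
    except np.linalg.LinAlgError:
        cov_scaled = np.full((len(sol.x), len(sol.x)), np.inf)
        converged = False

    pop_fits = []
    for j, (N, z, x0) in enumerate(pops):
        d, zp = sol.x[1 + 3 * j], sol.x[2 + 3 * j]
        var_d = cov_scaled[1 + 3 * j, 1 + 3 * j]
        var_zp = cov_scaled[2 + 3 * j, 2 + 3 * j]
        # delta method on N = 4 d ks kT xs^2 / (zp kT)^2, z = zp kT / xs
        if np.isfinite(var_d) and np.isfinite(var_zp) and identifiable:
            dN_dd = N / max(d, 1e-300)
            dN_dzp = -2.0 * N / max(zp, 1e-300)
            N_sd = float(np.sqrt(max(dN_dd**2 * var_d + dN_dzp**2 * var_zp, 0.0)))
            z_sd = float(np.sqrt(max(var_zp, 0.0)) * kT / xs)
        else:
            N_sd = z_sd = np.inf
        pop_fits.append(PopulationFit(N=N, z=z, X0=x0, N_sd=N_sd, z_sd=z_sd))

    # labelling convention: sensitive channels have the larger gating force
    pop_fits.sort(key=lambda p: -p.z)
    sensitive = pop_fits[0]
    insensitive = pop_fits[1] if len(pop_fits) > 1 else None

    fit = GatingSpringFit(
        k_total=k_tot,
        sensitive=sensitive,
        insensitive=insensitive,
        T=T,
        residual=rms,
        converged=converged,
        identifiable=identifiable,
        covariance=cov_scaled,
        n_points=X.size,
    )
    _split_k(fit, series_compliance_ratio)
    return fit


def _split_k(fit: GatingSpringFit, ratio: float | None) -> None:
    if ratio is not None:
        if not 0.0 < ratio < 1.0:
            raise ValueError("series_compliance_ratio must lie in (0, 1)")
        fit.K_GS = ratio * fit.k_total
        fit.K_steady = fit.k_total - fit.K_GS


# ---------------------------------------------------------------------------
# CAP curves


def fit_cap(curve: CAPCurve, monotone_tolerance: float = 3.0) -> CAPFit:
    """Fit a double sigmoid to per-level CAP medians.

    Replicates at each displacement level are collapsed to their median first,
    then the double sigmoid ``sum_j A_j / (1 + exp(-(|X| - X50_j)/w_j))`` is
    fitted by least squares. A warning flag is raised when the medians decrease
    along |X| by more than ``monotone_tolerance`` replicate standard errors.
    """
    X = np.abs(np.asarray(curve.displacement, dtype=float))
    amp = np.atleast_2d(np.asarray(curve.amplitude, dtype=float))
    if amp.shape[0] != X.size:
        amp = amp.T
    if X.size < 8:
        raise ValueError("need >= 8 stimulus levels")
    order = np.argsort(X)
    X = X[order]
    med = np.median(amp, axis=1)[order]

    n_rep = amp.shape[1]
    se = np.std(amp, axis=1, ddof=1)[order] / np.sqrt(n_rep) if n_rep > 1 else np.zeros_like(med)
    drops = np.diff(med)
    tol = monotone_tolerance * np.sqrt(se[1:] ** 2 + se[:-1] ** 2)
    monotone_warning = bool(np.any(drops < -(tol + 1e-12 * max(med.max(), 1.0))))
    if monotone_warning:
        warnings.warn("CAP level medians are non-monotonic beyond noise tolerance")

    top = med.max()
    span = X.max() - X.min()
    # quartile crossings seed the two half-points
    X50s0 = np.interp(0.25 * top, med, X)
    X50i0 = np.interp(0.75 * top, med, X)
    if X50i0 <= X50s0:
        X50i0 = X50s0 + 0.1 * span
    theta0 = [top / 2, top / 2, X50s0, X50i0, span / 20, span / 20]
    lb = [0.0, 0.0, X.min() - span, X.min() - span, span * 1e-4, span * 1e-4]
    ub = [10 * top + 1e-30, 10 * top + 1e-30, X.max() + span, X.max() + span, 10 * span, 10 * span]

    def resid(th):
        return cap_response(X, (th[0], th[1]), (th[2], th[3]), (th[4], th[5])) - med

    sol = optimize.least_squares(
        resid, x0=theta0, bounds=(lb, ub), xtol=1e-15, ftol=1e-15, gtol=1e-15
    )

    # model selection against a single sigmoid: a second population that does
    # not improve the fit is spurious (degenerate same-X50 splits included)
    def resid1(th):
        return cap_response(X, (th[0], 0.0), (th[1], th[1] + span), (th[2], span)) - med

    sol1 = optimize.least_squares(
        resid1,
        x0=[top, np.interp(0.5 * top, med, X), span / 20],
        bounds=([0.0, X.min() - span, span * 1e-4], [10 * top + 1e-30, X.max() + span, 10 * span]),
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    rms2 = np.sqrt(np.mean(sol.fun**2))
    rms1 = np.sqrt(np.mean(sol1.fun**2))
    if rms2 >= 0.90 * rms1:
        A = np.array([sol1.x[0], 0.0])
        X50 = np.array([sol1.x[1], sol1.x[1] + span])
        w = np.array([sol1.x[2], span])
        sol = sol1
    else:
        A = sol.x[:2]
        X50 = sol.x[2:4]
        w = sol.x[4:6]
    # sensitive population = smaller half-point
    s, i = (0, 1) if X50[0] <= X50[1] else (1, 0)
    return CAPFit(
        A_s=float(A[s]),
        A_i=float(A[i]),
        X50_s=float(X50[s]),
        X50_i=float(X50[i]),
        w_s=float(w[s]),
        w_i=float(w[i]),
        residual=float(np.sqrt(np.mean(sol.fun**2))),
        converged=bool(sol.success),
        monotone_warning=monotone_warning,
        level_medians=med,
    )


# ---------------------------------------------------------------------------
# N-z homeostasis


def nz_homeostasis(fits: list[GatingSpringFit], population: str = "sensitive") -> HomeostasisCorrelation:
    """Correlate log channel number against log gating force across fits.

    A perfect homeostatic compensation law N z^2 = const gives r = -1 on the
    log-log scale with zero coefficient of variation of N z^2; independently
    drawn N and z give r ~ 0.
    """
    pairs = []
    for f in fits:
        pop = getattr(f, population)
        if f.converged and pop is not None and pop.N > 0 and pop.z > 0:
            pairs.append((pop.N, pop.z))
    if len(pairs) < 5:
        raise ValueError(f"need >= 5 converged fits with a {population} population, got {len(pairs)}")
    N = np.array([p[0] for p in pairs])
    z = np.array([p[1] for p in pairs])
    r, p = stats.pearsonr(np.log(N), np.log(z))
    nz2 = N * z**2
    return HomeostasisCorrelation(
        n_pairs=len(pairs),
        r_log=float(r),
        p_value=float(p),
        nz2_mean=float(nz2.mean()),
        nz2_cv=float(nz2.std(ddof=0) / nz2.mean()),
    )
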