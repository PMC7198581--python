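"""Spectral analysis of receiver free fluctuations and SHO fitting.

The unstimulated antennal sound receiver behaves as a damped harmonic
oscillator driven by thermal noise plus, in the live ear, active energy
injection from the auditory neurons. Its velocity power spectrum

    S_v(f) = a f^2 / [(f0^2 - f^2)^2 + (f0 f / Q)^2]

yields three principal hearing parameters: the best frequency f0, the quality
factor Q, and — given the receiver stiffness K — the effective energy
E_eff = K <x^2> / k_B T in units of k_B T. A passive (dead or terminally aged)
receiver sits at thermal equilibrium, E_eff = 1; the power gain G = E_eff - 1
measures the energy injected by the active process and drops to ~0 with
age-related hearing loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal, special, stats

from .constants import ROOM_TEMPERATURE, kbt
from .synthdata import FluctuationRecording

__all__ = [
    "PowerSpectrum",
    "SHOFit",
    "LifeCourseSummary",
    "estimate_psd",
    "sho_velocity_psd",
    "fit_sho",
    "stable_best_frequency",
    "summarize_lifecourse",
]


@dataclass
class PowerSpectrum:
    """One-sided velocity PSD in (m/s)^2/Hz from averaged periodograms."""

    frequencies: np.ndarray
    psd: np.ndarray
    n_segments: int
    resolution: float

    def band(self, f_lo: float, f_hi: float) -> tuple[np.ndarray, np.ndarray]:
        sel = (self.frequencies >= f_lo) & (self.frequencies <= f_hi)
        return self.frequencies[sel], self.psd[sel]


@dataclass
class SHOFit:
    """Fitted oscillator parameters and energy content of one recording."""

    f0: float
    Q: float
    amplitude: float  # 'a' in the PSD model, (m/s)^2 Hz^3
    energy: float  # E_eff in k_B T units
    gain: float  # G = E_eff - 1
    residual: float  # RMS residual on log-PSD in the fitted band
    converged: bool
    displacement_variance: float  # <x^2> implied by the fit, m^2


@dataclass
class LifeCourseSummary:
    """Per-age medians of fitted hearing parameters and the gain trajectory."""

    ages: list
    median_f0: np.ndarray
    median_Q: np.ndarray
    median_gain: np.ndarray
    normalized_gain_pct: np.ndarray  # median gain in % of its maximum over ages
    pairwise_gain_p: dict  # (age_a, age_b) -> two-sided Mann-Whitney p on gains


def estimate_psd(
    rec: FluctuationRecording,
    segment_length_s: float = 1.0,
    overlap_frac: float = 0.5,
) -> PowerSpectrum:
    """Averaged-periodogram (Welch) one-sided velocity PSD of a recording.

    Velocity is taken from the recording if present, otherwise obtained by
    central differencing of the displacement trace.
    """
    if rec.velocity is not None and len(np.atleast_1d(rec.velocity)):
        v = np.asarray(rec.velocity, dtype=float)
    else:
        v = np.gradient(np.asarray(rec.displacement, dtype=float)) * rec.sample_rate
    if np.any(~np.isfinite(v)):
        raise ValueError("trace contains NaN or infinite samples")
    nperseg = int(round(segment_length_s * rec.sample_rate))
    if len(v) < 2 * nperseg:
        raise ValueError("trace shorter than two segments")
    noverlap = int(round(overlap_frac * nperseg))
    freqs, psd = signal.welch(
        v, fs=rec.sample_rate, nperseg=nperseg, noverlap=noverlap, detrend="constant"
    )
    step = nperseg - noverlap
    n_segments = 1 + (len(v) - nperseg) // step
    return PowerSpectrum(
        frequencies=freqs, psd=psd, n_segments=n_segments, resolution=freqs[1] - freqs[0]
    )


def sho_velocity_psd(f: np.ndarray, a: float, f0: float, Q: float) -> np.ndarray:
    """Velocity PSD of a noise-driven SHO: a f^2 / [(f0^2-f^2)^2 + (f0 f/Q)^2]."""
    f = np.asarray(f, dtype=float)
    return a * f**2 / ((f0**2 - f**2) ** 2 + (f0 * f / Q) ** 2)


def _initial_guess(f: np.ndarray, p: np.ndarray) -> tuple[float, float, float]:
    i = int(np.argmax(p))
    f0 = f[i]
    peak = p[i]
    # half-power bandwidth -> Q
    above = p >= peak / 2.0
    lo = f[above].min()
    hi = f[above].max()
    bw = max(hi - lo, f[1] - f[0])
    Q = max(f0 / bw, 0.3)
    a = peak * f0**2 / Q**2
    return a, f0, Q


def fit_sho(
    ps: PowerSpectrum,
    band: tuple[float, float],
    T: float = ROOM_TEMPERATURE,
    stiffness: float = 50e-6,
    residual_threshold: float = 1.0,
) -> SHOFit:
    """Least-squares SHO fit to the velocity PSD over a frequency band.

    The loss is least squares on the log-PSD, which tames the heavy dynamic
    range of velocity spectra. The effective energy follows from the analytic
    displacement variance of the fitted oscillator,

        <x^2> = a Q / (8 pi f0^3),    E_eff = K <x^2> / k_B T,

    so a passive receiver at bath temperature T has E_eff = 1 and gain G = 0.
    ``stiffness`` is the receiver's linear stiffness K in N/m, known from
    independent mechanical measurement.

    Non-convergence is reported via the ``converged`` flag, not raised.
    """
    f, p = ps.band(*band)
    valid = (f > 0) & (p > 0)
    f, p = f[valid], p[valid]
    if f.size < 8:
        raise ValueError("fewer than 8 positive PSD points in the fitted band")
    # peak presence check on a smoothed copy (raw Welch bins are ~10% noisy)
    from scipy.ndimage import uniform_filter1d

    p_smooth = uniform_filter1d(p, size=max(5, f.size // 20))
    imax = int(np.argmax(p_smooth))
    edge = max(3, f.size // 50)
    if imax < edge or imax >= f.size - edge or p_smooth[imax] <= 1.05 * max(
        p_smooth[0], p_smooth[-1]
    ):
        raise ValueError("no spectral peak inside the fitted band")

    a0, f00, Q0 = _initial_guess(f, p)
    # An averaged periodogram of K segments is ~Gamma(K); its log is biased by
    # psi(K) - ln K (~ -1/2K). Undo that so the log-domain fit stays unbiased.
    logp = np.log(p) + (np.log(ps.n_segments) - special.digamma(ps.n_segments))

    def resid(theta):
        la, lf0, lQ = theta
        model = sho_velocity_psd(f, np.exp(la), np.exp(lf0), np.exp(lQ))
        return np.log(model) - logp

    lb = [np.log(a0) - 20.0, np.log(band[0]), np.log(0.05)]
    ub = [np.log(a0) + 20.0, np.log(band[1]), np.log(1e3)]
    sol = optimize.least_squares(
        resid, x0=[np.log(a0), np.log(f00), np.log(Q0)], bounds=(lb, ub), method="trf"
    )
    a, f0, Q = np.exp(sol.x)
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    at_bounds = bool(np.any(np.isclose(sol.x, lb, atol=1e-6)) or np.any(np.isclose(sol.x, ub, atol=1e-6)))
    converged = bool(sol.success) and rms < residual_threshold and not at_bounds

    x_var = a * Q / (8.0 * np.pi * f0**3)
    energy = stiffness * x_var / kbt(T)
    return SHOFit(
        f0=float(f0),
        Q=float(Q),
        amplitude=float(a),
        energy=float(energy),
        gain=float(energy - 1.0),
        residual=rms,
        converged=converged,
        displacement_variance=float(x_var),
    )


def stable_best_frequency(before: SHOFit, after: SHOFit, max_change: float = 0.20) -> bool:
    """Quality gate: keep an individual only if f0 changed by <= 20 % between
    the recordings taken before and after the experiment."""
    return abs(after.f0 - before.f0) / before.f0 <= max_change


def summarize_lifecourse(fits_by_age: dict) -> LifeCourseSummary:
    """Collapse individual fits into per-age medians and a gain trajectory.

    ``fits_by_age`` maps age label -> list of SHOFit (>= 3 individuals per
    age). The gain trajectory is the per-age median gain expressed in % of its
    maximum across ages; ages are compared pairwise on individual gains with a
    two-sided Mann-Whitney U test (raw p-values, no multiplicity adjustment).
    """
    ages = sorted(fits_by_age)
    for age in ages:
        if len(fits_by_age[age]) == 0:
            raise ValueError(f"empty age group {age!r}")
        if len(fits_by_age[age]) < 3:
            raise ValueError(f"need >= 3 individuals per age, got {len(fits_by_age[age])} at {age!r}")
    med_f0 = np.array([np.median([x.f0 for x in fits_by_age[a]]) for a in ages])
    med_Q = np.array([np.median([x.Q for x in fits_by_age[a]]) for a in ages])
    med_G = np.array([np.median([x.gain for x in fits_by_age[a]]) for a in ages])
    norm = med_G / med_G.max() * 100.0
    pairwise = {}
    for i, a in enumerate(ages):
        for b in ages[i + 1 :]:
            ga = [x.gain for x in fits_by_age[a]]
            gb = [x.gain for x in fits_by_age[b]]
            pairwise[(a, b)] = float(stats.mannwhitneyu(ga, gb, alternative="two-sided").pvalue)
    return LifeCourseSummary(
        ages=ages,
        median_f0=med_f0,
        median_Q=med_Q,
        median_gain=med_G,
        normalized_gain_pct=norm,
        pairwise_gain_p=pairwise,
    )
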