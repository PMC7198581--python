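"""Seed-controlled generators for every input the pipeline consumes.

Each generator emulates one class of raw data from a life-course study of the
Drosophila antennal ear: free-fluctuation traces of the sound receiver,
stiffness-vs-displacement (gating compliance) curves, compound-action-potential
response curves, age-series RNA count matrices, beam-break locomotor activity,
and cohort death times. Ground-truth parameters are recorded on every output so
that downstream fits can be scored against them.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .constants import BOLTZMANN, ROOM_TEMPERATURE, kbt

__all__ = [
    "OscillatorParams",
    "GatingPopulation",
    "GatingTruth",
    "CountSimSpec",
    "BehaviorSimSpec",
    "FluctuationRecording",
    "StiffnessCurve",
    "CAPCurve",
    "AgeSeriesCounts",
    "ActivityTrace",
    "simulate_fluctuations",
    "simulate_stiffness_curve",
    "simulate_cap_curve",
    "simulate_counts",
    "simulate_activity",
    "simulate_qpcr_plate",
    "simulate_go_annotation",
    "simulate_deaths",
]


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class OscillatorParams:
    """Parameters of the damped harmonic oscillator standing in for the receiver.

    The active amplification of the live ear is modelled as an effective
    temperature ``T_eff >= T``: the white noise force driving the oscillator has
    one-sided spectral density ``4*gamma*k_B*T_eff``, so the stationary
    displacement variance is ``k_B*T_eff / K`` (equipartition at ``T_eff``).

    Parameters
    ----------
    f0 : best frequency in Hz.
    Q : quality factor (dimensionless).
    K : total linear stiffness in N/m.
    T : bath temperature in K.
    T_eff : effective temperature in K; equals ``T`` for a passive (dead) receiver.
    sample_rate : output sampling rate in Hz; must be >= 20*f0.
    duration : length of the stationary trace in s (burn-in is extra).
    seed : RNG seed.
    """

    f0: float = 250.0
    Q: float = 1.5
    K: float = 50e-6
    T: float = ROOM_TEMPERATURE
    T_eff: float = ROOM_TEMPERATURE
    sample_rate: float = 1e4
    duration: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        vals = (self.f0, self.Q, self.K, self.T, self.T_eff, self.sample_rate, self.duration)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("oscillator parameters must be finite")
        if self.f0 <= 0 or self.Q <= 0 or self.K <= 0 or self.T <= 0:
            raise ValueError("f0, Q, K and T must be positive")
        if self.T_eff < self.T:
            raise ValueError("T_eff < T: the active process only adds energy")
        if self.sample_rate < 20.0 * self.f0:
            raise ValueError(
                f"sample_rate {self.sample_rate} Hz < 20*f0 = {20 * self.f0} Hz (aliasing)"
            )

    @property
    def mass(self) -> float:
        """Effective mass m from f0 = sqrt(K/m)/(2*pi)."""
        return self.K / (2.0 * np.pi * self.f0) ** 2

    @property
    def damping(self) -> float:
        """Damping coefficient gamma from Q = sqrt(m*K)/gamma."""
        return np.sqrt(self.mass * self.K) / self.Q


@dataclass(frozen=True)
class GatingPopulation:
    """One mechanotransducer channel population (sensitive or insensitive).

    N : number of channels (0 disables the population).
    z : single-channel gating force in N.
    X0 : set-point displacement in m (open probability 1/2 there).
    """

    N: float
    z: float
    X0: float = 0.0

    def __post_init__(self) -> None:
        if self.N < 0:
            raise ValueError("channel count N must be >= 0")
        if self.N > 0 and self.z <= 0:
            raise ValueError("gating force z must be > 0 for an active population")


@dataclass(frozen=True)
class GatingTruth:
    """Ground truth for a gating-spring stiffness curve.

    The receiver's slope stiffness is

        K(X) = K_steady + K_GS - sum_j N_j z_j^2 / (k_B T) * p_j(X) (1 - p_j(X))

    with two-state Boltzmann open probability
    ``p_j(X) = 1 / (1 + exp(-z_j (X - X0_j) / (k_B T)))``. Each population
    carves a compliance dip of depth ``N_j z_j^2 / (4 k_B T)`` at its set point.
    """

    K_steady: float = 30e-6
    K_GS: float = 30e-6
    populations: tuple[GatingPopulation, ...] = (
        # sensitive (auditory) channels: few, large gating force;
        # insensitive (wind/gravity) channels: many, small gating force
        GatingPopulation(N=80, z=50e-15, X0=0.0),
        GatingPopulation(N=1600, z=10e-15, X0=500e-9),
    )
    T: float = ROOM_TEMPERATURE
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K_steady <= 0 or self.K_GS <= 0:
            raise ValueError("stiffnesses must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        dip_total = sum(p.N * p.z**2 / (4 * kbt(self.T)) for p in self.populations)
        if self.K_steady + self.K_GS - dip_total <= 0:
            raise ValueError("stiffness would go non-positive at the compliance dip")

    @property
    def k_total(self) -> float:
        """Asymptotic stiffness K_steady + K_GS (the level far from all dips)."""
        return self.K_steady + self.K_GS


@dataclass(frozen=True)
class CountSimSpec:
    """Design of a synthetic age-series RNA count matrix.

    Baseline per-gene means are drawn log-normally (``mean_log``/``sd_log`` on
    the natural-log scale); counts are negative binomial with a common
    dispersion alpha (var = mu + alpha*mu^2). A ``spike_fraction`` of genes is
    age-variable: their mean steps by ``spike_fold_change`` (up or down) at one
    randomly assigned transition between consecutive ages.
    """

    n_genes: int = 2000
    ages: tuple[int, ...] = (1, 5, 10, 25, 50)
    reps_per_age: int = 3
    mean_log: float = 5.5
    sd_log: float = 1.5
    dispersion: float = 0.05
    spike_fraction: float = 0.1
    spike_fold_change: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reps_per_age < 2:
            raise ValueError("need >= 2 replicates per age")
        if not 0.0 <= self.spike_fraction <= 1.0:
            raise ValueError("spike_fraction must lie in [0, 1]")
        if self.spike_fraction > 0 and self.spike_fold_change <= 1.0:
            raise ValueError("spike_fold_change must exceed 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if len(self.ages) < 2:
            raise ValueError("need at least two ages")


@dataclass(frozen=True)
class BehaviorSimSpec:
    """Design of a beam-break activity simulation.

    Sound plays during the first 15 min of every hour; the last 15 min of the
    hour are the silent baseline directly preceding the next stimulus. Counts
    per minute are Poisson with rate ``lambda_base * rho`` in stimulus minutes
    and ``lambda_base`` elsewhere.
    """

    n_tubes: int = 12
    hours: int = 24
    lambda_base: float = 1.0
    rho: float = 2.0
    stimulus_minutes: tuple[int, int] = (0, 15)
    baseline_minutes: tuple[int, int] = (45, 60)
    first_light_minute: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_base <= 0:
            raise ValueError("lambda_base must be > 0")
        if self.rho < 0:
            raise ValueError("rho must be >= 0")
        s0, s1 = self.stimulus_minutes
        b0, b1 = self.baseline_minutes
        if not (0 <= s0 < s1 <= 60 and 0 <= b0 < b1 <= 60):
            raise ValueError("windows must lie within the hour")
        if max(s0, b0) < min(s1, b1):
            raise ValueError("stimulus and baseline windows must be disjoint")


# ---------------------------------------------------------------------------
# output containers


@dataclass
class FluctuationRecording:
    """Sampled displacement/velocity trace of an unstimulated receiver."""

    time: np.ndarray
    displacement: np.ndarray
    velocity: np.ndarray
    sample_rate: float
    params: OscillatorParams | None = None

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class StiffnessCurve:
    """Slope stiffness K(X) samples against peak displacement X."""

    displacement: np.ndarray
    stiffness: np.ndarray
    stiffness_true: np.ndarray
    truth: GatingTruth | None = None


@dataclass
class CAPCurve:
    """Compound-action-potential amplitudes vs absolute antennal displacement.

    ``amplitude`` has shape (n_levels, n_replicates); ``truth`` holds the
    generating double-sigmoid parameters (A_s, A_i, X50_s, X50_i, w_s, w_i).
    """

    displacement: np.ndarray
    amplitude: np.ndarray
    truth: dict | None = None


@dataclass
class AgeSeriesCounts:
    """Gene x sample count matrix with an age-labelled sample sheet."""

    counts: pd.DataFrame
    samples: pd.DataFrame
    truth: pd.DataFrame | None = None

    def ages(self) -> list:
        return sorted(self.samples["age_day"].unique().tolist())

    def samples_for_age(self, age) -> list[str]:
        return self.samples.loc[self.samples["age_day"] == age, "sample_id"].tolist()


@dataclass
class ActivityTrace:
    """Per-minute beam-break counts per tube plus the stimulus schedule."""

    counts: pd.DataFrame  # columns: minute_index, tube_id, count
    stimulus_minutes: tuple[int, int]
    baseline_minutes: tuple[int, int]
    first_light_minute: int = 0
    spec: BehaviorSimSpec | None = None


# ---------------------------------------------------------------------------
# generators


def simulate_fluctuations(params: OscillatorParams) -> FluctuationRecording:
    """Integrate the receiver's Langevin equation and return a sampled trace.

    The SDE is ``m x'' + gamma x' + K x = xi(t)`` with white noise force of
    one-sided spectral density ``4 gamma k_B T_eff``. Because the system is
    linear, the transition over one sampling step is Gaussian with known
    moments, so the update uses the exact matrix-exponential discretization:
    the returned samples are drawn from the continuous process itself, with no
    step-size bias in the stationary variance (a plain stochastic-Euler scheme
    would inflate ``<x^2>`` by several percent at any practical step and bias
    the fitted power gain upward). A burn-in of ``20 Q / f0`` seconds is
    discarded so only the stationary portion is returned.
    """
    m = params.mass
    gamma = params.damping
    K = params.K
    dt = 1.0 / params.sample_rate

    burn_in = 20.0 * params.Q / params.f0
    n_keep = int(round(params.duration * params.sample_rate))
    n_burn = int(np.ceil(burn_in * params.sample_rate))
    n_steps = n_burn + n_keep + 1

    # state-space form d[x,v] = M [x,v] dt + [0, sqrt(2 gamma k_B T_eff)/m] dW
    g = gamma / m
    k = K / m
    M = np.array([[0.0, 1.0], [-k, -g]])
    A = _expm2(M * dt)
    # stationary covariance (equipartition at T_eff), exact one-step noise cov
    var_x = BOLTZMANN * params.T_eff / K
    var_v = BOLTZMANN * params.T_eff / m
    S_inf = np.diag([var_x, var_v])
    S_dt = S_inf - A @ S_inf @ A.T
    S_dt = (S_dt + S_dt.T) / 2.0
    L = np.linalg.cholesky(S_dt + 1e-30 * np.trace(S_dt) * np.eye(2))

    rng = np.random.default_rng(params.seed)
    w = rng.standard_normal((n_steps, 2)) @ L.T  # per-step Gaussian increments

    # eliminate v: x[n+1] = tr(A) x[n] - det(A) x[n-1] + u[n]
    #   with u[n] = w_x[n] + A12 w_v[n-1] - A22 w_x[n-1]
    trA = A[0, 0] + A[1, 1]
    detA = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    u = w[:, 0].copy()
    u[1:] += A[0, 1] * w[:-1, 1] - A[1, 1] * w[:-1, 0]
    x = signal.lfilter([1.0], [1.0, -trA, detA], u)
    # exact velocity state recovered from consecutive positions
    v = (x[1:] - A[0, 0] * x[:-1] - w[1:, 0]) / A[0, 1]
    v = np.concatenate([[0.0], v])

    x = x[n_burn + 1 :]
    v = v[n_burn + 1 :]
    time = np.arange(n_keep) / params.sample_rate
    return FluctuationRecording(
        time=time,
        displacement=x[:n_keep],
        velocity=v[:n_keep],
        sample_rate=params.sample_rate,
        params=params,
    )


def _expm2(B: np.ndarray) -> np.ndarray:
    """Matrix exponential of a real 2x2 matrix (closed form)."""
    tr = (B[0, 0] + B[1, 1]) / 2.0
    C = B - tr * np.eye(2)
    disc = C[0, 1] * C[1, 0] + C[0, 0] ** 2  # = -det(C)
    if disc > 0:
        s = np.sqrt(disc)
        cosh, sinhc = np.cosh(s), np.sinh(s) / s
    elif disc < 0:
        s = np.sqrt(-disc)
        cosh, sinhc = np.cos(s), np.sin(s) / s
    else:
        cosh, sinhc = 1.0, 1.0
    return np.exp(tr) * (cosh * np.eye(2) + sinhc * C)


def gating_open_probability(X: np.ndarray, z: float, X0: float, T: float) -> np.ndarray:
    """Two-state Boltzmann open probability p(X) = 1/(1 + exp(-z (X - X0)/k_B T))."""
    return 1.0 / (1.0 + np.exp(-z * (np.asarray(X, dtype=float) - X0) / kbt(T)))


def gating_stiffness(
    X: np.ndarray,
    k_total: float,
    populations: tuple[GatingPopulation, ...] | list[GatingPopulation],
    T: float,
) -> np.ndarray:
    """Noiseless gating-spring slope stiffness K(X) (closed form)."""
    X = np.asarray(X, dtype=float)
    K = np.full_like(X, k_total)
    for pop in populations:
        if pop.N > 0:
            p = gating_open_probability(X, pop.z, pop.X0, T)
            K = K - pop.N * pop.z**2 / kbt(T) * p * (1.0 - p)
    return K


def simulate_stiffness_curve(truth: GatingTruth, X_grid: np.ndarray) -> StiffnessCurve:
    """Sample the gating-spring stiffness on a displacement grid, plus noise.

    The grid must have >= 15 points and cover ``[X0 - 4 k_B T / z, X0 + 4 k_B T / z]``
    for every active population, otherwise the dip is unidentifiable.
    """
    X = np.asarray(X_grid, dtype=float)
    if X.size < 15:
        raise ValueError("need >= 15 displacement points")
    for pop in truth.populations:
        if pop.N > 0:
            span = 4.0 * kbt(truth.T) / pop.z
            if X.min() > pop.X0 - span or X.max() < pop.X0 + span:
                raise ValueError(
                    "displacement grid does not cover the compliance dip at "
                    f"X0 = {pop.X0:.3g} m +/- {span:.3g} m"
                )
    K_true = gating_stiffness(X, truth.k_total, truth.populations, truth.T)
    rng = np.random.default_rng(truth.seed)
    K_noisy = K_true + rng.standard_normal(X.size) * truth.noise_sd
    return StiffnessCurve(displacement=X, stiffness=K_noisy, stiffness_true=K_true, truth=truth)


def cap_response(
    X: np.ndarray,
    amplitudes: tuple[float, float],
    half_points: tuple[float, float],
    slopes: tuple[float, float],
) -> np.ndarray:
    """Noiseless double-sigmoid CAP amplitude vs absolute displacement."""
    aX = np.abs(np.asarray(X, dtype=float))
    out = np.zeros_like(aX)
    for A, X50, w in zip(amplitudes, half_points, slopes):
        out = out + A / (1.0 + np.exp(-(aX - X50) / w))
    return out


def simulate_cap_curve(
    amplitudes: tuple[float, float],
    half_points: tuple[float, float],
    slopes: tuple[float, float],
    X_grid: np.ndarray,
    noise_sd: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
) -> CAPCurve:
    """Generate noisy CAP-vs-displacement replicates.

    ``CAP(|X|) = sum_j A_j / (1 + exp(-(|X| - X50_j) / w_j))`` for the sensitive
    (small X50) and insensitive (large X50) populations; monotonically
    non-decreasing in |X|.
    """
    if any(A < 0 for A in amplitudes):
        raise ValueError("CAP amplitudes must be >= 0")
    if any(w <= 0 for w in slopes):
        raise ValueError("sigmoid widths must be > 0")
    if not half_points[0] < half_points[1]:
        raise ValueError("sensitive half-point X50_s must precede X50_i")
    X = np.asarray(X_grid, dtype=float)
    clean = cap_response(X, amplitudes, half_points, slopes)
    rng = np.random.default_rng(seed)
    amp = clean[:, None] + rng.standard_normal((X.size, n_replicates)) * noise_sd
    truth = {
        "A_s": amplitudes[0],
        "A_i": amplitudes[1],
        "X50_s": half_points[0],
        "X50_i": half_points[1],
        "w_s": slopes[0],
        "w_i": slopes[1],
    }
    return CAPCurve(displacement=X, amplitude=amp, truth=truth)


def simulate_counts(spec: CountSimSpec) -> AgeSeriesCounts:
    """Draw a negative-binomial age-series count matrix with spiked genes.

    Spiked genes have their mean multiplied (or divided, with equal
    probability) by ``spike_fold_change`` from one randomly assigned age
    transition onwards; all other genes keep a constant mean across ages.
    Truth labels (spiked flag, transition, direction) ride along for recovery
    tests.
    """
    rng = np.random.default_rng(spec.seed)
    n_ages = len(spec.ages)
    genes = [f"gene{i:05d}" for i in range(spec.n_genes)]

    base_mean = np.exp(rng.normal(spec.mean_log, spec.sd_log, size=spec.n_genes))
    n_spiked = int(round(spec.spike_fraction * spec.n_genes))
    spiked = np.zeros(spec.n_genes, dtype=bool)
    spiked[:n_spiked] = True
    rng.shuffle(spiked)
    transition = rng.integers(0, n_ages - 1, size=spec.n_genes)  # between ages[t] and ages[t+1]
    up = rng.random(spec.n_genes) < 0.5

    # per-gene, per-age mean: step at the assigned transition for spiked genes
    mu = np.tile(base_mean[:, None], (1, n_ages))
    for g in np.nonzero(spiked)[0]:
        fc = spec.spike_fold_change if up[g] else 1.0 / spec.spike_fold_change
        mu[g, transition[g] + 1 :] *= fc

    cols, data = [], []
    for ai, age in enumerate(spec.ages):
        for rep in range(1, spec.reps_per_age + 1):
            cols.append(f"d{age}_r{rep}")
            m = mu[:, ai]
            if spec.dispersion > 1e-12:
                r = 1.0 / spec.dispersion
                data.append(rng.negative_binomial(r, r / (r + m)))
            else:
                data.append(rng.poisson(m))
    counts = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    counts.index.name = "gene_id"

    samples = pd.DataFrame(
        {
            "sample_id": cols,
            "age_day": [spec.ages[i // spec.reps_per_age] for i in range(len(cols))],
            "sex": "mixed",
            "replicate": [i % spec.reps_per_age + 1 for i in range(len(cols))],
        }
    )
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "spiked": spiked,
            "base_mean": base_mean,
            "transition_from": [spec.ages[t] for t in transition],
            "transition_to": [spec.ages[t + 1] for t in transition],
            "direction": np.where(up, "up", "down"),
            "fold_change": np.where(
                spiked,
                np.where(up, spec.spike_fold_change, 1.0 / spec.spike_fold_change),
                1.0,
            ),
        }
    ).set_index("gene_id")
    return AgeSeriesCounts(counts=counts, samples=samples, truth=truth)


def simulate_activity(spec: BehaviorSimSpec) -> ActivityTrace:
    """Draw per-minute Poisson beam-break counts with sound-ON increments."""
    rng = np.random.default_rng(spec.seed)
    n_min = spec.hours * 60
    minute = np.arange(n_min)
    in_hour = minute % 60
    s0, s1 = spec.stimulus_minutes
    rate = np.where((in_hour >= s0) & (in_hour < s1), spec.lambda_base * spec.rho, spec.lambda_base)
    counts = rng.poisson(np.tile(rate, (spec.n_tubes, 1)))
    frames = []
    for tube in range(spec.n_tubes):
        frames.append(
            pd.DataFrame(
                {"minute_index": minute, "tube_id": f"tube{tube:02d}", "count": counts[tube]}
            )
        )
    return ActivityTrace(
        counts=pd.concat(frames, ignore_index=True),
        stimulus_minutes=spec.stimulus_minutes,
        baseline_minutes=spec.baseline_minutes,
        first_light_minute=spec.first_light_minute,
        spec=spec,
    )


def simulate_qpcr_plate(
    true_rq: dict[str, float] | None = None,
    n_bioreps: int = 3,
    n_techreps: int = 3,
    endogenous_control: str = "SdhA",
    ct_base: float = 20.0,
    ct_noise_sd: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthesize a qPCR plate for knockdown-vs-control quantification.

    ``true_rq`` maps target gene -> true knockdown/control expression ratio
    under the standard Livak convention (0.25 = 4-fold knockdown). Ct values
    follow Ct = ct_base - log2(relative expression) plus Gaussian technical
    noise; the endogenous control is constant across conditions.
    """
    if true_rq is None:
        true_rq = {"Dhc98D": 0.25, "nompC": 1.0}
    rng = np.random.default_rng(seed)
    rows = []
    for gene in list(true_rq) + [endogenous_control]:
        for condition in ("control", "knockdown"):
            if gene == endogenous_control:
                ct_true = ct_base - 2.0  # housekeeping: higher expression, stable
            else:
                expr = 1.0 if condition == "control" else true_rq[gene]
                ct_true = ct_base - np.log2(expr)
            for bio in range(1, n_bioreps + 1):
                bio_shift = rng.normal(0.0, ct_noise_sd / 2.0)
                for tech in range(1, n_techreps + 1):
                    rows.append(
                        {
                            "target": gene,
                            "condition": condition,
                            "bio_rep": bio,
                            "tech_rep": tech,
                            "Ct": ct_true + bio_shift + rng.normal(0.0, ct_noise_sd),
                        }
                    )
    return pd.DataFrame(rows)


def simulate_go_annotation(
    genes: list[str],
    n_terms: int = 20,
    mean_term_size: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Random gene -> GO-term annotation table for enrichment plumbing tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for t in range(n_terms):
        size = max(5, rng.poisson(mean_term_size))
        for g in rng.choice(genes, size=min(size, len(genes)), replace=False):
            rows.append({"gene": g, "term": f"GO:{t:07d}"})
    return pd.DataFrame(rows)


def simulate_deaths(
    n_cohorts: int = 3,
    cohort_size: int = 25,
    daily_hazard: float = 0.02,
    max_day: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Geometric-hazard death days for lifespan cohorts.

    Returns a tidy frame (cohort, day, deaths); flies alive at ``max_day`` are
    recorded as dying on that day (the hazard makes this vanishingly rare at
    default settings).
    """
    if daily_hazard <= 0 or daily_hazard >= 1:
        raise ValueError("daily_hazard must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_cohorts):
        days = rng.geometric(daily_hazard, size=cohort_size)
        days = np.minimum(days, max_day)
        uniq, cnt = np.unique(days, return_counts=True)
        for d, n in zip(uniq, cnt):
            rows.append({"cohort": f"cohort{c}", "day": int(d), "deaths": int(n)})
    return pd.DataFrame(rows)
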