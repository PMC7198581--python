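# Methods

This note documents the models, estimators and numerical choices behind each
pipeline stage, what the synthetic-data generators do and do not emulate, and
the design decisions taken where the underlying procedure was open.

## Units and constants

SI units repo-wide: displacement in m (reported in nm), force in N (pN/fN),
stiffness in N/m (µN/m), temperature in K. Energies are expressed in units of
k_BT with k_B = 1.380649×10⁻²³ J/K. The default bath temperature is 294.15 K
(21 °C, room temperature for the recordings this pipeline targets).

## Receiver fluctuations

**Model.** The unstimulated sound receiver is modelled as a damped harmonic
oscillator, m·x″ + γ·x′ + K·x = ξ(t), with m and γ derived from the best
frequency and quality factor via f₀ = √(K/m)/2π and Q = √(mK)/γ. The active
process of the live ear is represented as an effective temperature: the white
noise force has one-sided spectral density 4γk_B·T_eff with T_eff ≥ T, so the
stationary displacement variance is k_B·T_eff/K. This choice reflects that
receiver activity is quantified here purely as an energy gain; a mechanistic
motor-feedback model would add parameters without changing that observable.

**Simulation.** Because the SDE is linear, the transition density over one
sampling step is Gaussian with moments available in closed form, so the
generator uses the exact matrix-exponential update: Σ_dt = Σ_∞ − A·Σ_∞·Aᵀ with
A = exp(M·dt), evaluated through a second-order IIR recursion
(scipy.signal.lfilter) for speed. The samples are therefore draws from the
continuous process itself, with no step-size bias. (A stochastic-Euler scheme
at any practical step inflates ⟨x²⟩ by several percent — enough to bias the
fitted power gain of a passive receiver visibly away from zero, which is why
the exact update is used instead.) A burn-in of 20·Q/f₀ seconds is discarded;
output is deterministic under a fixed seed. Default recording: 60 s at
10 kHz, the regime in which all recovery tolerances here were established.

**Spectral estimation.** Velocity PSDs are averaged modified periodograms
(Welch, Hann window, 50 % overlap, 1 s segments by default; velocity by
central differencing when only displacement is stored). The estimate
integrates back to the trace variance within 2 % (Parseval check enforced in
tests).

**SHO fit.** Least squares on the log-PSD over the analysis band — the log
domain tames the ~4-decade dynamic range of velocity spectra. An averaged
periodogram of K segments is Gamma-distributed, so its log is biased by
ψ(K) − ln K ≈ −1/(2K); the fit removes this bias explicitly, without which
the fitted gain of a passive receiver sits systematically below zero.
Initialization: f₀ at the smoothed PSD argmax, Q from the half-power
bandwidth, amplitude from the peak height; bounded trust-region optimisation
in log-parameters. The effective energy uses the analytic variance of the
fitted oscillator, ⟨x²⟩ = aQ/(8πf₀³), and E_eff = K⟨x²⟩/k_BT; the stiffness K
is supplied by the caller (the velocity spectrum alone determines only
(a, f₀, Q) — absolute energy requires an independent stiffness, which for
real preparations comes from mechanical measurement and for synthetic data
from the generator truth). Power gain G = E_eff − 1, so a passive receiver
has G = 0 by construction. Non-convergence (residual above threshold, bounds
hit) is flagged, not raised.

**Quality gating.** An analysis comparing before/after recordings rejects
individuals whose best frequency changed by more than 20 %.

**Life-course summary.** Per-age medians of f₀, Q and G across individuals
(≥ 3 per age); the gain trajectory is normalized to % of its maximum median.
Pairwise age comparisons use the two-sided Mann-Whitney U test with raw
(unadjusted) p-values.

## Transducer gating

**Model.** Slope stiffness K(X) = K_steady + K_GS − Σⱼ Nⱼzⱼ²/(k_BT)·pⱼ(1−pⱼ)
with two-state Boltzmann open probabilities. Each population carves a dip of
depth Nⱼzⱼ²/(4k_BT) and FWHM 3.525·k_BT/zⱼ at its set point. K_steady
(antennal joint) and K_GS (gating springs) enter only through their sum and
are not separately identifiable from a single stiffness curve; the fit
reports k_total and fills the decomposition only when a series-compliance
ratio is supplied from an independent analysis.

**Fitting.** Dips are located by Savitzky-Golay smoothing and local-minimum
search; z is initialized from the dip width (z ≈ 4k_BT/width), N from the dip
depth. Because overlapping dips can merge into a single broad minimum, the
fit is staged: populations found by detection are fitted first, then further
populations (up to the requested count) are seeded from the largest residual
dip and refitted jointly. The optimisation runs in non-dimensionalized
variables (stiffness in units of the plateau level, displacement in units of
the half-range, each population parametrized by its scaled dip depth, scaled
gating force and set point) with tight tolerances, recovering noiseless
curves to machine precision. Populations are labelled by the |z| convention —
sensitive = larger single-channel gating force. Both set points are free
parameters; no symmetry between forcing directions is imposed. When no dip
rises above the noise the gating populations are dropped entirely and the
constant level is returned (no spurious dips); when the grid fails to cover a
fitted dip's Boltzmann flanks (±4k_BT/z) the fit is flagged unidentifiable
and that population's variances are set to infinity. Parameter uncertainties
come from the Gauss-Newton covariance with a delta-method transform to
(N, z).

**Default truth.** The generator's default two-population truth is
N_s = 80, z_s = 50 fN (sensitive, set point 0) and N_i = 1600, z_i = 10 fN
(insensitive, set point 500 nm) in K_steady + K_GS = 60 µN/m — channel counts
and forces in the range reported for wildtype fly ears, where the insensitive
(wind/gravity) population is roughly an order of magnitude more numerous than
the sensitive one with correspondingly smaller gating forces. This matters
for validation design: a Cramér-Rao analysis shows that a shallow insensitive
dip (e.g. N_i = 200, z_i = 15 fN, dip depth ≈ 2.8 µN/m) cannot be recovered
to 10 % from a 200-point curve at 2 % stiffness noise by *any* estimator —
the realistic deep-dip configuration is what makes the Monte-Carlo recovery
test meaningful. The Monte-Carlo grid spans the insensitive set point
±1.3×(4k_BT/z_i), which covers both dips and was chosen for identifiability
before noise was added.

**CAP curves.** Replicates at each stimulus level are collapsed to medians
first; a double sigmoid in |X| is then fitted by least squares, with a
single-sigmoid alternative fitted alongside — the second population is kept
only if it improves the RMS residual by more than 10 %, which prevents
degenerate equal-amplitude splits on single-population data. Median
non-monotonicity beyond replicate standard errors raises a warning flag.

**N–z homeostasis.** Pearson correlation of log N vs log z across converged
fits (≥ 5), per population, plus the coefficient of variation of N·z² — the
stabilized-nonlinearity statistic. The log scale is used because the
compensation law is multiplicative (N·z² ≈ const gives r = −1 exactly).

## Transcriptome ageing

**Differential expression.** The per-gene test is a deliberately simple
negative-binomial stand-in for a full DESeq2-style analysis (which is outside
this package's scope; no numeric agreement with DESeq2 is claimed or tested).
Size factors are DESeq-style median-of-ratios (median-library fallback for
small matrices); dispersion is pooled method-of-moments across the two groups
(α = max(0, (s² − μ)/μ²)); the Wald statistic on the natural-log fold change
uses the delta-method variance (1/μ + α)/n per group. The reference
distribution is t with n_a + n_b − 2 degrees of freedom rather than normal:
with 2-3 replicates the plug-in dispersion makes a normal reference
anti-conservative, and the t reference keeps the empirical false-positive
rate within its nominal bound (verified by null simulation). BH adjustment
yields the FDR column. Genes with all-zero counts in both groups get
log2FC = 0, p = 1. Sex is supported as a sample-sheet column; the default
analysis pools sexes.

**Age-variability filter.** A gene is age-variable iff in at least one
pairwise comparison |FC| > 1.5 (strict, per the printed criterion) AND
FDR < 0.10 AND p < 0.05. The complement within the expressed set is the
constant-expression set; the partition is exact.

**Enrichment.** Enrichment = (b/n)/(B/N) with b the target∩term count, n the
target size, B the term size in the background, N the background size;
p-values are plain hypergeometric upper tails P(X ≥ b) (not the
mHG statistic of the original online tool).

**Panel overlaps.** A foreign panel gene counts as conserved-and-expressed if
any fly ortholog is expressed, and as age-variable if any such ortholog is in
the age-variable set. Percentages are rounded at the precision of the table
caption they reproduce (integer or one decimal) and are exactly recomputable
from the integer counts.

**Submission lists.** Round I intersects the age-variable set with four
hearing-relevant GO groups (trafficking, structural, dynein motors,
receptors); round II keeps age-variable genes whose mean normalized count
strictly exceeds 10,000 ("more than" — boundary excluded); round III keeps
genes moved at least 4-fold in ≥ 1 comparison ("at least" — boundary
included). The ">10,000 reads" criterion is interpreted as the mean
normalized count across the gene's samples. TF candidates returned by the
external motif tool are filtered to expressed genes at NES ≥ 2.5 (boundary
inclusive).

## Assays

**qPCR.** Technical replicates are averaged to one Ct per (target, condition,
biological replicate); ΔCt subtracts the endogenous control (SdhA by default)
within the same condition and bio-rep; RQ = 2^−ΔΔCt is computed per bio-rep,
then averaged with its standard deviation. Two sign conventions are
implemented side by side: `printed` follows the source protocol's equations
literally (ΔΔCt = ΔCt_ctrl − ΔCt_KD, so a knockdown with a raised target Ct
yields RQ > 1), and `standard` is the usual Livak form (RQ < 1 for reduced
expression). The printed equations appear sign-inverted relative to the
standard convention, and published knockdown figures show RQ < 1; both forms
are therefore exposed and neither is silently corrected. RQ is invariant to
adding a constant to every Ct on the plate.

**Behaviour.** Analysis starts at the first light transition and covers up to
48 h. Per tube and hour, beam-break counts are summed over the stimulus
window (minutes 0-14, when courtship song plays) and the baseline window
(minutes 45-59, the silence directly preceding the next stimulus); hourly
values are collapsed to a per-tube median to cancel circadian variation.
Across tubes, paired stimulus-baseline differences are tested with a paired
t-test when they pass Shapiro normality at α = 0.05 and with the Wilcoxon
signed-rank test otherwise — a fixed decision rule standing in for the mixed
use of both tests in this assay's literature. The calibration was verified by
simulation: null rejection ≈ 5 % at α = 0.05, and a 2× stimulus-rate effect
at 12 tubes over one day is detected essentially always.

**Survival.** Plain cohort arithmetic: fraction alive per day from pooled
per-day death counts, median lifespan = first day below 50 %. No censoring
occurs in this design, so no Kaplan-Meier machinery is needed; the curve is
invariant to splitting or pooling cohorts. `align_healthspan` joins the curve
with the normalized gain trajectory for the lifespan/healthspan comparison.

## Synthetic data: what it does and does not emulate

The generators reproduce the statistical structure the analyses consume:
stationary Gaussian oscillator fluctuations with an active variance excess;
stiffness curves that follow the gating-spring closed form exactly plus
additive Gaussian noise (the additive error model is a package choice — no
error model for slope-stiffness estimates is prescribed by the assay);
monotone double-sigmoid CAP curves; negative-binomial count matrices across
ages 1/5/10/25/50 with 3 replicates each and step-change spiked genes;
homogeneous Poisson beam breaks with a rate multiplier during stimulus
minutes; geometric-hazard death times (2 %/day default, median ≈ 35 days).

They deliberately do not emulate: motor-feedback nonlinearities, spike
trains of individual JO neurons, read-level sequencing artefacts (mapping
bias, GC effects, library composition), circadian activity rhythms, or
age-dependent hazard shapes. Passing recovery tests therefore demonstrates
estimator correctness and calibration under the stated noise models, not
robustness to every artefact of real recordings.

## Problem sizes and determinism

Monte-Carlo checks use 50 seeds (gating recovery, passive-null gain,
homeostasis null), 500 simulated days for the behaviour null rate, 9
oscillator conditions at 60 s each, and 2,000-gene count matrices — sizes at
which every reported rate is stable to a few percent while the whole
validation runs in about a minute. All randomness flows from explicit seeds;
identical seed and spec produce bit-identical outputs.

## Known limitations

* The NB Wald test is a calibrated stand-in, not a DESeq2 replacement; shrinkage
  of fold changes and dispersion trends are out of scope.
* K_steady and K_GS are only reported separately when an external
  series-compliance ratio is provided.
* Gating-spring uncertainties are Gauss-Newton approximations and degrade
  near unidentifiable configurations (flagged, with infinite variances).
* The effective-temperature model cannot distinguish different active-process
  mechanisms that produce the same energy gain.
* The qPCR module omits amplification-efficiency correction (Pfaffl method).
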