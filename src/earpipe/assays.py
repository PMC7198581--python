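"""qPCR relative quantification, sound-evoked behaviour, and lifespan curves.

Three small assay analyses accompany the biophysics and transcriptomics:

* **qPCR** — comparative-Ct relative quantification of knockdown vs control,
  with SdhA as the default endogenous control. Two sign conventions are
  provided: ``"printed"`` follows the equations exactly as the source protocol
  prints them (which yields RQ > 1 for a knockdown whose target Ct rises), and
  ``"standard"`` is the usual Livak 2^-(dCt_KD - dCt_ctrl). Neither is silently
  corrected into the other.

* **Behaviour** — males increase locomotion during courtship-song playback.
  Sound plays in the first 15 min of every hour; the last 15 min are the
  silent baseline. Hourly window sums per tube are collapsed to a median
  (cancelling circadian variation), and stimulus vs baseline is compared with
  a paired t-test when the paired differences pass Shapiro normality, a
  Wilcoxon signed-rank test otherwise.

* **Survival** — cohort death counts per day to fraction-alive curves and
  median lifespan, plus alignment with the normalized auditory-gain
  trajectory for healthspan/lifespan comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthdata import ActivityTrace

__all__ = [
    "QPCRResult",
    "SoundResponse",
    "SurvivalCurve",
    "ddct_rq",
    "relative_quantification",
    "sound_response",
    "survival_analysis",
    "align_healthspan",
]

ENDOGENOUS_CONTROL_DEFAULT = "SdhA"


@dataclass
class QPCRResult:
    """Per-target relative quantification across biological replicates."""

    target: str
    rq_mean: float
    rq_sd: float
    rq_per_biorep: pd.Series
    ddct_per_biorep: pd.Series
    convention: str


@dataclass
class SoundResponse:
    """Stimulus/baseline activity summary and the paired test across tubes."""

    per_tube: pd.DataFrame  # index tube_id; columns stimulus_median, baseline_median
    effect: float  # median stimulus - median baseline across tubes
    p_value: float
    test_used: str  # "paired t-test" or "wilcoxon"
    shapiro_p: float
    n_hours: int
    flagged_tubes: list


@dataclass
class SurvivalCurve:
    """Pooled fraction-alive-per-day curve with median lifespan."""

    days: np.ndarray
    fraction_alive: np.ndarray
    cohort_size: int
    median_lifespan: float | None  # None when survival never drops below 0.5

    def __post_init__(self):
        assert np.all(np.diff(self.fraction_alive) <= 1e-12), "survival must be non-increasing"


# ---------------------------------------------------------------------------
# qPCR


def ddct_rq(
    ct_gene_control: float,
    ct_endo_control: float,
    ct_gene_kd: float,
    ct_endo_kd: float,
    convention: str = "printed",
) -> tuple[float, float]:
    """Compute (ddCt, RQ) for one target under either sign convention.

    ``printed``: dCt = Ct_gene,ctrl - Ct_endo,ctrl; ddCt = dCt - (Ct_gene,KD -
    Ct_endo,KD); RQ = 2^-ddCt — exactly as the source protocol writes it, so a
    knockdown with a *raised* target Ct gets RQ > 1.

    ``standard``: the Livak form ddCt = (Ct_gene,KD - Ct_endo,KD) -
    (Ct_gene,ctrl - Ct_endo,ctrl); RQ = 2^-ddCt, giving RQ < 1 for reduced
    expression.
    """
    dct_ctrl = ct_gene_control - ct_endo_control
    dct_kd = ct_gene_kd - ct_endo_kd
    if convention == "printed":
        ddct = dct_ctrl - dct_kd
    elif convention == "standard":
        ddct = dct_kd - dct_ctrl
    else:
        raise ValueError("convention must be 'printed' or 'standard'")
    return ddct, 2.0**-ddct


def relative_quantification(
    plate: pd.DataFrame,
    endogenous_control: str = ENDOGENOUS_CONTROL_DEFAULT,
    convention: str = "printed",
) -> dict[str, QPCRResult]:
    """Comparative-Ct quantification of every target gene on a plate.

    ``plate`` columns: target, condition ('control'/'knockdown'), bio_rep,
    tech_rep, Ct. Technical replicates are averaged to one Ct per (target,
    condition, biological replicate); dCt subtracts the endogenous control of
    the same condition and bio-rep; RQ = 2^-ddCt is computed per bio-rep and
    then averaged, with the standard deviation across bio-reps reported.
    """
    required = {"target", "condition", "bio_rep", "Ct"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate lacks columns {sorted(missing)}")
    if not np.isfinite(plate["Ct"]).all() or (plate["Ct"] <= 0).any():
        raise ValueError("Ct values must be finite and positive")
    conditions = set(plate["condition"])
    if not {"control", "knockdown"} <= conditions:
        raise ValueError("plate must contain both 'control' and 'knockdown' conditions")
    # mean over technical replicates
    ct = plate.groupby(["target", "condition", "bio_rep"])["Ct"].mean()
    if endogenous_control not in plate["target"].values:
        raise ValueError(f"endogenous control {endogenous_control!r} absent from plate")

    results: dict[str, QPCRResult] = {}
    targets = sorted(set(plate["target"]) - {endogenous_control})
    for gene in targets:
        ddcts = {}
        for rep in sorted(set(plate.loc[plate["target"] == gene, "bio_rep"])):
            try:
                vals = (
                    ct[(gene, "control", rep)],
                    ct[(endogenous_control, "control", rep)],
                    ct[(gene, "knockdown", rep)],
                    ct[(endogenous_control, "knockdown", rep)],
                )
            except KeyError as err:
                raise ValueError(
                    f"missing endogenous-control or condition measurement for "
                    f"target {gene!r}, bio_rep {rep!r}"
                ) from err
            ddcts[rep] = ddct_rq(*vals, convention=convention)[0]
        ddct_s = pd.Series(ddcts, name="ddct")
        rq_s = 2.0**-ddct_s
        results[gene] = QPCRResult(
            target=gene,
            rq_mean=float(rq_s.mean()),
            rq_sd=float(rq_s.std(ddof=1)) if len(rq_s) > 1 else 0.0,
            rq_per_biorep=rq_s,
            ddct_per_biorep=ddct_s,
            convention=convention,
        )
    return results


# ---------------------------------------------------------------------------
# sound-evoked behaviour


def sound_response(
    trace: ActivityTrace,
    min_hours: int = 12,
    analysis_hours: int = 48,
    shapiro_alpha: float = 0.05,
) -> SoundResponse:
    """Stimulus vs baseline activity with a normality-gated paired test.

    Starting at the first light transition, each complete hour contributes a
    stimulus-window sum (minutes 0-14 by default) and a baseline-window sum
    (minutes 45-59) per tube; the hourly values are collapsed to a per-tube
    median. Across tubes, paired differences are tested with a paired t-test
    if they pass Shapiro normality at ``shapiro_alpha``, otherwise with the
    Wilcoxon signed-rank test. Tubes with zero total counts are flagged but
    kept.
    """
    df = trace.counts
    start = trace.first_light_minute
    avail_min = int(df["minute_index"].max()) + 1 - start
    n_hours = min(avail_min // 60, analysis_hours)
    if n_hours < min_hours:
        raise ValueError(f"only {n_hours} complete hours after light transition; need >= {min_hours}")

    d = df[(df["minute_index"] >= start) & (df["minute_index"] < start + n_hours * 60)].copy()
    rel = d["minute_index"] - start
    d["hour"] = rel // 60
    d["in_hour"] = rel % 60
    s0, s1 = trace.stimulus_minutes
    b0, b1 = trace.baseline_minutes
    d["window"] = np.select(
        [(d["in_hour"] >= s0) & (d["in_hour"] < s1), (d["in_hour"] >= b0) & (d["in_hour"] < b1)],
        ["stimulus", "baseline"],
        default="other",
    )
    sums = (
        d[d["window"] != "other"]
        .groupby(["tube_id", "hour", "window"], sort=True)["count"]
        .sum()
        .unstack("window")
    )
    per_tube = sums.groupby("tube_id").median()
    per_tube = per_tube.rename(columns={"stimulus": "stimulus_median", "baseline": "baseline_median"})

    flagged = (
        df.groupby("tube_id")["count"].sum().pipe(lambda s: s.index[s == 0].tolist())
    )

    diff = (per_tube["stimulus_median"] - per_tube["baseline_median"]).to_numpy(dtype=float)
    if np.allclose(diff, diff[0]):
        # degenerate: identical differences in every tube
        shapiro_p = 1.0
        p = 1.0 if np.allclose(diff, 0) else 0.0
        test_used = "degenerate"
    else:
        shapiro_p = float(stats.shapiro(diff).pvalue)
        if shapiro_p >= shapiro_alpha:
            p = float(stats.ttest_rel(per_tube["stimulus_median"], per_tube["baseline_median"]).pvalue)
            test_used = "paired t-test"
        else:
            p = float(stats.wilcoxon(diff).pvalue)
            test_used = "wilcoxon"
    return SoundResponse(
        per_tube=per_tube,
        effect=float(np.median(per_tube["stimulus_median"]) - np.median(per_tube["baseline_median"])),
        p_value=p,
        test_used=test_used,
        shapiro_p=shapiro_p,
        n_hours=n_hours,
        flagged_tubes=list(flagged),
    )


# ---------------------------------------------------------------------------
# survival


def survival_analysis(deaths: pd.DataFrame, cohort_size: int | None = None) -> SurvivalCurve:
    """Fraction-alive-per-day curve and median lifespan from death counts.

    ``deaths`` is a tidy frame with columns day, deaths (an optional cohort
    column is pooled — the curve is invariant to splitting/pooling cohorts).
    ``cohort_size`` defaults to the total number of deaths (everyone observed
    to die); median lifespan is the first day on which the fraction alive
    drops below 0.5, or None if it never does.
    """
    if (deaths["deaths"] < 0).any():
        raise ValueError("negative death counts")
    per_day = deaths.groupby("day")["deaths"].sum().sort_index()
    total = int(per_day.sum())
    if cohort_size is None:
        cohort_size = total
    if total > cohort_size:
        raise ValueError("more deaths than flies in the cohort")
    last = int(per_day.index.max()) if len(per_day) else 0
    days = np.arange(0, last + 1)
    dead = np.zeros_like(days, dtype=float)
    for day, n in per_day.items():
        dead[days >= day] += n
    frac = 1.0 - dead / cohort_size
    below = np.nonzero(frac < 0.5)[0]
    median = float(days[below[0]]) if below.size else None
    return SurvivalCurve(
        days=days, fraction_alive=frac, cohort_size=cohort_size, median_lifespan=median
    )


def align_healthspan(curve: SurvivalCurve, gain_ages: list, gain_pct: np.ndarray) -> pd.DataFrame:
    """Join the survival curve with the normalized auditory-gain trajectory.

    Returns one row per profiled age with the fraction alive on that day and
    the median gain in % of maximum — the healthspan/lifespan alignment view.
    """
    rows = []
    for age, g in zip(gain_ages, gain_pct):
        day = int(age)
        alive = float(curve.fraction_alive[day]) if day < len(curve.days) else 0.0
        rows.append({"age_day": day, "fraction_alive": alive, "gain_pct_of_max": float(g)})
    return pd.DataFrame(rows)
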