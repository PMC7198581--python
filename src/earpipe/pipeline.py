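"""Top-level pipeline: run every applicable stage over a manifest of records.

Stages are independent; a failure in one is recorded in the report and the
remaining stages still run. The report is a plain JSON-serializable dict,
reproducible bit-for-bit (apart from its timestamp) for identical inputs and
seeds.
"""

from __future__ import annotations

import json
import time
import traceback
from pathlib import Path

import numpy as np

from . import __version__
from .ageomics import classify_age_variable, go_enrichment, pairwise_de
from .assays import relative_quantification, sound_response, survival_analysis
from .fluctuation import estimate_psd, fit_sho, summarize_lifecourse
from .gating import fit_cap, fit_gating_spring, nz_homeostasis
from .io import (
    Manifest,
    RunConfig,
    read_activity,
    read_cap,
    read_counts,
    read_fluctuation,
    read_stiffness,
    read_table,
)

__all__ = ["run_pipeline", "write_report"]


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return [_jsonable(v) for v in x]
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def run_pipeline(manifest: Manifest, config: RunConfig, base_dir=None) -> dict:
    """Execute all stages for which the manifest has records; return the report."""
    manifest.resolve_paths(base_dir)
    base = Path(base_dir) if base_dir else Path(".")

    def path_of(row):
        p = Path(row["path"])
        return p if p.is_absolute() else base / p

    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def stage(name, fn):
        try:
            result = fn()
            if result is not None:
                report["stages"][name] = {"status": "ok", **_jsonable(result)}
        except Exception as err:  # stage isolation: record and continue
            report["stages"][name] = {
                "status": "error",
                "error": f"{type(err).__name__}: {err}",
                "trace": traceback.format_exc(limit=3),
            }

    # --- fluctuation fits ---------------------------------------------------
    def fluctuation_stage():
        rows = manifest.records("fluctuation")
        if not len(rows):
            return None
        fits, by_age = {}, {}
        for _, row in rows.iterrows():
            rec = read_fluctuation(path_of(row))
            fit = fit_sho(
                estimate_psd(rec, config.segment_length_s),
                config.fit_band,
                T=config.temperature,
                stiffness=config.stiffness,
            )
            fits[row["record_id"]] = {
                "f0_hz": fit.f0, "Q": fit.Q, "energy_kbt": fit.energy,
                "gain_kbt": fit.gain, "converged": fit.converged,
            }
            by_age.setdefault(int(float(row["age_day"])), []).append(fit)
        out = {"fits": fits}
        if len(by_age) >= 2 and all(len(v) >= 3 for v in by_age.values()):
            s = summarize_lifecourse(by_age)
            out["lifecourse"] = {
                "ages": s.ages,
                "median_f0": s.median_f0,
                "median_Q": s.median_Q,
                "median_gain": s.median_gain,
                "normalized_gain_pct": s.normalized_gain_pct,
                "pairwise_gain_p": {f"{a}_vs_{b}": p for (a, b), p in s.pairwise_gain_p.items()},
            }
        return out

    # --- gating-spring fits --------------------------------------------------
    def gating_stage():
        rows = manifest.records("stiffness")
        if not len(rows):
            return None
        fits, objs = {}, []
        for _, row in rows.iterrows():
            fit = fit_gating_spring(read_stiffness(path_of(row)), T=config.temperature)
            objs.append(fit)
            fits[row["record_id"]] = {
                "k_total_N_per_m": fit.k_total,
                "N_s": fit.sensitive.N if fit.sensitive else 0.0,
                "z_s_N": fit.sensitive.z if fit.sensitive else 0.0,
                "N_i": fit.insensitive.N if fit.insensitive else 0.0,
                "z_i_N": fit.insensitive.z if fit.insensitive else 0.0,
                "converged": fit.converged,
                "identifiable": fit.identifiable,
            }
        out = {"fits": fits}
        usable = [f for f in objs if f.converged and f.sensitive is not None]
        if len(usable) >= 5:
            h = nz_homeostasis(usable)
            out["nz_homeostasis"] = {
                "n_pairs": h.n_pairs, "r_log": h.r_log, "p_value": h.p_value,
                "nz2_cv": h.nz2_cv,
            }
        return out

    # --- CAP curves ----------------------------------------------------------
    def cap_stage():
        rows = manifest.records("cap")
        if not len(rows):
            return None
        fits = {}
        for _, row in rows.iterrows():
            f = fit_cap(read_cap(path_of(row)))
            fits[row["record_id"]] = {
                "A_s": f.A_s, "A_i": f.A_i, "X50_s_m": f.X50_s, "X50_i_m": f.X50_i,
                "converged": f.converged, "monotone_warning": f.monotone_warning,
            }
        return {"fits": fits}

    # --- transcriptome ageing ------------------------------------------------
    def counts_stage():
        rows = manifest.records("counts")
        if not len(rows):
            return None
        out = {}
        for _, row in rows.iterrows():
            p = path_of(row)
            samples_path = Path(str(p).replace(".tsv", "") + ".samples.tsv")
            ac = read_counts(p, samples_path)
            ages = ac.ages()
            comparisons = [pairwise_de(ac, (a, b)) for a, b in zip(ages[:-1], ages[1:])]
            av = classify_age_variable(
                comparisons,
                fc_threshold=config.fc_threshold,
                fdr_threshold=config.fdr_threshold,
                p_threshold=config.p_threshold,
            )
            entry = {
                "n_expressed": len(av.expressed),
                "n_age_variable": len(av.variable),
                "n_constant": len(av.constant),
                "constant_fraction_pct": av.constant_fraction_pct,
                "comparisons": [c.pair for c in comparisons],
            }
            if config.go_annotation and av.variable:
                ann_path = Path(config.go_annotation)
                if not ann_path.is_absolute():
                    ann_path = base / ann_path
                ann = read_table(ann_path, {"gene": str, "term": str})
                term_sets = {t: set(g["gene"]) for t, g in ann.groupby("term")}
                enr = go_enrichment(av.variable & av.expressed, term_sets, av.expressed)
                entry["enrichment_top"] = [
                    {"term": r.term, "b": r.b, "n": r.n, "B": r.B, "N": r.N,
                     "enrichment": r.enrichment, "p": r.p_value}
                    for r in enr[:10]
                ]
            out[row["record_id"]] = entry
        return {"datasets": out}

    # --- qPCR ----------------------------------------------------------------
    def qpcr_stage():
        rows = manifest.records("qpcr")
        if not len(rows):
            return None
        out = {}
        for _, row in rows.iterrows():
            plate = read_table(
                path_of(row),
                {"target": str, "condition": str, "bio_rep": int, "tech_rep": int, "Ct": float},
            )
            res = relative_quantification(plate, convention=config.qpcr_convention)
            out[row["record_id"]] = {
                gene: {"rq_mean": r.rq_mean, "rq_sd": r.rq_sd} for gene, r in res.items()
            }
        return {"plates": out}

    # --- behaviour -----------------------------------------------------------
    def behavior_stage():
        rows = manifest.records("activity")
        if not len(rows):
            return None
        out = {}
        for _, row in rows.iterrows():
            p = path_of(row)
            schedule = Path(str(p).replace(".tsv", "") + ".schedule.json")
            r = sound_response(read_activity(p, schedule))
            out[row["record_id"]] = {
                "effect": r.effect, "p_value": r.p_value, "test_used": r.test_used,
                "n_hours": r.n_hours,
            }
        return {"traces": out}

    # --- survival ------------------------------------------------------------
    def survival_stage():
        rows = manifest.records("deaths")
        if not len(rows):
            return None
        out = {}
        for _, row in rows.iterrows():
            deaths = read_table(path_of(row), {"day": int, "deaths": int})
            curve = survival_analysis(deaths)
            out[row["record_id"]] = {
                "cohort_size": curve.cohort_size,
                "median_lifespan_day": curve.median_lifespan,
            }
        return {"cohorts": out}

    stage("fluctuation", fluctuation_stage)
    stage("gating", gating_stage)
    stage("cap", cap_stage)
    stage("transcriptome", counts_stage)
    stage("qpcr", qpcr_stage)
    stage("behavior", behavior_stage)
    stage("survival", survival_stage)
    return report


def write_report(report: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True))
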