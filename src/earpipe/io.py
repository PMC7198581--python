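"""Shared table I/O, manifest handling and run configuration.

Everything on disk is plain tab-delimited text (gzip accepted transparently);
domain objects carry their metadata in ``#``-prefixed header lines. Schemas
are small column->dtype mappings validated on read, with errors that name the
offending row and column.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import ROOM_TEMPERATURE
from .synthdata import ActivityTrace, AgeSeriesCounts, FluctuationRecording, StiffnessCurve

__all__ = [
    "RunConfig",
    "Manifest",
    "RECORD_KINDS",
    "read_table",
    "write_table",
    "write_fluctuation",
    "read_fluctuation",
    "write_stiffness",
    "read_stiffness",
    "write_counts",
    "read_counts",
    "write_activity",
    "read_activity",
]

RECORD_KINDS = ("fluctuation", "stiffness", "cap", "counts", "qpcr", "activity", "deaths")


@dataclass
class RunConfig:
    """Thresholds, physical constants and windows for a pipeline run.

    Defaults are the study's printed values: fold change 1.5, FDR 10 %,
    p 0.05, 10,000 reads for the high-expression list, 4-fold for the
    most-variable list, NES 2.5, and room temperature 294.15 K.
    """

    seed: int = 0
    fc_threshold: float = 1.5
    fdr_threshold: float = 0.10
    p_threshold: float = 0.05
    reads_threshold: float = 10_000.0
    fc_round3: float = 4.0
    nes_threshold: float = 2.5
    temperature: float = ROOM_TEMPERATURE
    stiffness: float = 50e-6
    fit_band: tuple = (50.0, 1200.0)
    segment_length_s: float = 1.0
    stimulus_minutes: tuple = (0, 15)
    baseline_minutes: tuple = (45, 60)
    qpcr_convention: str = "printed"
    go_annotation: str | None = None  # optional gene<TAB>term table for enrichment
    out_dir: str = "earpipe_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("fit_band", "stimulus_minutes", "baseline_minutes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("fit_band", "stimulus_minutes", "baseline_minutes"):
            d[key] = list(d[key])
        return d


@dataclass
class Manifest:
    """Record index for a pipeline run: one row per input file."""

    table: pd.DataFrame  # record_id, age_day, sex, genotype, path, kind

    REQUIRED = ("record_id", "age_day", "sex", "genotype", "path", "kind")

    def __post_init__(self):
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise ValueError(f"manifest lacks columns {sorted(missing)}")
        if len(self.table) == 0:
            raise ValueError(
                "empty manifest: need at least one record of kind "
                + "|".join(RECORD_KINDS)
            )
        dup = self.table["record_id"][self.table["record_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate record ids: {sorted(set(dup))}")
        bad = set(self.table["kind"]) - set(RECORD_KINDS)
        if bad:
            raise ValueError(f"unknown record kinds {sorted(bad)}; expected {RECORD_KINDS}")

    @classmethod
    def read(cls, path) -> "Manifest":
        return cls(read_table(path, {c: str for c in cls.REQUIRED}))

    def records(self, kind: str) -> pd.DataFrame:
        return self.table[self.table["kind"] == kind]

    def resolve_paths(self, base=None) -> None:
        base = Path(base) if base else Path(".")
        for _, row in self.table.iterrows():
            p = Path(row["path"])
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise FileNotFoundError(f"manifest record {row['record_id']}: {p} not found")


# ---------------------------------------------------------------------------
# generic tables


def read_table(path, schema: dict | None = None) -> pd.DataFrame:
    """Read a tab-delimited table, validating and typing columns by schema.

    ``schema`` maps column name -> dtype. Missing columns raise; a cell that
    cannot be coerced raises an error naming its row number and column.
    Gzip-compressed files are accepted transparently.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    if schema:
        missing = set(schema) - set(df.columns)
        if missing:
            raise ValueError(f"{path.name}: header lacks column(s) {sorted(missing)}")
        for col, dtype in schema.items():
            try:
                df[col] = df[col].astype(dtype)
            except (ValueError, TypeError):
                coerced = pd.to_numeric(df[col], errors="coerce")
                bad = df.index[coerced.isna() & df[col].notna()]
                row = int(bad[0]) if len(bad) else -1
                raise ValueError(
                    f"{path.name}: malformed value in column '{col}', row {row}"
                ) from None
    return df


def write_table(df: pd.DataFrame, path, metadata: dict | None = None) -> str:
    """Write a tab-delimited table with optional ``#`` metadata header.

    Returns the sha256 checksum of the written bytes (logged by the pipeline).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    if metadata:
        for k, v in metadata.items():
            lines.append(f"# {k}: {v}")
    body = df.to_csv(sep="\t", index=bool(df.index.name))
    text = "\n".join(lines) + ("\n" if lines else "") + body
    path.write_text(text)
    return hashlib.sha256(text.encode()).hexdigest()


# ---------------------------------------------------------------------------
# domain-specific round trips


def write_fluctuation(rec: FluctuationRecording, path) -> str:
    meta = {"sample_rate_hz": rec.sample_rate}
    if rec.params is not None:
        meta.update(
            f0=rec.params.f0, Q=rec.params.Q, K=rec.params.K, T=rec.params.T,
            T_eff=rec.params.T_eff, seed=rec.params.seed,
        )
    df = pd.DataFrame(
        {"time_s": rec.time, "displacement_m": rec.displacement, "velocity_m_per_s": rec.velocity}
    )
    return write_table(df, path, metadata=meta)


def read_fluctuation(path) -> FluctuationRecording:
    sample_rate = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "sample_rate_hz" in line:
                sample_rate = float(line.split(":", 1)[1])
    df = read_table(path, {"time_s": float, "displacement_m": float})
    if sample_rate is None:
        sample_rate = 1.0 / np.median(np.diff(df["time_s"]))
    velocity = (
        df["velocity_m_per_s"].to_numpy()
        if "velocity_m_per_s" in df.columns
        else np.gradient(df["displacement_m"].to_numpy()) * sample_rate
    )
    return FluctuationRecording(
        time=df["time_s"].to_numpy(),
        displacement=df["displacement_m"].to_numpy(),
        velocity=velocity,
        sample_rate=sample_rate,
    )


def write_stiffness(curve: StiffnessCurve, path) -> str:
    df = pd.DataFrame({"X_m": curve.displacement, "K_N_per_m": curve.stiffness})
    meta = {}
    if curve.truth is not None:
        meta = {"noise_sd": curve.truth.noise_sd, "T": curve.truth.T, "seed": curve.truth.seed}
    return write_table(df, path, metadata=meta)


def read_stiffness(path) -> StiffnessCurve:
    df = read_table(path, {"X_m": float, "K_N_per_m": float})
    k = df["K_N_per_m"].to_numpy()
    return StiffnessCurve(displacement=df["X_m"].to_numpy(), stiffness=k, stiffness_true=k)


def write_cap(curve, path) -> str:
    from .synthdata import CAPCurve  # noqa: F401  (type only)

    amp = np.atleast_2d(curve.amplitude)
    df = pd.DataFrame(amp, columns=[f"rep{i+1}" for i in range(amp.shape[1])])
    df.insert(0, "X_m", curve.displacement)
    return write_table(df, path)


def read_cap(path):
    from .synthdata import CAPCurve

    df = read_table(path, {"X_m": float})
    reps = [c for c in df.columns if c.startswith("rep")]
    return CAPCurve(displacement=df["X_m"].to_numpy(), amplitude=df[reps].to_numpy())


def write_counts(ac: AgeSeriesCounts, counts_path, samples_path) -> tuple[str, str]:
    c1 = write_table(ac.counts, counts_path)
    c2 = write_table(ac.samples, samples_path)
    return c1, c2


def read_counts(counts_path, samples_path) -> AgeSeriesCounts:
    counts = pd.read_csv(counts_path, sep="\t", comment="#", index_col=0)
    samples = read_table(samples_path, {"sample_id": str, "age_day": int})
    missing = set(counts.columns) - set(samples["sample_id"])
    if missing:
        raise ValueError(f"samples sheet lacks labels for {sorted(missing)}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts")
    counts.index.name = "gene_id"
    return AgeSeriesCounts(counts=counts, samples=samples)


def write_activity(trace: ActivityTrace, counts_path, schedule_path) -> tuple[str, str]:
    c1 = write_table(trace.counts, counts_path)
    schedule = {
        "stimulus_minutes": list(trace.stimulus_minutes),
        "baseline_minutes": list(trace.baseline_minutes),
        "first_light_minute": trace.first_light_minute,
    }
    Path(schedule_path).write_text(json.dumps(schedule, indent=1))
    return c1, hashlib.sha256(json.dumps(schedule).encode()).hexdigest()


def read_activity(counts_path, schedule_path) -> ActivityTrace:
    df = read_table(counts_path, {"minute_index": int, "tube_id": str, "count": int})
    sched = json.loads(Path(schedule_path).read_text())
    return ActivityTrace(
        counts=df,
        stimulus_minutes=tuple(sched["stimulus_minutes"]),
        baseline_minutes=tuple(sched["baseline_minutes"]),
        first_light_minute=int(sched.get("first_light_minute", 0)),
    )
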