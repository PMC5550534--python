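"""CSV schemas, configuration, and the end-to-end pipeline.

All interchange files are comma-separated UTF-8 with a mandatory header
and ``.`` as decimal separator. Units are encoded in column names
(``_kg``, ``_mg_per_kg``, ``_ug_per_l`` ...) so files are self-describing;
readers reject files whose columns do not match the declared schema.
"""

from __future__ import annotations

import json
import logging
import math
import time
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import biomarker as bm
from . import exposure as ex
from . import fish
from .constants import FRIED, RAW, SPECIES_REFERENCE

logger = logging.getLogger("hgintake")


class SchemaError(ValueError):
    """A delimited file does not match its declared schema."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


# --- Schemas ---------------------------------------------------------------

#: schema_id -> {column: (dtype kind, non-negative?)}; order is canonical
SCHEMAS: dict[str, dict[str, tuple[str, bool]]] = {
    "fish_samples": {
        "species_id": ("str", False),
        "academic_name": ("str", False),
        "state": ("str", False),
        "sample_index": ("int", True),
        "conc_mg_per_kg": ("float", True),
        "portion_mass_kg": ("float", True),
    },
    "meals": {
        "day": ("int", True),
        "species_id": ("str", False),
        "state": ("str", False),
        "mass_kg": ("float", True),
    },
    "cohort": {
        "subject_id": ("str", False),
        "body_weight_kg": ("float", True),
        "bmi": ("float", True),
        "height_m": ("float", True),
        "smoker": ("bool", False),
        "amalgam_fillings": ("int", True),
    },
    "biomarkers": {
        "subject_id": ("str", False),
        "timepoint": ("str", False),
        "matrix": ("str", False),
        "value": ("float", True),
    },
    "species_summary": {
        "species_id": ("str", False),
        "state": ("str", False),
        "n": ("int", True),
        "mean": ("float", True),
        "sd": ("float", True),
        "median": ("float", True),
        "p95": ("float", True),
        "min": ("float", True),
        "max": ("float", True),
        "portion_mass_mean": ("float", True),
        "portion_mass_sd": ("float", True),
        "mpc_compliant": ("bool", False),
        "mpc_margin": ("float", False),
    },
    "exposure": {
        "subject_id": ("str", False),
        "total_intake_ug": ("float", True),
        "daily_intake_ug": ("float", True),
        "weekly_intake_ug": ("float", True),
        "edi_ug_per_kg_day": ("float", True),
        "ewi_ug_per_kg_week": ("float", True),
        "pct_ptwi": ("float", True),
        "hazard_index": ("float", True),
        "exceeds_ptwi": ("bool", False),
        "exceeds_nrc": ("bool", False),
    },
}

#: columns that may legitimately be empty (resolved or derived downstream)
_NULLABLE: dict[str, set[str]] = {
    "cohort": {"body_weight_kg", "bmi", "height_m"},
    "fish_samples": {"academic_name", "portion_mass_kg"},
    "species_summary": {"portion_mass_mean", "portion_mass_sd"},
}


def read_table(path: str | Path, schema_id: str) -> pd.DataFrame:
    """Read and validate a delimited file against a declared schema.

    Raises :class:`SchemaError` naming the first missing or unexpected
    column, or the 1-based data row holding a unit-impossible value.
    For the cohort schema, missing body weights are derived as
    BMI x height² where both are present.
    """
    if schema_id not in SCHEMAS:
        raise KeyError(f"unknown schema {schema_id!r}")
    schema = SCHEMAS[schema_id]
    df = pd.read_csv(path)
    for col in schema:
        if col not in df.columns:
            raise SchemaError(f"missing column {col}")
    unexpected = [c for c in df.columns if c not in schema]
    if unexpected:
        raise SchemaError(f"unexpected column(s) {unexpected} "
                          f"for schema {schema_id!r}")
    nullable = _NULLABLE.get(schema_id, set())
    for col, (kind, nonneg) in schema.items():
        series = df[col]
        if kind in ("float", "int"):
            series = pd.to_numeric(series, errors="coerce")
            bad_null = series.isna() & df[col].notna()
            if bad_null.any():
                row = int(bad_null.idxmax()) + 1
                raise SchemaError(f"non-numeric value in {col!r} at row {row}")
            if series.isna().any() and col not in nullable:
                row = int(series.isna().idxmax()) + 1
                raise SchemaError(f"missing value in {col!r} at row {row}")
            if nonneg and (series.dropna() < 0).any():
                row = int((series < 0).idxmax()) + 1
                raise SchemaError(f"negative value in {col!r} at row {row}")
            df[col] = series
        elif kind == "bool":
            df[col] = series.map(_parse_bool)
    if schema_id == "cohort":
        df = _resolve_body_weight(df)
    return df


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise SchemaError(f"cannot parse boolean value {value!r}")


def _resolve_body_weight(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    missing = df["body_weight_kg"].isna()
    derivable = missing & df["bmi"].notna() & df["height_m"].notna()
    df.loc[derivable, "body_weight_kg"] = (
        df.loc[derivable, "bmi"] * df.loc[derivable, "height_m"] ** 2)
    still = df["body_weight_kg"].isna()
    if still.any():
        row = int(still.idxmax()) + 1
        raise SchemaError(
            f"row {row}: body_weight_kg absent and not derivable from bmi+height_m")
    return df


def write_table(df: pd.DataFrame, path: str | Path, schema_id: str,
                rounding: Mapping[str, int] | None = None) -> None:
    """Write a schema-ordered CSV; ``rounding`` maps column -> decimals."""
    schema = SCHEMAS[schema_id]
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column {missing[0]}")
    out = df[list(schema)].copy()
    for col, decimals in (rounding or {}).items():
        if col in out.columns:
            out[col] = out[col].round(decimals)
    out.to_csv(path, index=False)


# --- Frame <-> domain object conversion ------------------------------------


def frame_to_samples(df: pd.DataFrame,
                     ) -> dict[tuple[str, str], tuple[list[fish.FishSample], list[float]]]:
    """Group a fish_samples frame into (samples, portion masses) per species/state."""
    out: dict[tuple[str, str], tuple[list[fish.FishSample], list[float]]] = {}
    for (sid, state), grp in df.groupby(["species_id", "state"], sort=True):
        samples = [fish.FishSample(species_id=str(sid), state=str(state),
                                   conc=float(r.conc_mg_per_kg),
                                   sample_index=int(r.sample_index))
                   for r in grp.itertuples()]
        masses = [float(m) for m in grp["portion_mass_kg"].dropna()]
        out[(str(sid), str(state))] = (samples, masses)
    return out


def samples_to_frame(groups: Mapping[tuple[str, str], Sequence[fish.FishSample]],
                     portion_masses: Mapping[tuple[str, str], float] | None = None,
                     academic_names: Mapping[str, str] | None = None,
                     ) -> pd.DataFrame:
    rows = []
    for (sid, state), samples in groups.items():
        for s in samples:
            rows.append({
                "species_id": sid,
                "academic_name": (academic_names or {}).get(sid, ""),
                "state": state,
                "sample_index": s.sample_index,
                "conc_mg_per_kg": s.conc,
                "portion_mass_kg": (portion_masses or {}).get((sid, state),
                                                              float("nan")),
            })
    return pd.DataFrame(rows, columns=list(SCHEMAS["fish_samples"]))


def frame_to_schedule(df: pd.DataFrame,
                      n_weeks: int | None = None) -> ex.MealSchedule:
    """Build a MealSchedule; weeks default to ceil(max day / 7)."""
    if df.empty:
        raise ValueError("meal table is empty")
    events = [ex.MealEvent(day=int(r.day), species_id=str(r.species_id),
                           state=str(r.state), mass=float(r.mass_kg))
              for r in df.itertuples()]
    if n_weeks is None:
        n_weeks = math.ceil(max(e.day for e in events) / 7)
    return ex.MealSchedule(events, n_weeks=n_weeks)


def schedule_to_frame(schedule: ex.MealSchedule) -> pd.DataFrame:
    return pd.DataFrame(
        [{"day": e.day, "species_id": e.species_id, "state": e.state,
          "mass_kg": e.mass} for e in schedule.events],
        columns=list(SCHEMAS["meals"]))


def frame_to_subjects(df: pd.DataFrame) -> list[ex.Subject]:
    return [ex.Subject(subject_id=str(r.subject_id),
                       body_weight=float(r.body_weight_kg),
                       bmi=None if pd.isna(r.bmi) else float(r.bmi),
                       height=None if pd.isna(r.height_m) else float(r.height_m),
                       smoker=bool(r.smoker),
                       amalgam_fillings=int(r.amalgam_fillings))
            for r in df.itertuples()]


def subjects_to_frame(cohort: Sequence[ex.Subject]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"subject_id": s.subject_id, "body_weight_kg": s.body_weight,
          "bmi": s.bmi, "height_m": s.height, "smoker": s.smoker,
          "amalgam_fillings": s.amalgam_fillings} for s in cohort],
        columns=list(SCHEMAS["cohort"]))


def frame_to_biomarkers(df: pd.DataFrame) -> list[bm.BiomarkerRecord]:
    return [bm.BiomarkerRecord(subject_id=str(r.subject_id),
                               timepoint=str(r.timepoint),
                               matrix=str(r.matrix), value=float(r.value))
            for r in df.itertuples()]


def biomarkers_to_frame(records: Sequence[bm.BiomarkerRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"subject_id": r.subject_id, "timepoint": r.timepoint,
          "matrix": r.matrix, "value": r.value} for r in records],
        columns=list(SCHEMAS["biomarkers"]))


def summaries_to_frame(summaries: Sequence[fish.SpeciesSummary],
                       mpc: float) -> pd.DataFrame:
    rows = []
    for s in summaries:
        check = fish.mpc_check(s, mpc)
        rows.append({
            "species_id": s.species_id, "state": s.state, "n": s.n,
            "mean": s.mean, "sd": s.sd, "median": s.median, "p95": s.p95,
            "min": s.min, "max": s.max,
            "portion_mass_mean": s.portion_mass_mean,
            "portion_mass_sd": s.portion_mass_sd,
            "mpc_compliant": check["compliant"], "mpc_margin": check["margin"],
        })
    return pd.DataFrame(rows, columns=list(SCHEMAS["species_summary"]))


def results_to_frame(results: Sequence[ex.ExposureResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"subject_id": r.subject_id, "total_intake_ug": r.total_intake,
          "daily_intake_ug": r.daily_intake, "weekly_intake_ug": r.weekly_intake,
          "edi_ug_per_kg_day": r.edi, "ewi_ug_per_kg_week": r.ewi,
          "pct_ptwi": r.pct_ptwi, "hazard_index": r.hazard_index,
          "exceeds_ptwi": r.exceeds_ptwi, "exceeds_nrc": r.exceeds_nrc}
         for r in results],
        columns=list(SCHEMAS["exposure"]))


# --- Configuration ---------------------------------------------------------


def load_thresholds(path: str | Path) -> ex.ThresholdSet:
    """Read a thresholds YAML (keys as in :class:`ThresholdSet`)."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    known = {"ptwi_mehg", "ptwi_thg", "nrc_limit", "mpc", "ptwi_japan",
             "mehg_fraction"}
    unknown = set(data) - known
    if unknown:
        raise SchemaError(f"unknown threshold key(s): {sorted(unknown)}")
    return ex.ThresholdSet(**data)


#: report precision per quantity, applied only when rendering tables
DEFAULT_ROUNDING: dict[str, int] = {
    "mean": 3, "sd": 3, "median": 3, "p95": 3, "min": 3, "max": 3,
    "portion_mass_mean": 3, "portion_mass_sd": 3, "mpc_margin": 3,
}


@dataclass
class PipelineConfig:
    """Inputs, limits and report conventions for one pipeline run.

    Any missing input path falls back to the shipped reference data: the
    published species statistics, the intervention meal template, and a
    single 70 kg reference subject.
    """

    fish_samples: str | Path | None = None
    meals: str | Path | None = None
    cohort: str | Path | None = None
    biomarkers: str | Path | None = None
    thresholds: ex.ThresholdSet = field(default_factory=ex.ThresholdSet)
    out_dir: str | Path | None = None
    percentile_method: str = "linear"
    rounding: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_ROUNDING))


def reference_summaries() -> list[fish.SpeciesSummary]:
    """The shipped per-species statistics as SpeciesSummary objects."""
    return [fish.SpeciesSummary(
        species_id=r.species_id, state=r.state, n=r.n, mean=r.mean, sd=r.sd,
        median=r.median, p95=r.p95, min=r.conc_min, max=r.conc_max,
        portion_mass_mean=r.portion_mean, portion_mass_sd=r.portion_sd)
        for r in SPECIES_REFERENCE]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute summarize -> exposure -> risk -> biomarker and assemble a report.

    Each stage logs its timing and row counts to the ``hgintake`` logger;
    a failure raises :class:`PipelineError` naming the stage.
    """
    report: dict = {}

    # -- fish summary stage
    t0 = time.perf_counter()
    try:
        if config.fish_samples is not None:
            groups = frame_to_samples(read_table(config.fish_samples,
                                                 "fish_samples"))
            summaries = [fish.summarize_samples(samples, masses)
                         for samples, masses in groups.values()]
        else:
            summaries = reference_summaries()
        by_key = {(s.species_id, s.state): s for s in summaries}
        raw_fried = []
        for sid in sorted({s.species_id for s in summaries}):
            if (sid, RAW) in by_key and (sid, FRIED) in by_key:
                diff = fish.raw_fried_difference(by_key[(sid, RAW)],
                                                 by_key[(sid, FRIED)])
                raw_fried.append(vars(diff).copy())
        report["fish"] = {
            "species_summaries": summaries_to_frame(
                summaries, config.thresholds.mpc).to_dict(orient="records"),
            "raw_fried_differences": raw_fried,
        }
    except Exception as err:
        raise PipelineError(f"fish summary stage failed: {err}") from err
    logger.info("fish summary: %d species/state groups in %.3f s",
                len(summaries), time.perf_counter() - t0)

    # -- exposure stage
    t0 = time.perf_counter()
    try:
        if config.meals is not None:
            meals_df = read_table(config.meals, "meals")
            if meals_df.empty:
                raise ValueError("meal table is empty")
            schedule = frame_to_schedule(meals_df)
        else:
            from .simulate import generate_meal_schedule
            schedule = generate_meal_schedule()
        if config.cohort is not None:
            cohort = frame_to_subjects(read_table(config.cohort, "cohort"))
        else:
            cohort = [ex.Subject(subject_id="reference_70kg", body_weight=70.0)]
        conc_lookup = {key: s.mean for key, s in by_key.items()}
        results, summary = ex.cohort_exposure(cohort, schedule, conc_lookup,
                                              config.thresholds)
        report["exposure"] = {
            "total_intake_ug": results[0].total_intake,
            "daily_intake_ug": results[0].daily_intake,
            "weekly_intake_ug": results[0].weekly_intake,
            "consumption_days": schedule.consumption_days,
            "n_weeks": schedule.n_weeks,
            "per_subject": results_to_frame(results).to_dict(orient="records"),
            "summary": summary,
            "exceedance": {
                "ptwi_mehg": ex.exceedance_fraction(
                    results, config.thresholds.ptwi_mehg),
                "nrc": ex.exceedance_fraction(
                    results, config.thresholds.nrc_limit),
            },
        }
    except Exception as err:
        raise PipelineError(f"exposure stage failed: {err}") from err
    logger.info("exposure: %d subjects, %d meals in %.3f s",
                len(cohort), len(schedule.events), time.perf_counter() - t0)

    # -- biomarker stage (optional)
    if config.biomarkers is not None:
        t0 = time.perf_counter()
        try:
            records = frame_to_biomarkers(read_table(config.biomarkers,
                                                     "biomarkers"))
            tables = {}
            for matrix, timepoints in (("blood", bm.TIMEPOINTS),
                                       ("hair", bm.HAIR_TIMEPOINTS)):
                for tp in timepoints:
                    try:
                        tables[f"{matrix}_{tp}"] = bm.timepoint_summary(
                            records, matrix, tp)
                    except ValueError:
                        continue
            ids, x, y = bm.paired_hair_blood(records)
            fit = vars(bm.linear_fit(x, y)).copy() if len(ids) >= 2 else None
            report["biomarker"] = {
                "timepoint_summaries": tables,
                "ratio": bm.ratio_summary(records),
                "fit": fit,
            }
        except Exception as err:
            raise PipelineError(f"biomarker stage failed: {err}") from err
        logger.info("biomarker: %d records in %.3f s",
                    len(records), time.perf_counter() - t0)

    if config.out_dir is not None:
        _write_outputs(report, config)
    return report


def _write_outputs(report: dict, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(pd.DataFrame(report["fish"]["species_summaries"]),
                out / "species_summary.csv", "species_summary",
                rounding=config.rounding)
    write_table(pd.DataFrame(report["exposure"]["per_subject"]),
                out / "exposure.csv", "exposure")
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    logger.info("outputs written to %s", out)


def _jsonable(obj: object) -> object:
    if isinstance(obj, fish.SpeciesSummary):
        return vars(obj).copy()
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
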