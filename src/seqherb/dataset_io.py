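"""Reading, validating and subsetting effect-size tables.

The canonical record model mirrors one extracted comparison from a sequential
herbivory experiment: a treatment arm (plant previously attacked by an
inducing herbivore) versus a control arm (previously undamaged plant), both
receiving the same subsequent herbivore, plus the moderators describing the
species, their traits, and the experimental design.

Tables are UTF-8 CSV (or TSV) with a mandatory header row.  Because deposited
supplementary tables rarely use canonical column names, a YAML schema map can
translate arbitrary headers to the canonical field names.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

RESPONSE_CATEGORIES = ("herbivore_performance", "herbivore_preference", "plant_performance")
OUTCOMES = (
    "survival",
    "growth",
    "fecundity",
    "development_time",
    "feeding_choice",
    "oviposition_choice",
    "biomass",
    "damage",
    "reproduction",
)
#: Which outcomes belong to which response category.
CATEGORY_OUTCOMES: dict[str, tuple[str, ...]] = {
    "herbivore_performance": ("survival", "growth", "fecundity", "development_time"),
    "herbivore_preference": ("feeding_choice", "oviposition_choice"),
    "plant_performance": ("biomass", "damage", "reproduction"),
}
SETTINGS = ("glasshouse", "field")
LIFE_CYCLES = ("annual", "perennial")
GROWTH_FORMS = ("herbaceous", "woody")
PLANT_STATUSES = ("wild", "cultivated")
DIETS = ("generalist", "specialist")
LOCATIONS = ("aboveground", "belowground")

IDENTIFIER_COLUMNS = ("record_id", "study_id", "treatment_id")
NUMERIC_COLUMNS = (
    "mean_treatment",
    "mean_control",
    "sd_treatment",
    "sd_control",
    "n_treatment",
    "n_control",
    "events_treatment",
    "events_control",
    "publication_year",
    "duration_first",
    "duration_second",
)
CANONICAL_COLUMNS = (
    "record_id",
    "study_id",
    "treatment_id",
    "response_category",
    "outcome",
    "mean_treatment",
    "mean_control",
    "sd_treatment",
    "sd_control",
    "n_treatment",
    "n_control",
    "events_treatment",
    "events_control",
    "publication_year",
    "setting",
    "inducer_removed",
    "duration_first",
    "duration_second",
    "plant_species",
    "inducer_species",
    "subsequent_species",
    "plant_life_cycle",
    "plant_growth_form",
    "plant_status",
    "inducer_guild",
    "subsequent_guild",
    "inducer_diet",
    "subsequent_diet",
    "inducer_location",
    "subsequent_location",
    "same_species",
)
#: Columns that must be resolvable for a table to be readable at all.
MANDATORY_COLUMNS = (
    "record_id",
    "study_id",
    "treatment_id",
    "response_category",
    "outcome",
    "n_treatment",
    "n_control",
)

_ENUM_CHECKS: dict[str, tuple[str, ...]] = {
    "response_category": RESPONSE_CATEGORIES,
    "outcome": OUTCOMES,
    "setting": SETTINGS,
    "plant_life_cycle": LIFE_CYCLES,
    "plant_growth_form": GROWTH_FORMS,
    "plant_status": PLANT_STATUSES,
    "inducer_diet": DIETS,
    "subsequent_diet": DIETS,
    "inducer_location": LOCATIONS,
    "subsequent_location": LOCATIONS,
}


class SchemaError(ValueError):
    """A table cannot be mapped onto the canonical schema."""


class ValidationError(ValueError):
    """One or more rows violate the record invariants."""

    def __init__(self, problems: list[dict[str, str]]):
        self.problems = problems
        lines = "; ".join(f"{p['record_id']}: {p['message']}" for p in problems[:10])
        more = "" if len(problems) <= 10 else f" (+{len(problems) - 10} more)"
        super().__init__(f"{len(problems)} invalid row(s): {lines}{more}")


@dataclass(frozen=True)
class EffectSizeRecord:
    """One extracted comparison with its raw summaries and moderators."""

    record_id: str
    study_id: str
    treatment_id: str
    response_category: str
    outcome: str
    n_treatment: int
    n_control: int
    mean_treatment: float | None = None
    mean_control: float | None = None
    sd_treatment: float | None = None
    sd_control: float | None = None
    events_treatment: int | None = None
    events_control: int | None = None
    publication_year: int | None = None
    setting: str | None = None
    inducer_removed: bool | None = None
    duration_first: float | None = None
    duration_second: float | None = None
    plant_species: str | None = None
    inducer_species: str | None = None
    subsequent_species: str | None = None
    plant_life_cycle: str | None = None
    plant_growth_form: str | None = None
    plant_status: str | None = None
    inducer_guild: str | None = None
    subsequent_guild: str | None = None
    inducer_diet: str | None = None
    subsequent_diet: str | None = None
    inducer_location: str | None = None
    subsequent_location: str | None = None
    same_species: bool | None = None


@dataclass
class Dataset:
    """An ordered collection of effect-size records backed by a DataFrame."""

    frame: pd.DataFrame
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def records(self) -> Iterator[EffectSizeRecord]:
        fields = set(EffectSizeRecord.__dataclass_fields__)
        for _, row in self.frame.iterrows():
            kwargs = {}
            for name in fields:
                if name in row.index:
                    val = row[name]
                    kwargs[name] = None if pd.isna(val) else val
            kwargs["n_treatment"] = int(kwargs["n_treatment"])
            kwargs["n_control"] = int(kwargs["n_control"])
            yield EffectSizeRecord(**kwargs)

    def subset(self, predicate: Mapping[str, Any] | Callable[[pd.DataFrame], pd.Series]) -> "Dataset":
        """Records matching all clauses of a field->value(s) filter.

        Values may be scalars or iterables of allowed values; a callable
        predicate receives the frame and returns a boolean mask.  Order is
        preserved and an empty result is allowed.
        """
        if callable(predicate):
            mask = predicate(self.frame)
        else:
            mask = pd.Series(True, index=self.frame.index)
            for fld, val in predicate.items():
                if fld not in self.frame.columns:
                    raise KeyError(f"unknown field in filter: {fld!r}")
                if isinstance(val, (list, tuple, set, frozenset, np.ndarray)):
                    mask &= self.frame[fld].isin(list(val))
                else:
                    mask &= self.frame[fld] == val
        sub = self.frame.loc[mask].copy()
        prov = dict(self.provenance)
        prov.setdefault("filters", []).append(str(predicate))
        return Dataset(sub, prov)


def load_schema(path: str | Path) -> dict[str, str]:
    """Load a YAML column map {canonical_name: table_header}."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    cols = doc.get("columns", doc) if isinstance(doc, dict) else None
    if not isinstance(cols, dict):
        raise SchemaError(f"schema file {path} does not contain a column mapping")
    return {str(k): str(v) for k, v in cols.items()}


def read_dataset(
    path: str | Path,
    schema: Mapping[str, str] | str | Path | None = None,
    strict: bool = True,
    sep: str | None = None,
) -> Dataset:
    """Read and validate an effect-size table.

    ``schema`` maps canonical field names to the table's actual headers
    (a mapping, or a path to a YAML file with a ``columns`` section).  Rows
    violating type or invariant constraints raise :class:`ValidationError`
    listing the offending record ids (``strict=True``) or are dropped with
    the problems recorded in ``provenance['validation_problems']``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True)

    if schema is not None and not isinstance(schema, Mapping):
        schema = load_schema(schema)
    if schema:
        rename = {v: k for k, v in schema.items() if v in raw.columns}
        missing_mapped = [k for k, v in schema.items() if v not in raw.columns]
        if missing_mapped:
            raise SchemaError(
                f"schema maps columns not present in {path.name}: {missing_mapped}"
            )
        raw = raw.rename(columns=rename)

    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")

    frame, problems = _coerce_and_validate(raw)
    if problems and strict:
        raise ValidationError(problems)
    prov: dict[str, Any] = {
        "source": str(path),
        "schema_version": "1",
        "validation_problems": problems,
    }
    return Dataset(frame, prov)


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset back to CSV/TSV with canonical headers (round-trip safe)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    dataset.frame.to_csv(path, sep=sep, index=False)


def validation_report(dataset: Dataset) -> dict[str, Any]:
    """JSON-serializable summary of a read: counts and row-level problems."""
    frame = dataset.frame
    counts = (
        frame["response_category"].value_counts().to_dict()
        if "response_category" in frame
        else {}
    )
    return {
        "source": dataset.provenance.get("source"),
        "n_records": int(len(frame)),
        "n_studies": int(frame["study_id"].nunique()),
        "records_per_category": {k: int(v) for k, v in counts.items()},
        "problems": dataset.provenance.get("validation_problems", []),
    }


def _coerce_and_validate(raw: pd.DataFrame) -> tuple[pd.DataFrame, list[dict[str, str]]]:
    frame = raw.copy()
    problems: list[dict[str, str]] = []

    def flag(idx: int, message: str) -> None:
        rid = str(frame.at[idx, "record_id"]) if "record_id" in frame else f"row {idx}"
        problems.append({"record_id": rid, "message": message})

    for col in NUMERIC_COLUMNS:
        if col not in frame.columns:
            continue
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame[col].notna() & coerced.isna()
        for idx in frame.index[bad]:
            flag(idx, f"unparseable numeric value in {col}: {frame.at[idx, col]!r}")
        frame[col] = coerced

    for col in ("inducer_removed", "same_species"):
        if col in frame.columns:
            frame[col] = frame[col].map(_parse_bool)

    for col in ("inducer_guild", "subsequent_guild"):
        if col in frame.columns:
            frame[col] = frame[col].astype("string").str.strip().str.lower()

    bad_rows: set[int] = set()
    if frame["record_id"].duplicated().any():
        for idx in frame.index[frame["record_id"].duplicated(keep=False)]:
            flag(idx, "duplicate record_id")
            bad_rows.add(idx)

    # each treatment_id (within the table) must map to exactly one study_id
    combo = frame.groupby("treatment_id")["study_id"].nunique()
    ambiguous = set(combo.index[combo > 1])
    for idx in frame.index:
        tid = frame.at[idx, "treatment_id"]
        if tid in ambiguous:
            flag(idx, f"treatment_id {tid!r} maps to multiple study_ids")
            bad_rows.add(idx)

    for idx in frame.index:
        row = frame.loc[idx]
        for col in ("n_treatment", "n_control"):
            val = row[col]
            if pd.isna(val) or val < 1 or float(val) != int(val):
                flag(idx, f"{col} must be a positive integer (got {val!r})")
                bad_rows.add(idx)
        for arm in ("treatment", "control"):
            ev, n = row.get(f"events_{arm}"), row.get(f"n_{arm}")
            if pd.notna(ev) and pd.notna(n) and (ev < 0 or ev > n):
                flag(idx, f"events_{arm} outside [0, n_{arm}]")
                bad_rows.add(idx)
        for col in ("sd_treatment", "sd_control", "duration_first", "duration_second"):
            val = row.get(col)
            if pd.notna(val) and val < 0:
                flag(idx, f"{col} must be nonnegative")
                bad_rows.add(idx)
        for col, allowed in _ENUM_CHECKS.items():
            val = row.get(col)
            if col in frame.columns and pd.notna(val) and val not in allowed:
                flag(idx, f"{col}={val!r} not one of {allowed}")
                bad_rows.add(idx)
        if (
            pd.notna(row.get("same_species"))
            and pd.notna(row.get("inducer_species"))
            and pd.notna(row.get("subsequent_species"))
        ):
            expected = row["inducer_species"] == row["subsequent_species"]
            if bool(row["same_species"]) != expected:
                flag(idx, "same_species inconsistent with species columns")
                bad_rows.add(idx)

    for col in ("n_treatment", "n_control", "publication_year", "events_treatment", "events_control"):
        if col in frame.columns:
            frame[col] = frame[col].astype("float")

    clean = frame.drop(index=sorted(bad_rows)).reset_index(drop=True)
    return clean if problems else frame, problems


def _parse_bool(val: Any) -> Any:
    if pd.isna(val):
        return np.nan
    s = str(val).strip().lower()
    if s in {"true", "1", "yes", "t"}:
        return True
    if s in {"false", "0", "no", "f"}:
        return False
    return np.nan
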