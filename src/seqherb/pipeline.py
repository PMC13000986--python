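"""Orchestration of the full analysis: overall models per response category,
every moderator metaregression, the publication-bias battery and the
sensitivity suite, emitted as plot-ready tables.

An :class:`AnalysisPlan` is an ordered list of (label, subset filter,
model spec) entries; :func:`run_reproduction` executes them all, writing one
TSV per entry plus a JSON summary and a plain-text log.  Errors in one stage
are recorded and the remaining stages continue.  Plant-performance moderator
tables are additionally emitted split into biomass and damage sub-tables,
since those outcomes respond in opposite directions and are reported
separately.  No multiplicity correction is applied across moderator tests;
the tables carry raw p-values.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .bias import OLS_INVERSE_VARIANCE, WEIGHTED_SEI, cumulative_meta, egger_test, funnel_coordinates
from .dataset_io import CATEGORY_OUTCOMES, Dataset, RESPONSE_CATEGORIES
from .effect_sizes import HEDGES_G, compute_effect_sizes
from .reml import FitResult, ModelSpec, fit_multilevel, predict_mean_and_pi
from .sensitivity import lor_validation, leave_species_out, rank_species_by_representation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlanEntry:
    label: str
    subset: Mapping[str, Any]
    spec: ModelSpec
    anchor: str = ""  # which results table/figure this entry mirrors


@dataclass
class AnalysisPlan:
    entries: list[PlanEntry] = field(default_factory=list)
    run_bias: bool = True
    run_sensitivity: bool = True

    def __post_init__(self) -> None:
        labels = [e.label for e in self.entries]
        if len(labels) != len(set(labels)):
            raise ValueError("plan labels must be unique")

    @staticmethod
    def default() -> "AnalysisPlan":
        """Overall models plus the standard moderator battery per category."""
        entries: list[PlanEntry] = []
        for cat in RESPONSE_CATEGORIES:
            entries.append(
                PlanEntry(
                    label=f"overall_{cat}",
                    subset={"response_category": cat},
                    spec=ModelSpec.three_level(),
                    anchor="overall mean effects",
                )
            )
            entries.append(
                PlanEntry(
                    label=f"outcome_{cat}",
                    subset={"response_category": cat},
                    spec=ModelSpec.three_level(fixed="outcome"),
                    anchor="outcome-type moderators",
                )
            )
            for mod, anchor in (
                ("guild_pair", "feeding-guild combinations"),
                ("diet_pair", "diet-breadth combinations"),
                ("location_pair", "feeding-location combinations"),
                ("same_species", "conspecific vs heterospecific sequence"),
                ("life_history", "plant life history"),
                ("plant_status", "wild vs cultivated"),
                ("setting", "glasshouse vs field"),
                ("inducer_removed", "inducer removal"),
            ):
                entries.append(
                    PlanEntry(
                        label=f"{mod}_{cat}",
                        subset={"response_category": cat},
                        spec=ModelSpec.three_level(fixed=mod, fixed_kind="categorical"),
                        anchor=anchor,
                    )
                )
            for mod in ("duration_first", "duration_second"):
                entries.append(
                    PlanEntry(
                        label=f"{mod}_{cat}",
                        subset={"response_category": cat},
                        spec=ModelSpec.three_level(fixed=mod, fixed_kind="continuous"),
                        anchor="feeding-duration moderators",
                    )
                )
        return AnalysisPlan(entries)


def derive_moderator_columns(frame: pd.DataFrame) -> pd.DataFrame:
    """Add the combined moderator columns the analysis plan refers to."""
    out = frame.copy()
    out["guild_pair"] = (
        out["inducer_guild"].astype(str) + "->" + out["subsequent_guild"].astype(str)
    )
    out["diet_pair"] = (
        out["inducer_diet"].astype(str) + "->" + out["subsequent_diet"].astype(str)
    )
    out["location_pair"] = (
        out["inducer_location"].astype(str) + "->" + out["subsequent_location"].astype(str)
    )
    out["life_history"] = (
        out["plant_life_cycle"].astype(str) + "_" + out["plant_growth_form"].astype(str)
    )
    out["same_species"] = out["same_species"].astype(str)
    out["inducer_removed"] = out["inducer_removed"].astype(str)
    return out


def fit_table(fit: FitResult, label: str) -> pd.DataFrame:
    """One tidy row per coefficient, plus fit-level columns."""
    tab = fit.coef_table()
    tab.insert(0, "analysis", label)
    tab["k"] = fit.k
    tab["sigma2_study"] = fit.vc.components.get("study_id", np.nan)
    tab["sigma2_treatment"] = fit.vc.components.get("treatment_key", np.nan)
    tab["i2_pct"] = fit.i2
    tab["qm"] = fit.qm
    tab["qm_df"] = fit.qm_df
    tab["qm_p"] = fit.qm_p
    tab["pi_low"] = fit.pi_low
    tab["pi_high"] = fit.pi_high
    tab["converged"] = fit.converged
    return tab


def run_reproduction(
    dataset: Dataset,
    plan: AnalysisPlan | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, Any]:
    """Execute every plan entry plus the bias and sensitivity batteries.

    Returns a report bundle: ``fits`` (label -> FitResult), ``tables``
    (label -> tidy DataFrame), ``summary`` (JSON-serializable), ``errors``
    and ``log`` lines.  With ``out_dir`` set, tables are written as TSV, the
    summary as JSON, and the log as plain text; outputs are sorted so
    repeated runs on the same inputs are byte-identical.
    """
    plan = plan or AnalysisPlan.default()
    log: list[str] = []

    def note(msg: str) -> None:
        log.append(f"{datetime.now(timezone.utc).isoformat(timespec='seconds')} {msg}")
        logger.info(msg)

    es = compute_effect_sizes(dataset.frame)
    es = derive_moderator_columns(es)
    g_records = es[es["metric"] == HEDGES_G]
    note(f"effect sizes computed: {len(es)} of {len(dataset.frame)} records usable "
         f"({len(g_records)} mean-based)")

    fits: dict[str, FitResult] = {}
    tables: dict[str, pd.DataFrame] = {}
    errors: dict[str, str] = {}

    for entry in plan.entries:
        sub = g_records
        for fld, val in entry.subset.items():
            sub = sub[sub[fld] == val]
        try:
            if len(sub) < 3:
                raise ValueError(f"too few records ({len(sub)})")
            if entry.spec.fixed == "duration_first":
                sub = sub[sub["duration_first"].notna()]
            if entry.spec.fixed == "duration_second":
                sub = sub[sub["duration_second"].notna()]
            fit = fit_multilevel(
                sub["yi"].to_numpy(), sub["vi"].to_numpy(), entry.spec, sub
            )
            fits[entry.label] = fit
            tables[entry.label] = fit_table(fit, entry.label)
            note(f"{entry.label}: k={fit.k} estimate={fit.estimate:+.3f} "
                 f"I2={fit.i2:.1f}% converged={fit.converged}")
            # plant-performance moderators split into biomass / damage sub-rows
            if (
                entry.subset.get("response_category") == "plant_performance"
                and entry.spec.fixed is not None
            ):
                for outc in ("biomass", "damage"):
                    part = sub[sub["outcome"] == outc]
                    if part[entry.spec.fixed].nunique() >= 2 and len(part) >= 3:
                        try:
                            f2 = fit_multilevel(
                                part["yi"].to_numpy(), part["vi"].to_numpy(),
                                entry.spec, part,
                            )
                            tables[f"{entry.label}_{outc}"] = fit_table(
                                f2, f"{entry.label}_{outc}"
                            )
                        except Exception as exc:  # recorded, not fatal
                            errors[f"{entry.label}_{outc}"] = str(exc)
        except Exception as exc:
            errors[entry.label] = str(exc)
            note(f"{entry.label}: FAILED ({exc})")

    bias_summary: dict[str, Any] = {}
    if plan.run_bias:
        try:
            pooled = egger_test(
                g_records["yi"].to_numpy(), g_records["vi"].to_numpy(),
                variant=OLS_INVERSE_VARIANCE,
            )
            bias_summary["egger_pooled"] = {
                "slope": pooled.slope, "slope_se": pooled.slope_se,
                "F": pooled.statistic, "df": list(pooled.df), "p": pooled.p,
            }
            for cat in RESPONSE_CATEGORIES:
                part = g_records[g_records["response_category"] == cat]
                if len(part) >= 3:
                    res = egger_test(
                        part["yi"].to_numpy(), part["vi"].to_numpy(),
                        variant=WEIGHTED_SEI, frame=part,
                    )
                    bias_summary[f"egger_{cat}"] = {
                        "z": res.statistic, "p": res.p, "k": int(len(part)),
                    }
                    cum = cumulative_meta(part, ModelSpec.three_level())
                    tables[f"cumulative_{cat}"] = cum
                    points, rails = funnel_coordinates(
                        part["yi"].to_numpy(), part["vi"].to_numpy(),
                        pooled=fits.get(f"overall_{cat}", None)
                        and fits[f"overall_{cat}"].estimate,
                    )
                    tables[f"funnel_points_{cat}"] = points
                    tables[f"funnel_rails_{cat}"] = rails
            note("publication-bias battery complete")
        except Exception as exc:
            errors["bias"] = str(exc)
            note(f"bias battery FAILED ({exc})")

    sens_summary: dict[str, Any] = {}
    if plan.run_sensitivity:
        try:
            rank_rows = []
            for role in ("plant", "inducer", "subsequent"):
                ranking = rank_species_by_representation(dataset, role)
                ranking.insert(0, "role", role)
                rank_rows.append(ranking)
                for species in ranking["species"].head(3):
                    try:
                        rep = leave_species_out(
                            Dataset(g_records), species, role, ModelSpec.three_level()
                        )
                        sens_summary[f"loso_{role}_{species}"] = {
                            "share_pct": rep.share_of_observations,
                            "estimate": rep.fit.estimate,
                            "delta_vs_full": rep.delta_vs_full,
                            "ci_excludes_full": rep.refit_ci_excludes_full,
                        }
                    except Exception as exc:
                        errors[f"loso_{role}_{species}"] = str(exc)
            tables["species_representation"] = pd.concat(rank_rows, ignore_index=True)
            try:
                lor = lor_validation(dataset)
                for key in ("survival", "choice"):
                    if key in lor:
                        f = lor[key]
                        sens_summary[f"lor_{key}"] = {
                            "estimate": f.estimate,
                            "ci_low": float(f.ci_low[0]),
                            "ci_high": float(f.ci_high[0]),
                            "i2_pct": f.i2,
                            "k": f.k,
                        }
                if "class_qm" in lor:
                    qm, df, p = lor["class_qm"]
                    sens_summary["lor_class_qm"] = {"qm": qm, "df": df, "p": p}
            except Exception as exc:
                errors["lor_validation"] = str(exc)
            note("sensitivity suite complete")
        except Exception as exc:
            errors["sensitivity"] = str(exc)
            note(f"sensitivity suite FAILED ({exc})")

    summary: dict[str, Any] = {
        "k_total": int(len(es)),
        "n_studies": int(dataset.frame["study_id"].nunique()),
        "overall": {
            label: {
                "estimate": fit.estimate,
                "ci_low": float(fit.ci_low[0]),
                "ci_high": float(fit.ci_high[0]),
                "pi_low": fit.pi_low,
                "pi_high": fit.pi_high,
                "i2_pct": fit.i2,
                "k": fit.k,
            }
            for label, fit in sorted(fits.items())
            if label.startswith("overall_")
        },
        "moderators": {
            label: {"qm": fit.qm, "df": fit.qm_df, "p": fit.qm_p, "k": fit.k}
            for label, fit in sorted(fits.items())
            if not label.startswith("overall_")
        },
        "bias": bias_summary,
        "sensitivity": sens_summary,
        "errors": dict(sorted(errors.items())),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for label in sorted(tables):
            tables[label].to_csv(out / f"{label}.tsv", sep="\t", index=False)
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        (out / "run.log").write_text("\n".join(log) + "\n", encoding="utf-8")

    return {"fits": fits, "tables": tables, "summary": summary, "errors": errors, "log": log}
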