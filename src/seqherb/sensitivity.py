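"""Sensitivity analyses: leave-one-species-out refits, species representation,
and the binary-outcome (log odds ratio) validation subset.

Phylogeny-augmented refits are obtained by attaching one tree-derived
correlation matrix at a time to the model spec (``ModelSpec.with_phylo``);
fitting plant, inducer and subsequent-herbivore trees jointly is deliberately
not supported, as crossed correlated terms over the same records are poorly
identified.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .dataset_io import Dataset
from .effect_sizes import BINARY_OUTCOMES, compute_effect_sizes
from .reml import FitResult, ModelSpec, fit_multilevel, omnibus_from_cov

ROLE_COLUMNS = {
    "plant": "plant_species",
    "inducer": "inducer_species",
    "subsequent": "subsequent_species",
}


class SensitivityError(ValueError):
    pass


@dataclass
class ExclusionReport:
    """Refit after removing every record involving one species in one role."""

    excluded_species: str
    role: str
    share_of_observations: float  # percent of records removed
    fit: FitResult
    delta_vs_full: float  # refit estimate minus full-data estimate
    refit_ci_excludes_full: bool  # does the refit CI exclude the full estimate?


def rank_species_by_representation(dataset: Dataset, role: str) -> pd.DataFrame:
    """Species of one role ordered by their share (%) of records; shares sum to 100."""
    col = _role_column(role)
    frame = dataset.frame
    counts = frame[col].value_counts()
    shares = 100.0 * counts / counts.sum()
    return pd.DataFrame(
        {"species": counts.index, "n_records": counts.values, "share_pct": shares.values}
    ).reset_index(drop=True)


def leave_species_out(
    dataset: Dataset,
    species: str,
    role: str,
    spec: ModelSpec,
    yi: str = "yi",
    vi: str = "vi",
) -> ExclusionReport:
    """Refit ``spec`` on the dataset with one species (in one role) removed."""
    col = _role_column(role)
    frame = dataset.frame
    mask = frame[col] == species
    share = 100.0 * float(mask.sum()) / len(frame)
    kept = frame.loc[~mask]
    if spec.fixed is not None and spec.fixed in kept.columns:
        full_levels = set(frame[spec.fixed].dropna().astype(str))
        kept_levels = set(kept[spec.fixed].dropna().astype(str))
        lost = sorted(full_levels - kept_levels)
        if lost:
            raise SensitivityError(
                f"excluding {species!r} empties moderator level(s) {lost} of {spec.fixed!r}"
            )
    full_fit = fit_multilevel(frame[yi].to_numpy(), frame[vi].to_numpy(), spec, frame)
    refit = fit_multilevel(kept[yi].to_numpy(), kept[vi].to_numpy(), spec, kept)
    delta = refit.estimate - full_fit.estimate
    excludes = not (refit.ci_low[0] <= full_fit.estimate <= refit.ci_high[0])
    return ExclusionReport(
        excluded_species=species,
        role=role,
        share_of_observations=share,
        fit=refit,
        delta_vs_full=float(delta),
        refit_ci_excludes_full=bool(excludes),
    )


def lor_validation(
    dataset: Dataset, spec: ModelSpec | None = None
) -> dict[str, object]:
    """Multilevel analysis of the binary-count subset on the log odds ratio scale.

    Survival and choice outcomes are fitted separately (intercept-only), and a
    moderator fit across outcome classes provides the omnibus QM test for
    class differences.  Records lacking binary counts are ignored.
    """
    frame = dataset.frame
    has_counts = frame["events_treatment"].notna() & frame["events_control"].notna()
    sub = frame.loc[has_counts & frame["outcome"].isin(BINARY_OUTCOMES)].copy()
    if sub.empty:
        raise SensitivityError("no records with binary counts in the dataset")
    es = compute_effect_sizes(sub)
    es = es[es["metric"] == "log_odds_ratio"]
    if spec is None:
        spec = ModelSpec.three_level()
    out: dict[str, object] = {"k_total": int(len(es))}
    for label, outcomes in (
        ("survival", ["survival"]),
        ("choice", ["feeding_choice", "oviposition_choice"]),
    ):
        part = es[es["outcome"].isin(outcomes)]
        if len(part) >= 2:
            out[label] = fit_multilevel(
                part["yi"].to_numpy(), part["vi"].to_numpy(), spec, part
            )
    if es["outcome"].nunique() >= 2:
        mod_spec = ModelSpec(fixed="outcome", fixed_kind="categorical", random=spec.random)
        mod_fit = fit_multilevel(
            es["yi"].to_numpy(), es["vi"].to_numpy(), mod_spec, es
        )
        out["class_moderator"] = mod_fit
        out["class_qm"] = (mod_fit.qm, mod_fit.qm_df, mod_fit.qm_p)
    return out


def _role_column(role: str) -> str:
    try:
        return ROLE_COLUMNS[role]
    except KeyError:
        raise SensitivityError(
            f"role must be one of {sorted(ROLE_COLUMNS)}, got {role!r}"
        ) from None
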