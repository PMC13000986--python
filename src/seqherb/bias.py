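"""Publication-bias diagnostics: cumulative meta-analysis, funnel plots,
Egger-type asymmetry regressions.

Two asymmetry variants are provided because both appear in meta-analytic
practice for this kind of data: a weighted (random-effects) metaregression of
the effect value on its standard error (z statistic for the SE coefficient),
and an ordinary least-squares regression of the effect value on the inverse
of its sampling variance (F statistic with df (1, k-2)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .reml import ModelSpec, FitResult, Z975, fit_multilevel

OLS_INVERSE_VARIANCE = "ols_inverse_variance"
WEIGHTED_SEI = "weighted_sei"


class BiasError(ValueError):
    pass


@dataclass
class AsymmetryResult:
    """Result of one funnel-asymmetry regression."""

    slope: float
    slope_se: float
    statistic: float
    statistic_kind: str  # 'z' or 'F'
    df: tuple[int, ...]
    p: float
    variant: str


def cumulative_meta(
    frame: pd.DataFrame,
    spec: ModelSpec,
    yi: str = "yi",
    vi: str = "vi",
    year: str = "publication_year",
) -> pd.DataFrame:
    """Refit the model on each year-closing prefix of the chronologically
    ordered records.

    Records are sorted by (year, study_id, record_id) so the series is
    invariant to within-year input order; one step is emitted per distinct
    year.  Prefixes on which a variance component is not identifiable (fewer
    than two levels of its factor) have that component pinned at zero and the
    step flagged.  The final step equals the full-data fit exactly.
    """
    if frame[year].isna().any():
        raise BiasError("all records must carry a publication year")
    order = frame.sort_values(
        [year, "study_id", "record_id"], kind="mergesort"
    ).reset_index(drop=True)
    steps = []
    years = sorted(order[year].unique())
    for yr in years:
        prefix = order[order[year] <= yr]
        use_spec = spec
        pinned = []
        for term in spec.random:
            col = (
                prefix["study_id"].astype(str) + "/" + prefix["treatment_id"].astype(str)
                if term.factor == "treatment_key" and "treatment_key" not in prefix
                else prefix.get(term.factor, prefix["study_id"]).astype(str)
            )
            if col.nunique() < 2:
                pinned.append(term.factor)
        if pinned:
            kept = tuple(t for t in spec.random if t.factor not in pinned)
            # keep nesting legal: dropping study also drops treatment term
            if any(t.factor == "treatment_key" for t in kept) and not any(
                t.factor == "study_id" for t in kept
            ):
                kept = tuple(t for t in kept if t.factor != "treatment_key")
            use_spec = ModelSpec(spec.fixed, spec.fixed_kind, kept)
        fit = fit_multilevel(
            prefix[yi].to_numpy(), prefix[vi].to_numpy(), use_spec, prefix
        )
        steps.append(
            {
                "year": yr,
                "k_so_far": len(prefix),
                "estimate": fit.estimate,
                "ci_low": float(fit.ci_low[0]),
                "ci_high": float(fit.ci_high[0]),
                "pinned_components": ",".join(pinned),
            }
        )
    return pd.DataFrame(steps)


def funnel_coordinates(
    yi: np.ndarray, vi: np.ndarray, pooled: float | None = None, n_rail: int = 50
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready funnel scatter plus pseudo-confidence rails.

    Points are (value, standard error); the rails are pooled ± z_{.975}·se
    over the observed SE range (meeting at the pooled estimate at se = 0).
    """
    yi = np.asarray(yi, dtype=float)
    vi = np.asarray(vi, dtype=float)
    if np.any(vi <= 0):
        raise BiasError("sampling variances must be positive")
    se = np.sqrt(vi)
    if pooled is None:
        w = 1.0 / vi
        pooled = float(np.sum(w * yi) / np.sum(w))
    points = pd.DataFrame({"value": yi, "se": se})
    rail_se = np.linspace(0.0, float(se.max()), n_rail)
    rails = pd.DataFrame(
        {
            "se": rail_se,
            "low": pooled - Z975 * rail_se,
            "high": pooled + Z975 * rail_se,
            "pooled": pooled,
        }
    )
    return points, rails


def egger_test(
    yi: np.ndarray,
    vi: np.ndarray,
    variant: str = WEIGHTED_SEI,
    frame: pd.DataFrame | None = None,
    random: tuple | None = None,
) -> AsymmetryResult:
    """Funnel-asymmetry regression.

    ``ols_inverse_variance``: OLS of the effect value on 1/variance,
    F = t² with df (1, k-2).  ``weighted_sei``: random-effects
    metaregression of the value on its standard error (using ``frame`` and
    the ``random`` grouping terms when given, else a per-record random
    effect), z statistic for the SE coefficient.
    """
    yi = np.asarray(yi, dtype=float)
    vi = np.asarray(vi, dtype=float)
    k = len(yi)
    if k < 3:
        raise BiasError("asymmetry test requires k >= 3")
    if variant == OLS_INVERSE_VARIANCE:
        x = 1.0 / vi
        if np.ptp(x) == 0:
            raise BiasError("constant predictor: inverse variances all equal")
        X = sm.add_constant(x)
        res = sm.OLS(yi, X).fit()
        slope = float(res.params[1])
        slope_se = float(res.bse[1])
        f = float((slope / slope_se) ** 2)
        p = float(stats.f.sf(f, 1, k - 2))
        return AsymmetryResult(slope, slope_se, f, "F", (1, k - 2), p, variant)
    if variant == WEIGHTED_SEI:
        se = np.sqrt(vi)
        if np.ptp(se) == 0:
            raise BiasError("constant predictor: standard errors all equal")
        if frame is None:
            frame = pd.DataFrame(
                {
                    "record_id": [f"r{i}" for i in range(k)],
                    "study_id": [f"r{i}" for i in range(k)],
                }
            )
        work = frame.copy().reset_index(drop=True)
        work["sei"] = se
        from .reml import RandomSpec

        rnd = random if random is not None else (RandomSpec("study_id"),)
        spec = ModelSpec(fixed="sei", fixed_kind="continuous", random=tuple(rnd))
        fit = fit_multilevel(yi, vi, spec, work)
        slope = float(fit.beta[1])
        slope_se = float(fit.se[1])
        z = slope / slope_se
        p = float(2 * stats.norm.sf(abs(z)))
        return AsymmetryResult(slope, slope_se, float(z), "z", (1,), p, variant)
    raise BiasError(f"unknown asymmetry variant: {variant!r}")
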