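"""Standardized effect sizes for two-group comparisons.

Two metrics are supported: Hedges' g (standardized mean difference with the
small-sample correction J) for outcomes reported as mean/SD/n per arm, and
the log odds ratio (LOR) for outcomes reported as event counts per arm
(individual survival or choice).

The sign convention used throughout the package is that a *negative* effect
means lower herbivore or plant performance on induced plants (induced
resistance).  For outcomes where the raw difference points the other way —
development time (longer = worse for the herbivore) and tissue damage (more
damage = worse for the plant) — the sign of the computed effect is reversed
once, and the reversal is recorded on the effect so downstream tables remain
unambiguous.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Outcomes whose effect sign is flipped to make "negative = worse performance
#: after sequential herbivory" hold for every outcome.
SIGN_REVERSED_OUTCOMES = frozenset({"development_time", "damage"})

#: Outcomes that may be reported as individual binary events instead of means.
BINARY_OUTCOMES = frozenset({"survival", "feeding_choice", "oviposition_choice"})

HEDGES_G = "hedges_g"
LOG_ODDS_RATIO = "log_odds_ratio"


class EffectSizeError(ValueError):
    """Raised when an effect size cannot be computed from the given summaries."""


@dataclass(frozen=True)
class SummaryStats:
    """Per-arm summary statistics (mean, SD, n) of a two-group comparison."""

    mean_treatment: float
    mean_control: float
    sd_treatment: float
    sd_control: float
    n_treatment: int
    n_control: int

    def __post_init__(self) -> None:
        if self.n_treatment < 1 or self.n_control < 1:
            raise EffectSizeError("sample sizes must be positive integers")
        if self.sd_treatment < 0 or self.sd_control < 0:
            raise EffectSizeError("standard deviations must be nonnegative")
        if self.n_treatment + self.n_control < 3:
            raise EffectSizeError(
                "n_treatment + n_control must be >= 3 for a finite pooled SD"
            )


@dataclass(frozen=True)
class BinaryCounts:
    """Per-arm event counts (e.g. survivors, or individuals choosing a plant)."""

    events_treatment: int
    events_control: int
    n_treatment: int
    n_control: int

    def __post_init__(self) -> None:
        if self.n_treatment < 1 or self.n_control < 1:
            raise EffectSizeError("sample sizes must be positive integers")
        if not (0 <= self.events_treatment <= self.n_treatment):
            raise EffectSizeError("events_treatment must lie in [0, n_treatment]")
        if not (0 <= self.events_control <= self.n_control):
            raise EffectSizeError("events_control must lie in [0, n_control]")


@dataclass(frozen=True)
class EffectSize:
    """An effect size value with its sampling variance and metric tag."""

    value: float
    variance: float
    metric: str
    sign_reversed: bool = False
    j: float | None = None  # small-sample correction factor, Hedges' g only


def pooled_sd(stats: SummaryStats) -> float:
    """Pooled standard deviation of the two arms.

    sqrt( [ (n_t - 1) sd_t^2 + (n_c - 1) sd_c^2 ] / (n_t + n_c - 2) )
    """
    nt, nc = stats.n_treatment, stats.n_control
    denom = nt + nc - 2
    if denom <= 0:
        raise EffectSizeError("pooled SD undefined for n_t + n_c <= 2")
    num = (nt - 1) * stats.sd_treatment**2 + (nc - 1) * stats.sd_control**2
    return math.sqrt(num / denom)


def small_sample_correction(n_treatment: int, n_control: int) -> float:
    """Hedges' small-sample correction J = 1 - 3 / (4(n_t + n_c - 2) - 1)."""
    m = n_treatment + n_control - 2
    if m < 1:
        raise EffectSizeError("J undefined for n_t + n_c <= 2")
    return 1.0 - 3.0 / (4.0 * m - 1.0)


def hedges_g(stats: SummaryStats) -> EffectSize:
    """Hedges' g with its large-sample sampling variance.

    g = J (x̄_t - x̄_c) / s_pooled,
    var(g) = (n_t + n_c)/(n_t n_c) + g² / (2(n_t + n_c)).
    """
    sp = pooled_sd(stats)
    if sp <= 0:
        raise EffectSizeError("zero pooled SD: standardized difference undefined")
    nt, nc = stats.n_treatment, stats.n_control
    j = small_sample_correction(nt, nc)
    g = j * (stats.mean_treatment - stats.mean_control) / sp
    var = (nt + nc) / (nt * nc) + g**2 / (2.0 * (nt + nc))
    return EffectSize(value=g, variance=var, metric=HEDGES_G, j=j)


def log_odds_ratio(counts: BinaryCounts) -> EffectSize:
    """Log odds ratio of the treatment arm relative to the control arm.

    With the 2x2 cells a = events_t, b = n_t - a, c = events_c, d = n_c - c:
    LOR = log((a/b) / (c/d)), var = 1/a + 1/b + 1/c + 1/d.  When any cell is
    zero, 0.5 is added to all four cells of that table (continuity
    correction).  Tables with no events (or no non-events) in *both* arms
    carry no direction information and raise an error.
    """
    a = float(counts.events_treatment)
    c = float(counts.events_control)
    b = float(counts.n_treatment) - a
    d = float(counts.n_control) - c
    if (a == 0 and c == 0) or (b == 0 and d == 0):
        raise EffectSizeError(
            "odds ratio undefined: both arms all-events or all-nonevents"
        )
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    value = math.log((a / b) / (c / d))
    var = 1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d
    return EffectSize(value=value, variance=var, metric=LOG_ODDS_RATIO)


def apply_sign_convention(effect: EffectSize, outcome: str) -> EffectSize:
    """Reverse the effect sign for outcomes where larger raw values are worse.

    Applies exactly once; a second application on an already-reversed effect
    raises, so the convention can never be silently undone.
    """
    if effect.sign_reversed:
        raise EffectSizeError("sign convention already applied to this effect")
    if outcome in SIGN_REVERSED_OUTCOMES:
        return replace(effect, value=-effect.value, sign_reversed=True)
    return effect


def compute_effect_sizes(frame: pd.DataFrame) -> pd.DataFrame:
    """Append effect-size columns (yi, vi, metric, j, sign_reversed) to a table.

    Mean-based records get Hedges' g; records carrying binary event counts get
    a log odds ratio.  Records with incomplete summaries for their metric are
    excluded with a logged warning (one line per record).  Returns only the
    computable rows, in input order.  Vectorized; per-record results agree
    exactly with :func:`hedges_g` / :func:`log_odds_ratio` on the same inputs.
    """
    out = frame.reset_index(drop=True).copy()
    k = len(out)
    rid = (
        out["record_id"].astype(str)
        if "record_id" in out
        else pd.Series([f"row {i}" for i in range(k)])
    )
    num = {
        c: pd.to_numeric(out.get(c, pd.Series([np.nan] * k)), errors="coerce").to_numpy(
            dtype=float
        )
        for c in (
            "mean_treatment",
            "mean_control",
            "sd_treatment",
            "sd_control",
            "n_treatment",
            "n_control",
            "events_treatment",
            "events_control",
        )
    }
    nt, nc = num["n_treatment"], num["n_control"]
    has_binary = ~np.isnan(num["events_treatment"]) & ~np.isnan(num["events_control"])
    has_means = ~(
        np.isnan(num["mean_treatment"])
        | np.isnan(num["mean_control"])
        | np.isnan(num["sd_treatment"])
        | np.isnan(num["sd_control"])
    )

    yi = np.full(k, np.nan)
    vi = np.full(k, np.nan)
    jcol = np.full(k, np.nan)
    metric = np.array([""] * k, dtype=object)
    reason = np.array([""] * k, dtype=object)
    reason[~(has_binary | has_means)] = (
        "neither complete mean/SD summaries nor binary counts"
    )

    # --- Hedges' g on mean-based rows -------------------------------------
    m = has_means & ~has_binary & ~np.isnan(nt) & ~np.isnan(nc)
    with np.errstate(invalid="ignore", divide="ignore"):
        dfree = nt + nc - 2
        sp2 = np.where(
            dfree > 0,
            ((nt - 1) * num["sd_treatment"] ** 2 + (nc - 1) * num["sd_control"] ** 2)
            / np.where(dfree > 0, dfree, 1),
            np.nan,
        )
        sp = np.sqrt(sp2)
        bad_n = m & ((nt + nc < 3) | (nt < 1) | (nc < 1))
        bad_sp = m & ~bad_n & ~(sp > 0)
        ok = m & ~bad_n & ~bad_sp
        j = 1.0 - 3.0 / (4.0 * dfree - 1.0)
        g = j * (num["mean_treatment"] - num["mean_control"]) / sp
        yi = np.where(ok, g, yi)
        vi = np.where(ok, (nt + nc) / (nt * nc) + g**2 / (2.0 * (nt + nc)), vi)
        jcol = np.where(ok, j, jcol)
    metric[ok] = HEDGES_G
    reason[bad_n] = "n_treatment + n_control must be >= 3"
    reason[bad_sp] = "zero pooled SD: standardized difference undefined"

    # --- log odds ratio on binary rows ------------------------------------
    mb = has_binary & ~np.isnan(nt) & ~np.isnan(nc)
    a = num["events_treatment"]
    c = num["events_control"]
    b = nt - a
    d = nc - c
    invalid = mb & ((a < 0) | (c < 0) | (b < 0) | (d < 0))
    degenerate = mb & ~invalid & (((a == 0) & (c == 0)) | ((b == 0) & (d == 0)))
    okb = mb & ~invalid & ~degenerate
    zero_cell = okb & (np.minimum(np.minimum(a, b), np.minimum(c, d)) == 0)
    shift = np.where(zero_cell, 0.5, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        aa, bb, cc, dd = a + shift, b + shift, c + shift, d + shift
        lor = np.log((aa / bb) / (cc / dd))
        yi = np.where(okb, lor, yi)
        vi = np.where(okb, 1 / aa + 1 / bb + 1 / cc + 1 / dd, vi)
    metric[okb] = LOG_ODDS_RATIO
    reason[invalid] = "event counts outside [0, n]"
    reason[degenerate] = "odds ratio undefined: both arms all-events or all-nonevents"

    for i in np.flatnonzero(reason != ""):
        logger.warning("record %s excluded: %s", rid.iloc[i], reason[i])

    keep = metric != ""
    flip = keep & out["outcome"].isin(SIGN_REVERSED_OUTCOMES).to_numpy()
    yi = np.where(flip, -yi, yi)

    out["yi"] = yi
    out["vi"] = vi
    out["metric"] = metric
    out["j"] = jcol
    out["sign_reversed"] = flip
    return out.loc[keep].reset_index(drop=True)
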