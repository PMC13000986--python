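"""Multilevel random-effects meta-analytic models fitted by REML.

The model is

    y = X beta + sum_r Z_r u_r + e,      e_i ~ N(0, v_i)  (v known),
    u_r ~ N(0, sigma2_r * G_r),

where each random term r is a grouping factor (study, treatment within
study, a per-record term, or a taxon) with an identity level-covariance
G_r = I, except for a phylogenetic term whose G_r is a unit-diagonal
correlation matrix derived from a tree.  Variance components are estimated
by restricted maximum likelihood on the log scale (quasi-Newton with
multiple starts), and the fixed effects by generalized least squares at the
optimum.  Inference is Wald-type: z confidence intervals for coefficients
and chi-square omnibus (QM) tests for moderator coefficient blocks, matching
standard meta-analytic practice for models of this form.

When no random term carries a correlation matrix, the marginal covariance V
is block-diagonal over the connected components of records linked by shared
factor levels; the likelihood is then accumulated block by block, which
keeps fits on thousands of records fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

Z975 = float(stats.norm.ppf(0.975))

_LOG_LOWER = np.log(1e-12)
_ZERO_TOL = 1e-8  # components below this are reported as exactly zero


class ModelError(ValueError):
    """Raised for unfittable model specifications (rank deficiency etc.)."""


@dataclass(frozen=True)
class RandomSpec:
    """One random-intercept term: a grouping column, optionally correlated.

    ``corr`` (levels x levels unit-diagonal correlation, with ``corr_taxa``
    naming its rows) turns the term into a correlated (phylogenetic) random
    effect; its keys must cover every level appearing in the data.
    """

    factor: str
    corr: np.ndarray | None = None
    corr_taxa: tuple[str, ...] | None = None


@dataclass(frozen=True)
class ModelSpec:
    """Fixed and random structure of one model fit.

    ``fixed`` is None (intercept only) or a single moderator column;
    ``fixed_kind`` is 'categorical' or 'continuous' ('auto' infers from the
    column dtype).  ``random`` lists the grouping factors.  The conventional
    three-level structure is ``ModelSpec.three_level()``: a study intercept
    plus a treatment-within-study intercept, both on top of the known
    sampling variances.
    """

    fixed: str | None = None
    fixed_kind: str = "auto"
    random: tuple[RandomSpec, ...] = ()

    def __post_init__(self) -> None:
        factors = [r.factor for r in self.random]
        if "treatment_key" in factors and "study_id" not in factors:
            raise ModelError(
                "treatment-within-study term requires the study term as well"
            )

    @staticmethod
    def three_level(fixed: str | None = None, fixed_kind: str = "auto") -> "ModelSpec":
        return ModelSpec(
            fixed=fixed,
            fixed_kind=fixed_kind,
            random=(RandomSpec("study_id"), RandomSpec("treatment_key")),
        )

    def with_phylo(self, taxon_column: str, corr: Any) -> "ModelSpec":
        """Add a correlated taxon random term (one phylogeny at a time)."""
        term = RandomSpec(
            factor=taxon_column,
            corr=np.asarray(corr.matrix, dtype=float),
            corr_taxa=tuple(corr.taxa),
        )
        return ModelSpec(self.fixed, self.fixed_kind, self.random + (term,))


@dataclass
class VarianceComponents:
    components: dict[str, float]

    @property
    def total(self) -> float:
        return float(sum(self.components.values()))

    def __getitem__(self, name: str) -> float:
        return self.components[name]


@dataclass
class FitResult:
    """Everything one model fit produces."""

    beta: np.ndarray
    se: np.ndarray
    names: list[str]
    ci_low: np.ndarray
    ci_high: np.ndarray
    cov_beta: np.ndarray
    vc: VarianceComponents
    k: int
    qm: float | None
    qm_df: int | None
    qm_p: float | None
    i2: float | None
    pi_low: float | None
    pi_high: float | None
    reml_loglik: float
    converged: bool
    spec: ModelSpec | None = None
    diagnostics: dict[str, Any] = field(default_factory=dict)

    @property
    def estimate(self) -> float:
        """The first coefficient (the pooled mean for intercept-only fits)."""
        return float(self.beta[0])

    def coef_table(self) -> pd.DataFrame:
        z = self.beta / self.se
        return pd.DataFrame(
            {
                "name": self.names,
                "estimate": self.beta,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
            }
        )


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(
    frame: pd.DataFrame, fixed: str | None, fixed_kind: str = "auto"
) -> tuple[np.ndarray, list[str]]:
    """Intercept-first design matrix for an optional single moderator.

    Categorical moderators use treatment (reference-level) coding with the
    first sorted level as reference, so the omnibus test on the non-intercept
    coefficients has df = levels - 1.
    """
    k = len(frame)
    if fixed is None:
        return np.ones((k, 1)), ["intercept"]
    if fixed not in frame.columns:
        raise ModelError(f"moderator column not found: {fixed!r}")
    col = frame[fixed]
    if fixed_kind == "auto":
        fixed_kind = "continuous" if pd.api.types.is_numeric_dtype(col) else "categorical"
    if fixed_kind == "continuous":
        x = pd.to_numeric(col, errors="raise").to_numpy(dtype=float)
        if np.any(~np.isfinite(x)):
            raise ModelError(f"moderator {fixed!r} contains missing values")
        return np.column_stack([np.ones(k), x]), ["intercept", fixed]
    levels = sorted(col.astype(str).unique())
    if len(levels) < 2:
        raise ModelError(f"moderator {fixed!r} has a single level: {levels}")
    X = np.ones((k, len(levels)))
    names = ["intercept"]
    vals = col.astype(str).to_numpy()
    for j, lev in enumerate(levels[1:], start=1):
        X[:, j] = (vals == lev).astype(float)
        names.append(f"{fixed}[{lev}]")
    return X, names


def _term_codes(
    frame: pd.DataFrame, term: RandomSpec
) -> tuple[np.ndarray, int, np.ndarray | None]:
    """Integer level codes per record for one random term, plus its G matrix."""
    if term.factor == "treatment_key" and "treatment_key" not in frame.columns:
        labels = (
            frame["study_id"].astype(str) + "/" + frame["treatment_id"].astype(str)
        )
    else:
        if term.factor not in frame.columns:
            raise ModelError(f"random factor column not found: {term.factor!r}")
        labels = frame[term.factor].astype(str)
    if labels.isna().any():
        raise ModelError(f"random factor {term.factor!r} contains missing values")
    if term.corr is None:
        codes, _ = pd.factorize(labels, sort=True)
        return codes.astype(np.int64), int(codes.max()) + 1, None
    index = {t: i for i, t in enumerate(term.corr_taxa or ())}
    missing = sorted(set(labels) - set(index))
    if missing:
        raise ModelError(
            f"correlation matrix for {term.factor!r} lacks taxa: {missing[:5]}"
        )
    codes = np.array([index[x] for x in labels], dtype=np.int64)
    G = np.asarray(term.corr, dtype=float)
    return codes, G.shape[0], G


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------

class _REMLProblem:
    """Precomputed structures for repeated REML criterion evaluations."""

    def __init__(
        self,
        y: np.ndarray,
        v: np.ndarray,
        X: np.ndarray,
        terms: list[tuple[np.ndarray, int, np.ndarray | None]],
    ) -> None:
        self.y = y
        self.v = v
        self.X = X
        self.k, self.p = X.shape
        self.terms = terms
        self.q = len(terms)
        dense = any(G is not None for _, _, G in terms)
        if dense or self.q == 0:
            block_ids = [np.arange(self.k)] if self.k else []
        else:
            block_ids = _connected_components(self.k, [t[0] for t in terms])
        # batch blocks of equal size so criterion evaluations use stacked
        # (LAPACK-looped) cholesky/solve calls instead of per-block Python
        by_size: dict[int, list[np.ndarray]] = {}
        for idx in block_ids:
            by_size.setdefault(len(idx), []).append(idx)
        self.batches = []
        for size, idxs in by_size.items():
            nb = len(idxs)
            stack = np.stack(idxs)  # (nb, size)
            Bmat = np.empty((nb, size, self.p + 1))
            Bmat[:, :, : self.p] = X[stack]
            Bmat[:, :, self.p] = y[stack]
            Vdiag = np.zeros((nb, size, size))
            rows = np.arange(size)
            Vdiag[:, rows, rows] = v[stack]
            masks = []
            for codes, _, G in terms:
                sub = codes[stack]  # (nb, size)
                if G is None:
                    masks.append(
                        (sub[:, :, None] == sub[:, None, :]).astype(float)
                    )
                else:
                    masks.append(G[sub[:, :, None], sub[:, None, :]])
            self.batches.append({"Vdiag": Vdiag, "B": Bmat, "masks": masks})

    def criterion(self, sigma2: np.ndarray) -> tuple[float, dict[str, Any]]:
        """-2 * restricted log-likelihood (up to an additive constant)."""
        p = self.p
        A = np.zeros((p, p))
        b = np.zeros(p)
        yy = 0.0
        logdet = 0.0
        for batch in self.batches:
            V = batch["Vdiag"].copy()
            for s2, mask in zip(sigma2, batch["masks"]):
                if s2 > 0:
                    V += s2 * mask
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return np.inf, {}
            size = V.shape[1]
            diag = L[:, np.arange(size), np.arange(size)]
            logdet += 2.0 * float(np.sum(np.log(diag)))
            M = np.linalg.solve(L, batch["B"])  # stacked triangular systems
            G = np.einsum("bij,bik->jk", M, M)
            A += G[:p, :p]
            b += G[:p, p]
            yy += G[p, p]
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf, {}
        try:
            cf = cho_factor(A)
        except np.linalg.LinAlgError:
            return np.inf, {}
        beta = cho_solve(cf, b)
        quad = yy - float(b @ beta)
        crit = logdet + logdetA + quad
        aux = {"beta": beta, "cov_beta": cho_solve(cf, np.eye(p)), "A": A}
        return float(crit), aux


def _connected_components(k: int, code_lists: list[np.ndarray]) -> list[np.ndarray]:
    parent = np.arange(k)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for codes in code_lists:
        first: dict[int, int] = {}
        for i, c in enumerate(codes):
            if c in first:
                union(first[c], i)
            else:
                first[c] = i
    roots: dict[int, list[int]] = {}
    for i in range(k):
        roots.setdefault(find(i), []).append(i)
    return [np.asarray(ix, dtype=np.int64) for ix in roots.values()]


def _optimize_reml(problem: _REMLProblem, var_y: float) -> tuple[np.ndarray, bool]:
    q = problem.q
    mean_v = float(np.mean(problem.v))
    tau0 = max(var_y - mean_v, 0.05 * max(var_y, mean_v), 1e-4)
    starts = [
        np.full(q, tau0 / q),
        np.full(q, 1e-3),
        np.full(q, 0.5 * max(var_y, 1e-3)),
    ]
    upper = np.log(max(100.0, 100.0 * max(var_y, 1.0)))
    bounds = [(_LOG_LOWER, upper)] * q

    def objective(x: np.ndarray) -> float:
        return problem.criterion(np.exp(x))[0]

    best_x, best_val, converged = None, np.inf, False
    for s in starts:
        res = optimize.minimize(
            objective,
            np.log(np.clip(s, 1e-10, None)),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
        )
        if res.fun < best_val:
            best_x, best_val = res.x, float(res.fun)
            converged = bool(res.success) or converged
    s2 = np.exp(best_x)
    # boundary handling: clamp negligible components to exactly zero if that
    # does not worsen the criterion
    tiny = s2 < _ZERO_TOL
    if tiny.any():
        clamped = np.where(tiny, 0.0, s2)
        if problem.criterion(clamped)[0] <= best_val + 1e-9:
            s2 = clamped
    return s2, converged


def fit_multilevel(
    y: Sequence[float] | np.ndarray,
    v: Sequence[float] | np.ndarray,
    spec: ModelSpec,
    data: pd.DataFrame,
) -> FitResult:
    """Fit the multilevel random-effects model defined by ``spec``.

    ``y`` are effect-size values, ``v`` their known sampling variances (all
    positive), and ``data`` the table providing the moderator and grouping
    columns.  Returns a full :class:`FitResult`; non-convergence is reported
    through ``converged`` rather than by raising.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)
    k = len(y)
    if len(v) != k or len(data) != k:
        raise ModelError("y, v and data must have equal length")
    if k == 0:
        raise ModelError("cannot fit a model to zero records")
    if np.any(v <= 0) or np.any(~np.isfinite(v)) or np.any(~np.isfinite(y)):
        raise ModelError("all sampling variances must be positive and finite")

    X, names = build_design(data, spec.fixed, spec.fixed_kind)
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        aliased = _aliased_columns(X, names)
        raise ModelError(f"design matrix is rank deficient; aliased: {aliased}")
    if k < p:
        raise ModelError(f"k={k} records cannot identify {p} coefficients")

    terms = [_term_codes(data, t) for t in spec.random]
    term_names = [t.factor for t in spec.random]
    problem = _REMLProblem(y, v, X, terms)

    converged = True
    if problem.q == 0 or k == p:
        # no estimable heterogeneity: GLS with known variances (closed form)
        sigma2 = np.zeros(problem.q)
    else:
        var_y = float(np.var(y, ddof=1)) if k > 1 else 0.0
        sigma2, converged = _optimize_reml(problem, var_y)

    crit, aux = problem.criterion(sigma2)
    if not aux:
        raise ModelError("REML criterion not evaluable at the optimum")
    beta = aux["beta"]
    cov_beta = aux["cov_beta"]
    se = np.sqrt(np.diag(cov_beta))
    # REML loglik on the usual scale (includes the +0.5 log|X'X| constant, so
    # values are directly comparable with standard meta-analytic software)
    _, logdet_xx = np.linalg.slogdet(X.T @ X)
    ll = -0.5 * (crit + (k - p) * np.log(2.0 * np.pi) - logdet_xx)

    vc = VarianceComponents(
        {name: float(s2) for name, s2 in zip(term_names, sigma2)}
    )
    qm, qm_df, qm_p = _omnibus(beta, cov_beta, names)
    i2 = heterogeneity_i2_value(vc.total, v) if k >= 2 else None

    pi_low = pi_high = None
    if spec.fixed is None:
        half = Z975 * np.sqrt(se[0] ** 2 + vc.total)
        pi_low, pi_high = float(beta[0] - half), float(beta[0] + half)

    return FitResult(
        beta=beta,
        se=se,
        names=names,
        ci_low=beta - Z975 * se,
        ci_high=beta + Z975 * se,
        cov_beta=cov_beta,
        vc=vc,
        k=k,
        qm=qm,
        qm_df=qm_df,
        qm_p=qm_p,
        i2=i2,
        pi_low=pi_low,
        pi_high=pi_high,
        reml_loglik=float(ll),
        converged=converged,
        spec=spec,
    )


def fit_model(dataset_or_frame: Any, spec: ModelSpec, yi: str = "yi", vi: str = "vi") -> FitResult:
    """Convenience wrapper: fit ``spec`` to a dataset/frame carrying yi/vi columns."""
    frame = getattr(dataset_or_frame, "frame", dataset_or_frame)
    if yi not in frame.columns or vi not in frame.columns:
        raise ModelError(
            f"table lacks effect-size columns {yi!r}/{vi!r}; run compute_effect_sizes first"
        )
    return fit_multilevel(frame[yi].to_numpy(), frame[vi].to_numpy(), spec, frame)


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    aliased = []
    keep: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(j)
        else:
            aliased.append(names[j])
    return aliased


def _omnibus(
    beta: np.ndarray, cov_beta: np.ndarray, names: list[str]
) -> tuple[float, int, float]:
    if len(beta) == 1:
        idx = [0]
    else:
        idx = [j for j, n in enumerate(names) if n != "intercept"]
    return omnibus_from_cov(beta, cov_beta, idx)


def omnibus_from_cov(
    beta: np.ndarray, cov_beta: np.ndarray, which: Sequence[int]
) -> tuple[float, int, float]:
    which = list(which)
    if not which:
        raise ModelError("omnibus test requires a nonempty coefficient subset")
    b = beta[which]
    C = cov_beta[np.ix_(which, which)]
    try:
        qm = float(b @ np.linalg.solve(C, b))
    except np.linalg.LinAlgError as exc:
        raise ModelError("singular coefficient covariance in omnibus test") from exc
    df = len(which)
    return qm, df, float(stats.chi2.sf(qm, df))


def omnibus_moderator_test(
    fit: FitResult, which: Sequence[int] | None = None
) -> tuple[float, int, float]:
    """Wald chi-square test that the selected coefficients are jointly zero.

    Defaults to all non-intercept coefficients (the moderator omnibus QM).
    """
    if not fit.converged:
        raise ModelError("omnibus test on a non-converged fit")
    if which is None:
        if len(fit.beta) == 1:
            which = [0]
        else:
            which = [j for j, n in enumerate(fit.names) if n != "intercept"]
    return omnibus_from_cov(fit.beta, fit.cov_beta, which)


def heterogeneity_i2_value(total_sigma2: float, v: np.ndarray) -> float:
    """Multilevel I² (%) given summed variance components and sampling variances.

    Uses the typical sampling variance
    ṽ = (k-1) Σw / ((Σw)² - Σw²) with w_i = 1/v_i.
    """
    v = np.asarray(v, dtype=float)
    k = len(v)
    if k < 2:
        raise ModelError("I² undefined for fewer than 2 effect sizes")
    w = 1.0 / v
    sw = float(np.sum(w))
    v_typ = (k - 1) * sw / (sw**2 - float(np.sum(w**2)))
    return float(100.0 * total_sigma2 / (total_sigma2 + v_typ))


def heterogeneity_i2(fit: FitResult, v: Sequence[float] | np.ndarray) -> float:
    if not fit.converged:
        raise ModelError("I² on a non-converged fit")
    return heterogeneity_i2_value(fit.vc.total, np.asarray(v, dtype=float))


def predict_mean_and_pi(fit: FitResult) -> tuple[tuple[float, float], tuple[float, float]]:
    """95% CI and prediction interval for the pooled mean of an intercept-only fit.

    The prediction interval widens the CI by the summed heterogeneity:
    beta ± z_{.975} sqrt(se² + Σσ²).
    """
    if fit.spec is not None and fit.spec.fixed is not None:
        raise ModelError("prediction interval is defined for intercept-only fits")
    ci = (float(fit.ci_low[0]), float(fit.ci_high[0]))
    half = Z975 * np.sqrt(fit.se[0] ** 2 + fit.vc.total)
    pi = (float(fit.beta[0] - half), float(fit.beta[0] + half))
    return ci, pi
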