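"""Second stage: pooling study-specific curves across studies.

Two pooling routes are provided.  The *metacurve* route evaluates each
study's fitted log hazard-ratio contrast ``f_i(x) - f_i(x0)`` on an
exposure grid and runs a scalar meta-analysis at every grid point, so
each study's weight can vary with exposure and studies may even use
different FP powers.  The *mvmeta* route pools the whole coefficient
vector in one multivariate meta-analysis (common powers required) and
draws the pooled curve from the pooled coefficients, borrowing strength
across the exposure range through the coefficient correlations.

Also here: the categorized-exposure comparator, empirical-Bayes
(shrunken) study curves under the RE model, per-study weight-by-exposure
profiles, and the short-range linear sensitivity meta-analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .basis import FPSpec, contrast_matrix, fp_transform
from .errors import FitError, ValidationError
from .meta import (
    _check_psd,
    pool_multivariate,
    univariate_meta,
)
from .study import StudyData, StudyFit, fit_cox_fp
from .cox import cox_fit

logger = logging.getLogger("fpmeta")


@dataclass
class PooledCurve:
    """Pooled log hazard-ratio curve versus a reference exposure.

    ``estimate`` and ``se`` are exactly zero at ``x0``.  For metacurve
    output ``weights`` holds the per-study normalized weight at every
    grid point (columns sum to 1); mvmeta output keeps its matrix-valued
    study weights on the :class:`MvmetaResult` instead.
    """

    grid: np.ndarray
    x0: float
    estimate: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    method: str                      # "metacurve" | "mvmeta" | "empirical_bayes"
    model: str                       # "ce" | "re"
    level: float = 0.95
    study_ids: list = field(default_factory=list)
    weights: np.ndarray | None = None   # (n_studies, n_grid)
    tau2: np.ndarray | None = None      # per grid point (metacurve RE)
    n_studies: np.ndarray | None = None

    def to_frame(self, include_weights: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "x": self.grid,
                "estimate": self.estimate,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )
        if self.n_studies is not None:
            df["n_studies"] = self.n_studies
        if include_weights and self.weights is not None:
            for sid, row in zip(self.study_ids, self.weights):
                df[f"weight_{sid}"] = row
        return df

    def at(self, x: float) -> float:
        """Pooled estimate at a grid value (nearest grid point)."""
        return float(self.estimate[int(np.argmin(np.abs(self.grid - x)))])


@dataclass
class MvmetaResult:
    """Pooled coefficient vector from multivariate meta-analysis."""

    beta: np.ndarray
    cov: np.ndarray
    between_cov: np.ndarray
    study_weights: list          # list of (m, m) W_i, summing to identity
    spec: FPSpec
    model: str
    study_ids: list = field(default_factory=list)


def _ci(est: np.ndarray, se: np.ndarray, level: float):
    z = stats.norm.ppf(0.5 + level / 2.0)
    return est - z * se, est + z * se


def _prepare_grid(grid, x0: float) -> np.ndarray:
    g = np.atleast_1d(np.asarray(grid, dtype=float))
    if np.any(g <= 0):
        raise ValidationError("grid values must be positive")
    if float(x0) <= 0:
        raise ValidationError("reference exposure must be positive")
    if not np.any(np.isclose(g, x0)):
        g = np.sort(np.append(g, float(x0)))
    return g


def _screen_fits(fits: list[StudyFit]) -> list[StudyFit]:
    kept = []
    for fit in fits:
        if not _check_psd(fit.cov):
            logger.warning(
                "study %s dropped from pooling: covariance not PSD", fit.study_id
            )
            continue
        kept.append(fit)
    if not kept:
        raise ValidationError("no studies with usable covariance matrices")
    return kept


def metacurve_pool(
    fits: list[StudyFit],
    grid,
    x0: float,
    model: str = "ce",
    tau2_method: str = "dl",
    level: float = 0.95,
) -> PooledCurve:
    """Pointwise meta-analysis of study-specific curve contrasts.

    At every grid value ``x`` each study contributes
    ``a_i(x)^T beta_i`` with variance ``a_i(x)^T S_i a_i(x)``, where the
    contrast ``a_i`` is built from that study's own FP spec (study-specific
    powers are allowed).  Scalar CE/RE meta-analysis pools them per point;
    under RE the heterogeneity tau^2 is re-estimated independently at each
    point.  At the reference the contrast is identically zero, so estimate
    and SE are exactly 0 there and weights are reported as uniform.
    """
    fits = _screen_fits(fits)
    g = _prepare_grid(grid, x0)
    n_g = g.size
    I = len(fits)

    est = np.empty((I, n_g))
    var = np.empty((I, n_g))
    for i, fit in enumerate(fits):
        A = contrast_matrix(g, x0, fit.spec)
        est[i] = A @ fit.beta
        var[i] = np.einsum("ij,jk,ik->i", A, fit.cov, A)

    at_ref = np.isclose(g, x0)
    pooled = np.zeros(n_g)
    pooled_var = np.zeros(n_g)
    tau2 = np.zeros(n_g)
    weights = np.full((I, n_g), 1.0 / I)
    for j in range(n_g):
        if at_ref[j]:
            continue
        res = univariate_meta(est[:, j], var[:, j], model=model,
                              tau2_method=tau2_method)
        pooled[j] = res.pooled
        pooled_var[j] = res.pooled_var
        tau2[j] = res.tau2
        weights[:, j] = res.weights

    se = np.sqrt(pooled_var)
    lo, hi = _ci(pooled, se, level)
    lo[at_ref] = 0.0
    hi[at_ref] = 0.0
    return PooledCurve(
        grid=g, x0=float(x0), estimate=pooled, se=se, ci_low=lo, ci_high=hi,
        method="metacurve", model=model, level=level,
        study_ids=[f.study_id for f in fits], weights=weights, tau2=tau2,
        n_studies=np.full(n_g, I),
    )


def mvmeta_pool(
    fits: list[StudyFit],
    model: str = "ce",
    psi_method: str = "reml",
) -> MvmetaResult:
    """Multivariate meta-analysis of the FP coefficient vectors.

    All studies must share one common FP spec.  Under CE the pooled
    vector is the GLS combination with ``V_i = S_i``; under RE the
    between-study covariance is estimated (REML by default) and
    ``V_i = S_i + Psi``.  With a single study RE falls back to CE with a
    warning.
    """
    fits = _screen_fits(fits)
    specs = {fit.spec for fit in fits}
    if len(specs) > 1:
        offenders = ", ".join(
            f"{f.study_id}:{f.spec.label()}" for f in fits
        )
        raise ValidationError(
            "mvmeta pooling requires common powers across studies; got "
            + offenders
        )
    spec = fits[0].spec
    B = np.array([fit.beta for fit in fits])
    S = np.array([fit.cov for fit in fits])
    beta, cov, psi, W = pool_multivariate(B, S, model=model, psi_method=psi_method)
    return MvmetaResult(
        beta=beta, cov=cov, between_cov=psi,
        study_weights=[W[i] for i in range(len(fits))],
        spec=spec, model=model, study_ids=[f.study_id for f in fits],
    )


def curve_from_mvmeta(
    result: MvmetaResult,
    grid,
    x0: float,
    level: float = 0.95,
) -> PooledCurve:
    """Pooled curve ``a(x)^T beta`` with SE ``sqrt(a(x)^T S a(x))``.

    The reference only anchors the plot: re-referencing is an exact
    algebraic shift of the same fitted function.
    """
    g = _prepare_grid(grid, x0)
    A = contrast_matrix(g, x0, result.spec)
    est = A @ result.beta
    var = np.einsum("ij,jk,ik->i", A, result.cov, A)
    se = np.sqrt(np.clip(var, 0.0, None))
    lo, hi = _ci(est, se, level)
    at_ref = np.isclose(g, x0)
    est[at_ref] = 0.0
    se[at_ref] = 0.0
    lo[at_ref] = 0.0
    hi[at_ref] = 0.0
    return PooledCurve(
        grid=g, x0=float(x0), estimate=est, se=se, ci_low=lo, ci_high=hi,
        method="mvmeta", model=result.model, level=level,
        study_ids=list(result.study_ids),
        n_studies=np.full(g.size, len(result.study_ids)),
    )


def empirical_bayes_curves(
    fits: list[StudyFit],
    result: MvmetaResult,
    grid,
    x0: float,
    level: float = 0.95,
) -> list[PooledCurve]:
    """Empirical-Bayes (BLUP) study curves under the RE model.

    Each study's coefficients are shrunk towards the pooled mean,

        beta_i_eb = beta + Psi (Psi + S_i)^{-1} (beta_i - beta),

    with more shrinkage for noisier studies; the shrunken curves expose
    which studies drive estimated heterogeneity.  Requires an RE result
    (a CE fit has no shrinkage target distribution).
    """
    if result.model != "re":
        raise ValidationError("empirical Bayes curves require an RE mvmeta result")
    psi = result.between_cov
    curves = []
    for fit in fits:
        gain = psi @ np.linalg.inv(psi + fit.cov)
        b_eb = result.beta + gain @ (fit.beta - result.beta)
        # conditional covariance of the study effect given its estimate
        cov_eb = psi - gain @ psi
        g = _prepare_grid(grid, x0)
        A = contrast_matrix(g, x0, fit.spec)
        est = A @ b_eb
        se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", A, cov_eb, A), 0.0, None))
        lo, hi = _ci(est, se, level)
        at_ref = np.isclose(g, x0)
        est[at_ref] = 0.0
        se[at_ref] = 0.0
        lo[at_ref] = 0.0
        hi[at_ref] = 0.0
        curves.append(
            PooledCurve(
                grid=g, x0=float(x0), estimate=est, se=se, ci_low=lo,
                ci_high=hi, method="empirical_bayes", model="re", level=level,
                study_ids=[fit.study_id],
            )
        )
    return curves


def weight_profiles(curve: PooledCurve) -> pd.DataFrame:
    """Percentage meta-analysis weight of each study along the grid.

    Only defined for metacurve output (mvmeta weights are matrices, not
    pointwise scalars).  Rows are studies, columns grid values; each
    column sums to 100.
    """
    if curve.method != "metacurve" or curve.weights is None:
        raise ValidationError(
            "weight profiles are defined for metacurve-pooled curves only"
        )
    return pd.DataFrame(
        curve.weights * 100.0, index=curve.study_ids, columns=curve.grid
    )


# ---------------------------------------------------------------------------
# categorized-exposure comparator

@dataclass
class CategoryPooling:
    """Pooled per-category log hazard ratios versus the reference group."""

    table: pd.DataFrame          # category, low, high, estimate, se, ci, n_studies
    cuts: np.ndarray
    reference: int               # index of the reference category
    model: str
    joint: bool


def categorize_pool(
    studies: list[StudyData],
    K: int,
    x0: float,
    model: str = "ce",
    joint: bool = False,
    level: float = 0.95,
    ties: str = "breslow",
) -> CategoryPooling:
    """Pool per-category log hazard ratios from K quantile groups.

    Cut points are quantiles of the pooled (all-study) exposure; the
    reference is the category containing ``x0``.  Each study is fitted
    with K-1 dummies plus its confounders; a category with no events in a
    study contributes a missing cell there.  Pooling is per-category
    scalar meta-analysis, or joint multivariate meta-analysis of the
    dummy-coefficient vector when ``joint=True`` (missing cells enter
    with inflated variance, so they carry no weight).
    """
    if K < 2:
        raise ValidationError(f"K must be >= 2, got {K}")
    pooled_x = np.concatenate([s.exposure for s in studies])
    cuts = np.unique(np.quantile(pooled_x, np.linspace(0, 1, K + 1)[1:-1]))
    if cuts.size < K - 1:
        logger.warning("duplicate quantile cut points; using %d categories",
                       cuts.size + 1)
    n_cat = cuts.size + 1
    ref = int(np.searchsorted(cuts, float(x0), side="right"))

    est = np.full((len(studies), n_cat), np.nan)
    var = np.full((len(studies), n_cat), np.nan)
    cov_blocks: list[dict] = []
    for si, study in enumerate(studies):
        cat = np.searchsorted(cuts, study.exposure, side="right")
        present = [
            k for k in range(n_cat)
            if k != ref and study.event[cat == k].sum() > 0
        ]
        if not np.any(cat == ref) or study.event[cat == ref].sum() == 0:
            logger.warning(
                "study %s dropped from categorized pooling: reference "
                "category has no events", study.study_id)
            cov_blocks.append({})
            continue
        D = np.column_stack([(cat == k).astype(float) for k in present])
        X = np.hstack([D, study.confounders])
        try:
            res = cox_fit(X, study.time, study.event, entry=study.entry, ties=ties)
        except FitError as exc:
            logger.warning("study %s dropped from categorized pooling: %s",
                           study.study_id, exc)
            cov_blocks.append({})
            continue
        p = len(present)
        est[si, present] = res.beta[:p]
        var[si, present] = np.diag(res.cov)[:p]
        cov_blocks.append(
            {"present": present, "cov": res.cov[:p, :p]}
        )

    cats = [k for k in range(n_cat) if k != ref]
    dead = [k for k in cats if np.all(np.isnan(est[:, k]))]
    for k in dead:
        logger.warning("category %d has no events in any study; dropped", k)
    cats = [k for k in cats if k not in dead]
    if not cats:
        raise ValidationError("no non-reference category with events")

    if joint:
        big = 1e10
        m = len(cats)
        B = np.zeros((len(studies), m))
        S = np.zeros((len(studies), m, m))
        keep = []
        for si, block in enumerate(cov_blocks):
            if not block:
                continue
            pres = [k for k in block["present"] if k in cats]
            idx = {k: j for j, k in enumerate(block["present"])}
            pos = [cats.index(k) for k in pres]
            S[si] = np.eye(m) * big
            for a, ka in enumerate(pres):
                B[si, pos[a]] = est[si, ka]
                for b, kb in enumerate(pres):
                    S[si, pos[a], pos[b]] = block["cov"][idx[ka], idx[kb]]
            keep.append(si)
        beta, cov, psi, _ = pool_multivariate(
            B[keep], S[keep], model=model
        )
        pooled = beta
        pooled_se = np.sqrt(np.diag(cov))
        n_st = [int(np.sum(~np.isnan(est[:, k]))) for k in cats]
    else:
        pooled = np.empty(len(cats))
        pooled_se = np.empty(len(cats))
        n_st = []
        for j, k in enumerate(cats):
            mask = ~np.isnan(est[:, k])
            res = univariate_meta(est[mask, k], var[mask, k], model=model)
            pooled[j] = res.pooled
            pooled_se[j] = np.sqrt(res.pooled_var)
            n_st.append(int(mask.sum()))

    edges = np.concatenate([[pooled_x.min()], cuts, [pooled_x.max()]])
    rows = []
    z = stats.norm.ppf(0.5 + level / 2.0)
    for j, k in enumerate(cats):
        rows.append({
            "category": k, "low": edges[k], "high": edges[k + 1],
            "estimate": pooled[j], "se": pooled_se[j],
            "ci_low": pooled[j] - z * pooled_se[j],
            "ci_high": pooled[j] + z * pooled_se[j],
            "n_studies": n_st[j], "reference": False,
        })
    rows.append({
        "category": ref, "low": edges[ref], "high": edges[ref + 1],
        "estimate": 0.0, "se": 0.0, "ci_low": 0.0, "ci_high": 0.0,
        "n_studies": len(studies), "reference": True,
    })
    table = pd.DataFrame(rows).sort_values("category").reset_index(drop=True)
    return CategoryPooling(table=table, cuts=cuts, reference=ref,
                           model=model, joint=joint)


# ---------------------------------------------------------------------------
# short-range linear sensitivity analysis

@dataclass
class LinearRangeMeta:
    """Pooled linear slope within a short exposure window."""

    pooled: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    forest: pd.DataFrame    # study_id, estimate, se, weight, n_events


def linear_range_meta(
    studies: list[StudyData],
    x_low: float,
    x_high: float,
    model: str = "re",
    min_events: float = 10,
    level: float = 0.95,
    ties: str = "breslow",
) -> LinearRangeMeta:
    """Univariate meta-analysis of linear slopes within [x_low, x_high].

    Participants outside the window are discarded; studies contributing
    ``min_events`` or fewer events inside the window are excluded.  Used
    to probe, without any FP assumption, whether a short stretch of the
    curve really slopes the way the pooled FP curve says it does.
    """
    if not x_low < x_high:
        raise ValidationError("x_low must be below x_high")
    rows = []
    for study in studies:
        mask = (study.exposure >= x_low) & (study.exposure <= x_high)
        n_ev = int(study.event[mask].sum())
        if n_ev <= min_events or mask.sum() < 2:
            continue
        sub = StudyData(
            study_id=study.study_id,
            time=study.time[mask], event=study.event[mask],
            exposure=study.exposure[mask],
            confounders=study.confounders[mask],
            entry=None if study.entry is None else study.entry[mask],
        )
        try:
            fit = fit_cox_fp(sub, FPSpec((1.0,)), ties=ties)
        except FitError as exc:
            logger.warning("study %s excluded from range meta-analysis: %s",
                           study.study_id, exc)
            continue
        rows.append({
            "study_id": study.study_id,
            "estimate": float(fit.beta[0]),
            "se": float(np.sqrt(fit.cov[0, 0])),
            "n_events": n_ev,
        })
    if not rows:
        raise ValidationError(
            f"no studies with more than {min_events} events in "
            f"[{x_low}, {x_high}]"
        )
    forest = pd.DataFrame(rows)
    res = univariate_meta(forest["estimate"], forest["se"] ** 2, model=model)
    forest["weight"] = res.weights
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = float(np.sqrt(res.pooled_var))
    return LinearRangeMeta(
        pooled=res.pooled, se=se,
        ci_low=res.pooled - z * se, ci_high=res.pooled + z * se,
        tau2=res.tau2, forest=forest,
    )
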