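"""First stage: per-study confounder-adjusted FP Cox fits and model selection.

Each study contributes a proportional-hazards fit of

    log h_ij(t) = log h_0i(t) + basis(x_ij) @ beta_i + c_ij @ gamma_i

where ``basis`` is a fractional-polynomial transform of the exposure and
``c`` the confounder columns (passed as-is: their functional form is the
caller's subject-matter decision).  Degree and power selection operate on
the cross-study table of maximized partial log-likelihoods: selection of
the functional form inside single studies is biased towards simple shapes,
so powers are chosen by maximizing the *summed* log-likelihood across
studies, and the FP degree by a closed test on the summed likelihoods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .basis import FPSpec, LINEAR, NULL, fp_transform
from .cox import CoxResult, cox_fit
from .errors import FitError, ValidationError

logger = logging.getLogger("fpmeta")


@dataclass
class StudyData:
    """Individual participant data for one study.

    ``confounders`` is an (n, q) matrix (possibly q = 0); ``entry`` is an
    optional delayed-entry time column.  Exposure must be strictly
    positive (after winsorization) before FP transforms are applied; this
    is enforced at fit time so partially-clean data can still be loaded.
    """

    study_id: str
    time: np.ndarray
    event: np.ndarray
    exposure: np.ndarray
    confounders: np.ndarray | None = None
    confounder_names: tuple[str, ...] | None = None
    entry: np.ndarray | None = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.exposure = np.asarray(self.exposure, dtype=float)
        n = self.time.shape[0]
        if n < 1:
            raise ValidationError(f"study {self.study_id!r} is empty")
        if self.event.shape[0] != n or self.exposure.shape[0] != n:
            raise ValidationError(
                f"study {self.study_id!r}: vector lengths disagree"
            )
        if np.any(self.time <= 0):
            raise ValidationError(
                f"study {self.study_id!r}: follow-up times must be positive"
            )
        if not np.isin(self.event, (0, 1)).all():
            raise ValidationError(
                f"study {self.study_id!r}: event indicators must be 0/1"
            )
        if self.confounders is None:
            self.confounders = np.empty((n, 0))
        else:
            self.confounders = np.atleast_2d(np.asarray(self.confounders, dtype=float))
            if self.confounders.shape[0] != n:
                raise ValidationError(
                    f"study {self.study_id!r}: confounder rows != n"
                )
        if self.entry is not None:
            self.entry = np.asarray(self.entry, dtype=float)

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())


@dataclass
class StudyFit:
    """Estimated FP coefficients for one study.

    ``cov`` is the exposure block of the full inverse observed information
    (confounder coefficients are profiled out as nuisance parameters).
    """

    study_id: str
    spec: FPSpec
    beta: np.ndarray
    cov: np.ndarray
    gamma: np.ndarray
    loglik: float
    n_events: int


def fit_cox_fp(
    data: StudyData,
    spec: FPSpec,
    ties: str = "breslow",
    max_iter: int = 100,
) -> StudyFit:
    """Fit the confounder-adjusted FP Cox model to one study."""
    if not isinstance(spec, FPSpec):
        spec = FPSpec(tuple(spec))
    if data.n_events == 0:
        raise FitError(f"study {data.study_id!r} has zero events")
    B = fp_transform(data.exposure, spec)
    X = np.hstack([B, data.confounders])
    res: CoxResult = cox_fit(
        X, data.time, data.event, entry=data.entry, ties=ties, max_iter=max_iter
    )
    m = spec.degree
    return StudyFit(
        study_id=data.study_id,
        spec=spec,
        beta=res.beta[:m].copy(),
        cov=res.cov[:m, :m].copy(),
        gamma=res.beta[m:].copy(),
        loglik=res.loglik,
        n_events=res.n_events,
    )


@dataclass
class LogLikTable:
    """Cross-study table of maximized partial log-likelihoods.

    ``table`` has one row per study and one column per candidate
    :class:`FPSpec`; cells where a fit failed are NaN with the reason
    recorded in ``failures``.
    """

    table: pd.DataFrame
    failures: dict = field(default_factory=dict)

    def specs(self, degree: int | None = None) -> list[FPSpec]:
        out = [s for s in self.table.columns]
        if degree is not None:
            out = [s for s in out if s.degree == degree]
        return out

    def complete_specs(self, degree: int | None = None) -> list[FPSpec]:
        """Specs with a log-likelihood for every study (comparable sums)."""
        cols = self.specs(degree)
        ok = [s for s in cols if not self.table[s].isna().any()]
        dropped = set(cols) - set(ok)
        for s in dropped:
            logger.warning(
                "spec %s dropped from common selection (missing fits)", s.label()
            )
        return ok

    def summed(self, spec: FPSpec) -> float:
        return float(self.table[spec].sum())


def profile_logliks(
    studies: list[StudyData],
    specs: list[FPSpec],
    ties: str = "breslow",
) -> LogLikTable:
    """Fit every spec to every study and tabulate the log-likelihoods.

    Fit failures are recorded as missing cells (with the reason), never
    raised: downstream selection decides how to handle incomplete specs.
    """
    specs = [s if isinstance(s, FPSpec) else FPSpec(tuple(s)) for s in specs]
    ids = [s.study_id for s in studies]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate study_id values")
    cells: dict[FPSpec, dict[str, float]] = {spec: {} for spec in specs}
    failures: dict = {}
    for study in studies:
        for spec in specs:
            try:
                fit = fit_cox_fp(study, spec, ties=ties)
                cells[spec][study.study_id] = fit.loglik
            except FitError as exc:
                cells[spec][study.study_id] = np.nan
                failures[(study.study_id, spec)] = str(exc)
                logger.warning(
                    "study %s, spec %s: fit failed (%s)",
                    study.study_id, spec.label(), exc,
                )
    table = pd.DataFrame(
        {spec: pd.Series(vals, dtype=float) for spec, vals in cells.items()}
    ).reindex(index=sorted(ids))
    table.columns = pd.Index(specs, tupleize_cols=False)
    return LogLikTable(table=table, failures=failures)


def _argmax_spec(candidates: list[tuple[FPSpec, float]]) -> FPSpec:
    """Highest log-likelihood; ties broken by smallest power tuple."""
    best = max(ll for _, ll in candidates)
    tied = [s for s, ll in candidates if ll >= best - 0.0]
    return min(tied, key=lambda s: s.powers)


def select_common_powers(logliks: LogLikTable, degree: int) -> FPSpec:
    """The degree-m spec maximizing the summed log-likelihood across studies."""
    specs = logliks.complete_specs(degree)
    if not specs:
        raise ValidationError(
            f"no complete degree-{degree} specs available for selection"
        )
    return _argmax_spec([(s, logliks.summed(s)) for s in specs])


def select_study_specific_powers(
    logliks: LogLikTable, degree: int
) -> dict[str, FPSpec]:
    """Per-study argmax analogue of :func:`select_common_powers`."""
    specs = logliks.specs(degree)
    if not specs:
        raise ValidationError(f"no degree-{degree} specs in table")
    out: dict[str, FPSpec] = {}
    for study_id, row in logliks.table.iterrows():
        avail = [(s, row[s]) for s in specs if np.isfinite(row[s])]
        if not avail:
            raise ValidationError(
                f"study {study_id!r} has no successful degree-{degree} fit"
            )
        out[study_id] = _argmax_spec(avail)
    return out


def select_degree(logliks: LogLikTable, alpha: float = 0.05):
    """Closed test for the FP degree on summed partial log-likelihoods.

    Tests, in order, best-FP2 against the no-exposure model, against the
    linear model, and against best-FP1, each on twice the difference of
    summed log-likelihoods.  Returns 0 (no exposure effect), ``"linear"``,
    1, or 2.

    Because each of the I studies carries its own coefficient vector, the
    summed comparison has study-specific-parameter degrees of freedom plus
    the usual one per selected power: FP2 vs null uses 2I + 2 df, FP2 vs
    linear I + 2, and FP2 vs FP1 I + 1 (the single-study convention
    4 / 3 / 2 at I = 1).

    The table must contain the null spec, the linear spec, and complete
    degree-1 and degree-2 candidates.
    """
    if not (0 < alpha <= 1):
        raise ValidationError(f"alpha must be in (0, 1], got {alpha}")
    cols = set(logliks.table.columns)
    if NULL not in cols or LINEAR not in cols:
        raise ValidationError(
            "degree selection needs the null and linear specs in the table"
        )
    ll_null = logliks.summed(NULL)
    ll_lin = logliks.summed(LINEAR)
    best1 = select_common_powers(logliks, 1)
    best2 = select_common_powers(logliks, 2)
    ll_1 = logliks.summed(best1)
    ll_2 = logliks.summed(best2)

    n_studies = logliks.table.shape[0]

    def pval(ll_big, ll_small, df):
        lr = max(0.0, 2.0 * (ll_big - ll_small))
        return float(stats.chi2.sf(lr, df))

    if not pval(ll_2, ll_null, 2 * n_studies + 2) < alpha:
        return 0
    if not pval(ll_2, ll_lin, n_studies + 2) < alpha:
        return "linear"
    if not pval(ll_2, ll_1, n_studies + 1) < alpha:
        return 1
    return 2
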