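"""Cox proportional-hazards partial-likelihood engine.

A compact Newton-Raphson maximizer of the Cox partial likelihood used by
the per-study (first-stage) fits.  Breslow's tie approximation is the
default, matching the convention of the Stata survival tooling this
package's workflow descends from; Efron's is available for data with
heavily tied event times.  Delayed entry (left truncation) is supported
through an optional entry-time column: a subject is at risk at event time
``t`` when ``entry < t <= time``.

All risk-set sums are evaluated with sorted reverse cumulative sums, so a
full likelihood/score/information evaluation is O(n log n + n p^2) with
O(n p) memory; the Efron correction loops only over tied event times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConvergenceError, FitError, RankError


@dataclass
class CoxResult:
    """Maximum partial-likelihood estimate and observed information."""

    beta: np.ndarray          # (p,) coefficients
    cov: np.ndarray           # (p, p) inverse observed information
    loglik: float             # maximized partial log-likelihood
    n_events: int
    n_iter: int
    converged: bool
    score: np.ndarray         # score vector at the optimum


def _revcumsum(a: np.ndarray) -> np.ndarray:
    return np.cumsum(a[::-1], axis=0)[::-1]


class _CoxData:
    """Pre-sorted views of the data reused across Newton iterations."""

    def __init__(self, X, time, event, entry=None):
        X = np.ascontiguousarray(X, dtype=float)
        time = np.asarray(time, dtype=float)
        event = np.asarray(event)
        if X.ndim != 2 or X.shape[0] != time.shape[0]:
            raise FitError("design matrix and time vector shapes disagree")
        order = np.argsort(time, kind="stable")
        self.X = X[order]
        self.t = time[order]
        self.d = event[order].astype(bool)
        self.n, self.p = self.X.shape
        self.n_events = int(self.d.sum())
        # first index of each tie group, per row
        self.first = np.searchsorted(self.t, self.t, side="left")
        self.ev_idx = np.where(self.d)[0]
        self.ev_first = self.first[self.ev_idx]
        if entry is not None:
            entry = np.asarray(entry, dtype=float)[order]
            if np.any(entry >= self.t):
                raise FitError("entry times must precede follow-up times")
            eorder = np.argsort(entry, kind="stable")
            self.entry_sorted = entry[eorder]
            self.entry_perm = eorder
            self.entry = entry
        else:
            self.entry_sorted = None
            self.entry_perm = None
            self.entry = None


def _risk_sums(dat: _CoxData, w: np.ndarray, Xw: np.ndarray):
    """S0 and S1 over the risk set of each event, via reverse cumsums."""
    R0 = _revcumsum(w)
    R1 = _revcumsum(Xw)
    S0 = R0[dat.ev_first]
    S1 = R1[dat.ev_first]
    if dat.entry_sorted is not None:
        we = w[dat.entry_perm]
        E0 = np.concatenate([_revcumsum(we), [0.0]])
        E1 = np.vstack([_revcumsum(Xw[dat.entry_perm]), np.zeros(dat.p)])
        pos = np.searchsorted(dat.entry_sorted, dat.t[dat.ev_idx], side="left")
        S0 = S0 - E0[pos]
        S1 = S1 - E1[pos]
    return S0, S1


def _evaluate(dat: _CoxData, beta: np.ndarray, ties: str, need_hess: bool):
    """Partial log-likelihood, score and observed information at ``beta``."""
    lp = dat.X @ beta if dat.p else np.zeros(dat.n)
    shift = lp.max() if dat.n else 0.0  # location shift cancels exactly
    w = np.exp(lp - shift)
    Xw = dat.X * w[:, None]
    S0, S1 = _risk_sums(dat, w, Xw)
    m = S1 / S0[:, None]

    loglik = float(np.sum(lp[dat.ev_idx] - shift - np.log(S0)))
    score = dat.X[dat.ev_idx].sum(axis=0) - m.sum(axis=0)

    info = None
    if need_hess:
        # sum_events S2/S0 == sum_j w_j c_j x_j x_j^T with c_j the
        # cumulated 1/S0 over event times at which subject j is at risk.
        inv = 1.0 / S0
        ev_t = dat.t[dat.ev_idx]
        cum = np.concatenate([[0.0], np.cumsum(inv)])
        c = cum[np.searchsorted(ev_t, dat.t, side="right")]
        if dat.entry is not None:
            c = c - cum[np.searchsorted(ev_t, dat.entry, side="right")]
        info = (dat.X * (w * c)[:, None]).T @ dat.X - m.T @ m

    if ties == "efron":
        loglik, score, info = _efron_correct(
            dat, w, Xw, S0, S1, loglik, score, info, need_hess
        )
    return loglik, score, info


def _efron_correct(dat, w, Xw, S0, S1, loglik, score, info, need_hess):
    """Replace Breslow terms by Efron terms within tied event-time groups."""
    ev_first = dat.ev_first
    uniq, start, counts = np.unique(ev_first, return_index=True, return_counts=True)
    for g, (f, cnt) in enumerate(zip(uniq, counts)):
        if cnt < 2:
            continue
        tied = dat.ev_idx[ev_first == f]
        s0 = w[tied].sum()
        s1 = Xw[tied].sum(axis=0)
        S0g, S1g = S0[start[g]], S1[start[g]]
        mg = S1g / S0g
        frac = np.arange(cnt) / cnt
        S0k = S0g - frac * s0
        S1k = S1g[None, :] - frac[:, None] * s1[None, :]
        mk = S1k / S0k[:, None]
        loglik += cnt * np.log(S0g) - np.log(S0k).sum()
        score += cnt * mg - mk.sum(axis=0)
        if need_hess:
            at_risk = dat.t >= dat.t[tied[0]]
            if dat.entry is not None:
                at_risk &= dat.entry < dat.t[tied[0]]
            Xr = dat.X[at_risk]
            S2g = (Xr * w[at_risk][:, None]).T @ Xr
            s2 = (dat.X[tied] * w[tied][:, None]).T @ dat.X[tied]
            breslow = cnt * (S2g / S0g - np.outer(mg, mg))
            efron = sum(
                (S2g - frac[k] * s2) / S0k[k] - np.outer(mk[k], mk[k])
                for k in range(cnt)
            )
            info += efron - breslow
    return loglik, score, info


def cox_fit(
    X,
    time,
    event,
    entry=None,
    ties: str = "breslow",
    max_iter: int = 100,
    loglik_tol: float = 1e-9,
    score_tol: float = 1e-6,
) -> CoxResult:
    """Maximize the Cox partial likelihood by Newton-Raphson.

    Starts from ``beta = 0`` with step-halving on any likelihood decrease;
    converges when the relative log-likelihood change falls below
    ``loglik_tol`` and the largest score component (on the internally
    standardized covariate scale) falls below ``score_tol`` per event.

    Raises
    ------
    FitError : no events in the data.
    RankError : singular observed information (collinear design).
    ConvergenceError : iteration limit reached; carries the last iterate.
    """
    if ties not in ("breslow", "efron"):
        raise FitError(f"unknown ties method {ties!r}")
    # standardize columns internally: the partial likelihood is invariant
    # to centering, and unit-scale columns make the score tolerance
    # meaningful and the information well conditioned (x and x^2 columns
    # are otherwise nearly collinear for BMI-like exposures)
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0) if X.size else np.zeros(X.shape[1])
    sd = X.std(axis=0) if X.size else np.ones(X.shape[1])
    sd = np.where(sd > 0, sd, 1.0)
    dat = _CoxData((X - mu) / sd, time, event, entry)
    if dat.n_events == 0:
        raise FitError("cannot fit a Cox model to data with zero events")

    if dat.p == 0:
        loglik, _, _ = _evaluate(dat, np.zeros(0), ties, need_hess=False)
        return CoxResult(
            beta=np.zeros(0), cov=np.zeros((0, 0)), loglik=loglik,
            n_events=dat.n_events, n_iter=0, converged=True, score=np.zeros(0),
        )

    beta = np.zeros(dat.p)
    loglik, score, info = _evaluate(dat, beta, ties, need_hess=True)
    n_iter = 0
    converged = False
    # the score criterion is per event: an absolute bound is unattainable
    # in float64 once risk-set sums run over tens of thousands of subjects
    score_bound = score_tol * max(1, dat.n_events)
    for n_iter in range(1, max_iter + 1):
        if not np.all(np.isfinite(info)):
            raise RankError("non-finite information matrix")
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise RankError(f"singular information matrix: {exc}") from exc
        # step-halving
        new_beta, new_ll = beta, loglik
        for _ in range(40):
            cand = beta + step
            cand_ll, _, _ = _evaluate(dat, cand, ties, need_hess=False)
            if np.isfinite(cand_ll) and cand_ll >= loglik - 1e-12:
                new_beta, new_ll = cand, cand_ll
                break
            step = step / 2.0
        else:
            break  # no improving step found
        rel_change = abs(new_ll - loglik) / (abs(loglik) + 1.0)
        beta = new_beta
        loglik, score, info = _evaluate(dat, beta, ties, need_hess=True)
        if rel_change < loglik_tol and np.max(np.abs(score)) < score_bound:
            converged = True
            break

    if not converged:
        raise ConvergenceError(
            f"Newton-Raphson did not converge in {n_iter} iterations "
            f"(max |score| = {np.max(np.abs(score)):.3g})",
            beta=beta / sd, loglik=loglik, n_iter=n_iter,
        )
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise RankError(f"singular information at optimum: {exc}") from exc
    # back-transform to the original column scale
    beta = beta / sd
    cov = cov / np.outer(sd, sd)
    return CoxResult(
        beta=beta, cov=cov, loglik=loglik, n_events=dat.n_events,
        n_iter=n_iter, converged=True, score=score,
    )
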