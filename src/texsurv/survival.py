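"""Survival primitives: Kaplan-Meier, log-rank, Cox proportional hazards.

These are implemented from first principles (product-limit estimator,
pooled-ties log-rank with hypergeometric variance, Newton-Raphson
maximisation of the Efron partial likelihood) because every discovery
step downstream — the optimised cutoff search, the cross-validated
recombined test, the multivariate model — reuses exactly these
operations, including a vectorised all-candidate log-rank scan that must
agree with the scalar test to machine precision.

Conventions:

- times are in months, strictly positive; ``event`` is 1 for death and 0
  for right censoring;
- censored subjects sharing a time with deaths are counted at risk for
  those deaths;
- tied death times are pooled within a time point (log-rank) and handled
  with the Efron correction (Cox); Breslow is available by option;
- confidence intervals and p-values are Wald, matching the two-sided 95%
  hazard-ratio reporting convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "KMCurve",
    "LogrankResult",
    "CoxPH",
    "CoxPHResults",
    "km_estimate",
    "logrank_test",
    "logrank_scan",
    "binary_group_hr",
    "BinaryGroupHR",
]


def _validate_surv(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.ndim != 1 or event.shape != time.shape:
        raise ValueError("time and event must be 1-D arrays of equal length")
    if time.size == 0:
        raise ValueError("no subjects")
    if not np.all(np.isfinite(time)) or np.any(time <= 0):
        raise ValueError("survival times must be finite and positive")
    if not np.all(np.isin(event, (0, 1))):
        raise ValueError("event indicator must be 0 (censored) or 1 (death)")
    return time, event.astype(int)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve, defined at the observed event times."""

    event_times: np.ndarray  # distinct death times, ascending
    survival: np.ndarray  # S(t) just after each event time
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function evaluation; S = 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    @property
    def median(self) -> float:
        """Smallest event time with S(t) <= 0.5; NaN if never reached."""
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.event_times[below[0]]) if below.size else float("nan")

    def plot(self, ax=None, label: str | None = None, **kwargs):
        """Step plot of the survival curve (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.concatenate([[0.0], self.event_times])
        s = np.concatenate([[1.0], self.survival])
        ax.step(t, s, where="post", label=label, **kwargs)
        ax.set_xlabel("time (months)")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.05)
        if label:
            ax.legend()
        return ax


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimate from right-censored data."""
    time, event = _validate_surv(time, event)
    t_sorted = np.sort(time)
    death_times, n_events = np.unique(time[event == 1], return_counts=True)
    n_at_risk = time.size - np.searchsorted(t_sorted, death_times, side="left")
    surv = np.cumprod(1.0 - n_events / n_at_risk)
    return KMCurve(death_times, surv, n_at_risk.astype(int), n_events.astype(int))


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogrankResult:
    chi2: float
    p: float
    observed: float  # deaths observed in group 1
    expected: float  # deaths expected in group 1 under H0


def _risk_death_tables(time: np.ndarray, event: np.ndarray):
    """Indicator matrices over distinct death times.

    Returns ``(death_times, R, D)`` with ``R[i, j] = 1`` if subject i is at
    risk at death time j and ``D[i, j] = 1`` if subject i dies at it.
    """
    death_times = np.unique(time[event == 1])
    R = time[:, None] >= death_times[None, :]
    D = (time[:, None] == death_times[None, :]) & (event[:, None] == 1)
    return death_times, R.astype(float), D.astype(float)


def logrank_scan(time, event, membership: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-group log-rank statistics for many candidate group-1 memberships.

    ``membership`` is a (n_candidates, n_subjects) boolean matrix; row c
    defines group 1 of candidate c.  Returns ``(chi2, o_minus_e)`` arrays;
    ``o_minus_e > 0`` means group 1 sees more deaths than expected (worse
    survival).  Degenerate candidates (zero variance, e.g. a group that is
    empty or everyone) get chi2 = 0.

    This is the same statistic as :func:`logrank_test` (pooled ties,
    hypergeometric variance), evaluated for all rows at once.
    """
    time, event = _validate_surv(time, event)
    Z = np.asarray(membership, dtype=float)
    if Z.ndim != 2 or Z.shape[1] != time.size:
        raise ValueError("membership must be (n_candidates, n_subjects)")
    if event.sum() == 0:
        raise ValueError("no events: log-rank undefined")
    _, R, D = _risk_death_tables(time, event)
    d = D.sum(axis=0)  # total deaths per death time
    n = R.sum(axis=0)  # total at risk
    N1 = Z @ R  # (C, T) group-1 at risk
    D1 = Z @ D  # (C, T) group-1 deaths
    O = D1.sum(axis=1)
    frac = N1 / n
    E = (d * frac).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vterm = d * frac * (1.0 - frac) * (n - d) / (n - 1.0)
    vterm = np.where(n > 1, vterm, 0.0)
    V = vterm.sum(axis=1)
    diff = O - E
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(V > 0, diff**2 / V, 0.0)
    return chi2, diff


def logrank_test(time, event, group) -> LogrankResult:
    """Two-group log-rank test (pooled ties, hypergeometric variance).

    ``group`` is a boolean/0-1 vector marking group 1; both groups must be
    non-empty.  The p-value is the chi-square(1) upper tail.
    """
    time, event = _validate_surv(time, event)
    group = np.asarray(group).astype(bool)
    if group.shape != time.shape:
        raise ValueError("group labels must match subjects")
    if group.all() or not group.any():
        raise ValueError("log-rank requires two non-empty groups")
    chi2, diff = logrank_scan(time, event, group[None, :])
    chi2, diff = float(chi2[0]), float(diff[0])
    _, R, D = _risk_death_tables(time, event)
    observed = float((D[group]).sum())
    expected = observed - diff
    p = float(sps.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    return LogrankResult(chi2=chi2, p=p, observed=observed, expected=expected)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoxPHResults:
    """Newton-Raphson fit of the Cox partial likelihood.

    ``params`` are log-hazard coefficients; HR = exp(params); CIs and
    p-values are Wald.  ``converged`` is False for monotone likelihoods
    (perfect separation) — estimates are then not trustworthy and are
    reported only with the flag.
    """

    params: np.ndarray
    bse: np.ndarray
    names: list[str]
    loglik: float
    n_iter: int
    converged: bool
    ties: str

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.params)

    @property
    def conf_int(self) -> np.ndarray:
        """95% Wald CI for the hazard ratios, shape (k, 2)."""
        z = sps.norm.ppf(0.975)
        lo = np.exp(self.params - z * self.bse)
        hi = np.exp(self.params + z * self.bse)
        return np.column_stack([lo, hi])

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * sps.norm.sf(np.abs(self.zvalues))

    def summary(self) -> "pd.DataFrame":
        import pandas as pd

        ci = self.conf_int
        return pd.DataFrame(
            {
                "coef": self.params,
                "se(coef)": self.bse,
                "HR": self.hazard_ratios,
                "HR 95% low": ci[:, 0],
                "HR 95% high": ci[:, 1],
                "z": self.zvalues,
                "p": self.pvalues,
            },
            index=self.names,
        )

    def to_dict(self) -> dict:
        ci = self.conf_int
        return {
            "converged": self.converged,
            "loglik": self.loglik,
            "ties": self.ties,
            "covariates": {
                name: {
                    "coef": float(self.params[i]),
                    "se": float(self.bse[i]),
                    "hr": float(self.hazard_ratios[i]),
                    "ci95": [float(ci[i, 0]), float(ci[i, 1])],
                    "p": float(self.pvalues[i]),
                }
                for i, name in enumerate(self.names)
            },
        }


class CoxPH:
    """Cox proportional-hazards model for right-censored data.

    Parameters
    ----------
    time, event : array-like
        Months of follow-up and death indicator per subject.
    X : array-like, shape (n, k)
        Covariate matrix (binary marker indicators in the discovery
        pipeline; continuous covariates work equally).
    names : list of str, optional
        Covariate names for reporting.
    ties : ``"efron"`` (default) or ``"breslow"``
        Tied-death handling; monthly-resolution follow-up makes ties
        likely, so Efron is the default.
    """

    def __init__(self, time, event, X, names=None, ties: str = "efron"):
        self.time, self.event = _validate_surv(time, event)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != self.time.size:
            X = X.T
        if X.shape[0] != self.time.size:
            raise ValueError("X must have one row per subject")
        if self.event.sum() == 0:
            raise ValueError("Cox fit requires at least one event")
        if ties not in ("efron", "breslow"):
            raise ValueError(f"unknown tie handling {ties!r}")
        # collinearity guard: rank-deficient design has no unique maximiser
        if np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
            raise ValueError("covariates are collinear-degenerate")
        self.X = X
        self.names = list(names) if names is not None else [
            f"x{i}" for i in range(X.shape[1])
        ]
        self.ties = ties
        self._prepare()

    # -- partial likelihood machinery -------------------------------------
    #
    # Everything is precomputed on time-sorted data; risk-set sums are
    # reverse cumulative sums indexed by searchsorted, and the Efron
    # within-tie corrections are expanded to one row per death so the whole
    # evaluation is a handful of vectorised reductions.

    def _prepare(self) -> None:
        order = np.argsort(self.time, kind="stable")
        self._t = self.time[order]
        self._e = self.event[order]
        self._X = self.X[order]
        self._dt, self._d = np.unique(self._t[self._e == 1], return_counts=True)
        self._risk_start = np.searchsorted(self._t, self._dt, side="left")
        lo = np.searchsorted(self._t, self._dt, side="left")
        hi = np.searchsorted(self._t, self._dt, side="right")
        self._tie_lo, self._tie_hi = lo, hi
        # Efron fraction l/d for every individual death, grouped by time
        D = int(self._d.sum())
        starts = np.concatenate([[0], np.cumsum(self._d)[:-1]])
        self._frac = (np.arange(D) - np.repeat(starts, self._d)) / np.repeat(
            self._d, self._d
        )
        if self.ties == "breslow":
            self._frac = np.zeros_like(self._frac)
        self._rep = np.repeat(np.arange(self._dt.size), self._d)

    def _loglik_score_info(self, beta: np.ndarray):
        t, e, X = self._t, self._e, self._X
        k = X.shape[1]
        eta = X @ beta
        eta = eta - eta.max()  # guard overflow; partial lik is shift-invariant
        w = np.exp(eta)
        wX = w[:, None] * X
        wXX = np.einsum("i,ij,il->ijl", w, X, X)

        s0_suf = np.cumsum(w[::-1])[::-1]
        s1_suf = np.cumsum(wX[::-1], axis=0)[::-1]
        s2_suf = np.cumsum(wXX[::-1], axis=0)[::-1]
        s0r = s0_suf[self._risk_start]
        s1r = s1_suf[self._risk_start]
        s2r = s2_suf[self._risk_start]

        we = w * e
        c0 = np.concatenate([[0.0], np.cumsum(we)])
        c1 = np.concatenate([np.zeros((1, k)), np.cumsum(wX * e[:, None], axis=0)])
        c2 = np.concatenate(
            [np.zeros((1, k, k)), np.cumsum(wXX * e[:, None, None], axis=0)]
        )
        s0d = c0[self._tie_hi] - c0[self._tie_lo]
        s1d = c1[self._tie_hi] - c1[self._tie_lo]
        s2d = c2[self._tie_hi] - c2[self._tie_lo]

        rep, frac = self._rep, self._frac
        phi = s0r[rep] - frac * s0d[rep]
        num1 = s1r[rep] - frac[:, None] * s1d[rep]
        num2 = s2r[rep] - frac[:, None, None] * s2d[rep]

        dead = e == 1
        loglik = float(eta[dead].sum() - np.log(phi).sum())
        score = X[dead].sum(axis=0) - (num1 / phi[:, None]).sum(axis=0)
        info = (num2 / phi[:, None, None]).sum(axis=0) - np.einsum(
            "ij,il,i->jl", num1, num1, 1.0 / phi**2
        )
        return loglik, score, info

    def fit(self, max_iter: int = 50, score_tol: float = 1e-8) -> CoxPHResults:
        """Maximise the partial likelihood by damped Newton-Raphson.

        Convergence when ``max |score| < score_tol``; a fit whose
        coefficients run away (monotone likelihood / perfect separation)
        is flagged ``converged=False`` rather than silently reported.
        """
        k = self.X.shape[1]
        beta = np.zeros(k)
        loglik, score, info = self._loglik_score_info(beta)
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            if np.max(np.abs(score)) < score_tol:
                converged = True
                break
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError:
                break
            # step-halving line search on the partial log-likelihood
            for _ in range(30):
                cand = beta + step
                ll_new, sc_new, in_new = self._loglik_score_info(cand)
                if np.isfinite(ll_new) and ll_new >= loglik - 1e-12:
                    break
                step = step / 2.0
            beta, loglik, score, info = cand, ll_new, sc_new, in_new
            if np.max(np.abs(beta)) > 20 or not np.all(np.isfinite(beta)):
                converged = False  # monotone likelihood: coefficient running away
                break
        else:
            converged = bool(np.max(np.abs(score)) < score_tol)
        # a "converged" score at an absurd coefficient is perfect separation,
        # not a maximum worth reporting
        if converged and np.max(np.abs(beta)) > 20:
            converged = False
        try:
            cov = np.linalg.inv(info)
            bse = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            bse = np.full(k, np.nan)
            converged = False
        return CoxPHResults(
            params=beta,
            bse=bse,
            names=self.names,
            loglik=float(loglik),
            n_iter=n_iter,
            converged=converged,
            ties=self.ties,
        )


@dataclass(frozen=True)
class BinaryGroupHR:
    """Hazard ratio of a binary stratification, in reporting format.

    The HR and its 95% CI come from a one-covariate Cox fit on the group
    indicator; the p-value is the two-group log-rank p (the conventional
    pairing when reporting dichotomised markers).
    """

    hr: float
    ci_low: float
    ci_high: float
    logrank_p: float
    n_group1: int
    n_group0: int
    converged: bool

    def __str__(self) -> str:
        return (
            f"HR {self.hr:.2f} ({self.ci_low:.2f}-{self.ci_high:.2f}); "
            f"p = {self.logrank_p:.3g}"
        )


def binary_group_hr(time, event, group, ties: str = "efron") -> BinaryGroupHR:
    """HR + 95% CI (Cox) and log-rank p for a two-group stratification."""
    group = np.asarray(group).astype(bool)
    lr = logrank_test(time, event, group)
    fit = CoxPH(time, event, group.astype(float)[:, None], names=["group"], ties=ties).fit()
    ci = fit.conf_int
    return BinaryGroupHR(
        hr=float(fit.hazard_ratios[0]),
        ci_low=float(ci[0, 0]),
        ci_high=float(ci[0, 1]),
        logrank_p=lr.p,
        n_group1=int(group.sum()),
        n_group0=int((~group).sum()),
        converged=fit.converged,
    )
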