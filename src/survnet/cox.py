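"""Cox proportional-hazards machinery built from first principles.

The subnetwork score is a multivariate Cox model fitted by Newton-Raphson on
the log partial likelihood, with Breslow (default) or Efron handling of tied
event times, tested by a global Wald chi-square statistic

    W = beta' I(beta) beta  ~  chi2(p)  under H0: beta = 0,

where I is the observed information at the optimum.  The greedy search fits
thousands of small models against one fixed survival dataset, so the
risk-set bookkeeping (sort order, tie groups) is precomputed once per cohort
in :class:`CoxEngine` and reused across fits; the engine also accepts a warm
start so each forward-selection step begins from its parent model.

lifelines implements the same model and serves as an independent cross-check
in the test suite; it is never on the computation path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaincc

from survnet.expression_io import SurvivalData

logger = logging.getLogger(__name__)

_MAX_ITER = 50
_GRAD_TOL = 1e-8
_MAX_COND = 1e10
# |beta| beyond this signals monotone likelihood (separation): the partial
# likelihood has no interior maximum and the Wald quantities are meaningless
_MAX_ABS_BETA = 30.0


def chi2_sf(x: float, df: float) -> float:
    """Upper-tail probability of a chi-square distribution.

    Thin wrapper over the regularized upper incomplete gamma function,
    which avoids the per-call overhead of a frozen scipy distribution in
    the inner search loop.
    """
    return float(gammaincc(df / 2.0, x / 2.0))


@dataclass(frozen=True)
class CoxFit:
    """One fitted proportional-hazards model.

    ``beta`` are log hazard ratios per covariate (per expression SD when the
    matrix was z-scored); ``covariance`` is the inverse observed information;
    ``p_value`` is the global Wald test of all coefficients jointly.  A fit
    that failed to converge (flat or ill-conditioned likelihood) is flagged
    ``converged=False`` and carries ``p_value=1.0`` so callers can treat it
    as uninformative rather than crash.
    """

    gene_ids: tuple[str, ...]
    beta: np.ndarray = field(repr=False)
    covariance: np.ndarray = field(repr=False)
    log_partial_likelihood: float
    wald_stat: float
    df: int
    p_value: float
    converged: bool
    n_events: int

    @property
    def se(self) -> np.ndarray:
        """Per-coefficient standard errors."""
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, np.inf))

    @property
    def per_coef_p(self) -> np.ndarray:
        """Per-coefficient Wald P values (chi-square with 1 df)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            z2 = np.where(self.se > 0, (self.beta / self.se) ** 2, np.inf)
        return gammaincc(0.5, z2 / 2.0)


class CoxEngine:
    """Partial-likelihood evaluator bound to one survival dataset.

    Samples are sorted once by decreasing follow-up time; the risk set of an
    event time is then a prefix of the sorted arrays and all risk-set sums
    are cumulative sums.  Tied event times form groups handled by the
    Breslow or Efron approximation.
    """

    def __init__(self, surv: SurvivalData, ties: str = "breslow"):
        if ties not in ("breslow", "efron"):
            raise ValueError(f"unknown tie handling: {ties!r}")
        self.ties = ties
        self.surv = surv
        time = surv.time
        event = surv.event
        if event.sum() == 0:
            raise ValueError("no events in survival data: Cox model undefined")
        self.n = len(time)
        self.n_events = int(event.sum())
        # descending time; stable so results are reproducible under relabeling
        self.order = np.argsort(-time, kind="stable")
        t = time[self.order]
        e = event[self.order]
        self._event_rows = np.flatnonzero(e == 1)
        # contiguous blocks of equal time that contain at least one event
        block_start = np.flatnonzero(np.r_[True, t[1:] != t[:-1]])
        block_end = np.r_[block_start[1:], self.n] - 1
        risk_end, d, grp_ev = [], [], []
        for a, b in zip(block_start, block_end):
            ev = np.flatnonzero(e[a : b + 1] == 1) + a
            if ev.size:
                risk_end.append(b)
                d.append(ev.size)
                grp_ev.append(ev)
        self.risk_end = np.asarray(risk_end)
        self.d = np.asarray(d, dtype=float)
        self._grp_event_rows = grp_ev
        self.has_ties = bool((self.d > 1).any())

    # -- likelihood, gradient, information ---------------------------------

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != self.n:
            raise ValueError("covariate matrix row count != number of samples")
        return X[self.order]

    def loglik(self, Xs: np.ndarray, beta: np.ndarray) -> float:
        """Log partial likelihood at ``beta`` (rows already sorted)."""
        eta = Xs @ beta
        c = eta.max()
        w = np.exp(eta - c)
        cw = np.cumsum(w)
        ll = float(eta[self._event_rows].sum())
        if self.ties == "breslow" or not self.has_ties:
            S0 = cw[self.risk_end]
            ll -= float(self.d @ (np.log(S0) + c))
        else:
            for g, ev in enumerate(self._grp_event_rows):
                S0 = cw[self.risk_end[g]]
                dg = int(self.d[g])
                S0D = w[ev].sum()
                frac = np.arange(dg) / dg
                ll -= float(np.log(S0 - frac * S0D).sum() + dg * c)
        return ll

    def _score_info(
        self, Xs: np.ndarray, beta: np.ndarray
    ) -> tuple[float, np.ndarray, np.ndarray]:
        """(loglik, gradient, observed information) at ``beta``."""
        eta = Xs @ beta
        c = eta.max()
        w = np.exp(eta - c)
        wX = Xs * w[:, None]
        cw = np.cumsum(w)
        cwX = np.cumsum(wX, axis=0)
        sx_ev = Xs[self._event_rows].sum(axis=0)
        ll = float(eta[self._event_rows].sum())
        grad = sx_ev.copy()
        if self.ties == "breslow" or not self.has_ties:
            S0 = cw[self.risk_end]
            S1 = cwX[self.risk_end]
            xbar = S1 / S0[:, None]
            ll -= float(self.d @ (np.log(S0) + c))
            grad -= self.d @ xbar
            # sum_g d_g S2_g / S0_g collapses to a weighted Gram matrix:
            # sample i participates with weight w_i * sum_{g: i in risk set} d_g/S0_g,
            # a suffix cumulation over event groups (risk sets are prefixes
            # of the descending-time sort).
            contrib = np.zeros(self.n)
            np.add.at(contrib, self.risk_end, self.d / S0)
            q = np.cumsum(contrib[::-1])[::-1]
            info = (Xs * (w * q)[:, None]).T @ Xs - (xbar * self.d[:, None]).T @ xbar
        else:
            cwXX = np.cumsum(wX[:, :, None] * Xs[:, None, :], axis=0)
            p = Xs.shape[1]
            info = np.zeros((p, p))
            for g, ev in enumerate(self._grp_event_rows):
                r = self.risk_end[g]
                dg = int(self.d[g])
                S0, S1, S2 = cw[r], cwX[r], cwXX[r]
                S0D = w[ev].sum()
                S1D = wX[ev].sum(axis=0)
                S2D = (wX[ev][:, :, None] * Xs[ev][:, None, :]).sum(axis=0)
                frac = (np.arange(dg) / dg)[:, None]
                phi = S0 - frac[:, 0] * S0D                     # (d,)
                z = S1[None, :] - frac * S1D[None, :]           # (d,p)
                Z = S2[None, :, :] - frac[:, :, None] * S2D     # (d,p,p)
                zbar = z / phi[:, None]
                ll -= float(np.log(phi).sum() + dg * c)
                grad -= zbar.sum(axis=0)
                info += np.einsum("l,lij->ij", 1.0 / phi, Z) - np.einsum(
                    "li,lj->ij", zbar, zbar
                )
        return ll, grad, info

    # -- Newton-Raphson ----------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        gene_ids: tuple[str, ...] | None = None,
        beta0: np.ndarray | None = None,
        max_iter: int = _MAX_ITER,
        tol: float = _GRAD_TOL,
    ) -> CoxFit:
        """Maximize the partial likelihood by damped Newton-Raphson.

        Converges when the gradient max-norm drops below ``tol``; steps that
        would decrease the likelihood are halved (up to 30 times).  A
        singular or ill-conditioned information matrix (condition number
        above 1e10), or failure to reach the tolerance, yields a flagged
        non-converged fit instead of an exception.
        """
        Xs = self._prepare(X)
        p = Xs.shape[1]
        if gene_ids is None:
            gene_ids = tuple(f"x{i}" for i in range(p))
        beta = (
            np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
        )
        if (np.ptp(Xs, axis=0) == 0).any():
            # a constant column carries no information; flag, don't crash
            return CoxFit(
                gene_ids=tuple(gene_ids),
                beta=np.zeros(p),
                covariance=np.full((p, p), np.nan),
                log_partial_likelihood=self.loglik(Xs, np.zeros(p)),
                wald_stat=0.0,
                df=p,
                p_value=1.0,
                converged=False,
                n_events=self.n_events,
            )
        ll, grad, info = self._score_info(Xs, beta)
        converged = False
        for _ in range(max_iter):
            if np.max(np.abs(grad)) <= tol:
                converged = True
                break
            try:
                delta = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError:
                break
            step = 1.0
            for _half in range(30):
                cand = beta + step * delta
                ll_new = self.loglik(Xs, cand)
                if ll_new >= ll - 1e-12:
                    break
                step *= 0.5
            else:
                break
            beta = beta + step * delta
            ll, grad, info = self._score_info(Xs, beta)
        else:
            converged = np.max(np.abs(grad)) <= tol

        cov = np.full((p, p), np.nan)
        wald = 0.0
        if converged and np.max(np.abs(beta)) > _MAX_ABS_BETA:
            converged = False
        if converged:
            # guard against a flat/collinear optimum masquerading as converged;
            # the 1-norm condition estimate avoids an SVD in the hot loop
            try:
                inv = np.linalg.inv(info)
                cond = np.linalg.norm(info, 1) * np.linalg.norm(inv, 1)
            except np.linalg.LinAlgError:
                cond = np.inf
            if not np.isfinite(cond) or cond > _MAX_COND:
                converged = False
            else:
                cov = inv
                wald = float(beta @ info @ beta)
        p_value = chi2_sf(wald, p) if converged else 1.0
        return CoxFit(
            gene_ids=tuple(gene_ids),
            beta=beta,
            covariance=cov,
            log_partial_likelihood=ll,
            wald_stat=wald,
            df=p,
            p_value=p_value,
            converged=converged,
            n_events=self.n_events,
        )


def cox_fit(
    X: np.ndarray | pd.DataFrame,
    surv: SurvivalData,
    ties: str = "breslow",
    beta0: np.ndarray | None = None,
) -> CoxFit:
    """Fit one multivariate Cox model.

    Parameters
    ----------
    X
        samples x p covariate matrix, rows in ``surv.sample_ids`` order.
        A DataFrame contributes its column names as covariate ids.
    surv
        Survival data with at least one observed event.
    ties
        ``"breslow"`` (default) or ``"efron"``.
    """
    gene_ids = None
    if isinstance(X, pd.DataFrame):
        gene_ids = tuple(map(str, X.columns))
        X = X.to_numpy(float)
    return CoxEngine(surv, ties=ties).fit(X, gene_ids=gene_ids, beta0=beta0)


def wald_p(fit: CoxFit) -> float:
    """Global Wald chi-square P value of a converged fit.

    Upper tail of chi2(df) at the Wald statistic; raises on a
    non-converged fit, whose statistic is undefined.
    """
    if not fit.converged:
        raise ValueError("Wald test undefined for a non-converged fit")
    return chi2_sf(fit.wald_stat, fit.df)


def univariate_cox(
    m: pd.DataFrame, surv: SurvivalData, ties: str = "breslow"
) -> pd.DataFrame:
    """Single-gene Cox screen: one univariate fit per expression row.

    Returns a DataFrame indexed by gene with columns ``beta``, ``p`` and
    ``converged``.  Non-converged genes carry beta as fitted, p = 1, and
    ``converged=False``.
    """
    if m.empty:
        raise ValueError("empty expression matrix")
    if list(m.columns) != list(surv.sample_ids):
        m = m[list(surv.sample_ids)]
    engine = CoxEngine(surv, ties=ties)
    vals = m.to_numpy(float)
    rows = []
    for i, gene in enumerate(m.index):
        fit = engine.fit(vals[i][:, None], gene_ids=(str(gene),))
        rows.append((gene, fit.beta[0], fit.p_value, fit.converged))
    out = pd.DataFrame(rows, columns=["gene", "beta", "p", "converged"])
    return out.set_index("gene")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values, in input order.

    q_(i) = min_{j >= i} ( n * p_(j) / j ), clipped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out
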