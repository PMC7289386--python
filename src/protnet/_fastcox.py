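"""Vectorised univariate Cox partial likelihood and two-group log-rank.

The leave-one-out permutation validation refits a univariate Cox model and a
log-rank statistic hundreds of thousands of times on the *same* (time, event)
data with different covariate vectors.  This module therefore precomputes the
risk-set structure once (:class:`CoxStructure`) and evaluates score
coefficients, Newton fits and log-rank statistics for whole batches of
covariate rows in single numpy passes.  Ties are handled with the Efron
convention throughout.

Correctness is pinned against lifelines on shared fixtures in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _sstats

from .errors import InsufficientDataError


class CoxStructure:
    """Risk-set bookkeeping for right-censored data, reusable across fits.

    Samples are sorted by time (ascending, stable).  For each distinct event
    time ``t_j``: ``starts[j]`` is the first sorted position in the risk set
    (all samples with time >= t_j), ``r[j]`` the risk-set size and ``d[j]``
    the number of events at t_j.  ``ev_idx``/``ev_ptr`` index the event
    samples grouped by event time, so per-time death sums are reduceat calls.
    """

    def __init__(self, times, events) -> None:
        times = np.asarray(times, float)
        events = np.asarray(events, bool)
        if times.ndim != 1 or times.shape != events.shape:
            raise ValueError("times and events must be equal-length 1-D arrays")
        self.n = len(times)
        self.n_events = int(events.sum())
        self.order = np.argsort(times, kind="stable")
        self.ts = times[self.order]
        self.es = events[self.order]
        self.ut = np.unique(self.ts[self.es]) if self.n_events else np.empty(0)
        self.starts = np.searchsorted(self.ts, self.ut, side="left")
        self.r = self.n - self.starts
        self.ev_idx = np.flatnonzero(self.es)
        self.ev_ptr = np.searchsorted(self.ts[self.ev_idx], self.ut, side="left")
        self.d = np.diff(np.append(self.ev_ptr, len(self.ev_idx)))
        self.max_d = int(self.d.max()) if len(self.d) else 0
        # Efron per-time constants at beta = 0 used by score0_coeffs
        a = np.zeros(len(self.ut))
        b = np.zeros(len(self.ut))
        for l in range(self.max_d):
            mask = self.d > l
            denom = self.r[mask] - l
            a[mask] += 1.0 / denom
            b[mask] += (l / self.d[mask]) / denom
        self._a, self._b = a, b

    # -- linear score functional at beta = 0 -------------------------------
    def score0_coeffs(self) -> np.ndarray:
        """Coefficients c (original sample order) with U(0) = c . x.

        The Cox score at beta=0 is linear in the covariate; its sign equals
        the sign of the partial-likelihood MLE (the likelihood is concave),
        which is all the LOO risk-direction assignment needs.
        """
        c_sorted = np.zeros(self.n)
        if len(self.ut):
            # cumulative sum of a_j over event times <= each sample's time
            idx = np.searchsorted(self.ut, self.ts, side="right")
            cum_a = np.concatenate([[0.0], np.cumsum(self._a)])
            c_sorted -= cum_a[idx]
            # event contribution: 1 + b_j for the sample's own event time
            grp = np.searchsorted(self.ut, self.ts[self.ev_idx], side="left")
            c_sorted[self.ev_idx] += 1.0 + self._b[grp]
        c = np.empty(self.n)
        c[self.order] = c_sorted
        return c

    # -- helpers -----------------------------------------------------------
    def _suffix_sums(self, arr: np.ndarray) -> np.ndarray:
        """Suffix sums of (m, n) rows evaluated at the risk-set starts."""
        cs = np.cumsum(arr[:, ::-1], axis=1)[:, ::-1]
        return cs[:, self.starts]

    def _death_sums(self, arr: np.ndarray) -> np.ndarray:
        return np.add.reduceat(arr[:, self.ev_idx], self.ev_ptr, axis=1)

    def _grad_info(self, xs_sorted: np.ndarray, beta: np.ndarray):
        """Efron gradient and information for a batch of covariate rows."""
        eta = beta[:, None] * xs_sorted
        eta -= eta.max(axis=1, keepdims=True)  # scale-invariant ratios
        w = np.exp(eta)
        xw = xs_sorted * w
        x2w = xs_sorted * xw
        S0, S1, S2 = (self._suffix_sums(v) for v in (w, xw, x2w))
        D0, D1, D2 = (self._death_sums(v) for v in (w, xw, x2w))
        DX = self._death_sums(np.broadcast_to(xs_sorted, w.shape))
        grad = DX.sum(axis=1)
        info = np.zeros_like(grad)
        for l in range(self.max_d):
            mask = self.d > l
            frac = (l / self.d[mask])[None, :]
            phi = S0[:, mask] - frac * D0[:, mask]
            z = (S1[:, mask] - frac * D1[:, mask]) / phi
            q = (S2[:, mask] - frac * D2[:, mask]) / phi
            grad -= z.sum(axis=1)
            info += (q - z**2).sum(axis=1)
        return grad, info

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        xs: np.ndarray,
        tol: float = 1e-9,
        max_iter: int = 50,
        beta_bound: float = 15.0,
    ):
        """Newton-Raphson Cox MLE for each covariate row of ``xs``.

        ``xs`` is (m, n) or (n,), in original sample order.  Returns
        ``(beta, info, converged)``; ``converged`` is False for rows that hit
        the monotone-likelihood bound or the iteration cap.
        """
        if self.n_events < 1:
            raise InsufficientDataError("no events; Cox model undefined")
        xs = np.atleast_2d(np.asarray(xs, float))
        xs_sorted = xs[:, self.order]
        m = xs.shape[0]
        beta = np.zeros(m)
        converged = np.zeros(m, bool)
        info = np.ones(m)
        for _ in range(max_iter):
            grad, info = self._grad_info(xs_sorted, beta)
            safe = info > 1e-12
            step = np.where(safe, grad / np.where(safe, info, 1.0), 0.0)
            step = np.clip(step, -1.0, 1.0)
            done = (np.abs(grad) < tol) | ~safe
            converged |= done
            beta = np.where(done, beta, beta + step)
            out_of_bounds = np.abs(beta) > beta_bound
            beta = np.clip(beta, -beta_bound, beta_bound)
            converged &= ~out_of_bounds
            if done.all():
                break
        # one final gradient/information evaluation for SEs
        grad, info = self._grad_info(xs_sorted, beta)
        converged = converged | (np.abs(grad) < 1e-6)
        converged &= np.abs(beta) < beta_bound
        return beta, info, converged

    def score_test(self, xs: np.ndarray):
        """Cox score test at beta = 0: returns (U0, I0) per covariate row."""
        xs = np.atleast_2d(np.asarray(xs, float))
        xs_sorted = xs[:, self.order]
        grad, info = self._grad_info(xs_sorted, np.zeros(xs.shape[0]))
        return grad, info

    # -- log-rank ----------------------------------------------------------
    def logrank_multi(self, labels: np.ndarray) -> np.ndarray:
        """Two-group log-rank chi-square for each boolean label row.

        ``labels`` is (m, n) in original sample order; True marks group 1.
        Uses the hypergeometric variance at each distinct event time (ties
        enter as simultaneous events).  Rows whose labels are degenerate
        (all one group) get statistic 0.
        """
        labels = np.atleast_2d(np.asarray(labels, bool))
        ls = labels[:, self.order].astype(float)
        r1 = self._suffix_sums(ls)
        d1 = self._death_sums(ls)
        r = self.r[None, :].astype(float)
        d = self.d[None, :].astype(float)
        frac1 = r1 / r
        e1 = d * frac1
        with np.errstate(divide="ignore", invalid="ignore"):
            v_terms = d * frac1 * (1 - frac1) * (r - d) / (r - 1)
        v_terms = np.where(r > 1, v_terms, 0.0)
        o_minus_e = (d1 - e1).sum(axis=1)
        v = v_terms.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = np.where(v > 0, o_minus_e**2 / np.where(v > 0, v, 1.0), 0.0)
        return chi2

    def logrank_signed(self, labels: np.ndarray) -> np.ndarray:
        """Signed standardised log-rank excess of group 1: (O1-E1)/sqrt(V).

        Positive values mean group 1 (the predicted high-risk group) fails
        *earlier* than expected — the directional statistic the
        cross-validated permutation test refers to its null.  Degenerate
        label rows get 0.
        """
        labels = np.atleast_2d(np.asarray(labels, bool))
        ls = labels[:, self.order].astype(float)
        r1 = self._suffix_sums(ls)
        d1 = self._death_sums(ls)
        r = self.r[None, :].astype(float)
        d = self.d[None, :].astype(float)
        frac1 = r1 / r
        e1 = d * frac1
        with np.errstate(divide="ignore", invalid="ignore"):
            v_terms = d * frac1 * (1 - frac1) * (r - d) / (r - 1)
        v_terms = np.where(r > 1, v_terms, 0.0)
        o_minus_e = (d1 - e1).sum(axis=1)
        v = v_terms.sum(axis=1)
        return np.where(v > 0, o_minus_e / np.sqrt(np.where(v > 0, v, 1.0)), 0.0)


def logrank_p(chi2) -> np.ndarray:
    """Upper-tail p of a 1-df chi-square log-rank statistic."""
    return _sstats.chi2.sf(chi2, df=1)
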