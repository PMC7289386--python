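"""Gaussian conditional-independence testing.

The constraint-based structure learner asks many queries of the form
"is X_i independent of X_j given the set S?".  Under a multivariate-normal
model that is equivalent to a zero partial correlation rho(i,j | S), tested
with the Fisher z transform: z = arctanh(r) is approximately
N(arctanh(rho), 1/(n - |S| - 3)) so sqrt(n - |S| - 3) * |z| is referred to a
standard normal.

Two test front-ends share this module's arithmetic:

* :class:`GaussianCITest` - finite-sample test on a correlation matrix.
* :class:`OracleCITest`   - answers d-separation queries on a known DAG
  (the noiseless oracle used to validate the learner itself).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .errors import InsufficientSampleError, NumericalRankError

logger = logging.getLogger(__name__)

# condition number above which we fall back to pseudo-inversion
_COND_LIMIT = 1e12


@dataclass(frozen=True)
class CITestResult:
    """Outcome of one conditional-independence query."""

    partial_correlation: float
    statistic: float
    p_value: float
    independent: bool
    conditioning_size: int
    alpha: float


def partial_correlation(
    corr: np.ndarray,
    i: int,
    j: int,
    S: tuple[int, ...] | list[int] = (),
    method: str = "inversion",
) -> float:
    """Partial correlation of variables ``i`` and ``j`` given the set ``S``.

    ``corr`` is a full correlation matrix; indices are positions into it.
    ``method='inversion'`` inverts the {i,j} u S submatrix and reads the
    partial correlation off the precision matrix; ``method='recursive'``
    applies the classical one-variable-at-a-time recursion.  The two agree to
    ~1e-10 on well-conditioned inputs and the recursion serves as an internal
    cross-check in the test-suite.
    """
    S = tuple(S)
    if i == j:
        raise ValueError("i and j must differ")
    if i in S or j in S:
        raise ValueError("i and j must not be in the conditioning set")
    if method == "recursive":
        return _pcor_recursive(corr, i, j, S)
    if method != "inversion":
        raise ValueError(f"unknown method {method!r}")
    if not S:
        return float(corr[i, j])
    idx = (i, j) + S
    sub = corr[np.ix_(idx, idx)]
    cond = np.linalg.cond(sub)
    if not np.isfinite(cond):
        raise NumericalRankError(
            f"singular correlation submatrix for ({i},{j}|{S})"
        )
    if cond > _COND_LIMIT:
        logger.warning(
            "near-singular conditioning set for (%d,%d|%s); using pseudo-inverse",
            i, j, S,
        )
        prec = np.linalg.pinv(sub)
    else:
        prec = np.linalg.inv(sub)
    denom = prec[0, 0] * prec[1, 1]
    if denom <= 0:
        raise NumericalRankError(
            f"rank-deficient submatrix for ({i},{j}|{S}): nonpositive precision diagonal"
        )
    r = -prec[0, 1] / np.sqrt(denom)
    return float(np.clip(r, -1.0, 1.0))


def _pcor_recursive(corr: np.ndarray, i: int, j: int, S: tuple[int, ...]) -> float:
    if not S:
        return float(corr[i, j])
    k, rest = S[-1], S[:-1]
    r_ij = _pcor_recursive(corr, i, j, rest)
    r_ik = _pcor_recursive(corr, i, k, rest)
    r_jk = _pcor_recursive(corr, j, k, rest)
    denom = (1.0 - r_ik**2) * (1.0 - r_jk**2)
    if denom <= 0:
        raise NumericalRankError(
            f"recursive partial correlation undefined for ({i},{j}|{S})"
        )
    return float((r_ij - r_ik * r_jk) / np.sqrt(denom))


def fisher_z_test(r: float, n: int, s: int, alpha: float = 0.01) -> CITestResult:
    """Fisher-z test of a (partial) correlation ``r``.

    ``n`` is the sample count and ``s`` the conditioning-set size.  Requires
    the effective degrees of freedom ``n - s - 3`` to be at least 1.
    Correlations at the +-1 boundary are clamped to 1 - 1e-12 with a warning
    (they arise from numerically deterministic relations).
    """
    dof = n - s - 3
    if dof < 1:
        raise InsufficientSampleError(
            f"n={n} too small for conditioning-set size s={s} (need n - s - 3 >= 1)"
        )
    if abs(r) >= 1.0:
        warnings.warn(
            f"|r|={abs(r)} at the boundary; clamping to 1 - 1e-12", stacklevel=2
        )
        r = np.sign(r) * (1.0 - 1e-12)
    z = np.arctanh(r)
    statistic = float(np.sqrt(dof) * abs(z))
    p_value = float(2.0 * stats.norm.sf(statistic))
    return CITestResult(
        partial_correlation=float(r),
        statistic=statistic,
        p_value=p_value,
        independent=p_value > alpha,
        conditioning_size=s,
        alpha=alpha,
    )


class GaussianCITest:
    """Fisher-z conditional-independence test bound to one dataset.

    Built once from the z-scored matrix (Pearson correlations, the Gaussian
    test's assumption; Spearman available via ``corr_method``).  Queries use
    node names.  Queries whose conditioning set is too large for the sample
    size are *skipped*: the edge is retained (treated as dependent) and the
    skip is counted, so structure learning degrades conservatively rather
    than erring towards sparsity.
    """

    def __init__(
        self,
        data: np.ndarray,
        node_names: list[str],
        alpha: float = 0.01,
        corr_method: str = "pearson",
    ) -> None:
        # data: variables x samples
        if data.shape[0] != len(node_names):
            raise ValueError("node_names length must match the variable axis")
        if corr_method == "pearson":
            self.corr = np.corrcoef(data)
        elif corr_method == "spearman":
            ranks = stats.rankdata(data, axis=1)
            self.corr = np.corrcoef(ranks)
        else:
            raise ValueError(f"unknown corr_method {corr_method!r}")
        self.n = data.shape[1]
        self.alpha = alpha
        self.nodes = list(node_names)
        self._index = {v: k for k, v in enumerate(self.nodes)}
        self.n_tests = 0
        self.n_skipped = 0

    def test(self, i: str, j: str, S: tuple[str, ...]) -> CITestResult:
        s = len(S)
        if self.n - s - 3 < 1:
            self.n_skipped += 1
            return CITestResult(
                partial_correlation=np.nan,
                statistic=np.inf,
                p_value=0.0,
                independent=False,
                conditioning_size=s,
                alpha=self.alpha,
            )
        self.n_tests += 1
        r = partial_correlation(
            self.corr, self._index[i], self._index[j], tuple(self._index[k] for k in S)
        )
        return fisher_z_test(r, self.n, s, self.alpha)


class OracleCITest:
    """Perfect conditional-independence oracle on a known DAG.

    Answers each query with the d-separation truth of the generating graph;
    used to validate the structure learner free of sampling noise.
    """

    def __init__(self, dag: nx.DiGraph) -> None:
        if not nx.is_directed_acyclic_graph(dag):
            raise ValueError("oracle requires an acyclic digraph")
        self.dag = dag
        self.nodes = sorted(dag.nodes)
        self.n_tests = 0
        self.n_skipped = 0

    def test(self, i: str, j: str, S: tuple[str, ...]) -> CITestResult:
        self.n_tests += 1
        sep = nx.is_d_separator(self.dag, {i}, {j}, set(S))
        return CITestResult(
            partial_correlation=0.0 if sep else 1.0,
            statistic=0.0 if sep else np.inf,
            p_value=1.0 if sep else 0.0,
            independent=sep,
            conditioning_size=len(S),
            alpha=0.0,
        )


def simulate_null_rejection_rate(
    n: int = 100, reps: int = 10_000, alpha: float = 0.05, seed: int = 0
) -> float:
    """Empirical type-I error of the marginal Fisher-z test under independence.

    Draws ``reps`` independent bivariate standard-normal samples of size ``n``
    and returns the fraction rejected at ``alpha`` (vectorised; used for
    calibration checks).
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((reps, n))
    y = rng.standard_normal((reps, n))
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    r = (xc * yc).sum(axis=1) / np.sqrt(
        (xc**2).sum(axis=1) * (yc**2).sum(axis=1)
    )
    z = np.arctanh(r)
    statistic = np.sqrt(n - 3) * np.abs(z)
    p = 2.0 * stats.norm.sf(statistic)
    return float(np.mean(p <= alpha))
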