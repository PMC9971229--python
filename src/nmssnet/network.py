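"""Regularized partial-correlation network estimation (EBICglasso).

Pipeline: nonparanormal transform of the ordinal scores -> Pearson
correlation -> graphical lasso over a descending penalty grid -> EBIC
(gamma = 0.5) model selection -> precision standardized to partial
correlations w_ij = -theta_ij / sqrt(theta_ii theta_jj).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri
from sklearn.covariance import graphical_lasso
from sklearn.exceptions import ConvergenceWarning

from .scale import DomainMatrix, ItemMatrix

__all__ = [
    "EstimatorSettings",
    "PcorNetwork",
    "EbicPath",
    "npn_transform",
    "make_lambda_grid",
    "glasso_path",
    "ebic",
    "estimate_network",
]

log = logging.getLogger(__name__)

_ZERO_TOL = 1e-10  # below this an off-diagonal precision entry counts as no edge


@dataclass(frozen=True)
class EstimatorSettings:
    """Network estimator settings, shared verbatim by every bootstrap and
    permutation replicate.

    gamma is the EBIC hyperparameter (0.5 = edge-conservative default);
    the penalty grid has n_lambda log-spaced points from lambda_max (largest
    off-diagonal absolute correlation) down to lambda_min_ratio * lambda_max.
    """

    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    npn: bool = True
    solver_tol: float = 1e-4
    solver_max_iter: int = 500


@dataclass
class PcorNetwork:
    """Symmetric partial-correlation weight matrix with zero diagonal."""

    node_ids: tuple[str, ...]
    weights: np.ndarray
    lambda_selected: float
    gamma: float
    n_obs: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        p = len(self.node_ids)
        if self.weights.shape != (p, p):
            raise ValueError(f"weights must be {p}x{p}")
        if not np.allclose(self.weights, self.weights.T, atol=1e-10):
            raise ValueError("weights not symmetric")
        if np.abs(np.diag(self.weights)).max() > 0:
            raise ValueError("diagonal must be exactly zero")
        if np.abs(self.weights).max() >= 1:
            raise ValueError("partial correlations must satisfy |w| < 1")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_possible_edges(self) -> int:
        p = self.n_nodes
        return p * (p - 1) // 2

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices(self.n_nodes, 1)
        return int((np.abs(self.weights[iu]) > _ZERO_TOL).sum())

    def edge_list(self) -> pd.DataFrame:
        iu = np.triu_indices(self.n_nodes, 1)
        df = pd.DataFrame(
            {
                "node_i": [self.node_ids[i] for i in iu[0]],
                "node_j": [self.node_ids[j] for j in iu[1]],
                "weight": self.weights[iu],
            }
        )
        return df[df.weight.abs() > _ZERO_TOL].reset_index(drop=True)


@dataclass
class EbicPath:
    """Per-lambda diagnostics of the model-selection path (lambda descending)."""

    lambdas: np.ndarray
    edge_counts: np.ndarray
    logliks: np.ndarray
    ebic_values: np.ndarray
    selected_index: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.ebic_values)):
            raise ValueError("EBIC not finite on the whole path")
        if self.selected_index != int(np.argmin(self.ebic_values)):
            raise ValueError("selected index does not attain the EBIC minimum")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lambda": self.lambdas,
                "n_edges": self.edge_counts,
                "loglik": self.logliks,
                "ebic": self.ebic_values,
                "selected": np.arange(len(self.lambdas)) == self.selected_index,
            }
        )


def npn_transform(x: np.ndarray) -> np.ndarray:
    """Nonparanormal (Gaussian copula) transform, column-wise.

    Each column is mapped through its empirical CDF (ranks / n, average
    midranks for ties), Winsorized at delta = 1 / (4 n^{1/4} sqrt(pi log n))
    and 1 - delta, passed through the standard normal quantile function and
    rescaled to unit variance.  The map is monotone, so tied scores receive
    identical transformed values and ranks are preserved.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected an n x p matrix")
    n = x.shape[0]
    if n < 10:
        raise ValueError(f"npn transform needs n >= 10 rows, got {n}")
    const = set(np.flatnonzero(np.ptp(x, axis=0) == 0))
    if const:
        raise ValueError(f"constant column(s) {sorted(const)} cannot be transformed")
    delta = 1.0 / (4.0 * n**0.25 * np.sqrt(np.pi * np.log(n)))
    u = stats.rankdata(x, axis=0, method="average") / n
    z = ndtri(np.clip(u, delta, 1.0 - delta))
    return z / z.std(axis=0, ddof=1)


def make_lambda_grid(
    correlation: np.ndarray, n_lambda: int = 100, min_ratio: float = 0.01
) -> np.ndarray:
    """Descending log-spaced penalty grid from lambda_max = max |r_ij|, i != j."""
    off = correlation - np.diag(np.diag(correlation))
    lam_max = float(np.abs(off).max())
    if lam_max <= 0:
        lam_max = min_ratio  # diagonal input: any grid selects the empty graph
    return np.geomspace(lam_max, min_ratio * lam_max, n_lambda)


def glasso_path(
    correlation: np.ndarray,
    lambda_grid: np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Graphical-lasso precision estimates along a penalty grid.

    Each estimate maximizes log det(Theta) - tr(S Theta) - lambda ||Theta||_1
    over the off-diagonal entries (diagonal unpenalized).  lambda = 0 returns
    the unpenalized MLE S^{-1}.  Non-converging grid points are dropped with
    a warning; the kept lambdas are returned alongside the estimates.
    """
    S = np.asarray(correlation, dtype=float)
    precisions: list[np.ndarray] = []
    kept: list[float] = []
    for lam in np.asarray(lambda_grid, dtype=float):
        try:
            if lam == 0.0:
                theta = np.linalg.inv(S)
            else:
                with warnings.catch_warnings():
                    # near-convergence warnings at dense (small-lambda) grid
                    # points are routine; estimates are kept if finite and PD
                    warnings.simplefilter("ignore", category=ConvergenceWarning)
                    _, theta = graphical_lasso(
                        S, alpha=float(lam), tol=tol, max_iter=max_iter
                    )
            if not np.all(np.isfinite(theta)) or np.linalg.eigvalsh(theta).min() <= 0:
                raise FloatingPointError("estimate not finite positive definite")
        except (FloatingPointError, np.linalg.LinAlgError, ValueError) as exc:
            log.warning("graphical lasso failed at lambda=%.5g (%s); point dropped", lam, exc)
            continue
        precisions.append(theta)
        kept.append(float(lam))
    if not precisions:
        raise RuntimeError("graphical lasso failed on every grid point")
    return precisions, np.asarray(kept)


def ebic(loglik: float, n_edges: int, n: int, p: int, gamma: float = 0.5) -> float:
    """Extended BIC: -2 loglik + E log n + 4 E gamma log p."""
    return -2.0 * loglik + n_edges * np.log(n) + 4.0 * n_edges * gamma * np.log(p)


def _gaussian_profile_loglik(theta: np.ndarray, S: np.ndarray, n: int) -> float:
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return -np.inf
    return 0.5 * n * (logdet - np.trace(S @ theta))


def _edge_count(theta: np.ndarray) -> int:
    iu = np.triu_indices(theta.shape[0], 1)
    return int((np.abs(theta[iu]) > _ZERO_TOL).sum())


def precision_to_pcor(theta: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(theta))
    pcor = -theta / np.outer(d, d)
    np.fill_diagonal(pcor, 0.0)
    return pcor


def _coerce_data(
    matrix, node_ids: tuple[str, ...] | None
) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(matrix, ItemMatrix):
        complete = matrix.complete_rows()
        return complete.scores.astype(float), tuple(complete.item_ids)
    if isinstance(matrix, DomainMatrix):
        return matrix.scores.astype(float), tuple(matrix.domain_ids)
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float), tuple(str(c) for c in matrix.columns)
    arr = np.asarray(matrix, dtype=float)
    if node_ids is None:
        node_ids = tuple(f"v{k + 1}" for k in range(arr.shape[1]))
    return arr, tuple(node_ids)


def estimate_network(
    matrix,
    settings: EstimatorSettings = EstimatorSettings(),
    node_ids: tuple[str, ...] | None = None,
) -> tuple[PcorNetwork, EbicPath]:
    """EBICglasso network from an item/domain matrix (complete rows only).

    Accepts an ItemMatrix (rows with missing items are dropped), a
    DomainMatrix, a DataFrame or a plain n x p array.
    """
    X, nodes = _coerce_data(matrix, node_ids)
    n, p = X.shape
    if np.isnan(X).any():
        raise ValueError("input contains missing values; estimation needs complete rows")
    const = np.flatnonzero(np.ptp(X, axis=0) == 0)
    if const.size:
        raise ValueError(f"constant column(s): {[nodes[c] for c in const]}")
    if n <= p:
        warnings.warn(f"n = {n} <= p = {p}: estimates may be unstable", stacklevel=2)
    Z = npn_transform(X) if settings.npn else X
    S = np.corrcoef(Z, rowvar=False)
    cond = np.linalg.cond(S)
    if not np.all(np.isfinite(S)) or cond > 1e12:
        raise ValueError(f"degenerate correlation matrix (condition number {cond:.3g})")
    grid = make_lambda_grid(S, settings.n_lambda, settings.lambda_min_ratio)
    precisions, kept = glasso_path(
        S, grid, tol=settings.solver_tol, max_iter=settings.solver_max_iter
    )
    edge_counts = np.array([_edge_count(t) for t in precisions])
    logliks = np.array([_gaussian_profile_loglik(t, S, n) for t in precisions])
    ebics = np.array(
        [ebic(ll, e, n, p, settings.gamma) for ll, e in zip(logliks, edge_counts)]
    )
    best = int(np.argmin(ebics))
    theta = precisions[best]
    weights = precision_to_pcor(theta)
    weights[np.abs(weights) <= _ZERO_TOL] = 0.0
    network = PcorNetwork(
        node_ids=nodes,
        weights=weights,
        lambda_selected=float(kept[best]),
        gamma=settings.gamma,
        n_obs=n,
    )
    path = EbicPath(
        lambdas=kept,
        edge_counts=edge_counts,
        logliks=logliks,
        ebic_values=ebics,
        selected_index=best,
    )
    return network, path
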