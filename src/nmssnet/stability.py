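"""Bootstrap stability of the estimated network.

Case-dropping bootstrap: re-estimate the network on subsamples with a
growing fraction of cases removed and correlate the bootstrap strength
vector with the original; summarized by the correlation-stability (CS)
coefficient — the largest drop fraction at which the correlation stays
>= 0.7 in >= 95% of subsamples (acceptable above 0.25, good above 0.5).

Nonparametric bootstrap: resample subjects with replacement for edge-weight
95% quantile CIs and bootstrapped difference tests between node strengths
(and edges).

Replicates are independent given a per-replicate seed derived from the
master seed by a counter scheme, so results do not depend on execution
order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .centrality import strength
from .network import EstimatorSettings, estimate_network

__all__ = [
    "CaseDropResult",
    "CsCoefficient",
    "EdgeCiTable",
    "DifferenceTestMatrix",
    "DEFAULT_DROP_GRID",
    "case_dropping_bootstrap",
    "cs_coefficient",
    "edge_ci_bootstrap",
    "difference_tests",
]

log = logging.getLogger(__name__)

#: Drop fractions h = 0.05, 0.10, ..., 0.75.
DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.05, 0.76, 0.05), 2))

# stream tag separating with-replacement bootstrap seeds from the
# case-dropping streams (which use the drop-grid index)
_EDGE_BOOT_TAG = 10_000


@dataclass
class CaseDropResult:
    drop_fractions: np.ndarray
    correlations: np.ndarray  # shape (n_fractions, B); NaN = failed replicate
    n_failed: np.ndarray
    original_strength: np.ndarray

    def summary(self) -> pd.DataFrame:
        with np.errstate(invalid="ignore"):
            return pd.DataFrame(
                {
                    "drop_fraction": self.drop_fractions,
                    "median": np.nanmedian(self.correlations, axis=1),
                    "q025": np.nanquantile(self.correlations, 0.025, axis=1),
                    "q975": np.nanquantile(self.correlations, 0.975, axis=1),
                    "n_failed": self.n_failed,
                }
            )

    def to_long_frame(self) -> pd.DataFrame:
        h, b = np.meshgrid(
            self.drop_fractions, np.arange(self.correlations.shape[1]), indexing="ij"
        )
        return pd.DataFrame(
            {
                "drop_fraction": h.ravel(),
                "replicate": b.ravel(),
                "correlation": self.correlations.ravel(),
            }
        )


@dataclass
class CsCoefficient:
    value: float
    criterion_correlation: float = 0.7
    criterion_probability: float = 0.95


@dataclass
class EdgeCiTable:
    """Per-edge point estimate and bootstrap quantile CI, plus the raw draws
    needed by the difference tests."""

    node_ids: tuple[str, ...]
    table: pd.DataFrame
    edge_draws: np.ndarray = field(repr=False)      # (B_ok, n_pairs)
    strength_draws: np.ndarray = field(repr=False)  # (B_ok, p)
    n_replicates: int = 0
    n_failed: int = 0


@dataclass
class DifferenceTestMatrix:
    labels: tuple[str, ...]
    significant: np.ndarray  # boolean, symmetric, diagonal False
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.significant, index=list(self.labels), columns=list(self.labels)
        )


def _replicate_rng(seed: int, fraction_index: int, replicate: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(fraction_index), int(replicate)])
    )


def _scores_of(matrix) -> np.ndarray:
    from .network import _coerce_data

    X, _ = _coerce_data(matrix, None)
    return X


def case_dropping_bootstrap(
    matrix,
    settings: EstimatorSettings = EstimatorSettings(),
    drop_grid: tuple[float, ...] = DEFAULT_DROP_GRID,
    B: int = 1000,
    seed: int = 0,
) -> CaseDropResult:
    """Correlations between subsample and original strength per drop fraction.

    Fractions whose subsample would leave fewer than p + 10 rows are skipped
    with a warning; failed replicates are recorded as NaN and counted.
    """
    if B <= 0:
        raise ValueError("B must be positive")
    X = _scores_of(matrix)
    n, p = X.shape
    net0, _ = estimate_network(X, settings)
    s0 = strength(net0).raw
    kept_fracs: list[float] = []
    rows: list[np.ndarray] = []
    failed: list[int] = []
    for fi, h in enumerate(drop_grid):
        m = int(np.ceil((1.0 - h) * n))
        if m < p + 10:
            log.warning("drop fraction %.2f leaves %d < p+10 rows; skipped", h, m)
            continue
        cors = np.full(B, np.nan)
        nf = 0
        for b in range(B):
            rng = _replicate_rng(seed, fi, b)
            idx = rng.choice(n, size=m, replace=False)
            try:
                net, _ = estimate_network(X[idx], settings)
                sb = strength(net).raw
                if s0.std() == 0 or sb.std() == 0:
                    raise ValueError("degenerate strength vector")
                cors[b] = np.corrcoef(s0, sb)[0, 1]
            except Exception as exc:  # noqa: BLE001 - replicate-level robustness
                nf += 1
                log.debug("replicate (h=%.2f, b=%d) failed: %s", h, b, exc)
        kept_fracs.append(float(h))
        rows.append(cors)
        failed.append(nf)
    return CaseDropResult(
        drop_fractions=np.asarray(kept_fracs),
        correlations=np.vstack(rows) if rows else np.empty((0, B)),
        n_failed=np.asarray(failed),
        original_strength=s0,
    )


def cs_coefficient(
    result: CaseDropResult, cor: float = 0.7, prob: float = 0.95
) -> CsCoefficient:
    """Largest drop fraction h with P(correlation >= cor) >= prob; 0 if none."""
    if result.drop_fractions.size == 0:
        raise ValueError("empty case-dropping result")
    value = 0.0
    for h, row in zip(result.drop_fractions, result.correlations):
        ok = row[~np.isnan(row)]
        if ok.size == 0:
            continue
        if np.mean(ok >= cor) >= prob:
            value = max(value, float(h))
    return CsCoefficient(value=value, criterion_correlation=cor, criterion_probability=prob)


def edge_ci_bootstrap(
    matrix,
    settings: EstimatorSettings = EstimatorSettings(),
    B: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> EdgeCiTable:
    """Nonparametric bootstrap (resampling subjects with replacement):
    per-edge quantile CIs plus edge-weight and strength draws."""
    if B <= 0:
        raise ValueError("B must be positive")
    X = _scores_of(matrix)
    n, p = X.shape
    net0, _ = estimate_network(X, settings)
    iu = np.triu_indices(p, 1)
    point = net0.weights[iu]
    draws = []
    sdraws = []
    nf = 0
    for b in range(B):
        rng = _replicate_rng(seed, _EDGE_BOOT_TAG, b)
        idx = rng.choice(n, size=n, replace=True)
        try:
            net, _ = estimate_network(X[idx], settings)
        except Exception as exc:  # noqa: BLE001
            nf += 1
            log.debug("bootstrap replicate %d failed: %s", b, exc)
            continue
        draws.append(net.weights[iu])
        sdraws.append(strength(net).raw)
    if not draws:
        raise RuntimeError("all bootstrap replicates failed")
    E = np.vstack(draws)
    Sd = np.vstack(sdraws)
    lo = (1.0 - ci) / 2.0
    table = pd.DataFrame(
        {
            "node_i": [net0.node_ids[i] for i in iu[0]],
            "node_j": [net0.node_ids[j] for j in iu[1]],
            "estimate": point,
            "ci_lower": np.quantile(E, lo, axis=0),
            "ci_upper": np.quantile(E, 1.0 - lo, axis=0),
            "n_replicates": E.shape[0],
        }
    )
    return EdgeCiTable(
        node_ids=net0.node_ids,
        table=table,
        edge_draws=E,
        strength_draws=Sd,
        n_replicates=E.shape[0],
        n_failed=nf,
    )


def difference_tests(
    boot: EdgeCiTable, what: str = "strength", alpha: float = 0.05
) -> DifferenceTestMatrix:
    """Bootstrapped difference test: a pair differs when the bootstrap CI of
    the difference of its two values excludes zero."""
    if what == "strength":
        D = boot.strength_draws
        labels = boot.node_ids
    elif what == "edge":
        D = boot.edge_draws
        labels = tuple(
            f"{i}--{j}" for i, j in zip(boot.table.node_i, boot.table.node_j)
        )
    else:
        raise ValueError("what must be 'strength' or 'edge'")
    k = D.shape[1]
    sig = np.zeros((k, k), dtype=bool)
    lo = alpha / 2.0
    for a in range(k):
        diff = D[:, a, None] - D[:, a + 1:]
        ql = np.quantile(diff, lo, axis=0)
        qu = np.quantile(diff, 1.0 - lo, axis=0)
        flag = (ql > 0) | (qu < 0)
        sig[a, a + 1:] = flag
        sig[a + 1:, a] = flag
    return DifferenceTestMatrix(labels=labels, significant=sig, alpha=alpha)
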