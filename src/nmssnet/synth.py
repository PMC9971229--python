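"""Synthetic NMSS-like data from a latent Gaussian copula graphical model.

Each subject has a latent multivariate-normal vector whose precision matrix
encodes the ground-truth conditional-dependence network.  Every item score
is a monotone discretization of its latent coordinate: ordered cut-points
give the severity level (0-3), coarser cut-points on the same latent give
the frequency (1-4), and the reported score is their product.  Because the
score is a monotone map of the latent, the true partial-correlation network
of the latents is exactly the recovery target of the nonparanormal pipeline.

The follow-up visit reuses the same graphical model: the follow-up latent is
a retest-correlated copy of the baseline latent plus a per-item mean drift,
so marginal severities worsen while the conditional dependence structure is
preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .scale import ItemMatrix, ScaleDefinition, ScaleValidationError, nmss_scale

__all__ = [
    "GeneratorConfig",
    "default_config",
    "small_scale",
    "small_config",
    "simulate",
    "true_partial_correlations",
    "implied_rank_correlation",
]


@dataclass
class GeneratorConfig:
    """Ground truth and discretization rules for the simulator.

    severity_thresholds[i] are the three strictly increasing latent cuts for
    severities 1, 2, 3 of item i; frequency_thresholds[i] the three cuts for
    frequencies 2, 3, 4.  followup_drift is a per-item latent mean shift at
    the second visit; retest_correlation is the latent correlation between a
    subject's two visits.
    """

    n_subjects: int
    precision_matrix: np.ndarray
    severity_thresholds: np.ndarray
    frequency_thresholds: np.ndarray
    followup_drift: np.ndarray
    retest_correlation: float
    seed: int
    scale: ScaleDefinition = field(default_factory=nmss_scale)

    def __post_init__(self) -> None:
        p = self.scale.n_items
        self.precision_matrix = np.asarray(self.precision_matrix, dtype=float)
        if self.precision_matrix.shape != (p, p):
            raise ScaleValidationError(
                f"precision_matrix must be {p}x{p}, got {self.precision_matrix.shape}"
            )
        if not np.allclose(self.precision_matrix, self.precision_matrix.T):
            raise ScaleValidationError("precision_matrix not symmetric")
        if np.linalg.eigvalsh(self.precision_matrix).min() <= 0:
            raise ScaleValidationError("precision_matrix not positive definite")
        self.severity_thresholds = np.asarray(self.severity_thresholds, dtype=float)
        self.frequency_thresholds = np.asarray(self.frequency_thresholds, dtype=float)
        for name, arr in (
            ("severity_thresholds", self.severity_thresholds),
            ("frequency_thresholds", self.frequency_thresholds),
        ):
            if arr.shape != (p, 3):
                raise ScaleValidationError(f"{name} must be {p}x3")
            if not (np.diff(arr, axis=1) > 0).all():
                raise ScaleValidationError(f"{name} rows must be strictly increasing")
        self.followup_drift = np.asarray(self.followup_drift, dtype=float)
        if self.followup_drift.shape != (p,):
            raise ScaleValidationError(f"followup_drift must have length {p}")
        if not (0 <= self.retest_correlation <= 1):
            raise ScaleValidationError("retest_correlation must be in [0, 1]")

    @property
    def n_items(self) -> int:
        return self.scale.n_items


def true_partial_correlations(config: GeneratorConfig) -> np.ndarray:
    """Partial correlations implied by the precision matrix (zero diagonal)."""
    theta = config.precision_matrix
    d = np.sqrt(np.diag(theta))
    pcor = -theta / np.outer(d, d)
    np.fill_diagonal(pcor, 0.0)
    return pcor


def latent_correlation(config: GeneratorConfig) -> np.ndarray:
    """Marginal latent correlation matrix (inverse precision, standardized)."""
    cov = np.linalg.inv(config.precision_matrix)
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def _build_precision(
    rng: np.random.Generator,
    scale: ScaleDefinition,
    n_cross_edges: int,
    within_range: tuple[float, float],
    cross_range: tuple[float, float],
    forced_cross: tuple[tuple[int, int], ...] = (),
    negative_fraction: float = 0.2,
    min_eigval: float = 0.05,
) -> np.ndarray:
    """Sparse precision: full within-domain blocks plus random cross edges.

    Off-diagonals are shrunk geometrically if needed until the smallest
    eigenvalue clears ``min_eigval``.
    """
    p = scale.n_items
    item_index = {it: k for k, it in enumerate(scale.item_ids)}
    pcor = np.zeros((p, p))
    within_pairs = set()
    for dom in scale.domain_ids:
        idx = [item_index[i] for i in scale.domain_items(dom)]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                i, j = idx[a], idx[b]
                w = rng.uniform(*within_range)
                pcor[i, j] = pcor[j, i] = w
                within_pairs.add((min(i, j), max(i, j)))
    cross_candidates = [
        (i, j)
        for i in range(p)
        for j in range(i + 1, p)
        if (i, j) not in within_pairs and (i, j) not in forced_cross
    ]
    chosen = list(forced_cross)
    n_extra = max(0, n_cross_edges - len(forced_cross))
    pick = rng.choice(len(cross_candidates), size=n_extra, replace=False)
    chosen += [cross_candidates[k] for k in pick]
    for i, j in chosen:
        w = rng.uniform(*cross_range)
        if rng.random() < negative_fraction:
            w = -w
        pcor[i, j] = pcor[j, i] = w
    theta = np.eye(p) - pcor  # theta_ij = -pcor_ij with unit diagonal
    while np.linalg.eigvalsh(theta).min() < min_eigval:
        off = theta - np.eye(p)
        theta = np.eye(p) + 0.95 * off
    return theta


def default_config(seed: int, n_subjects: int = 499) -> GeneratorConfig:
    """NMSS-like defaults: strong per-item floor effects, 9-domain block
    structure with a dense web of weak cross-domain edges (~190 of 435 true
    edges, including a cardiovascular/perceptual fainting-delusions edge),
    mild longitudinal worsening on most items.
    """
    scale = nmss_scale()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2023]))
    item_index = {it: k for k, it in enumerate(scale.item_ids)}
    fainting_delusions = (
        min(item_index["fainting"], item_index["delusions"]),
        max(item_index["fainting"], item_index["delusions"]),
    )
    theta = _build_precision(
        rng,
        scale,
        n_cross_edges=150,
        within_range=(0.15, 0.30),
        cross_range=(0.03, 0.09),
        forced_cross=(fainting_delusions,),
    )
    p = scale.n_items
    # Floor cut at or above the latent median => >=50% zeros per item.
    c1 = rng.uniform(0.1, 1.1, size=p)
    sev = np.column_stack([c1, c1 + 0.7, c1 + 1.4])
    freq = np.column_stack([c1 + 0.35, c1 + 0.9, c1 + 1.6])
    drift = rng.uniform(0.05, 0.22, size=p)
    drift[rng.choice(p, size=4, replace=False)] = 0.0  # a few stable symptoms
    return GeneratorConfig(
        n_subjects=n_subjects,
        precision_matrix=theta,
        severity_thresholds=sev,
        frequency_thresholds=freq,
        followup_drift=drift,
        retest_correlation=0.6,
        seed=seed,
        scale=scale,
    )


def small_scale(n_items: int = 8, n_domains: int = 2) -> ScaleDefinition:
    """A reduced synthetic sub-scale for fast tests and calibration studies."""
    items = tuple(f"item_{k + 1:02d}" for k in range(n_items))
    per = n_items // n_domains
    domain_map = {
        it: f"domain_{k // per + 1}" for k, it in enumerate(items)
    }
    return ScaleDefinition(
        item_ids=items,
        severity_levels=(0, 1, 2, 3),
        frequency_levels=(1, 2, 3, 4),
        domain_map=domain_map,
    )


def small_config(
    seed: int,
    n_subjects: int = 300,
    n_items: int = 8,
    n_cross_edges: int = 4,
    drift: float = 0.0,
    retest_correlation: float = 0.6,
) -> GeneratorConfig:
    """Small-network analogue of :func:`default_config` (same latent model)."""
    scale = small_scale(n_items=n_items)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 811]))
    theta = _build_precision(
        rng,
        scale,
        n_cross_edges=n_cross_edges,
        within_range=(0.2, 0.35),
        cross_range=(0.08, 0.15),
        min_eigval=0.1,
    )
    p = scale.n_items
    c1 = rng.uniform(0.0, 0.8, size=p)
    sev = np.column_stack([c1, c1 + 0.7, c1 + 1.4])
    freq = np.column_stack([c1 + 0.35, c1 + 0.9, c1 + 1.6])
    return GeneratorConfig(
        n_subjects=n_subjects,
        precision_matrix=theta,
        severity_thresholds=sev,
        frequency_thresholds=freq,
        followup_drift=np.full(p, float(drift)),
        retest_correlation=retest_correlation,
        seed=seed,
        scale=scale,
    )


def _discretize(z: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    """Latent matrix -> item scores; monotone non-decreasing per item."""
    p = config.n_items
    scores = np.zeros_like(z, dtype=int)
    for j in range(p):
        sev = np.searchsorted(config.severity_thresholds[j], z[:, j], side="right")
        freq = 1 + np.searchsorted(config.frequency_thresholds[j], z[:, j], side="right")
        scores[:, j] = sev * freq
    return scores


def simulate(config: GeneratorConfig) -> tuple[ItemMatrix, ItemMatrix]:
    """Draw paired baseline / follow-up item matrices; fully seeded."""
    rng = np.random.default_rng(config.seed)
    n, p = config.n_subjects, config.n_items
    corr = latent_correlation(config)
    chol = np.linalg.cholesky(corr)
    z1 = rng.standard_normal((n, p)) @ chol.T
    eps = rng.standard_normal((n, p)) @ chol.T
    rho = config.retest_correlation
    z2 = rho * z1 + np.sqrt(1.0 - rho**2) * eps + config.followup_drift
    ids = [f"S{k + 1:04d}" for k in range(n)]
    baseline = ItemMatrix(
        subject_ids=ids, timepoint="baseline",
        scores=_discretize(z1, config), scale=config.scale,
    )
    followup = ItemMatrix(
        subject_ids=ids, timepoint="followup",
        scores=_discretize(z2, config), scale=config.scale,
    )
    return baseline, followup


def _score_intervals(config: GeneratorConfig, item: int):
    """Distinct achievable scores of an item and their latent z-intervals."""
    cuts = np.unique(
        np.concatenate([config.severity_thresholds[item], config.frequency_thresholds[item]])
    )
    edges = np.concatenate([[-np.inf], cuts, [np.inf]])
    sev = np.searchsorted(config.severity_thresholds[item], cuts, side="right")
    sev = np.concatenate([[0], sev])
    freq = 1 + np.searchsorted(config.frequency_thresholds[item], cuts, side="right")
    freq = np.concatenate([[1], freq])
    values = sev * freq
    return values, edges


def implied_rank_correlation(config: GeneratorConfig, i: int, j: int) -> float:
    """Population Spearman correlation of the discretized scores of items i, j.

    Computed from the exact joint cell probabilities of the bivariate normal
    latent pair via rectangle probabilities, with the midrank convention for
    ties — the value the sample rank correlation converges to.
    """
    rho = latent_correlation(config)[i, j]
    vals_i, edges_i = _score_intervals(config, i)
    vals_j, edges_j = _score_intervals(config, j)
    bvn = stats.multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]])

    def rect_cdf(x, y):
        if np.isinf(x) and x < 0 or np.isinf(y) and y < 0:
            return 0.0
        xx = min(x, 10.0)
        yy = min(y, 10.0)
        return float(bvn.cdf([xx, yy]))

    ni, nj = len(vals_i), len(vals_j)
    pmf = np.zeros((ni, nj))
    for a in range(ni):
        for b in range(nj):
            pmf[a, b] = (
                rect_cdf(edges_i[a + 1], edges_j[b + 1])
                - rect_cdf(edges_i[a], edges_j[b + 1])
                - rect_cdf(edges_i[a + 1], edges_j[b])
                + rect_cdf(edges_i[a], edges_j[b])
            )
    pmf = np.clip(pmf, 0.0, None)
    pmf /= pmf.sum()
    pi = pmf.sum(axis=1)
    pj = pmf.sum(axis=0)
    # midranks on the [0, 1] probability scale
    ri = np.cumsum(pi) - pi / 2
    rj = np.cumsum(pj) - pj / 2
    mi = ri @ pi
    mj = rj @ pj
    cov = (pmf * np.outer(ri - mi, rj - mj)).sum()
    vi = pi @ (ri - mi) ** 2
    vj = pj @ (rj - mj) ** 2
    return float(cov / np.sqrt(vi * vj))
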