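"""Scale psychometrics: acceptability, reliability and paired comparisons.

Acceptability covers the computable fraction of total scores (criterion
> 95%) and per-item floor/ceiling shares (criterion <= 15%).  Reliability
covers Cronbach's alpha per domain (>= 0.7), item homogeneity (mean
inter-item correlation, >= 0.3) and corrected item-total correlations
(>= 0.4).  Longitudinal change uses the paired Wilcoxon signed-rank test
with the effect size r = |Z| / sqrt(N).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scale import ItemMatrix, ScaleDefinition, aggregate_domains, total_score

__all__ = [
    "AcceptabilityReport",
    "ReliabilityReport",
    "PairedComparison",
    "acceptability",
    "cronbach_alpha",
    "item_homogeneity",
    "corrected_item_total",
    "reliability",
    "paired_wilcoxon",
    "effect_size_r",
    "shapiro_normality",
    "table_one",
]

COMPUTABLE_THRESHOLD = 0.95
FLOOR_CEILING_THRESHOLD = 0.15
ALPHA_THRESHOLD = 0.7
HOMOGENEITY_THRESHOLD = 0.3
ITEM_TOTAL_THRESHOLD = 0.4


@dataclass
class AcceptabilityReport:
    computable_fraction: float
    floor: pd.Series        # per item, share of subjects at the minimum (0)
    ceiling: pd.Series      # per item, share at the maximum (12)
    item_missing: pd.Series  # per item, share of missing cells
    computable_ok: bool
    floor_ok: pd.Series
    ceiling_ok: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "floor": self.floor,
                "ceiling": self.ceiling,
                "missing": self.item_missing,
                "floor_ok": self.floor_ok,
                "ceiling_ok": self.ceiling_ok,
            }
        )


@dataclass
class ReliabilityReport:
    domain_alpha: pd.Series
    domain_homogeneity: pd.Series
    corrected_item_total: pd.Series
    inter_item_corr: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"alpha": self.domain_alpha, "homogeneity": self.domain_homogeneity}
        )


@dataclass
class PairedComparison:
    """One descriptive-table row: paired Wilcoxon Z, p, effect size r, medians/IQRs."""

    variable: str
    n: int
    z: float
    p: float
    r: float
    median_baseline: float
    iqr_baseline: tuple[float, float]
    median_followup: float
    iqr_followup: tuple[float, float]
    degenerate: bool = False


def acceptability(matrix: ItemMatrix) -> AcceptabilityReport:
    """Computable fraction of the total score and per-item floor/ceiling shares.

    Reported on the full file before any listwise deletion: floor/ceiling
    shares are among subjects with an observed value for the item.
    """
    if matrix.n_subjects == 0:
        raise ValueError("empty matrix")
    obs = ~matrix.missing
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        raise ValueError("item with no observed values")
    max_score = matrix.scale.max_item_score
    floor = (matrix.scores == 0) & obs
    ceiling = (matrix.scores == max_score) & obs
    items = list(matrix.item_ids)
    floor_s = pd.Series(floor.sum(axis=0) / n_obs, index=items)
    ceil_s = pd.Series(ceiling.sum(axis=0) / n_obs, index=items)
    miss_s = pd.Series(matrix.missing.mean(axis=0), index=items)
    computable = float((~matrix.missing.any(axis=1)).mean())
    return AcceptabilityReport(
        computable_fraction=computable,
        floor=floor_s,
        ceiling=ceil_s,
        item_missing=miss_s,
        computable_ok=computable > COMPUTABLE_THRESHOLD,
        floor_ok=floor_s <= FLOOR_CEILING_THRESHOLD,
        ceiling_ok=ceil_s <= FLOOR_CEILING_THRESHOLD,
    )


def cronbach_alpha(scores: np.ndarray) -> float:
    """alpha = k/(k-1) * (1 - sum of item variances / variance of the sum)."""
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need an n x k matrix with k >= 2")
    k = X.shape[1]
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance: alpha undefined")
    return float(k / (k - 1) * (1.0 - X.var(axis=0, ddof=1).sum() / total_var))


def item_homogeneity(scores: np.ndarray) -> float:
    """Mean of the off-diagonal pairwise Pearson correlations.

    Pairs involving a constant column are undefined and excluded with a
    warning.
    """
    X = np.asarray(scores, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need >= 2 items")
    sd = X.std(axis=0)
    if (sd == 0).any():
        warnings.warn("constant column(s) excluded from homogeneity", stacklevel=2)
        X = X[:, sd > 0]
        if X.shape[1] < 2:
            return float("nan")
    R = np.corrcoef(X, rowvar=False)
    iu = np.triu_indices(R.shape[0], 1)
    return float(np.mean(R[iu]))


def corrected_item_total(scores: np.ndarray, item: int) -> float:
    """Correlation of one item with the sum of all remaining items."""
    X = np.asarray(scores, dtype=float)
    rest = np.delete(X, item, axis=1).sum(axis=1)
    col = X[:, item]
    if col.std() == 0 or rest.std() == 0:
        warnings.warn("constant column: corrected item-total undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(col, rest)[0, 1])


def reliability(matrix: ItemMatrix, scale: ScaleDefinition | None = None) -> ReliabilityReport:
    """Per-domain alpha/homogeneity, per-item corrected item-total, and the
    full inter-item correlation matrix (complete rows)."""
    scale = scale or matrix.scale
    X = matrix.complete_rows().scores.astype(float)
    items = list(scale.item_ids)
    alphas, homog = {}, {}
    for dom in scale.domain_ids:
        idx = [items.index(i) for i in scale.domain_items(dom)]
        sub = X[:, idx]
        try:
            alphas[dom] = cronbach_alpha(sub)
        except ValueError:
            alphas[dom] = float("nan")
        homog[dom] = item_homogeneity(sub)
    cit = {it: corrected_item_total(X, k) for k, it in enumerate(items)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        R = np.corrcoef(X, rowvar=False)
    return ReliabilityReport(
        domain_alpha=pd.Series(alphas),
        domain_homogeneity=pd.Series(homog),
        corrected_item_total=pd.Series(cit),
        inter_item_corr=pd.DataFrame(R, index=items, columns=items),
    )


def effect_size_r(z: float, n: int) -> float:
    """Effect size of a paired Wilcoxon test: r = |Z| / sqrt(N)."""
    if n <= 0:
        raise ValueError("n must be positive")
    return abs(z) / np.sqrt(n)


def _iqr(x: np.ndarray) -> tuple[float, float]:
    return (float(np.percentile(x, 25)), float(np.percentile(x, 75)))


def paired_wilcoxon(
    x_baseline: np.ndarray, x_followup: np.ndarray, variable: str = ""
) -> PairedComparison:
    """Paired Wilcoxon signed-rank test with the normal approximation.

    Ties are rank-averaged with the variance tie correction and zero
    differences are dropped (classical Wilcoxon convention).  The effect
    size uses N = number of submitted pairs, not the post-exclusion count.
    """
    x = np.asarray(x_baseline, dtype=float)
    y = np.asarray(x_followup, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("need two equal-length 1-D vectors")
    n = len(x)
    if n < 10:
        warnings.warn("n < 10: normal approximation is crude", stacklevel=2)
    base = dict(
        variable=variable,
        n=n,
        median_baseline=float(np.median(x)),
        iqr_baseline=_iqr(x),
        median_followup=float(np.median(y)),
        iqr_followup=_iqr(y),
    )
    if np.all(x == y):
        return PairedComparison(z=0.0, p=1.0, r=0.0, degenerate=True, **base)
    res = stats.wilcoxon(
        y, x, zero_method="wilcox", correction=False, method="approx"
    )
    z = float(res.zstatistic)
    p = float(res.pvalue)
    return PairedComparison(z=z, p=p, r=effect_size_r(z, n), **base)


def shapiro_normality(matrix: ItemMatrix) -> pd.Series:
    """Shapiro-Wilk p-value per item (descriptive screen; selects median/IQR
    reporting only, never branches the network pipeline)."""
    X = matrix.complete_rows().scores.astype(float)
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for k, it in enumerate(matrix.item_ids):
            col = X[:, k]
            out[it] = float("nan") if np.ptp(col) == 0 else float(stats.shapiro(col).pvalue)
    return pd.Series(out)


def table_one(baseline: ItemMatrix, followup: ItemMatrix) -> pd.DataFrame:
    """Descriptive comparison rows for the total score, each domain and each
    item: median (IQR) at both visits, Wilcoxon Z, p and r."""
    b = baseline.complete_rows()
    f = followup.complete_rows()
    common = [s for s in b.subject_ids if s in set(f.subject_ids)]
    bi = [b.subject_ids.index(s) for s in common]
    fi = [f.subject_ids.index(s) for s in common]
    rows: list[PairedComparison] = []
    rows.append(
        paired_wilcoxon(
            total_score(b)[bi], total_score(f)[fi], variable="total_score"
        )
    )
    db = aggregate_domains(b).scores[bi]
    df_ = aggregate_domains(f).scores[fi]
    for k, dom in enumerate(b.scale.domain_ids):
        rows.append(paired_wilcoxon(db[:, k], df_[:, k], variable=f"domain:{dom}"))
    for k, it in enumerate(b.item_ids):
        rows.append(
            paired_wilcoxon(b.scores[bi, k], f.scores[fi, k], variable=f"item:{it}")
        )
    return pd.DataFrame(
        {
            "variable": [r.variable for r in rows],
            "n": [r.n for r in rows],
            "median_baseline": [r.median_baseline for r in rows],
            "iqr25_baseline": [r.iqr_baseline[0] for r in rows],
            "iqr75_baseline": [r.iqr_baseline[1] for r in rows],
            "median_followup": [r.median_followup for r in rows],
            "iqr25_followup": [r.iqr_followup[0] for r in rows],
            "iqr75_followup": [r.iqr_followup[1] for r in rows],
            "z": [r.z for r in rows],
            "p": [r.p for r in rows],
            "r": [r.r for r in rows],
        }
    )
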