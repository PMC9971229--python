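"""NMSS instrument structure, scoring rules and item-matrix I/O.

The Non-Motor Symptoms Scale in Parkinson's Disease (NMSS) has 30 items,
each scored as severity (0-3) times frequency (1-4), so the achievable item
scores are the products {0, 1, 2, 3, 4, 6, 8, 9, 12} and the total score
ranges 0-360.  Items group into nine domains (cardiovascular, sleep/fatigue,
mood/cognition, perceptual problems, attention/memory, gastrointestinal,
urinary, sexual function, miscellaneous).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ScaleDefinition",
    "ItemMatrix",
    "DomainMatrix",
    "ScaleValidationError",
    "ACHIEVABLE_SCORES",
    "nmss_scale",
    "item_score",
    "total_score",
    "aggregate_domains",
    "read_item_csv",
    "write_item_csv",
]

#: Achievable severity x frequency products.
ACHIEVABLE_SCORES = frozenset({0, 1, 2, 3, 4, 6, 8, 9, 12})

SEVERITY_LEVELS = (0, 1, 2, 3)
FREQUENCY_LEVELS = (1, 2, 3, 4)

# Item short names in instrument order (items 1-30).
NMSS_ITEM_IDS = (
    "light_headedness",      # 1
    "fainting",              # 2
    "daytime_sleepiness",    # 3
    "fatigue",               # 4
    "sleep_initiation",      # 5
    "restless_legs",         # 6
    "loss_of_interest",      # 7
    "lack_of_motivation",    # 8
    "feeling_nervous",       # 9
    "feeling_sad",           # 10
    "flat_mood",             # 11
    "anhedonia",             # 12
    "hallucinations",        # 13
    "delusions",             # 14
    "diplopia",              # 15
    "concentration",         # 16
    "forgetfulness",         # 17
    "forget_to_do_things",   # 18
    "sialorrhea",            # 19
    "dysphagia",             # 20
    "constipation",          # 21
    "urinary_urgency",       # 22
    "urinary_frequency",     # 23
    "nocturia",              # 24
    "sexual_interest",       # 25
    "sexual_problems",       # 26
    "pain",                  # 27
    "taste_smell",           # 28
    "weight_change",         # 29
    "hyperhidrosis",         # 30
)

NMSS_DOMAIN_IDS = (
    "cardiovascular",        # 1: items 1-2
    "sleep_fatigue",         # 2: items 3-6
    "mood_cognition",        # 3: items 7-12
    "perceptual",            # 4: items 13-15
    "attention_memory",      # 5: items 16-18
    "gastrointestinal",      # 6: items 19-21
    "urinary",               # 7: items 22-24
    "sexual_function",       # 8: items 25-26
    "miscellaneous",         # 9: items 27-30
)

_NMSS_DOMAIN_SIZES = (2, 4, 6, 3, 3, 3, 3, 2, 4)


class ScaleValidationError(ValueError):
    """Raised when scale structure, levels or scores violate the instrument."""


def _nmss_domain_map() -> dict[str, str]:
    mapping: dict[str, str] = {}
    i = 0
    for dom, size in zip(NMSS_DOMAIN_IDS, _NMSS_DOMAIN_SIZES):
        for _ in range(size):
            mapping[NMSS_ITEM_IDS[i]] = dom
            i += 1
    return mapping


@dataclass(frozen=True)
class ScaleDefinition:
    """Item labels, level grids and the item -> domain mapping of a scale."""

    item_ids: tuple[str, ...]
    severity_levels: tuple[int, ...]
    frequency_levels: tuple[int, ...]
    domain_map: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.item_ids) != len(set(self.item_ids)):
            raise ScaleValidationError("duplicate item_ids")
        missing = [i for i in self.item_ids if i not in self.domain_map]
        if missing:
            raise ScaleValidationError(f"items missing from domain_map: {missing}")
        extra = set(self.domain_map) - set(self.item_ids)
        if extra:
            raise ScaleValidationError(f"domain_map entries for unknown items: {sorted(extra)}")

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    @property
    def domain_ids(self) -> tuple[str, ...]:
        """Domains in first-appearance (instrument) order."""
        seen: list[str] = []
        for item in self.item_ids:
            dom = self.domain_map[item]
            if dom not in seen:
                seen.append(dom)
        return tuple(seen)

    @property
    def n_domains(self) -> int:
        return len(self.domain_ids)

    def domain_items(self, domain: str) -> tuple[str, ...]:
        return tuple(i for i in self.item_ids if self.domain_map[i] == domain)

    @property
    def max_item_score(self) -> int:
        return max(self.severity_levels) * max(self.frequency_levels)

    @property
    def max_total_score(self) -> int:
        return self.max_item_score * self.n_items

    @property
    def achievable_scores(self) -> frozenset[int]:
        return frozenset(
            s * f for s in self.severity_levels for f in self.frequency_levels
        )


def nmss_scale() -> ScaleDefinition:
    """The 30-item / 9-domain NMSS with severity 0-3 and frequency 1-4."""
    scale = ScaleDefinition(
        item_ids=NMSS_ITEM_IDS,
        severity_levels=SEVERITY_LEVELS,
        frequency_levels=FREQUENCY_LEVELS,
        domain_map=_nmss_domain_map(),
    )
    assert scale.n_items == 30 and scale.n_domains == 9
    return scale


def item_score(severity: int, frequency: int) -> int:
    """Score one item: severity (0-3) times frequency (1-4), in 0..12."""
    severity = int(severity)
    frequency = int(frequency)
    if severity not in SEVERITY_LEVELS:
        raise ScaleValidationError(f"severity {severity} outside 0..3")
    if frequency not in FREQUENCY_LEVELS:
        raise ScaleValidationError(f"frequency {frequency} outside 1..4")
    return severity * frequency


def _as_2d_int(scores, n_cols: int, what: str) -> np.ndarray:
    arr = np.asarray(scores)
    if arr.ndim != 2 or arr.shape[1] != n_cols:
        raise ScaleValidationError(
            f"{what} must be a 2-D array with {n_cols} columns, got shape {arr.shape}"
        )
    return arr


@dataclass
class ItemMatrix:
    """Subjects x items ordinal score matrix for one time point.

    ``scores`` holds integers from the achievable product set; ``missing``
    is a boolean mask of the same shape (True = missing).  Masked cells may
    hold any placeholder value and are ignored by every consumer.
    """

    subject_ids: list[str]
    timepoint: str
    scores: np.ndarray
    missing: np.ndarray = None  # type: ignore[assignment]
    scale: ScaleDefinition = field(default_factory=nmss_scale)

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.scores = _as_2d_int(self.scores, self.scale.n_items, "scores").astype(int)
        if self.missing is None:
            self.missing = np.zeros_like(self.scores, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != self.scores.shape:
            raise ScaleValidationError("missing mask shape mismatch")
        if len(self.subject_ids) != self.scores.shape[0]:
            raise ScaleValidationError(
                f"{len(self.subject_ids)} subject_ids but {self.scores.shape[0]} score rows"
            )
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ScaleValidationError("duplicate subject_ids")
        achievable = self.scale.achievable_scores
        observed = self.scores[~self.missing]
        bad = set(np.unique(observed)) - achievable
        if bad:
            raise ScaleValidationError(
                f"scores {sorted(bad)} are not achievable severity x frequency products"
            )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def item_ids(self) -> tuple[str, ...]:
        return self.scale.item_ids

    def complete_rows(self) -> "ItemMatrix":
        """Subjects with no missing item (listwise deletion)."""
        keep = ~self.missing.any(axis=1)
        return replace(
            self,
            subject_ids=[s for s, k in zip(self.subject_ids, keep) if k],
            scores=self.scores[keep],
            missing=self.missing[keep],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores.astype(float), columns=list(self.item_ids), index=self.subject_ids
        )
        df[self.missing] = np.nan
        df.index.name = "subject_id"
        return df


@dataclass
class DomainMatrix:
    """Subjects x domains matrix of within-domain item sums."""

    subject_ids: list[str]
    timepoint: str
    scores: np.ndarray
    scale: ScaleDefinition = field(default_factory=nmss_scale)

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.scores = _as_2d_int(self.scores, self.scale.n_domains, "scores").astype(int)
        if len(self.subject_ids) != self.scores.shape[0]:
            raise ScaleValidationError("subject_ids / rows mismatch")
        max_item = self.scale.max_item_score
        for j, dom in enumerate(self.scale.domain_ids):
            cap = max_item * len(self.scale.domain_items(dom))
            if (self.scores[:, j] > cap).any() or (self.scores[:, j] < 0).any():
                raise ScaleValidationError(f"domain {dom!r} score outside 0..{cap}")

    @property
    def domain_ids(self) -> tuple[str, ...]:
        return self.scale.domain_ids

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, columns=list(self.domain_ids), index=self.subject_ids)
        df.index.name = "subject_id"
        return df


def total_score(matrix: ItemMatrix) -> np.ndarray:
    """Per-subject total (sum over the 30 items); NaN where any item is missing."""
    totals = matrix.scores.sum(axis=1).astype(float)
    totals[matrix.missing.any(axis=1)] = np.nan
    return totals


def aggregate_domains(matrix: ItemMatrix, scale: ScaleDefinition | None = None) -> DomainMatrix:
    """Sum items within each domain, in documented domain order.

    Requires complete rows; rows with missing items are dropped (the
    longitudinal analysis is restricted to completers).
    """
    scale = scale or matrix.scale
    complete = matrix.complete_rows()
    cols = []
    for dom in scale.domain_ids:
        idx = [scale.item_ids.index(i) for i in scale.domain_items(dom)]
        cols.append(complete.scores[:, idx].sum(axis=1))
    return DomainMatrix(
        subject_ids=complete.subject_ids,
        timepoint=complete.timepoint,
        scores=np.column_stack(cols),
        scale=scale,
    )


def read_item_csv(
    path, scale: ScaleDefinition | None = None, timepoint: str = ""
) -> ItemMatrix:
    """Read a subject x item CSV (header: subject_id then items in scale order).

    Empty cells are treated as missing.  Scores outside the achievable
    product set raise with the offending row and column.
    """
    scale = scale or nmss_scale()
    df = pd.read_csv(path, dtype={0: str})
    if df.columns[0] != "subject_id":
        raise ScaleValidationError(
            f"first column must be 'subject_id', got {df.columns[0]!r}"
        )
    expected = list(scale.item_ids)
    got = list(df.columns[1:])
    if got != expected:
        unknown = [c for c in got if c not in expected]
        if unknown:
            raise ScaleValidationError(f"unknown item columns: {unknown}")
        raise ScaleValidationError(
            f"item columns out of order or incomplete: expected {expected}, got {got}"
        )
    values = df[expected].to_numpy(dtype=float)
    missing = np.isnan(values)
    achievable = scale.achievable_scores
    scores = np.zeros_like(values, dtype=int)
    obs = ~missing
    rounded = np.where(obs, np.round(values), 0.0)
    if not np.allclose(np.where(obs, values, 0.0), rounded):
        r, c = np.argwhere(obs & (values != rounded))[0]
        raise ScaleValidationError(
            f"non-integer score {values[r, c]} at row {r + 2}, column {expected[c]!r}"
        )
    scores[obs] = rounded[obs].astype(int)
    bad = obs & ~np.isin(scores, sorted(achievable))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ScaleValidationError(
            f"score {scores[r, c]} at row {r + 2}, column {expected[c]!r} is not an "
            f"achievable severity x frequency product"
        )
    return ItemMatrix(
        subject_ids=df["subject_id"].tolist(),
        timepoint=timepoint,
        scores=scores,
        missing=missing,
        scale=scale,
    )


def write_item_csv(matrix: ItemMatrix, path) -> None:
    """Write an ItemMatrix as CSV; missing cells are left empty."""
    df = matrix.to_dataframe().reset_index()
    df.to_csv(path, index=False, float_format="%.0f")
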