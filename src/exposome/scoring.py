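"""Questionnaire scoring: chained PMM imputation, min-max scaling,
dimension composites, outcome inversion, and per-group rescaling.

The pipeline turns a subjects x items response table into ten bounded
dimension composites (the latent-model indicators) plus prepared
outcome columns.  Conventions:

* after scaling, higher values mean *less* adversity (items whose raw
  coding points the other way are polarity-flipped);
* composites are plain or weighted means of the scaled items mapped to
  each dimension;
* functional-ability and neuropsychiatric outcomes are inverted
  (``max - value``) so all three outcomes share a direction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DIMENSIONS = (
    "education",
    "food_insecurity",
    "financial_status",
    "assets",
    "access_healthcare",
    "childhood_labor",
    "subjective_ses",
    "childhood_experiences",
    "traumatic_events",
    "relations",
)

POLARITIES = ("adversity_high", "adversity_low")


class DegenerateItemError(ValueError):
    """Raised when an item has no observed spread (max == min)."""


class UnimputableItemError(ValueError):
    """Raised when an item cannot be imputed (e.g. fully missing)."""


@dataclass(frozen=True)
class ItemMeta:
    """Metadata for one questionnaire item."""

    item_id: str
    dimension: str
    polarity: str = "adversity_low"
    vmin: float | None = None
    vmax: float | None = None
    excluded: bool = False  # dementia-confounded items are dropped

    def __post_init__(self) -> None:
        if self.dimension not in DIMENSIONS:
            raise ValueError(f"unknown dimension {self.dimension!r}")
        if self.polarity not in POLARITIES:
            raise ValueError(f"unknown polarity {self.polarity!r}")


@dataclass
class ItemResponseTable:
    """Subjects x items responses plus per-item metadata."""

    values: pd.DataFrame
    meta: dict[str, ItemMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("subject ids must be unique")
        missing_meta = [c for c in self.values.columns if c not in self.meta]
        if missing_meta:
            raise ValueError(f"items without metadata: {missing_meta[:5]}")

    @property
    def items(self) -> list[str]:
        return list(self.values.columns)

    def active_items(self) -> list[str]:
        return [c for c in self.values.columns if not self.meta[c].excluded]

    def missing_fraction(self) -> float:
        return float(self.values.isna().to_numpy().mean())

    def copy(self) -> "ItemResponseTable":
        return ItemResponseTable(self.values.copy(), dict(self.meta))


def meta_from_frame(frame: pd.DataFrame) -> dict[str, ItemMeta]:
    """Parse an item-meta table (item_id, dimension, polarity, min, max, excluded)."""
    metas: dict[str, ItemMeta] = {}
    for row in frame.itertuples(index=False):
        metas[str(row.item_id)] = ItemMeta(
            item_id=str(row.item_id),
            dimension=str(row.dimension),
            polarity=str(getattr(row, "polarity", "adversity_low")),
            vmin=None if pd.isna(getattr(row, "min", np.nan)) else float(row.min),
            vmax=None if pd.isna(getattr(row, "max", np.nan)) else float(row.max),
            excluded=bool(getattr(row, "excluded", False)),
        )
    return metas


# ---------------------------------------------------------------------------
# chained predictive-mean-matching imputation
# ---------------------------------------------------------------------------

def impute_chained_pmm(
    table: ItemResponseTable,
    k_donors: int = 5,
    n_iterations: int = 10,
    seed: int | None = None,
) -> ItemResponseTable:
    """Chained-equations imputation with predictive mean matching.

    Items are visited in order of ascending missingness.  Each item with
    missing cells is regressed (OLS, ridge-stabilised) on every other
    item using the current working values; each missing cell receives
    the observed value of one of the ``k_donors`` donors whose predicted
    means are closest to the cell's prediction.  Every imputed value is
    therefore an observed value of the same item.
    """
    if k_donors < 1:
        raise ValueError("k_donors must be >= 1")
    values = table.values.copy()
    cols = list(values.columns)
    X = values.to_numpy(dtype=float)
    n, p = X.shape
    miss = np.isnan(X)
    if not miss.any():
        return table.copy()
    fully_missing = [cols[j] for j in range(p) if miss[:, j].all()]
    if fully_missing:
        raise UnimputableItemError(f"items with no observed values: {fully_missing[:5]}")
    for j in range(p):
        if (~miss[:, j]).sum() < k_donors:
            raise UnimputableItemError(
                f"item {cols[j]!r} has fewer observed values than k_donors={k_donors}"
            )
    rng = np.random.default_rng(seed)

    # initial fill: per-item observed mean
    col_means = np.nanmean(X, axis=0)
    work = np.where(miss, col_means, X)

    order = np.argsort(miss.sum(axis=0))
    ridge = 1e-8
    for _ in range(max(1, n_iterations)):
        for j in order:
            mj = miss[:, j]
            if not mj.any():
                continue
            obs = ~mj
            predictors = np.delete(work, j, axis=1)
            Z = np.column_stack([np.ones(n), predictors])
            Zo, yo = Z[obs], X[obs, j]
            gram = Zo.T @ Zo + ridge * np.eye(Z.shape[1])
            beta = np.linalg.solve(gram, Zo.T @ yo)
            pred = Z @ beta
            donors_pred = pred[obs]
            donors_y = yo
            for i in np.where(mj)[0]:
                d = np.abs(donors_pred - pred[i])
                k = min(k_donors, d.size)
                nearest = np.argpartition(d, k - 1)[:k]
                work[i, j] = donors_y[rng.choice(nearest)]

    out = pd.DataFrame(work, index=values.index, columns=values.columns)
    return ItemResponseTable(out, dict(table.meta))


# ---------------------------------------------------------------------------
# scaling and composites
# ---------------------------------------------------------------------------

def min_max_scale(
    values: np.ndarray | pd.Series,
    polarity: str = "adversity_low",
    vmin: float | None = None,
    vmax: float | None = None,
) -> np.ndarray:
    """Scale a vector to [0, 1]; flip adversity-coded items.

    ``adversity_high`` items (higher raw value = more adversity) are
    inverted so that the output convention is higher = less adversity.
    Bounds default to the observed min/max.
    """
    if polarity not in POLARITIES:
        raise ValueError(f"unknown polarity {polarity!r}")
    x = np.asarray(values, dtype=float)
    lo = np.nanmin(x) if vmin is None else float(vmin)
    hi = np.nanmax(x) if vmax is None else float(vmax)
    if not hi > lo:
        raise DegenerateItemError(f"degenerate item: max ({hi}) must exceed min ({lo})")
    scaled = (x - lo) / (hi - lo)
    if polarity == "adversity_high":
        scaled = 1.0 - scaled
    return scaled


def scale_table(table: ItemResponseTable, use_meta_bounds: bool = False) -> ItemResponseTable:
    """Min-max scale every active item; constant items dropped with a warning."""
    scaled: dict[str, np.ndarray] = {}
    meta: dict[str, ItemMeta] = {}
    for item in table.active_items():
        m = table.meta[item]
        try:
            scaled[item] = min_max_scale(
                table.values[item],
                m.polarity,
                vmin=m.vmin if use_meta_bounds else None,
                vmax=m.vmax if use_meta_bounds else None,
            )
        except DegenerateItemError:
            warnings.warn(f"dropping constant item {item!r}", stacklevel=2)
            continue
        meta[item] = m
    frame = pd.DataFrame(scaled, index=table.values.index)
    return ItemResponseTable(frame, meta)


def compute_dimension_scores(
    scaled: ItemResponseTable,
    weights: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Average scaled items within each dimension (optionally weighted).

    Returns subjects x dimensions scores in [0, 1].  Weights must be
    nonnegative; they are normalised within each dimension.
    """
    arr = scaled.values.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("scaled table contains missing values; impute first")
    if (arr < -1e-9).any() or (arr > 1 + 1e-9).any():
        raise ValueError("items must be scaled to [0, 1] before averaging")
    out: dict[str, np.ndarray] = {}
    for dim in DIMENSIONS:
        items = [c for c in scaled.values.columns if scaled.meta[c].dimension == dim]
        if not items:
            raise ValueError(f"dimension {dim!r} has no items")
        block = scaled.values[items].to_numpy(dtype=float)
        if weights is None:
            out[dim] = block.mean(axis=1)
        else:
            w = np.array([weights.get(i, 0.0) for i in items], dtype=float)
            if (w < 0).any():
                raise ValueError("weights must be nonnegative")
            if w.sum() <= 0:
                raise ValueError(f"dimension {dim!r} has zero total weight")
            out[dim] = block @ (w / w.sum())
    return pd.DataFrame(out, index=scaled.values.index)


def invert_outcome(values: np.ndarray | pd.Series, instrument_max: float) -> np.ndarray:
    """Reverse-score an instrument: ``max - value``.  Involution."""
    x = np.asarray(values, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size and (finite.min() < 0 or finite.max() > instrument_max):
        raise ValueError("values outside [0, instrument_max]")
    return instrument_max - x


def per_group_feature_rescale(
    matrix: pd.DataFrame | np.ndarray,
    group_labels: np.ndarray | pd.Series,
) -> pd.DataFrame:
    """Min-max rescale each feature *within* each group to [0, 1].

    Removes between-group location/scale offsets (the per-scanner
    harmonisation step).  Features constant within a group are left
    unscaled there, with a logged warning.
    """
    frame = pd.DataFrame(matrix).copy()
    labels = np.asarray(group_labels)
    if len(labels) != len(frame):
        raise ValueError("group_labels length mismatch")
    for g in np.unique(labels):
        sel = labels == g
        if sel.sum() < 2:
            raise ValueError(f"group {g!r} needs >= 2 subjects")
        block = frame.loc[sel]
        lo, hi = block.min(axis=0), block.max(axis=0)
        span = hi - lo
        flat = span <= 0
        if flat.any():
            logger.warning(
                "group %s: features %s constant, left unscaled",
                g, list(block.columns[flat]),
            )
        ok = ~flat
        frame.loc[sel, frame.columns[ok]] = (
            (block.loc[:, ok.index[ok]] - lo[ok]) / span[ok]
        )
    return frame
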