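"""Seeded synthetic cohorts with the latent structure the pipeline assumes.

A single adversity factor loads on items grouped into ten bounded
dimensions; three outcomes are linear in the latent; missingness,
group-specific demographics, connectomes, and motion traces are all
generated from one fanned-out integer seed so every downstream stage is
testable without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import ConnectomeSet, MotionTrace
from .scoring import DIMENSIONS, ItemMeta, ItemResponseTable

__all__ = [
    "CohortSpec",
    "OutcomePathSpec",
    "MissingnessSpec",
    "ConnectomeSpec",
    "SyntheticCohort",
    "generate_cohort",
    "apply_missingness",
    "generate_connectomes",
    "generate_motion_trace",
    "default_item_counts",
]

GROUPS = ("HC", "AD", "FTLD")
OUTCOMES = ("cognition", "functional_ability", "neuropsychiatric")

ITEM_FAMILIES = ("continuous", "likert", "binary", "count")

# native bounds per item family (pre-scaling questionnaire scales)
_FAMILY_BOUNDS = {
    "continuous": (0.0, 10.0),
    "likert": (0.0, 4.0),
    "binary": (0.0, 1.0),
    "count": (0.0, 12.0),
}


def default_item_counts(total: int = 319) -> dict[str, int]:
    """Split a total item budget over the ten dimensions (uneven, like a
    real instrument: trauma and asset batteries dominate)."""
    base = {
        "education": 20,
        "food_insecurity": 6,
        "financial_status": 40,
        "assets": 60,
        "access_healthcare": 30,
        "childhood_labor": 10,
        "subjective_ses": 3,
        "childhood_experiences": 30,
        "traumatic_events": 90,
        "relations": 30,
    }
    scale = total / sum(base.values())
    counts = {d: max(1, int(round(c * scale))) for d, c in base.items()}
    # adjust the largest dimension so the total is exact
    counts["traumatic_events"] += total - sum(counts.values())
    return counts


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level generating parameters."""

    n_per_group: dict[str, int]
    latent_mean_by_group: dict[str, float]
    loading_by_dimension: dict[str, float]
    item_counts: dict[str, int] = field(default_factory=default_item_counts)
    item_noise_sd: float = 0.5
    item_families: tuple[str, ...] = ("continuous", "likert", "binary")
    age_mean_sd_by_group: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"HC": (60.2, 11.6), "AD": (70.5, 8.4), "FTLD": (67.0, 7.8)}
    )
    sex_prob_by_group: dict[str, float] = field(
        default_factory=lambda: {"HC": 0.73, "AD": 0.63, "FTLD": 0.51}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 2:
                raise ValueError(f"group {g}: size must be >= 2, got {n}")
        for d, lam in self.loading_by_dimension.items():
            if d not in DIMENSIONS:
                raise ValueError(f"unknown dimension {d!r}")
            if not 0 < lam <= 1:
                raise ValueError(f"loading for {d} must be in (0, 1], got {lam}")
        for d in self.item_counts:
            if d not in DIMENSIONS:
                raise ValueError(f"unknown dimension {d!r}")
        for fam in self.item_families:
            if fam not in ITEM_FAMILIES:
                raise ValueError(f"unknown item family {fam!r}")
        for g, p in self.sex_prob_by_group.items():
            if not 0 <= p <= 1:
                raise ValueError(f"sex probability for {g} must be in [0, 1]")


@dataclass(frozen=True)
class OutcomePathSpec:
    """Standardized latent-to-outcome paths and residual noise."""

    path_by_outcome: dict[str, float]
    residual_sd_by_outcome: dict[str, float]
    floor_by_group: dict[str, dict[str, tuple[float, float]]] | None = None

    def __post_init__(self) -> None:
        for k, b in self.path_by_outcome.items():
            if k not in OUTCOMES:
                raise ValueError(f"unknown outcome {k!r}")
            if abs(b) >= 1:
                raise ValueError(f"|path| must be < 1 for {k}, got {b}")
        for k, s in self.residual_sd_by_outcome.items():
            if s <= 0:
                raise ValueError(f"residual sd must be > 0 for {k}")


@dataclass(frozen=True)
class MissingnessSpec:
    overall_rate: float
    mechanism: str = "MCAR"
    age_slope: float = 1.0  # logistic slope on standardized age (MAR-on-age)

    def __post_init__(self) -> None:
        if not 0 <= self.overall_rate < 0.5:
            raise ValueError("overall_rate must be in [0, 0.5)")
        if self.mechanism not in ("MCAR", "MAR-on-age"):
            raise ValueError("mechanism must be MCAR or MAR-on-age")


@dataclass(frozen=True)
class ConnectomeSpec:
    n_rois: int
    effect_edges: tuple[tuple[int, int, float], ...] = ()
    noise_sd: float = 1.0
    covariate_slopes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_rois < 4:
            raise ValueError("n_rois must be >= 4")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        seen = set()
        for i, j, _ in self.effect_edges:
            if i == j:
                raise ValueError("effect edge must connect distinct ROIs")
            if not (0 <= i < self.n_rois and 0 <= j < self.n_rois):
                raise ValueError("effect edge index out of range")
            key = frozenset((i, j))
            if key in seen:
                raise ValueError(f"duplicate effect edge {(i, j)}")
            seen.add(key)


@dataclass
class SyntheticCohort:
    items: ItemResponseTable
    latent: pd.Series
    outcomes: pd.DataFrame
    demographics: pd.DataFrame  # age, sex (1 = female), group

    def write(self, out_dir: str | Path) -> None:
        """Write items/outcomes/demographics CSV and item-meta TSV."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.items.values.to_csv(out / "items.csv", na_rep="NA")
        self.outcomes.to_csv(out / "outcomes.csv")
        self.demographics.to_csv(out / "demographics.csv")
        self.latent.rename("latent").to_csv(out / "latent.csv")
        meta = pd.DataFrame(
            [
                {
                    "item_id": m.item_id,
                    "dimension": m.dimension,
                    "polarity": m.polarity,
                    "min": m.vmin,
                    "max": m.vmax,
                    "excluded": m.excluded,
                }
                for m in self.items.meta.values()
            ]
        )
        meta.to_csv(out / "meta.tsv", sep="\t", index=False)


def _squash(h: np.ndarray, family: str, jitter: float, cut: float) -> np.ndarray:
    """Map an unbounded item signal monotonically into its native range."""
    lo, hi = _FAMILY_BOUNDS[family]
    if family == "binary":
        return (h > cut).astype(float)
    # linear map: ~1 sd of h covers a tenth of the range, so clipping is rare
    centered = 0.5 + h / 10.0 + jitter
    vals = lo + (hi - lo) * np.clip(centered, 0.0, 1.0)
    if family in ("likert", "count"):
        vals = np.round(vals)
    return vals


def generate_cohort(spec: CohortSpec, paths: OutcomePathSpec) -> SyntheticCohort:
    """Generate items, outcomes, demographics and the true latent.

    Item ``j`` of dimension ``d`` is ``loading_d * latent + noise`` squashed
    monotonically into the item's native bounded scale; alternating items
    are adversity-coded (sign-flipped before squashing, with polarity
    recorded in the metadata).  Outcomes are ``path_k * latent + residual``.
    """
    root = np.random.SeedSequence(spec.seed)
    rng_demo, rng_latent, rng_items, rng_out = (
        np.random.default_rng(s) for s in root.spawn(4)
    )

    groups: list[str] = []
    ages: list[np.ndarray] = []
    sexes: list[np.ndarray] = []
    for g in GROUPS:
        n_g = spec.n_per_group.get(g, 0)
        if n_g == 0:
            continue
        groups.extend([g] * n_g)
        mu, sd = spec.age_mean_sd_by_group.get(g, (65.0, 10.0))
        ages.append(rng_demo.normal(mu, sd, size=n_g))
        sexes.append(
            (rng_demo.random(n_g) < spec.sex_prob_by_group.get(g, 0.5)).astype(int)
        )
    n = len(groups)
    if n == 0:
        raise ValueError("empty cohort")
    group_arr = np.array(groups)
    subject_ids = [f"s{i:05d}" for i in range(n)]
    demo = pd.DataFrame(
        {"age": np.concatenate(ages), "sex": np.concatenate(sexes), "group": group_arr},
        index=subject_ids,
    )

    latent = np.empty(n)
    for g in GROUPS:
        sel = group_arr == g
        if sel.any():
            latent[sel] = spec.latent_mean_by_group.get(g, 0.0) + rng_latent.normal(
                size=sel.sum()
            )

    values: dict[str, np.ndarray] = {}
    metas: dict[str, ItemMeta] = {}
    fam_cycle = spec.item_families
    for d in DIMENSIONS:
        count = spec.item_counts.get(d, 0)
        if count == 0:
            continue
        lam = spec.loading_by_dimension.get(d)
        if lam is None:
            raise ValueError(f"no loading specified for dimension {d!r}")
        for j in range(count):
            family = fam_cycle[j % len(fam_cycle)]
            polarity = "adversity_low" if j % 2 == 0 else "adversity_high"
            g_signal = lam * latent + spec.item_noise_sd * rng_items.normal(size=n)
            h = g_signal if polarity == "adversity_low" else -g_signal
            jitter = rng_items.uniform(-0.05, 0.05)
            cut = rng_items.uniform(-0.5, 0.5)
            item_id = f"{d}_{j:03d}"
            values[item_id] = _squash(h, family, jitter, cut)
            lo, hi = _FAMILY_BOUNDS[family]
            metas[item_id] = ItemMeta(item_id, d, polarity, lo, hi)
    items = ItemResponseTable(pd.DataFrame(values, index=subject_ids), metas)

    out_cols: dict[str, np.ndarray] = {}
    for k in OUTCOMES:
        beta = paths.path_by_outcome.get(k, 0.0)
        sd = paths.residual_sd_by_outcome.get(k, 1.0)
        out_cols[k] = beta * latent + sd * rng_out.normal(size=n)
    outcomes = pd.DataFrame(out_cols, index=subject_ids)
    if paths.floor_by_group:
        for g, bounds in paths.floor_by_group.items():
            sel = group_arr == g
            for k, (lo, hi) in bounds.items():
                outcomes.loc[sel, k] = outcomes.loc[sel, k].clip(lo, hi)

    return SyntheticCohort(items, pd.Series(latent, index=subject_ids), outcomes, demo)


def apply_missingness(
    table: ItemResponseTable,
    m: MissingnessSpec,
    seed: int | None = None,
    age: np.ndarray | pd.Series | None = None,
) -> ItemResponseTable:
    """Blank item cells at the target overall rate.

    MCAR blanks uniformly; MAR-on-age makes a subject's missingness
    probability a logistic function of standardized age, with the
    intercept calibrated so the expected overall rate matches the target.
    """
    if m.overall_rate == 0:
        return table.copy()
    rng = np.random.default_rng(seed)
    values = table.values.copy()
    n, p = values.shape
    if m.mechanism == "MCAR":
        prob = np.full(n, m.overall_rate)
    else:
        if age is None:
            raise ValueError("MAR-on-age requires an age vector")
        z = np.asarray(age, dtype=float)
        z = (z - z.mean()) / (z.std() if z.std() > 0 else 1.0)
        # calibrate the intercept so mean sigmoid(b0 + slope*z) == rate
        lo, hi = -20.0, 20.0
        for _ in range(100):
            b0 = (lo + hi) / 2
            if np.mean(1 / (1 + np.exp(-(b0 + m.age_slope * z)))) > m.overall_rate:
                hi = b0
            else:
                lo = b0
        prob = 1 / (1 + np.exp(-(b0 + m.age_slope * z)))
    mask = rng.random((n, p)) < prob[:, None]
    # never blank an entire item
    full = mask.all(axis=0)
    if full.any():
        mask[rng.integers(0, n, size=int(full.sum())), np.where(full)[0]] = False
    arr = values.to_numpy(dtype=float)
    arr[mask] = np.nan
    out = pd.DataFrame(arr, index=values.index, columns=values.columns)
    return ItemResponseTable(out, dict(table.meta))


def generate_connectomes(
    spec: ConnectomeSpec,
    exposure: np.ndarray | pd.Series,
    covariates: pd.DataFrame | None = None,
    seed: int | None = None,
) -> ConnectomeSet:
    """Symmetric zero-diagonal matrices whose effect edges are linear in
    the exposure (plus covariate terms); all other edges are pure noise."""
    x = np.asarray(exposure, dtype=float)
    n = x.shape[0]
    if covariates is not None and len(covariates) != n:
        raise ValueError("covariates length mismatch")
    rng = np.random.default_rng(seed)
    r = spec.n_rois
    iu, ju = np.triu_indices(r, k=1)
    edges = rng.normal(0.0, spec.noise_sd, size=(n, iu.size))
    edge_index = {frozenset((i, j)): e for e, (i, j) in enumerate(zip(iu, ju))}
    for i, j, slope in spec.effect_edges:
        e = edge_index[frozenset((i, j))]
        edges[:, e] += slope * x
        if covariates is not None:
            for name, cslope in spec.covariate_slopes.items():
                if name in covariates:
                    edges[:, e] += cslope * np.asarray(covariates[name], dtype=float)
    mats = np.zeros((n, r, r))
    mats[:, iu, ju] = edges
    mats[:, ju, iu] = edges
    if isinstance(exposure, pd.Series):
        ids = [str(s) for s in exposure.index]
    else:
        ids = [f"s{i:05d}" for i in range(n)]
    return ConnectomeSet(ids, mats, [f"roi{i:03d}" for i in range(r)], covariates)


def generate_motion_trace(
    n_frames: int,
    spike_frames: tuple[int, ...] = (),
    spike_amplitude: float = 0.5,
    seed: int | None = None,
    baseline: float = 0.05,
) -> MotionTrace:
    """Motion parameters whose FD equals ``spike_amplitude`` exactly at
    spike frames and fluctuates around ``baseline`` elsewhere."""
    if n_frames < 20:
        raise ValueError("n_frames must be >= 20")
    for t in spike_frames:
        if not 1 <= t < n_frames:
            raise ValueError(f"spike frame {t} out of range [1, {n_frames - 1}]")
    rng = np.random.default_rng(seed)
    fd = baseline * rng.uniform(0.5, 1.5, size=n_frames)
    fd[0] = 0.0
    for t in spike_frames:
        fd[t] = spike_amplitude
    # realize the target FD on the x-translation alone, sign-alternating
    increments = fd[1:] * np.where(np.arange(n_frames - 1) % 2 == 0, 1.0, -1.0)
    params = np.zeros((n_frames, 6))
    params[1:, 0] = np.cumsum(increments)
    gs = rng.normal(size=n_frames)
    return MotionTrace(params, gs)
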