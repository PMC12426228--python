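"""Shared fixtures and generators for the test suite."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from exposome.scoring import DIMENSIONS
from exposome.sem import DEFAULT_OUTCOMES

DATA_DIR = Path(__file__).parent / "data"


def latent_cohort_frame(
    n: int,
    loading: float = 0.7,
    paths: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Gaussian dimension scores + outcomes driven by one latent factor.

    Dimensions have unit variance and the given standardized loading;
    outcomes have unit variance and the given standardized paths.
    Returns (frame, true_latent).
    """
    if paths is None:
        paths = {"cognition": 0.3, "functional_ability": 0.3, "neuropsychiatric": 0.3}
    rng = np.random.default_rng(seed)
    lat = rng.normal(size=n)
    cols: dict[str, np.ndarray] = {}
    for d in DIMENSIONS:
        cols[d] = loading * lat + np.sqrt(1 - loading**2) * rng.normal(size=n)
    for o in DEFAULT_OUTCOMES:
        b = paths.get(o, 0.0)
        cols[o] = b * lat + np.sqrt(1 - b**2) * rng.normal(size=n)
    return pd.DataFrame(cols), lat


@pytest.fixture(scope="session")
def sem_oracle_records() -> list[dict]:
    """Frozen external-implementation fits of 20 random covariance matrices."""
    with open(DATA_DIR / "sem_oracle.json") as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def medium_cohort() -> tuple[pd.DataFrame, np.ndarray]:
    return latent_cohort_frame(2000, seed=42)
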