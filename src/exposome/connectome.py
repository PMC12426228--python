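"""ROI-to-ROI connectivity association, per-ROI FDR, binarized degree
centrality, and motion/signal quality control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConnectomeSet",
    "EdgeStats",
    "MotionTrace",
    "QCReport",
    "fisher_z",
    "inverse_fisher_z",
    "edge_association",
    "bh_adjust",
    "row_fdr_mask",
    "degree_centrality",
    "framewise_displacement",
    "scrub_and_qc",
    "signal_quality",
]

_SYM_TOL = 1e-12


@dataclass
class ConnectomeSet:
    """Per-subject symmetric Fisher-z ROI x ROI matrices with covariates."""

    subject_ids: list[str]
    matrices: np.ndarray  # (n_subjects, n_rois, n_rois)
    roi_labels: list[str]
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrices, dtype=float)
        if m.ndim != 3 or m.shape[1] != m.shape[2]:
            raise ValueError("matrices must be (n_subjects, n_rois, n_rois)")
        if m.shape[0] != len(self.subject_ids):
            raise ValueError("subject_ids length mismatch")
        if m.shape[1] != len(self.roi_labels):
            raise ValueError("roi_labels length mismatch")
        if np.abs(m - m.transpose(0, 2, 1)).max(initial=0.0) > _SYM_TOL:
            raise ValueError("matrices must be symmetric")
        diag = m[:, np.arange(m.shape[1]), np.arange(m.shape[1])]
        if np.abs(diag).max(initial=0.0) > _SYM_TOL:
            raise ValueError("matrices must have zero diagonal")
        self.matrices = m

    @property
    def n_rois(self) -> int:
        return self.matrices.shape[1]

    def edge_vectors(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Upper-triangle values as (n_subjects, n_edges) plus (i, j) index arrays."""
        iu, ju = np.triu_indices(self.n_rois, k=1)
        return self.matrices[:, iu, ju], iu, ju


@dataclass
class EdgeStats:
    """Per-edge association statistics on the upper triangle."""

    roi_labels: list[str]
    edge_i: np.ndarray
    edge_j: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df: int

    def as_matrix(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        n = len(self.roi_labels)
        out = np.full((n, n), fill)
        out[self.edge_i, self.edge_j] = values
        out[self.edge_j, self.edge_i] = values
        np.fill_diagonal(out, fill)
        return out

    def t_matrix(self) -> np.ndarray:
        return self.as_matrix(self.t)

    def p_matrix(self) -> np.ndarray:
        return self.as_matrix(self.p, fill=1.0)


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher z-transform, ``z = atanh(r)``; requires |r| < 1."""
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) >= 1):
        raise ValueError("|r| must be < 1")
    return np.arctanh(r)


def inverse_fisher_z(z: np.ndarray | float) -> np.ndarray | float:
    return np.tanh(z)


def edge_association(
    cset: ConnectomeSet,
    predictor: np.ndarray | pd.Series,
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> EdgeStats:
    """OLS of every edge on the predictor plus nuisance covariates.

    Returns two-sided t statistics and p-values for the predictor
    coefficient, computed jointly for all upper-triangle edges.
    """
    Y, iu, ju = cset.edge_vectors()
    x = np.asarray(predictor, dtype=float)
    n = Y.shape[0]
    if x.shape[0] != n:
        raise ValueError("predictor length mismatch")
    cols = [np.ones(n), x]
    if covariates is None and cset.covariates is not None:
        covariates = cset.covariates
    if covariates is not None:
        C = np.asarray(pd.DataFrame(covariates), dtype=float)
        if C.shape[0] != n:
            raise ValueError("covariate length mismatch")
        cols.extend(C.T)
    X = np.column_stack(cols)
    k = X.shape[1]
    if n <= k:
        raise ValueError("fewer subjects than design parameters")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("rank-deficient design")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y  # (k, n_edges)
    resid = Y - X @ beta
    df = n - k
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[1] / se, np.sign(beta[1]) * np.inf)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return EdgeStats(list(cset.roi_labels), iu, ju, t, p, df)


def bh_adjust(p: np.ndarray, q: float) -> np.ndarray:
    """Benjamini–Hochberg step-up decisions for one family of p-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresh = q * (np.arange(1, m + 1) / m)
    below = ranked <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        kmax = np.max(np.nonzero(below)[0])
        reject[order[: kmax + 1]] = True
    return reject


def row_fdr_mask(stats_: EdgeStats, q: float = 0.05, scope: str = "row") -> np.ndarray:
    """FDR significance mask over the ROI x ROI matrix.

    ``scope="row"`` applies BH separately within each ROI's row of
    ``n_rois - 1`` p-values and symmetrises the decisions by union (the
    per-ROI connection-level correction).  ``scope="global"`` runs one BH
    pass over all upper-triangle edges.
    """
    n = len(stats_.roi_labels)
    P = stats_.p_matrix()
    mask = np.zeros((n, n), dtype=bool)
    if scope == "global":
        rej = bh_adjust(stats_.p, q)
        mask[stats_.edge_i[rej], stats_.edge_j[rej]] = True
        mask |= mask.T
        return mask
    if scope != "row":
        raise ValueError("scope must be 'row' or 'global'")
    for r in range(n):
        idx = np.array([c for c in range(n) if c != r])
        rej = bh_adjust(P[r, idx], q)
        mask[r, idx[rej]] = True
    mask |= mask.T  # union of the two row-wise decisions per edge
    return mask


def degree_centrality(
    mask: np.ndarray,
    roi_labels: list[str] | None = None,
    t_matrix: np.ndarray | None = None,
) -> pd.DataFrame:
    """Binarized degree: count of significant incident edges per ROI.

    If a t matrix is given, counts are also split by edge sign.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] != mask.shape[1] or not np.array_equal(mask, mask.T):
        raise ValueError("mask must be square and symmetric")
    m = mask.copy()
    np.fill_diagonal(m, False)
    labels = roi_labels if roi_labels is not None else [f"roi{i}" for i in range(m.shape[0])]
    out = pd.DataFrame({"degree": m.sum(axis=1).astype(int)}, index=labels)
    if t_matrix is not None:
        t_matrix = np.asarray(t_matrix, dtype=float)
        out["degree_pos"] = (m & (t_matrix > 0)).sum(axis=1).astype(int)
        out["degree_neg"] = (m & (t_matrix < 0)).sum(axis=1).astype(int)
    return out


# ---------------------------------------------------------------------------
# motion / signal quality control
# ---------------------------------------------------------------------------

ROTATION_RADIUS_MM = 50.0  # rotations converted to arc length on a 50 mm sphere


@dataclass
class MotionTrace:
    """Six rigid-body motion parameters per frame (mm, radians) plus an
    optional global-signal z series."""

    params: np.ndarray  # (n_frames, 6): tx ty tz rx ry rz
    global_signal_z: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.params, dtype=float)
        if p.ndim != 2 or p.shape[1] != 6:
            raise ValueError("params must be (n_frames, 6)")
        if p.shape[0] < 2:
            raise ValueError("need at least two frames")
        self.params = p
        if self.global_signal_z is not None:
            g = np.asarray(self.global_signal_z, dtype=float)
            if g.shape[0] != p.shape[0]:
                raise ValueError("global_signal_z length mismatch")
            self.global_signal_z = g

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]


def framewise_displacement(trace: MotionTrace) -> np.ndarray:
    """Power-style FD: sum of absolute frame-to-frame parameter changes,
    rotations expressed as arc length on a 50 mm sphere.  First frame is 0."""
    d = np.abs(np.diff(trace.params, axis=0))
    d[:, 3:] *= ROTATION_RADIUS_MM
    fd = np.concatenate([[0.0], d.sum(axis=1)])
    return fd


@dataclass
class QCReport:
    fd: np.ndarray
    global_signal_z: np.ndarray | None
    kept: np.ndarray
    artifact_free_proportion: float
    excluded: bool
    spatial_snr: float | None = None
    tsnr: list[float] | None = None
    tsnr_undefined_segments: int = 0


def scrub_and_qc(
    trace: MotionTrace,
    fd_threshold: float = 0.2,
    gs_z_threshold: float = 5.0,
    min_keep: float = 0.70,
) -> QCReport:
    """Flag high-motion frames and compute the artifact-free proportion.

    A frame is rejected when FD exceeds ``fd_threshold`` or the global
    signal |z| exceeds ``gs_z_threshold``.  Subjects retaining less than
    ``min_keep`` of frames are marked excluded (exactly ``min_keep`` is
    retained).
    """
    if trace.n_frames < 20:
        raise ValueError("need at least 20 frames")
    fd = framewise_displacement(trace)
    bad = fd > fd_threshold
    if trace.global_signal_z is not None:
        bad |= np.abs(trace.global_signal_z) > gs_z_threshold
    kept = ~bad
    prop = float(kept.mean())
    return QCReport(
        fd=fd,
        global_signal_z=trace.global_signal_z,
        kept=kept,
        artifact_free_proportion=prop,
        excluded=prop < min_keep,
    )


def signal_quality(
    series: np.ndarray,
    segment_len: int = 20,
) -> tuple[float | None, list[float | None]]:
    """Spatial SNR and segment-wise temporal SNR of a signal series.

    Spatial SNR is ``mean / sd`` over the whole series (undefined when
    the sd is zero); tSNR is the mean/sd within each non-overlapping
    ``segment_len``-frame segment, ``None`` where a segment is constant.
    """
    x = np.asarray(series, dtype=float).ravel()
    if segment_len < 2:
        raise ValueError("segment_len must be >= 2")
    if x.size < segment_len:
        raise ValueError("series shorter than one segment")
    sd = float(x.std(ddof=1))
    snr = float(x.mean()) / sd if sd > 0 else None
    tsnr: list[float | None] = []
    for start in range(0, x.size - segment_len + 1, segment_len):
        seg = x[start : start + segment_len]
        ssd = float(seg.std(ddof=1))
        tsnr.append(float(seg.mean()) / ssd if ssd > 0 else None)
    return snr, tsnr
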