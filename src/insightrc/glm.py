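"""Single-trial (least-squares-all) GLM beta estimation.

One HRF-convolved regressor per event, six motion regressors, per-run
mean and a discrete-cosine high-pass basis (128 s cutoff), per-voxel
ordinary least squares with optional AR(1) prewhitening, and extraction
of per-ROI pattern vectors from the event betas.

Pre- and post-solution events are fitted in two *separate* models in the
pipeline because their regressors overlap heavily for fast solutions;
this module is agnostic to that and simply fits whatever events it is
given.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .containers import PatternSet

logger = logging.getLogger(__name__)

__all__ = [
    "EventSpec",
    "DesignMatrix",
    "BetaPatternSet",
    "hrf_kernel",
    "build_single_trial_design",
    "fit_glm_ols",
    "extract_roi_patterns",
]

HRF_LENGTH_S = 32.0
HRF_PEAK_DELAY = 6.0
HRF_UNDERSHOOT_DELAY = 16.0
HRF_PEAK_DISP = 1.0
HRF_UNDERSHOOT_DISP = 1.0
HRF_RATIO = 6.0
HIGHPASS_CUTOFF_S = 128.0
_OVERSAMPLE = 16
_COLLINEARITY_R = 0.9


@dataclass
class EventSpec:
    """Events of one run: onsets/durations in seconds from run start."""

    onsets: np.ndarray
    durations: np.ndarray
    event_ids: list
    tr: float
    n_scans: int
    kinds: list = None  # per-event {"pre","post","nuisance"}; optional

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.n_scans <= 0:
            raise ValueError("n_scans must be positive")
        if len(self.onsets) != len(self.durations) or len(self.onsets) != len(
            self.event_ids
        ):
            raise ValueError("onsets, durations and event_ids must align")
        if np.any(self.onsets < 0):
            raise ValueError("onsets must be non-negative")
        run_len = self.n_scans * self.tr
        if np.any(self.onsets + self.durations > run_len + 1e-9):
            raise ValueError("event extends past the end of the run")
        if self.kinds is None:
            self.kinds = ["pre"] * len(self.onsets)

    @property
    def run_length_s(self) -> float:
        return self.n_scans * self.tr


@dataclass
class DesignMatrix:
    matrix: np.ndarray           # scans x regressors
    columns: list[str]
    event_columns: list[str]
    collinearity_flag: bool = False
    rank_deficient: bool = False

    def column_index(self, name: str) -> int:
        return self.columns.index(name)


def hrf_kernel(tr: float) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``tr`` seconds over 32 s.

    Difference of two gamma densities (peak delay 6 s, undershoot delay
    16 s, unit dispersions, peak:undershoot ratio 6), peak-normalized to
    a maximum of 1. The density maximum sits near 5 s.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    n = int(np.ceil(HRF_LENGTH_S / tr))
    t = np.arange(n) * tr
    h = (
        gamma_dist.pdf(t, HRF_PEAK_DELAY / HRF_PEAK_DISP, scale=HRF_PEAK_DISP)
        - gamma_dist.pdf(
            t, HRF_UNDERSHOOT_DELAY / HRF_UNDERSHOOT_DISP,
            scale=HRF_UNDERSHOOT_DISP,
        ) / HRF_RATIO
    )
    return h / h.max()


def _dct_highpass_basis(n_scans: int, tr: float,
                        cutoff_s: float = HIGHPASS_CUTOFF_S) -> np.ndarray:
    """Discrete-cosine drift basis, orders k = 1 .. floor(2 T / cutoff)."""
    total_s = n_scans * tr
    k_max = int(np.floor(2.0 * total_s / cutoff_s))
    n = np.arange(n_scans)
    cols = [
        np.sqrt(2.0 / n_scans) * np.cos(np.pi * k * (2 * n + 1) / (2 * n_scans))
        for k in range(1, k_max + 1)
    ]
    if not cols:
        return np.empty((n_scans, 0))
    return np.column_stack(cols)


def build_single_trial_design(
    events: EventSpec,
    motion: np.ndarray | None = None,
) -> DesignMatrix:
    """HRF-convolved single-trial design for one run.

    One column per event (boxcar of the event's duration convolved with
    the canonical HRF on a 16x oversampled grid, sampled at scan times),
    followed by six motion regressors (if given), a run-mean column and
    the 128-s discrete-cosine high-pass basis.

    Identical onsets (or near-identical ones) are legal but produce
    nearly collinear columns; the returned design carries a
    ``collinearity_flag`` when any pair of event columns correlates
    above 0.9.
    """
    tr = events.tr
    dt = tr / _OVERSAMPLE
    n_fine = events.n_scans * _OVERSAMPLE
    hrf_fine = hrf_kernel(dt)

    cols, names = [], []
    seen = {}
    for onset, dur, eid in zip(events.onsets, events.durations, events.event_ids):
        if (onset, dur) in seen:
            warnings.warn(
                f"events {seen[(onset, dur)]!r} and {eid!r} share onset {onset}s; "
                "their regressors are collinear",
                stacklevel=2,
            )
        seen[(onset, dur)] = eid
        box = np.zeros(n_fine)
        i0 = int(round(onset / dt))
        i1 = min(n_fine, int(round((onset + max(dur, dt)) / dt)))
        box[i0:i1] = 1.0
        reg = np.convolve(box, hrf_fine)[:n_fine][:: _OVERSAMPLE]
        cols.append(reg)
        names.append(str(eid))
    event_columns = list(names)

    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (events.n_scans, 6):
            raise ValueError("motion must be (n_scans, 6)")
        for j in range(6):
            cols.append(motion[:, j])
            names.append(f"motion_{j + 1}")

    cols.append(np.ones(events.n_scans))
    names.append("run_mean")

    dct = _dct_highpass_basis(events.n_scans, tr)
    for k in range(dct.shape[1]):
        cols.append(dct[:, k])
        names.append(f"dct_{k + 1}")

    X = np.column_stack(cols) if cols else np.empty((events.n_scans, 0))

    collinear = False
    if len(event_columns) >= 2:
        E = X[:, : len(event_columns)]
        sd = E.std(axis=0)
        ok = sd > 0
        if ok.sum() >= 2:
            C = np.corrcoef(E[:, ok].T)
            np.fill_diagonal(C, 0.0)
            collinear = bool(np.nanmax(np.abs(C)) > _COLLINEARITY_R)
        if np.any(~ok) or collinear:
            collinear = True
    rank_deficient = np.linalg.matrix_rank(X) < X.shape[1] if X.size else False
    return DesignMatrix(
        matrix=X,
        columns=names,
        event_columns=event_columns,
        collinearity_flag=collinear,
        rank_deficient=rank_deficient,
    )


@dataclass
class BetaPatternSet:
    """Per-voxel beta estimates for the event regressors of one run."""

    betas: np.ndarray        # events x voxels
    event_ids: list[str]
    se: np.ndarray           # events x voxels, OLS standard errors
    sigma2: np.ndarray       # per-voxel residual variance
    df_resid: int
    ar1_rho: float | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.betas, index=self.event_ids)


def _ols(Y: np.ndarray, X: np.ndarray, pinv: bool) -> tuple[np.ndarray, np.ndarray]:
    if pinv:
        Xp = np.linalg.pinv(X)
        B = Xp @ Y
        xtx_inv_diag = np.sum(Xp * Xp, axis=1)
    else:
        B, *_ = np.linalg.lstsq(X, Y, rcond=None)
        xtx_inv_diag = np.diag(np.linalg.inv(X.T @ X))
    return B, xtx_inv_diag


def fit_glm_ols(
    Y: np.ndarray,
    design: DesignMatrix,
    ar1: bool = False,
    allow_pinv: bool = False,
) -> BetaPatternSet:
    """Per-voxel least squares for every event column of the design.

    Parameters
    ----------
    Y:
        ``(n_voxels, n_scans)`` data matrix.
    ar1:
        When True, a single pooled lag-1 autocorrelation coefficient is
        estimated from the OLS residuals and both data and design are
        prewhitened (first-difference quasi-differencing) before a
        second pass. Off by default.
    allow_pinv:
        Rank-deficient designs raise unless this is set, in which case
        the Moore-Penrose pseudo-inverse is used.
    """
    Y = np.asarray(Y, dtype=float)
    X = design.matrix
    if Y.ndim != 2 or Y.shape[1] != X.shape[0]:
        raise ValueError("Y must be (n_voxels, n_scans) matching the design")
    if design.rank_deficient and not allow_pinv:
        raise np.linalg.LinAlgError(
            "design matrix is rank deficient; pass allow_pinv=True to fit anyway"
        )
    Yt = Y.T  # scans x voxels
    B, xtx_diag = _ols(Yt, X, design.rank_deficient)
    resid = Yt - X @ B
    rho = None
    if ar1:
        num = np.sum(resid[1:] * resid[:-1])
        den = np.sum(resid[:-1] ** 2)
        rho = float(num / den) if den > 0 else 0.0
        Yw = Yt[1:] - rho * Yt[:-1]
        Xw = X[1:] - rho * X[:-1]
        B, xtx_diag = _ols(Yw, Xw, design.rank_deficient)
        resid = Yw - Xw @ B
        X = Xw

    n, p = X.shape
    df = max(n - np.linalg.matrix_rank(X), 1)
    sigma2 = np.sum(resid**2, axis=0) / df
    se_all = np.sqrt(np.outer(xtx_diag, sigma2))

    n_ev = len(design.event_columns)
    return BetaPatternSet(
        betas=B[:n_ev],
        event_ids=list(design.event_columns),
        se=se_all[:n_ev],
        sigma2=sigma2,
        df_resid=df,
        ar1_rho=rho,
    )


def extract_roi_patterns(
    betas: BetaPatternSet,
    roi_assignment: dict[str, np.ndarray],
    subject=None,
    timepoint: str = "pre",
    event_to_item=None,
) -> PatternSet:
    """Slice event betas into per-ROI pattern vectors.

    ``roi_assignment`` maps ROI name -> voxel index array; voxels may be
    assigned to at most one ROI. ``event_to_item`` optionally maps event
    ids to item ids (defaults to the event id itself). Events are rows;
    missing events are simply absent.
    """
    all_idx = np.concatenate([np.asarray(v) for v in roi_assignment.values()])
    if len(np.unique(all_idx)) != len(all_idx):
        raise ValueError("a voxel is assigned to more than one ROI")
    ps = PatternSet()
    mapper = event_to_item or (lambda e: e)
    items = [mapper(e) for e in betas.event_ids]
    for roi, idx in roi_assignment.items():
        idx = np.asarray(idx, dtype=int)
        if idx.size == 0:
            raise ValueError(f"ROI {roi!r} contains no voxels")
        ps.add(subject, roi, timepoint,
               pd.DataFrame(betas.betas[:, idx], index=items))
    return ps
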