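"""Representational-change statistics.

Two complementary measures of how a region's multivoxel code changes
when a hidden object is recognized:

* **Pre/post pattern similarity** — the Spearman correlation between a
  trial's pre-solution and post-solution voxel patterns; its complement
  ``1 - rho`` is the multivoxel pattern similarity (MVPS) *change*.
* **Representational strength** — for each solved item, the Pearson
  partial correlation between that item's row of the neural
  representational similarity matrix (RSM) and the same row of a
  conceptual model RSM, with partner run order partialled out. Higher
  strength means the region's geometry looks more like the conceptual
  model's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .containers import ModelEmbedding, PatternSet

logger = logging.getLogger(__name__)

__all__ = [
    "RSM",
    "RepStrengthRecord",
    "prepost_similarity",
    "mvps_change",
    "mvps_table",
    "neural_rsm",
    "model_rsm",
    "representational_strength",
    "build_strength_table",
    "MIN_PREPOST_SEPARATION_S",
    "MIN_PARTNERS",
]

#: Trials whose pre and post events are closer than this (seconds) are
#: excluded: their HRFs overlap too much for separable patterns.
MIN_PREPOST_SEPARATION_S = 2.0
#: Onset of the pre-solution event after stimulus onset (seconds).
PRE_EVENT_OFFSET_S = 0.5
#: Minimum usable partner items for an item-wise partial correlation.
MIN_PARTNERS = 4


@dataclass
class RSM:
    """Item x item similarity matrix with provenance.

    Symmetric with unit diagonal; ``items`` names the rows/columns.
    """

    items: np.ndarray
    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.items = np.asarray(self.items)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.items)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match items")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("similarity matrix must be symmetric")
        finite = np.isfinite(self.values)
        if np.any(np.abs(self.values[finite]) > 1 + 1e-8):
            raise ValueError("similarities must lie in [-1, 1]")

    def row(self, item) -> pd.Series:
        idx = np.flatnonzero(self.items == item)
        if idx.size == 0:
            raise KeyError(f"item {item!r} not in RSM")
        return pd.Series(self.values[idx[0]], index=self.items)


@dataclass
class RepStrengthRecord:
    item: object
    strength: float
    n_pairs_used: int
    subject: object = None
    roi: str | None = None
    timepoint: str | None = None
    model: str | None = None
    reason: str | None = None  # set when the record is masked


def prepost_similarity(pre: np.ndarray, post: np.ndarray) -> float:
    """Spearman correlation between pre- and post-solution patterns."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be 1-D vectors of equal length")
    if pre.size < 3:
        raise ValueError("need at least 3 voxels")
    if np.ptp(pre) == 0 or np.ptp(post) == 0:
        raise ValueError("correlation undefined for a constant pattern")
    rho, _ = spearmanr(pre, post)
    return float(rho)


def mvps_change(rho: float) -> float:
    """Multivoxel pattern similarity change: ``1 - rho``, in [0, 2]."""
    if not -1 - 1e-9 <= rho <= 1 + 1e-9:
        raise ValueError("rho must lie in [-1, 1]")
    return 1.0 - float(rho)


def _rank_rows(mat: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(rankdata, 1, mat)


def _pairwise_spearman(mat: np.ndarray) -> np.ndarray:
    """Spearman similarity of the rows of ``mat`` (items x features)."""
    ranks = _rank_rows(mat)
    sd = ranks.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("constant row: Spearman correlation undefined")
    c = np.corrcoef(ranks)
    return np.clip(c, -1.0, 1.0)


def neural_rsm(patterns: PatternSet, roi: str, timepoint: str, subject) -> RSM:
    """Item x item Spearman RSM from one subject's voxel patterns."""
    frame = patterns.get(subject, roi, timepoint)
    if len(frame) < 2:
        raise ValueError("need at least 2 items to build an RSM")
    values = _pairwise_spearman(frame.to_numpy())
    np.fill_diagonal(values, 1.0)
    return RSM(
        items=frame.index.to_numpy(),
        values=values,
        provenance={"kind": "neural", "roi": roi, "timepoint": timepoint,
                    "subject": subject},
    )


def model_rsm(embeddings: ModelEmbedding, metric: str = "spearman") -> RSM:
    """Item x item similarity of model embedding vectors.

    ``metric="spearman"`` matches how CNN-layer activations are usually
    compared; ``metric="cosine"`` matches word-embedding practice.
    """
    vec = embeddings.vectors
    if vec.shape[0] < 2:
        raise ValueError("need at least 2 items")
    if metric == "spearman":
        values = _pairwise_spearman(vec)
    elif metric == "cosine":
        norms = np.linalg.norm(vec, axis=1)
        if np.any(norms == 0):
            raise ValueError("cosine similarity undefined for a zero vector")
        unit = vec / norms[:, None]
        values = np.clip(unit @ unit.T, -1.0, 1.0)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(values, 1.0)
    return RSM(
        items=embeddings.item_ids,
        values=values,
        provenance={"kind": "model", "name": embeddings.name, "metric": metric},
    )


def _partial_corr(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """First-order Pearson partial correlation r_{xy.z} (closed form)."""
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant row")
    if np.ptp(z) == 0:
        return float(np.corrcoef(x, y)[0, 1])
    rxy = np.corrcoef(x, y)[0, 1]
    rxz = np.corrcoef(x, z)[0, 1]
    ryz = np.corrcoef(y, z)[0, 1]
    denom = np.sqrt((1 - rxz**2) * (1 - ryz**2))
    if denom == 0:
        raise ValueError("covariate fully explains one of the rows")
    return float(np.clip((rxy - rxz * ryz) / denom, -1.0, 1.0))


def representational_strength(
    neural: RSM,
    model: RSM,
    item,
    run_of_items,
    solved_mask,
    subject=None,
    roi: str | None = None,
    timepoint: str | None = None,
    model_name: str | None = None,
) -> RepStrengthRecord:
    """Item-wise brain-model second-order (partial) correlation.

    Correlates the item's neural-RSM row with its model-RSM row across
    *solved* partner items (the self-pair excluded from both rows),
    partialling out the partners' run order (1-4, numeric). The result is
    invariant to affine rescaling of the covariate; a constant covariate
    reduces to the plain Pearson correlation.

    ``run_of_items`` and ``solved_mask`` are mappings (dict or Series)
    from item id to run number / solved flag. Items missing from either
    RSM are ignored. With fewer than 4 usable partners a masked record
    (``strength = nan``) is returned with the reason recorded.
    """
    context = {
        "subject": subject,
        "roi": roi,
        "timepoint": timepoint,
        "model": model_name or (model.provenance or {}).get("name"),
    }
    run_of_items = pd.Series(run_of_items)
    solved_mask = pd.Series(solved_mask)
    nrow = neural.row(item)
    mrow = model.row(item)
    partners = [
        it
        for it in neural.items
        if it != item
        and it in mrow.index
        and bool(solved_mask.get(it, False))
        and it in run_of_items.index
        and np.isfinite(nrow[it])
        and np.isfinite(mrow[it])
    ]
    if len(partners) < MIN_PARTNERS:
        return RepStrengthRecord(
            item=item, strength=np.nan, n_pairs_used=len(partners),
            reason="too few solved partner items", **context,
        )
    x = nrow[partners].to_numpy(dtype=float)
    y = mrow[partners].to_numpy(dtype=float)
    z = run_of_items[partners].to_numpy(dtype=float)
    strength = _partial_corr(x, y, z)
    return RepStrengthRecord(
        item=item, strength=strength, n_pairs_used=len(partners), **context
    )


def _retained_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Correct trials whose pre and post events are >= 2 s apart."""
    sep = trials["solution_time"] - PRE_EVENT_OFFSET_S
    keep = (
        trials["solved"].astype(bool)
        & trials["correct"].astype(bool)
        & (sep >= MIN_PREPOST_SEPARATION_S)
    )
    dropped = int((trials["solved"].astype(bool) & trials["correct"].astype(bool)).sum()
                  - keep.sum())
    logger.info(
        "pre/post separation filter: dropped %d correct trials (< %.1f s apart)",
        dropped, MIN_PREPOST_SEPARATION_S,
    )
    return trials.loc[keep]


def mvps_table(
    patterns: PatternSet,
    trials: pd.DataFrame,
    rois=None,
) -> pd.DataFrame:
    """Trial-wise pre/post similarity and change per ROI.

    One row per retained (correct, separation-filtered) trial x ROI with
    columns ``rho`` and ``change = 1 - rho`` plus the behavioral
    covariates needed by the mixed models (insight, solution time, run,
    memory).
    """
    rois = list(rois) if rois is not None else patterns.rois
    kept = _retained_trials(trials)
    rows = []
    for subject, sdf in kept.groupby("subject_id"):
        for roi in rois:
            pre = patterns.get(subject, roi, "pre")
            post = patterns.get(subject, roi, "post")
            for _, tr in sdf.iterrows():
                item = tr.item_id
                if item not in pre.index or item not in post.index:
                    continue
                rho = prepost_similarity(
                    pre.loc[item].to_numpy(), post.loc[item].to_numpy()
                )
                rows.append(
                    {
                        "subject_id": subject,
                        "item_id": item,
                        "roi": roi,
                        "rho": rho,
                        "change": mvps_change(rho),
                        "insight": tr.insight,
                        "solution_time": tr.solution_time,
                        "run": tr.run,
                        "memory": tr.get("memory", "n/a"),
                    }
                )
    return pd.DataFrame(rows)


def build_strength_table(
    patterns: PatternSet,
    embeddings,
    trials: pd.DataFrame,
    rois=None,
    metrics: dict | None = None,
) -> pd.DataFrame:
    """Representational strength for every retained trial.

    Produces one row per (subject, item, ROI, timepoint, model) for
    correct trials with pre/post separation >= 2 s. Partner items for the
    item-wise rows are the subject's *solved* items (symmetric for the
    neural and model rows); run order is partialled out.

    ``embeddings`` is an iterable of :class:`ModelEmbedding`;
    ``metrics`` maps model name to similarity metric (default: spearman
    for image-like models, cosine for word-like models).
    """
    rois = list(rois) if rois is not None else patterns.rois
    metrics = metrics or {}
    model_rsms = {}
    for emb in embeddings:
        default = "cosine" if "word" in emb.name else "spearman"
        model_rsms[emb.name] = model_rsm(emb, metrics.get(emb.name, default))

    kept = _retained_trials(trials)
    rows = []
    for subject, sdf in kept.groupby("subject_id"):
        subj_all = trials[trials.subject_id == subject]
        run_of_items = subj_all.set_index("item_id")["run"]
        solved_mask = subj_all.set_index("item_id")["solved"].astype(bool)
        meta = sdf.set_index("item_id")
        for roi in rois:
            for tp in ("pre", "post"):
                nrsm = neural_rsm(patterns, roi, tp, subject)
                for mname, mrsm in model_rsms.items():
                    for item in meta.index:
                        rec = representational_strength(
                            nrsm, mrsm, item, run_of_items, solved_mask,
                            subject=subject, roi=roi, timepoint=tp,
                            model_name=mname,
                        )
                        tr = meta.loc[item]
                        rows.append(
                            {
                                "subject_id": subject,
                                "item_id": item,
                                "roi": roi,
                                "timepoint": tp,
                                "model": mname,
                                "strength": rec.strength,
                                "n_pairs_used": rec.n_pairs_used,
                                "insight": tr.insight,
                                "solution_time": tr.solution_time,
                                "run": tr.run,
                                "memory": tr.get("memory", "n/a"),
                            }
                        )
    out = pd.DataFrame(rows)
    if len(out):
        n_masked = int(out["strength"].isna().sum())
        if n_masked:
            logger.info("strength table: %d masked records (too few partners)",
                        n_masked)
    return out
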