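"""Synthetic data generation for the insight / representational-change pipeline.

Every downstream stage of the package can be exercised on data produced
here with known ground truth: a trial table for a Mooney-image problem
solving study (ratings loading on one latent insight factor, solution
times, accuracy, 5-day subsequent memory), per-item conceptual embedding
vectors (image-model and word-model stand-ins), per-ROI voxel patterns
whose post-solution geometry aligns with the embeddings in proportion to
insight, ROI time series with condition-dependent covariance, and raw
BOLD runs generated from a known design for GLM recovery tests.

All generators are deterministic under a fixed ``(config, seed)`` pair.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .containers import ModelEmbedding, PatternSet, TimeSeriesSet

__all__ = [
    "SimulationConfig",
    "simulate_trials",
    "simulate_embeddings",
    "simulate_patterns",
    "simulate_roi_timeseries",
    "simulate_bold_run",
    "simulate_new_item_responses",
    "BoldSimResult",
]

#: Default ventral visual stream ROIs carrying multivoxel patterns.
DEFAULT_PATTERN_ROIS = ("iLOC", "aFusG", "pFusG", "aITG", "mITG", "pITG")

#: Default 18-node "solution network" for connectivity (hemisphere split).
DEFAULT_FC_ROIS = tuple(
    f"{roi}_{hemi}"
    for roi in ("iLOC", "aFusG", "pFusG", "aITG", "mITG", "pITG", "Amy", "aHC", "pHC")
    for hemi in ("L", "R")
)

RECOG_OLD = ("definitely old", "probably old")
RECOG_NEW = ("don't know", "probably new", "definitely new")
SOLVED_YES = ("definitely solved", "probably solved")
SOLVED_NO = ("don't know", "probably not solved", "definitely not solved")


@dataclass
class SimulationConfig:
    """Declarative description of one simulated study.

    The defaults reproduce the study conditions the pipeline targets:
    31 subjects solving 120 Mooney items over 4 runs; suddenness, emotion
    and certainty ratings loading (0.65, 0.60, 0.53) on a single latent
    insight factor; faster solutions and higher accuracy with more
    insight; a conditional high-vs-low-insight subsequent-memory odds
    ratio of 2.10; and post-solution embedding-aligned pattern signal in
    the representational-change ROIs (iLOC, pFusG) only.

    Parameters
    ----------
    rating_loadings:
        One-factor loadings of the three 4-point ratings on the latent
        insight factor; each in (0, 1).
    rt_insight_slope:
        Effect of the (standard normal) latent insight factor on log
        solution time. Negative: more insight, faster solutions.
    accuracy_insight_or:
        Odds ratio on correct identification per SD of latent insight.
        The default skews correct trials toward the high-insight class
        (and incorrect trials toward the low class), with chance-adjusted
        accuracy near 43% of presented trials.
    memory_insight_or:
        Conditional odds ratio of remembering a correctly solved item
        five days later for high- versus low-insight trials.
    signal_gain:
        Scale of the post-solution embedding-aligned pattern signal;
        multiplied by the insight ramp ``g = (composite - 3) / 9``.
    fc_condition_delta:
        Increment in inter-ROI correlation within ``fc_subnetwork``
        during high-insight stimulus blocks relative to low-insight
        blocks.
    """

    n_subjects: int = 31
    n_items: int = 120
    n_runs: int = 4
    trials_per_run: int = 30
    rating_loadings: tuple[float, float, float] = (0.65, 0.60, 0.53)
    rt_insight_slope: float = -0.30
    rt_log_mean: float = 1.25  # log-seconds; exp(1.25) ~ 3.5 s median
    rt_log_sd: float = 0.45
    solve_rate: float = 0.684
    accuracy_base_rate: float = 0.77
    accuracy_insight_or: float = 2.4
    memory_base_rate: float = 0.35
    memory_insight_or: float = 2.10
    subject_sd: float = 0.35
    item_sd: float = 0.35
    n_voxels_per_roi: dict = field(
        default_factory=lambda: {roi: 60 for roi in DEFAULT_PATTERN_ROIS}
    )
    embedding_dim: int = 300
    embedding_latent_dim: int = 12
    embedding_model_correlation: float = 0.3
    rc_rois: tuple = ("iLOC", "pFusG")
    signal_gain: float = 1.2
    noise_sd: float = 1.0
    pattern_baseline_sd: float = 0.8
    fc_rois: tuple = DEFAULT_FC_ROIS
    fc_subnetwork: tuple = ("iLOC_L", "iLOC_R", "pFusG_L", "pFusG_R")
    fc_base_r: float = 0.10
    fc_condition_delta: float = 0.30
    tr_seconds: float = 0.8
    iti_mean: float = 3.0
    iti_jitter: float = 1.0
    stimulus_duration: float = 10.0
    unsolved_post_onset: float = 3.7
    new_item_false_alarm_rate: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_items", "n_runs", "trials_per_run",
                     "embedding_dim"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive count")
        if len(self.rating_loadings) != 3 or not all(
            0 < lam < 1 for lam in self.rating_loadings
        ):
            raise ValueError("rating_loadings must be three values in (0, 1)")
        for name in ("accuracy_insight_or", "memory_insight_or"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive odds ratio")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.signal_gain < 0:
            raise ValueError("signal_gain must be non-negative")
        if self.trials_per_run * self.n_runs != self.n_items:
            raise ValueError(
                "trials_per_run x n_runs must equal n_items "
                f"({self.trials_per_run} x {self.n_runs} != {self.n_items})"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not 0 <= self.fc_base_r + self.fc_condition_delta < 1:
            raise ValueError("fc_base_r + fc_condition_delta must lie in [0, 1)")
        missing = [r for r in self.rc_rois if r not in self.n_voxels_per_roi]
        if missing:
            raise ValueError(
                f"rc_rois {missing} absent from n_voxels_per_roi"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rating_loadings"] = list(self.rating_loadings)
        for key in ("rc_rois", "fc_rois", "fc_subnetwork"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("rating_loadings", "rc_rois", "fc_rois", "fc_subnetwork"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _rng(config: SimulationConfig, seed: int, stage: str) -> np.random.Generator:
    """Stage-specific generator so stages are independently reproducible.

    Uses a stable (process-independent) hash of the stage name; Python's
    built-in ``hash`` is salted per process and would break determinism.
    """
    stage_key = zlib.crc32(stage.encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage_key]))


# --------------------------------------------------------------------------
# Trial table
# --------------------------------------------------------------------------

_QUARTILE_CUTS = norm.ppf([0.25, 0.5, 0.75])


def _discretize_rating(x: np.ndarray) -> np.ndarray:
    """Cut a standard normal indicator at quartiles into 1..4."""
    return 1 + np.searchsorted(_QUARTILE_CUTS, x, side="left").astype(int)


def _per_subject_hi(df: pd.DataFrame) -> pd.Series:
    """High-insight flag from a per-subject median split over solved trials.

    The split median is computed over each subject's *analyzable* solved
    trials (solution time inside the 1.5-9.5 s window the behavior module
    enforces), so the generative insight class coincides with the class
    the downstream median split assigns on filtered data. Trials strictly
    above the median are high insight; ties go to the low class.
    """
    from .behavior import RT_MAX, RT_MIN

    hi = np.zeros(len(df), dtype=bool)
    solved = df["solved"].to_numpy(bool)
    rt = df["solution_time"].to_numpy(float)
    analyzable = solved & (rt >= RT_MIN) & (rt <= RT_MAX)
    med = df.loc[analyzable].groupby("subject_id")["insight"].median()
    comp = df.loc[solved, "insight"].to_numpy()
    subj = df.loc[solved, "subject_id"].to_numpy()
    hi[solved] = comp > med.reindex(subj).fillna(np.inf).to_numpy()
    return pd.Series(hi, index=df.index)


def simulate_trials(config: SimulationConfig, seed: int) -> pd.DataFrame:
    """Simulate the full trial table, one row per subject x item.

    For each solved trial a latent insight factor eta ~ N(0, 1) drives
    (i) the three 4-point ratings through the configured one-factor
    loadings (discretized at quartile thresholds), (ii) log solution
    time, and (iii) the log-odds of correct identification. Subsequent
    memory for correctly solved trials follows a logistic model with
    crossed subject and item random intercepts and a high-vs-low-insight
    odds ratio of ``memory_insight_or``, where the high-insight class is
    the per-subject median split the behavior module reproduces.

    Ground-truth columns are prefixed ``gt_`` and are never consumed by
    the analysis stages; they exist for parameter-recovery tests.
    """
    rng = _rng(config, seed, "trials")
    n_s, n_i = config.n_subjects, config.n_items
    subjects = np.repeat(np.arange(1, n_s + 1), n_i)
    items = np.tile(np.arange(1, n_i + 1), n_s)

    # counterbalanced run assignment: a fresh item permutation per subject
    run = np.empty(n_s * n_i, dtype=int)
    for s in range(n_s):
        order = rng.permutation(n_i)
        run[s * n_i + order] = 1 + np.repeat(
            np.arange(config.n_runs), config.trials_per_run
        )

    n = n_s * n_i
    solved = rng.random(n) < config.solve_rate
    eta = np.where(solved, rng.standard_normal(n), np.nan)

    lam = np.asarray(config.rating_loadings)
    ratings = {}
    for k, name in enumerate(("suddenness", "emotion", "certainty")):
        x = lam[k] * eta + np.sqrt(1 - lam[k] ** 2) * rng.standard_normal(n)
        r = _discretize_rating(x).astype(float)
        r[~solved] = np.nan
        ratings[name] = r
    composite = ratings["suddenness"] + ratings["emotion"] + ratings["certainty"]

    log_rt = (
        config.rt_log_mean
        + config.rt_insight_slope * eta
        + config.rt_log_sd * rng.standard_normal(n)
    )
    solution_time = np.clip(np.exp(log_rt), 0.05, config.stimulus_duration)
    solution_time[~solved] = np.nan

    p_correct = expit(
        logit(config.accuracy_base_rate) + np.log(config.accuracy_insight_or) * eta
    )
    correct = solved & (rng.random(n) < p_correct)

    df = pd.DataFrame(
        {
            "subject_id": subjects,
            "item_id": items,
            "run": run,
            "solved": solved,
            "correct": correct,
            "solution_time": np.round(solution_time, 4),
            "suddenness": ratings["suddenness"],
            "emotion": ratings["emotion"],
            "certainty": ratings["certainty"],
            "insight": composite,
            "gt_latent_insight": eta,
        }
    )

    hi = _per_subject_hi(df)
    df["gt_hi"] = hi

    b_subj = config.subject_sd * rng.standard_normal(n_s)
    b_item = config.item_sd * rng.standard_normal(n_i)
    lin = (
        logit(config.memory_base_rate)
        + b_subj[subjects - 1]
        + b_item[items - 1]
        + np.log(config.memory_insight_or) * hi.to_numpy()
    )
    remembered = correct & (rng.random(n) < expit(lin))

    # Memory-test gate responses consistent with the drawn binary outcome.
    recog = np.full(n, "", dtype=object)
    solved_resp = np.full(n, "", dtype=object)
    name_ok = np.zeros(n, dtype=bool)
    rem_idx = np.flatnonzero(remembered)
    recog[rem_idx] = rng.choice(RECOG_OLD, size=rem_idx.size)
    solved_resp[rem_idx] = rng.choice(SOLVED_YES, size=rem_idx.size)
    name_ok[rem_idx] = True
    forg_idx = np.flatnonzero(correct & ~remembered)
    # Failure mode split: ~53% not recognized at all, ~47% incorrectly
    # remembered (passes the recognition gate but fails a later gate).
    not_recog = rng.random(forg_idx.size) < 0.53
    a = forg_idx[not_recog]
    recog[a] = rng.choice(RECOG_NEW, size=a.size)
    b = forg_idx[~not_recog]
    recog[b] = rng.choice(RECOG_OLD, size=b.size)
    fail_name = rng.random(b.size) < 0.5
    solved_resp[b[fail_name]] = rng.choice(SOLVED_YES, size=int(fail_name.sum()))
    name_ok[b[fail_name]] = False
    solved_resp[b[~fail_name]] = rng.choice(SOLVED_NO, size=int((~fail_name).sum()))
    other = ~correct
    recog[other] = rng.choice(RECOG_OLD + RECOG_NEW, size=int(other.sum()))

    df["recognition_response"] = recog
    df["solved_memory_response"] = solved_resp
    df["recalled_name_correct"] = name_ok
    memory = np.where(correct, np.where(remembered, "remembered", "forgotten"), "n/a")
    df["memory"] = memory
    return df


def simulate_new_item_responses(config: SimulationConfig, seed: int,
                                n_new: int = 60) -> pd.DataFrame:
    """Recognition responses to never-seen foil items (false-alarm input)."""
    rng = _rng(config, seed, "foils")
    rows = []
    for s in range(1, config.n_subjects + 1):
        fa = rng.random(n_new) < config.new_item_false_alarm_rate
        resp = np.where(
            fa,
            rng.choice(RECOG_OLD, size=n_new),
            rng.choice(RECOG_NEW, size=n_new),
        )
        rows.append(pd.DataFrame({
            "subject_id": s,
            "item_id": [f"new_{i}" for i in range(1, n_new + 1)],
            "recognition_response": resp,
        }))
    return pd.concat(rows, ignore_index=True)


# --------------------------------------------------------------------------
# Embeddings
# --------------------------------------------------------------------------

def simulate_embeddings(
    config: SimulationConfig, seed: int
) -> tuple[ModelEmbedding, ModelEmbedding]:
    """Two unit-norm per-item embedding sets with correlated geometries.

    Items live on a low-dimensional conceptual manifold: each item has
    latent coordinates in ``embedding_latent_dim`` dimensions that are
    mapped into the full embedding space through an orthonormal basis,
    giving the wide spread of pairwise similarities real conceptual
    embeddings show (random full-rank vectors would be mutually
    near-orthogonal and carry no usable geometry).
    ``embedding_model_correlation`` c controls how much latent structure
    the image-model and word-model stand-ins share: each model's latent
    coordinates are ``sqrt(c) * shared + sqrt(1 - c) * private``, so
    c = 1 yields identical similarity matrices and c = 0 independent
    ones.
    """
    if config.embedding_dim < 2:
        raise ValueError("embedding_dim must be >= 2")
    k = int(config.embedding_latent_dim)
    if not 1 <= k <= config.embedding_dim:
        raise ValueError("embedding_latent_dim must be in [1, embedding_dim]")
    rng = _rng(config, seed, "embeddings")
    c = float(config.embedding_model_correlation)
    if not 0 <= c <= 1:
        raise ValueError("embedding_model_correlation must be in [0, 1]")
    shared = rng.standard_normal((config.n_items, k))
    items = np.arange(1, config.n_items + 1)
    out = []
    for name in ("image_model", "word_model"):
        private = rng.standard_normal((config.n_items, k))
        latent = np.sqrt(c) * shared + np.sqrt(1 - c) * private
        basis, _ = np.linalg.qr(
            rng.standard_normal((config.embedding_dim, k))
        )
        vec = latent @ basis.T
        vec /= np.linalg.norm(vec, axis=1, keepdims=True)
        out.append(ModelEmbedding(name, items, vec))
    return out[0], out[1]


# --------------------------------------------------------------------------
# Voxel patterns
# --------------------------------------------------------------------------

def insight_ramp(composite) -> np.ndarray:
    """Linear insight weighting g = (composite - 3) / 9, in [0, 1]."""
    return (np.asarray(composite, dtype=float) - 3.0) / 9.0


def simulate_patterns(
    trials: pd.DataFrame,
    embeddings: ModelEmbedding,
    config: SimulationConfig,
    seed: int,
) -> PatternSet:
    """Per (subject, ROI, timepoint) voxel patterns for every trial.

    Each (subject, ROI, item) carries a stable baseline pattern (scale
    ``pattern_baseline_sd``) shared by the pre- and post-solution
    timepoints, plus independent Gaussian noise of scale ``noise_sd``
    at each timepoint; without any solution signal the pre/post Spearman
    correlation therefore sits at a positive baseline level. For solved
    trials, representational-change ROIs additionally receive, at the
    post timepoint only, the item's embedding projected into voxel space
    through one fixed Gaussian random matrix per ROI, scaled by
    ``signal_gain * g(insight)`` — this aligns the post-solution
    geometry with the conceptual model and, by displacing the post
    pattern away from the shared baseline, lowers pre/post similarity in
    proportion to insight. The fixed projection gives every item a
    stable voxel-space geometry across trials and subjects, which is
    what representational similarity analysis assumes.
    """
    present = set(trials["item_id"].unique())
    covered = set(np.asarray(embeddings.item_ids).tolist())
    if not present <= covered:
        raise ValueError("embeddings do not cover all items in the trial table")
    rng = _rng(config, seed, "patterns")
    item_index = {it: i for i, it in enumerate(embeddings.item_ids)}

    # One fixed projection per ROI; unit-variance columns so a unit-norm
    # embedding lands with per-voxel variance ~1 (commensurate with noise_sd).
    projections = {
        roi: rng.standard_normal((nv, config.embedding_dim))
        for roi, nv in config.n_voxels_per_roi.items()
    }

    ps = PatternSet()
    for subject, sdf in trials.groupby("subject_id"):
        items = sdf["item_id"].to_numpy()
        solved = sdf["solved"].to_numpy(bool)
        g = insight_ramp(sdf["insight"].to_numpy())
        g = np.where(solved, g, 0.0)
        emb = embeddings.vectors[[item_index[i] for i in items]]
        for roi, nv in config.n_voxels_per_roi.items():
            proj = (projections[roi] @ emb.T).T  # items x voxels
            baseline = config.pattern_baseline_sd * rng.standard_normal(
                (len(items), nv)
            )
            for tp in ("pre", "post"):
                noise = config.noise_sd * rng.standard_normal((len(items), nv))
                pat = baseline + noise
                if tp == "post" and roi in config.rc_rois:
                    pat = pat + config.signal_gain * g[:, None] * proj
                ps.add(subject, roi, tp, pd.DataFrame(pat, index=items))
    return ps


# --------------------------------------------------------------------------
# ROI time series
# --------------------------------------------------------------------------

def simulate_roi_timeseries(
    trials: pd.DataFrame, config: SimulationConfig, seed: int
) -> TimeSeriesSet:
    """ROI x time series per subject and run with condition-coupled FC.

    Each trial is a 10-s stimulus block preceded by a jittered fixation
    interval. Every ROI loads sqrt(fc_base_r) on a network-wide common
    fluctuation; during high-insight blocks the ``fc_subnetwork`` ROIs
    additionally load sqrt(fc_condition_delta) on a second shared
    fluctuation, raising their pairwise correlation by
    ``fc_condition_delta`` relative to low-insight blocks.
    """
    rng = _rng(config, seed, "timeseries")
    rois = list(config.fc_rois)
    n_roi = len(rois)
    sub_mask = np.array([r in config.fc_subnetwork for r in rois])
    tr = config.tr_seconds
    r0, delta = config.fc_base_r, config.fc_condition_delta

    data = {}
    block_rows = []
    for subject, sdf in trials.groupby("subject_id"):
        for run, rdf in sdf.groupby("run"):
            t = 0.0
            onsets, conds, item_ids = [], [], []
            for _, row in rdf.iterrows():
                t += config.iti_mean + rng.uniform(-config.iti_jitter,
                                                   config.iti_jitter)
                onsets.append(t)
                if row.solved:
                    conds.append("HI" if row.gt_hi else "LO")
                else:
                    conds.append("unsolved")
                item_ids.append(row.item_id)
                t += config.stimulus_duration
            run_len = t + config.iti_mean
            n_samp = int(np.ceil(run_len / tr))
            times = np.arange(n_samp) * tr

            hi_mask = np.zeros(n_samp, dtype=bool)
            for onset, cond in zip(onsets, conds):
                if cond == "HI":
                    hi_mask |= (times >= onset) & (times < onset + config.stimulus_duration)

            common = rng.standard_normal(n_samp)
            extra = rng.standard_normal(n_samp)
            noise = rng.standard_normal((n_roi, n_samp))
            load_extra = np.where(
                sub_mask[:, None] & hi_mask[None, :], np.sqrt(delta), 0.0
            )
            resid = np.sqrt(1.0 - r0 - load_extra**2)
            ts = np.sqrt(r0) * common[None, :] + load_extra * extra[None, :] + resid * noise

            data[(subject, run)] = ts
            for onset, cond, item in zip(onsets, conds, item_ids):
                block_rows.append(
                    (subject, run, item, onset, config.stimulus_duration, cond)
                )

    blocks = pd.DataFrame(
        block_rows,
        columns=["subject_id", "run", "item_id", "onset", "duration", "condition"],
    )
    return TimeSeriesSet(data=data, roi_names=rois, tr=tr, blocks=blocks)


# --------------------------------------------------------------------------
# Raw BOLD runs (GLM fixture)
# --------------------------------------------------------------------------

@dataclass
class BoldSimResult:
    """A simulated BOLD run with the ground truth that produced it."""

    bold: np.ndarray          # voxels x scans
    beta_true: np.ndarray     # regressors x voxels
    design: "object"          # the DesignMatrix used
    noise_sd: float


def simulate_bold_run(
    events,
    config: SimulationConfig,
    seed: int,
    n_voxels: int = 40,
    noise_sd: float = 1.0,
    motion: np.ndarray | None = None,
    beta_true: np.ndarray | None = None,
) -> BoldSimResult:
    """Generate ``Y = X beta + noise`` from the single-trial design.

    ``events`` is an :class:`insightrc.glm.EventSpec`; the design matrix
    is built by the GLM module itself so recovery tests exercise the
    same code path the pipeline uses.
    """
    from .glm import build_single_trial_design

    rng = _rng(config, seed, "bold")
    if motion is None:
        motion = 0.1 * rng.standard_normal((events.n_scans, 6))
    design = build_single_trial_design(events, motion=motion)
    p = design.matrix.shape[1]
    if beta_true is None:
        beta_true = rng.standard_normal((p, n_voxels))
    else:
        beta_true = np.asarray(beta_true, dtype=float)
        if beta_true.shape[0] != p:
            raise ValueError("beta_true rows must match design columns")
        n_voxels = beta_true.shape[1]
    bold = (design.matrix @ beta_true).T
    if noise_sd > 0:
        bold = bold + noise_sd * rng.standard_normal(bold.shape)
    return BoldSimResult(bold=bold, beta_true=beta_true, design=design,
                         noise_sd=noise_sd)
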