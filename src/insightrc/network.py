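"""ROI-network connectivity, the NBS mass statistic and graph measures.

Functional connectivity is the Fisher-z-transformed Pearson correlation
between ROI time series over condition blocks. The high-minus-low
insight contrast is a paired t statistic per connection; network-level
inference uses the network-based-statistic (NBS) *mass* — the sum of
squared t values over suprathreshold connections — against a
sign-flipping permutation null. Graph measures (degree, clustering,
local/global efficiency, path length) are computed on binary adjacency
matrices thresholded at correlations 0.1 .. 0.8 and aggregated across
thresholds before a one-sided paired contrast with per-ROI FDR
correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import signal
from scipy.stats import t as t_dist

from .containers import ConnectivityStack, TimeSeriesSet

logger = logging.getLogger(__name__)

__all__ = [
    "fc_matrix",
    "build_connectivity_stack",
    "connection_contrast",
    "nbs_mass_test",
    "NBSResult",
    "threshold_adjacency",
    "graph_measures",
    "aggregate_and_contrast",
    "DEFAULT_THRESHOLDS",
    "GRAPH_MEASURES",
]

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.1, 0.81, 0.1), 1))
GRAPH_MEASURES = (
    "degree",
    "clustering",
    "local_efficiency",
    "global_efficiency",
    "path_length",
)
BANDPASS_HZ = (0.008, 0.09)


def _bandpass(ts: np.ndarray, tr: float) -> np.ndarray:
    """Zero-phase 0.008-0.09 Hz band-pass along the time axis."""
    nyq = 0.5 / tr
    lo, hi = BANDPASS_HZ[0] / nyq, min(BANDPASS_HZ[1] / nyq, 0.99)
    b, a = signal.butter(2, [lo, hi], btype="band")
    return signal.filtfilt(b, a, ts, axis=-1)


def fc_matrix(
    timeseries: np.ndarray,
    condition_blocks,
    roi_names=None,
    bandpass: bool = False,
    tr: float | None = None,
) -> np.ndarray:
    """Fisher-z connectivity over the samples of one condition.

    Parameters
    ----------
    timeseries:
        ``(n_rois, n_samples)`` array.
    condition_blocks:
        Boolean sample mask, or an iterable of ``(start, stop)`` sample
        index pairs, selecting the condition's samples; they are
        concatenated before correlating.
    bandpass:
        Apply the 0.008-0.09 Hz zero-phase band-pass first (requires
        ``tr``).

    Returns the ``(R, R)`` matrix of ``atanh(r)`` values with a NaN
    diagonal. Perfectly correlated pairs (|r| = 1) are masked NaN with a
    warning; a constant ROI series raises an error naming the ROI.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2 or ts.shape[0] < 2:
        raise ValueError("timeseries must be (n_rois >= 2, n_samples)")
    if bandpass:
        if tr is None:
            raise ValueError("bandpass filtering requires tr")
        ts = _bandpass(ts, tr)
    mask = np.asarray(condition_blocks)
    if mask.dtype != bool:
        m = np.zeros(ts.shape[1], dtype=bool)
        for start, stop in condition_blocks:
            m[int(start):int(stop)] = True
        mask = m
    if mask.sum() < 5:
        raise ValueError("need at least 5 samples in the condition blocks")
    seg = ts[:, mask]
    sd = seg.std(axis=1)
    if np.any(sd == 0):
        names = roi_names or [str(i) for i in range(ts.shape[0])]
        bad = [names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant time series for ROI(s): {bad}")
    r = np.corrcoef(seg)
    np.fill_diagonal(r, np.nan)
    degenerate = np.abs(r) >= 1.0 - 1e-15
    degenerate &= ~np.isnan(r)
    if degenerate.any():
        warnings.warn(
            "perfectly correlated ROI pair(s): Fisher z undefined, masked NaN",
            stacklevel=2,
        )
        r[degenerate] = np.nan
    return np.arctanh(r)


def build_connectivity_stack(
    tsset: TimeSeriesSet,
    bandpass: bool = False,
) -> ConnectivityStack:
    """Per (subject, condition, run) Fisher-z matrices from time series.

    Conditions are the high/low insight stimulus blocks recorded in the
    time-series block table; runs without at least 5 samples of a
    condition yield an all-NaN slice.
    """
    subjects = tsset.subjects
    runs = tsset.runs
    R = len(tsset.roi_names)
    z = np.full((len(subjects), 2, len(runs), R, R), np.nan)
    for si, subject in enumerate(subjects):
        for ri, run in enumerate(runs):
            if (subject, run) not in tsset.data:
                continue
            ts = tsset.series(subject, run)
            for ci, cond in enumerate(("HI", "LO")):
                m = tsset.block_mask(subject, run, cond)
                if m.sum() < 5:
                    logger.warning(
                        "subject %s run %s: <5 samples for condition %s",
                        subject, run, cond,
                    )
                    continue
                z[si, ci, ri] = fc_matrix(
                    ts, m, roi_names=tsset.roi_names,
                    bandpass=bandpass, tr=tsset.tr,
                )
    return ConnectivityStack(z=z, subjects=subjects, roi_names=list(tsset.roi_names))


def _paired_differences(stack: ConnectivityStack) -> tuple[np.ndarray, list]:
    """Run-averaged HI - LO difference matrices per subject.

    Subjects missing a condition entirely are excluded with a warning.
    Returns ``(diffs, kept_subjects)`` with diffs ``(S', R, R)``.
    """
    avg = stack.run_average()  # S x 2 x R x R
    diffs, kept = [], []
    offdiag = ~np.eye(stack.n_rois, dtype=bool)
    for si, subject in enumerate(stack.subjects):
        d = avg[si, 0] - avg[si, 1]
        if np.isnan(d[offdiag]).all():
            warnings.warn(
                f"subject {subject!r} missing a condition; excluded from contrast",
                stacklevel=3,
            )
            continue
        diffs.append(d)
        kept.append(subject)
    if len(kept) < 2:
        raise ValueError("need at least 2 subjects with both conditions")
    return np.asarray(diffs), kept


def connection_contrast(stack: ConnectivityStack) -> np.ndarray:
    """Per-edge paired t statistic (HI - LO) across subjects.

    Uses run-averaged z values; df = number of complete subjects - 1.
    The result is antisymmetric in the condition labels: swapping HI and
    LO flips every sign.
    """
    diffs, kept = _paired_differences(stack)
    n = len(kept)
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return t


@dataclass
class NBSResult:
    """Outcome of the NBS mass permutation test."""

    mass: float
    fwe_p: float
    n_permutations: int
    edges: list            # suprathreshold (roi_i, roi_j) pairs
    component_rois: list   # ROIs of the largest connected component
    edge_alpha: float
    t_threshold: float
    null_mass: np.ndarray = field(repr=False, default=None)


def nbs_mass_test(
    stack: ConnectivityStack,
    edge_alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> NBSResult:
    """Network-based-statistic mass test for the HI > LO contrast.

    Connection-level screening keeps edges with one-sided p <
    ``edge_alpha`` (t above the upper critical value); the observed mass
    is the sum of squared t statistics over those edges. The null is
    built by randomly sign-flipping each subject's HI-LO difference
    matrix (exchangeable under the no-difference hypothesis for a
    within-subject contrast) and recomputing the mass ``n_perm`` times;
    ``fwe_p = (1 + #{null >= observed}) / (1 + n_perm)``.
    """
    diffs, kept = _paired_differences(stack)
    n = len(kept)
    if n < 6:
        raise ValueError("NBS needs at least 6 complete subjects")
    R = stack.n_rois
    iu = np.triu_indices(R, k=1)
    d = diffs[:, iu[0], iu[1]]  # S x E
    t_crit = float(t_dist.ppf(1 - edge_alpha, n - 1))

    def edge_t(dmat):
        mean = dmat.mean(axis=0)
        sd = dmat.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return mean / (sd / np.sqrt(dmat.shape[0]))

    def mass_of(tvec):
        sup = tvec > t_crit
        return float(np.nansum(tvec[sup] ** 2)), sup

    t_obs = edge_t(d)
    mass_obs, sup = mass_of(t_obs)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n)
        null[b], _ = mass_of(edge_t(d * signs[:, None]))
    fwe_p = (1.0 + np.sum(null >= mass_obs)) / (1.0 + n_perm)

    names = stack.roi_names
    edges = [(names[i], names[j])
             for i, j in zip(iu[0][sup], iu[1][sup])]
    comp_rois: list = []
    if edges:
        g = nx.Graph(edges)
        comp = max(nx.connected_components(g), key=len)
        comp_rois = sorted(comp)
    return NBSResult(
        mass=mass_obs,
        fwe_p=float(fwe_p) if edges else 1.0,
        n_permutations=n_perm,
        edges=edges,
        component_rois=comp_rois,
        edge_alpha=edge_alpha,
        t_threshold=t_crit,
        null_mass=null,
    )


def threshold_adjacency(z_matrix: np.ndarray, r_threshold: float) -> np.ndarray:
    """Binary adjacency: correlation (back-transformed) above threshold.

    Only positive correlations form edges; self-loops never. NaN cells
    never form edges. Edge sets are nested across increasing thresholds.
    """
    if not 0 < r_threshold < 1:
        raise ValueError("r_threshold must lie in (0, 1)")
    z = np.asarray(z_matrix, dtype=float)
    with np.errstate(invalid="ignore"):
        r = np.tanh(z)
        adj = r > r_threshold
    adj &= ~np.isnan(z)
    np.fill_diagonal(adj, False)
    return adj | adj.T  # enforce symmetry


def _node_path_length(g: nx.Graph, node) -> float:
    """Mean shortest-path distance from ``node`` to its reachable nodes."""
    lengths = nx.single_source_shortest_path_length(g, node)
    del lengths[node]
    if not lengths:
        return np.nan
    return float(np.mean(list(lengths.values())))


def graph_measures(adjacency: np.ndarray, roi_names=None) -> pd.DataFrame:
    """Standard binary-graph measures per node plus a network row.

    Per node: degree, clustering coefficient, local efficiency (global
    efficiency of the neighbor-induced subgraph), and average shortest
    path length to reachable nodes. The ``__network__`` row holds the
    node means for those plus global efficiency (mean of 1/d over all
    distinct pairs, unreachable pairs contributing 0) and the network
    average path length over reachable pairs. Isolated nodes have degree
    0, clustering 0 and undefined (NaN) path length.
    """
    adj = np.asarray(adjacency, dtype=bool)
    n = adj.shape[0]
    if n < 2 or adj.shape != (n, n):
        raise ValueError("adjacency must be square with >= 2 nodes")
    names = list(roi_names) if roi_names is not None else list(range(n))
    g = nx.from_numpy_array(adj.astype(int))
    clustering = nx.clustering(g)

    rows = []
    inv_dist_sum = 0.0
    reach_dists = []
    for i in range(n):
        neigh = list(g.neighbors(i))
        if len(neigh) >= 2:
            leff = nx.global_efficiency(g.subgraph(neigh))
        else:
            leff = 0.0
        lengths = nx.single_source_shortest_path_length(g, i)
        del lengths[i]
        dists = list(lengths.values())
        inv_dist_sum += sum(1.0 / d for d in dists)
        reach_dists.extend(dists)
        rows.append(
            {
                "node": names[i],
                "degree": g.degree(i),
                "clustering": clustering[i],
                "local_efficiency": leff,
                "global_efficiency": np.nan,
                "path_length": float(np.mean(dists)) if dists else np.nan,
            }
        )
    geff = inv_dist_sum / (n * (n - 1))
    net_pl = float(np.mean(reach_dists)) if reach_dists else np.nan
    node_df = pd.DataFrame(rows)
    network_row = {
        "node": "__network__",
        "degree": node_df["degree"].mean(),
        "clustering": node_df["clustering"].mean(),
        "local_efficiency": node_df["local_efficiency"].mean(),
        "global_efficiency": geff,
        "path_length": net_pl,
    }
    return pd.concat([node_df, pd.DataFrame([network_row])], ignore_index=True)


def _subject_condition_measures(
    z: np.ndarray, roi_names, thresholds
) -> pd.DataFrame:
    """Graph measures of one run-averaged z matrix, mean over thresholds."""
    frames = []
    for thr in thresholds:
        adj = threshold_adjacency(z, thr)
        m = graph_measures(adj, roi_names)
        m["threshold"] = thr
        frames.append(m)
    stacked = pd.concat(frames, ignore_index=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return stacked.groupby("node", sort=False)[list(GRAPH_MEASURES)].mean()


def aggregate_and_contrast(
    stack: ConnectivityStack,
    thresholds=DEFAULT_THRESHOLDS,
) -> dict:
    """Threshold-aggregated graph measures and the HI > LO contrast.

    For each subject and condition the run-averaged z matrix is
    thresholded at each correlation level, graph measures are computed,
    and measures are averaged (unweighted) over thresholds. The contrast
    is a one-sided paired t (HI > LO) per measure, at the network level
    and per ROI; per-ROI p values are Benjamini-Hochberg corrected
    within measure. Subjects for whom a measure is undefined at every
    threshold are dropped for that measure (df reported per test).

    Returns ``{"subject_measures": ..., "network": ..., "roi": ...}``.
    """
    from .stats import fdr_correct

    avg = stack.run_average()
    records = []
    for si, subject in enumerate(stack.subjects):
        for ci, cond in enumerate(stack.conditions):
            table = _subject_condition_measures(
                avg[si, ci], stack.roi_names, thresholds
            )
            for node, row in table.iterrows():
                rec = {"subject_id": subject, "condition": cond, "node": node}
                rec.update(row.to_dict())
                records.append(rec)
    subj = pd.DataFrame(records)

    def paired_tests(node_value: str) -> pd.DataFrame:
        out = []
        sub = subj[subj.node == node_value] if node_value != "__roi__" else subj[
            subj.node != "__network__"
        ]
        nodes = ["__network__"] if node_value == "__network__" else sorted(
            set(sub.node)
        )
        for node in nodes:
            nd = sub[sub.node == node]
            wide = nd.pivot_table(
                index="subject_id", columns="condition", values=list(GRAPH_MEASURES)
            )
            for measure in GRAPH_MEASURES:
                try:
                    pair = wide[measure][["HI", "LO"]].dropna()
                except KeyError:
                    continue
                nsub = len(pair)
                if nsub < 2:
                    logger.warning(
                        "measure %s at %s: fewer than 2 complete subjects", measure,
                        node,
                    )
                    continue
                d = pair["HI"] - pair["LO"]
                sd = d.std(ddof=1)
                tval = (d.mean() / (sd / np.sqrt(nsub))) if sd > 0 else 0.0
                p = float(t_dist.sf(tval, nsub - 1))  # one-sided HI > LO
                out.append(
                    {
                        "node": node,
                        "measure": measure,
                        "mean_HI": pair["HI"].mean(),
                        "mean_LO": pair["LO"].mean(),
                        "t": tval,
                        "df": nsub - 1,
                        "p_one_sided": p,
                    }
                )
        return pd.DataFrame(out)

    network = paired_tests("__network__")
    roi = paired_tests("__roi__")
    if len(roi):
        roi["p_fdr"] = np.nan
        for measure in roi["measure"].unique():
            m = roi.measure == measure
            roi.loc[m, "p_fdr"] = fdr_correct(roi.loc[m, "p_one_sided"].to_numpy())
    return {"subject_measures": subj, "network": network, "roi": roi}
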