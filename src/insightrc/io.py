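"""File formats, configuration and run manifests.

Trial tables travel as TSV (one row per subject x item, documented
columns); patterns, time series and connectivity stacks as HDF5;
pipeline configuration as YAML validated through pydantic; and every
pipeline run appends to a JSON manifest recording the config snapshot,
per-stage seeds, file digests and exclusion counts so a run can be
reproduced bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from . import __version__
from .containers import ConnectivityStack, PatternSet, TimeSeriesSet
from .synthetic import SimulationConfig

logger = logging.getLogger(__name__)

__all__ = [
    "read_trial_table",
    "write_trial_table",
    "save_array",
    "load_array",
    "write_patterns",
    "read_patterns",
    "write_timeseries",
    "read_timeseries",
    "write_connectivity",
    "read_connectivity",
    "PipelineConfig",
    "load_config",
    "RunManifest",
    "stage_seed",
]

MANDATORY_TRIAL_COLUMNS = (
    "subject_id",
    "item_id",
    "run",
    "solved",
    "correct",
    "solution_time",
    "suddenness",
    "emotion",
    "certainty",
    "insight",
)

_NUMERIC_TRIAL_COLUMNS = ("run", "solution_time", "suddenness", "emotion",
                          "certainty", "insight")
_BOOL_TRIAL_COLUMNS = ("solved", "correct")


# --------------------------------------------------------------------------
# Trial tables (TSV)
# --------------------------------------------------------------------------

def write_trial_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_trial_table(path) -> pd.DataFrame:
    """Read a TSV trial table with type checking.

    Missing mandatory columns raise naming the column; rows whose
    mandatory numeric fields cannot be parsed are rejected with their
    line numbers. Extra columns are preserved untouched.
    """
    path = Path(path)
    # keep_default_na=False: the literal memory label "n/a" is data, not NaN
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    if df.empty:
        raise ValueError(f"{path}: empty trial table")
    for col in MANDATORY_TRIAL_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    bad_lines: list[int] = []
    for col in _NUMERIC_TRIAL_COLUMNS:
        parsed = pd.to_numeric(df[col], errors="coerce")
        # NaN is legal (unsolved trials); flag values that failed parsing
        newly_bad = parsed.isna() & df[col].notna() & (df[col].astype(str) != "")
        bad_lines.extend((df.index[newly_bad] + 2).tolist())  # header is line 1
        df[col] = parsed
    if bad_lines:
        raise ValueError(
            f"{path}: unparseable numeric values on line(s) {sorted(set(bad_lines))}"
        )
    for col in _BOOL_TRIAL_COLUMNS:
        if df[col].dtype != bool:
            df[col] = df[col].astype(str).str.lower().isin(("true", "1"))
    # extra columns stay opaque, except fully numeric ones which are typed
    known = set(MANDATORY_TRIAL_COLUMNS) | set(_BOOL_TRIAL_COLUMNS)
    for col in df.columns:
        if col in known or df[col].dtype != object:
            continue
        nonempty = df[col].astype(str) != ""
        parsed = pd.to_numeric(df[col], errors="coerce")
        if parsed[nonempty].notna().all():
            df[col] = parsed
        elif set(df.loc[nonempty, col].astype(str).str.lower()) <= {"true", "false"}:
            df[col] = df[col].astype(str).str.lower() == "true"
    return df


# --------------------------------------------------------------------------
# HDF5 array containers
# --------------------------------------------------------------------------

def save_array(path, dataset_path: str, array: np.ndarray) -> None:
    """Write one array to an HDF5 dataset (bit-exact round trip)."""
    with h5py.File(path, "a") as f:
        if dataset_path in f:
            del f[dataset_path]
        f.create_dataset(dataset_path, data=np.asarray(array))


def load_array(path, dataset_path: str, expected_shape=None) -> np.ndarray:
    with h5py.File(path, "r") as f:
        if dataset_path not in f:
            raise KeyError(f"{path}: no dataset at {dataset_path!r}")
        arr = f[dataset_path][()]
    if expected_shape is not None and tuple(arr.shape) != tuple(expected_shape):
        raise ValueError(
            f"{path}:{dataset_path}: shape {arr.shape} != manifest shape "
            f"{tuple(expected_shape)}"
        )
    return arr


def _encode_ids(ids) -> np.ndarray:
    return np.asarray([str(i) for i in ids], dtype="S")


def _decode_ids(raw) -> list:
    out = []
    for b in raw:
        s = b.decode()
        out.append(int(s) if s.lstrip("-").isdigit() else s)
    return out


def write_patterns(patterns: PatternSet, path) -> None:
    """HDF5 layout: ``/patterns/{subject}/{roi}/{pre|post}/{data,items}``."""
    with h5py.File(path, "w") as f:
        for (subject, roi, tp), frame in patterns.data.items():
            grp = f.require_group(f"patterns/{subject}/{roi}/{tp}")
            grp.create_dataset("data", data=frame.to_numpy())
            grp.create_dataset("items", data=_encode_ids(frame.index))


def read_patterns(path) -> PatternSet:
    ps = PatternSet()
    with h5py.File(path, "r") as f:
        root = f["patterns"]
        for subject in root:
            for roi in root[subject]:
                for tp in root[subject][roi]:
                    grp = root[subject][roi][tp]
                    items = _decode_ids(grp["items"][()])
                    subj = int(subject) if subject.lstrip("-").isdigit() else subject
                    ps.add(subj, roi, tp,
                           pd.DataFrame(grp["data"][()], index=items))
    return ps


def write_timeseries(tsset: TimeSeriesSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["tr"] = tsset.tr
        f.attrs["roi_names"] = [str(r) for r in tsset.roi_names]
        for (subject, run), ts in tsset.data.items():
            f.create_dataset(f"timeseries/{subject}/run{run}", data=ts)
        blk = f.require_group("blocks")
        for col in tsset.blocks.columns:
            vals = tsset.blocks[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype("S")
            blk.create_dataset(col, data=vals)


def read_timeseries(path) -> TimeSeriesSet:
    data = {}
    with h5py.File(path, "r") as f:
        tr = float(f.attrs["tr"])
        roi_names = [str(r) for r in f.attrs["roi_names"]]
        for subject in f["timeseries"]:
            subj = int(subject) if subject.lstrip("-").isdigit() else subject
            for run_key in f["timeseries"][subject]:
                run = int(run_key.removeprefix("run"))
                data[(subj, run)] = f[f"timeseries/{subject}/{run_key}"][()]
        cols = {}
        for col in f["blocks"]:
            vals = f["blocks"][col][()]
            if vals.dtype.kind == "S":
                vals = np.asarray([v.decode() for v in vals])
            cols[col] = vals
    blocks = pd.DataFrame(cols)
    return TimeSeriesSet(data=data, roi_names=roi_names, tr=tr, blocks=blocks)


def write_connectivity(stack: ConnectivityStack, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("connectivity/z", data=stack.z)
        f.create_dataset("connectivity/subjects", data=_encode_ids(stack.subjects))
        f.attrs["roi_names"] = [str(r) for r in stack.roi_names]
        f.attrs["conditions"] = list(stack.conditions)


def read_connectivity(path) -> ConnectivityStack:
    with h5py.File(path, "r") as f:
        z = f["connectivity/z"][()]
        subjects = _decode_ids(f["connectivity/subjects"][()])
        roi_names = [str(r) for r in f.attrs["roi_names"]]
        conditions = tuple(str(c) for c in f.attrs["conditions"])
    return ConnectivityStack(z=z, subjects=subjects, roi_names=roi_names,
                             conditions=conditions)


# --------------------------------------------------------------------------
# Pipeline configuration (YAML + pydantic validation)
# --------------------------------------------------------------------------

class NetworkOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    edge_alpha: float = 0.05
    n_perm: int = 1000
    thresholds: list[float] = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]
    bandpass: bool = False

    @field_validator("edge_alpha")
    @classmethod
    def _alpha(cls, v):
        if not 0 < v < 1:
            raise ValueError("edge_alpha must lie in (0, 1)")
        return v


class StatsOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_perm: int = 999
    n_boot: int = 1000
    fisher_z_strength: bool = False  # carry strength untransformed by default


class GlmOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_voxels: int = 40
    noise_sd: float = 1.0
    n_subjects: int = 3  # GLM recovery demo runs on a subset of subjects


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    simulation: dict = {}
    network: NetworkOptions = NetworkOptions()
    stats: StatsOptions = StatsOptions()
    glm: GlmOptions = GlmOptions()

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig.from_dict(self.simulation)


def load_config(path=None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    return PipelineConfig(**raw)


# --------------------------------------------------------------------------
# Run manifest
# --------------------------------------------------------------------------

def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed spawned from the master seed."""
    import zlib

    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunManifest:
    """Provenance record for one pipeline run directory."""

    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    stage_versions: dict = field(default_factory=dict)
    digests: dict = field(default_factory=dict)
    exclusions: dict = field(default_factory=dict)

    @classmethod
    def load(cls, path) -> "RunManifest":
        path = Path(path)
        if not path.exists():
            return cls()
        with open(path) as f:
            return cls(**json.load(f))

    def save(self, path) -> None:
        with open(path, "w") as f:
            json.dump(asdict(self), f, indent=2, sort_keys=True, default=str)

    def record_stage(self, stage: str, seed: int, outputs: dict[str, Path],
                     exclusions: dict | None = None) -> None:
        self.seeds[stage] = seed
        self.stage_versions[stage] = __version__
        for name, p in outputs.items():
            self.digests[f"{stage}/{name}"] = sha256_of(p)
        if exclusions:
            self.exclusions[stage] = exclusions
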