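"""Delimited-text input/output.

Designs travel as BIDS-style events tables, design matrices and RDMs as
labeled TSV matrices, force traces as time x finger tables, and simulation
settings as plain key = value config files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import CONDITIONS, REST_PADDING, ExperimentDesign, RunDesign, TrialSpec
from .designmatrix import DesignMatrix
from .rdm import RDM
from .simulate import DEFAULT_VARIANCES, HIGH_SNR_NOISE, ForceTrace

__all__ = [
    "write_events",
    "read_events",
    "write_design_matrix",
    "write_rdm",
    "read_rdm",
    "write_force_trace",
    "read_force_trace",
    "write_patterns",
    "read_patterns",
    "SimulationConfig",
    "read_config",
]


def write_events(design: ExperimentDesign, path, run: int | None = None) -> None:
    """Write trials as a tab-delimited events table (one file, all runs).

    Columns follow BIDS events.tsv conventions: onset, duration (of the
    preparation phase), trial_type, plus go_nogo, iti and run.
    """
    rows = []
    runs = design.runs if run is None else [design.runs[run]]
    offset = 0 if run is None else run
    for r, rd in enumerate(runs, start=offset):
        for t in rd.trials:
            rows.append(
                {
                    "onset": t.onset,
                    "duration": t.prep_duration,
                    "trial_type": t.trial_type,
                    "go_nogo": "go" if t.is_go else "no-go",
                    "iti": t.iti,
                    "run": r,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_events(path, *, tr: float = 1.0, rest_padding: float = REST_PADDING) -> ExperimentDesign:
    """Read an events table written by :func:`write_events`."""
    df = pd.read_csv(path, sep="\t")
    runs = []
    n_trials = None
    for _, sub in df.groupby("run", sort=True):
        trials = []
        for _, row in sub.sort_values("onset").iterrows():
            ttype = str(row["trial_type"])
            is_seq = ttype.startswith("s")
            trials.append(
                TrialSpec(
                    finger=int(ttype[1:] if is_seq else ttype),
                    is_sequence=is_seq,
                    prep_duration=float(row["duration"]),
                    is_go=str(row["go_nogo"]).lower() == "go",
                    iti=float(row["iti"]),
                    onset=float(row["onset"]),
                )
            )
        runs.append(RunDesign(trials=tuple(trials), rest_padding=rest_padding))
        n_trials = len(trials)
    return ExperimentDesign(runs=tuple(runs), trials_per_run=n_trials, rest_padding=rest_padding, tr=tr)


def write_design_matrix(dm: DesignMatrix, path) -> None:
    dm.to_frame().to_csv(path, sep="\t", index=False)


def write_rdm(rdm: RDM, path, *, long: bool = False) -> None:
    """Write an RDM as a labeled 6x6 table or long-format (pair, value)."""
    if long:
        rdm.to_long().to_csv(path, sep="\t", index=False)
    else:
        rdm.to_frame().to_csv(path, sep="\t")


def read_rdm(path) -> RDM:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return RDM(values=df.to_numpy(dtype=float), labels=tuple(df.columns), n_partitions=0)


def write_force_trace(trace: ForceTrace, path) -> None:
    """Write a force trace as a tab-delimited time x finger table."""
    df = pd.DataFrame(trace.samples, columns=[f"finger_{d}" for d in (1, 2, 3, 4, 5)])
    df.insert(0, "time", trace.times)
    df["phase"] = trace.phase_labels
    df["trial"] = trace.trial_index
    df.to_csv(path, sep="\t", index=False, float_format="%.5f")


def read_force_trace(path, run: RunDesign) -> ForceTrace:
    """Read a force-trace table (the run design supplies trial timing)."""
    df = pd.read_csv(path, sep="\t")
    times = df["time"].to_numpy()
    if times.size > 1:
        dts = np.diff(times)
        if not np.allclose(dts, dts[0], atol=1e-9):
            raise ValueError("force trace must be uniformly sampled")
        dt = float(dts[0])
    else:
        dt = 0.002
    cols = [c for c in df.columns if c.startswith("finger_")]
    return ForceTrace(
        samples=df[cols].to_numpy(dtype=float),
        dt=dt,
        phase_labels=df["phase"].to_numpy(dtype=np.int8),
        trial_index=df["trial"].to_numpy(dtype=np.int32),
        run=run,
    )


def write_searchlight_map(sl_map, path) -> None:
    """Write a searchlight map as a node-value table (node coords + value)."""
    coords = sl_map.neighborhoods.centers
    df = pd.DataFrame(coords, columns=[f"x{i}" for i in range(coords.shape[1])])
    df["value"] = sl_map.values
    df["boundary"] = sl_map.neighborhoods.boundary
    df.to_csv(path, sep="\t", index=False)


def write_searchlight_nifti(sl_map, shape, path, affine=None) -> None:
    """Write a grid searchlight map as a NIfTI volume (optional extra)."""
    import nibabel as nib  # deferred: optional dependency

    vol = np.full(shape, np.nan)
    idx = tuple(sl_map.neighborhoods.centers.astype(int).T)
    vol[idx] = sl_map.values
    nib.save(nib.Nifti1Image(vol, affine if affine is not None else np.eye(4)), str(path))


def write_patterns(patterns: np.ndarray, path, labels=CONDITIONS) -> None:
    """Write (runs, conditions, voxels) patterns as long-format TSV."""
    patterns = np.asarray(patterns)
    r, c, v = patterns.shape
    df = pd.DataFrame(patterns.reshape(r * c, v), columns=[f"v{i}" for i in range(v)])
    df.insert(0, "condition", list(labels) * r)
    df.insert(0, "run", np.repeat(np.arange(r), c))
    df.to_csv(path, sep="\t", index=False)


def read_patterns(path, labels=CONDITIONS) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    runs = sorted(df["run"].unique())
    out = []
    for r in runs:
        sub = df[df["run"] == r].set_index("condition")
        out.append(sub.loc[list(labels)].drop(columns=["run"]).to_numpy(dtype=float))
    return np.stack(out)


@dataclass(frozen=True)
class SimulationConfig:
    """Settings of a full synthetic dataset."""

    n_subjects: int = 22
    n_runs: int = 10
    n_voxels: int = 200
    true_r: float = 0.8
    variances: tuple[float, float, float, float] = DEFAULT_VARIANCES
    sigma2: float = HIGH_SNR_NOISE
    leak: float = 0.0
    seed: int = 0


def read_config(path) -> SimulationConfig:
    """Parse a plain-text ``key = value`` config file ('#' comments)."""
    values = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {line!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        values[key] = val
    kwargs = {}
    casts = {
        "n_subjects": int,
        "n_runs": int,
        "n_voxels": int,
        "true_r": float,
        "sigma2": float,
        "leak": float,
        "seed": int,
    }
    for key, val in values.items():
        if key == "variances":
            parts = [float(p) for p in val.replace(",", " ").split()]
            if len(parts) != 4:
                raise ValueError("variances must hold 4 values: a_plan a_exec s_plan s_exec")
            kwargs[key] = tuple(parts)
        elif key in casts:
            kwargs[key] = casts[key](val)
        else:
            raise KeyError(f"unknown config key: {key}")
    return SimulationConfig(**kwargs)
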