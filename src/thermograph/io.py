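"""File I/O and synthetic fixture subjects.

Time series are delimited text (T rows x N columns, optional header of
region labels); trajectories are written as CSV plus a JSON sidecar; graph
sequences persist as compressed ``.npz`` with a JSON sidecar of window
metadata.  ``make_fixture_subject`` generates a synthetic resting-state-like
subject with planted covariance-regime switches, standing in for real
extracted regional series.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .thermo import ThermoTrajectory
from .windows import NodeTimeSeries, WindowedGraphSequence

__all__ = [
    "read_time_series",
    "write_time_series",
    "write_trajectory",
    "read_trajectory",
    "write_graph_sequence",
    "read_graph_sequence",
    "write_summary",
    "make_fixture_subject",
]


def read_time_series(path: str | Path, subject_id: str | None = None) -> NodeTimeSeries:
    """Read a T x N delimited text file (comma or tab; optional header row).

    A NaN cell is a hard error naming its row and column.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    head = pd.read_csv(path, sep=sep, header=None, nrows=1)
    has_header = head.iloc[0].apply(
        lambda v: isinstance(v, str) and not _is_number(v)).any()
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None)
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise ValueError(f"{path}: NaN at row {r}, column {c}")
    labels = [str(c) for c in df.columns] if has_header else None
    return NodeTimeSeries(values=values, subject_id=subject_id or path.stem,
                          region_labels=labels)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_time_series(ts: NodeTimeSeries, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    cols = ts.region_labels or [f"r{i}" for i in range(ts.n_regions)]
    pd.DataFrame(ts.values, columns=cols).to_csv(path, sep=sep, index=False)


def write_trajectory(traj: ThermoTrajectory, outdir: str | Path,
                     prefix: str = "trajectory") -> Path:
    """Write U/S/VNE/T as CSV plus node energies and a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame({
        "window_index": np.arange(traj.n_windows),
        "U": traj.U,
        "S": traj.S,
        "VNE": traj.VNE if traj.VNE is not None else np.full(traj.n_windows, np.nan),
        "T": traj.T,
    })
    csv_path = outdir / f"{prefix}.csv"
    frame.to_csv(csv_path, index=False, float_format="%.15g")
    pd.DataFrame(traj.node_energy).to_csv(
        outdir / f"{prefix}_node_energy.csv", index=False, float_format="%.15g")
    sidecar = {"alpha": traj.alpha, "n_degenerate_ds": traj.n_degenerate_ds,
               "n_windows": traj.n_windows, **traj.meta}
    (outdir / f"{prefix}.json").write_text(json.dumps(sidecar, indent=2))
    return csv_path


def read_trajectory(outdir: str | Path, prefix: str = "trajectory") -> ThermoTrajectory:
    outdir = Path(outdir)
    frame = pd.read_csv(outdir / f"{prefix}.csv")
    energy = pd.read_csv(outdir / f"{prefix}_node_energy.csv").to_numpy()
    meta = json.loads((outdir / f"{prefix}.json").read_text())
    vne = frame["VNE"].to_numpy()
    return ThermoTrajectory(
        U=frame["U"].to_numpy(), S=frame["S"].to_numpy(), T=frame["T"].to_numpy(),
        node_energy=energy,
        VNE=None if np.isnan(vne).all() else vne,
        n_degenerate_ds=int(meta.get("n_degenerate_ds", 0)),
        alpha=int(meta.get("alpha", 20)),
    )


def write_graph_sequence(seq: WindowedGraphSequence, path: str | Path) -> None:
    """Persist as ``.npz`` (windows x N x N) with a JSON metadata sidecar."""
    path = Path(path)
    np.savez_compressed(path, graphs=seq.graphs)
    meta = {
        "window_length": seq.window_length, "stride": seq.stride,
        "binary": seq.binary, "threshold": seq.threshold,
        "node_labels": seq.node_labels, **seq.meta,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_graph_sequence(path: str | Path) -> WindowedGraphSequence:
    path = Path(path)
    graphs = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))["graphs"]
    meta = json.loads(path.with_suffix(".json").read_text())
    return WindowedGraphSequence(
        graphs=graphs,
        window_length=meta.pop("window_length", 0),
        stride=meta.pop("stride", 1),
        binary=meta.pop("binary", True),
        threshold=meta.pop("threshold", 0.5),
        node_labels=meta.pop("node_labels", None),
        meta=meta,
    )


def write_summary(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify))


def _jsonify(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    raise TypeError(f"not JSON serializable: {type(v)}")


def make_fixture_subject(
    n_regions: int = 60,
    n_timepoints: int = 240,
    event_times: tuple = (120,),
    seed: int = 0,
    *,
    n_blocks: int = 6,
    within_corr: float = 0.8,
    sync_levels: tuple = (0.0, 0.65),
    permute_blocks: bool = True,
    subject_id: str | None = None,
) -> NodeTimeSeries:
    """Synthetic subject with planted covariance-regime switches.

    Regions are grouped into blocks sharing a latent factor (total
    within-block correlation ``within_corr``); on top of that, each regime
    has a global-synchronization level cycled through ``sync_levels``,
    emulating episodes of widespread co-activation in which all region pairs
    correlate.  At each planted event time the regime switches: the global
    level toggles (a strength-dominated change that moves edge mass) and,
    with ``permute_blocks``, the block assignment is permuted (a rewiring
    change).  Sliding-window SSIM troughs therefore concentrate near the
    planted switches.  Samples are temporally independent — a deliberate
    simplification relative to real hemodynamic series.
    """
    if any(not 0 < t < n_timepoints for t in event_times):
        raise ValueError("event times must lie strictly inside the series")
    if any(g < 0 or g > within_corr for g in sync_levels):
        raise ValueError("sync levels must lie in [0, within_corr]")
    rng = np.random.default_rng(seed)
    blocks = np.repeat(np.arange(n_blocks), int(np.ceil(n_regions / n_blocks)))[:n_regions]
    boundaries = [0, *sorted(event_times), n_timepoints]
    values = np.empty((n_timepoints, n_regions))
    assign = blocks.copy()
    for k in range(len(boundaries) - 1):
        t0, t1 = boundaries[k], boundaries[k + 1]
        if k > 0 and permute_blocks:
            assign = rng.permutation(assign)
        g = sync_levels[k % len(sync_levels)]
        r_blk = within_corr - g  # block + global shares sum to within_corr
        length = t1 - t0
        factors = rng.standard_normal((length, n_blocks))
        global_factor = rng.standard_normal((length, 1))
        noise = rng.standard_normal((length, n_regions))
        values[t0:t1] = (np.sqrt(r_blk) * factors[:, assign]
                         + np.sqrt(g) * global_factor
                         + np.sqrt(1 - within_corr) * noise)
    return NodeTimeSeries(
        values=values,
        subject_id=subject_id or f"fixture_{seed:04d}",
        region_labels=[f"region_{i:03d}" for i in range(n_regions)],
    )
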