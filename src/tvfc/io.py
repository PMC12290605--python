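"""File formats: time-series TSV, long-format trajectory TSV, JSON sidecars.

TSV (not CSV) avoids locale decimal ambiguity; floats are written with 17
significant digits so round trips are bit-exact. Trajectories use a long
format (``n, i, j, value``) so readers need not know D in advance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from tvfc.datatypes import CovTrajectory, TimeSeriesData

FLOAT_FMT = "%.17g"


def save_timeseries(data: TimeSeriesData, path: str | Path) -> None:
    """Write a scan as TSV: header ``time`` + node columns, one row per volume."""
    path = Path(path)
    cols = {"time": np.arange(data.n) * data.tr}
    for j in range(data.d):
        cols[f"node_{j + 1}"] = data.y[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def load_timeseries(
    path: str | Path, tr: float | None = None, zscore: bool = False
) -> TimeSeriesData:
    """Read a scan from TSV.

    Accepts either the headered format written by :func:`save_timeseries`
    (TR inferred from the time column) or a headerless numeric matrix, in
    which case ``tr`` must be supplied. Index locations are mapped to [0, 1].
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    has_header = first.lower().lstrip().startswith("time")
    try:
        df = pd.read_csv(path, sep="\t", header=0 if has_header else None,
                         float_precision="round_trip")
        values = df.to_numpy(dtype=float)
    except (ValueError, TypeError) as err:
        raise ValueError(f"{path}: non-numeric or ragged content ({err})") from err
    if has_header:
        time = values[:, 0]
        y = values[:, 1:]
        diffs = np.diff(time)
        if np.any(diffs <= 0):
            rows = (np.flatnonzero(diffs <= 0) + 2).tolist()
            raise ValueError(f"{path}: non-monotone time column at row(s) {rows}")
        tr = float(np.median(diffs)) if tr is None else tr
    else:
        if tr is None:
            raise ValueError(f"{path}: headerless input requires an explicit TR")
        y = values
    data = TimeSeriesData(y=y, tr=tr)
    return data.zscored() if zscore else data


def save_trajectory(traj: CovTrajectory, path: str | Path) -> None:
    """Write a trajectory as long-format TSV (n, i, j, value); 1-based indices."""
    n_idx, i_idx, j_idx = np.meshgrid(
        np.arange(traj.n), np.arange(traj.d), np.arange(traj.d), indexing="ij"
    )
    df = pd.DataFrame({
        "n": n_idx.ravel() + 1,
        "i": i_idx.ravel() + 1,
        "j": j_idx.ravel() + 1,
        "value": traj.sigmas.ravel(),
    })
    df.to_csv(Path(path), sep="\t", index=False, float_format=FLOAT_FMT)


def load_trajectory(path: str | Path) -> CovTrajectory:
    df = pd.read_csv(Path(path), sep="\t", float_precision="round_trip")
    n = int(df["n"].max())
    d = int(df["i"].max())
    sig = np.empty((n, d, d))
    sig[df["n"] - 1, df["i"] - 1, df["j"] - 1] = df["value"].to_numpy(dtype=float)
    return CovTrajectory(sigmas=sig)


def save_sidecar(meta: dict, path: str | Path) -> None:
    """JSON sidecar with run metadata (resolved config, seed, version)."""
    from tvfc import __version__

    payload = {"tvfc_version": __version__, **meta}

    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return str(obj)

    Path(path).write_text(json.dumps(payload, indent=2, default=_default) + "\n")


def load_config(path: str | Path) -> dict:
    """Read a run configuration from YAML or JSON."""
    text = Path(path).read_text()
    return yaml.safe_load(text)


def save_wp_model(model, path: str | Path) -> None:
    """Checkpoint a fitted Wishart-process model as a single .npz archive.

    Stores every unconstrained parameter array, the inducing locations, and
    the training configuration; :func:`load_wp_model` restores it exactly.
    """
    from dataclasses import asdict

    np.savez(
        Path(path),
        z=model.z,
        d=model.d,
        nu=model.nu,
        m=model.m,
        config=json.dumps(asdict(model.config)),
        **{f"param_{k}": v for k, v in model.params.items()},
    )


def load_wp_model(path: str | Path):
    """Restore a Wishart-process model checkpoint written by save_wp_model."""
    from tvfc.wishart import WPConfig, WPModel

    with np.load(Path(path), allow_pickle=False) as archive:
        config = WPConfig(**json.loads(str(archive["config"])))
        params = {
            k[len("param_"):]: archive[k] for k in archive.files if k.startswith("param_")
        }
        return WPModel(
            d=int(archive["d"]), nu=int(archive["nu"]), m=int(archive["m"]),
            z=archive["z"], params=params, config=config,
        )
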