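"""HDF5 / CSV containers for trial-segmented multichannel recordings.

The canonical container is an HDF5 file with datasets ``/lfp``
[channel × trial × sample], ``/time_ms`` [sample] and ``/positions_um``
[channel × 2], plus root attributes ``sampling_rate_hz`` and ``pitch_um``.
A directory of per-channel CSVs (rows = trials) is accepted as a plain-text
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .csd import ElectrodeGrid
from .errors import ConfigError

__all__ = ["GridDataset", "save_grid_dataset", "load_grid_dataset", "load_csv_dataset"]


@dataclass
class GridDataset:
    """In-memory view of a grid recording."""

    lfp: np.ndarray  # [channel, trial, sample], µV
    time_ms: np.ndarray  # [sample], relative to stimulus onset
    sampling_rate: float  # Hz
    grid: ElectrodeGrid

    @property
    def n_channels(self) -> int:
        return self.lfp.shape[0]

    @property
    def n_trials(self) -> int:
        return self.lfp.shape[1]


def save_grid_dataset(
    path, *, lfp, time_ms, sampling_rate, positions_um, pitch_um, extra=None
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("lfp", data=np.asarray(lfp, dtype=np.float64))
        f.create_dataset("time_ms", data=np.asarray(time_ms, dtype=np.float64))
        f.create_dataset(
            "positions_um", data=np.asarray(positions_um, dtype=np.float64)
        )
        f.attrs["sampling_rate_hz"] = float(sampling_rate)
        f.attrs["pitch_um"] = float(pitch_um)
        for key, value in (extra or {}).items():
            f.attrs[key] = value
    return path


def load_grid_dataset(path) -> GridDataset:
    path = Path(path)
    with h5py.File(path, "r") as f:
        lfp = f["lfp"][...]
        time_ms = f["time_ms"][...]
        positions = f["positions_um"][...]
        rate = float(f.attrs["sampling_rate_hz"])
        pitch = float(f.attrs["pitch_um"])
    return GridDataset(
        lfp=lfp,
        time_ms=time_ms,
        sampling_rate=rate,
        grid=ElectrodeGrid(positions=positions, pitch=pitch),
    )


def load_csv_dataset(
    directory, *, sampling_rate, t_start_ms, positions_um, pitch_um
) -> GridDataset:
    """Load a directory of per-channel CSVs (``channel_*.csv``, rows = trials).

    Channel order follows the sorted file names and must match the order of
    ``positions_um``.
    """
    directory = Path(directory)
    files = sorted(directory.glob("channel_*.csv"))
    if not files:
        raise ConfigError(f"no channel_*.csv files in {directory}")
    mats = [pd.read_csv(f, header=None).to_numpy(dtype=float) for f in files]
    shapes = {m.shape for m in mats}
    if len(shapes) != 1:
        raise ConfigError("per-channel CSVs have inconsistent trial/sample counts")
    lfp = np.stack(mats)
    n_samp = lfp.shape[2]
    time_ms = t_start_ms + np.arange(n_samp) * 1000.0 / sampling_rate
    return GridDataset(
        lfp=lfp,
        time_ms=time_ms,
        sampling_rate=sampling_rate,
        grid=ElectrodeGrid(positions=np.asarray(positions_um), pitch=pitch_um),
    )
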