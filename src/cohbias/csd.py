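"""Two-dimensional current source density on a regular microelectrode grid.

The CSD at an interior electrode is the potential minus the mean of its four
lattice neighbors:

    CSD(x, y) = V(x, y) − [V(x−d, y) + V(x+d, y) + V(x, y+d) + V(x, y−d)] / 4

i.e. a (negated, scaled) discrete Laplacian.  Conductivity and the 1/d²
factor are omitted: they are common positive scalings and cancel in every
coherence-type measure.  Any component common to all electrodes — the
signature of volume conduction — is removed exactly, and affine potential
fields are annihilated.

Edge electrodes (fewer than four neighbors at one pitch) are excluded by
default.  An optional Vaknin-style padding replicates the nearest available
ring outward so edge channels can be retained; it is off by default because
it invents data at the array border.

Caveat for downstream correlation analyses: two CSDs one pitch apart each
contain −1/4 of the other's center potential, so nearest-neighbor CSD pairs
are correlated by construction even for independent channel noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GridError

__all__ = ["ElectrodeGrid", "csd_2d"]

# positions matched to the lattice within pitch/100
_LATTICE_TOL = 0.01


@dataclass
class ElectrodeGrid:
    """Electrode positions on a regular square lattice.

    Parameters
    ----------
    positions
        (n_channels, 2) x/y coordinates in µm.
    pitch
        Lattice spacing d in µm.
    valid_mask
        Per-channel validity flag (dead channels False).
    """

    positions: np.ndarray
    pitch: float
    valid_mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise GridError("positions must be (n_channels, 2)")
        if not self.pitch > 0:
            raise GridError("pitch must be positive")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.n_channels, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.size != self.n_channels:
                raise GridError("valid_mask length mismatch")
        lattice = self.positions / self.pitch
        if np.any(np.abs(lattice - np.round(lattice)) > _LATTICE_TOL):
            raise GridError("positions do not lie on a regular lattice")
        self._index = {
            (int(i), int(j)): ch
            for ch, (i, j) in enumerate(np.round(lattice).astype(int))
        }

    @classmethod
    def regular(
        cls, n_rows: int, n_cols: int, pitch: float, valid_mask=None
    ) -> "ElectrodeGrid":
        """Full n_rows × n_cols grid, channels in row-major order."""
        cols, rows = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
        positions = np.column_stack([cols.ravel(), rows.ravel()]) * pitch
        return cls(positions=positions, pitch=pitch, valid_mask=valid_mask)

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    def neighbors(self, channel: int) -> list[int]:
        """Valid channels exactly one pitch away in the four lattice
        directions (may be fewer than 4 at edges)."""
        i, j = np.round(self.positions[channel] / self.pitch).astype(int)
        out = []
        for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            ch = self._index.get((i + di, j + dj))
            if ch is not None and self.valid_mask[ch]:
                out.append(ch)
        return out

    def interior_channels(self) -> np.ndarray:
        """Valid channels with four valid one-pitch neighbors."""
        return np.array(
            [
                ch
                for ch in range(self.n_channels)
                if self.valid_mask[ch] and len(self.neighbors(ch)) == 4
            ],
            dtype=int,
        )

    def pair_distances(self) -> tuple[np.ndarray, np.ndarray]:
        """All unordered valid-channel pairs and their Euclidean distances (µm).

        Returns (pairs [m, 2], distances [m]).
        """
        valid = np.flatnonzero(self.valid_mask)
        if valid.size < 2:
            raise GridError("need at least 2 valid channels for pairs")
        ii, jj = np.triu_indices(valid.size, k=1)
        pairs = np.column_stack([valid[ii], valid[jj]])
        d = np.linalg.norm(
            self.positions[pairs[:, 0]] - self.positions[pairs[:, 1]], axis=1
        )
        return pairs, d


def csd_2d(
    voltages: np.ndarray, grid: ElectrodeGrid, pad_edges: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Current source density traces for interior channels.

    Parameters
    ----------
    voltages
        Array [channel, ...] (typically [channel, trial, samples]); leading
        axis indexes grid channels.
    grid
        Electrode geometry.
    pad_edges
        If True, apply Vaknin-style edge padding (missing neighbors replaced
        by the center electrode's own potential) so every valid channel gets
        a CSD.  Off by default.

    Returns
    -------
    csd : array [n_kept, ...]
        CSD traces, same trailing shape as the input.
    channels : array [n_kept]
        Original channel indices of the rows of ``csd``.
    """
    voltages = np.asarray(voltages, dtype=float)
    if voltages.shape[0] != grid.n_channels:
        raise GridError(
            f"voltages leading axis {voltages.shape[0]} != "
            f"{grid.n_channels} grid channels"
        )
    if pad_edges:
        kept = np.flatnonzero(grid.valid_mask)
    else:
        kept = grid.interior_channels()
    if kept.size == 0:
        raise GridError("no channels with four valid neighbors")
    out = np.empty((kept.size,) + voltages.shape[1:])
    for row, ch in enumerate(kept):
        nbrs = grid.neighbors(ch)
        nbr_sum = voltages[nbrs].sum(axis=0)
        if len(nbrs) < 4:  # only reachable with pad_edges
            nbr_sum = nbr_sum + (4 - len(nbrs)) * voltages[ch]
        out[row] = voltages[ch] - nbr_sum / 4.0
    return out, kept
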