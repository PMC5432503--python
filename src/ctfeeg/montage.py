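"""Electrode montages: names, 2-D scalp coordinates, neighbourhood graph.

Coordinates come from the standard 10-05 electrode scheme (via MNE's
built-in montage) projected onto the unit disc with an azimuthal-equidistant
projection (vertex at the origin, nose up). Two electrodes are neighbours
when their 2-D distance is below a configurable threshold; the resulting
adjacency graph is symmetric and, for the shipped layouts at the default
threshold, connected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: The 23 scalp sites of the 4-position (midline target) recording layout.
EXP1_ELECTRODES = [
    "Fpz", "F7", "F3", "Fz", "F4", "F8", "FC5", "FC6", "T7", "C3", "Cz",
    "C4", "T8", "CP5", "CP6", "P7", "P3", "Pz", "P4", "P8", "PO7", "PO8",
    "Oz",
]

#: The 8-position circular-display layout adds four posterior sites.
EXP2_ELECTRODES = EXP1_ELECTRODES + ["P9", "P10", "PO9", "PO10"]

# the 23/27-site layouts are sparse (inter-electrode spacing ~0.3-0.5 on
# the disc); 0.6 links nearest neighbours and keeps both layouts connected
DEFAULT_NEIGHBOR_DISTANCE = 0.6


@dataclass
class Montage:
    """Named electrodes with unit-disc coordinates and adjacency."""

    names: list[str]
    coords: np.ndarray        # (m, 2), unit disc, nose up (+y)
    adjacency: np.ndarray     # (m, m) boolean, symmetric, zero diagonal

    def __post_init__(self) -> None:
        self.names = list(self.names)
        self.coords = np.asarray(self.coords, dtype=float)
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        m = len(self.names)
        if self.coords.shape != (m, 2):
            raise ValueError("coords must be (n_electrodes, 2)")
        if self.adjacency.shape != (m, m):
            raise ValueError("adjacency must be square over electrodes")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")

    @property
    def n_electrodes(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"electrode {name!r} not in montage") from None

    def neighbors(self, name: str) -> list[str]:
        i = self.index(name)
        return [self.names[j] for j in np.flatnonzero(self.adjacency[i])]

    def to_csv(self, path) -> None:
        """Write ``name,x,y`` rows."""
        with open(path, "w") as fh:
            fh.write("name,x,y\n")
            for name, (x, y) in zip(self.names, self.coords):
                fh.write(f"{name},{x:.6f},{y:.6f}\n")

    @classmethod
    def from_csv(cls, path, neighbor_distance: float = DEFAULT_NEIGHBOR_DISTANCE,
                 ) -> "Montage":
        names, xy = [], []
        with open(path) as fh:
            header = fh.readline().strip().split(",")
            if header[:3] != ["name", "x", "y"]:
                raise ValueError("montage CSV must have header name,x,y")
            for line in fh:
                if not line.strip():
                    continue
                name, x, y = line.strip().split(",")[:3]
                names.append(name)
                xy.append((float(x), float(y)))
        coords = np.array(xy)
        return cls(names, coords, _distance_adjacency(coords, neighbor_distance))


def _distance_adjacency(coords: np.ndarray, threshold: float) -> np.ndarray:
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    adj = (d < threshold) & (d > 0)
    return adj


def _standard_1005_disc_positions(names: list[str]) -> np.ndarray:
    """Unit-disc coordinates for 10-05 electrode names (nose up)."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mont = mne.channels.make_standard_montage("standard_1005")
    pos = mont.get_positions()["ch_pos"]
    missing = [n for n in names if n not in pos]
    if missing:
        raise ValueError(f"unknown 10-05 electrode names: {missing}")
    xyz = np.array([pos[n] for n in names])
    r = np.linalg.norm(xyz, axis=1)
    polar = np.arccos(np.clip(xyz[:, 2] / r, -1.0, 1.0))
    azim = np.arctan2(xyz[:, 0], xyz[:, 1])  # 0 = nose, positive = right
    # fixed scale (equator -> radius 1) so coordinates do not depend on
    # which electrodes a layout happens to include
    xy = polar[:, None] * np.c_[np.sin(azim), np.cos(azim)]
    return xy / (np.pi / 2)


def make_montage(layout_name: str, n: int | None = None,
                 neighbor_distance: float = DEFAULT_NEIGHBOR_DISTANCE,
                 ) -> Montage:
    """Build a named montage.

    Parameters
    ----------
    layout_name : {"exp1_23", "exp2_27", "ring_n"}
        ``exp1_23``: the 23-site layout used with 4-position midline
        displays. ``exp2_27``: the same plus P9/P10/PO9/PO10, used with
        8-position circular displays. ``ring_n``: ``n`` synthetic
        electrodes evenly spaced on a circle of radius 0.8 (for toy
        fixtures).
    n : int, optional
        Electrode count, required for ``ring_n``.
    neighbor_distance : float
        Two electrodes closer than this (unit-disc distance) are
        neighbours in the adjacency graph.
    """
    if layout_name == "exp1_23":
        names = EXP1_ELECTRODES
        coords = _standard_1005_disc_positions(names)
    elif layout_name == "exp2_27":
        names = EXP2_ELECTRODES
        coords = _standard_1005_disc_positions(names)
    elif layout_name == "ring_n":
        if n is None or n < 3:
            raise ValueError("ring_n layout requires n >= 3")
        names = [f"R{i + 1}" for i in range(n)]
        ang = 2 * np.pi * np.arange(n) / n
        coords = 0.8 * np.c_[np.sin(ang), np.cos(ang)]
        # neighbour threshold that links adjacent ring sites
        neighbor_distance = max(neighbor_distance,
                                1.1 * 2 * 0.8 * np.sin(np.pi / n))
    else:
        raise ValueError(f"unknown montage layout {layout_name!r}")
    return Montage(names, coords, _distance_adjacency(coords, neighbor_distance))
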