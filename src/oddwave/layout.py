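"""Channel layouts and neighbor graphs.

The analysis operates on a 64-channel 10/20-family scalp montage referenced
to linked mastoids.  Scalp positions come from the standard idealized-head
montage shipped with MNE-Python, projected to a 2-D head schematic; the
spatial neighbor graph is a Delaunay triangulation of those positions with
implausibly long (hull-spanning) edges pruned.  Mastoids are carried as
reference channels and excluded from the adjacency.

Micro-layouts (``chain-N``, ``complete-N``, ``mesh-RxC``) exist for exact,
hand-checkable tests of neighbor-dependent algorithms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChannelLayout", "make_layout", "GRID64_SCALP"]

#: 64 scalp labels of the extended 10/20 (10-10) system, anterior to posterior.
GRID64_SCALP = [
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P9", "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8", "P10",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2", "Iz",
]

MASTOIDS = ["M1", "M2"]


@dataclass
class ChannelLayout:
    """Channel names, schematic 2-D positions, and scalp adjacency."""

    name: str
    channel_names: list[str]
    positions: np.ndarray                     # (n_channels, 2)
    neighbors: dict[str, list[str]]           # scalp channels only
    reference_channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.channel_names), 2):
            raise ValueError("positions must be (n_channels, 2)")
        scalp = set(self.scalp_channels)
        for ch, nbrs in self.neighbors.items():
            if ch not in scalp:
                raise ValueError(f"adjacency lists non-scalp channel {ch!r}")
            if ch in nbrs:
                raise ValueError(f"self-neighbor at {ch!r}")
            if not nbrs:
                raise ValueError(f"isolated scalp channel {ch!r}")
            for nb in nbrs:
                if ch not in self.neighbors.get(nb, []):
                    raise ValueError(f"asymmetric adjacency {ch!r}->{nb!r}")

    @property
    def scalp_channels(self) -> list[str]:
        ref = set(self.reference_channels)
        return [c for c in self.channel_names if c not in ref]

    def index(self, name: str) -> int:
        return self.channel_names.index(name)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def scalp_indices(self) -> np.ndarray:
        return np.array([self.index(c) for c in self.scalp_channels])

    def adjacency_matrix(self, channels: list[str] | None = None) -> np.ndarray:
        """Boolean spatial adjacency over ``channels`` (default: scalp)."""
        channels = self.scalp_channels if channels is None else channels
        pos = {c: i for i, c in enumerate(channels)}
        A = np.zeros((len(channels), len(channels)), dtype=bool)
        for ch in channels:
            for nb in self.neighbors.get(ch, []):
                if nb in pos:
                    A[pos[ch], pos[nb]] = True
        return A

    # -- serialization ------------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "name": self.name,
            "channel_names": self.channel_names,
            "positions": self.positions.tolist(),
            "neighbors": self.neighbors,
            "reference_channels": self.reference_channels,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ChannelLayout":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            name=payload["name"],
            channel_names=payload["channel_names"],
            positions=np.asarray(payload["positions"], dtype=float),
            neighbors={k: list(v) for k, v in payload["neighbors"].items()},
            reference_channels=list(payload["reference_channels"]),
        )


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def _grid64_positions() -> dict[str, np.ndarray]:
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        try:
            montage = mne.channels.make_standard_montage("standard_1005")
        except ValueError:  # renamed in newer MNE releases
            montage = mne.channels.make_standard_montage("colin27_1005")
    pos3d = montage.get_positions()["ch_pos"]
    out = {}
    for ch in GRID64_SCALP + MASTOIDS:
        x, y, _ = pos3d[ch]
        out[ch] = np.array([x, y]) * 1000.0  # head-schematic units (mm)
    return out


def _delaunay_neighbors(names: list[str], pos: np.ndarray) -> dict[str, list[str]]:
    from scipy.spatial import Delaunay

    tri = Delaunay(pos)
    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                i, j = sorted((simplex[a], simplex[b]))
                edges.add((i, j))
    lengths = np.array([np.linalg.norm(pos[i] - pos[j]) for i, j in edges])
    # drop hull-spanning edges much longer than the typical electrode spacing
    cutoff = 1.8 * np.median(lengths)
    nbrs: dict[str, set[str]] = {n: set() for n in names}
    for (i, j), L in zip(edges, lengths):
        if L <= cutoff:
            nbrs[names[i]].add(names[j])
            nbrs[names[j]].add(names[i])
    for (i, j), L in sorted(zip(edges, lengths), key=lambda e: e[1]):
        # re-attach any channel left isolated by the pruning via its shortest edge
        if not nbrs[names[i]] or not nbrs[names[j]]:
            nbrs[names[i]].add(names[j])
            nbrs[names[j]].add(names[i])
    return {n: sorted(v) for n, v in nbrs.items()}


def make_layout(preset: str = "grid64") -> ChannelLayout:
    """Build a named layout preset.

    ``grid64``
        64 scalp channels (10-10 names, incl. Cz) + M1/M2 mastoid references,
        Delaunay neighbor graph.
    ``chain-N``
        N channels in a line, consecutive channels adjacent.
    ``complete-N``
        N mutually adjacent channels.
    ``mesh-RxC``
        R-by-C rectangular grid with 4-connectivity.
    """
    if preset == "grid64":
        posmap = _grid64_positions()
        names = GRID64_SCALP + MASTOIDS
        pos = np.array([posmap[c] for c in names])
        scalp_pos = np.array([posmap[c] for c in GRID64_SCALP])
        neighbors = _delaunay_neighbors(GRID64_SCALP, scalp_pos)
        return ChannelLayout("grid64", names, pos, neighbors, reference_channels=list(MASTOIDS))

    if preset.startswith("chain-"):
        n = int(preset.split("-", 1)[1])
        names = [chr(ord("A") + i) if n <= 26 else f"ch{i}" for i in range(n)]
        pos = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
        neighbors = {
            names[i]: sorted(names[j] for j in (i - 1, i + 1) if 0 <= j < n)
            for i in range(n)
        }
        return ChannelLayout(preset, names, pos, neighbors)

    if preset.startswith("complete-"):
        n = int(preset.split("-", 1)[1])
        names = [chr(ord("A") + i) if n <= 26 else f"ch{i}" for i in range(n)]
        theta = 2 * np.pi * np.arange(n) / n
        pos = np.column_stack([np.cos(theta), np.sin(theta)])
        neighbors = {a: sorted(b for b in names if b != a) for a in names}
        return ChannelLayout(preset, names, pos, neighbors)

    if preset.startswith("mesh-"):
        r, c = (int(v) for v in preset.split("-", 1)[1].split("x"))
        names = [f"E{i}{j}" for i in range(r) for j in range(c)]
        pos = np.array([[j, -i] for i in range(r) for j in range(c)], dtype=float)
        neighbors: dict[str, list[str]] = {}
        for i in range(r):
            for j in range(c):
                nb = []
                for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                    ii, jj = i + di, j + dj
                    if 0 <= ii < r and 0 <= jj < c:
                        nb.append(f"E{ii}{jj}")
                neighbors[f"E{i}{j}"] = sorted(nb)
        return ChannelLayout(preset, names, pos, neighbors)

    raise KeyError(f"unknown layout preset {preset!r}")
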