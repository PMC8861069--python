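"""Containers for averaged ERP cohorts and channel geometry.

The central exchange object is :class:`ERPDataset`: per-subject,
per-condition channel x time arrays on a shared time axis, together with the
electrode layout. Everything downstream (preprocessing, the conditional GAN,
the statistics) consumes and produces this container.

Time conventions
----------------
All windows are half-open ``[start, stop)`` in milliseconds, and the sample
index of a time point is ``floor(t_ms * fs / 1000)``. At 256 Hz the analysis
window 0-1000 ms therefore holds exactly 256 samples.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

GO = "Go"
NOGO = "Nogo"
CONDITIONS = (GO, NOGO)

#: Schematic desk-scale montage: fronto-central sites carrying the N2/P3
#: inhibition components, parietal sites for the parietal P3, and the
#: posterior-lateral pair used for P1/N1.
DEFAULT_8 = ("Fz", "FC1", "FC2", "Cz", "P1", "Pz", "P7", "P8")


def time_to_index(t_ms: float, fs: float) -> int:
    """Sample index of a time point under the half-open convention."""
    return int(np.floor(t_ms * fs / 1000.0))


def window_slice(window_ms: tuple[float, float], fs: float, t0_ms: float = 0.0) -> slice:
    """Slice of samples covering ``[start, stop)`` ms relative to ``t0_ms``."""
    lo, hi = window_ms
    if hi <= lo:
        raise ValueError(f"empty window {window_ms}")
    return slice(time_to_index(lo - t0_ms, fs), time_to_index(hi - t0_ms, fs))


@dataclass
class ChannelLayout:
    """Electrode names with spherical (3-D, unit radius) and planar positions.

    The 2-D positions drive the neighborhood graph of the cluster test; the
    3-D positions drive the spherical-spline CSD / interpolation operators.
    """

    names: list[str]
    pos3d: np.ndarray  # (n_ch, 3), unit sphere
    pos2d: np.ndarray  # (n_ch, 2)

    def __post_init__(self) -> None:
        self.names = list(self.names)
        self.pos3d = np.asarray(self.pos3d, dtype=float)
        self.pos2d = np.asarray(self.pos2d, dtype=float)
        if self.pos3d.shape != (len(self.names), 3):
            raise ValueError("pos3d must be (n_channels, 3)")
        if self.pos2d.shape != (len(self.names), 2):
            raise ValueError("pos2d must be (n_channels, 2)")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in layout {self.names}") from None

    @classmethod
    def standard(cls, names=DEFAULT_8) -> "ChannelLayout":
        """Layout for named 10-05 electrodes on an idealized spherical head."""
        from mne.channels import make_standard_montage

        montage = make_standard_montage("spherical_1005")
        ch_pos = montage.get_positions()["ch_pos"]
        pos = []
        for name in names:
            if name not in ch_pos:
                raise KeyError(f"electrode {name!r} not in the 10-05 system")
            pos.append(ch_pos[name])
        pos3d = np.asarray(pos, dtype=float)
        pos3d /= np.linalg.norm(pos3d, axis=1, keepdims=True)
        return cls(list(names), pos3d, _azimuthal_projection(pos3d))

    @classmethod
    def standard_60(cls) -> "ChannelLayout":
        """A 60-electrode 10-10 montage (schematic full-cap geometry)."""
        return cls.standard(STANDARD_60)

    def adjacency(self, mean_degree: float = 4.0) -> np.ndarray:
        """Boolean neighbor matrix from a 2-D distance threshold.

        The threshold is the smallest inter-electrode distance whose graph
        reaches at least ``mean_degree`` average neighbors, mirroring the
        minimum-neighborhood conventions of spatiotemporal cluster tests.
        """
        d = np.linalg.norm(self.pos2d[:, None, :] - self.pos2d[None, :, :], axis=-1)
        off = d[~np.eye(self.n_channels, dtype=bool)]
        for thr in np.sort(np.unique(off)):
            adj = (d <= thr) & ~np.eye(self.n_channels, dtype=bool)
            if adj.sum() / self.n_channels >= mean_degree:
                break
        if not _is_connected(adj):
            warnings.warn("channel adjacency graph is not connected")
        return adj

    def to_json(self) -> dict:
        return {
            "names": self.names,
            "pos3d": self.pos3d.tolist(),
            "pos2d": self.pos2d.tolist(),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "ChannelLayout":
        return cls(obj["names"], np.asarray(obj["pos3d"]), np.asarray(obj["pos2d"]))


def _azimuthal_projection(pos3d: np.ndarray) -> np.ndarray:
    """Polar azimuthal-equidistant projection (vertex Cz maps to the origin)."""
    x, y, z = pos3d.T
    theta = np.arccos(np.clip(z / np.linalg.norm(pos3d, axis=1), -1.0, 1.0))
    phi = np.arctan2(y, x)
    return np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])


def _is_connected(adj: np.ndarray) -> bool:
    n = adj.shape[0]
    seen = np.zeros(n, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        i = stack.pop()
        for j in np.flatnonzero(adj[i]):
            if not seen[j]:
                seen[j] = True
                stack.append(j)
    return bool(seen.all())


@dataclass
class ERPDataset:
    """Per-subject, per-condition averaged ERPs on a common time axis.

    ``data[condition]`` has shape ``(n_subjects, n_channels, n_times)``.
    Units are µV for scalp potentials and µV/m² after the CSD transform.
    """

    subjects: list[str]
    data: dict[str, np.ndarray]
    fs: float
    t0_ms: float
    layout: ChannelLayout
    units: str = "uV"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.subjects = list(self.subjects)
        shapes = set()
        for cond, arr in self.data.items():
            arr = np.asarray(arr, dtype=float)
            self.data[cond] = arr
            if arr.ndim != 3:
                raise ValueError(f"{cond}: expected (subject, channel, time) array")
            if arr.shape[0] != len(self.subjects):
                raise ValueError(f"{cond}: {arr.shape[0]} rows for {len(self.subjects)} subjects")
            if arr.shape[1] != self.layout.n_channels:
                raise ValueError(f"{cond}: channel axis does not match layout")
            if not np.isfinite(arr).all():
                raise ValueError(f"{cond}: non-finite values")
            shapes.add(arr.shape)
        if len({s[2] for s in shapes}) > 1:
            raise ValueError("conditions disagree on time-axis length")

    @property
    def conditions(self) -> list[str]:
        return list(self.data)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_times(self) -> int:
        return next(iter(self.data.values())).shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n_times) * 1000.0 / self.fs

    def copy(self) -> "ERPDataset":
        return ERPDataset(
            list(self.subjects),
            {c: a.copy() for c, a in self.data.items()},
            self.fs,
            self.t0_ms,
            self.layout,
            self.units,
            dict(self.meta),
        )

    def grand_average(self, condition: str) -> np.ndarray:
        """Cohort mean, shape (n_channels, n_times)."""
        return self.data[condition].mean(axis=0)

    # -- container on disk: JSON sidecar + one little-endian float64 .npy per
    # -- condition, axis order (subject, channel, time)

    def save(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        sidecar = {
            "subjects": self.subjects,
            "conditions": self.conditions,
            "fs": self.fs,
            "t0_ms": self.t0_ms,
            "units": self.units,
            "layout": self.layout.to_json(),
            "axis_order": ["subject", "channel", "time"],
            "byte_order": "little",
            "n_times": self.n_times,
            "meta": self.meta,
        }
        (directory / "dataset.json").write_text(json.dumps(sidecar, indent=1))
        for cond, arr in self.data.items():
            np.save(directory / f"{cond}.npy", arr.astype("<f8"))
        return directory

    @classmethod
    def load(cls, directory) -> "ERPDataset":
        directory = Path(directory)
        sidecar = json.loads((directory / "dataset.json").read_text())
        data = {c: np.load(directory / f"{c}.npy") for c in sidecar["conditions"]}
        return cls(
            sidecar["subjects"],
            data,
            sidecar["fs"],
            sidecar["t0_ms"],
            ChannelLayout.from_json(sidecar["layout"]),
            sidecar.get("units", "uV"),
            sidecar.get("meta", {}),
        )


#: 60 names from the 10-10 system for the full-cap schematic montage.
STANDARD_60 = (
    "Fp1", "Fp2", "AF7", "AF3", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2", "Iz",
)
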