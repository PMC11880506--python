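"""Standard 64-electrode layout: names, 3-D positions, 2-D scalp projection.

Positions come from the BioSemi 64-channel montage placed on the 10-20
derived standard head.  The 2-D coordinates are an azimuthal-equidistant
projection (arc length from the vertex preserved), the usual flattening for
scalp maps, searchlight adjacency, and region-of-interest splits.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import mne
import numpy as np


@dataclass(frozen=True)
class ChannelLayout:
    names: tuple[str, ...]
    pos3d: np.ndarray   # (n, 3) meters, head frame (x right, y front, z up)
    pos2d: np.ndarray   # (n, 2) flattened scalp coordinates

    def subset(self, names: list[str] | None = None, n: int | None = None) -> "ChannelLayout":
        if names is None:
            names = list(self.names[:n])
        idx = [self.names.index(ch) for ch in names]
        return ChannelLayout(tuple(names), self.pos3d[idx], self.pos2d[idx])

    def __len__(self) -> int:
        return len(self.names)


def _azimuthal_project(pos3d: np.ndarray) -> np.ndarray:
    """Flatten head-surface points; radial distance = arc from vertex."""
    p = pos3d - pos3d.mean(axis=0, keepdims=True) * 0  # head frame already centered
    r = np.linalg.norm(p, axis=1)
    r = np.where(r == 0, 1.0, r)
    theta = np.arccos(np.clip(p[:, 2] / r, -1, 1))     # polar angle from vertex
    rho_xy = np.linalg.norm(p[:, :2], axis=1)
    scale = np.where(rho_xy > 0, theta * r / np.maximum(rho_xy, 1e-12), 0.0)
    return p[:, :2] * scale[:, None]


@lru_cache(maxsize=1)
def biosemi64() -> ChannelLayout:
    """The standard 64-channel layout used throughout the package."""
    mont = mne.channels.make_standard_montage("biosemi64")
    ch_pos = mont.get_positions()["ch_pos"]
    names = tuple(mont.ch_names)
    pos3d = np.array([ch_pos[ch] for ch in names])
    return ChannelLayout(names=names, pos3d=pos3d, pos2d=_azimuthal_project(pos3d))


def layout_for(n_channels: int) -> ChannelLayout:
    """Layout for the first ``n_channels`` electrodes (full montage for 64)."""
    lay = biosemi64()
    if n_channels > len(lay):
        raise ValueError(f"at most {len(lay)} channels available, got {n_channels}")
    return lay if n_channels == len(lay) else lay.subset(n=n_channels)
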