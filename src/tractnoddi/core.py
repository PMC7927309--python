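"""Shared containers: scalar volumes on a grid and streamline bundles.

World coordinates are RAS millimetres throughout; voxel indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass
class ScalarVolume:
    """A 3-D scalar grid with a 4x4 voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    def world_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Map world-mm points (N, 3) to continuous voxel indices (N, 3)."""
        points_mm = np.atleast_2d(np.asarray(points_mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        return points_mm @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def sample(self, points_mm: np.ndarray, method: str = "trilinear") -> np.ndarray:
        """Sample the volume at world-mm points.

        Trilinear interpolation (order-1 spline, which is exact on linear
        fields) or nearest-neighbour. Points outside the grid, or touching
        NaN background under trilinear, come back as NaN.
        """
        vox = self.world_to_voxel(points_mm)
        order = {"trilinear": 1, "nearest": 0}.get(method)
        if order is None:
            raise ValueError(f"unknown interpolation method {method!r}")
        return ndimage.map_coordinates(
            self.data, vox.T, order=order, mode="constant", cval=np.nan, prefilter=False
        )


@dataclass
class TractModel:
    """A named, sided white-matter bundle: ordered streamlines in world mm.

    ``origin_mm`` is the common anatomical origin used for reorientation
    (e.g. the frontalmost point for the arcuate fasciculus).
    """

    name: str
    side: str
    streamlines: list = field(default_factory=list)
    origin_mm: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.streamlines:
            raise ValueError("a tract needs at least one streamline")
        cleaned = []
        for sl in self.streamlines:
            sl = np.asarray(sl, dtype=float)
            if sl.ndim != 2 or sl.shape[1] != 3 or sl.shape[0] < 2:
                raise ValueError("each streamline must be an (N>=2, 3) array")
            cleaned.append(sl)
        self.streamlines = cleaned
        if self.origin_mm is not None:
            self.origin_mm = np.asarray(self.origin_mm, dtype=float).reshape(3)

    def __len__(self) -> int:
        return len(self.streamlines)


def arc_length(vertices: np.ndarray) -> float:
    """Total polyline arc length in mm."""
    vertices = np.asarray(vertices, dtype=float)
    return float(np.sum(np.linalg.norm(np.diff(vertices, axis=0), axis=1)))
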