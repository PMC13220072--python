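"""Ordered vessel centerlines: arc length, tangents, radial projections."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Centerline"]


@dataclass
class Centerline:
    """Ordered polyline through the vessel lumen, coordinates in mm."""

    points: np.ndarray
    arc_length: np.ndarray | None = None  # analytic override; chord sum if None

    def __post_init__(self):
        self.points = np.ascontiguousarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("centerline points must be (n, 3)")
        if len(self.points) < 2:
            raise ValueError("centerline needs at least 2 points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("duplicated consecutive centerline points")
        if self.arc_length is None:
            self.arc_length = np.concatenate([[0.0], np.cumsum(seg)])
        else:
            self.arc_length = np.ascontiguousarray(self.arc_length, dtype=float)
            if self.arc_length.shape != (len(self.points),) or np.any(
                np.diff(self.arc_length) <= 0
            ):
                raise ValueError("arc_length must be strictly increasing, one per point")

    @property
    def length(self) -> float:
        return float(self.arc_length[-1])

    @property
    def tangents(self) -> np.ndarray:
        """Unit tangents by central differences (one-sided at the ends)."""
        t = np.gradient(self.points, self.arc_length, axis=0)
        return t / np.linalg.norm(t, axis=1, keepdims=True)

    def point_at(self, s: float) -> np.ndarray:
        return np.array(
            [np.interp(s, self.arc_length, self.points[:, k]) for k in range(3)]
        )

    def tangent_at(self, s: float) -> np.ndarray:
        tg = self.tangents
        t = np.array([np.interp(s, self.arc_length, tg[:, k]) for k in range(3)])
        return t / np.linalg.norm(t)

    def project(self, pts: np.ndarray):
        """Project points onto the polyline (nearest-sample approximation).

        Returns ``(s, radial_dir, radial_dist)``: arc-length station, unit
        radial direction (orthogonalised against the local tangent) and the
        radial distance of each point.
        """
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        d2 = ((pts[:, None, :] - self.points[None, :, :]) ** 2).sum(axis=2)
        idx = np.argmin(d2, axis=1)
        s = self.arc_length[idx]
        base = self.points[idx]
        tg = self.tangents[idx]
        v = pts - base
        # refine station along the local tangent, then re-orthogonalise
        along = np.einsum("ij,ij->i", v, tg)
        s = np.clip(s + along, 0.0, self.length)
        v = v - along[:, None] * tg
        dist = np.linalg.norm(v, axis=1)
        safe = np.where(dist > 0, dist, 1.0)
        rdir = v / safe[:, None]
        return s, rdir, dist
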