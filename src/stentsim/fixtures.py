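"""Synthetic vessel fixtures: straight, stenotic and curved tubes.

The study geometries are patient-specific and not redistributable, so these
parameterised tubes — with exact centerlines and analytic diameter profiles —
serve as ground truth for the metrics and the end-to-end deployment tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .centerline import Centerline
from .simplex import TriMesh

__all__ = ["TubeSpec", "TruthProfile", "make_tube", "make_stenotic_tube", "make_curved_tube"]


@dataclass
class TubeSpec:
    """Parameters of a synthetic tube, lengths in mm."""

    length: float = 30.0
    diameter: float = 3.0
    n_axial: int = 60
    n_circ: int = 32
    stenosis_severity: float = 0.0  # fractional diameter reduction in [0, 1)
    stenosis_center: float = 15.0
    stenosis_width: float = 3.0
    curvature_radius: float = float("inf")  # inf = straight
    jitter: float = 0.0  # optional vertex jitter amplitude (mm)
    seed: int = 0

    def validate(self):
        if self.n_circ < 3 or self.n_axial < 2:
            raise ValueError("need n_circ >= 3 and n_axial >= 2")
        if not (0.0 <= self.stenosis_severity < 1.0):
            raise ValueError("stenosis severity must be in [0, 1)")
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError("length and diameter must be positive")


@dataclass
class TruthProfile:
    """Exact analytic diameter d(s) along the tube, s = arc length in mm."""

    radius_fn: Callable[[np.ndarray], np.ndarray]

    def diameter(self, s):
        return 2.0 * self.radius_fn(np.asarray(s, dtype=float))


def _radius_fn(spec: TubeSpec) -> Callable[[np.ndarray], np.ndarray]:
    r0 = spec.diameter / 2.0
    if spec.stenosis_severity == 0.0:
        return lambda s: np.full_like(np.asarray(s, dtype=float), r0)
    sev, z0, w = spec.stenosis_severity, spec.stenosis_center, spec.stenosis_width

    def fn(s):
        s = np.asarray(s, dtype=float)
        return r0 * (1.0 - sev * np.exp(-((s - z0) ** 2) / (2.0 * w**2)))

    return fn


def _grid_faces(n_axial: int, n_circ: int) -> np.ndarray:
    """Two triangles per quad, wound so normals point away from the axis."""
    faces = []
    for i in range(n_axial - 1):
        for j in range(n_circ):
            a = i * n_circ + j
            b = i * n_circ + (j + 1) % n_circ
            c = a + n_circ
            d = b + n_circ
            faces.append([a, b, d])
            faces.append([a, d, c])
    return np.asarray(faces, dtype=np.int64)


def make_tube(spec: TubeSpec):
    """Open-ended straight cylinder along +z.

    Returns ``(TriMesh, Centerline, TruthProfile)``.
    """
    spec.validate()
    return _make_straight(spec, _radius_fn(spec))


def make_stenotic_tube(spec: TubeSpec):
    """Straight tube with a Gaussian radius dip at ``stenosis_center``."""
    spec.validate()
    if not (0.0 <= spec.stenosis_center <= spec.length):
        raise ValueError("stenosis window must lie within the tube")
    return _make_straight(spec, _radius_fn(spec))


def _make_straight(spec: TubeSpec, rfn):
    z = np.linspace(0.0, spec.length, spec.n_axial)
    theta = np.arange(spec.n_circ) * 2.0 * np.pi / spec.n_circ
    r = rfn(z)
    verts = np.empty((spec.n_axial * spec.n_circ, 3))
    for i in range(spec.n_axial):
        base = i * spec.n_circ
        verts[base : base + spec.n_circ, 0] = r[i] * np.cos(theta)
        verts[base : base + spec.n_circ, 1] = r[i] * np.sin(theta)
        verts[base : base + spec.n_circ, 2] = z[i]
    verts = _apply_jitter(verts, spec)
    tri = TriMesh(verts, _grid_faces(spec.n_axial, spec.n_circ))
    cl_z = np.linspace(0.0, spec.length, max(spec.n_axial, 61))
    cl = Centerline(np.column_stack([np.zeros_like(cl_z), np.zeros_like(cl_z), cl_z]))
    return tri, cl, TruthProfile(rfn)


def make_curved_tube(spec: TubeSpec):
    """Tube swept along a circular arc in the x-z plane.

    Cross-sections stay circular in the plane normal to the arc; arc length
    of the centerline equals ``spec.length``.
    """
    spec.validate()
    Rc = spec.curvature_radius
    if not np.isfinite(Rc):
        return make_tube(spec)
    if Rc <= spec.diameter / 2.0:
        raise ValueError("curvature radius too small: tube would self-intersect")
    rfn = _radius_fn(spec)
    z = np.linspace(0.0, spec.length, spec.n_axial)
    theta = np.arange(spec.n_circ) * 2.0 * np.pi / spec.n_circ
    r = rfn(z)
    # arc parameterised by arc length: center (Rc, 0, 0), start at origin
    phi = z / Rc
    centers = np.column_stack([Rc * (1 - np.cos(phi)), np.zeros_like(phi), Rc * np.sin(phi)])
    verts = np.empty((spec.n_axial * spec.n_circ, 3))
    for i in range(spec.n_axial):
        # local frame: in-plane normal u (reduces to +x at phi = 0), out-of-plane y
        u = np.array([np.cos(phi[i]), 0.0, -np.sin(phi[i])])
        e2 = np.array([0.0, 1.0, 0.0])
        ring = centers[i] + r[i] * (np.outer(np.cos(theta), u) + np.outer(np.sin(theta), e2))
        verts[i * spec.n_circ : (i + 1) * spec.n_circ] = ring
    verts = _apply_jitter(verts, spec)
    tri = TriMesh(verts, _grid_faces(spec.n_axial, spec.n_circ))
    ncl = max(4 * spec.n_axial, 121)
    phic = np.linspace(0.0, spec.length / Rc, ncl)
    cl = Centerline(
        np.column_stack([Rc * (1 - np.cos(phic)), np.zeros_like(phic), Rc * np.sin(phic)]),
        arc_length=Rc * phic,
    )
    return tri, cl, TruthProfile(rfn)


def _apply_jitter(verts, spec: TubeSpec):
    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        verts = verts + rng.normal(scale=spec.jitter, size=verts.shape)
    return verts
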