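"""Lumen-diameter profiles and agreement statistics.

The per-frame mean lumen diameter (MLD) is the area-equivalent diameter of
the lumen polygon cut by the plane normal to the centerline tangent:
MLD = 2 sqrt(A / pi).  Agreement between two MLD series is summarised by
Bland-Altman bias / 95% limits of agreement and by max|e|, RMSE and MARE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .centerline import Centerline
from .simplex import TriMesh

__all__ = [
    "MLDProfile",
    "AgreementReport",
    "slice_lumen_area",
    "mld_profile",
    "cross_section_diameters",
    "bland_altman",
    "error_stats",
    "agreement_report",
]


@dataclass
class MLDProfile:
    stations: np.ndarray  # arc-length positions, mm
    mld: np.ndarray  # per-frame mean lumen diameter, mm
    spacing: float

    def __post_init__(self):
        self.stations = np.asarray(self.stations, dtype=float)
        self.mld = np.asarray(self.mld, dtype=float)
        if np.any(np.diff(self.stations) <= 0):
            raise ValueError("stations must be strictly increasing")


@dataclass
class AgreementReport:
    bias: float
    loa_low: float
    loa_high: float
    max_abs_error: float
    rmse: float
    mare: float  # percent

    def as_dict(self) -> dict:
        return {
            "bias_mm": self.bias,
            "loa_low_mm": self.loa_low,
            "loa_high_mm": self.loa_high,
            "max_abs_error_mm": self.max_abs_error,
            "rmse_mm": self.rmse,
            "mare_percent": self.mare,
        }


def _chain_loops(segments):
    """Chain (key_a, key_b, pt_a, pt_b) segments into closed point loops."""
    adj: dict = {}
    pts: dict = {}
    for ka, kb, pa, pb in segments:
        pts[ka] = pa
        pts[kb] = pb
        adj.setdefault(ka, []).append(kb)
        adj.setdefault(kb, []).append(ka)
    visited = set()
    loops = []
    for start in adj:
        if start in visited or len(adj[start]) != 2:
            continue
        loop = [start]
        visited.add(start)
        prev, cur = start, adj[start][0]
        while cur != start:
            if cur in visited or len(adj.get(cur, [])) != 2:
                loop = None
                break
            loop.append(cur)
            visited.add(cur)
            nxt = adj[cur][0] if adj[cur][0] != prev else adj[cur][1]
            prev, cur = cur, nxt
        if loop is not None and len(loop) >= 3:
            loops.append(np.asarray([pts[k] for k in loop]))
    return loops


def slice_lumen_area(mesh: TriMesh, origin, normal, near=None):
    """Area of the closed lumen polygon cut by a plane.

    Returns ``(area, loop_points)`` for the intersection loop whose centroid
    is nearest ``near`` (default: the plane origin), or ``None`` if the slice
    yields no closed loop.
    """
    origin = np.asarray(origin, dtype=float)
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    V = mesh.vertices
    d = (V - origin) @ normal
    # nudge vertices lying exactly in the plane
    eps = 1e-9 * max(float(np.abs(d).max()), 1.0)
    d = np.where(np.abs(d) < eps, eps, d)

    F = mesh.faces
    df = d[F]
    crossing = ~(np.all(df > 0, axis=1) | np.all(df < 0, axis=1))
    segments = []
    for f in np.nonzero(crossing)[0]:
        ids = F[f]
        cuts = []
        for e in range(3):
            i, j = int(ids[e]), int(ids[(e + 1) % 3])
            if d[i] * d[j] < 0:
                t = d[i] / (d[i] - d[j])
                p = V[i] + t * (V[j] - V[i])
                key = (i, j) if i < j else (j, i)
                cuts.append((key, p))
        if len(cuts) == 2:
            segments.append((cuts[0][0], cuts[1][0], cuts[0][1], cuts[1][1]))
    loops = _chain_loops(segments)
    if not loops:
        return None
    ref = origin if near is None else np.asarray(near, dtype=float)
    loop = min(loops, key=lambda lp: np.linalg.norm(lp.mean(axis=0) - ref))
    # project onto an in-plane basis and apply the shoelace formula
    u = np.cross(normal, [1.0, 0.0, 0.0])
    if np.linalg.norm(u) < 1e-8:
        u = np.cross(normal, [0.0, 1.0, 0.0])
    u /= np.linalg.norm(u)
    w = np.cross(normal, u)
    x = (loop - origin) @ u
    y = (loop - origin) @ w
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return float(area), loop


def mld_profile(
    mesh: TriMesh,
    centerline: Centerline,
    spacing: float = 0.5,
    margin: float | None = None,
    s_range: tuple[float, float] | None = None,
) -> MLDProfile:
    """Frame-wise MLD along the centerline at the given station spacing.

    Stations whose slice produces no closed polygon are skipped with a
    warning.  ``margin`` trims that distance off both centerline ends
    (defaults to one spacing, keeping slices off the open tube rims);
    ``s_range`` restricts stations to an explicit arc-length interval.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if margin is None:
        margin = spacing
    if s_range is not None:
        s0, s1 = s_range
    else:
        s0, s1 = margin, centerline.length - margin
    if s1 <= s0:
        raise ValueError("centerline shorter than twice the margin")
    stations = np.arange(s0, s1 + 1e-9, spacing)
    out_s, out_d = [], []
    for s in stations:
        c = centerline.point_at(s)
        t = centerline.tangent_at(s)
        res = slice_lumen_area(mesh, c, t, near=c)
        if res is None:
            warnings.warn(f"no closed lumen polygon at station s={s:.3f} mm", stacklevel=2)
            continue
        area, _ = res
        out_s.append(float(s))
        out_d.append(2.0 * np.sqrt(area / np.pi))
    return MLDProfile(np.asarray(out_s), np.asarray(out_d), spacing)


def cross_section_diameters(mesh: TriMesh, centerline: Centerline, stations) -> np.ndarray:
    """MLD evaluated at explicit arc-length stations only."""
    stations = np.asarray(stations, dtype=float)
    if stations.size == 0:
        return np.zeros(0)
    if np.any(stations < 0) or np.any(stations > centerline.length):
        raise ValueError("station outside the centerline extent")
    out = []
    for s in stations:
        c = centerline.point_at(s)
        t = centerline.tangent_at(s)
        res = slice_lumen_area(mesh, c, t, near=c)
        if res is None:
            raise ValueError(f"no closed lumen polygon at station s={s:.3f} mm")
        out.append(2.0 * np.sqrt(res[0] / np.pi))
    return np.asarray(out)


def bland_altman(s, r):
    """(bias, loa_low, loa_high): mean difference and 95% limits of agreement."""
    s = np.asarray(s, dtype=float)
    r = np.asarray(r, dtype=float)
    if s.shape != r.shape:
        raise ValueError("series length mismatch")
    if s.size < 2:
        raise ValueError("need at least 2 paired values")
    diff = s - r
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def error_stats(s, r):
    """(max|e|, RMSE, MARE%) between paired series; MARE needs r != 0."""
    s = np.asarray(s, dtype=float)
    r = np.asarray(r, dtype=float)
    if s.shape != r.shape:
        raise ValueError("series length mismatch")
    if np.any(r == 0):
        raise ValueError("MARE undefined: reference series contains zeros")
    e = s - r
    max_abs = float(np.max(np.abs(e)))
    rmse = float(np.sqrt(np.mean(e**2)))
    mare = float(np.mean(np.abs(e / r)) * 100.0)
    return max_abs, rmse, mare


def agreement_report(s, r) -> AgreementReport:
    bias, lo, hi = bland_altman(s, r)
    mx, rmse, mare = error_stats(s, r)
    return AgreementReport(bias, lo, hi, mx, rmse, mare)
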