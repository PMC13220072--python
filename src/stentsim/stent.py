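"""Balloon-expandable stent: device parameters and the expansion force.

The device is treated as purely elastic and uniformly expanding.  Its
mechanics enter the simulation through three derived quantities:

* radial rigidity  k = 3 E I / L^3  with  I = pi D^4 / 64,
* radial force     F_RF = P_nom * D * L  (F_unit = P_nom * D),
* inflection scale delta = L / (2 pi t k r_crimp),  chi = T * delta.

Units are mm-N-MPa throughout; balloon pressures given in atm are converted
with 1 atm = 0.101325 MPa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .centerline import Centerline
from .simplex import SimplexMesh

__all__ = ["StentSpec", "build_stent_mesh", "internal_force", "ATM_TO_MPA"]

ATM_TO_MPA = 0.101325


@dataclass
class StentSpec:
    """Device geometry and material, plus all derived force parameters.

    Parameters
    ----------
    E : Young's modulus in MPa (233 GPa cobalt alloy = 233000.0).
    nu : Poisson ratio.
    r_crimp : crimped stent radius in mm.
    D : target fully-expanded diameter in mm.
    L : stent length in mm.
    t_strut : strut thickness in mm (also the contact threshold diameter).
    P_nom : nominal balloon pressure in MPa.
    T : expansion-threshold fraction; chi = T * delta must land in [0, 1).
    """

    E: float = 233000.0
    nu: float = 0.35
    r_crimp: float = 0.5
    D: float = 2.15
    L: float = 34.0
    t_strut: float = 0.08
    P_nom: float = 9 * ATM_TO_MPA
    T: float = 0.01

    def __post_init__(self):
        for name in ("E", "r_crimp", "D", "L", "t_strut"):
            if getattr(self, name) <= 0:
                raise ValueError(f"stent parameter {name!r} must be positive")
        if self.P_nom <= 0:
            raise ValueError("nominal pressure must be positive")
        if not (0.0 <= self.chi < 1.0):
            raise ValueError(
                f"chi = T*delta = {self.chi:.4g} outside [0, 1); lower the threshold T"
            )

    @classmethod
    def from_pressure_atm(cls, pressure_atm: float, **kw) -> "StentSpec":
        return cls(P_nom=pressure_atm * ATM_TO_MPA, **kw)

    # -- derived quantities ---------------------------------------------------

    @property
    def I(self) -> float:
        """Second moment of area, pi D^4 / 64 (mm^4)."""
        return np.pi * self.D**4 / 64.0

    @property
    def k(self) -> float:
        """Radial rigidity 3 E I / L^3 (N/mm)."""
        return 3.0 * self.E * self.I / self.L**3

    @property
    def F_unit(self) -> float:
        """Radial force per unit length, P_nom * D (N/mm)."""
        return self.P_nom * self.D

    @property
    def F_RF(self) -> float:
        """Total radial force, F_unit * L (N)."""
        return self.F_unit * self.L

    @property
    def delta(self) -> float:
        """Inflection position L / (2 pi t k r_crimp), evaluated in mm-N."""
        return self.L / (2.0 * np.pi * self.t_strut * self.k * self.r_crimp)

    @property
    def chi(self) -> float:
        """Dimensionless scaling factor T * delta."""
        return self.T * self.delta

    @property
    def equilibrium_diameter(self) -> float:
        """Fixed point of the expansion force: (1 - chi) * D."""
        return (1.0 - self.chi) * self.D

    def derived(self) -> dict:
        return {
            "I_mm4": self.I,
            "k_N_per_mm": self.k,
            "F_unit_N_per_mm": self.F_unit,
            "F_RF_N": self.F_RF,
            "delta": self.delta,
            "chi": self.chi,
            "equilibrium_diameter_mm": self.equilibrium_diameter,
        }


def internal_force(
    local_diameter: np.ndarray,
    normals: np.ndarray,
    spec: StentSpec,
    free: np.ndarray | None = None,
) -> np.ndarray:
    """Per-vertex expansion force.

    F_i = k/(F_RF * D) * ((1-chi) D - |dP_i|) * n_i, where |dP_i| is the
    local diameter (twice the radial distance to the stent centerline).
    Outward while under-expanded, inward past equilibrium, zero on
    constrained vertices.
    """
    local_diameter = np.asarray(local_diameter, dtype=float)
    coeff = spec.k / (spec.F_RF * spec.D)
    mag = coeff * (spec.equilibrium_diameter - local_diameter)
    F = mag[:, None] * normals
    if free is not None:
        F[~free] = 0.0
    return F


def build_stent_mesh(
    artery: SimplexMesh,
    centerline: Centerline,
    spec: StentSpec,
    s0: float | None = None,
):
    """Crimped stent mesh by inward projection of the artery mesh.

    Every artery vertex whose centerline station lies in ``[s0, s0 + L]`` is
    projected to radial distance ``r_crimp`` along its own inward radial
    direction; connectivity is inherited from the artery mesh.  Returns
    ``(stent: SimplexMesh, pairing: (m,) int array)`` where ``pairing[j]`` is
    the artery vertex index paired with stent vertex ``j``.

    Stent vertices whose artery counterpart is constrained, or whose
    neighbourhood is truncated by the segment boundary, are constrained.
    """
    if s0 is None:
        s0 = max(0.0, 0.5 * (centerline.length - spec.L))
    if spec.L > centerline.length + 1e-9:
        raise ValueError(
            f"stent length {spec.L} mm exceeds centerline length {centerline.length:.3f} mm"
        )
    if s0 < -1e-9 or s0 + spec.L > centerline.length + 1e-9:
        raise ValueError("stented segment outside the centerline extent")

    s, rdir, dist = centerline.project(artery.vertices)
    inside = (s >= s0 - 1e-9) & (s <= s0 + spec.L + 1e-9)
    pairing = np.nonzero(inside)[0]
    if pairing.size == 0:
        raise ValueError("no artery vertices in the stented segment")
    if np.any(dist[pairing] <= spec.r_crimp):
        import warnings

        warnings.warn(
            "crimped stent radius meets or exceeds the local lumen radius: "
            "pre-loaded contact at initiation",
            stacklevel=2,
        )

    base = artery.vertices[pairing] - dist[pairing, None] * rdir[pairing]
    stent_verts = base + spec.r_crimp * rdir[pairing]

    remap = -np.ones(artery.n_vertices, dtype=np.int64)
    remap[pairing] = np.arange(pairing.size)
    nbrs = artery.neighbors[pairing].copy()
    valid = nbrs >= 0
    nbrs[valid] = remap[nbrs[valid]]  # neighbours outside the segment become -1
    constrained = artery.constrained[pairing] | np.any(nbrs < 0, axis=1)

    faces = []
    for poly in artery.faces:
        mapped = [int(remap[v]) for v in poly]
        if all(m >= 0 for m in mapped):
            faces.append(mapped)

    stent = SimplexMesh(
        vertices=stent_verts,
        neighbors=nbrs,
        constrained=constrained,
        source_face=artery.source_face[pairing],
        faces=faces,
        normal_sign=artery.normal_sign[pairing].copy(),
    )
    return stent, pairing
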