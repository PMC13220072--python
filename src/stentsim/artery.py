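"""Arterial wall response: hyperelastic stress, contact, resistance force.

The wall follows a sixth-order reduced-polynomial strain-energy function
W = sum_i C_i0 (I1 - 3)^i.  Converted to a circumferential Cauchy stress
under incompressible uniaxial kinematics (I1 = lambda^2 + 2/lambda):

    sigma(lambda) = 2 (lambda^2 - 1/lambda) * sum_i i C_i0 (I1 - 3)^(i-1)

The resistance reference stress is sigma(lambda = 1.4), i.e. a 40%%
circumferential over-stretch.  The wall only acts on stent vertices that
have made contact; contact is declared when a stent vertex comes within one
strut diameter of its paired wall vertex, and the flag is sticky.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .simplex import SimplexMesh

__all__ = [
    "ArteryMaterial",
    "ContactState",
    "cauchy_stress",
    "resistance_stress",
    "detect_contact",
    "external_force",
    "TABLE1_COEFFS",
]

# normal-wall reduced-polynomial coefficients, MPa
TABLE1_COEFFS = (6.52e-3, 4.89e-2, 9.26e-3, 7.60e-1, -4.30e-1, 8.69e-2)


def cauchy_stress(lam, coeffs=TABLE1_COEFFS):
    """Circumferential Cauchy stress (MPa) at stretch ``lam`` >= 1."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 1.0):
        raise ValueError("stretch < 1: compressive regime out of scope")
    I1 = lam**2 + 2.0 / lam
    x = I1 - 3.0
    dW = np.zeros_like(lam)
    for i, c in enumerate(coeffs, start=1):
        dW += i * c * x ** (i - 1)
    return 2.0 * (lam**2 - 1.0 / lam) * dW


def resistance_stress(coeffs=TABLE1_COEFFS, lambda_res: float = 1.4) -> float:
    """Reference wall stress at the resistance stretch (default 1.4)."""
    return float(cauchy_stress(lambda_res, coeffs))


@dataclass
class ArteryMaterial:
    """Reduced-polynomial wall with cached resistance stress."""

    coeffs: tuple = TABLE1_COEFFS
    lambda_res: float = 1.4
    nu: float = 0.35
    sigma_res: float = field(init=False)

    def __post_init__(self):
        if len(self.coeffs) != 6:
            raise ValueError("expected six coefficients C10..C60")
        self.sigma_res = resistance_stress(self.coeffs, self.lambda_res)
        if self.sigma_res <= 0:
            raise ValueError("resistance stress must be positive")

    def stress(self, lam):
        return cauchy_stress(lam, self.coeffs)


@dataclass
class ContactState:
    """Sticky per-stent-vertex contact bookkeeping."""

    flags: np.ndarray  # (m,) bool
    distance: np.ndarray  # (m,) float, mm
    pairing: np.ndarray  # (m,) int, artery vertex per stent vertex
    first_step: np.ndarray  # (m,) int, -1 until first contact

    @classmethod
    def initial(cls, pairing: np.ndarray) -> "ContactState":
        m = len(pairing)
        return cls(
            flags=np.zeros(m, dtype=bool),
            distance=np.full(m, np.inf),
            pairing=np.asarray(pairing, dtype=np.int64),
            first_step=-np.ones(m, dtype=np.int64),
        )

    @property
    def n_contacts(self) -> int:
        return int(self.flags.sum())


def detect_contact(
    stent_positions: np.ndarray,
    artery_positions: np.ndarray,
    state: ContactState,
    d_strut: float,
    step: int = 0,
) -> ContactState:
    """Flag stent vertices within one strut diameter of their wall vertex.

    Flags are sticky: once a vertex is in contact it stays in contact
    (prevents chatter at the threshold).  Mutates and returns ``state``.
    """
    d = np.linalg.norm(stent_positions - artery_positions[state.pairing], axis=1)
    state.distance = d
    new = (~state.flags) & (d < d_strut)
    state.first_step[new] = step
    state.flags |= new
    return state


def external_force(
    positions: np.ndarray,
    mesh: SimplexMesh,
    material: ArteryMaterial,
    contacts: ContactState,
    stretch: np.ndarray,
    normals: np.ndarray | None = None,
) -> np.ndarray:
    """Inward wall-resistance force on contacting stent vertices.

    F_i = nu * sigma(lam_i) / (2 sigma_res) * |(N2-N1) x (N3-N1)| * (-n_i)
    with n_i the outward unit normal; zero wherever no contact has occurred.
    Stretches below 1 are clamped to a stress-free wall (with a warning).
    """
    F = np.zeros_like(positions)
    idx = np.nonzero(contacts.flags & mesh.free)[0]
    if idx.size == 0:
        return F
    lam = np.asarray(stretch, dtype=float)[idx]
    if np.any(lam < 1.0):
        warnings.warn("stretch < 1 at a contact vertex; treating wall as stress-free", stacklevel=2)
    sigma = np.zeros(idx.size)
    ok = lam >= 1.0
    sigma[ok] = material.stress(lam[ok])
    nb = mesh.neighbors[idx]
    a, b, c = positions[nb[:, 0]], positions[nb[:, 1]], positions[nb[:, 2]]
    cross = np.cross(b - a, c - a)
    area2 = np.linalg.norm(cross, axis=1)
    if normals is None:
        normals = mesh.normals(positions)
    mag = material.nu * sigma / (2.0 * material.sigma_res) * area2
    F[idx] = -mag[:, None] * normals[idx]
    return F
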