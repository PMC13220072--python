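"""Damped explicit vertex dynamics.

Positions advance by a centered-difference update

    P(t+1) = P(t) + (1 - gamma) (P(t) - P(t-1)) + alpha F_int + beta F_ext

with the expansion force always on and the wall resistance gated by
contact.  Convergence is displacement-based: the run stops once the maximum
per-vertex displacement stays below ``tol_disp`` for ``window`` consecutive
steps.  The solver contains no randomness: identical inputs give
bit-identical histories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .artery import ArteryMaterial, ContactState, detect_contact, external_force
from .centerline import Centerline
from .simplex import SimplexMesh
from .stent import StentSpec, internal_force

__all__ = ["DynamicsConfig", "SimState", "History", "step", "run", "DivergenceError"]


class DivergenceError(RuntimeError):
    pass


@dataclass
class DynamicsConfig:
    """Integrator knobs; the displacement scale of the forces is absorbed
    into the weights alpha / beta."""

    gamma: float = 0.65
    alpha: float = 0.1
    beta: float = 0.1
    max_steps: int = 5000
    tol_disp: float = 1e-4
    window: int = 10
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("gamma must be in (0, 1]")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("force weights must be positive")
        if self.tol_disp <= 0:
            raise ValueError("tol_disp must be positive")


@dataclass
class SimState:
    """Mutable solver state for one mesh."""

    P: np.ndarray
    P_prev: np.ndarray
    step: int = 0

    @classmethod
    def from_mesh(cls, mesh: SimplexMesh) -> "SimState":
        return cls(P=mesh.vertices.copy(), P_prev=mesh.vertices.copy())


@dataclass
class History:
    """Per-step force totals (sums of nodal magnitudes) and contact counts."""

    F_int_total: list = field(default_factory=list)
    F_ext_total: list = field(default_factory=list)
    n_contacts: list = field(default_factory=list)
    max_disp: list = field(default_factory=list)
    first_contact_step: int = -1
    converged: bool = False
    steps: int = 0

    def as_columns(self) -> dict:
        return {
            "step": list(range(len(self.F_int_total))),
            "F_int_total": self.F_int_total,
            "F_ext_total": self.F_ext_total,
            "n_contacts": self.n_contacts,
            "max_disp": self.max_disp,
        }


def step(state: SimState, F_int, F_ext, free, config: DynamicsConfig) -> float:
    """One centered-difference update; returns the max free-vertex displacement."""
    P, P_prev = state.P, state.P_prev
    new = P + (1.0 - config.gamma) * (P - P_prev) + config.alpha * F_int + config.beta * F_ext
    new[~free] = P[~free]
    if not np.all(np.isfinite(new)):
        bad = int(np.nonzero(~np.isfinite(new).all(axis=1))[0][0])
        raise DivergenceError(f"non-finite position at step {state.step + 1}, vertex {bad}")
    disp = float(np.max(np.linalg.norm(new - P, axis=1))) if len(P) else 0.0
    state.P_prev = P
    state.P = new
    state.step += 1
    return disp


def run(
    stent: SimplexMesh,
    spec: StentSpec,
    centerline: Centerline,
    config: DynamicsConfig | None = None,
    artery: SimplexMesh | None = None,
    pairing: np.ndarray | None = None,
    material: ArteryMaterial | None = None,
):
    """Deploy the stent; returns ``(stent_pos, artery_pos, history, contacts)``.

    With ``artery=None`` the stent expands freely (no contact, no wall
    resistance).  Otherwise each contacting wall vertex is kinematically
    slaved to its stent vertex: it keeps the radial offset recorded at first
    contact and is only ever pushed outward.
    """
    config = config or DynamicsConfig()
    state = SimState.from_mesh(stent)
    free = stent.free
    hist = History()

    coupled = artery is not None
    if coupled:
        if pairing is None or material is None:
            raise ValueError("artery runs need a pairing and a wall material")
        contacts = ContactState.initial(pairing)
        artery_pos = artery.vertices.copy()
        sA, rdirA, distA0 = centerline.project(artery.vertices)
        distA = distA0.copy()
        baseA = artery.vertices - distA0[:, None] * rdirA
        offset = np.zeros(len(pairing))
    else:
        contacts = ContactState.initial(np.zeros(0, dtype=np.int64))
        artery_pos = None

    # stent vertices move radially; their centerline foot stays put
    _, rdirS, distS0 = centerline.project(stent.vertices)
    baseS = stent.vertices - distS0[:, None] * rdirS

    below = 0
    for _ in range(config.max_steps):
        v = state.P - baseS
        radial = np.einsum("ij,ij->i", v, rdirS)
        local_diam = 2.0 * np.abs(radial)

        normals = stent.normals(state.P)
        F_int = internal_force(local_diam, normals, spec, free=free)

        if coupled:
            detect_contact(state.P, artery_pos, contacts, spec.t_strut, step=state.step)
            newly = contacts.first_step == state.step
            offset[newly] = distA[pairing[newly]] - radial[newly]
            if hist.first_contact_step < 0 and contacts.n_contacts > 0:
                hist.first_contact_step = state.step
            pa = pairing
            lam = np.where(distA0[pa] > 0, distA[pa] / distA0[pa], 1.0)
            F_ext = external_force(state.P, stent, material, contacts, lam, normals=normals)
        else:
            F_ext = np.zeros_like(state.P)

        hist.F_int_total.append(float(np.linalg.norm(F_int, axis=1).sum()))
        hist.F_ext_total.append(float(np.linalg.norm(F_ext, axis=1).sum()))
        hist.n_contacts.append(contacts.n_contacts)

        disp = step(state, F_int, F_ext, free, config)
        hist.max_disp.append(disp)

        if coupled:
            # slave contacting wall vertices: radial push with frozen offset
            v = state.P - baseS
            radial = np.einsum("ij,ij->i", v, rdirS)
            idx = np.nonzero(contacts.flags)[0]
            if idx.size:
                pa = pairing[idx]
                target = radial[idx] + offset[idx]
                pushed = np.maximum(distA[pa], target)
                distA[pa] = pushed
                artery_pos[pa] = baseA[pa] + pushed[:, None] * rdirA[pa]

        below = below + 1 if disp < config.tol_disp else 0
        if below >= config.window:
            hist.converged = True
            break

    hist.steps = state.step
    return state.P, artery_pos, hist, contacts
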