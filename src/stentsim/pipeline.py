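"""End-to-end deployment pipeline: pre-process, solve, post-process."""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .artery import ArteryMaterial
from .centerline import Centerline
from .dynamics import DynamicsConfig, History, run
from .metrics import MLDProfile, mld_profile
from .simplex import SimplexMesh, TriMesh, triangulation_to_simplex
from .stent import StentSpec, build_stent_mesh

__all__ = ["DeploymentResult", "ensure_outward", "deploy"]


def ensure_outward(tri: TriMesh, centerline: Centerline) -> TriMesh:
    """Flip the whole triangulation if its normals face the centerline.

    Assumes consistent winding (checked by ``TriMesh.validate``); the luminal
    convention is normals pointing away from the vessel axis.
    """
    cent = tri.face_centroids()
    _, rdir, _ = centerline.project(cent)
    dots = np.einsum("ij,ij->i", tri.face_normals(), rdir)
    if np.median(dots) < 0:
        return TriMesh(tri.vertices, tri.faces[:, [0, 2, 1]])
    return tri


@dataclass
class DeploymentResult:
    converged: bool
    steps: int
    first_contact_step: int
    history: History
    stent_mesh: SimplexMesh
    stent_positions: np.ndarray
    artery_mesh: SimplexMesh
    artery_positions: np.ndarray
    pre_profile: MLDProfile
    post_profile: MLDProfile  # lumen of the deployed stent
    post_artery_profile: MLDProfile | None
    derived: dict
    timings: dict = field(default_factory=dict)
    segment: tuple[float, float] = (0.0, 0.0)

    def report(self) -> dict:
        return {
            "units": "mm",
            "converged": self.converged,
            "steps": self.steps,
            "first_contact_step": self.first_contact_step,
            "stented_segment_mm": list(self.segment),
            "derived": self.derived,
            "pre_mld": {
                "s_mm": self.pre_profile.stations.tolist(),
                "mld_mm": self.pre_profile.mld.tolist(),
            },
            "post_mld": {
                "s_mm": self.post_profile.stations.tolist(),
                "mld_mm": self.post_profile.mld.tolist(),
            },
            "timings_s": self.timings,
        }


def deploy(
    tri: TriMesh,
    centerline: Centerline,
    spec: StentSpec,
    material: ArteryMaterial,
    dynamics: DynamicsConfig | None = None,
    s0: float | None = None,
    mld_spacing: float = 0.5,
) -> DeploymentResult:
    """Run the full workflow on a triangulated luminal surface."""
    timings = {}
    t0 = time.perf_counter()

    tri.validate()
    tri = ensure_outward(tri, centerline)
    artery = triangulation_to_simplex(tri)
    stent, pairing = build_stent_mesh(artery, centerline, spec, s0=s0)
    if s0 is None:
        s0 = max(0.0, 0.5 * (centerline.length - spec.L))
    timings["pre_process"] = time.perf_counter() - t0

    t1 = time.perf_counter()
    stent_pos, artery_pos, hist, contacts = run(
        stent, spec, centerline, dynamics, artery=artery, pairing=pairing, material=material
    )
    timings["main_process"] = time.perf_counter() - t1

    t2 = time.perf_counter()
    pre = mld_profile(tri, centerline, spacing=mld_spacing)
    seg = (s0 + 2 * mld_spacing, s0 + spec.L - 2 * mld_spacing)
    post = mld_profile(
        stent.to_trimesh(stent_pos), centerline, spacing=mld_spacing, s_range=seg
    )
    try:
        post_artery = mld_profile(
            artery.to_trimesh(artery_pos), centerline, spacing=mld_spacing
        )
    except ValueError:
        post_artery = None
    timings["post_process"] = time.perf_counter() - t2

    return DeploymentResult(
        converged=hist.converged,
        steps=hist.steps,
        first_contact_step=hist.first_contact_step,
        history=hist,
        stent_mesh=stent,
        stent_positions=stent_pos,
        artery_mesh=artery,
        artery_positions=artery_pos,
        pre_profile=pre,
        post_profile=post,
        post_artery_profile=post_artery,
        derived=spec.derived(),
        timings=timings,
        segment=(s0, s0 + spec.L),
    )
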