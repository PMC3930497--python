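"""Collision detection among capsules, the anchoring plane and the bead.

Overlaps produce temporary contact joints: a single unilateral constraint
row (lambda >= 0, restitution 0, no friction) at the midpoint of closest
approach, with the normal directed from body 2 to body 1 and an
(erp/dt) * depth stabilization term pushing the bodies apart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from .constraint_dynamics import ANCHOR
from .model_state import ChainState

__all__ = ["ContactJoint", "broad_phase", "capsule_capsule_contact",
           "capsule_plane_contact", "capsule_sphere_contact", "contact_rows",
           "detect_all_contacts", "exclusion_window"]


def exclusion_window(state: ChainState) -> int:
    """Chain-neighbour exclusion |i-j| <= n_ex for self-collision.

    Pairs closer than this along the chain overlap permanently in a
    straight configuration (capsule cap reach 2r vs endpoint gap
    (|i-j|-1) b); steric protection at those separations is carried by the
    bending rigidity instead.
    """
    n = state.n_cyl
    b = 2.0 * float(np.max(state.half_length[:n]))
    r = float(np.max(state.radius[:n]))
    return int(np.floor(2.0 * r / b)) + 1


@dataclass(frozen=True)
class ContactJoint:
    """One detected overlap: contact point, unit normal (2 -> 1), depth."""

    body_1: int
    body_2: int  # ANCHOR (-1) for the static plane
    contact_point: np.ndarray
    normal: np.ndarray
    depth: float

    def __post_init__(self):
        object.__setattr__(self, "contact_point",
                           np.asarray(self.contact_point, float))
        object.__setattr__(self, "normal", np.asarray(self.normal, float))


def broad_phase(state: ChainState, cutoff: Optional[float] = None
                ) -> list[tuple[int, int]]:
    """Candidate cylinder pairs from a uniform spatial hash grid.

    Superset of all pairs within ``cutoff`` (default: largest contact reach
    b + 2r); chain-adjacent pairs are excluded.  Permanently attached pairs
    (first cylinder / plane, last cylinder / bead) are excluded in
    :func:`detect_all_contacts`.
    """
    n = state.n_cyl
    reach = 2.0 * float(np.max(state.half_length[:n] + state.radius[:n]))
    cell = max(cutoff if cutoff is not None else reach, reach)
    buf = np.empty((n * 64 + 64, 2), dtype=np.int64)
    npair = _kernels.broad_phase_pairs(state.pos[:n], n, cell,
                                       exclusion_window(state), buf)
    out = []
    for i in range(npair):
        a, b = int(buf[i, 0]), int(buf[i, 1])
        if np.linalg.norm(state.pos[a] - state.pos[b]) < cell:
            out.append((a, b))
    return out


def capsule_capsule_contact(state: ChainState, i: int, j: int
                            ) -> Optional[ContactJoint]:
    """Contact between capsules i and j, or None if separated."""
    R = state.frames()
    d0 = np.linalg.norm(state.pos[i] - state.pos[j])
    hit, pt, nrm, dep = _kernels.capsule_capsule(
        state.pos[i], np.ascontiguousarray(R[i][:, 2]), state.half_length[i],
        state.radius[i],
        state.pos[j], np.ascontiguousarray(R[j][:, 2]), state.half_length[j],
        state.radius[j])
    if not hit:
        return None
    if d0 < 1e-12:
        warnings.warn("coincident capsule axes: fallback contact normal",
                      stacklevel=2)
    return ContactJoint(i, j, pt, nrm, float(dep))


def capsule_plane_contact(state: ChainState, i: int) -> Optional[ContactJoint]:
    """Contact of capsule i with the anchoring plane z = 0 (normal +z)."""
    R = state.frames()
    hit, pt, nrm, dep = _kernels.capsule_plane(
        state.pos[i], np.ascontiguousarray(R[i][:, 2]), state.half_length[i],
        state.radius[i])
    return ContactJoint(i, ANCHOR, pt, nrm, float(dep)) if hit else None


def capsule_sphere_contact(state: ChainState, i: int, bead_index: int
                           ) -> Optional[ContactJoint]:
    """Contact of capsule i with the bead sphere."""
    R = state.frames()
    hit, pt, nrm, dep = _kernels.capsule_sphere(
        state.pos[i], np.ascontiguousarray(R[i][:, 2]), state.half_length[i],
        state.radius[i], state.pos[bead_index], state.radius[bead_index])
    return ContactJoint(i, bead_index, pt, nrm, float(dep)) if hit else None


def detect_all_contacts(state: ChainState, plane: bool = True
                        ) -> list[ContactJoint]:
    """All scene contacts with the standard exclusions applied."""
    n = state.n_cyl
    nb = state.n_bodies
    R = state.frames()
    reach = 2.0 * float(np.max(state.half_length[:n] + state.radius[:n]))
    max_con = 8 * nb + 8
    pairs_buf = np.empty((nb * 64 + 64, 2), dtype=np.int64)
    b1 = np.empty(max_con, np.int64)
    b2 = np.empty(max_con, np.int64)
    pt = np.empty((max_con, 3))
    nrm = np.empty((max_con, 3))
    dep = np.empty(max_con)
    nc = _kernels.detect_contacts(state.pos, R, state.radius,
                                  state.half_length, n, state.has_bead,
                                  plane, reach, exclusion_window(state),
                                  pairs_buf, b1, b2, pt, nrm, dep, max_con)
    return [ContactJoint(int(b1[k]), int(b2[k]), pt[k].copy(), nrm[k].copy(),
                         float(dep[k])) for k in range(nc)]


def contact_rows(contacts: Sequence[ContactJoint], state: ChainState,
                 erp: float, dt: float):
    """Constraint rows for the contacts: (J, C, lo) with C = -depth.

    The solver rhs then contains +(erp/dt^2)*depth, i.e. a velocity target
    of (erp/dt)*depth along the normal, pushing the bodies apart; the row
    bound lo = 0 makes the joint push-only.
    """
    from .constraint_dynamics import assemble_jacobian

    J = assemble_jacobian(state, [], contacts)
    C = -np.array([c.depth for c in contacts])
    lo = np.zeros(len(contacts))
    return J, C, lo
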