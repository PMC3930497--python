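"""Velocity-level constrained dynamics: system assembly and solvers.

Each timestep the Lagrange multipliers lambda solve

    A lambda = rhs,   A = J W^-1 J^T + diag(cfm)/dt

with rhs = kvel/dt - (erp/dt^2) C - (1/dt) J (u + dt W^-1 F_ext), so that
the post-step generalized velocity u' = u + dt W^-1 (F_ext + J^T lambda)
satisfies J u' = kvel - (erp/dt) C - cfm lambda.  lambda carries force
units and the constraint force is F_c = J^T lambda.

Three solvers are available: an O(N) banded direct solve exploiting the
block-tridiagonal structure of a serial chain (exact), projected SOR for
systems with unilateral contact rows, and an active-set direct solver for
the mixed complementarity problem (always converges for SPD A).  The
dispatcher routes between them exactly as the simulation loop does.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from .model_state import ChainState, InvalidParameterError

ANCHOR = -1  # sentinel body index for the static world

UNBOUNDED = -1.0e300


class StructuralError(ValueError):
    """Inconsistent joint/contact structure."""


class NumericalError(RuntimeError):
    """Solver-level numerical failure (e.g. non-SPD matrix)."""


@dataclass(frozen=True)
class BallSocketJoint:
    """Ball-and-socket joint between ``body_a`` and ``body_b``.

    Anchors are attachment points in each body's frame; if a body index is
    ``ANCHOR`` (-1) the corresponding anchor is a fixed world point.
    """

    body_a: int
    body_b: int
    anchor_a: np.ndarray
    anchor_b: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "anchor_a", np.asarray(self.anchor_a, float))
        object.__setattr__(self, "anchor_b", np.asarray(self.anchor_b, float))


def chain_ball_joints(state: ChainState, anchored: bool = False
                      ) -> list[BallSocketJoint]:
    """Ball joints at the shared endpoints of consecutive cylinders.

    With ``anchored`` an extra joint pins the minus-end of the first
    cylinder to its current world position.
    """
    joints = []
    hl = state.half_length
    if anchored:
        R0 = state.frames()[0]
        world_pt = state.pos[0] - hl[0] * R0[:, 2]
        joints.append(BallSocketJoint(0, ANCHOR, np.array([0.0, 0.0, -hl[0]]),
                                      world_pt))
    for i in range(state.n_cyl - 1):
        joints.append(BallSocketJoint(
            i + 1, i, np.array([0.0, 0.0, -hl[i + 1]]),
            np.array([0.0, 0.0, hl[i]])))
    return joints


# ---------------------------------------------------------------------------
# kernel-facing joint container (includes welds and bead clamps)
# ---------------------------------------------------------------------------

KIND_BALL = 0
KIND_WELD = 1
KIND_CLAMP_TURN = 2
KIND_CLAMP_XY = 3
_ROWS = {KIND_BALL: 3, KIND_WELD: 6, KIND_CLAMP_TURN: 3, KIND_CLAMP_XY: 2}


@dataclass
class JointSet:
    """Flat arrays describing the permanent joints, in path order."""

    kind: np.ndarray
    body_a: np.ndarray
    body_b: np.ndarray
    anchor_a: np.ndarray
    anchor_b: np.ndarray
    q0: np.ndarray

    @classmethod
    def empty(cls) -> "JointSet":
        return cls(kind=np.zeros(0, np.int64), body_a=np.zeros(0, np.int64),
                   body_b=np.zeros(0, np.int64), anchor_a=np.zeros((0, 3)),
                   anchor_b=np.zeros((0, 3)), q0=np.zeros((0, 4)))

    @property
    def n_rows(self) -> int:
        return int(sum(_ROWS[int(k)] for k in self.kind))

    def append(self, kind, body_a, body_b, anchor_a, anchor_b, q0=None):
        self.kind = np.append(self.kind, np.int64(kind))
        self.body_a = np.append(self.body_a, np.int64(body_a))
        self.body_b = np.append(self.body_b, np.int64(body_b))
        self.anchor_a = np.vstack([self.anchor_a, np.asarray(anchor_a, float)])
        self.anchor_b = np.vstack([self.anchor_b, np.asarray(anchor_b, float)])
        q0 = np.array([1.0, 0.0, 0.0, 0.0]) if q0 is None else np.asarray(q0)
        self.q0 = np.vstack([self.q0, q0])

    @classmethod
    def serial_chain(cls, state: ChainState, anchor: Optional[str] = None,
                     bead_attach_world: Optional[np.ndarray] = None,
                     clamp: Optional[str] = None) -> "JointSet":
        """Joints of the standard rig, in path order along the chain.

        ``anchor``: None | 'ball' | 'weld' (first cylinder to the world);
        ``bead_attach_world``: world attachment point welding the bead to
        the last cylinder (requires ``state.has_bead``);
        ``clamp``: None | 'turn' | 'xy' (bead orientation clamp rows).
        All joints are constructed exactly satisfied for the given state.
        """
        js = cls.empty()
        R = state.frames()
        hl = state.half_length
        if anchor is not None:
            world_pt = state.pos[0] - hl[0] * R[0][:, 2]
            kind = KIND_WELD if anchor == "weld" else KIND_BALL
            js.append(kind, 0, ANCHOR, np.array([0.0, 0.0, -hl[0]]), world_pt,
                      q0=state.quat[0].copy())
        for i in range(state.n_cyl - 1):
            js.append(KIND_BALL, i + 1, i, np.array([0.0, 0.0, -hl[i + 1]]),
                      np.array([0.0, 0.0, hl[i]]))
        if bead_attach_world is not None:
            if not state.has_bead:
                raise StructuralError("bead weld requested without a bead")
            ib = state.n_cyl
            p = np.asarray(bead_attach_world, float)
            anc_a = R[ib].T @ (p - state.pos[ib])
            anc_b = R[ib - 1].T @ (p - state.pos[ib - 1])
            q0 = _kernels.quat_mul(_kernels.quat_conj(state.quat[ib - 1]),
                                   state.quat[ib])
            js.append(KIND_WELD, ib, ib - 1, anc_a, anc_b, q0=q0)
        if clamp is not None:
            if not state.has_bead:
                raise StructuralError("bead clamp requested without a bead")
            ib = state.n_cyl
            kind = KIND_CLAMP_TURN if clamp == "turn" else KIND_CLAMP_XY
            js.append(kind, ib, ANCHOR, np.zeros(3), np.zeros(3),
                      q0=state.quat[ib].copy())
        return js

    def build_rows(self, state: ChainState, psi: float = 0.0,
                   omega_clamp: float = 0.0):
        """Evaluate all permanent rows for the current state.

        Returns (body_a, body_b, JA, JB, C, kvel, lo) row arrays.
        """
        m = self.n_rows
        rbA = np.empty(m, np.int64)
        rbB = np.empty(m, np.int64)
        JA = np.zeros((m, 6))
        JB = np.zeros((m, 6))
        C = np.zeros(m)
        kvel = np.zeros(m)
        lo = np.zeros(m)
        R = state.frames()
        _kernels.build_joint_rows(state.pos, state.quat, R, self.kind,
                                  self.body_a, self.body_b, self.anchor_a,
                                  self.anchor_b, self.q0, psi, omega_clamp,
                                  rbA, rbB, JA, JB, C, kvel, lo)
        return rbA, rbB, JA, JB, C, kvel, lo


# ---------------------------------------------------------------------------
# dense (test/analysis-grade) API
# ---------------------------------------------------------------------------


def evaluate_constraints(state: ChainState,
                         joints: Sequence[BallSocketJoint]) -> np.ndarray:
    """Stacked joint-bearing separations, 3 components per ball joint.

    Sign convention: world position of anchor_a minus anchor_b.
    """
    R = state.frames()
    out = np.empty(3 * len(joints))
    for k, j in enumerate(joints):
        if j.body_a == ANCHOR:
            pa = j.anchor_a
        else:
            pa = state.pos[j.body_a] + R[j.body_a] @ j.anchor_a
        if j.body_b == ANCHOR:
            pb = j.anchor_b
        else:
            pb = state.pos[j.body_b] + R[j.body_b] @ j.anchor_b
        out[3 * k:3 * k + 3] = pa - pb
    return out


def _skew(v):
    return np.array([[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]],
                     [-v[1], v[0], 0.0]])


def assemble_jacobian(state: ChainState, joints: Sequence[BallSocketJoint],
                      contacts: Sequence = ()) -> np.ndarray:
    """Dense Jacobian J with dC/dt = J u (columns body-major v, omega)."""
    n6 = 6 * state.n_bodies
    R = state.frames()
    rows = []
    for j in joints:
        if not (-1 <= j.body_a < state.n_bodies
                and -1 <= j.body_b < state.n_bodies):
            raise StructuralError("joint body index out of range")
        block = np.zeros((3, n6))
        if j.body_a != ANCHOR:
            la = R[j.body_a] @ j.anchor_a
            block[:, 6 * j.body_a:6 * j.body_a + 3] = np.eye(3)
            block[:, 6 * j.body_a + 3:6 * j.body_a + 6] = -_skew(la)
        if j.body_b != ANCHOR:
            lb = R[j.body_b] @ j.anchor_b
            block[:, 6 * j.body_b:6 * j.body_b + 3] = -np.eye(3)
            block[:, 6 * j.body_b + 3:6 * j.body_b + 6] = _skew(lb)
        rows.append(block)
    for c in contacts:
        row = np.zeros((1, n6))
        n = c.normal
        r1 = c.contact_point - state.pos[c.body_1]
        row[0, 6 * c.body_1:6 * c.body_1 + 3] = n
        row[0, 6 * c.body_1 + 3:6 * c.body_1 + 6] = np.cross(r1, n)
        if c.body_2 != ANCHOR:
            r2 = c.contact_point - state.pos[c.body_2]
            row[0, 6 * c.body_2:6 * c.body_2 + 3] = -n
            row[0, 6 * c.body_2 + 3:6 * c.body_2 + 6] = -np.cross(r2, n)
        rows.append(row)
    if not rows:
        return np.zeros((0, n6))
    return np.vstack(rows)


def build_system(J: np.ndarray, W: np.ndarray, F_ext: np.ndarray,
                 u: np.ndarray, dt: float, erp: float, cfm,
                 C: np.ndarray, kvel: Optional[np.ndarray] = None,
                 lo: Optional[np.ndarray] = None):
    """Assemble (A, rhs, lo) for A lambda = rhs (force-unit multipliers)."""
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    if not (0.0 <= erp <= 1.0):
        raise InvalidParameterError("erp must be in [0, 1]")
    cfm = np.asarray(cfm, float) * np.ones(J.shape[0])
    if np.any(cfm < 0):
        raise InvalidParameterError("cfm must be >= 0")
    Winv = np.linalg.inv(W)
    A = J @ Winv @ J.T + np.diag(cfm) / dt
    kvel = np.zeros(J.shape[0]) if kvel is None else kvel
    rhs = kvel / dt - erp * C / dt ** 2 - J @ (u / dt + Winv @ F_ext)
    lo = np.full(J.shape[0], UNBOUNDED) if lo is None else lo
    return A, rhs, lo


def _bandwidth(A, tol=0.0):
    m = A.shape[0]
    hb = 0
    for i in range(m):
        nz = np.nonzero(np.abs(A[i]) > tol)[0]
        if nz.size:
            hb = max(hb, int(max(i - nz[0], nz[-1] - i)))
    return hb


def solve_chain_exact(A: np.ndarray, rhs: np.ndarray,
                      lo: Optional[np.ndarray] = None) -> np.ndarray:
    """O(N) banded Cholesky solve of the serial-chain system.

    For a serial anchored chain with ball joints only, A is block
    tridiagonal with 3x3 blocks, i.e. banded; this solves it by forward
    elimination and back substitution in the band.  Calling it with contact
    (bounded) rows present is a contract violation.
    """
    if lo is not None and np.any(np.asarray(lo) > UNBOUNDED / 2):
        raise StructuralError("exact chain solver cannot handle contact rows")
    A = np.asarray(A, float)
    m = A.shape[0]
    if m == 0:
        return np.zeros(0)
    hb = _bandwidth(A)
    ab = np.zeros((hb + 1, m))
    for d in range(hb + 1):
        ab[d, :m - d] = np.diagonal(A, -d)
    lam = np.zeros(m)
    ok = _kernels.band_cholesky_solve(ab, hb, m, np.asarray(rhs, float).copy(),
                                      lam)
    if not ok:
        raise NumericalError("banded Cholesky failed: A not positive definite")
    return lam


def solve_sor(A: np.ndarray, rhs: np.ndarray, lo: Optional[np.ndarray] = None,
              omega: float = 1.3, n_iter: int = 60) -> np.ndarray:
    """Projected successive over-relaxation (bounded rows clamped at lo)."""
    if not (0.0 < omega < 2.0):
        raise InvalidParameterError("SOR relaxation factor must be in (0, 2)")
    m = A.shape[0]
    lo = np.full(m, UNBOUNDED) if lo is None else np.asarray(lo, float)
    lam = np.zeros(m)
    _kernels.solve_sor_dense(np.asarray(A, float), np.asarray(rhs, float),
                             lo, m, omega, n_iter, lam)
    return lam


def solve_direct(A: np.ndarray, rhs: np.ndarray,
                 lo: Optional[np.ndarray] = None) -> np.ndarray:
    """Direct mixed-complementarity solve (Cholesky + active set).

    Unbounded rows are solved exactly; rows with lo = 0 satisfy
    lambda >= 0, w = (A lambda - rhs) >= 0, lambda * w = 0.
    """
    A = np.asarray(A, float)
    m = A.shape[0]
    try:
        np.linalg.cholesky(A)
    except np.linalg.LinAlgError as e:
        raise NumericalError(f"A is not SPD: {e}") from e
    lo = np.full(m, UNBOUNDED) if lo is None else np.asarray(lo, float)
    lam = np.zeros(m)
    ok = _kernels.solve_active_set(A, np.asarray(rhs, float), lo, m, lam)
    if not ok:
        raise NumericalError("active-set iteration did not converge")
    return lam


def dispatch_solver(A: np.ndarray, rhs: np.ndarray, lo: np.ndarray,
                    has_collisions: bool, dt: float,
                    sor_omega: float = 1.3, sor_iters: int = 60,
                    accept_tol: float = 1e-6) -> tuple[np.ndarray, str]:
    """Routing used by the step loop.

    No collisions: exact banded solve.  With collisions: projected SOR,
    accepted iff the predicted joint-separation growth dt^2 |A lambda - rhs|
    (complementarity-aware) stays below accept_tol, else the direct solver.
    Returns (lambda, solver_name).
    """
    if not has_collisions:
        return solve_chain_exact(A, rhs, lo), "exact"
    lam = solve_sor(A, rhs, lo, sor_omega, sor_iters)
    m = A.shape[0]
    viol = _kernels.constraint_violation_metric(
        m, np.zeros(m, np.int64), np.zeros(m, np.int64),
        np.zeros((m, 6)), np.zeros((m, 6)), lam, np.asarray(rhs, float),
        np.asarray(A, float), True, np.asarray(lo, float), dt)
    if viol <= accept_tol:
        return lam, "sor"
    return solve_direct(A, rhs, lo), "direct"


def constraint_force(J: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Generalized constraint force F_c = J^T lambda (virtual work)."""
    return np.asarray(J).T @ np.asarray(lam)
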