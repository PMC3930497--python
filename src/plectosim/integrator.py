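"""Semi-implicit Euler integration with exponential-map quaternion update.

Velocities are updated first from all generalized forces (including the
constraint force J^T lambda), then positions advance with the new
velocities and orientations advance by the quaternion exponential of
omega * dt.  The gyroscopic torque -omega x (I omega) is included in the
force assembly (world-frame angular velocity, body-frame inertia rotated
each step).  The scheme is dissipative-stable but not time-reversible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _kernels
from .constraint_dynamics import JointSet
from .model_state import ChainState, InvalidParameterError

__all__ = ["StepParams", "exp_map_update", "step"]

DEFAULT_DT = 0.000592  # tau units


@dataclass(frozen=True)
class StepParams:
    dt: float = DEFAULT_DT
    erp: float = 0.8
    cfm: float = 1e-10
    sor_omega: float = 1.3
    sor_iters: int = 60
    accept_tol: float = 1e-6
    force_direct: bool = False

    def __post_init__(self):
        if self.dt <= 0:
            raise InvalidParameterError("dt must be positive")
        if not (0.0 <= self.erp <= 1.0):
            raise InvalidParameterError("erp must be in [0, 1]")
        if self.cfm < 0:
            raise InvalidParameterError("cfm must be >= 0")


def exp_map_update(q, omega, dt: float) -> np.ndarray:
    """q' = exp(omega dt / 2) (x) q, renormalized; |q'| = 1 to 1e-12."""
    q = np.asarray(q, float)
    if abs(np.linalg.norm(q) - 1.0) > 1e-6:
        raise InvalidParameterError("quaternion not normalized")
    return _kernels.exp_map_update(q, np.asarray(omega, float), dt)


def step(state: ChainState, joints: Optional[JointSet] = None,
         F_ext: Optional[np.ndarray] = None,
         params: StepParams = StepParams(),
         elastic=None, collisions: bool = False, plane: bool = False,
         thermostat_mode: int = 0, gamma: float = 10.0, kBT: float = 1.0,
         n_dof: int = 0) -> int:
    """Advance the state by one timestep in place.

    ``F_ext`` is an additional constant generalized force (body-major 6N)
    applied on top of the internally assembled elastic/gyroscopic/thermostat
    forces.  Returns the kernel status code (0 = ok).

    This is a convenience wrapper over the compiled loop for single-step
    use in tests and interactive work; production runs drive the loop
    directly through :class:`plectosim.tweezers.Simulation`.
    """
    joints = JointSet.empty() if joints is None else joints
    g_b, g_t = (0.0, 0.0) if elastic is None else (elastic.g_b, elastic.g_t)
    nrec = 1
    rec = {k: np.zeros(nrec) for k in
           ["t", "z", "ree", "ek", "mc", "sig", "tw", "md"]}
    rec_nc = np.zeros(nrec, np.int64)
    rec_sv = np.zeros(nrec, np.int64)
    fpos = np.zeros((1, 1, 3))
    fquat = np.zeros((1, 1, 4))
    tw_cum = np.zeros(max(state.n_cyl - 1, 1))
    bead_state = np.zeros(3)
    t_state = np.array([state.t])
    fz = 0.0
    tz = 0.0
    if F_ext is not None:
        F = np.asarray(F_ext, float).reshape(state.n_bodies, 6)
        # fold constant external force into per-step velocity seed
        Winv_blocks_v = F[:, :3] / state.mass[:, None]
        state.vel += params.dt * Winv_blocks_v
        R = state.frames()
        for i in range(state.n_bodies):
            Iw = R[i] @ np.diag(state.inertia_body[i]) @ R[i].T
            state.omega[i] += params.dt * np.linalg.solve(Iw, F[i, 3:])
    n = state.n_cyl
    reach = 2.0 * float(np.max(state.half_length[:n] + state.radius[:n]))
    from .collision import exclusion_window
    # index-adjacency exclusion applies only to serially jointed chains
    n_ex = exclusion_window(state) if joints.kind.size else 0
    status = _kernels.run_loop(
        state.pos, state.quat, state.vel, state.omega, state.mass,
        state.inertia_body, state.radius, state.half_length,
        state.n_cyl, state.has_bead,
        joints.kind, joints.body_a, joints.body_b, joints.anchor_a,
        joints.anchor_b, joints.q0,
        g_b, g_t, tw_cum,
        thermostat_mode, gamma, kBT, n_dof,
        params.erp, params.cfm, params.sor_omega, params.sor_iters,
        params.accept_tol, params.force_direct,
        collisions, plane, reach, n_ex,
        params.dt, 1,
        fz, tz, False,
        0.0, 0.0,
        1, rec["t"], rec["z"], rec["ree"], rec["ek"], rec["mc"],
        rec_nc, rec["sig"], rec["tw"], rec["md"], rec_sv,
        False, fpos, fquat,
        bead_state, t_state)
    state.t = float(t_state[0])
    return int(status)
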