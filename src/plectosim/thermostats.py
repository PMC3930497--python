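"""Local Langevin and global (stochastic velocity rescaling) thermostats.

The local thermostat adds, per body, a friction force -gamma M v and
torque -gamma I w plus Gaussian noise whose per-component variance
2 gamma k_BT M / dt (masses/principal inertias in the body frame) satisfies
the fluctuation-dissipation theorem; gamma is the velocity relaxation rate.

The global thermostat is a stochastic-velocity-rescaling scheme extended to
the rotational degrees of freedom: the correction force is an exact scalar
multiple of the generalized momentum P = W u, so it leaves the constraint
equations untouched (J W^-1 F_glob is proportional to J u, which vanishes
on the constraint manifold) and drives the total kinetic energy to the
canonical Gamma(n_dof/2, k_BT) distribution at any timestep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .model_state import ChainState, InvalidParameterError

__all__ = ["ThermostatParams", "local_langevin_force",
           "global_thermostat_force", "thermostat_constraint_decoupling_check"]

MODE_OFF = 0
MODE_LOCAL = 1
MODE_GLOBAL = 2
_MODES = {"off": MODE_OFF, "local": MODE_LOCAL, "global": MODE_GLOBAL}


@dataclass(frozen=True)
class ThermostatParams:
    """Coupling frequency gamma (1/tau), thermal energy and mode."""

    gamma: float = 10.0
    kBT: float = 1.0
    mode: str = "global"
    seed: int = 0

    def __post_init__(self):
        if self.mode not in _MODES:
            raise InvalidParameterError(f"unknown thermostat mode {self.mode}")
        if self.mode != "off" and self.gamma <= 0:
            raise InvalidParameterError("gamma must be positive")

    @property
    def mode_code(self) -> int:
        return _MODES[self.mode]


def local_langevin_force(state: ChainState, params: ThermostatParams,
                         dt: float, rng_seed: int | None = None) -> np.ndarray:
    """Generalized Langevin force (friction + FDT noise), body-major 6N.

    Noise is drawn in each body's principal-axis frame and rotated to the
    world frame; draw order is fixed by body index.  Seeding is through the
    shared kernel RNG stream (``rng_seed`` reseeds it when given).
    """
    if params.mode != "local":
        raise InvalidParameterError("params.mode must be 'local'")
    if rng_seed is not None:
        _kernels.seed_rng(rng_seed)
    nb = state.n_bodies
    force = np.zeros((nb, 3))
    torque = np.zeros((nb, 3))
    R = state.frames()
    _kernels.add_local_langevin(state.vel, state.omega, state.mass,
                                state.inertia_body, R, params.gamma,
                                params.kBT, dt, force, torque)
    return np.column_stack([force, torque]).ravel()


def global_thermostat_force(state: ChainState, params: ThermostatParams,
                            n_dof: int, dt: float,
                            rng_seed: int | None = None) -> np.ndarray:
    """Global thermostat force, an exact scalar multiple of P = W u.

    Computed from the closed-form stochastic-velocity-rescaling factor
    alpha for timestep dt: F_glob = ((alpha - 1)/dt) W u, so that the
    explicit velocity update u + dt W^-1 F_glob = alpha u reproduces the
    exact rescaling.  Returns zero for a cold start (u = 0).
    """
    if params.mode != "global":
        raise InvalidParameterError("params.mode must be 'global'")
    if rng_seed is not None:
        _kernels.seed_rng(rng_seed)
    K = state.kinetic_energy()
    if K < 1e-300:
        return np.zeros(6 * state.n_bodies)
    alpha = _kernels.svr_alpha(K, n_dof, params.kBT, params.gamma, dt)
    return (alpha - 1.0) / dt * (state.W @ state.u)


def thermostat_constraint_decoupling_check(state: ChainState, J: np.ndarray,
                                           force: np.ndarray) -> float:
    """Residual ||J W^-1 F||_inf; ~0 for the global thermostat on states
    satisfying J u = 0 (the thermostat does not disturb the constraint
    forces), generically > 0 for local Langevin noise."""
    Winv = np.linalg.inv(state.W)
    return float(np.max(np.abs(J @ Winv @ force))) if J.size else 0.0
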