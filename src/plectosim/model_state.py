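"""Core state representation: reduced units, rigid bodies and chain state.

Internally everything is expressed in reduced units where the cylinder
length b, the cylinder mass m and the thermal energy k_BT are all 1; SI
values appear only at the I/O boundary through :class:`UnitSystem`.
Quaternions are stored (w, x, y, z) and angular velocities are world-frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels

KB = 1.380649e-23  # J/K
DALTON = 1.66053906660e-27  # kg
DEFAULT_BP_MASS_DA = 650.0


class InvalidParameterError(ValueError):
    """Raised for non-physical configuration values."""


@dataclass(frozen=True)
class UnitSystem:
    """Reduced-unit system: length b, mass m, energy k_BT, time tau.

    tau = b * sqrt(m / k_BT); the derived force unit is k_BT/b and the
    torque unit is k_BT.
    """

    length_m: float
    mass_kg: float
    energy_J: float

    def __post_init__(self):
        if self.length_m <= 0 or self.mass_kg <= 0 or self.energy_J <= 0:
            raise InvalidParameterError("all base units must be positive")

    @property
    def time_s(self) -> float:
        return self.length_m * np.sqrt(self.mass_kg / self.energy_J)

    @property
    def force_N(self) -> float:
        return self.energy_J / self.length_m

    @property
    def torque_Nm(self) -> float:
        return self.energy_J

    # -- conversions ------------------------------------------------------
    def to_SI_length(self, x):
        return np.asarray(x) * self.length_m

    def from_SI_length(self, x):
        return np.asarray(x) / self.length_m

    def to_SI_time(self, x):
        return np.asarray(x) * self.time_s

    def from_SI_time(self, x):
        return np.asarray(x) / self.time_s

    def to_SI_force(self, x):
        return np.asarray(x) * self.force_N

    def from_SI_force(self, x):
        return np.asarray(x) / self.force_N

    def force_pN_to_reduced(self, f_pN):
        return np.asarray(f_pN) * 1e-12 / self.force_N

    def force_reduced_to_pN(self, f):
        return np.asarray(f) * self.force_N * 1e12


def make_unit_system(b_nm: float, bp_per_cylinder: int = 10,
                     temperature_K: float = 300.0,
                     bp_mass_Da: float = DEFAULT_BP_MASS_DA) -> UnitSystem:
    """Unit system for a chain of cylinders of length ``b_nm`` nanometres.

    The cylinder mass is ``bp_per_cylinder`` base pairs at ``bp_mass_Da``
    daltons each; the energy unit is k_B * temperature.
    """
    if b_nm <= 0 or bp_per_cylinder < 1 or temperature_K <= 0 or bp_mass_Da <= 0:
        raise InvalidParameterError("non-positive unit-system input")
    return UnitSystem(
        length_m=b_nm * 1e-9,
        mass_kg=bp_per_cylinder * bp_mass_Da * DALTON,
        energy_J=KB * temperature_K,
    )


def capsule_inertia(mass: float, radius: float, length: float) -> np.ndarray:
    """Principal moments of a solid cylinder (axis = local z).

    Returns (I_perp, I_perp, I_axis).  A radius approaching or exceeding
    length/2 is allowed (near-spherical body) but geometrically degenerate
    for a slender-chain model.
    """
    if mass <= 0 or radius <= 0 or length <= 0:
        raise InvalidParameterError("mass, radius and length must be positive")
    i_perp = mass * (3.0 * radius ** 2 + length ** 2) / 12.0
    i_axis = 0.5 * mass * radius ** 2
    return np.array([i_perp, i_perp, i_axis])


def sphere_inertia(mass: float, radius: float) -> np.ndarray:
    if mass <= 0 or radius <= 0:
        raise InvalidParameterError("mass and radius must be positive")
    i = 0.4 * mass * radius ** 2
    return np.array([i, i, i])


def body_frame(q) -> np.ndarray:
    """Orthonormal triad (t, u, t x u) as columns, t = tangent.

    The triad is the rotation of the reference triad (e_z, e_x, e_y) by q:
    t = R e_z, u = R e_x, t x u = R e_y.
    """
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q)
    if abs(n - 1.0) > 1e-6:
        raise InvalidParameterError("quaternion not normalized")
    R = _kernels.quat_to_rot(q / n)
    return np.column_stack([R[:, 2], R[:, 0], R[:, 1]])


@dataclass
class ChainState:
    """Array-of-bodies state: ``n_cyl`` capsules plus an optional bead.

    ``pos`` (N,3), ``quat`` (N,4, wxyz), ``vel`` (N,3), ``omega`` (N,3,
    world frame), ``mass`` (N,), ``inertia_body`` (N,3) principal moments,
    ``radius``/``half_length`` shape parameters (half_length = 0 marks a
    sphere).  Time ``t`` is in tau units.
    """

    pos: np.ndarray
    quat: np.ndarray
    vel: np.ndarray
    omega: np.ndarray
    mass: np.ndarray
    inertia_body: np.ndarray
    radius: np.ndarray
    half_length: np.ndarray
    n_cyl: int
    has_bead: bool = False
    t: float = 0.0

    @property
    def n_bodies(self) -> int:
        return self.pos.shape[0]

    def copy(self) -> "ChainState":
        return ChainState(
            pos=self.pos.copy(), quat=self.quat.copy(), vel=self.vel.copy(),
            omega=self.omega.copy(), mass=self.mass.copy(),
            inertia_body=self.inertia_body.copy(), radius=self.radius.copy(),
            half_length=self.half_length.copy(), n_cyl=self.n_cyl,
            has_bead=self.has_bead, t=self.t)

    @property
    def u(self) -> np.ndarray:
        """Generalized velocity, body-major: (v_0, w_0, v_1, w_1, ...)."""
        return np.concatenate(
            [np.column_stack([self.vel, self.omega]).ravel()])

    def set_u(self, u: np.ndarray) -> None:
        u = np.asarray(u).reshape(self.n_bodies, 6)
        self.vel[:] = u[:, :3]
        self.omega[:] = u[:, 3:]

    def frames(self) -> np.ndarray:
        """Rotation matrices R_i (N,3,3)."""
        R = np.empty((self.n_bodies, 3, 3))
        _kernels.compute_frames(self.quat, R)
        return R

    @property
    def W(self) -> np.ndarray:
        """Generalized mass matrix, block diagonal (6N x 6N), world frame."""
        n = self.n_bodies
        R = self.frames()
        W = np.zeros((6 * n, 6 * n))
        for i in range(n):
            W[6 * i:6 * i + 3, 6 * i:6 * i + 3] = self.mass[i] * np.eye(3)
            Iw = R[i] @ np.diag(self.inertia_body[i]) @ R[i].T
            W[6 * i + 3:6 * i + 6, 6 * i + 3:6 * i + 6] = Iw
        return W

    def kinetic_energy(self) -> float:
        R = self.frames()
        return float(_kernels.kinetic_energy(self.vel, self.omega, self.mass,
                                             R, self.inertia_body))

    def tangents(self) -> np.ndarray:
        """Unit tangents of the cylinders (n_cyl, 3)."""
        return self.frames()[:self.n_cyl, :, 2]

    def vertices(self) -> np.ndarray:
        """Chain centreline vertices v_0..v_N (cylinder endpoints)."""
        R = self.frames()
        t = R[:self.n_cyl, :, 2]
        hl = self.half_length[:self.n_cyl, None]
        ends_minus = self.pos[:self.n_cyl] - hl * t
        ends_plus = self.pos[:self.n_cyl] + hl * t
        return np.vstack([ends_minus[0], ends_plus])


def make_free_chain(n_cyl: int, radius: float = 0.3, b: float = 1.0,
                    mass: float = 1.0, direction=(0.0, 0.0, 1.0),
                    origin=(0.0, 0.0, 0.0)) -> ChainState:
    """Straight free chain of ``n_cyl`` capsules along ``direction``."""
    if n_cyl < 1:
        raise InvalidParameterError("n_cyl must be >= 1")
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    # quaternion rotating e_z onto d
    ez = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(ez, d))
    if c > 1.0 - 1e-12:
        q = np.array([1.0, 0.0, 0.0, 0.0])
    elif c < -1.0 + 1e-12:
        q = np.array([0.0, 1.0, 0.0, 0.0])
    else:
        axis = np.cross(ez, d)
        axis /= np.linalg.norm(axis)
        half = 0.5 * np.arccos(c)
        q = np.concatenate([[np.cos(half)], np.sin(half) * axis])
    pos = np.array(origin) + (np.arange(n_cyl)[:, None] + 0.5) * b * d
    quat = np.tile(q, (n_cyl, 1))
    inertia = np.tile(capsule_inertia(mass, radius, b), (n_cyl, 1))
    return ChainState(
        pos=pos, quat=quat, vel=np.zeros((n_cyl, 3)),
        omega=np.zeros((n_cyl, 3)), mass=np.full(n_cyl, mass),
        inertia_body=inertia, radius=np.full(n_cyl, radius),
        half_length=np.full(n_cyl, 0.5 * b), n_cyl=n_cyl, has_bead=False)
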