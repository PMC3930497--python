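"""Magnetic-tweezers rig: assembly construction and experiment protocols.

The standard assembly is a serial chain of N capsules (effective radius
r_eff) anchored to the impenetrable plane z = 0 and welded, at the other
end, to a rotatable bead.  The end cylinders are tangent to their
attachment surfaces.  Three protocols drive it:

* force clamp      -- constant +z force on the bead, bead free to rotate;
* turn clamp       -- bead rotation about z kinematically prescribed
                      (ramped, then held), x/y bead rotations locked;
* torque clamp     -- constant external z-torque on the bead, z-rotation
                      free, x/y locked.

All protocol functions return tidy pandas DataFrames with
autocorrelation-corrected standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernels, observables
from .constraint_dynamics import JointSet
from .dna_elasticity import ElasticParams
from .integrator import DEFAULT_DT, StepParams
from .model_state import (ChainState, InvalidParameterError, UnitSystem,
                          capsule_inertia, make_unit_system, sphere_inertia)
from .thermostats import ThermostatParams

__all__ = ["Assembly", "ExperimentProtocol", "Simulation", "effective_radius",
           "debye_length_nm", "build_assembly", "chain_from_vertices",
           "run_force_extension", "run_turn_clamp", "run_torque_clamp"]


def debye_length_nm(salt_mM: float) -> float:
    """Debye screening length of a monovalent buffer: 0.304 nm / sqrt(c[M])."""
    if salt_mM <= 0:
        raise InvalidParameterError("salt concentration must be positive")
    return 0.304 / np.sqrt(salt_mM * 1e-3)


def effective_radius(salt_mM: float, r_crystallographic_nm: float = 1.0
                     ) -> float:
    """Effective DNA radius (nm): crystallographic radius + Debye length."""
    return r_crystallographic_nm + debye_length_nm(salt_mM)


def _quat_from_z_to(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, float)
    d = d / np.linalg.norm(d)
    c = d[2]
    if c > 1.0 - 1e-12:
        return np.array([1.0, 0.0, 0.0, 0.0])
    if c < -1.0 + 1e-12:
        return np.array([0.0, 1.0, 0.0, 0.0])
    axis = np.cross([0.0, 0.0, 1.0], d)
    axis /= np.linalg.norm(axis)
    half = 0.5 * np.arccos(c)
    return np.concatenate([[np.cos(half)], np.sin(half) * axis])


def chain_from_vertices(vertices: np.ndarray, radius: float,
                        mass: float = 1.0) -> ChainState:
    """Chain of capsules along a polyline of equal-length segments."""
    v = np.asarray(vertices, float)
    segs = np.diff(v, axis=0)
    lengths = np.linalg.norm(segs, axis=1)
    b = float(lengths[0])
    if np.max(np.abs(lengths - b)) > 1e-9 * b:
        raise InvalidParameterError("polyline segments must have equal length")
    n = segs.shape[0]
    pos = 0.5 * (v[:-1] + v[1:])
    quat = np.array([_quat_from_z_to(s) for s in segs])
    inertia = np.tile(capsule_inertia(mass, radius, b), (n, 1))
    return ChainState(pos=pos, quat=quat, vel=np.zeros((n, 3)),
                      omega=np.zeros((n, 3)), mass=np.full(n, mass),
                      inertia_body=inertia, radius=np.full(n, radius),
                      half_length=np.full(n, 0.5 * b), n_cyl=n)


@dataclass
class Assembly:
    """Chain + plane + bead scene with its permanent joints."""

    state: ChainState
    joints: JointSet
    elastic: ElasticParams
    n_cyl: int
    radius: float
    bead_radius: float = 0.0
    plane: bool = True
    collisions: bool = True
    clamp: Optional[str] = None
    units: Optional[UnitSystem] = None

    @property
    def contour_length(self) -> float:
        return self.n_cyl * 2.0 * float(self.state.half_length[0])

    @property
    def Lk0(self) -> float:
        """Intrinsic linking number: one double-helix pitch per cylinder."""
        return float(self.n_cyl)

    @property
    def n_dof(self) -> int:
        return observables.count_dof(self.joints, self.state.n_bodies)


def build_assembly(n_cyl: int, radius: float = 0.576,
                   elastic: Optional[ElasticParams] = None,
                   bead: bool = True, bead_radius: float = 10.0,
                   bead_mass: float = 4.0, bead_inertia_radius: float = 2.0,
                   tangent_ends: bool = True, anchor: str = "weld",
                   clamp: Optional[str] = None, plane: bool = True,
                   collisions: bool = True,
                   units: Optional[UnitSystem] = None) -> Assembly:
    """Build the anchored chain + plane + bead assembly (reduced units).

    The default geometry places the first and last cylinders tangent to
    their attachment surfaces (lying parallel to the plane / bead surface)
    with the chain rising vertically in between; all joints are satisfied
    exactly at build time and velocities are zero.  With
    ``tangent_ends=False`` the chain is built straight and vertical from
    the origin (minimal geometry used for ideal-chain comparisons).

    ``bead_inertia_radius``: the bead's moments of inertia are those of a
    solid sphere of this radius (not the steric radius) so that bead
    kinetics does not dominate sampling; equilibrium statistics are
    independent of inertia.
    """
    if n_cyl < 2:
        raise InvalidParameterError("need at least 2 cylinders")
    b = 1.0
    r = radius
    if elastic is None:
        elastic = ElasticParams(g_b=0.0, g_t=0.0)
    if tangent_ends:
        verts = [np.array([0.0, 0.0, r])]
        verts.append(np.array([b, 0.0, r]))
        for i in range(n_cyl - 2):
            verts.append(np.array([b, 0.0, r + (i + 1) * b]))
        top = verts[-1]
        verts.append(top + np.array([b, 0.0, 0.0]))
        verts = np.array(verts)
    else:
        verts = np.zeros((n_cyl + 1, 3))
        verts[:, 2] = np.arange(n_cyl + 1) * b
    chain = chain_from_vertices(verts, r)
    if bead:
        if tangent_ends:
            attach = 0.5 * (verts[-2] + verts[-1])
            center = attach + np.array([0.0, 0.0, r + bead_radius])
        else:
            attach = verts[-1]
            center = attach + np.array([0.0, 0.0, bead_radius])
        pos = np.vstack([chain.pos, center])
        quat = np.vstack([chain.quat, [1.0, 0.0, 0.0, 0.0]])
        state = ChainState(
            pos=pos, quat=quat, vel=np.zeros((n_cyl + 1, 3)),
            omega=np.zeros((n_cyl + 1, 3)),
            mass=np.append(chain.mass, bead_mass),
            inertia_body=np.vstack([chain.inertia_body,
                                    sphere_inertia(bead_mass,
                                                   bead_inertia_radius)]),
            radius=np.append(chain.radius, bead_radius),
            half_length=np.append(chain.half_length, 0.0),
            n_cyl=n_cyl, has_bead=True)
        joints = JointSet.serial_chain(state, anchor=anchor,
                                       bead_attach_world=attach, clamp=clamp)
    else:
        state = chain
        joints = JointSet.serial_chain(state, anchor=anchor)
    # overlap sanity check at build (excluded pairs aside)
    from .collision import detect_all_contacts
    if collisions and detect_all_contacts(state, plane=plane):
        raise InvalidParameterError("initial bodies overlap")
    return Assembly(state=state, joints=joints, elastic=elastic, n_cyl=n_cyl,
                    radius=r, bead_radius=bead_radius if bead else 0.0,
                    plane=plane, collisions=collisions, clamp=clamp,
                    units=units)


def _sample_vmf(axis: np.ndarray, kappa: float, rng) -> np.ndarray:
    """von Mises-Fisher unit vector around ``axis`` with concentration
    kappa (kappa = 0: uniform on the sphere)."""
    if kappa < 1e-10:
        v = rng.standard_normal(3)
        return v / np.linalg.norm(v)
    u = rng.random()
    w = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    w = min(max(w, -1.0), 1.0)
    ref = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 \
        else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    psi = 2.0 * np.pi * rng.random()
    perp = np.cos(psi) * e1 + np.sin(psi) * e2
    return w * axis + np.sqrt(max(1.0 - w * w, 0.0)) * perp


def _quat_from_matrix(R: np.ndarray) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    x, y, z, w = Rotation.from_matrix(R).as_quat()
    return np.array([w, x, y, z])


def sample_equilibrium_chain(state: ChainState, elastic: ElasticParams,
                             f_reduced: float, rng,
                             plane: bool = False,
                             max_tries: int = 200) -> bool:
    """Redraw the chain conformation from the Boltzmann weight of the
    discrete chain under tension.

    Tangents are sampled sequentially from the transfer conditional
    p(t_i) ~ exp(g_b t_i . t_{i-1} + f b t_i . z) (von Mises-Fisher) and
    twists from p(phi) ~ exp(g_t cos phi); material frames are parallel
    transported.  Used to start sampling runs near equilibrium; any
    residual bias (the conditional ignores the downstream coupling)
    relaxes during equilibration.  Assemblies with a bead are left
    untouched (returns False); with ``plane`` the draw is retried until
    the chain clears z = 0.
    """
    if state.has_bead:
        return False
    n = state.n_cyl
    b = 2.0 * float(state.half_length[0])
    R0 = state.frames()
    v0 = state.pos[0] - state.half_length[0] * R0[0][:, 2]
    fz = f_reduced * b
    ez = np.array([0.0, 0.0, 1.0])
    g = elastic.g_b
    for _ in range(max_tries):
        # one directed pass for a starting point ...
        tangents = np.empty((n, 3))
        for i in range(n):
            v = fz * ez if i == 0 else g * tangents[i - 1] + fz * ez
            kappa = float(np.linalg.norm(v))
            axis = v / kappa if kappa > 1e-12 else ez
            tangents[i] = _sample_vmf(axis, kappa, rng)
        # ... then exact Gibbs sweeps: the single-tangent conditional is
        # von Mises-Fisher with field g (t_{i-1} + t_{i+1}) + f b z.
        # Without tension the directed pass is already the exact transfer
        # sampling of the chain, so no sweeps are needed.
        n_sweeps = 4 * n if fz != 0.0 else 0
        for _sweep in range(n_sweeps):
            for i in range(n):
                v = fz * ez.copy()
                if i > 0:
                    v += g * tangents[i - 1]
                if i < n - 1:
                    v += g * tangents[i + 1]
                kappa = float(np.linalg.norm(v))
                axis = v / kappa if kappa > 1e-12 else ez
                tangents[i] = _sample_vmf(axis, kappa, rng)
        # material frames: parallel transport + twist draw
        frames = np.empty((n, 3, 3))
        t_prev = None
        u_prev = None
        for i in range(n):
            t = tangents[i]
            if t_prev is None:
                ref = np.array([1.0, 0.0, 0.0]) if abs(t[0]) < 0.9 \
                    else np.array([0.0, 1.0, 0.0])
                u = np.cross(t, ref)
                u /= np.linalg.norm(u)
            else:
                # parallel transport u_prev across t_prev -> t
                c = np.cross(t_prev, t)
                s2 = float(np.linalg.norm(c))
                if s2 > 1e-12:
                    axis_r = c / s2
                    ang = np.arctan2(s2, float(np.dot(t_prev, t)))
                    u = (u_prev * np.cos(ang)
                         + np.cross(axis_r, u_prev) * np.sin(ang)
                         + axis_r * np.dot(axis_r, u_prev) * (1 - np.cos(ang)))
                else:
                    u = u_prev.copy()
                if elastic.g_t > 0:
                    phi = rng.vonmises(0.0, elastic.g_t)
                else:
                    phi = 2.0 * np.pi * rng.random() - np.pi
                u = (u * np.cos(phi) + np.cross(t, u) * np.sin(phi))
            u -= t * np.dot(u, t)
            u /= np.linalg.norm(u)
            tangents[i] = t
            frames[i] = np.column_stack([u, np.cross(t, u), t])
            t_prev, u_prev = t, u
        verts = np.vstack([v0, v0 + b * np.cumsum(tangents, axis=0)])
        if plane and np.min(verts[:, 2]) < float(np.max(state.radius[:n])):
            continue
        state.pos[:n] = 0.5 * (verts[:-1] + verts[1:])
        for i in range(n):
            state.quat[i] = _quat_from_matrix(frames[i])
        return True
    return False


@dataclass
class Records:
    """Per-stride observable log of a run segment."""

    t: np.ndarray
    z_end: np.ndarray
    ree: np.ndarray
    ekin: np.ndarray
    max_c: np.ndarray
    n_contacts: np.ndarray
    bead_angle: np.ndarray
    twist_rad: np.ndarray
    max_depth: np.ndarray
    solver: np.ndarray
    frames_pos: Optional[np.ndarray] = None
    frames_quat: Optional[np.ndarray] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t, "z_end": self.z_end, "ree": self.ree,
            "ekin": self.ekin, "max_c": self.max_c,
            "n_contacts": self.n_contacts, "bead_angle": self.bead_angle,
            "twist_rad": self.twist_rad, "max_depth": self.max_depth,
            "solver": self.solver})

    @staticmethod
    def concat(parts: Sequence["Records"]) -> "Records":
        keep_frames = all(p.frames_pos is not None for p in parts)
        return Records(
            *(np.concatenate([getattr(p, f) for p in parts]) for f in
              ("t", "z_end", "ree", "ekin", "max_c", "n_contacts",
               "bead_angle", "twist_rad", "max_depth", "solver")),
            frames_pos=(np.concatenate([p.frames_pos for p in parts])
                        if keep_frames else None),
            frames_quat=(np.concatenate([p.frames_quat for p in parts])
                         if keep_frames else None))


class Simulation:
    """Driver binding an assembly to the compiled step loop.

    One shared RNG stream is seeded once at construction; repeated ``run``
    calls continue the trajectory (and the stream) deterministically.
    """

    def __init__(self, assembly: Assembly,
                 thermostat: ThermostatParams = ThermostatParams(),
                 step_params: StepParams = StepParams(),
                 force: float = 0.0, torque: float = 0.0, seed: int = 0):
        self.assembly = assembly
        self.state = assembly.state.copy()
        self.joints = assembly.joints
        self.thermostat = thermostat
        self.step_params = step_params
        self.force = float(force)
        self.torque = float(torque)
        self.tw_cum = np.zeros(max(assembly.n_cyl - 1, 1))
        self.bead_angle_state = np.zeros(3)
        self._t_state = np.array([0.0])
        self._psi0 = 0.0
        self._omega_clamp = 0.0
        self.n_dof = assembly.n_dof
        _kernels.seed_rng(int(seed) & 0x7FFFFFFF)
        if thermostat.mode != "off":
            self._thermalize_velocities(int(seed) & 0x7FFFFFFF)

    def _thermalize_velocities(self, seed: int) -> None:
        """Maxwell-Boltzmann initial velocities (the constraint solver
        projects them onto the constraint manifold on the first step).

        Required for the global thermostat, which rescales momenta and
        therefore cannot heat a perfectly cold start.
        """
        st = self.state
        rng = np.random.default_rng(seed + 0x5D5D)
        kBT = self.thermostat.kBT
        st.vel[:] = rng.standard_normal(st.vel.shape) \
            * np.sqrt(kBT / st.mass)[:, None]
        wb = rng.standard_normal(st.omega.shape) \
            * np.sqrt(kBT / st.inertia_body)
        R = st.frames()
        st.omega[:] = np.einsum("nij,nj->ni", R, wb)

    # -- clamp scheduling --------------------------------------------------
    @property
    def clamp_angle(self) -> float:
        return self._psi0 + self._omega_clamp * float(self._t_state[0])

    def set_clamp_rate(self, omega: float) -> None:
        """Change the prescribed bead angular velocity, keeping the target
        angle continuous."""
        psi_now = self.clamp_angle
        self._omega_clamp = float(omega)
        self._psi0 = psi_now - self._omega_clamp * float(self._t_state[0])

    @property
    def bead_turns(self) -> float:
        return float(self.bead_angle_state[0]) / (2.0 * np.pi)

    @property
    def sigma(self) -> float:
        return self.bead_turns / self.assembly.Lk0

    def run(self, n_steps: int, stride: int = 0,
            record_frames: bool = False) -> Records:
        st = self.state
        sp = self.step_params
        n = st.n_cyl
        nrec = n_steps // stride if stride > 0 else 0
        rec = {k: np.zeros(nrec) for k in
               ("t", "z", "ree", "ek", "mc", "sig", "tw", "md")}
        rec_nc = np.zeros(nrec, np.int64)
        rec_sv = np.zeros(nrec, np.int64)
        nb = st.n_bodies
        if record_frames and nrec > 0:
            fpos = np.zeros((nrec, nb, 3))
            fquat = np.zeros((nrec, nb, 4))
        else:
            fpos = np.zeros((1, 1, 3))
            fquat = np.zeros((1, 1, 4))
        reach = 2.0 * float(np.max(st.half_length[:n] + st.radius[:n]))
        from .collision import exclusion_window
        n_ex = exclusion_window(st)
        tip_force = (not st.has_bead) and self.force != 0.0
        status = _kernels.run_loop(
            st.pos, st.quat, st.vel, st.omega, st.mass, st.inertia_body,
            st.radius, st.half_length, st.n_cyl, st.has_bead,
            self.joints.kind, self.joints.body_a, self.joints.body_b,
            self.joints.anchor_a, self.joints.anchor_b, self.joints.q0,
            self.assembly.elastic.g_b, self.assembly.elastic.g_t, self.tw_cum,
            self.thermostat.mode_code, self.thermostat.gamma,
            self.thermostat.kBT, self.n_dof,
            sp.erp, sp.cfm, sp.sor_omega, sp.sor_iters, sp.accept_tol,
            sp.force_direct,
            self.assembly.collisions, self.assembly.plane, reach, n_ex,
            sp.dt, n_steps,
            self.force, self.torque, tip_force,
            self._psi0, self._omega_clamp,
            stride, rec["t"], rec["z"], rec["ree"], rec["ek"], rec["mc"],
            rec_nc, rec["sig"], rec["tw"], rec["md"], rec_sv,
            record_frames and nrec > 0, fpos, fquat,
            self.bead_angle_state, self._t_state)
        if status == 1:
            raise FloatingPointError("NaN/Inf encountered in forces; "
                                     "diagnostic state retained on .state")
        if status == 2:
            raise RuntimeError("constraint solver failure")
        self.state.t = float(self._t_state[0])
        return Records(rec["t"], rec["z"], rec["ree"], rec["ek"], rec["mc"],
                       rec_nc, rec["sig"], rec["tw"], rec["md"], rec_sv,
                       frames_pos=fpos if record_frames and nrec else None,
                       frames_quat=fquat if record_frames and nrec else None)

    def ramp_turns(self, turns: float, ramp_rate: float = 0.05,
                   stride: int = 0) -> Records:
        """Ramp the bead clamp by ``turns`` at ``ramp_rate`` turns per 10^3
        steps, then stop the rotation."""
        dt = self.step_params.dt
        if turns == 0.0:
            return self.run(0, stride)
        n_steps = int(round(abs(turns) / ramp_rate * 1000.0))
        if n_steps == 0:
            raise InvalidParameterError("ramp rate too fast for the timestep")
        omega = 2.0 * np.pi * turns / (n_steps * dt)
        # twist added per joint per step must stay well below pi
        if abs(omega) * dt > np.pi / 4:
            raise InvalidParameterError("ramp rate too fast for the timestep")
        self.set_clamp_rate(omega)
        recs = self.run(n_steps, stride)
        self.set_clamp_rate(0.0)
        return recs


@dataclass(frozen=True)
class ExperimentProtocol:
    """Clamp schedules and sampling plan for the three experiment modes."""

    mode: str = "force_extension"  # force_extension | turn_clamp | torque_clamp
    equil_steps: int = 20_000
    sample_steps: int = 100_000
    stride: int = 50
    ramp_rate: float = 0.05  # turns per 10^3 steps
    n_replicas: int = 1
    seed: int = 0
    thermostat: ThermostatParams = field(default_factory=ThermostatParams)
    step_params: StepParams = field(default_factory=StepParams)

    def __post_init__(self):
        if self.mode not in ("force_extension", "turn_clamp", "torque_clamp"):
            raise InvalidParameterError(f"unknown protocol mode {self.mode}")


def _sample_extension(sim: Simulation, protocol: ExperimentProtocol, L0):
    sim.run(protocol.equil_steps)
    rec = sim.run(protocol.sample_steps, stride=protocol.stride)
    z = rec.z_end / L0
    mean, se, neff = observables.mean_with_autocorr_se(z)
    return rec, mean, se, neff


def run_force_extension(assembly: Assembly, forces: Sequence[float],
                        protocol: ExperimentProtocol) -> pd.DataFrame:
    """Mean relative extension vs stretching force (reduced force units).

    Each force starts from the build state with a force-dependent seed
    offset; extension is the height of the chain end above the anchor
    plane.  A drift test flags non-equilibrated runs.
    """
    rows = []
    L0 = assembly.contour_length
    for k, f in enumerate(forces):
        if protocol.n_replicas > 1:
            # independent replicas, each started from a fresh Boltzmann
            # draw; the standard error comes from the replica spread,
            # which is immune to slow-mode autocorrelation
            reps = []
            for r in range(protocol.n_replicas):
                seed = protocol.seed + 1009 * k + 131 * r
                sim = Simulation(assembly, thermostat=protocol.thermostat,
                                 step_params=protocol.step_params,
                                 force=float(f), seed=seed)
                rng = np.random.default_rng(seed + 77)
                sample_equilibrium_chain(sim.state, assembly.elastic,
                                         float(f), rng, plane=assembly.plane)
                sim.run(protocol.equil_steps)
                rec = sim.run(protocol.sample_steps, stride=protocol.stride)
                reps.append(float(np.mean(rec.z_end)) / L0)
            reps = np.asarray(reps)
            mean = float(np.mean(reps))
            se = float(np.std(reps, ddof=1) / np.sqrt(len(reps)))
            rows.append({"force": f, "rel_ext": mean, "se": se,
                         "n_eff": float(len(reps)), "drift": 0.0,
                         "equilibrated": True})
            continue
        sim = Simulation(assembly, thermostat=protocol.thermostat,
                         step_params=protocol.step_params, force=float(f),
                         seed=protocol.seed + 1009 * k)
        rng = np.random.default_rng(protocol.seed + 1009 * k + 77)
        sample_equilibrium_chain(sim.state, assembly.elastic, float(f), rng,
                                 plane=assembly.plane)
        rec, mean, se, neff = _sample_extension(sim, protocol, L0)
        half = len(rec.z_end) // 2
        drift = (np.mean(rec.z_end[half:]) - np.mean(rec.z_end[:half])) / L0
        rows.append({"force": f, "rel_ext": mean, "se": se,
                     "n_eff": neff, "drift": drift,
                     "equilibrated": bool(abs(drift) < 5 * se * np.sqrt(2.0))})
    return pd.DataFrame(rows)


def run_turn_clamp(assembly: Assembly, force: float,
                   n_values: Sequence[float],
                   protocol: ExperimentProtocol) -> pd.DataFrame:
    """Hat curve: mean relative extension vs imposed bead turns n."""
    if assembly.clamp != "turn":
        raise InvalidParameterError("assembly must be built with clamp='turn'")
    rows = []
    L0 = assembly.contour_length
    for k, n in enumerate(n_values):
        sim = Simulation(assembly, thermostat=protocol.thermostat,
                         step_params=protocol.step_params, force=float(force),
                         seed=protocol.seed + 2003 * k)
        sim.ramp_turns(float(n), protocol.ramp_rate)
        rec, mean, se, neff = _sample_extension(sim, protocol, L0)
        rows.append({"turns": n, "sigma": n / assembly.Lk0, "force": force,
                     "rel_ext": mean, "se": se, "n_eff": neff})
    return pd.DataFrame(rows)


def run_torque_clamp(assembly: Assembly, force: float,
                     torques: Sequence[float],
                     protocol: ExperimentProtocol,
                     return_series: bool = False):
    """Mean overtwist sigma vs imposed bead torque (k_BT units).

    sigma = (cumulative bead angle)/(2 pi Lk0).  Near the buckling torque
    the sigma series is bistable; runs whose drift test fails are flagged
    rather than rejected.
    """
    if assembly.clamp != "xy":
        raise InvalidParameterError("assembly must be built with clamp='xy'")
    rows = []
    series = {}
    L0 = assembly.contour_length
    Lk0 = assembly.Lk0
    for k, gam in enumerate(torques):
        sim = Simulation(assembly, thermostat=protocol.thermostat,
                         step_params=protocol.step_params, force=float(force),
                         torque=float(gam), seed=protocol.seed + 4001 * k)
        sim.run(protocol.equil_steps)
        rec = sim.run(protocol.sample_steps, stride=protocol.stride)
        sig = rec.bead_angle / (2.0 * np.pi * Lk0)
        mean, se, neff = observables.mean_with_autocorr_se(sig)
        half = len(sig) // 2
        drift = np.mean(sig[half:]) - np.mean(sig[:half])
        rows.append({"torque": gam, "force": force, "sigma": mean, "se": se,
                     "sigma_var": float(np.var(sig)), "n_eff": neff,
                     "stationary": bool(abs(drift) < 5 * se * np.sqrt(2.0)),
                     "rel_ext": float(np.mean(rec.z_end)) / L0})
        if return_series:
            series[gam] = (rec.z_end / L0, sig)
    df = pd.DataFrame(rows)
    return (df, series) if return_series else df
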