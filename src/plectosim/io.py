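"""Trajectory/observable persistence, XYZ export, fixtures and manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .dna_elasticity import ElasticParams
from .model_state import ChainState, InvalidParameterError
from .tweezers import (Assembly, Records, build_assembly, chain_from_vertices)
from .constraint_dynamics import JointSet

__all__ = ["write_trajectory", "read_trajectory", "write_observables",
           "read_observables", "export_xyz", "fixtures", "RunManifest"]

OBS_DTYPES = {
    "t": float, "z_end": float, "ree": float, "ekin": float, "max_c": float,
    "n_contacts": int, "bead_angle": float, "twist_rad": float,
    "max_depth": float, "solver": int,
}


def write_trajectory(path, times: np.ndarray, pos: np.ndarray,
                     quat: np.ndarray, meta: Optional[dict] = None) -> None:
    """Columnar container: per-frame positions and quaternions + time.

    Lossless float64 storage; a checksum over the payload detects
    truncated files on read.
    """
    times = np.asarray(times, float)
    pos = np.asarray(pos, float)
    quat = np.asarray(quat, float)
    if pos.ndim != 3 or quat.ndim != 3 or pos.shape[:2] != quat.shape[:2]:
        raise InvalidParameterError("inconsistent frame shapes")
    digest = hashlib.sha256()
    for a in (times, pos, quat):
        digest.update(a.tobytes())
    with h5py.File(path, "w") as fh:
        fh.create_dataset("times", data=times)
        fh.create_dataset("pos", data=pos)
        fh.create_dataset("quat", data=quat)
        fh.attrs["checksum"] = digest.hexdigest()
        if meta:
            fh.attrs["meta"] = json.dumps(meta)


def read_trajectory(path):
    """Inverse of :func:`write_trajectory`; verifies the payload checksum."""
    with h5py.File(path, "r") as fh:
        times = fh["times"][...]
        pos = fh["pos"][...]
        quat = fh["quat"][...]
        stored = fh.attrs.get("checksum", "")
        meta = json.loads(fh.attrs["meta"]) if "meta" in fh.attrs else {}
    digest = hashlib.sha256()
    for a in (times, pos, quat):
        digest.update(a.tobytes())
    if stored and digest.hexdigest() != stored:
        raise IOError("trajectory file corrupt: checksum mismatch")
    return times, pos, quat, meta


def write_observables(records: Records, path) -> None:
    records.to_frame().to_csv(path, index=False)


def read_observables(path) -> pd.DataFrame:
    """Strict re-read with declared dtypes."""
    return pd.read_csv(path, dtype=OBS_DTYPES)


def export_xyz(path, times, pos, quat, half_length, n_cyl: int,
               has_bead: bool) -> None:
    """Pseudo-atom XYZ export: one atom per cylinder end plus the bead.

    Line count: frames * (n_cyl + 2 + (1 if bead)) plus 2 header lines per
    frame.
    """
    from . import _kernels

    times = np.asarray(times, float)
    with open(path, "w") as fh:
        for fidx in range(times.shape[0]):
            n_atoms = n_cyl + 1 + (1 if has_bead else 0)
            fh.write(f"{n_atoms}\n")
            fh.write(f"t={times[fidx]:.6f}\n")
            for i in range(n_cyl):
                R = _kernels.quat_to_rot(np.ascontiguousarray(quat[fidx, i]))
                t = R[:, 2]
                e = pos[fidx, i] - half_length[i] * t
                fh.write(f"C {e[0]:.6f} {e[1]:.6f} {e[2]:.6f}\n")
                if i == n_cyl - 1:
                    e2 = pos[fidx, i] + half_length[i] * t
                    fh.write(f"C {e2[0]:.6f} {e2[1]:.6f} {e2[2]:.6f}\n")
            if has_bead:
                bpos = pos[fidx, n_cyl]
                fh.write(f"O {bpos[0]:.6f} {bpos[1]:.6f} {bpos[2]:.6f}\n")


@dataclass(frozen=True)
class RunManifest:
    """Resolved config + seed + code version; identical manifests imply
    bitwise identical outputs."""

    config: dict
    seed: int
    version: str
    n_steps: int

    def digest(self) -> str:
        payload = json.dumps(
            {"config": self.config, "seed": self.seed,
             "version": self.version, "n_steps": self.n_steps},
            sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config, "seed": self.seed,
                       "version": self.version, "n_steps": self.n_steps,
                       "digest": self.digest()}, fh, indent=2)


# ---------------------------------------------------------------------------
# deterministic fixture scenes
# ---------------------------------------------------------------------------


def _hairpin_assembly(n_arm: int = 8, radius: float = 0.576,
                      gap_scale: float = 1.8,
                      elastic: Optional[ElasticParams] = None) -> Assembly:
    """Folded chain whose two arms touch (capsule gap < 2r): contact-rich."""
    b = 1.0
    z0 = 2.0 * radius + 0.3
    verts = [np.array([k * b, 0.0, z0]) for k in range(n_arm + 1)]
    off = np.array([0.0, 0.0, gap_scale * radius])
    # two-segment bridge from arm tip to the offset return arm
    tip = verts[-1]
    mid_dir = np.array([0.0, 1.0, 0.0])
    half_off = tip + 0.5 * off
    h = np.sqrt(b ** 2 - 0.25 * float(off @ off))
    verts.append(half_off + h * mid_dir)
    verts.append(tip + off)
    for k in range(1, n_arm + 1):
        verts.append(tip + off - np.array([k * b, 0.0, 0.0]))
    chain = chain_from_vertices(np.array(verts), radius)
    joints = JointSet.serial_chain(chain, anchor="ball")
    if elastic is None:
        elastic = ElasticParams(g_b=5.0, g_t=0.0)
    return Assembly(state=chain, joints=joints, elastic=elastic,
                    n_cyl=chain.n_cyl, radius=radius, plane=True,
                    collisions=True)


def fixtures(seed: int = 0) -> dict:
    """Small deterministic scenes used across the test suite.

    * ``four_chain``   -- 4-cylinder anchored chain (the worked serial-chain
      example: block-tridiagonal Jacobian structure);
    * ``free50``       -- 50-cylinder free chain;
    * ``hairpin``      -- folded chain with touching arms (produces
      contacts on the first collision pass);
    * ``micro_rig``    -- 8-cylinder anchored chain with plane and bead.
    """
    rng = np.random.default_rng(seed)
    from .model_state import make_free_chain

    four = make_free_chain(4, radius=0.3, origin=(0.0, 0.0, 1.0))
    four_joints = JointSet.serial_chain(four, anchor="ball")
    free50 = make_free_chain(50, radius=0.3, origin=(0.0, 0.0, 2.0))
    free50_joints = JointSet.serial_chain(free50, anchor=None)
    micro = build_assembly(8, radius=0.5, bead=True, bead_radius=2.0,
                           elastic=ElasticParams(g_b=10.0, g_t=10.0))
    # small deterministic perturbation field for property tests
    noise = rng.standard_normal((free50.n_cyl, 3)) * 0.01
    return {
        "four_chain": (four, four_joints),
        "free50": (free50, free50_joints),
        "hairpin": _hairpin_assembly(),
        "micro_rig": micro,
        "noise50": noise,
    }
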