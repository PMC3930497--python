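import numpy as np
import pytest

from plectosim.constraint_dynamics import JointSet, chain_ball_joints
from plectosim.model_state import make_free_chain
from plectosim.tweezers import chain_from_vertices


def random_walk_vertices(n, rng, b=1.0, origin=(0.0, 0.0, 0.0)):
    """Equal-length random polyline with mild direction persistence so the
    chain does not immediately self-intersect."""
    d = np.array([0.0, 0.0, 1.0])
    verts = [np.asarray(origin, float)]
    for _ in range(n):
        d = d + 0.7 * rng.standard_normal(3)
        d /= np.linalg.norm(d)
        verts.append(verts[-1] + b * d)
    return np.asarray(verts)


def random_chain(n, rng, radius=0.3, randomize_velocities=True):
    state = chain_from_vertices(random_walk_vertices(n, rng), radius)
    if randomize_velocities:
        state.vel[:] = rng.standard_normal(state.vel.shape)
        state.omega[:] = rng.standard_normal(state.omega.shape)
    return state


def dense_system(state, anchored=True):
    """(J, W, u, joints) for the ball-jointed chain, dense analysis-grade."""
    from plectosim.constraint_dynamics import assemble_jacobian

    joints = chain_ball_joints(state, anchored=anchored)
    J = assemble_jacobian(state, joints)
    return J, state.W, state.u, joints


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def warm_kernels():
    """Touch the compiled loop once so per-test timings stay small."""
    from plectosim import Simulation, ThermostatParams
    from plectosim.tweezers import Assembly
    from plectosim.dna_elasticity import ElasticParams

    st = make_free_chain(3, radius=0.3, origin=(0, 0, 2))
    asm = Assembly(state=st, joints=JointSet.serial_chain(st),
                   elastic=ElasticParams(g_b=1.0, g_t=1.0), n_cyl=3,
                   radius=0.3, plane=False, collisions=False)
    Simulation(asm, thermostat=ThermostatParams(mode="global"), seed=0).run(5)
    return True
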