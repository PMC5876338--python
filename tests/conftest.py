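import numpy as np
import pytest

import oxiline as ox


@pytest.fixture(scope="session")
def straight_net():
    return ox.build_straight_fixture()


@pytest.fixture(scope="session")
def curved_net():
    return ox.build_curved_fixture()


@pytest.fixture(scope="session")
def bifurcated_net():
    return ox.build_bifurcated_fixture()


@pytest.fixture(scope="session")
def steady_flow_straight(straight_net):
    """Constant-inflow periodic solution on the straight fixture (steady limit)."""
    wf = ox.constant_waveform(3.0e-5, period=1.0)
    return ox.solve_periodic_flow(straight_net, wf, dt=1e-4, cycle_tol=1e-10, max_cycles=100)


@pytest.fixture(scope="session")
def pulsatile_flow_curved(curved_net):
    wf = ox.waveform_preset("coronary")
    return ox.solve_periodic_flow(curved_net, wf, dt=1e-4, cycle_tol=1e-8, max_cycles=100)


@pytest.fixture(scope="session")
def steady_sink_solution(straight_net, steady_flow_straight):
    """Steady Sherwood-sink oxygen solution on the straight fixture."""
    bc = ox.OxygenBoundary(inlet_po2_mmhg=85.0, wall_po2_mmhg=60.0)
    return ox.solve_oxygen(straight_net, steady_flow_straight, bc,
                           cycle_tol=1e-12, max_cycles=200)


def strong_sink_closure(net, target_kl_over_v=0.8, flow=None, velocity=None):
    """Fixed-coefficient closure giving a steady outlet decay exponent ~target.

    Physical oxygen extraction over these short tubes is O(1e-4) relative,
    which makes solver comparisons trivially easy; a strengthened sink makes
    the discretization error observable.
    """
    v = velocity if velocity is not None else float(flow.velocity[-1, 0])
    geom = net.segment(net.topological_order()[0]).geometry
    k = target_kl_over_v * v / net.total_length
    return ox.FixedCoefficientClosure(k * geom.radius / 2.0)
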