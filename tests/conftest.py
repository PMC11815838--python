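"""Shared fixtures: parameter tables, synthetic structures, cached heavy
pipeline runs (the helix and charge-probe predictions are computed once per
session and reused by the engine and acceptance tests)."""
from __future__ import annotations

import numpy as np
import pytest

from siepka.electrostatics import SolverSettings
from siepka.engine import predict
from siepka.fixtures import FixtureSpec, make_fixture
from siepka.params import ParameterSet
from siepka.structure import read_structure


@pytest.fixture(scope="session")
def tables() -> ParameterSet:
    return ParameterSet.load_default()


def load_fixture_structure(fx, chains=None):
    ps = ParameterSet.load_default()
    if fx.extra_params is not None:
        ps.add_charge_table(fx.extra_params)
    return read_structure(fx.pdb_text, chains=chains,
                          het_whitelist=fx.het_whitelist, params=ps)


@pytest.fixture(scope="session")
def helix_his_structure():
    return load_fixture_structure(
        make_fixture(FixtureSpec(kind="helix_with_target")))


@pytest.fixture(scope="session")
def helix_his_prediction(helix_his_structure):
    """Default-settings end-to-end prediction for the exposed helix His."""
    return predict(helix_his_structure, [("A", 5, "")])[0]


@pytest.fixture(scope="session")
def probe_his_prediction():
    """Same helix with a −1 e probe charge 4 Å from the imidazole centroid."""
    fx = make_fixture(FixtureSpec(kind="charge_probe", q=-1.0, distance=4.0))
    st = load_fixture_structure(fx)
    return predict(st, [("A", 5, "")])[0]


@pytest.fixture(scope="session")
def fast_settings() -> SolverSettings:
    """Coarser grids for tests whose tolerances do not need the defaults."""
    return SolverSettings(grid_spacing=0.55, surface_spacing=0.55,
                          fine_margin=3.0, margin=6.0)


@pytest.fixture(scope="session")
def free_his_structure():
    return load_fixture_structure(make_fixture(FixtureSpec(kind="free_residue")))


def titration_oracle_pair(cond_a, cond_b, lo=-10.0, hi=25.0, iters=100):
    """Independent solution of the coupled two-residue titration equations
    by nested bisection on a dense pH interval.

    ``cond_x`` = (pKa given neutral neighbour, pKa given protonated
    neighbour). Returns (pKa_eff_A, pKa_eff_B).
    """
    def f_h(ph, pka):
        return 1.0 / (1.0 + 10.0 ** (ph - pka))

    def g_b(p_b, p_a):
        f = f_h(p_b, p_a)
        return f * cond_b[1] + (1.0 - f) * cond_b[0]

    def solve_b(p_a):
        a, b = lo, hi
        for _ in range(iters):
            m = 0.5 * (a + b)
            a, b = (m, b) if m - g_b(m, p_a) < 0 else (a, m)
        return 0.5 * (a + b)

    def resid_a(p_a):
        f = f_h(p_a, solve_b(p_a))
        return p_a - (f * cond_a[1] + (1.0 - f) * cond_a[0])

    a, b = lo, hi
    for _ in range(iters):
        m = 0.5 * (a + b)
        a, b = (m, b) if resid_a(m) < 0 else (a, m)
    p_a = 0.5 * (a + b)
    return p_a, solve_b(p_a)
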