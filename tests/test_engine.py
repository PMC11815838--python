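"""Linear pKa model, burial correction, titration arithmetic, cluster
decoupling and the end-to-end prediction pipeline."""
import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from siepka.electrostatics import SolverSettings
from siepka.engine import (ConditionalPkaMatrix, DEFAULT_PARAMS, EngineError,
                           PkaModelParams, burial_correction, decouple_cluster,
                           delta_e_inter, linear_pka, predict,
                           predictions_to_tsv, protonated_fraction)
from siepka.fixtures import FixtureSpec, make_fixture, _pdb_lines, _peptide
from siepka.structure import read_structure

from conftest import load_fixture_structure, titration_oracle_pair

HIS = PkaModelParams(C=6.5, alpha=0.29, restype="HIS")


# ---------------------------------------------------------------------------
# linear model

def test_linear_pka_intercept_and_slope():
    assert linear_pka(0.0, HIS) == 6.5
    assert linear_pka(-1.3643, HIS) == pytest.approx(6.79, abs=1e-9)


@hyp_settings(deadline=None, max_examples=200, derandomize=True)
@given(de=st.floats(-50, 50), step=st.floats(0.01, 5.0))
def test_linear_pka_strictly_decreasing(de, step):
    assert linear_pka(de + step, HIS) < linear_pka(de, HIS)


# ---------------------------------------------------------------------------
# burial correction

@pytest.mark.parametrize("sesa,psesa", [
    (s, p) for s in (0.0, 5.0, 19.9, 20.0, 25.0, 60.0)
    for p in (0.0, 4.0, 7.9, 8.0, 12.0) if p <= s])
def test_burial_step_threshold_grid(sesa, psesa):
    """Exactly −2.0 pH iff SESA < 20 and PSESA < 8; His only, never Asp."""
    raw = 6.2
    out = burial_correction(raw, sesa, psesa, HIS)
    if sesa < 20.0 and psesa < 8.0:
        assert out == raw - 2.0
    else:
        assert out == raw
    asp = PkaModelParams(C=4.0, alpha=0.21, restype="ASP")
    assert burial_correction(raw, sesa, psesa, asp) == raw


def test_burial_correction_deterministic_single_shift():
    a = burial_correction(6.2, 10.0, 2.0, HIS)
    assert a == burial_correction(6.2, 10.0, 2.0, HIS)
    assert a == 6.2 - HIS.burial_shift


def test_negative_area_rejected():
    with pytest.raises(ValueError):
        burial_correction(6.2, -1.0, 0.0, HIS)


# ---------------------------------------------------------------------------
# protonated fraction

def test_protonated_fraction_closed_form_points():
    assert protonated_fraction(6.0, 6.0) == 0.5
    assert protonated_fraction(7.0, 6.0) == pytest.approx(1 / 11, rel=1e-12)
    assert protonated_fraction(-400.0, 6.0) == 1.0
    assert protonated_fraction(400.0, 6.0) == pytest.approx(0.0, abs=1e-300)


def test_protonated_fraction_strictly_decreasing_many_points():
    rng = np.random.default_rng(11)
    for _ in range(1000):
        pka = rng.uniform(0, 14)
        # stay within the double-resolvable part of the sigmoid
        ph = pka + rng.uniform(-8.0, 8.0)
        d = rng.uniform(1e-4, 2.0)
        assert protonated_fraction(ph + d, pka) < protonated_fraction(ph, pka)
        assert protonated_fraction(pka, pka) == 0.5


# ---------------------------------------------------------------------------
# decoupling

def test_zero_coupling_returns_conditional_value():
    m = ConditionalPkaMatrix(members=["A"], conditional={"A": {(): 6.0}})
    assert decouple_cluster(m) == {"A": 6.0}
    m2 = ConditionalPkaMatrix(members=["A", "B"], conditional={
        "A": {(False,): 6.0, (True,): 6.0},
        "B": {(False,): 6.0, (True,): 6.0}})
    assert decouple_cluster(m2) == pytest.approx({"A": 6.0, "B": 6.0})


def test_symmetric_pair_stays_symmetric():
    m = ConditionalPkaMatrix(members=["A", "B"], conditional={
        "A": {(False,): 7.0, (True,): 5.0},
        "B": {(False,): 7.0, (True,): 5.0}})
    eff = decouple_cluster(m)
    assert eff["A"] == pytest.approx(eff["B"], abs=1e-9)


def test_pair_fixed_point_matches_titration_oracle_100_random():
    """100 random conditional matrices (values in [2,10], repulsive coupling
    inside the contraction regime where the fixed point is provably
    unique) agree with the independent nested-bisection titration oracle
    to 1e-3 pH."""
    rng = np.random.default_rng(0)
    for _ in range(100):
        c0 = rng.uniform(3.5, 10.0, 2)
        shift = rng.uniform(0.0, 0.8, 2)
        cond_a = (float(c0[0]), float(c0[0] - shift[0]))
        cond_b = (float(c0[1]), float(c0[1] - shift[1]))
        m = ConditionalPkaMatrix(members=["A", "B"], conditional={
            "A": {(False,): cond_a[0], (True,): cond_a[1]},
            "B": {(False,): cond_b[0], (True,): cond_b[1]}})
        eff = decouple_cluster(m, tol=1e-6, max_iter=500)
        oa, ob = titration_oracle_pair(cond_a, cond_b)
        assert eff["A"] == pytest.approx(oa, abs=1e-3)
        assert eff["B"] == pytest.approx(ob, abs=1e-3)


def test_strong_coupling_returns_valid_fixed_point():
    """Under bistable strong coupling the iterate is still a true root."""
    rng = np.random.default_rng(5)
    for _ in range(50):
        c = rng.uniform(2.0, 10.0, 4)
        cond = {"A": {(False,): max(c[0], c[1]), (True,): min(c[0], c[1])},
                "B": {(False,): max(c[2], c[3]), (True,): min(c[2], c[3])}}
        m = ConditionalPkaMatrix(members=["A", "B"], conditional=cond)
        eff = decouple_cluster(m, tol=1e-6, max_iter=1000)
        pa, pb = eff["A"], eff["B"]
        fa = protonated_fraction(pa, pb)
        fb = protonated_fraction(pb, pa)
        ra = pa - (fa * cond["A"][(True,)] + (1 - fa) * cond["A"][(False,)])
        rb = pb - (fb * cond["B"][(True,)] + (1 - fb) * cond["B"][(False,)])
        assert abs(ra) < 1e-5 and abs(rb) < 1e-5


def test_incomplete_matrix_rejected():
    m = ConditionalPkaMatrix(members=["A", "B"], conditional={
        "A": {(False,): 6.0}, "B": {(False,): 6.0, (True,): 5.0}})
    with pytest.raises(ValueError):
        decouple_cluster(m)


def test_asymmetric_pair_oracle_example():
    m = ConditionalPkaMatrix(members=["A", "B"], conditional={
        "A": {(False,): 7.0, (True,): 5.0},
        "B": {(False,): 7.5, (True,): 5.5}})
    eff = decouple_cluster(m, tol=1e-6)
    oa, ob = titration_oracle_pair((7.0, 5.0), (7.5, 5.5))
    assert eff["A"] == pytest.approx(oa, abs=1e-3)
    assert eff["B"] == pytest.approx(ob, abs=1e-3)


# ---------------------------------------------------------------------------
# ΔE^inter and prediction

def test_isolated_his_delta_e_negative(free_his_structure, fast_settings):
    """Charging the imidazole is stabilized by solvation: ΔE < 0."""
    de = delta_e_inter(free_his_structure, ("A", 1, ""),
                       settings=fast_settings)
    assert de.mean < 0
    assert np.isfinite(de.mean)
    assert de.winner_protonated.startswith("HIP")


def test_duplicate_models_average_identically(tables, fast_settings):
    body = "\n".join(l for l in make_fixture(
        FixtureSpec(kind="free_residue")).pdb_text.splitlines()
        if l.startswith("ATOM"))
    pdb = (f"MODEL        1\n{body}\nENDMDL\n"
           f"MODEL        2\n{body}\nENDMDL\nEND\n")
    st = read_structure(pdb, params=tables)
    de = delta_e_inter(st, ("A", 1, ""), settings=fast_settings)
    assert len(de.per_model) == 2
    assert de.per_model[0] == de.per_model[1]
    assert de.mean == de.per_model[0]


def test_probe_charge_raises_pka(helix_his_prediction, probe_his_prediction):
    """A −1 e charge 4 Å from the imidazole stabilizes HIP: ΔE drops and
    the predicted pKa strictly rises."""
    assert probe_his_prediction.delta_e < helix_his_prediction.delta_e
    assert (probe_his_prediction.effective_pka
            > helix_his_prediction.effective_pka)


def test_exposed_his_near_nominal_pka(helix_his_prediction):
    """Unperturbed exposed His on the helix: corrected pKa in [5.5, 7.5]."""
    p = helix_his_prediction
    assert 5.5 <= p.corrected_pka <= 7.5
    assert not p.correction_applied
    assert p.sesa > 20.0


def test_empty_target_list_gives_empty_report(helix_his_structure):
    assert predict(helix_his_structure, []) == []


def test_coupled_pair_prediction(fast_settings):
    """The pair fixture yields one 2-cluster; repulsion caps each member's
    effective pKa at its neutral-neighbour conditional value."""
    fx = make_fixture(FixtureSpec(kind="coupled_pair", gap=5.0))
    st = load_fixture_structure(fx)
    preds = predict(st, fx.manifest["targets"], settings=fast_settings)
    assert len(preds) == 2
    for p in preds:
        assert p.cluster == (("A", 2, ""), ("B", 2, ""))
        assert p.effective_pka <= p.corrected_pka + 1e-9


def test_oversized_cluster_refused(tables):
    base = _peptide("HIS", 1, 1)
    lines = []
    for i, chain in enumerate("ABCDE"):
        out = [(n, num, {k: v + np.array([4.5 * i, 0.0, 0.0])
                         for k, v in atoms.items()})
               for n, num, atoms in base]
        lines += _pdb_lines(out, chain=chain)[0]
    st = read_structure("\n".join(lines + ["END"]) + "\n", params=tables)
    targets = [(c, 1, "") for c in "ABCDE"]
    with pytest.raises(EngineError, match="refused"):
        predict(st, targets)


def test_end_to_end_determinism(fast_settings):
    """Identical input → bitwise-identical report."""
    def run():
        fx = make_fixture(FixtureSpec(kind="free_residue"))
        st = load_fixture_structure(fx)
        preds = predict(st, [("A", 1, "")], settings=fast_settings)
        return predictions_to_tsv(preds)
    assert run() == run()


def test_unusable_target_refused(tables):
    lines = [l for l in make_fixture(
        FixtureSpec(kind="free_residue")).pdb_text.splitlines()
        if l.startswith("ATOM") and " CA " not in l]
    st = read_structure("\n".join(lines + ["END"]) + "\n", params=tables)
    with pytest.raises(EngineError):
        delta_e_inter(st, ("A", 1, ""))
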