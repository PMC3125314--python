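"""Model validation, graphs, and conserved-sum detection."""

import pytest

import robnet as rn
from robnet.io import model_from_dict
from robnet.model import StructuralError, detect_conserved_sums
from robnet.tags import PropertyTag as P

ALL_CASES = ["srna", "arabinose", "camp", "lac", "mapk", "mapk_full"]


@pytest.mark.parametrize("name", ALL_CASES)
def test_every_packaged_model_passes_validation(name):
    model = rn.load_packaged_model(name)
    report = rn.validate_model(model)
    assert report.passed, report.diagnostics


@pytest.mark.parametrize("name", ALL_CASES)
def test_validation_is_idempotent(name):
    model = rn.load_packaged_model(name)
    r1 = rn.validate_model(model)
    r2 = rn.validate_model(model)
    assert r1.passed == r2.passed and r1.diagnostics == r2.diagnostics


def test_d_kind_term_with_increasing_tag_fails_citing_a4():
    model = model_from_dict({
        "name": "bad", "states": ["x1"], "inputs": [],
        "terms": [
            {"name": "d11", "target": "x1", "kind": "d", "arg": "x1",
             "tag": "sigmoidal"},
            {"name": "b11", "target": "x1", "kind": "b", "mult": "x1",
             "tag": "positive-constant"},
        ]})
    report = rn.validate_model(model)
    assert not report.passed
    assert any(d["assumption"] == "A4" for d in report.diagnostics)


def test_off_target_conversion_without_vanishing_coefficient_fails_a5():
    model = model_from_dict({
        "name": "bad5", "states": ["x1", "x2"], "inputs": [],
        "terms": [
            {"name": "c1", "target": "x1", "kind": "c",
             "tag": "positive-constant"},
            # degrades x1 proportionally to x2 with a coefficient that does
            # not vanish at x1 = 0: positivity of x1 would break
            {"name": "b12", "target": "x1", "kind": "b", "mult": "x2",
             "tag": "positive-constant"},
            {"name": "c2", "target": "x2", "kind": "c",
             "tag": "positive-constant"},
            {"name": "b22", "target": "x2", "kind": "b", "mult": "x2",
             "tag": "positive-constant"},
        ]})
    report = rn.validate_model(model)
    assert not report.passed
    assert any(d["assumption"] == "A5" for d in report.diagnostics)


def test_malformed_index_is_a_structural_error_not_a_diagnostic():
    model = rn.NetworkModel(
        state_names=("x1",),
        terms=(rn.Term(name="c1", target=3, kind="c",
                       tag=P.POSITIVE_CONSTANT),))
    with pytest.raises(StructuralError):
        rn.validate_model(model)


# --- graphs -----------------------------------------------------------------

def toy_repression_model():
    """Protein represses an RNA that is also removed by an input RNA and
    translated into a protein: 2 inputs, 3 species, one d-arc x1 -> x2."""
    return model_from_dict({
        "name": "toy", "states": ["x1", "x2", "x3"], "inputs": ["u1", "u2"],
        "terms": [
            {"name": "a1u1", "target": "x1", "kind": "a", "mult": "u1",
             "tag": "positive-constant"},
            {"name": "b11", "target": "x1", "kind": "b", "mult": "x1",
             "tag": "positive-constant"},
            {"name": "d21", "target": "x2", "kind": "d", "arg": "x1",
             "tag": "complementary-sigmoidal"},
            {"name": "b22", "target": "x2", "kind": "b", "mult": "x2",
             "tag": "positive-constant"},
            {"name": "b2u2", "target": "x2", "kind": "b", "mult": "x2",
             "arg": "u2", "tag": "increasing-asymptotically-unbounded"},
            {"name": "a32", "target": "x3", "kind": "a", "mult": "x2",
             "tag": "positive-constant"},
            {"name": "b33", "target": "x3", "kind": "b", "mult": "x3",
             "tag": "positive-constant"},
        ]})


def test_toy_graph_topology():
    g = rn.build_graph(toy_repression_model())
    species = [n for n, d in g.nodes(data=True)
               if d["node_class"] == "species"]
    inputs = [n for n, d in g.nodes(data=True) if d["node_class"] == "input"]
    assert sorted(species) == ["x1", "x2", "x3"]
    assert sorted(inputs) == ["u1", "u2"]
    d_arcs = [(u, v) for u, v, d in g.edges(data=True) if d["kind"] == "d"]
    assert d_arcs == [("x1", "x2")]
    assert g.has_edge("u1", "x1") and g.has_edge("u2", "x2")
    assert g.has_edge("x2", "x3")


def test_empty_model_graph_has_no_arcs():
    model = rn.NetworkModel(state_names=("x1",), terms=())
    g = rn.build_graph(model)
    assert g.number_of_edges() == 0 and g.number_of_nodes() == 1


def test_modulator_becomes_dashed_arc():
    model = rn.load_packaged_model("arabinose")
    g = rn.build_graph(model)
    dashed = [(u, v) for u, v, d in g.edges(data=True) if d["dashed"]]
    assert ("x1", "x2") in dashed


def test_graph_csv_export(tmp_path):
    g = rn.build_graph(toy_repression_model())
    path = tmp_path / "edges.csv"
    rn.export_graph_csv(g, path)
    lines = path.read_text().strip().splitlines()
    assert lines[0] == "source,target,kind,dashed"
    assert len(lines) == 1 + g.number_of_edges()


# --- conserved sums ---------------------------------------------------------

def test_mapk_full_has_the_two_pool_sums(cases):
    case = cases("mapk")
    sums = detect_conserved_sums(case.extras["full_model"],
                                 case.extras["full_instance"], seed=3)
    weights = sorted(tuple(s.weights) for s in sums)
    assert weights == [(0, 0, 0, 0, 1, 1, 1), (0, 1, 1, 1, 0, 0, 0)]


def test_conserved_sums_invariant_to_seed(cases):
    case = cases("mapk")
    model = case.extras["full_model"]
    inst = case.extras["full_instance"]
    w1 = sorted(tuple(s.weights) for s in
                detect_conserved_sums(model, inst, n_samples=14, seed=1))
    w2 = sorted(tuple(s.weights) for s in
                detect_conserved_sums(model, inst, n_samples=14, seed=99))
    assert w1 == w2


def test_srna_has_no_conserved_sum(unit_srna):
    model, inst, _ = unit_srna
    assert detect_conserved_sums(model, inst, seed=0) == []


def test_degenerate_single_state_zero_field():
    model = model_from_dict({
        "name": "still", "states": ["x1"], "inputs": [],
        "terms": [{"name": "c1", "target": "x1", "kind": "c",
                   "tag": "nonnegative-constant"}]})
    cfg = rn.SamplingConfig(term_params={"c1": {"value": 0.0}})
    inst = rn.sample_instance(model, cfg, seed=0)
    sums = detect_conserved_sums(model, inst, seed=0)
    assert [s.weights for s in sums] == [(1,)]
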