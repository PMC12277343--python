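"""Modified-cosine scoring, network assembly and consensus diagnostics."""

import io

import networkx as nx
import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from bbmn.filtering import FilterHit
from bbmn.network import (
    MolecularNetwork,
    build_network,
    consensus_diagnostic,
    export_graphml,
    export_tables,
    flag_building_blocks,
    modified_cosine,
)
from bbmn.spectra import MsmsSpectrum

from conftest import random_spectrum


def _spec(spec_id, precursor, peaks):
    return MsmsSpectrum(id=spec_id, precursor_mz=precursor, peaks=peaks)


def assignment_oracle(a: MsmsSpectrum, b: MsmsSpectrum, tol: float = 0.02) -> float:
    """Exact maximum-weight one-to-one assignment score (Hungarian
    algorithm over the candidate-pair weight matrix) — the upper bound
    the greedy assignment is checked against."""
    prepared = []
    for spec in (a, b):
        w = [(p.mz, p.intensity**0.5) for p in spec.peaks if p.intensity > 0]
        norm = sum(x * x for _, x in w) ** 0.5
        prepared.append([(mz, x / norm) for mz, x in w])
    wa, wb = prepared
    shift = b.precursor_mz - a.precursor_mz
    weights = np.zeros((len(wa), len(wb)))
    for i, (mza, xa) in enumerate(wa):
        for j, (mzb, xb) in enumerate(wb):
            if min(abs(mza - mzb), abs(mza + shift - mzb)) <= tol:
                weights[i, j] = xa * xb
    rows, cols = linear_sum_assignment(weights, maximize=True)
    return float(weights[rows, cols].sum())


class TestModifiedCosine:
    def test_self_similarity_is_one(self):
        spec = _spec("s", 400.0, [(100.0, 5.0e4), (150.0, 2.0e4), (300.0, 8.0e4)])
        score, matched = modified_cosine(spec, spec)
        assert score == pytest.approx(1.0, abs=1e-9)
        assert matched == 3

    def test_disjoint_spectra_score_zero(self):
        a = _spec("a", 400.0, [(100.0, 1.0e4)])
        b = _spec("b", 400.0, [(200.0, 1.0e4)])
        assert modified_cosine(a, b) == (0.0, 0)

    def test_precursor_shift_pairing(self):
        """Two shared-scaffold peaks, one aligned directly and one via the
        precursor mass difference, give a perfect score."""
        a = _spec("a", 200.0, [(100.0, 1.0), (150.0, 1.0)])
        b = _spec("b", 210.0, [(100.0, 1.0), (160.0, 1.0)])
        score, matched = modified_cosine(a, b, 0.02)
        assert score == pytest.approx(1.0, abs=1e-9)
        assert matched == 2

    def test_zero_intensity_spectrum(self):
        a = _spec("a", 400.0, [(100.0, 0.0)])
        b = _spec("b", 400.0, [(100.0, 1.0e4)])
        assert modified_cosine(a, b) == (0.0, 0)

    def test_precursor_window_removes_near_precursor_peaks(self):
        a = _spec("a", 400.0, [(100.0, 1.0e4), (395.0, 1.0e6)])
        b = _spec("b", 400.0, [(100.0, 1.0e4), (395.0, 1.0e6)])
        score, matched = modified_cosine(a, b)
        assert matched == 1  # the 395 peak sits inside the 17 Da window
        score_off, matched_off = modified_cosine(a, b, precursor_window=None)
        assert matched_off == 2

    def test_symmetry_range_and_self_similarity_random(self):
        rng = np.random.default_rng(42)
        spectra = [random_spectrum(rng, f"s{i}") for i in range(40)]
        for spec in spectra:
            score, _ = modified_cosine(spec, spec, precursor_window=None)
            assert score == pytest.approx(1.0, abs=1e-9)
        for _ in range(100):
            i, j = rng.integers(0, len(spectra), size=2)
            ab, ma = modified_cosine(spectra[i], spectra[j])
            ba, mb = modified_cosine(spectra[j], spectra[i])
            assert ab == pytest.approx(ba, abs=1e-9)
            assert ma == mb
            assert 0.0 <= ab <= 1.0

    def test_greedy_matches_assignment_oracle(self):
        """Greedy one-to-one assignment equals the exhaustive maximum on
        small (<= 6 peak) random instances."""
        rng = np.random.default_rng(12345)
        mismatches = []
        for case in range(500):
            a = random_spectrum(rng, "a", n_peaks=int(rng.integers(2, 7)))
            b = random_spectrum(rng, "b", n_peaks=int(rng.integers(2, 7)))
            greedy, _ = modified_cosine(a, b, 0.02, precursor_window=None)
            exact = assignment_oracle(a, b, 0.02)
            assert greedy <= exact + 1e-9
            if abs(greedy - exact) > 1e-9:
                mismatches.append(case)
        assert mismatches == []


class TestBuildNetwork:
    def test_single_spectrum(self):
        net = build_network([_spec("s", 400.0, [(100.0, 1.0e4)])])
        assert net.node_ids == ["s"]
        assert net.edges == []

    def test_threshold_arithmetic_on_triangle(self):
        """Pairwise scores {~0.89, 0.75, ~0.67} at threshold 0.7 leave
        two edges and a single 3-member component.  With equal-intensity
        peaks the scores are closed-form: a-b = 2/sqrt(5), a-c = 3/4,
        b-c = (3/4)(2/sqrt(5)) < 0.7."""
        shared = [(100.0, 1.0e4), (150.0, 1.0e4), (200.0, 1.0e4), (250.0, 1.0e4)]
        a = _spec("a", 400.0, shared)
        b = _spec("b", 400.0, shared + [(300.0, 1.0e4)])
        c = _spec("c", 400.0, [(97.0, 1.0e4)] + shared[:3])
        assert modified_cosine(a, b)[0] == pytest.approx(2 / 5**0.5, abs=1e-9)
        assert modified_cosine(a, c)[0] == pytest.approx(0.75, abs=1e-9)
        net = build_network([a, b, c], score_threshold=0.7, min_matched=2)
        pairs = {(e.id_a, e.id_b) for e in net.edges}
        scores = {
            tuple(sorted((x.id, y.id))): modified_cosine(x, y)[0]
            for x, y in [(a, b), (a, c), (b, c)]
        }
        expected = {p for p, s in scores.items() if s >= 0.7}
        assert pairs == expected
        assert len(expected) == 2
        assert net.components() == [{"a", "b", "c"}]

    def test_raising_threshold_never_adds_edges(self):
        rng = np.random.default_rng(3)
        spectra = [random_spectrum(rng, f"s{i}") for i in range(12)]
        lo = build_network(spectra, score_threshold=0.2, min_matched=1)
        hi = build_network(spectra, score_threshold=0.6, min_matched=1)
        lo_pairs = {(e.id_a, e.id_b) for e in lo.edges}
        hi_pairs = {(e.id_a, e.id_b) for e in hi.edges}
        assert hi_pairs <= lo_pairs

    def test_top_k_bounds_degree(self):
        shared = [(100.0 + i, 1.0e4) for i in range(6)]
        spectra = [_spec(f"s{i}", 400.0, shared) for i in range(8)]
        net = build_network(spectra, min_matched=2, top_k=3)
        # every surviving edge ranks within the top-3 edges of both ends
        for u, v in net.graph.edges:
            for node in (u, v):
                incident = sorted(
                    net.graph.edges(node),
                    key=lambda e: -net.graph.edges[e]["score"],
                )
                assert tuple(sorted((u, v))) in {tuple(sorted(e)) for e in incident[:3]}

    def test_max_component_split(self):
        shared = [(100.0 + i, 1.0e4) for i in range(6)]
        spectra = [_spec(f"s{i}", 400.0, shared) for i in range(9)]
        net = build_network(spectra, min_matched=2, max_component=4)
        assert all(len(c) <= 4 for c in net.components())

    def test_component_ids_deterministic(self):
        a = _spec("a", 400.0, [(100.0, 1.0e4), (150.0, 1.0e4), (200.0, 1.0e4), (250.0, 1.0e4)])
        b = _spec("b", 400.0, a.peaks)
        z = _spec("z", 500.0, [(300.0, 1.0e4)])
        net = build_network([z, b, a], min_matched=2)
        assert net.graph.nodes["a"]["component"] == net.graph.nodes["b"]["component"] == 0
        assert net.graph.nodes["z"]["component"] == 1


class TestFlagBuildingBlocks:
    def _net(self):
        g = nx.Graph()
        for n in "abc":
            g.add_node(n, precursor_mz=300.0, retention_time=0.0, building_block=False, component=0)
        return MolecularNetwork(g)

    def _hit(self, sid):
        return FilterHit(sid, 300.0, 180.0671, 180.067, -0.0001, 2.0e4)

    def test_empty_hits_all_false(self):
        net = flag_building_blocks(self._net(), [])
        assert not any(nx.get_node_attributes(net.graph, "building_block").values())

    def test_flags_exactly_hit_nodes_and_idempotent(self):
        net = self._net()
        flag_building_blocks(net, [self._hit("a"), self._hit("c")])
        once = dict(nx.get_node_attributes(net.graph, "building_block"))
        assert once == {"a": True, "b": False, "c": True}
        flag_building_blocks(net, [self._hit("a"), self._hit("c")])
        assert dict(nx.get_node_attributes(net.graph, "building_block")) == once

    def test_unknown_ids_error(self):
        with pytest.raises(KeyError, match="ghost"):
            flag_building_blocks(self._net(), [self._hit("ghost")])


class TestConsensusDiagnostic:
    def test_shared_ion_full_support(self):
        family = [
            _spec(f"f{i}", 298.0 + i, [(180.0671, 1.0e5), (100.0 + 7 * i, 2.0e4)])
            for i in range(4)
        ]
        top = consensus_diagnostic(family)[0]
        assert top.mz == 180.0671
        assert top.support == 4

    def test_disjoint_spectra_support_one(self):
        a = _spec("a", 300.0, [(100.0, 1.0e4)])
        b = _spec("b", 300.0, [(200.0, 1.0e4)])
        assert all(c.support == 1 for c in consensus_diagnostic([a, b]))

    def test_single_linkage_merges_close_ions(self):
        a = _spec("a", 300.0, [(180.065, 1.0e4)])
        b = _spec("b", 300.0, [(180.069, 1.0e4)])
        clusters = consensus_diagnostic([a, b])
        assert len(clusters) == 1
        assert clusters[0].support == 2
        assert clusters[0].mz == pytest.approx(180.067, abs=1e-3)

    def test_needs_two_spectra(self):
        with pytest.raises(ValueError):
            consensus_diagnostic([_spec("a", 300.0, [(100.0, 1.0)])])


class TestExport:
    def _network(self):
        shared = [(100.0, 1.0e4), (150.0, 1.0e4), (200.0, 1.0e4), (250.0, 1.0e4)]
        a = _spec("a", 400.0, shared)
        b = _spec("b", 400.0, shared)
        return build_network([a, b], min_matched=2)

    def test_graphml_round_trip(self, tmp_path):
        net = self._network()
        path = tmp_path / "net.graphml"
        export_graphml(net, str(path))
        back = nx.read_graphml(str(path))
        assert set(back.nodes) == {"a", "b"}
        assert back.edges["a", "b", ]["score"] == pytest.approx(1.0, abs=1e-9)
        assert back.nodes["a"]["building_block"] is False

    def test_graphml_empty_network(self, tmp_path):
        net = MolecularNetwork(nx.Graph())
        path = tmp_path / "empty.graphml"
        export_graphml(net, str(path))
        assert len(nx.read_graphml(str(path)).nodes) == 0

    def test_graphml_deterministic(self, tmp_path):
        p1, p2 = tmp_path / "n1.graphml", tmp_path / "n2.graphml"
        export_graphml(self._network(), str(p1))
        export_graphml(self._network(), str(p2))
        assert p1.read_bytes() == p2.read_bytes()

    def test_tables(self):
        nodes, edges = export_tables(self._network())
        assert len(nodes) == 2
        assert len(edges) == 1
        assert list(edges.loc[0, ["id_a", "id_b"]]) == ["a", "b"]
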