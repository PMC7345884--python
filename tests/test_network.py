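"""Modified cosine and molecular network topology."""

import numpy as np
import pytest

from lipidnet.msio import Spectrum
from lipidnet.network import (
    NetworkParams,
    build_network,
    modified_cosine,
    read_graphml,
    write_graphml,
)
from lipidnet.synthetic import SimConfig, noiseless, simulate_spectrum
from lipidnet.chem import parse_lipid_name

from conftest import exhaustive_modified_cosine, random_spectrum_pair


def _spec(id, precursor, peaks):
    arr = np.asarray(peaks, dtype=float)
    return Spectrum(id=id, precursor_mz=precursor,
                    mz=arr[:, 0], intensity=arr[:, 1])


class TestModifiedCosine:
    def test_self_similarity_is_one(self):
        s = _spec("a", 700.0, [(100, 10), (200, 50), (300, 5)])
        cos, n = modified_cosine(s, s)
        assert cos == pytest.approx(1.0, abs=1e-12)
        assert n == s.n_peaks

    def test_disjoint_spectra_score_zero(self):
        a = _spec("a", 700.0, [(100, 10), (200, 50)])
        b = _spec("b", 700.0, [(150, 10), (250, 50)])
        assert modified_cosine(a, b) == (0.0, 0)

    def test_precursor_shifted_copy_scores_like_self(self):
        """Shifting precursor and all chain ions by one block leaves the
        score at the exhaustive-oracle self-similarity."""
        a = _spec("a", 700.0, [(100, 10), (200, 50), (300, 5), (400, 20)])
        delta = 26.0157
        b = _spec("b", 700.0 + delta,
                  [(m + delta, i) for m, i in zip(a.mz, a.intensity)])
        cos, n = modified_cosine(a, b)
        assert cos == pytest.approx(exhaustive_modified_cosine(a, b), abs=1e-9)
        assert cos == pytest.approx(1.0, abs=1e-9)
        assert n == a.n_peaks

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a, b = random_spectrum_pair(rng)
            assert modified_cosine(a, b) == modified_cosine(b, a)

    def test_bounded_zero_one(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            a, b = random_spectrum_pair(rng)
            cos, n = modified_cosine(a, b)
            assert 0.0 <= cos <= 1.0 and n >= 0

    def test_matches_exhaustive_assignment_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            a, b = random_spectrum_pair(rng)
            cos, _ = modified_cosine(a, b)
            assert cos == pytest.approx(
                exhaustive_modified_cosine(a, b), abs=1e-9)

    def test_empty_spectrum_rejected(self):
        a = _spec("a", 700.0, [(100, 10)])
        empty = Spectrum(id="e", precursor_mz=700.0, mz=[], intensity=[])
        with pytest.raises(ValueError):
            modified_cosine(a, empty)

    def test_agrees_with_matchms_on_conflict_free_spectra(self):
        """Cross-check against an independent implementation.

        matchms scores raw intensity products, so spectra carrying
        sqrt-transformed intensities must reproduce our sqrt-weighted score
        when every peak has a unique match.
        """
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import ModifiedCosine

        rng = np.random.default_rng(8)
        for _ in range(20):
            na, nb = rng.integers(4, 10), rng.integers(4, 10)
            mza = np.sort(rng.choice(np.arange(100, 600, 5.0), na, False))
            mzb = np.sort(rng.choice(np.arange(100, 600, 5.0), nb, False))
            ia, ib = rng.uniform(1, 100, na), rng.uniform(1, 100, nb)
            a = Spectrum(id="a", precursor_mz=700.0, mz=mza, intensity=ia)
            b = Spectrum(id="b", precursor_mz=700.0, mz=mzb, intensity=ib)
            ma = matchms.Spectrum(mz=mza, intensities=np.sqrt(ia),
                                  metadata={"precursor_mz": 700.0},
                                  metadata_harmonization=False)
            mb = matchms.Spectrum(mz=mzb, intensities=np.sqrt(ib),
                                  metadata={"precursor_mz": 700.0},
                                  metadata_harmonization=False)
            score = ModifiedCosine(tolerance=0.02).pair(ma, mb)
            cos, n = modified_cosine(a, b)
            assert cos == pytest.approx(float(score["score"]), abs=1e-9)
            assert n == int(score["matches"])


class TestBuildNetwork:
    def _triplet(self):
        """Three spectra with pairwise structure: a~b strong, b~c medium,
        a~c weak."""
        base = [(100.0 + 10 * k, 50.0) for k in range(8)]
        a = _spec("a", 700.0, base)
        b = _spec("b", 700.0, base[:7] + [(550.0, 10.0)])
        c = _spec("c", 700.0, base[:2] + [(300.5 + k, 30.0) for k in range(5)])
        return [a, b, c]

    def test_edges_respect_thresholds(self):
        net = build_network(self._triplet(), NetworkParams())
        for _, _, data in net.graph.edges(data=True):
            assert data["cosine"] > 0.60
            assert data["n_matched"] >= 6

    def test_low_matched_peak_pair_not_linked(self):
        base = [(100.0 + 50 * k, 50.0) for k in range(4)]
        a = _spec("a", 700.0, base)          # only 4 peaks shared
        b = _spec("b", 700.0, base + [(500.0, 1.0), (600.0, 1.0)])
        filler1 = _spec("f1", 900.0, [(700.0 + k, 5.0) for k in range(8)])
        filler2 = _spec("f2", 900.0, [(700.0 + k, 5.0) for k in range(8)])
        net = build_network([a, b, filler1, filler2], NetworkParams())
        assert not net.graph.has_edge("a", "b")  # cosine high, matches < 6

    def test_min_cluster_size_removes_singletons(self):
        spectra = self._triplet()
        lone = _spec("lone", 900.0, [(601.0 + 7 * k, 5.0) for k in range(8)])
        net = build_network(spectra + [lone], NetworkParams())
        assert "lone" not in net.graph
        assert all(len(c) >= 2 for c in net.components())

    def test_needs_two_spectra(self):
        with pytest.raises(ValueError):
            build_network(self._triplet()[:1], NetworkParams())

    def test_shared_chain_species_connect_but_distant_ones_do_not(self):
        """Species sharing a head group and a chain connect; a plasmalogen
        and its diacyl counterpart share too few ions to be linked."""
        config = noiseless(SimConfig())
        names = ["PC (16:0/18:1)", "PC (18:0/18:1)",
                 "PE (16:0/16:1)", "PE-P (16:0/16:1)"]
        spectra = [simulate_spectrum(parse_lipid_name(n), config,
                                     rng=0, spectrum_id=n)
                   for n in names]
        net = build_network(spectra, NetworkParams())
        assert net.graph.has_edge("PC (16:0/18:1)", "PC (18:0/18:1)")
        assert not net.graph.has_edge("PE (16:0/16:1)", "PE-P (16:0/16:1)")


class TestGraphml:
    def test_round_trip_preserves_topology_and_attributes(self, tmp_path):
        net = build_network(TestBuildNetwork()._triplet(), NetworkParams())
        path = tmp_path / "net.graphml"
        write_graphml(net, path)
        restored = read_graphml(path)
        assert set(restored.graph.nodes) == set(net.graph.nodes)
        assert set(map(frozenset, restored.graph.edges)) == \
            set(map(frozenset, net.graph.edges))
        for u, v, data in net.graph.edges(data=True):
            rdata = restored.graph.edges[u, v]
            assert rdata["cosine"] == pytest.approx(data["cosine"])
            assert rdata["n_matched"] == data["n_matched"]

    def test_empty_network_writes_valid_graphml(self, tmp_path):
        import networkx as nx
        from lipidnet.network import MolecularNetwork
        net = MolecularNetwork(graph=nx.Graph(), params=NetworkParams())
        path = tmp_path / "empty.graphml"
        write_graphml(net, path)
        assert read_graphml(path).n_nodes == 0
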