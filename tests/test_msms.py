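"""MS2 I/O round-trips, modified-cosine similarity and molecular-network
construction."""

import numpy as np
import networkx as nx
import pytest

from xenomet import (
    Ms2Spectrum,
    annotate_network_with_candidates,
    build_network,
    enumerate_biotransformations,
    ion_mz,
    match_coverage,
    read_spectra,
    spectral_similarity,
    write_spectra,
)
from xenomet.chem import DEFAULT_TRANSFORMATIONS
from xenomet.msms import connected_components


def spec(name, precursor, peaks, **kw):
    return Ms2Spectrum(name, precursor, np.array(peaks, float), **kw)


@pytest.fixture
def two_spectra():
    return [
        spec("a", 200.1, [[60.0, 50.0], [80.5, 100.0], [120.2, 30.0]],
             rt=5.0),
        spec("b", 310.2, [[70.1, 10.0], [150.0, 100.0]], rt=7.5,
             polarity="neg"),
    ]


class TestIo:
    @pytest.mark.parametrize("fmt", ["mgf", "msp"])
    def test_round_trip_identity(self, two_spectra, tmp_path, fmt):
        path = tmp_path / f"fix.{fmt}"
        write_spectra(two_spectra, path)
        back = read_spectra(path)
        assert len(back) == 2
        for orig, rt in zip(two_spectra, back):
            assert rt.identifier == orig.identifier
            assert rt.precursor_mz == pytest.approx(orig.precursor_mz)
            assert rt.n_peaks == orig.n_peaks
            np.testing.assert_allclose(rt.peaks, orig.peaks, atol=1e-4)
            assert rt.polarity == orig.polarity
        # write -> read -> write is byte-stable
        path2 = tmp_path / f"fix2.{fmt}"
        write_spectra(back, path2)
        assert path.read_text() == path2.read_text()

    def test_msp_missing_precursor_skipped(self, tmp_path):
        text = ("Name: broken\nNum Peaks: 1\n100.0 50.0\n\n"
                "Name: good\nPrecursorMZ: 150.0\nNum Peaks: 1\n100.0 50.0\n")
        p = tmp_path / "lib.msp"
        p.write_text(text)
        got = read_spectra(p)
        assert [s.identifier for s in got] == ["good"]

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            read_spectra(tmp_path / "x.abc")

    def test_peaks_sorted_on_construction(self):
        s = spec("s", 300.0, [[200.0, 10.0], [100.0, 20.0]])
        assert list(s.peaks[:, 0]) == [100.0, 200.0]

    def test_fragment_above_precursor_rejected(self):
        with pytest.raises(ValueError, match="precursor"):
            spec("s", 100.0, [[150.0, 10.0]])


class TestSimilarity:
    def test_self_similarity_100(self, two_spectra):
        for s in two_spectra:
            score, matched = spectral_similarity(s, s)
            assert score == pytest.approx(100.0)
            assert matched == s.n_peaks

    def test_symmetry_exact(self, two_spectra):
        a, b = two_spectra
        assert spectral_similarity(a, b) == spectral_similarity(b, a)

    def test_disjoint_no_shift_zero(self):
        a = spec("a", 200.0, [[60.0, 100.0], [70.0, 50.0]])
        b = spec("b", 200.0, [[100.0, 100.0], [110.0, 50.0]])
        assert spectral_similarity(a, b) == (0.0, 0)

    def test_hand_computed_three_peak_cosine(self):
        """Two 3-peak spectra sharing two direct matches: the score equals the
        pencil-and-paper cosine of the matched intensity products."""
        a = spec("a", 250.0, [[100.0, 80.0], [120.0, 60.0], [140.0, 20.0]])
        b = spec("b", 250.0, [[100.0, 40.0], [120.0, 90.0], [180.0, 30.0]])
        score, matched = spectral_similarity(a, b)
        dot = 80 * 40 + 60 * 90
        na = np.sqrt(80**2 + 60**2 + 20**2)
        nb = np.sqrt(40**2 + 90**2 + 30**2)
        assert matched == 2
        assert score == pytest.approx(100 * dot / (na * nb))

    def test_precursor_shift_matching(self):
        """A neutral-loss-shifted fragment set matches via the precursor
        delta (the modified-cosine property)."""
        a = spec("a", 200.0, [[100.0, 100.0], [150.0, 50.0]])
        b = spec("b", 216.0, [[116.0, 100.0], [166.0, 50.0]])  # all +16
        score, matched = spectral_similarity(a, b)
        assert matched == 2
        assert score == pytest.approx(100.0)

    def test_empty_spectrum_zero(self):
        a = spec("a", 200.0, np.empty((0, 2)))
        b = spec("b", 200.0, [[100.0, 10.0]])
        assert spectral_similarity(a, b) == (0.0, 0)

    def test_coverage_of_identical_is_100(self, two_spectra):
        for s in two_spectra:
            assert match_coverage(s, s) == pytest.approx(100.0)


def _family(n_children=4, seed=0):
    """Parent + children sharing shifted scaffold fragments."""
    rng = np.random.default_rng(seed)
    scaffold = np.sort(rng.uniform(60, 150, 6))
    inten = rng.uniform(30, 100, 6)
    parent = spec("parent", 163.12, np.column_stack([scaffold, inten]))
    out = [parent]
    for i in range(n_children):
        shift = [14.0, 16.0, -2.0, 30.0][i % 4] * (1 + i // 4)
        # perturb intensities: related but not identical spectra
        jitter = inten * rng.uniform(0.7, 1.3, len(inten))
        out.append(
            spec(f"child{i}", 163.12 + shift,
                 np.column_stack([scaffold + shift, jitter]))
        )
    return out


class TestNetwork:
    def test_scaffold_family_single_component(self):
        fam = _family(4)
        g = build_network(fam)
        comps = connected_components(g)
        assert len(comps) == 1
        assert comps[0] == {s.identifier for s in fam}

    def test_decoys_stay_singletons(self):
        fam = _family(4)
        rng = np.random.default_rng(99)
        decoys = [
            spec(f"decoy{i}", float(rng.uniform(200, 600)),
                 np.column_stack([np.sort(rng.uniform(60, 180, 8)),
                                  rng.uniform(10, 100, 8)]))
            for i in range(3)
        ]
        g = build_network(fam + decoys)
        comps = {frozenset(c) for c in connected_components(g)}
        for d in decoys:
            assert frozenset({d.identifier}) in comps

    def test_limiting_thresholds_only_duplicates(self):
        fam = _family(4)
        dup = spec("parent_copy", fam[0].precursor_mz, fam[0].peaks.copy())
        g = build_network(fam + [dup], min_score=100.0,
                          min_fragments=fam[0].n_peaks, min_coverage=100.0)
        assert set(map(frozenset, connected_components(g))) >= {
            frozenset({"parent", "parent_copy"})
        }

    def test_min_fragments_conjunction(self):
        """High cosine on two shared peaks still fails min_fragments=3."""
        a = spec("a", 200.0, [[100.0, 100.0], [150.0, 80.0]])
        b = spec("b", 200.0, [[100.0, 100.0], [150.0, 80.0]])
        g = build_network([a, b], min_score=50, min_fragments=3,
                          min_coverage=0)
        assert g.number_of_edges() == 0

    def test_order_invariance(self):
        fam = _family(5, seed=3)
        g1 = build_network(fam)
        g2 = build_network(list(reversed(fam)))
        assert set(g1.edges) == set(g2.edges)

    def test_tightening_never_adds_edges(self):
        fam = _family(5, seed=4)
        loose = build_network(fam, min_score=30, min_fragments=2,
                              min_coverage=40)
        tight = build_network(fam, min_score=60, min_fragments=4,
                              min_coverage=80)
        assert set(tight.edges) <= set(loose.edges)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_network([])


class TestNetworkAnnotation:
    def test_node_label_from_exact_mass(self):
        lactam_mz = ion_mz("C10H12N2O", "[M+H]+")
        parent_mz = ion_mz("C10H14N2", "[M+H]+")
        peaks = [[80.0, 100.0], [110.0, 50.0], [130.0, 60.0]]
        nodes = [
            spec("n_parent", parent_mz, peaks),
            spec("n_lactam", lactam_mz, [[p + lactam_mz - parent_mz, i]
                                         for p, i in peaks]),
        ]
        g = build_network(nodes, min_coverage=0)
        cands = enumerate_biotransformations("C10H14N2", max_depth=2)
        g = annotate_network_with_candidates(g, cands, DEFAULT_TRANSFORMATIONS)
        assert g.nodes["n_lactam"]["candidate_formula"] == "C10H12N2O"
        assert g.nodes["n_parent"]["candidate_formula"] == "C10H14N2"

    def test_edge_label_oxidation_shift(self):
        a = spec("a", 200.0, [[100.0, 100.0], [120.0, 50.0], [130.0, 40.0]])
        b = spec("b", 215.9949, [[115.9949, 100.0], [135.9949, 50.0],
                                 [145.9949, 40.0]])
        g = build_network([a, b], min_coverage=0)
        assert g.number_of_edges() == 1
        g = annotate_network_with_candidates(g, [], DEFAULT_TRANSFORMATIONS)
        assert g.edges["a", "b"]["transformation"] == "oxidation"

    def test_no_candidates_network_unchanged(self):
        fam = _family(3)
        g = build_network(fam)
        before = dict(g.nodes(data=True))
        g2 = annotate_network_with_candidates(g, [])
        assert dict(g2.nodes(data=True)) == before
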