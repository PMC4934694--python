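"""Structure parsing, interface annotation, and dataset-admission filters."""

import numpy as np
import pytest

from rnaiface.structures import (
    Atom,
    ComplexStructure,
    EmptyComplexError,
    InterfaceAnnotation,
    Residue,
    annotate_interfaces,
    filter_dataset,
    greedy_identity_filter,
    pairwise_identity,
    parse_complex,
    read_label_file,
    write_label_file,
)
from rnaiface.synthetic import complex_to_pdb, synth_complex

MINIMAL_PDB = """\
REMARK   2 RESOLUTION.    2.00 ANGSTROMS.
ATOM      1  CA  ALA A   1      10.000   0.000   0.000  1.00 20.00           C
ATOM      2  CA  GLY A   2      20.000   0.000   0.000  1.00 20.00           C
TER
ATOM      3  P     A R   1      10.000   3.000   0.000  1.00 20.00           P
END
"""

RNA_ONLY_PDB = """\
ATOM      1  P     A R   1      10.000   3.000   0.000  1.00 20.00           P
END
"""


def make_complex(protein_atoms, rna_atoms, resolution=2.0):
    """One protein chain with single-atom residues at given coords, one RNA chain."""
    protein = [
        Residue("A", i + 1, "A", [Atom("C", c, "CA")], "protein")
        for i, c in enumerate(protein_atoms)
    ]
    rna = [
        Residue("R", i + 1, "A", [Atom("P", c, "P")], "rna")
        for i, c in enumerate(rna_atoms)
    ]
    return ComplexStructure("test", [protein], [rna] if rna else [], resolution)


def brute_force_labels(complex_, cutoff):
    """All-pairs distance scan, independent of the KD-tree implementation."""
    rna = [a.coords for ch in complex_.rna_chains for r in ch for a in r.atoms]
    out = []
    for chain in complex_.protein_chains:
        labels = []
        for res in chain:
            dmin = min(
                (float(np.linalg.norm(a.coords - rc)) for a in res.atoms for rc in rna),
                default=np.inf,
            )
            labels.append(1 if dmin <= cutoff else 0)
        out.append(np.array(labels))
    return out


class TestParseComplex:
    def test_minimal_complex(self):
        cx = parse_complex(MINIMAL_PDB)
        assert len(cx.protein_chains) == 1
        assert len(cx.protein_chains[0]) == 2
        assert cx.protein_sequence(cx.protein_chains[0]) == "AG"
        assert len(cx.rna_chains) == 1
        assert cx.resolution == pytest.approx(2.0)

    def test_round_trip_preserves_geometry(self):
        cx = synth_complex(12, {2, 5, 9}, seed=3)
        cx2 = parse_complex(complex_to_pdb(cx), "rt")
        assert len(cx2.protein_chains[0]) == 12
        assert len(cx2.rna_chains[0]) == len(cx.rna_chains[0])
        for orig, parsed in zip(cx.protein_chains[0], cx2.protein_chains[0]):
            assert np.allclose(orig.atoms[0].coords, parsed.atoms[0].coords, atol=1e-3)

    def test_rna_only_structure_is_an_error(self):
        with pytest.raises(EmptyComplexError):
            parse_complex(RNA_ONLY_PDB)


class TestAnnotateInterfaces:
    def test_atom_within_cutoff_is_interface(self):
        cx = make_complex([(0.0, 0.0, 0.0)], [(4.9, 0.0, 0.0)])
        assert annotate_interfaces(cx, cutoff=5.0)[0].labels.tolist() == [1]

    def test_atom_beyond_cutoff_is_not(self):
        cx = make_complex([(0.0, 0.0, 0.0)], [(5.1, 0.0, 0.0)])
        assert annotate_interfaces(cx, cutoff=5.0)[0].labels.tolist() == [0]

    def test_boundary_distance_counts_as_interface(self):
        cx = make_complex([(0.0, 0.0, 0.0)], [(5.0, 0.0, 0.0)])
        assert annotate_interfaces(cx, cutoff=5.0)[0].labels.tolist() == [1]

    def test_planted_positions_recovered(self):
        cx = synth_complex(10, {3, 7}, seed=0)
        labels = annotate_interfaces(cx)[0].labels
        assert set(np.flatnonzero(labels) + 1) == {3, 7}

    def test_no_rna_yields_all_zero_labels(self, caplog):
        cx = make_complex([(0.0, 0.0, 0.0), (10.0, 0.0, 0.0)], [])
        anns = annotate_interfaces(cx)
        assert anns[0].labels.tolist() == [0, 0]

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_all_pairs_scan(self, seed, rng):
        gen = np.random.default_rng(seed)
        prot = gen.uniform(-20, 20, size=(15, 3))
        rna = gen.uniform(-20, 20, size=(6, 3))
        cx = make_complex(list(prot), list(rna))
        got = annotate_interfaces(cx, cutoff=5.0)[0].labels
        expected = brute_force_labels(cx, 5.0)[0]
        assert np.array_equal(got, expected)

    def test_invariant_under_atom_and_chain_permutation(self, rng):
        prot = rng.uniform(-15, 15, size=(10, 3))
        rna = rng.uniform(-15, 15, size=(8, 3))
        cx = make_complex(list(prot), list(rna))
        base = annotate_interfaces(cx)[0].labels
        perm = rng.permutation(len(rna))
        cx_perm = make_complex(list(prot), list(rna[perm]))
        assert np.array_equal(base, annotate_interfaces(cx_perm)[0].labels)

    def test_lowering_cutoff_never_adds_interfaces(self, rng):
        prot = rng.uniform(-15, 15, size=(12, 3))
        rna = rng.uniform(-15, 15, size=(5, 3))
        cx = make_complex(list(prot), list(rna))
        counts = [
            annotate_interfaces(cx, cutoff=c)[0].labels.sum()
            for c in (10.0, 7.0, 5.0, 3.0, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestFilterDataset:
    def test_short_chain_rejected_for_length(self):
        cx = synth_complex(39, set(range(1, 11)), seed=0)
        result = filter_dataset([cx])
        assert result.kept == []
        assert result.rejections["length"] == 1

    def test_too_few_interfaces_rejected(self):
        cx = synth_complex(60, {5, 30}, seed=0)
        result = filter_dataset([cx])
        assert result.kept == []
        assert result.rejections["interfaces"] == 1

    def test_missing_resolution_rejected(self):
        cx = synth_complex(60, {5, 30, 45}, seed=0)
        cx.resolution = None
        result = filter_dataset([cx])
        assert result.rejections["unknown resolution"] == 1

    def test_resolution_criterion_is_strict(self):
        cx = synth_complex(60, {5, 30, 45}, seed=0)
        cx.resolution = 3.5
        assert filter_dataset([cx]).rejections["resolution"] == 1
        cx.resolution = 3.49
        assert len(filter_dataset([cx]).kept) == 1

    def test_engineered_set_keeps_exactly_passing_chains(self):
        complexes = [
            synth_complex(60, {5, 30, 45}, seed=1),      # passes everything
            synth_complex(39, {5, 20, 30}, seed=2),      # too short
            synth_complex(60, {5, 30}, seed=3),          # too few interfaces
            synth_complex(80, {2, 40, 60, 70}, seed=4),  # passes everything
            synth_complex(60, set(), seed=5),            # no interfaces
        ]
        result = filter_dataset(complexes)
        assert len(result.kept) == 2
        assert sum(result.rejections.values()) == 3
        for chain, ann in result.kept:
            assert ann.n_interface >= 3
            assert len(chain) >= 40

    def test_kept_chains_are_subset_of_input(self):
        complexes = [synth_complex(50, {3, 20, 40}, seed=s) for s in range(3)]
        result = filter_dataset(complexes)
        all_chains = [c for cx in complexes for c in cx.protein_chains]
        assert all(any(kc is c for c in all_chains) for kc, _ in result.kept)
        assert len(result.kept) + sum(result.rejections.values()) == len(all_chains)


class TestGreedyIdentityFilter:
    def test_identical_sequences_collapse(self):
        assert greedy_identity_filter(["ACDEFGHIKL", "ACDEFGHIKL"]) == ["ACDEFGHIKL"]

    def test_unrelated_sequences_both_kept(self):
        a, b = "AAAAAAAAAA", "WWWWWWWWWW"
        assert pairwise_identity(a, b) == 0.0
        assert set(greedy_identity_filter([a, b])) == {a, b}

    def test_triplet_keeps_only_dissimilar_pair(self):
        a = "ACDEFGHIKLMNPQRSTVWY"
        b = "ACDEFGHIKLWYWYWYWYWY"  # well above the 30% identity cap vs a
        c = "WWHHWWHHWWHHWWHHWWHA"  # far below the cap vs both a and b
        assert pairwise_identity(a, b) == pytest.approx(0.6)
        assert pairwise_identity(a, c) <= 0.15
        kept = greedy_identity_filter([a, b, c], max_identity=0.30)
        assert set(kept) == {a, c}

    def test_deterministic(self):
        seqs = ["ACDEFGHIKL", "ACDEFGHIKV", "WYWYWYWYWY", "MNPQRSTVWY"]
        assert greedy_identity_filter(seqs) == greedy_identity_filter(seqs)


class TestLabelFileIO:
    def test_round_trip(self):
        anns = [
            InterfaceAnnotation("c1", "ACDEF", np.array([0, 1, 0, 0, 1])),
            InterfaceAnnotation("c2", "WY", np.array([1, 0])),
        ]
        parsed = read_label_file(write_label_file(anns))
        assert [a.chain_id for a in parsed] == ["c1", "c2"]
        assert parsed[0].sequence == "ACDEF"
        assert np.array_equal(parsed[0].labels, anns[0].labels)
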