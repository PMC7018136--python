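import numpy as np
import pytest

from jet2dna.descriptors import (
    PropensityTable,
    circular_variance,
    conservation_from_file,
    load_propensities,
    map_scores_to_chain,
    residue_cv,
    scale_propensities,
    structure_cv,
    tree_trace_conservation,
)
from jet2dna.fixtures import make_alignment


class TestCircularVariance:
    def test_single_neighbor_is_zero(self):
        assert circular_variance([0, 0, 0], [[3, 0, 0]], 5.0) == pytest.approx(0.0, abs=1e-12)

    def test_antipodal_pair_is_one(self):
        cv = circular_variance([0, 0, 0], [[2, 0, 0], [-2, 0, 0]], 5.0)
        assert cv == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_triple(self):
        cv = circular_variance([0, 0, 0], [[1, 0, 0], [0, 1, 0], [0, 0, 1]], 5.0)
        assert cv == pytest.approx(1.0 - np.sqrt(3.0) / 3.0, abs=1e-12)

    def test_no_neighbor_within_cutoff_is_undefined(self):
        assert circular_variance([0, 0, 0], [[10, 0, 0]], 5.0) is None

    def test_cutoff_is_inclusive(self):
        assert circular_variance([0, 0, 0], [[5.0, 0, 0]], 5.0) == pytest.approx(0.0)

    def test_rigid_motion_invariance(self, rng):
        points = rng.normal(size=(40, 3)) * 4.0
        center = points[0]
        others = points[1:]
        base = circular_variance(center, others, 8.0)
        for _ in range(100):
            q, r = np.linalg.qr(rng.normal(size=(3, 3)))
            q *= np.sign(np.diag(r))
            t = rng.normal(size=3) * 10.0
            moved = circular_variance(q @ center + t, others @ q.T + t, 8.0)
            assert moved == pytest.approx(base, abs=1e-10)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(50):
            pts = rng.normal(size=(rng.integers(2, 30), 3)) * 5.0
            cv = circular_variance(pts[0], pts[1:], 12.0)
            if cv is not None:
                assert 0.0 <= cv <= 1.0

    def test_scaling_invariance_with_scaled_cutoff(self, rng):
        pts = rng.normal(size=(20, 3)) * 3.0
        base = circular_variance(pts[0], pts[1:], 6.0)
        scaled = circular_variance(pts[0] * 2.5, pts[1:] * 2.5, 15.0)
        assert scaled == pytest.approx(base, abs=1e-10)

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            circular_variance([0, 0, 0], [[1, 0, 0]], -1.0)


class TestResidueCv:
    def test_single_atom_residue_equals_atomic_cv(self):
        all_coords = np.array([[0, 0, 0], [2, 0, 0], [0, 2, 0]])
        res = residue_cv(np.array([[0, 0, 0]]), all_coords, 5.0)
        atom = circular_variance([0, 0, 0], all_coords, 5.0)
        assert res == pytest.approx(atom)

    def test_mean_over_atoms(self):
        # construct two atoms with known CVs: one neighbor (0) and antipodal pair (1)
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0], [100.0, 0, 0], [103.0, 0, 0], [97.0, 0, 0]])
        res = residue_cv(coords[[0, 2]], coords, 5.0)
        assert res == pytest.approx(0.5)

    def test_global_radius_covers_whole_structure(self, sphere_fixture):
        structure, _ = sphere_fixture
        coords = np.concatenate([r.coords() for r in structure.residues("protein")])
        diameter = np.linalg.norm(coords.max(0) - coords.min(0))
        assert diameter < 100.0
        # with r_c >= diameter every atom sees all N-1 others: CV equals the
        # value computed with an infinite cutoff
        cv100 = structure_cv(structure, 100.0)
        cvbig = structure_cv(structure, 1e6)
        for key in cv100:
            assert cv100[key] == pytest.approx(cvbig[key], abs=1e-12)

    def test_buried_residue_more_enclosed_than_protruding(self):
        from jet2dna.fixtures import FixtureSpec, make_pseudo_protein
        from jet2dna.structure import parse_structure

        spec = FixtureSpec(seed=9, n_residues=100, n_buried=30, patch_size=8)
        pdb_text, truth = make_pseudo_protein(spec)
        s = parse_structure(pdb_text, "b")
        cvl = structure_cv(s, 12.0)
        buried = [cvl[k] for k in truth.buried if cvl[k] is not None]
        exposed = [v for k, v in cvl.items() if k not in set(truth.buried) and v is not None]
        assert np.mean(buried) > np.mean(exposed)


class TestPropensities:
    def test_shipped_table_scales_to_unit_max(self):
        table = load_propensities()
        assert max(table.raw.values()) == pytest.approx(2.534)
        assert max(table.scaled.values()) == pytest.approx(1.0)
        assert min(table.scaled.values()) >= 0.0

    def test_linear_scaling(self):
        raw = {aa: 0.0 for aa in "ACDEFGHIKLMNPQRSTVWY"}
        raw["R"] = 2.534
        raw["K"] = 1.267
        scaled = scale_propensities(raw)
        assert scaled["R"] == pytest.approx(1.0)
        assert scaled["K"] == pytest.approx(0.5)
        assert scaled["A"] == 0.0

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            scale_propensities({aa: 0.0 for aa in "ACDEFGHIKLMNPQRSTVWY"})

    def test_wrong_entry_count_rejected(self):
        with pytest.raises(ValueError):
            PropensityTable(raw={"A": 1.0})


class TestConservationFile:
    def test_clamping_passthrough_and_default(self, tmp_path):
        path = tmp_path / "cons.tsv"
        path.write_text("A\t1\t1.2\nA\t2\t0.35\nA\t10B\t0.5\n")
        scores = conservation_from_file(str(path))
        assert scores[("A", 1, "")] == 1.0  # clamped
        assert scores[("A", 2, "")] == 0.35
        assert scores[("A", 10, "B")] == 0.5
        assert ("A", 3, "") not in scores  # absent -> defaulted downstream

    def test_malformed_line_reports_position(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("A\t1\t0.5\nnot a line\n")
        with pytest.raises(ValueError, match="line 2"):
            conservation_from_file(str(path))


class TestTreeTrace:
    def test_fully_conserved_column_traces_to_one(self):
        aln, tree, truth = make_alignment(12, 40, conserved_columns=[0, 5], noise=0.4, seed=3)
        scores = tree_trace_conservation(aln, "query", trees=[tree])
        assert scores[0] == pytest.approx(1.0)
        assert scores[5] == pytest.approx(1.0)
        # conserved columns dominate every other column
        assert scores[0] >= scores.max() - 1e-12

    def test_query_unique_amino_acid_traces_to_zero(self):
        from Bio.Align import MultipleSeqAlignment
        from Bio.Phylo.BaseTree import Clade, Tree
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        # 4-leaf balanced tree: ((query,a),(b,c))
        inner1 = Clade(branch_length=1.0)
        inner1.clades = [Clade(branch_length=1.0, name="query"),
                         Clade(branch_length=1.0, name="a")]
        inner2 = Clade(branch_length=1.0)
        inner2.clades = [Clade(branch_length=1.0, name="b"),
                         Clade(branch_length=1.0, name="c")]
        root = Clade()
        root.clades = [inner1, inner2]
        tree = Tree(root=root, rooted=True)

        # col0: query-only; col1: conserved in query's 2-leaf clade; col2: all
        aln = MultipleSeqAlignment([
            SeqRecord(Seq("WWA"), id="query"),
            SeqRecord(Seq("CWA"), id="a"),
            SeqRecord(Seq("CCA"), id="b"),
            SeqRecord(Seq("CCA"), id="c"),
        ])
        scores = tree_trace_conservation(aln, "query", trees=[tree])
        assert scores[0] == pytest.approx(0.0)
        assert scores[1] == pytest.approx(0.5)  # conserved one level up of two
        assert scores[2] == pytest.approx(1.0)

    def test_deterministic_given_seed(self):
        aln, _, _ = make_alignment(15, 30, conserved_columns=5, noise=0.2, seed=8)
        a = tree_trace_conservation(aln, "query", seed=4, n_samples=3, sample_size=8)
        b = tree_trace_conservation(aln, "query", seed=4, n_samples=3, sample_size=8)
        assert np.array_equal(a, b)

    def test_query_absent_and_tiny_alignment_rejected(self):
        aln, _, _ = make_alignment(5, 10, conserved_columns=2, noise=0.2, seed=1)
        with pytest.raises(ValueError):
            tree_trace_conservation(aln, "missing")
        from Bio.Align import MultipleSeqAlignment

        small = MultipleSeqAlignment([aln[0], aln[1]])
        with pytest.raises(ValueError):
            tree_trace_conservation(small, "query")


def test_map_scores_to_chain_requires_matching_length(sphere_fixture):
    structure, _ = sphere_fixture
    n = len(structure.chains["A"])
    mapped = map_scores_to_chain(np.linspace(0, 1, n), structure, "A")
    assert len(mapped) == n
    with pytest.raises(ValueError):
        map_scores_to_chain(np.zeros(n - 1), structure, "A")
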