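"""Domain trimming, column filtering, distances, NJ and bootstrap."""

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from dlhscan.classifier import DomainHit
from dlhscan.phylogeny import (
    PhylogenyError,
    bootstrap_support,
    distance_matrix,
    extract_domain_region,
    filter_columns,
    from_newick,
    neighbor_joining,
    to_newick,
    tree_bipartitions,
)
from dlhscan.seq_core import Alignment, ProteinRecord
from dlhscan.synthetic import (
    generate_family_alignment,
    generate_two_clade_alignment,
    random_additive_tree,
)


class TestExtractDomain:
    def test_coordinates(self):
        rec = ProteinRecord("r", "A" * 300)
        out = extract_domain_region(rec, DomainHit(51, 250, 10.0))
        assert len(out.residues) == 200 and out.id == "r/51-250"

    def test_full_span_identity(self):
        rec = ProteinRecord("r", "MKVLACDE")
        out = extract_domain_region(rec, DomainHit(1, 8, 1.0))
        assert out.residues == rec.residues

    def test_two_hits_distinct_ids(self):
        rec = ProteinRecord("r", "MKVLACDEMKVLACDE")
        a = extract_domain_region(rec, DomainHit(1, 8, 1.0))
        b = extract_domain_region(rec, DomainHit(9, 16, 1.0))
        assert a.id != b.id and a.residues == b.residues

    def test_out_of_range_error(self):
        with pytest.raises(PhylogenyError):
            extract_domain_region(ProteinRecord("r", "MKVL"), DomainHit(2, 9, 1.0))


def _gapped_alignment(n_rows, length, gap_prob, seed):
    rng = np.random.default_rng(seed)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    rows = []
    for i in range(n_rows):
        chars = [
            "-" if rng.random() < gap_prob else aa[int(rng.integers(20))]
            for _ in range(length)
        ]
        rows.append(ProteinRecord(f"s{i}", "".join(chars)))
    return Alignment(rows)


class TestFilterColumns:
    def test_boundary_at_exactly_ten(self):
        # column 0: 10 residues (kept); column 1: 9 residues (removed)
        rows = []
        for i in range(20):
            c0 = "A" if i < 10 else "-"
            c1 = "C" if i < 9 else "-"
            rows.append(ProteinRecord(f"s{i}", c0 + c1 + "DD"))
        out = filter_columns(Alignment(rows), min_occupancy=10)
        assert out.length == 3
        assert out.records[0].residues == "ADD"

    def test_gapless_alignment_unchanged(self):
        aln = _gapped_alignment(12, 30, 0.0, 1)
        out = filter_columns(aln, min_occupancy=10)
        assert out.length == aln.length

    def test_occupancy_property_and_idempotence(self):
        aln = _gapped_alignment(15, 60, 0.5, 7)
        out = filter_columns(aln, min_occupancy=10)
        for j in range(out.length):
            assert sum(c != "-" for c in out.column(j)) >= 10
        again = filter_columns(out, min_occupancy=10)
        assert [r.residues for r in again.records] == [r.residues for r in out.records]

    def test_all_columns_removed_error(self):
        aln = _gapped_alignment(5, 20, 0.9, 3)
        with pytest.raises(PhylogenyError):
            filter_columns(aln, min_occupancy=5)


class TestDistances:
    def _aln(self, *rows):
        return Alignment([ProteinRecord(f"s{i}", r) for i, r in enumerate(rows)])

    def test_identical_rows_zero(self):
        dm = distance_matrix(self._aln("MKVL", "MKVL", "MKVL"))
        assert np.allclose(dm.data, 0.0)

    def test_poisson_closed_form(self):
        dm = distance_matrix(self._aln("AAAA", "AAAC", "CCCC"), model="poisson")
        assert dm["s0", "s1"] == pytest.approx(-np.log(0.75))

    def test_kimura_closed_form(self):
        dm = distance_matrix(self._aln("AAAA", "AAAC", "CCCC"), model="kimura_protein")
        assert dm["s0", "s1"] == pytest.approx(-np.log(1 - 0.25 - 0.2 * 0.25**2))

    def test_model_ordering(self):
        aln = _gapped_alignment(6, 120, 0.0, 11)
        p = distance_matrix(aln, model="p_distance").condensed_form()
        po = distance_matrix(aln, model="poisson").condensed_form()
        ki = distance_matrix(aln, model="kimura_protein").condensed_form()
        assert np.all(p <= po + 1e-12) and np.all(po <= ki + 1e-12)

    def test_saturated_pair_capped(self):
        dm = distance_matrix(self._aln("AAAA", "CCCC", "DDDD"), model="poisson")
        assert dm["s0", "s1"] == 10.0

    def test_disjoint_gap_pattern_error(self):
        with pytest.raises(PhylogenyError):
            distance_matrix(self._aln("AA--", "--CC", "AACC"))


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float), ids=list("abc")
        )
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"a": 1.0, "b": 1.0, "c": 3.0})

    def test_additive_tree_recovery(self):
        for seed in range(30):
            n = 4 + seed % 7
            true_tree, dm = random_additive_tree(n, seed=seed)
            out = neighbor_joining(dm)
            assert tree_bipartitions(out) == tree_bipartitions(true_tree)
            recovered = out.tip_tip_distances().filter(dm.ids)
            assert np.allclose(recovered.data, dm.data, atol=1e-9)

    def test_matches_skbio_topology(self):
        _, dm = random_additive_tree(9, seed=99)
        ours = neighbor_joining(dm)
        theirs = from_newick(str(skbio_nj(dm)))
        assert tree_bipartitions(ours) == tree_bipartitions(theirs)

    def test_tie_determinism(self):
        d = np.array(
            [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], float
        )
        dm = DistanceMatrix(d, ids=list("abcd"))
        t1 = to_newick(neighbor_joining(dm))
        t2 = to_newick(neighbor_joining(dm))
        assert t1 == t2

    def test_too_few_taxa_rejected(self):
        with pytest.raises((PhylogenyError, ValueError)):
            neighbor_joining(DistanceMatrix(np.zeros((2, 2)), ids=list("ab")))


class TestBootstrap:
    def test_two_clades_high_support(self):
        aln = generate_two_clade_alignment(n_per_clade=2, seed=13)
        tree = bootstrap_support(aln, n_replicates=200, seed=4)
        supports = [int(n.name) for n in tree.non_tips(include_self=False) if n.name]
        assert supports and min(supports) >= 95

    def test_single_replicate_support_binary(self):
        aln, _ = generate_family_alignment(n_leaves=6, seed=21)
        tree = bootstrap_support(aln, n_replicates=1, seed=2)
        supports = [int(n.name) for n in tree.non_tips(include_self=False) if n.name]
        assert set(supports) <= {0, 100}

    def test_seed_reproducibility(self):
        aln, _ = generate_family_alignment(n_leaves=6, seed=22)
        t1 = to_newick(bootstrap_support(aln, n_replicates=50, seed=5))
        t2 = to_newick(bootstrap_support(aln, n_replicates=50, seed=5))
        assert t1 == t2


class TestNewick:
    def test_three_leaf_form(self):
        dm = DistanceMatrix(
            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float), ids=list("abc")
        )
        text = to_newick(neighbor_joining(dm))
        assert text.endswith(";") and "a:1" in text.replace(".0", "")

    def test_round_trip_random_tree(self):
        true_tree, dm = random_additive_tree(20, seed=17)
        text = to_newick(true_tree)
        back = from_newick(text)
        assert tree_bipartitions(back) == tree_bipartitions(true_tree)
        d1 = back.tip_tip_distances().filter(dm.ids)
        assert np.allclose(d1.data, dm.data, atol=1e-6)

    def test_support_labels_parsed(self):
        tree = from_newick("(a:1,(b:0.5,c:0.5)95:0.1,d:2);")
        labels = [n.name for n in tree.non_tips(include_self=False)]
        assert "95" in labels

    def test_malformed_error(self):
        with pytest.raises(PhylogenyError):
            from_newick("((a:1,b:2;")
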