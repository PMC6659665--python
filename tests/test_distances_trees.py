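"""Model distances, correlation profiles, neighbor joining and RF
distance: closed-form checks, simulator-calibrated recovery, and
independent cross-checks against dendropy."""

import itertools
import math
import random

import dendropy
import numpy as np
import pytest

from dendromito.distances_trees import (
    DistanceMatrix,
    _bipartitions,
    distance_matrix,
    group_distance,
    neighbor_joining,
    pairwise_distance,
    read_newick,
    rf_distance,
    row_correlation,
)
from dendromito.errors import DendromitoError, SaturationError
from dendromito.synthetic_data import simulate_pair


def _random_pair(rng, n, p):
    a = "".join(rng.choice("ACGT") for _ in range(n))
    b = "".join(
        (rng.choice([c2 for c2 in "ACGT" if c2 != c]) if rng.random() < p else c)
        for c in a
    )
    return a, b


class TestPairwiseDistance:
    def test_identical_rows_zero_under_every_model(self):
        row = "ACGT" * 50
        for model in ("p", "jc69", "k80", "gtr"):
            assert pairwise_distance(row, row, model) == pytest.approx(0.0, abs=1e-8)

    def test_jc69_closed_form(self):
        a = "A" * 100
        b = "A" * 90 + "C" * 10
        expected = -0.75 * math.log(1 - 0.4 / 3)
        assert pairwise_distance(a, b, "jc69") == pytest.approx(
            expected, abs=1e-9
        )

    def test_jc69_exceeds_p_and_is_monotone(self):
        rng = random.Random(0)
        last = 0.0
        for p in (0.05, 0.15, 0.30, 0.50, 0.70):
            a, b = _random_pair(rng, 4000, p)
            p_obs = pairwise_distance(a, b, "p")
            d = pairwise_distance(a, b, "jc69")
            assert d >= p_obs
            assert d > last
            last = d

    def test_jc69_saturation_flagged(self):
        a = "A" * 100
        b = "C" * 100
        with pytest.raises(SaturationError):
            pairwise_distance(a, b, "jc69")

    def test_pairwise_deletion_of_gaps_and_ns(self):
        a = "ACGTACGTA-"
        b = "ACGTACGTNN"
        assert pairwise_distance(a, b, "p") == 0.0
        with pytest.raises(DendromitoError):
            pairwise_distance("----", "AAAA", "p")

    def test_gtr_reduces_to_jc69_with_equal_parameters(self):
        rng = random.Random(3)
        for p in (0.02, 0.10, 0.25):
            a, b = _random_pair(rng, 6000, p)
            dj = pairwise_distance(a, b, "jc69")
            dg = pairwise_distance(
                a, b, "gtr", freqs=[0.25] * 4, rates=[1.0] * 6
            )
            assert dg == pytest.approx(dj, abs=1e-6)

    def test_k80_on_pure_transversion_free_data(self):
        # transitions only (A<->G): K80's P-term dominates and the
        # estimate must exceed the raw p-distance
        a = "AG" * 500 + "C" * 200
        b = "GA" * 500 + "C" * 200
        with pytest.raises(SaturationError):
            pairwise_distance(a, b, "k80")  # P = 5/6 is saturated
        rng = random.Random(4)
        a2, b2 = _random_pair(rng, 5000, 0.1)
        assert pairwise_distance(a2, b2, "k80") >= pairwise_distance(a2, b2, "p")

    @pytest.mark.parametrize("d_true", [0.01, 0.05, 0.12])
    def test_gtr_recovery_within_five_percent(self, d_true):
        # simulator as oracle: 100 replicate 15 kb pairs per true distance
        rng = np.random.default_rng(int(d_true * 1000))
        estimates = [
            pairwise_distance(*simulate_pair(d_true, 15000, rng), "gtr")
            for _ in range(100)
        ]
        rel_bias = (np.mean(estimates) - d_true) / d_true
        assert abs(rel_bias) < 0.05


class TestDistanceMatrix:
    def test_identical_taxa_zero_matrix(self):
        rows = {k: "ACGT" * 25 for k in "abc"}
        dm = distance_matrix(rows, "jc69")
        assert np.allclose(dm.matrix, 0.0)

    def test_symmetry_and_zero_diagonal(self):
        rng = random.Random(5)
        rows = {
            f"t{i}": "".join(rng.choice("ACGT") for _ in range(300))
            for i in range(5)
        }
        dm = distance_matrix(rows, "p")
        assert np.allclose(dm.matrix, dm.matrix.T)
        assert np.allclose(np.diag(dm.matrix), 0.0)

    def test_saturated_pairs_flagged_not_raised(self):
        rows = {"a": "A" * 50, "b": "C" * 50, "c": "A" * 50}
        dm = distance_matrix(rows, "jc69")
        assert ("a", "b") in dm.saturated
        assert np.isnan(dm.get("a", "b"))

    def test_two_clade_structure_recovered(self, preset_bundle):
        rows = {r.id: r.sequence for r in preset_bundle.records}
        dm = distance_matrix(rows, "gtr")
        within = dm.get("MW04", "MW05")
        assert within == pytest.approx(0.002, abs=0.002)
        between = dm.get("MW04", "SM12")
        assert between > 10 * within


class TestGroupDistance:
    @pytest.fixture()
    def dm(self):
        ids = ["a", "b", "c"]
        mat = np.array([[0, 0.02, 0.04], [0.02, 0, 0.06], [0.04, 0.06, 0]])
        return DistanceMatrix(ids, mat, "p")

    def test_singleton_groups_identity(self, dm):
        gdm = group_distance(dm, {"A": ["a"], "B": ["b"], "C": ["c"]})
        assert np.allclose(gdm.matrix, dm.matrix)

    def test_mean_linkage(self, dm):
        gdm = group_distance(dm, {"AB": ["a", "b"], "C": ["c"]})
        assert gdm.get("AB", "C") == pytest.approx(0.05)
        gmin = group_distance(dm, {"AB": ["a", "b"], "C": ["c"]}, "min")
        assert gmin.get("AB", "C") == pytest.approx(0.04)

    def test_empty_group_raises(self, dm):
        with pytest.raises(DendromitoError):
            group_distance(dm, {"A": [], "B": ["b"]})


class TestRowCorrelation:
    def test_identical_profiles_correlate_perfectly(self):
        ids = ["a", "b", "c", "d", "e"]
        mat = np.zeros((5, 5))
        # a and b sit at the same point; their distances to c, d, e match
        coords = {"a": 0.0, "b": 0.0, "c": 1.0, "d": 2.0, "e": 4.0}
        for i, x in enumerate(ids):
            for j, y in enumerate(ids):
                mat[i, j] = abs(coords[x] - coords[y])
        cm = row_correlation(DistanceMatrix(ids, mat, "p"))
        assert cm.get("a", "b") == pytest.approx(1.0)

    def test_anticorrelated_profiles(self):
        ids = ["a", "b", "c", "d", "e"]
        mat = np.zeros((5, 5))
        prof_a = {"c": 0.1, "d": 0.2, "e": 0.3}
        for j, y in enumerate(ids[2:], start=2):
            mat[0, j] = mat[j, 0] = prof_a[y]
            mat[1, j] = mat[j, 1] = 0.5 - prof_a[y]  # x -> -x + const
        mat[0, 1] = mat[1, 0] = 0.25
        cm = row_correlation(DistanceMatrix(ids, mat, "p"))
        assert cm.get("a", "b") == pytest.approx(-1.0)

    def test_matches_brute_force_pearson(self):
        rng = np.random.default_rng(11)
        n = 6
        ids = [f"t{i}" for i in range(n)]
        mat = rng.random((n, n))
        mat = (mat + mat.T) / 2
        np.fill_diagonal(mat, 0.0)
        cm = row_correlation(DistanceMatrix(ids, mat, "p"))
        for i, j in itertools.combinations(range(n), 2):
            ks = [k for k in range(n) if k not in (i, j)]
            x = mat[i, ks] - mat[i, ks].mean()
            y = mat[j, ks] - mat[j, ks].mean()
            expected = (x @ y) / math.sqrt((x @ x) * (y @ y))
            assert cm.matrix[i, j] == pytest.approx(expected)

    def test_too_few_taxa_raises(self):
        mat = np.zeros((3, 3))
        with pytest.raises(DendromitoError):
            row_correlation(DistanceMatrix(["a", "b", "c"], mat, "p"))


def _additive_matrix_from_tree(newick):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    ids = [t.label for t in taxa]
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(ids, mat, "true"), tree


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        ids = ["a", "b", "c"]
        mat = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        tree = neighbor_joining(DistanceMatrix(ids, mat, "p"))
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_additive_four_taxon_matrix_recovers_tree(self):
        newick = "((a:0.1,b:0.2):0.05,(c:0.15,d:0.3):0.05);"
        dm, truth = _additive_matrix_from_tree(newick)
        tree = neighbor_joining(dm)
        assert rf_distance(tree, truth) == 0
        # on an additive matrix NJ recovers the exact branch lengths
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["d"] == pytest.approx(0.3)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dendropy_on_random_additive_matrices(self, seed):
        rng = random.Random(seed)
        taxa = [f"t{i}" for i in range(7)]
        rng.shuffle(taxa)
        # random additive tree
        parts = [f"{t}:{rng.uniform(0.05, 0.3):.3f}" for t in taxa]
        while len(parts) > 3:
            i, j = sorted(rng.sample(range(len(parts)), 2), reverse=True)
            merged = (
                f"({parts[i]},{parts[j]}):{rng.uniform(0.02, 0.2):.3f}"
            )
            del parts[i]  # i > j, so j stays valid
            del parts[j]
            parts.append(merged)
        newick = f"({','.join(parts)});"
        dm, truth = _additive_matrix_from_tree(newick)
        mine = neighbor_joining(dm)
        assert rf_distance(mine, truth) == 0
        # independent implementation agrees
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=_dm_to_csv(dm), delimiter=","
        )
        theirs = dendropy.Tree.get(
            data=pdm.nj_tree().as_string(schema="newick"), schema="newick"
        )
        assert rf_distance(mine, theirs) == 0

    def test_saturated_matrix_raises_with_advice(self):
        mat = np.array(
            [[0, 0.1, np.nan], [0.1, 0, 0.2], [np.nan, 0.2, 0]]
        )
        with pytest.raises(SaturationError, match="model"):
            neighbor_joining(DistanceMatrix(["a", "b", "c"], mat, "jc69"))

    def test_consistency_with_sequence_length(self):
        # RF distance to the truth shrinks as simulated sequences grow
        from dendromito.synthetic_data import (
            DEFAULT_EXCHANGEABILITIES,
            DEFAULT_FREQS,
            SimulationConfig,
            default_layout,
            simulate_bundle,
        )

        layout, junctions = default_layout()
        rng = np.random.default_rng(2)
        newick = (
            "((a:0.02,b:0.04):0.01,(c:0.03,d:0.05):0.01,e:0.06);"
        )
        truth = read_newick(newick)
        rfs = {}
        for nsites, label in ((1000, "short"), (15000, "long")):
            # subsample alignment columns from one full-genome simulation
            cfg = SimulationConfig(
                tree_newick=newick, layout=layout, junctions=junctions,
                seed=7,
            )
            bundle = simulate_bundle(cfg)
            rows = {
                r.id: r.sequence[:nsites] for r in bundle.records
            }
            dm = distance_matrix(rows, "jc69")
            rfs[label] = rf_distance(neighbor_joining(dm), truth)
        assert rfs["long"] == 0
        assert rfs["long"] <= rfs["short"]


def _dm_to_csv(dm):
    import io

    buf = io.StringIO()
    buf.write("," + ",".join(dm.ids) + "\n")
    for i, rid in enumerate(dm.ids):
        buf.write(rid + "," + ",".join(str(v) for v in dm.matrix[i]) + "\n")
    buf.seek(0)
    return buf


class TestRFDistance:
    def test_identical_trees(self):
        t = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        t2 = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        assert rf_distance(t, t2) == 0

    def test_conflicting_quartets(self):
        t1 = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
        t2 = read_newick("((a:1,c:1):1,(b:1,d:1):1);")
        assert rf_distance(t1, t2) == 2

    def test_leaf_set_mismatch_raises(self):
        t1 = read_newick("((a:1,b:1):1,c:1);")
        t2 = read_newick("((a:1,b:1):1,d:1);")
        with pytest.raises(DendromitoError):
            rf_distance(t1, t2)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_set_comparison_oracle(self, seed):
        rng = random.Random(100 + seed)

        def random_tree(taxa):
            parts = [f"{t}:1" for t in taxa]
            while len(parts) > 3:
                i, j = sorted(rng.sample(range(len(parts)), 2), reverse=True)
                merged = f"({parts[i]},{parts[j]}):1"
                del parts[i]  # i > j, so j stays valid
                del parts[j]
                parts.append(merged)
            return read_newick(f"({','.join(parts)});")

        taxa = [f"t{i}" for i in range(8)]
        t1, t2 = random_tree(list(taxa)), random_tree(list(taxa))
        # oracle: explicit symmetric difference of the bipartition sets
        expected = len(_bipartitions(t1) ^ _bipartitions(t2))
        assert rf_distance(t1, t2) == expected
        # and dendropy's own count agrees once both trees share a namespace
        ns = dendropy.TaxonNamespace()
        u1 = dendropy.Tree.get(
            data=t1.as_string(schema="newick"), schema="newick",
            taxon_namespace=ns,
        )
        u2 = dendropy.Tree.get(
            data=t2.as_string(schema="newick"), schema="newick",
            taxon_namespace=ns,
        )
        u1.encode_bipartitions()
        u2.encode_bipartitions()
        assert rf_distance(t1, t2) == (
            dendropy.calculate.treecompare.symmetric_difference(u1, u2)
        )
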