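"""The synthetic mitogenome generator: layout fidelity, composition,
determinism, substitution calibration against the transition-matrix
expectation, and indel re-coordination."""

import numpy as np
import pytest

from dendromito.composition import composition_profile
from dendromito.distances_trees import pairwise_distance
from dendromito.errors import ConfigError
from dendromito.genome_model import PCG
from dendromito.organization import (
    compute_junctions,
    codon_survey,
    gene_order_signature,
    overlap_summary,
)
from dendromito.synthetic_data import (
    SimulationConfig,
    build_ancestor,
    default_layout,
    evolve,
    expected_p_distance,
    paper_shaped_preset,
    simulate_bundle,
    simulate_pair,
    write_bundle,
)

TWO_LEAF = "(A:0.025,B:0.025);"


@pytest.fixture(scope="module")
def layout_and_junctions():
    return default_layout()


def _config(layout_and_junctions, **kw):
    layout, junctions = layout_and_junctions
    return SimulationConfig(
        tree_newick=kw.pop("tree", TWO_LEAF),
        layout=layout,
        junctions=junctions,
        **kw,
    )


class TestAncestor:
    def test_layout_echoes_real_genome_structure(self, layout_and_junctions):
        anc = build_ancestor(_config(layout_and_junctions, seed=0))
        assert len(anc.features) == 38
        assert anc.genome_length == 15417
        ledger = compute_junctions(anc)
        count, lo, hi = overlap_summary(ledger)
        assert (count, lo, hi) == (6, 1, 8)
        overlaps = sorted(
            j.signed_length for j in ledger.junctions if j.signed_length < 0
        )
        assert overlaps == [-8, -7, -3, -2, -1, -1]
        assert gene_order_signature(anc)[1] == "standard"

    def test_at_content_near_target(self, layout_and_junctions):
        # stop-codon rejection in PCG bodies nudges composition slightly
        # off-target, so the band is wider than the binomial bound alone
        cfg = _config(layout_and_junctions, seed=1)
        anc = build_ancestor(cfg)
        at = composition_profile(anc.sequence).at_content
        assert abs(at - cfg.at_content) < 0.015

    def test_valid_codons_and_no_internal_stops(self, layout_and_junctions):
        cfg = _config(layout_and_junctions, seed=2)
        anc = build_ancestor(cfg)
        survey = codon_survey(anc)
        assert survey.start_codons == cfg.start_codons
        from dendromito.genome_model import extract_gene_sequence

        for feat in anc.features:
            if feat.category != PCG:
                continue
            sense = extract_gene_sequence(anc, feat)
            body = sense[: len(sense) - len(sense) % 3][:-3]
            codons = {body[k : k + 3] for k in range(0, len(body), 3)}
            assert not codons & {"TAA", "TAG"}, feat.name

    def test_same_seed_identical_ancestor(self, layout_and_junctions):
        a = build_ancestor(_config(layout_and_junctions, seed=9))
        b = build_ancestor(_config(layout_and_junctions, seed=9))
        assert a.sequence == b.sequence

    def test_inconsistent_layout_rejected(self, layout_and_junctions):
        layout, junctions = layout_and_junctions
        bad = SimulationConfig(
            tree_newick=TWO_LEAF,
            layout=layout,
            junctions=junctions[:-2],
        )
        with pytest.raises(ConfigError):
            bad.validate()
        with pytest.raises(ConfigError):
            SimulationConfig(
                tree_newick=TWO_LEAF, layout=layout, junctions=junctions,
                freqs=(0.5, 0.5, 0.5, 0.5),
            ).validate()


class TestEvolve:
    def test_zero_length_branches_keep_ancestor(self, layout_and_junctions):
        cfg = _config(layout_and_junctions, tree="(A:0.0,B:0.0);", seed=3)
        bundle = simulate_bundle(cfg)
        for rec in bundle.records:
            assert rec.sequence == bundle.ancestor.sequence

    def test_observed_p_matches_transition_matrix_expectation(
        self, layout_and_junctions
    ):
        # aggregate over 40 two-leaf replicates at d = 0.05: the mean
        # observed mismatch proportion must sit within 3 binomial SE of
        # the closed-form expectation
        d = 0.05
        expected = expected_p_distance(d)
        rng = np.random.default_rng(13)
        length = 15000
        obs = []
        for _ in range(40):
            a, b = simulate_pair(d, length, rng)
            obs.append(sum(x != y for x, y in zip(a, b)) / length)
        se = np.sqrt(expected * (1 - expected) / (length * len(obs)))
        assert abs(np.mean(obs) - expected) < 3 * se

    def test_indel_free_runs_preserve_layout(self, layout_and_junctions):
        cfg = _config(layout_and_junctions, seed=4)
        bundle = simulate_bundle(cfg)
        anc_led = compute_junctions(bundle.ancestor)
        for rec in bundle.records:
            assert rec.genome_length == bundle.ancestor.genome_length
            led = compute_junctions(rec)
            assert [
                (j.upstream_gene, j.downstream_gene, j.signed_length)
                for j in led.junctions
            ] == [
                (j.upstream_gene, j.downstream_gene, j.signed_length)
                for j in anc_led.junctions
            ]

    @pytest.mark.parametrize("seed", range(4))
    def test_indels_only_noncoding_and_conserve_accounting(
        self, layout_and_junctions, seed
    ):
        cfg = _config(
            layout_and_junctions,
            tree="(A:0.05,(B:0.04,C:0.02):0.03);",
            indel_rate=0.05,
            seed=seed,
        )
        bundle = simulate_bundle(cfg)
        changed = False
        for rec in bundle.records:
            led = compute_junctions(rec)
            total = sum(
                f.length(rec.genome_length) for f in rec.features
            ) + sum(j.signed_length for j in led.junctions)
            assert total == rec.genome_length
            for feat in rec.features:
                if feat.category in ("PCG", "tRNA", "rRNA"):
                    anc_feat = bundle.ancestor.feature(feat.name)
                    assert feat.length() == anc_feat.length(), feat.name
            changed |= rec.genome_length != bundle.ancestor.genome_length
        assert changed  # at this rate some indel must have landed

    def test_missing_multiplier_is_config_error(self, layout_and_junctions):
        cfg = _config(layout_and_junctions, seed=5)
        cfg.rate_multipliers = {"tRNA": 1.0}
        with pytest.raises(ConfigError, match="multiplier"):
            evolve(build_ancestor(_config(layout_and_junctions, seed=5)), cfg)

    def test_stationary_frequencies_approached_on_long_branches(
        self, layout_and_junctions
    ):
        cfg = _config(layout_and_junctions, tree="(A:3.0,B:3.0);", seed=6)
        bundle = simulate_bundle(cfg)
        prof = composition_profile(bundle.records[0].sequence)
        freqs = cfg.freqs
        n = prof.total
        for observed, expected in zip(
            (prof.a, prof.c, prof.g, prof.t), freqs
        ):
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(observed / n - expected) < 5 * se


class TestPreset:
    def test_truth_tree_contains_both_clades(self):
        cfg = paper_shaped_preset(seed=0)
        tree = simulate_bundle(cfg).tree
        leaf_sets = []
        for node in tree.preorder_node_iter():
            if not node.is_leaf() and node.parent_node is not None:
                leaf_sets.append(
                    frozenset(lf.taxon.label for lf in node.leaf_iter())
                )
        assert frozenset({"SM12", "SM22", "YN05", "YN11"}) in leaf_sets
        assert (
            frozenset({"CS02", "CS13", "MW04", "MW05", "WS03", "WS06",
                       "YS06", "YS38"}) in leaf_sets
        )

    def test_group_distance_ordering(self, preset_bundle):
        truth = preset_bundle.true_distances
        d_cs = np.mean(
            [truth.get(a, b) for a in ("CS02", "CS13")
             for b in ("MW04", "YS06")]
        )
        d_ly = np.mean(
            [truth.get(a, b) for a in ("LY04", "LY08")
             for b in ("MW04", "YS06")]
        )
        assert d_cs < d_ly
        assert d_cs == pytest.approx(0.05, abs=0.01)
        assert d_ly == pytest.approx(0.07, abs=0.01)

    def test_true_distance_range_is_congeneric(self, preset_bundle):
        mat = preset_bundle.true_distances.matrix
        off = mat[np.triu_indices(mat.shape[0], 1)]
        assert off.min() == pytest.approx(0.002, abs=0.0005)
        assert off.max() < 0.125

    def test_repeat_run_is_byte_identical(self, tmp_path):
        p1 = write_bundle(
            simulate_bundle(paper_shaped_preset(seed=11)), tmp_path / "a"
        )
        p2 = write_bundle(
            simulate_bundle(paper_shaped_preset(seed=11)), tmp_path / "b"
        )
        assert p1["fasta"].read_bytes() == p2["fasta"].read_bytes()
        assert p1["annotations"].read_bytes() == p2["annotations"].read_bytes()
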