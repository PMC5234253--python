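import numpy as np
import pytest

from ohnotrace.synthetic_data import (
    QUERY_FAMILY,
    SUBLINEAGE_CUP2,
    SimulationConfig,
    apply_truncation,
    evolve_sequence,
    read_config,
    simulate,
    write_simulation,
)

#: small, fast study system: 4 leaves (2 post-WGD), 8 background families
SMALL = dict(
    species_tree="((wgda:0.1,wgdb:0.1)postwgd:0.3,(prea:0.1,preb:0.1)preclade:0.3);",
    n_background_families=8,
    ancestral_query_len=300,
    conserved_prefix_len=60,
    truncation_target_range=(120, 180),
    background_len_range=(80, 120),
)


def small_config(**kw):
    return SimulationConfig(**{**SMALL, **kw})


class TestSimulate:
    def test_copy_number_conservation(self):
        db, truth = simulate(small_config(retention_prob=1.0, indel_rate=0.0, seed=3))
        for g in db.genomes:
            n_query = sum(
                1 for o in g.orfs if truth.family_membership[o.orf_id] == QUERY_FAMILY
            )
            assert n_query == (2 if g.pre_post_wgd == "post" else 1)

    def test_same_seed_identical_output(self):
        db1, t1 = simulate(small_config(seed=9))
        db2, t2 = simulate(small_config(seed=9))
        assert {o: r.protein_seq for o, r in db1.orf_index.items()} == {
            o: r.protein_seq for o, r in db2.orf_index.items()
        }
        assert t1.sublineage == t2.sublineage
        assert t1.ohnolog_pairs == t2.ohnolog_pairs

    def test_different_seed_differs(self):
        db1, _ = simulate(small_config(seed=1))
        db2, _ = simulate(small_config(seed=2))
        assert {o.protein_seq for o in db1.orf_index.values()} != {
            o.protein_seq for o in db2.orf_index.values()
        }

    def test_zero_divergence_family_identical(self):
        cfg = small_config(sub_rate=0.0, indel_rate=0.0, truncation_target_range=None, seed=4)
        db, truth = simulate(cfg)
        seqs = {db[o].protein_seq for o in truth.query_members()}
        assert len(seqs) == 1

    def test_ohnolog_pairs_only_post_wgd(self):
        db, truth = simulate(small_config(seed=5))
        post_ids = {
            o.orf_id for g in db.genomes if g.pre_post_wgd == "post" for o in g.orfs
        }
        for a, b in truth.ohnolog_pairs:
            assert a in post_ids and b in post_ids
            assert truth.family_membership[a] == truth.family_membership[b]

    def test_truncation_restricted_to_cup2_lineage(self):
        db, truth = simulate(small_config(seed=6))
        for orf_id, lineage in truth.sublineage.items():
            if lineage == SUBLINEAGE_CUP2:
                assert 120 <= db[orf_id].length <= 180
            else:
                assert db[orf_id].length > 180

    def test_gene_count_bookkeeping_without_loss(self):
        db, _ = simulate(
            small_config(retention_prob=1.0, indel_rate=0.0, shuffle_rate=0.0, seed=7)
        )
        pre = next(g for g in db.genomes if g.pre_post_wgd == "pre")
        post = next(g for g in db.genomes if g.pre_post_wgd == "post")
        pre_counts = sorted(
            sum(1 for o in pre.orfs if o.scaffold_id == s)
            for s in {o.scaffold_id for o in pre.orfs}
        )
        post_counts = sorted(
            sum(1 for o in post.orfs if o.scaffold_id == s)
            for s in {o.scaffold_id for o in post.orfs}
        )
        assert post_counts == sorted(pre_counts * 2)

    def test_shuffling_permutes_but_preserves_content(self):
        base, tb = simulate(small_config(shuffle_rate=0.0, seed=8))
        shuf, ts = simulate(small_config(shuffle_rate=3.0, seed=8))
        fam_of = lambda truth, g: [truth.family_membership[o.orf_id]
                                   for o in sorted(g.orfs, key=lambda o: (o.scaffold_id, o.ordinal))]
        g0 = next(g for g in base.genomes if g.pre_post_wgd == "pre")
        g1 = next(g for g in shuf.genomes if g.species_code == g0.species_code)
        assert sorted(fam_of(tb, g0)) == sorted(fam_of(ts, g1))
        assert fam_of(tb, g0) != fam_of(ts, g1)

    def test_malformed_tree_rejected(self):
        with pytest.raises(Exception):
            simulate(small_config(species_tree="((a:1,b:1"))


class TestEvolveSequence:
    def test_zero_rate_is_identity(self):
        rng = np.random.default_rng(0)
        assert evolve_sequence("MKVLA" * 20, 1.0, 0.0, 0.0, 10, rng) == "MKVLA" * 20

    def test_conserved_prefix_untouched(self):
        rng = np.random.default_rng(1)
        seq = "MKVLAWWCE" * 30
        out = evolve_sequence(seq, 2.0, 5.0, 0.05, 50, rng)
        assert out[:50] == seq[:50]

    def test_substitution_fraction_matches_model(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 500))
        rate, t = 1.2, 0.5
        p = 1 - np.exp(-rate * t)
        fracs = []
        for _ in range(100):
            out = evolve_sequence(seq, t, rate, 0.0, 0, rng)
            fracs.append(np.mean([a != b for a, b in zip(seq, out)]))
        se = np.sqrt(p * (1 - p) / 500 / 100)
        assert abs(np.mean(fracs) - p) < 5 * se


class TestApplyTruncation:
    def test_prefix_preserved_and_length_in_range(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 620))
        out = apply_truncation(seq, (221, 356), 124, rng)
        assert out[:124] == seq[:124]
        assert 221 <= len(out) <= 356

    def test_noop_when_already_within_range(self):
        rng = np.random.default_rng(4)
        seq = "M" * 300
        assert apply_truncation(seq, (221, 356), 124, rng) == seq
        assert apply_truncation(seq, (100, 300), 50, rng) == seq

    def test_infeasible_range_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError):
            apply_truncation("M" * 300, (50, 100), 124, rng)
        with pytest.raises(ValueError):
            apply_truncation("M" * 300, (200, 150), 10, rng)


class TestEmission:
    def test_files_and_config_round_trip(self, tmp_path):
        cfg = small_config(seed=11)
        db, truth = simulate(cfg)
        write_simulation(db, truth, cfg, tmp_path)
        assert (tmp_path / "genomes.tsv").exists()
        assert (tmp_path / "truth_sublineage.tsv").exists()
        assert read_config(tmp_path / "sim_config.yaml") == cfg

        from ohnotrace.pipeline import load_workspace

        db2 = load_workspace(tmp_path)
        assert db2.total_orf_count == db.total_orf_count
        assert set(db2.orf_index) == set(db.orf_index)
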