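import json

import numpy as np
import pytest

from keyrate.keyrank import RankEntry, rank_best
from keyrate.parsimony import StepCount, step_table
from keyrate.simulate import SimConfig
from keyrate.study import (
    StudyConfig,
    correlate_steps_vs_rank,
    run_study,
    stratify_by_state_count,
    write_report,
)
from keyrate.matrix import CharacterDef

from conftest import make_matrix


def fake_steps(values):
    return [
        StepCount(
            char_id=i,
            steps=s,
            min_steps=1,
            max_steps=max(s, 1),
            k_obs=2,
            n_scored=10,
            ci=1.0 if s <= 1 else 1 / s,
            ri=None,
            homoplastic=s > 1,
        )
        for i, s in enumerate(values)
    ]


def fake_ranks(ranks, usable=None):
    usable = usable or [True] * len(ranks)
    return [
        RankEntry(char_id=i, best_score=r / (len(ranks) + 1), rank=r, usable=u)
        for i, (r, u) in enumerate(zip(ranks, usable))
    ]


def fake_chars(ks):
    return [
        CharacterDef(id=i, name=f"c{i}", state_labels=tuple(str(s) for s in range(k)))
        for i, k in enumerate(ks)
    ]


class TestCorrelate:
    def test_perfect_inverse_relation(self):
        # more steps -> better (smaller) rank
        steps = fake_steps([10, 8, 6, 4, 2])
        ranks = fake_ranks([1, 2, 3, 4, 5])
        res = correlate_steps_vs_rank(steps, ranks, n_perm=999, seed=0)
        assert res.rho == pytest.approx(-1.0)
        assert res.n == 5

    def test_zero_variance_flagged(self):
        steps = fake_steps([3, 3, 3, 3])
        ranks = fake_ranks([1, 2, 3, 4])
        res = correlate_steps_vs_rank(steps, ranks, n_perm=999, seed=0)
        assert not res.tested and res.rho is None and "variance" in res.note

    def test_unusable_characters_excluded_and_counted(self):
        steps = fake_steps([5, 4, 3, 2, 1])
        ranks = fake_ranks([1, 2, 3, 4, 5], usable=[True, True, True, True, False])
        res = correlate_steps_vs_rank(steps, ranks, n_perm=999, seed=0)
        assert res.n == 4 and res.n_excluded == 1

    def test_invariant_to_character_order(self):
        steps = fake_steps([7, 2, 9, 4, 1, 6])
        ranks = fake_ranks([2, 5, 1, 4, 6, 3])
        a = correlate_steps_vs_rank(steps, ranks, n_perm=2000, seed=1)
        b = correlate_steps_vs_rank(steps[::-1], ranks[::-1], n_perm=2000, seed=1)
        assert a.rho == pytest.approx(b.rho)

    def test_too_few_pairs_rejected(self):
        steps = fake_steps([1, 2])
        ranks = fake_ranks([1, 2])
        with pytest.raises(ValueError, match="fewer than 3"):
            correlate_steps_vs_rank(steps, ranks)

    def test_sign_flips_with_rank_convention(self):
        steps = fake_steps([9, 7, 5, 3, 1, 8, 2])
        ranks = [1, 2, 3, 5, 7, 2, 6]
        fwd = correlate_steps_vs_rank(fake_steps([9, 7, 5, 3, 1, 8, 2]), fake_ranks(ranks), n_perm=999, seed=0)
        flipped = fake_ranks([max(ranks) + 1 - r for r in ranks])
        rev = correlate_steps_vs_rank(steps, flipped, n_perm=999, seed=0)
        assert fwd.rho == pytest.approx(-rev.rho)


class TestStratify:
    def test_single_k_equals_overall(self):
        steps = fake_steps([5, 4, 3, 2, 1, 6])
        ranks = fake_ranks([2, 3, 4, 5, 6, 1])
        chars = fake_chars([2] * 6)
        overall = correlate_steps_vs_rank(steps, ranks, n_perm=999, seed=0)
        strata = stratify_by_state_count(steps, ranks, chars, n_perm=999, seed=0)
        assert list(strata) == [2]
        assert strata[2].rho == pytest.approx(overall.rho)

    def test_small_stratum_not_tested(self):
        steps = fake_steps([5, 4, 3, 9, 8, 7, 6, 2])
        ranks = fake_ranks([4, 5, 6, 1, 2, 3, 7, 8])
        chars = fake_chars([2, 2, 2, 3, 3, 3, 3, 3])
        strata = stratify_by_state_count(steps, ranks, chars, min_n=5)
        assert not strata[2].tested and "not tested" in strata[2].note
        assert strata[3].tested

    def test_strata_partition_characters(self):
        steps = fake_steps(list(range(1, 13)))
        ranks = fake_ranks(list(range(12, 0, -1)))
        chars = fake_chars([2, 2, 2, 2, 3, 3, 3, 4, 4, 4, 4, 4])
        strata = stratify_by_state_count(steps, ranks, chars, min_n=3, n_perm=999)
        assert sum(r.n for r in strata.values()) == 12


class TestRunStudy:
    def test_flat_rates_weaken_signal(self):
        """Without rate heterogeneity the steps-rank correlation shrinks.

        A residual negative correlation survives even at a single shared
        rate, because a character that happened to change more is both
        steppier and more evenly distributed at the leaves; what rate
        variation adds is the dominant share of the signal.
        """

        def rho_for(rate_low, rate_high):
            cfg = StudyConfig(
                sim=SimConfig(
                    seed=77,
                    n_taxa=60,
                    state_counts=(3,) * 30,  # one k, so no state-count confound
                    rate_low=rate_low,
                    rate_high=rate_high,
                    missing_fraction=0.0,
                ),
                n_perm=500,
                seed=77,
                key_depth_sample=0,
            )
            return run_study(cfg).overall.rho

        flat = rho_for(1.0, 1.0)
        spread = rho_for(0.05, 5.0)
        assert spread < flat < 0  # both negative, heterogeneity strengthens it
        assert spread < -0.8

    def test_spread_rates_give_strong_negative_signal(self):
        cfg = StudyConfig(
            sim=SimConfig(seed=5, n_taxa=100, rate_low=0.05, rate_high=5.0),
            n_perm=2000,
            seed=5,
            key_depth_sample=0,
        )
        rep = run_study(cfg)
        assert rep.overall.rho < -0.5
        assert rep.overall.p < 0.01
        assert rep.n_homoplastic + rep.n_invariant <= rep.n_characters

    def test_deterministic_byte_identical_reports(self, tmp_path):
        cfg = StudyConfig(
            sim=SimConfig(seed=3, n_taxa=40),
            n_perm=500,
            seed=3,
            key_depth_sample=5,
        )
        write_report(run_study(cfg), tmp_path / "a")
        write_report(run_study(cfg), tmp_path / "b")
        for name in ("report.json", "per_character.tsv", "steps.tsv", "ranking.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_report_json_contents(self, tmp_path):
        cfg = StudyConfig(
            sim=SimConfig(seed=3, n_taxa=40), n_perm=500, seed=3, key_depth_sample=5
        )
        rep = run_study(cfg)
        write_report(rep, tmp_path)
        data = json.loads((tmp_path / "report.json").read_text())
        assert data["n_characters"] == 47
        assert -1 <= data["overall"]["rho"] <= 1
        assert 0 < data["overall"]["p"] <= 1
        assert "rank 1 = most useful" in data["sign_convention"]
        assert data["config"]["sim"]["seed"] == 3

    def test_taxa_mismatch_names_symmetric_difference(self, tmp_path):
        from keyrate.simulate import simulate_yule_tree
        from keyrate.matrix import write_matrix

        tree = simulate_yule_tree(6, seed=1)
        m = make_matrix(
            {t: [0] for t in list(tree.leaf_labels[:-1]) + ["ghost"]}, [2]
        )
        tree_path = tmp_path / "t.nwk"
        tree_path.write_text(tree.to_newick())
        matrix_path = tmp_path / "m.csv"
        write_matrix(m, matrix_path)
        cfg = StudyConfig(
            tree_path=str(tree_path), matrix_path=str(matrix_path), n_perm=100
        )
        with pytest.raises(ValueError) as err:
            run_study(cfg)
        assert "ghost" in str(err.value)

    def test_file_mode_with_tree_subset_flags_populations(self, tmp_path):
        """Ranking population larger than the tree is allowed and flagged."""
        from keyrate.simulate import simulate_yule_tree, simulate_matrix
        from keyrate.matrix import write_matrix, CharacterMatrix

        tree = simulate_yule_tree(12, seed=2)
        m, _ = simulate_matrix(
            tree, SimConfig(seed=2, n_taxa=12, missing_fraction=0.0)
        )
        # drop two leaves from the tree but keep them in the matrix
        keep = tree.leaf_labels[:10]
        sub = _prune_to(tree, keep)
        tree_path = tmp_path / "t.nwk"
        tree_path.write_text(sub.to_newick())
        matrix_path = tmp_path / "m.csv"
        write_matrix(m, matrix_path)
        cfg = StudyConfig(
            tree_path=str(tree_path),
            matrix_path=str(matrix_path),
            n_perm=200,
            key_depth_sample=0,
        )
        rep = run_study(cfg)
        assert rep.populations_differ

    def test_config_requires_exactly_one_source(self):
        with pytest.raises(ValueError):
            StudyConfig()
        with pytest.raises(ValueError):
            StudyConfig(sim=SimConfig(seed=1), tree_path="x", matrix_path="y")


def _prune_to(tree, keep):
    """Minimal leaf-prune helper for the population-difference test."""
    from keyrate.tree import parse_newick

    clone = tree.copy()
    keep = set(keep)
    changed = True
    while changed:
        changed = False
        for node in clone.preorder():
            if node.is_leaf and node.label not in keep and node.parent is not None:
                node.parent.children.remove(node)
                changed = True
            elif (
                not node.children
                and node.label is None
                and node.parent is not None
            ):
                node.parent.children.remove(node)
                changed = True
    return parse_newick(clone.to_newick())
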