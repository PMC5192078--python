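import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from traitpred import events as ev
from traitpred.phylo import Phylogeny, prune_to_labeled
from traitpred.synthetic import simulate_tree

from conftest import brute_force_posteriors

probs = st.floats(0, 1, allow_nan=False)


class TestCombineEventPosteriors:
    @pytest.mark.parametrize(
        "chain,expected",
        [
            ([0.4], 0.4),          # single branch passes through
            ([1.0, 0.3], 1.0),     # a certain event is absorbing
            ([0.5, 0.5], 0.75),    # two-branch merge formula g1 + (1-g1)*g2
            ([0.2, 0.3, 0.4], 0.664),
        ],
    )
    def test_known_chains(self, chain, expected):
        assert ev.combine_event_posteriors(chain) == pytest.approx(expected)

    def test_empty_chain_rejected(self):
        with pytest.raises(ValueError):
            ev.combine_event_posteriors([])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(probs, min_size=1, max_size=8))
    def test_equals_closed_form(self, chain):
        closed = 1.0 - np.prod([1.0 - g for g in chain])
        assert ev.combine_event_posteriors(chain) == pytest.approx(closed, abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(probs, min_size=2, max_size=8), st.integers(1, 7))
    def test_invariant_under_regrouping(self, chain, cut):
        cut = min(cut, len(chain) - 1)
        grouped = ev.combine_event_posteriors(
            [ev.combine_event_posteriors(chain[:cut])] + chain[cut:]
        )
        assert grouped == pytest.approx(ev.combine_event_posteriors(chain), abs=1e-12)


class TestJointEventProbability:
    @pytest.mark.parametrize("g,l,expected", [(0, 0, 0), (1, 0.7, 1), (0.3, 0.2, 0.44)])
    def test_known_values(self, g, l, expected):
        assert ev.joint_event_probability(g, l) == pytest.approx(expected)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(probs, probs)
    def test_symmetric_and_equals_inclusion_exclusion(self, g, l):
        x = ev.joint_event_probability(g, l)
        assert x == pytest.approx(ev.joint_event_probability(l, g))
        assert x == pytest.approx(g + l - g * l)
        assert 0 <= x <= 1

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ev.joint_event_probability(1.2, 0.0)


class TestInferPosteriors:
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_enumeration(self, seed):
        """Inside/outside inference equals summing over all ancestral states."""
        rng = np.random.default_rng(seed)
        tree = simulate_tree(int(rng.integers(4, 7)), seed=seed)
        leaves = tree.leaf_labels()
        states = pd.DataFrame(
            rng.integers(0, 2, size=(len(leaves), 5)),
            index=leaves,
            columns=[f"c{j}" for j in range(5)],
        )
        a, b = float(rng.uniform(0.1, 1.5)), float(rng.uniform(0.1, 1.5))
        post = ev.infer_posteriors(tree, states, gain_rate=a, loss_rate=b)
        for ch in states.columns:
            leaf_states = {l: int(states.at[l, ch]) for l in leaves}
            gain, loss = brute_force_posteriors(tree, leaf_states, a, b)
            for bid in tree.branch_ids():
                assert post.gain.at[bid, ch] == pytest.approx(gain[bid], abs=1e-10)
                assert post.loss.at[bid, ch] == pytest.approx(loss[bid], abs=1e-10)

    def test_constant_present_character_has_low_event_posteriors(self, four_leaf_tree):
        states = pd.DataFrame({"c": [1, 1, 1, 1]}, index=["A", "B", "C", "D"])
        post = ev.infer_posteriors(four_leaf_tree, states, gain_rate=0.1, loss_rate=0.1)
        assert (post.gain["c"] < 0.05).all()
        assert (post.loss["c"] < 0.05).all()

    def test_singleton_presence_peaks_on_terminal_branch(self, four_leaf_tree):
        states = pd.DataFrame({"c": [1, 0, 0, 0]}, index=["A", "B", "C", "D"])
        post = ev.infer_posteriors(four_leaf_tree, states, gain_rate=0.2, loss_rate=0.2)
        assert post.gain["c"].idxmax() == "A"

    def test_constant_absent_with_state0_root_has_no_gain_evidence(self, four_leaf_tree):
        states = pd.DataFrame({"c": [0, 0, 0, 0]}, index=["A", "B", "C", "D"])
        post = ev.infer_posteriors(
            four_leaf_tree, states, gain_rate=0.05, loss_rate=0.05, root_prior="state0"
        )
        # terminal branches end in an observed absent leaf: gain impossible
        for leaf in ("A", "B", "C", "D"):
            assert post.gain.at[leaf, "c"] == pytest.approx(0.0, abs=1e-15)
        # internal branches admit only second-order gain-then-loss histories
        assert (post.gain["c"] < 1e-3).all()

    def test_leaf_mismatch_rejected(self, four_leaf_tree):
        states = pd.DataFrame({"c": [1, 0]}, index=["A", "B"])
        with pytest.raises(ValueError, match="leaf"):
            ev.infer_posteriors(four_leaf_tree, states, gain_rate=0.1, loss_rate=0.1)

    def test_estimated_rates_reproduce_exact_inference(self, four_leaf_tree):
        states = pd.DataFrame({"c": [1, 1, 0, 0]}, index=["A", "B", "C", "D"])
        a, b = ev.estimate_rates(four_leaf_tree, states)
        post_default = ev.infer_posteriors(four_leaf_tree, states)
        post_explicit = ev.infer_posteriors(four_leaf_tree, states, gain_rate=a, loss_rate=b)
        pd.testing.assert_frame_equal(post_default.gain, post_explicit.gain)


class TestMapPosteriors:
    def test_identity_mapping_is_identity(self, four_leaf_tree):
        rng = np.random.default_rng(3)
        states = pd.DataFrame(
            rng.integers(0, 2, size=(4, 3)), index=["A", "B", "C", "D"], columns=list("xyz")
        )
        post = ev.infer_posteriors(four_leaf_tree, states, gain_rate=0.4, loss_rate=0.3)
        _, mapping = prune_to_labeled(four_leaf_tree, ["A", "B", "C", "D"])
        mapped = ev.map_posteriors(post, mapping)
        pd.testing.assert_frame_equal(
            mapped.gain.loc[post.gain.index], post.gain, check_exact=False
        )

    def test_collapsed_chain_combines_probabilities(self, four_leaf_tree):
        rng = np.random.default_rng(4)
        states = pd.DataFrame(
            rng.integers(0, 2, size=(4, 2)), index=["A", "B", "C", "D"], columns=["u", "v"]
        )
        post = ev.infer_posteriors(four_leaf_tree, states, gain_rate=0.4, loss_rate=0.3)
        _, mapping = prune_to_labeled(four_leaf_tree, ["A", "C", "D"])
        mapped = ev.map_posteriors(post, mapping)
        for ch in ("u", "v"):
            expected = ev.combine_event_posteriors(
                [post.gain.at[b, ch] for b in mapping.chains["A"]]
            )
            assert mapped.gain.at["A", ch] == pytest.approx(expected)


class TestPosteriorTableIO:
    def test_round_trip_identity(self, four_leaf_tree, tmp_path):
        rng = np.random.default_rng(5)
        states = pd.DataFrame(
            rng.integers(0, 2, size=(4, 3)), index=["A", "B", "C", "D"], columns=list("pqr")
        )
        post = ev.infer_posteriors(four_leaf_tree, states, gain_rate=0.2, loss_rate=0.5)
        path = tmp_path / "post.tsv"
        ev.write_event_posteriors(post, path)
        back = ev.read_event_posteriors(path)
        pd.testing.assert_frame_equal(back.gain, post.gain)
        pd.testing.assert_frame_equal(back.loss, post.loss)

    def test_sparse_table_defaults_missing_pairs_to_zero(self):
        text = "branch_id\tcharacter_id\tgain_prob\tloss_prob\nb1\tc1\t0.4\t0.1\nb2\tc2\t0.2\t0.0\n"
        post = ev.read_event_posteriors(io.StringIO(text))
        assert post.gain.at["b1", "c1"] == 0.4
        assert post.gain.at["b1", "c2"] == 0.0
        assert post.loss.at["b2", "c1"] == 0.0

    def test_out_of_range_probability_names_row(self):
        text = "branch_id\tcharacter_id\tgain_prob\tloss_prob\nb1\tc1\t1.5\t0.1\n"
        with pytest.raises(ValueError, match="row 2"):
            ev.read_event_posteriors(io.StringIO(text))


class TestBuildEventSamples:
    def make_posteriors(self, y_values):
        branches = [f"b{i}" for i in range(len(y_values))]
        gain = pd.DataFrame(
            {"f1": np.linspace(0, 0.9, len(branches)), "ph": y_values}, index=branches
        )
        loss = pd.DataFrame({"f1": 0.0, "ph": 0.0}, index=branches)
        return ev.BranchEventPosteriors(gain=gain, loss=loss)

    def test_threshold_rules(self):
        post = self.make_posteriors([0.6, 0.2, 0.01])
        out = ev.build_event_samples(post, "ph", t=0.5, r=0.05)
        assert list(out.y_binary.index) == ["b0", "b2"]  # 0.2 is uncertain, dropped
        assert out.y_binary.tolist() == [1, 0]

    def test_x_is_joint_gain_or_loss(self):
        gain = pd.DataFrame({"f1": [0.3], "ph": [0.9]}, index=["b0"])
        loss = pd.DataFrame({"f1": [0.2], "ph": [0.0]}, index=["b0"])
        out = ev.build_event_samples(ev.BranchEventPosteriors(gain, loss), "ph")
        assert out.X.at["b0", "f1"] == pytest.approx(0.3 + 0.7 * 0.2)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_no_retained_uncertainty_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.random(50)
        post = self.make_posteriors(y)
        out = ev.build_event_samples(post, "ph", t=0.5, r=0.05)
        expected_retained = int(((y < 0.05) | (y >= 0.5)).sum())
        assert len(out.y) == expected_retained
        assert not ((out.y >= 0.05) & (out.y < 0.5)).any()
        assert (out.y_binary == (out.y >= 0.5).astype(int)).all()

    def test_unknown_phenotype_rejected(self):
        with pytest.raises(ValueError, match="phenotype"):
            ev.build_event_samples(self.make_posteriors([0.5]), "nope")

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ev.build_event_samples(self.make_posteriors([0.5]), "ph", t=0.5, r=0.6)
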