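"""Tests for ancestral gene-content reconstruction.

Parsimony is checked against exhaustive enumeration of all internal
labellings; the Markov pruning likelihood and marginal posteriors
against brute-force summation over ancestral state combinations.
"""

import itertools

import numpy as np
import pandas as pd
import pytest

from dtlflux.ancestral import (
    BranchEventTally,
    GainLossModel,
    ReconciliationMismatchError,
    extract_branch_events,
    filter_families,
    fit_gain_loss_model,
    ingest_event_table,
    marginal_ancestral_posterior,
    profile_log_likelihood,
    reconstruct_ancestral_states,
    sankoff_parsimony,
)
from dtlflux.matrix import PresenceMatrix
from dtlflux.simulate import simulate_binary_gain_loss
from dtlflux.tree import SpeciesTree

from conftest import random_tree


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def enumerate_parsimony(tree, profile, gain, loss):
    """Brute-force minimum cost over all 2^internal labellings."""
    internal = [n for n in tree.preorder() if not tree.is_tip(n)]
    best = float("inf")
    for combo in itertools.product((0, 1), repeat=len(internal)):
        states = dict(zip(internal, combo))
        states.update({t: int(profile[t]) for t in tree.tips})
        cost = 0.0
        for nid in tree.preorder():
            parent = tree.parent(nid)
            if parent is None:
                continue
            p, c = states[parent], states[nid]
            if p == 0 and c == 1:
                cost += gain
            elif p == 1 and c == 0:
                cost += loss
        best = min(best, cost)
    return best


def enumerate_likelihood(tree, profile, model):
    """Brute-force likelihood: sum over all ancestral state combos."""
    internal = [n for n in tree.preorder() if not tree.is_tip(n)]
    prior = np.array([1 - model.root_prior, model.root_prior])
    total = 0.0
    for combo in itertools.product((0, 1), repeat=len(internal)):
        states = dict(zip(internal, combo))
        states.update({t: int(profile[t]) for t in tree.tips})
        p = prior[states[tree.root]]
        for nid in tree.preorder():
            parent = tree.parent(nid)
            if parent is None:
                continue
            P = model.transition_matrix(tree.length(nid))
            p *= P[states[parent], states[nid]]
        total += p
    return total


def enumerate_posterior(tree, profile, model, node):
    """Brute-force marginal posterior of presence at one node."""
    internal = [n for n in tree.preorder() if not tree.is_tip(n)]
    prior = np.array([1 - model.root_prior, model.root_prior])
    mass = {0: 0.0, 1: 0.0}
    for combo in itertools.product((0, 1), repeat=len(internal)):
        states = dict(zip(internal, combo))
        states.update({t: int(profile[t]) for t in tree.tips})
        p = prior[states[tree.root]]
        for nid in tree.preorder():
            parent = tree.parent(nid)
            if parent is None:
                continue
            P = model.transition_matrix(tree.length(nid))
            p *= P[states[parent], states[nid]]
        mass[states[node]] += p
    return mass[1] / (mass[0] + mass[1])


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

class TestFilterFamilies:
    def make(self, rows, genomes=("g1", "g2", "g3", "g4")):
        return PresenceMatrix(pd.DataFrame(
            rows, index=[f"f{i}" for i in range(len(rows))],
            columns=list(genomes)))

    def test_presence_in_three_genomes_dropped_at_four(self):
        m = self.make([[1, 1, 1, 0], [1, 1, 1, 1]])
        out = filter_families(m, 4)
        assert out.families == ["f1"]

    def test_min_one_is_identity(self):
        m = self.make([[1, 0, 0, 0], [0, 0, 1, 1]])
        assert filter_families(m, 1) == m

    def test_copy_counts_are_members(self):
        # 5 gene copies spread over 2 genomes still count as 5 members
        m = self.make([[3, 2, 0, 0]])
        assert filter_families(m, 5).families == ["f0"]
        assert filter_families(m, 6).families == []

    def test_empty_matrix_passes_through(self):
        m = PresenceMatrix(pd.DataFrame(columns=["g1", "g2"]))
        assert filter_families(m, 4).shape[0] == 0


# ---------------------------------------------------------------------------
# Sankoff parsimony
# ---------------------------------------------------------------------------

class TestSankoff:
    def test_constant_present_costs_nothing(self, quartet):
        states, cost = sankoff_parsimony(
            quartet, {t: 1 for t in quartet.tips}, 2.0, 1.0)
        assert cost == 0
        assert all(states[n] == 1 for n in quartet.preorder())

    def test_single_tip_presence_one_gain(self, quartet):
        profile = {"A": 1, "B": 0, "C": 0, "D": 0}
        states, cost = sankoff_parsimony(quartet, profile, 2.0, 1.0)
        assert cost == 2.0  # one gain on A's terminal branch
        assert states["A"] == 1
        assert all(states[n] == 0 for n in quartet.preorder() if n != "A")
        assert cost == enumerate_parsimony(quartet, profile, 2.0, 1.0)

    def test_two_tip_presence_asymmetric_penalties(self, quartet):
        # presence in A and C, gain 2 / loss 1: the root state is free
        # (no root edge), so ancestral presence with two terminal losses
        # (cost 2) beats two independent gains (cost 4); enumeration
        # confirms the minimum
        profile = {"A": 1, "B": 0, "C": 1, "D": 0}
        states, cost = sankoff_parsimony(quartet, profile, 2.0, 1.0)
        assert cost == 2.0
        assert cost == enumerate_parsimony(quartet, profile, 2.0, 1.0)
        assert states["root"] == 1 and states["ab"] == 1 and states["cd"] == 1

    def test_equal_penalty_tie_resolved_to_two_gains(self, quartet):
        # with gain = loss = 1 the same profile is a genuine tie (two
        # gains vs ancestral presence + two losses, both cost 2); the
        # absent-preferring root-ward rule picks the two-gain labelling
        profile = {"A": 1, "B": 0, "C": 1, "D": 0}
        states, cost = sankoff_parsimony(quartet, profile, 1.0, 1.0)
        assert cost == 2.0
        assert cost == enumerate_parsimony(quartet, profile, 1.0, 1.0)
        assert states["ab"] == 0 and states["cd"] == 0 and states["root"] == 0

    def test_invalid_inputs(self, quartet):
        with pytest.raises(ValueError):
            sankoff_parsimony(quartet, {"A": 1}, 2.0, 1.0)
        with pytest.raises(ValueError):
            sankoff_parsimony(quartet, {t: 1 for t in quartet.tips}, 0.0, 1.0)

    def test_matches_enumeration_on_random_instances(self):
        # parsimony optimality over random trees, profiles and penalties
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n_tips = int(rng.integers(3, 9))
            tree = random_tree(rng, n_tips)
            profile = {t: int(rng.integers(0, 2)) for t in tree.tips}
            gain = float(rng.uniform(0.2, 3.0))
            loss = float(rng.uniform(0.2, 3.0))
            states, cost = sankoff_parsimony(tree, profile, gain, loss)
            assert cost == pytest.approx(
                enumerate_parsimony(tree, profile, gain, loss), abs=1e-9)
            # returned labelling attains the reported cost
            realised = 0.0
            for nid in tree.preorder():
                parent = tree.parent(nid)
                if parent is None:
                    continue
                p, c = states[parent], states[nid]
                realised += gain if (p, c) == (0, 1) else \
                    loss if (p, c) == (1, 0) else 0.0
            assert realised == pytest.approx(cost, abs=1e-9)


# ---------------------------------------------------------------------------
# Markov model
# ---------------------------------------------------------------------------

class TestMarkovLikelihood:
    def test_zero_length_two_tip_limit(self):
        tree = SpeciesTree.from_newick("(A:0,B:0)root;")
        model = GainLossModel(0.3, 0.7, 0.6)

        def lik(pa, pb):
            m = PresenceMatrix(pd.DataFrame([[pa, pb]], index=["f"],
                                            columns=["A", "B"]))
            return np.exp(profile_log_likelihood(tree, m, model))

        assert lik(1, 1) == pytest.approx(0.6, abs=1e-12)
        assert lik(0, 0) == pytest.approx(0.4, abs=1e-12)
        assert profile_log_likelihood(
            tree, PresenceMatrix(pd.DataFrame([[1, 0]], index=["f"],
                                              columns=["A", "B"])),
            model) == -np.inf

    def test_matches_exhaustive_summation(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            n_tips = int(rng.integers(3, 7))
            tree = random_tree(rng, n_tips)
            profile = {t: int(rng.integers(0, 2)) for t in tree.tips}
            model = GainLossModel(float(rng.uniform(0.05, 2.0)),
                                  float(rng.uniform(0.05, 2.0)),
                                  float(rng.uniform(0.1, 0.9)))
            m = PresenceMatrix(pd.DataFrame(
                [[profile[t] for t in tree.tips]], index=["f"],
                columns=tree.tips))
            pruned = np.exp(profile_log_likelihood(tree, m, model))
            brute = enumerate_likelihood(tree, profile, model)
            assert abs(pruned - brute) / brute <= 1e-10

    def test_fit_recovers_rates(self):
        from dtlflux.simulate import simulate_species_tree
        tree = simulate_species_tree(32, 1.0, 0.0, seed=5)
        matrix = simulate_binary_gain_loss(tree, 0.3, 0.9, 0.25, 1_000,
                                           seed=6)
        model = fit_gain_loss_model(tree, matrix)
        assert abs(model.gain - 0.3) / 0.3 < 0.3
        assert abs(model.loss - 0.9) / 0.9 < 0.3

    def test_fit_beats_grid_starts(self, quartet):
        matrix = simulate_binary_gain_loss(quartet, 0.5, 0.5, 0.5, 60, seed=2)
        model = fit_gain_loss_model(quartet, matrix)
        fitted = profile_log_likelihood(quartet, matrix, model)
        for mu in (0.02, 0.2, 1.0):
            for lam in (0.02, 0.2, 1.0):
                for pi in (0.2, 0.8):
                    start = profile_log_likelihood(
                        quartet, matrix, GainLossModel(mu, lam, pi))
                    assert fitted >= start - 1e-8

    def test_degenerate_matrix_warns(self, quartet):
        ones = PresenceMatrix(pd.DataFrame(
            np.ones((12, 4), dtype=int),
            index=[f"f{i}" for i in range(12)], columns=quartet.tips))
        with pytest.warns(UserWarning):
            model = fit_gain_loss_model(quartet, ones)
        assert model.root_prior == 1.0


class TestMarginalPosterior:
    def test_symmetric_two_tip_root_is_half(self, two_tip):
        model = GainLossModel(0.4, 0.4, 0.5)
        post = marginal_ancestral_posterior(two_tip, {"A": 1, "B": 0}, model)
        assert post["root"] == pytest.approx(0.5, abs=1e-12)
        assert post["A"] == 1.0 and post["B"] == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            tree = random_tree(rng, int(rng.integers(3, 6)))
            profile = {t: int(rng.integers(0, 2)) for t in tree.tips}
            model = GainLossModel(float(rng.uniform(0.05, 1.5)),
                                  float(rng.uniform(0.05, 1.5)),
                                  float(rng.uniform(0.1, 0.9)))
            post = marginal_ancestral_posterior(tree, profile, model)
            for nid in tree.preorder():
                if tree.is_tip(nid):
                    continue
                brute = enumerate_posterior(tree, profile, model, nid)
                assert post[nid] == pytest.approx(brute, abs=1e-10)

    def test_absorbing_all_present(self, quartet):
        model = GainLossModel(0.5, 0.0, 1.0)
        post = marginal_ancestral_posterior(
            quartet, {t: 1 for t in quartet.tips}, model)
        assert all(p == pytest.approx(1.0, abs=1e-12) for p in post.values())


# ---------------------------------------------------------------------------
# event extraction
# ---------------------------------------------------------------------------

class TestExtractEvents:
    def states(self, tree, mapping):
        return pd.DataFrame(mapping, index=tree.node_ids())

    def test_single_gain_is_origination(self, quartet):
        profile = {"A": 1, "B": 0, "C": 0, "D": 0}
        s, _ = sankoff_parsimony(quartet, profile)
        states = pd.DataFrame({"fam1": pd.Series(s)})
        tally, events = extract_branch_events(states, quartet)
        assert tally.counts.loc["A", "O"] == 1
        assert tally.totals().to_dict() == {"D": 0, "T": 0, "L": 0, "O": 1}
        assert events[0].type == "O" and events[0].branch == "A"

    def test_constant_present_family_has_no_events(self, quartet):
        states = pd.DataFrame(
            {"fam1": {n: 1 for n in quartet.node_ids()}}).loc[quartet.node_ids()]
        tally, events = extract_branch_events(states, quartet)
        assert events == []
        assert (tally.counts.to_numpy() == 0).all()

    def test_two_gains_split_o_then_t(self, quartet):
        # equal penalties make the two-gain labelling win the tie
        profile = {"A": 1, "B": 0, "C": 1, "D": 0}
        s, _ = sankoff_parsimony(quartet, profile, 1.0, 1.0)
        states = pd.DataFrame({"fam1": pd.Series(s)})
        tally, events = extract_branch_events(states, quartet)
        assert tally.totals()["O"] == 1 and tally.totals()["T"] == 1
        # preorder-first gain (A, visited before C) is the origination
        o = [e for e in events if e.type == "O"][0]
        t = [e for e in events if e.type == "T"][0]
        assert o.branch == "A" and t.branch == "C" and t.donor == "A"

    def test_event_conservation_along_paths(self, quartet):
        # #gains - #losses along any root-to-tip path = tip - root state
        rng = np.random.default_rng(3)
        cols = {}
        for i in range(30):
            profile = {t: int(rng.integers(0, 2)) for t in quartet.tips}
            s, _ = sankoff_parsimony(quartet, profile)
            cols[f"f{i}"] = pd.Series(s)
        states = pd.DataFrame(cols).loc[quartet.node_ids()]
        _, events = extract_branch_events(states, quartet)
        for fam in states.columns:
            for tip in quartet.tips:
                path = []
                cur = tip
                while cur is not None:
                    path.append(cur)
                    cur = quartet.parent(cur)
                gains = sum(1 for e in events
                            if e.family == fam and e.branch in path
                            and e.type in ("T", "O"))
                losses = sum(1 for e in events
                             if e.family == fam and e.branch in path
                             and e.type == "L")
                assert gains - losses == (int(states.loc[tip, fam])
                                          - int(states.loc[quartet.root, fam]))

    def test_posteriors_need_threshold(self, quartet):
        states = pd.DataFrame(
            {"f": {n: 0.7 for n in quartet.node_ids()}}).loc[quartet.node_ids()]
        with pytest.raises(ValueError):
            extract_branch_events(states, quartet)
        tally, _ = extract_branch_events(states, quartet, threshold=0.5)
        assert (tally.counts.to_numpy() == 0).all()

    def test_threshold_tie_goes_absent(self, quartet):
        states = pd.DataFrame(
            {"f": {n: 0.5 for n in quartet.node_ids()}}).loc[quartet.node_ids()]
        tally, events = extract_branch_events(states, quartet, threshold=0.5)
        assert events == []  # exactly-0.5 posteriors binarise to absent


# ---------------------------------------------------------------------------
# ingestion
# ---------------------------------------------------------------------------

class TestIngestEventTable:
    def write(self, tmp_path, rows, header="node\tfamily\tD\tT\tL\tO"):
        path = tmp_path / "events.tsv"
        path.write_text(header + "\n" + "\n".join(rows) + ("\n" if rows else ""))
        return path

    def test_single_row(self, tmp_path, quartet):
        path = self.write(tmp_path, ["ab\tf1\t0\t1\t0\t0"])
        tally, report = ingest_event_table(path, quartet)
        assert tally.counts.loc["ab", "T"] == 1
        assert report.loc["ab", "T_rounded"] == 1

    def test_rows_summed_per_node(self, tmp_path, quartet):
        path = self.write(tmp_path, ["ab\tf1\t0\t1\t0\t0", "ab\tf2\t0\t2\t1\t0"])
        tally, _ = ingest_event_table(path, quartet)
        assert tally.counts.loc["ab", "T"] == 3
        assert tally.counts.loc["ab", "L"] == 1

    def test_fractional_frequencies_rounded_half_to_even(self, tmp_path, quartet):
        path = self.write(tmp_path,
                          ["ab\tf1\t0\t0.6\t0\t0", "ab\tf2\t0\t0.6\t0\t0"])
        tally, report = ingest_event_table(path, quartet)
        assert tally.counts.loc["ab", "T"] == pytest.approx(1.2)
        assert report.loc["ab", "T"] == pytest.approx(1.2)  # raw retained
        assert report.loc["ab", "T_rounded"] == 1  # 1.2 -> 1

    def test_half_to_even_boundary(self, tmp_path, quartet):
        path = self.write(tmp_path,
                          ["ab\tf1\t0\t0.5\t0\t0", "cd\tf1\t0\t1.5\t0\t0"])
        _, report = ingest_event_table(path, quartet)
        assert report.loc["ab", "T_rounded"] == 0
        assert report.loc["cd", "T_rounded"] == 2

    def test_unknown_node_label(self, tmp_path, quartet):
        path = self.write(tmp_path, ["zz\tf1\t0\t1\t0\t0"])
        with pytest.raises(ReconciliationMismatchError, match="zz"):
            ingest_event_table(path, quartet)

    def test_negative_counts(self, tmp_path, quartet):
        path = self.write(tmp_path, ["ab\tf1\t0\t-1\t0\t0"])
        with pytest.raises(ValueError):
            ingest_event_table(path, quartet)


class TestReconstructStates:
    def test_tips_reproduce_matrix(self, quartet):
        rng = np.random.default_rng(4)
        matrix = PresenceMatrix(pd.DataFrame(
            rng.integers(0, 2, size=(20, 4)),
            index=[f"f{i}" for i in range(20)], columns=quartet.tips))
        states = reconstruct_ancestral_states(quartet, matrix)
        for t in quartet.tips:
            assert (states.loc[t] == matrix.binary[t]).all()

    def test_markov_tips_match_observations(self, quartet):
        matrix = simulate_binary_gain_loss(quartet, 0.4, 0.6, 0.5, 30, seed=9)
        states = reconstruct_ancestral_states(
            quartet, matrix, method="markov",
            model=GainLossModel(0.4, 0.6, 0.5))
        for t in quartet.tips:
            assert np.allclose(states.loc[t], matrix.binary[t])
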