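"""Plurality sequences, motif probabilities, Fisher tests, randomization nulls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clonedyn import history as hist
from clonedyn import synthetic as syn
from clonedyn.dynamics import motility_table
from clonedyn.normalization import state_proportions


def seq_frame(seqs):
    """List of tuples -> sequence DataFrame with id column."""
    cols = [f"t{k}" for k in range(len(seqs[0]))]
    df = pd.DataFrame(seqs, columns=cols)
    df.insert(0, "barcode", [f"L{i}" for i in range(len(seqs))])
    return df


class TestPlurality:
    def test_majority_state_wins(self):
        state, tie = hist.plurality_state([1000, 500, 500])
        assert state == "State1" and not tie

    def test_only_occupied_state(self):
        state, _ = hist.plurality_state([0, 0, 7])
        assert state == "State3"

    def test_tie_breaks_low_and_flags(self):
        state, tie = hist.plurality_state([500, 500, 0])
        assert state == "State1" and tie

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hist.plurality_state([0, 0, 0])


class TestStateSequences:
    def test_sequences_from_cells(self):
        rows = []
        for t, winner in zip((0, 6, 12), ("State1", "State2", "State1")):
            for s in syn.STATES:
                rows.append({"barcode": "a", "timepoint": t, "state": s,
                             "cells": 10.0 if s == winner else 1.0})
        seqs = hist.state_sequences(pd.DataFrame(rows))
        assert seqs.iloc[0].tolist() == ["a", "State1", "State2", "State1"]

    def test_min_share_drops_weak_votes(self):
        rows = [{"barcode": "a", "timepoint": 0, "state": s, "cells": c}
                for s, c in zip(syn.STATES, (4.0, 3.0, 3.0))]
        assert len(hist.state_sequences(pd.DataFrame(rows))) == 1
        assert len(hist.state_sequences(pd.DataFrame(rows), min_share=0.5)) == 0


class TestMotifProbs:
    def test_constant_sequences(self):
        seqs = seq_frame([("1", "1", "1", "1")] * 5)
        t = hist.motif_conditional_probs(seqs, depth=3)
        assert len(t) == 1
        assert t["probability"].iloc[0] == 1.0 and t["count"].iloc[0] == 5

    def test_toy_enumeration(self):
        seqs = seq_frame([
            ("1", "1", "1", "2"), ("1", "1", "1", "2"), ("1", "1", "1", "3"),
            ("2", "2", "2", "1"), ("2", "2", "2", "2"),
        ])
        t = hist.motif_conditional_probs(seqs, depth=3).set_index(
            ["motif", "next_state"]
        )
        assert t.loc[("1|1|1", "2"), "probability"] == pytest.approx(2 / 3)
        assert t.loc[("1|1|1", "2"), "count"] == 2
        assert t.loc[("2|2|2", "1"), "probability"] == pytest.approx(1 / 2)

    def test_marginalization_consistency(self):
        """Summing a depth-k table over the oldest history element reproduces
        the depth-(k-1) table exactly."""
        rng = np.random.default_rng(5)
        seqs = seq_frame([tuple(rng.choice(["1", "2", "3"], 5)) for _ in range(300)])
        deep = hist.motif_conditional_probs(seqs, depth=3)
        shallow = hist.motif_conditional_probs(seqs, depth=2)
        deep["short"] = deep["motif"].str.split("|").str[1:].str.join("|")
        marg = deep.groupby(["short", "next_state"])["count"].sum()
        ref = shallow.set_index(["motif", "next_state"])["count"]
        assert marg.to_dict() == ref.to_dict()

    def test_depth1_equals_depth3_under_markov_null(self):
        """Sequences generated by a memoryless chain: deep conditioning adds
        nothing (within 3 binomial SE for motifs with >= 100 observations)."""
        rng = np.random.default_rng(6)
        M = syn.default_transition_matrix(0.4)
        n = 5000
        states = np.array(["1", "2", "3"])
        seqs = []
        for _ in range(n):
            s = [int(rng.choice(3, p=[0.7, 0.15, 0.15]))]
            for _ in range(4):
                s.append(int(rng.choice(3, p=M[s[-1]])))
            seqs.append(tuple(states[s]))
        frame = seq_frame(seqs)
        p1 = hist.motif_conditional_probs(frame, 1).set_index(["motif", "next_state"])
        p3 = hist.motif_conditional_probs(frame, 3)
        totals = p3.groupby("motif")["count"].sum()
        for _, row in p3.iterrows():
            n_motif = totals[row["motif"]]
            if n_motif < 100:
                continue
            ref = p1.loc[(row["motif"].split("|")[-1], row["next_state"]), "probability"]
            se = np.sqrt(ref * (1 - ref) / n_motif)
            assert abs(row["probability"] - ref) < 3.5 * se

    def test_empty_input(self):
        out = hist.motif_conditional_probs(
            pd.DataFrame(columns=["barcode", "t0", "t1"]), 1
        )
        assert out.empty


class TestFisher:
    def test_identical_rows_p_one(self):
        p = hist.fisher_exact_2xk(np.array([[10, 10, 10], [10, 10, 10]]))
        assert p == pytest.approx(1.0)

    def test_extreme_2x2_closed_form(self):
        from math import comb

        p = hist.fisher_exact_2xk(np.array([[10, 0], [0, 10]]))
        assert p == pytest.approx(2 / comb(20, 10))

    def test_matches_scipy_oracle_on_2x2(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            tab = rng.integers(1, 8, size=(2, 2))
            ours = hist.fisher_exact_2xk(tab)
            ref = stats.fisher_exact(tab).pvalue
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            hist.fisher_exact_2xk(np.array([[5, 5], [0, 0]]))

    def test_type_one_error_controlled_under_null(self):
        """Memoryless sequences: the fraction of BH-significant motif pairs
        stays at or below the nominal 0.05 (pooled over 20 seeds)."""
        sig = total = 0
        states = np.array(["1", "2", "3"])
        M = syn.default_transition_matrix(0.4)
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            seqs = []
            for _ in range(400):
                s = [int(rng.choice(3, p=[0.7, 0.15, 0.15]))]
                for _ in range(4):
                    s.append(int(rng.choice(3, p=M[s[-1]])))
                seqs.append(tuple(states[s]))
            res = hist.history_fisher_tests(seq_frame(seqs), depth=2)
            sig += sum(r.adjusted_p < 0.05 for r in res)
            total += len(res)
        assert total > 100
        assert sig / total <= 0.05

    def test_planted_history_divergence_detected(self):
        """Two histories ending in the same state but with sharply different
        next-state distributions (a 21%-vs-64% style contrast) are flagged."""
        seqs = []
        # history 1|1|2: next state mostly 1; history 2|2|2: next mostly 2
        seqs += [("1", "1", "2", "1")] * 79 + [("1", "1", "2", "2")] * 21
        seqs += [("2", "2", "2", "1")] * 36 + [("2", "2", "2", "2")] * 64
        res = hist.history_fisher_tests(seq_frame(seqs), depth=3)
        assert len(res) == 1
        assert res[0].adjusted_p < 1e-6


class TestMotilityStates:
    def motility_of(self, cfg):
        truth = syn.simulate_lineages(cfg)
        props = state_proportions(truth, id_col="lineage")
        return motility_table(props, id_col="lineage")

    def test_binarization_and_motifs(self):
        tbl = pd.DataFrame({
            "barcode": list("abcd"),
            "m_0_6": [0.1, 0.9, 0.1, 0.9],
            "m_6_12": [0.2, 0.8, 0.8, 0.2],
        })
        seqs = hist.motility_states(tbl)
        assert seqs.columns.tolist() == ["barcode", "h_0_6", "h_6_12"]
        assert seqs.set_index("barcode").loc["b"].tolist() == ["high", "high"]
        motifs = hist.motif_conditional_probs(seqs, depth=1)
        got = motifs.set_index(["motif", "next_state"])
        assert got.loc[("high", "low"), "count"] == 1

    def test_degenerate_motility_rejected(self):
        tbl = pd.DataFrame({"barcode": list("ab"), "m_0_6": [0.5, 0.5]})
        with pytest.raises(ValueError):
            hist.motility_states(tbl)

    def test_persistent_high_motility_in_mixed_mode(self):
        """Lineages highly motile at all prior transitions stay high more
        often than lineages that only just became high (pooled counts over
        10 simulations)."""
        counts = {"high|high|high": [0, 0], "low|low|high": [0, 0]}
        for seed in range(10):
            cfg = syn.SimulationConfig(
                n_lineages=300, initial_cells_per_lineage=300, mode="mixed",
                coordination_prob=0.6, mixed_fraction=0.5, seed=200 + seed,
            )
            seqs = hist.motility_states(self.motility_of(cfg), id_col="lineage")
            t = hist.motif_conditional_probs(seqs, depth=3, id_col="lineage")
            for motif in counts:
                sub = t[t["motif"] == motif]
                hi = sub[sub["next_state"] == "high"]["count"].sum()
                counts[motif][0] += hi
                counts[motif][1] += sub["count"].sum()
        p_hhh = counts["high|high|high"][0] / max(counts["high|high|high"][1], 1)
        p_llh = counts["low|low|high"][0] / max(counts["low|low|high"][1], 1)
        assert p_hhh > p_llh


class TestRandomizationNull:
    def test_exact_copy_observed_r_one(self):
        rng = np.random.default_rng(13)
        vals = rng.exponential(20, 500)
        shared = pd.DataFrame({"rep1": vals, "rep2": vals})
        res = hist.motility_randomization_null(shared, vals, vals,
                                               n_trials=500, seed=3)
        assert res["observed_r"] == pytest.approx(1.0)
        assert res["null_r2"].max() < 0.1

    def test_seeded_determinism(self):
        rng = np.random.default_rng(14)
        shared = pd.DataFrame({"rep1": rng.exponential(1, 100),
                               "rep2": rng.exponential(1, 100)})
        pool = rng.exponential(1, 400)
        a = hist.motility_randomization_null(shared, pool, pool, 200, seed=5)
        b = hist.motility_randomization_null(shared, pool, pool, 200, seed=5)
        np.testing.assert_array_equal(a["null_r"], b["null_r"])

    def test_null_r2_mean_matches_theory(self):
        """Independent assignments give E[R^2] ~ 1/(n-1)."""
        rng = np.random.default_rng(15)
        n = 2560
        shared = pd.DataFrame({"rep1": rng.exponential(20, n),
                               "rep2": rng.exponential(20, n)})
        pool = rng.exponential(20, 4 * n)
        res = hist.motility_randomization_null(shared, pool, pool,
                                               n_trials=10_000, seed=8)
        assert res["null_r2"].mean() == pytest.approx(1 / (n - 1), rel=0.2)


class TestReadReassignment:
    def test_identity_permutation_preserves_counts(self, small_world):
        truth = small_world["truth"].rename(
            columns={"lineage": "barcode", "cells": "reads"}
        )
        out = hist.read_reassignment_null(truth, seed=1, identity=True)
        pd.testing.assert_frame_equal(out, truth)

    def test_permutation_destroys_motility_correlation(self):
        """After shuffling read counts within samples, early and late motility
        are uncorrelated."""
        cfg = syn.SimulationConfig(
            n_lineages=2000, initial_cells_per_lineage=300, mode="mixed",
            coordination_prob=0.6, mixed_fraction=0.5, seed=17,
        )
        truth = syn.simulate_lineages(cfg)
        reads = truth.rename(columns={"lineage": "barcode", "cells": "reads"})
        for seed in (1, 2):
            perm = hist.read_reassignment_null(reads, seed=seed)
            cells = perm.rename(columns={"reads": "cells"})
            cells = cells[cells.groupby("barcode")["cells"].transform("sum") > 0]
            props = state_proportions(cells)
            mot = motility_table(props)
            corr = hist.transition_motility_correlations(mot)
            assert abs(corr.loc["m_0_6", "m_18_24"]) < 0.05


class TestDecisionTree:
    def test_single_chain(self):
        seqs = seq_frame([("1", "1", "1")] * 4)
        edges = hist.decision_tree_export(seqs)
        assert len(edges) == 2
        assert (edges["proportion"] == 1.0).all()
        assert (edges["n_lineages"] == 4).all()

    def test_toy_counts_by_enumeration(self):
        seqs = seq_frame([("1", "1"), ("1", "2"), ("1", "2"), ("2", "1")])
        edges = hist.decision_tree_export(seqs).set_index(["from_state", "to_state"])
        assert edges.loc[("1", "2"), "n_lineages"] == 2
        assert edges.loc[("1", "2"), "proportion"] == pytest.approx(2 / 3)
        assert edges.loc[("2", "1"), "proportion"] == pytest.approx(1.0)

    def test_outgoing_proportions_sum_to_one(self):
        rng = np.random.default_rng(19)
        seqs = seq_frame([tuple(rng.choice(["1", "2", "3"], 5)) for _ in range(100)])
        edges = hist.decision_tree_export(seqs)
        sums = edges.groupby(["from_timepoint", "from_state"])["proportion"].sum()
        np.testing.assert_allclose(sums, 1.0)
        g = hist.decision_tree_graph(edges)
        assert g.number_of_edges() == len(edges)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hist.decision_tree_export(pd.DataFrame(columns=["barcode"]))
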