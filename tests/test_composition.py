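"""Composition matrices, transitions, flower color, ordination."""

import numpy as np
import pandas as pd
import pytest

import hetrack as h
from hetrack.composition import chrom_set_note
from hetrack.states import MISSING_LABEL


def call_matrix(calls: pd.DataFrame, roles=None, markers=None):
    if markers is None:
        markers = pd.DataFrame(
            {
                "chrom_B": ["B01"] * len(calls),
                "pos_B": np.arange(1, len(calls) + 1) * 100,
            },
            index=calls.index,
        )
    return h.DosageCallMatrix(
        calls=calls, roles=roles or {c: "tetraploid" for c in calls.columns},
        markers=markers,
    )


class TestMapChromSet:
    def test_numerical_correspondence(self):
        assert h.map_chrom_set("B03") == "03"
        assert h.map_chrom_set("B10") == "10"

    def test_rearranged_sets_are_annotated(self):
        assert h.map_chrom_set("B07") == "07"
        assert "A07" in chrom_set_note("07") and "A08" in chrom_set_note("07")
        assert chrom_set_note("08") != chrom_set_note("07")
        assert chrom_set_note("03") is None

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError):
            h.map_chrom_set("Bxx")


class TestBuildMatrix:
    def calls(self):
        df = pd.DataFrame(
            {"s1": [2, 3, np.nan], "s2": [0, 4, 1]},
            index=pd.Index(["Ma", "Mb", "Mc"], name="marker"),
        )
        return df

    def positions(self):
        return pd.DataFrame(
            {
                "marker": ["Ma", "Mb", "Mc"],
                "chrom_B": ["B02", "B01", "B01"],
                "pos_B": [500, 900, 100],
            }
        )

    def test_labels_and_ordering(self):
        cm = h.build_matrix(call_matrix(self.calls(), markers=None), self.positions())
        # rows sorted by (set, position): Mc(01:100), Mb(01:900), Ma(02:500)
        assert list(cm.labels.index) == ["Mc", "Mb", "Ma"]
        assert cm.labels.loc["Ma", "s1"] == "AABB"
        assert cm.labels.loc["Mb", "s1"] == "AAAB"
        assert cm.labels.loc["Mc", "s1"] == MISSING_LABEL
        assert cm.labels.loc["Mb", "s2"] == "AAAA"
        assert cm.labels.loc["Mc", "s2"] == "ABBB"

    def test_shuffled_input_gives_identical_matrix(self):
        base = h.build_matrix(call_matrix(self.calls(), markers=None), self.positions())
        shuffled = self.calls().iloc[[2, 0, 1]]
        out = h.build_matrix(call_matrix(shuffled, markers=None), self.positions())
        pd.testing.assert_frame_equal(base.labels, out.labels)

    def test_duplicate_marker_rejected(self):
        dup = pd.concat([self.calls(), self.calls().iloc[:1]])
        with pytest.raises(ValueError, match="duplicate"):
            h.build_matrix(call_matrix(dup, markers=None), self.positions())

    def test_unanchored_marker_rejected(self):
        with pytest.raises(ValueError, match="unanchored"):
            h.build_matrix(
                call_matrix(self.calls(), markers=None), self.positions().iloc[:2]
            )


class TestUnbalancedFraction:
    def matrix_from_labels(self, labels: pd.DataFrame, sets: list[str]):
        positions = pd.DataFrame(
            {"chrom_set": sets, "pos_B": np.arange(len(sets)) * 10 + 1},
            index=labels.index,
        )
        return h.CompositionMatrix(labels=labels, positions=positions)

    def test_all_balanced_gives_zeros(self):
        labels = pd.DataFrame(
            {"s1": ["AABB"] * 4, "s2": ["AABB"] * 4},
            index=[f"M{i}" for i in range(4)],
        )
        out = h.unbalanced_fraction(self.matrix_from_labels(labels, ["01"] * 4))
        assert (out.to_numpy() == 0).all()

    def test_per_individual_mean_and_sum_modes(self):
        labels = pd.DataFrame(
            {
                "s1": ["AAAA"] * 10 + ["AABB"] * 10,
                "s2": ["AAAA"] * 10 + ["AABB"] * 10,
            },
            index=[f"M{i}" for i in range(20)],
        )
        cm = self.matrix_from_labels(labels, ["01"] * 20)
        mean_mode = h.unbalanced_fraction(cm, mode="mean")
        assert mean_mode.loc["01", "AAAA"] == pytest.approx(0.5)
        sum_mode = h.unbalanced_fraction(cm, mode="sum")
        assert sum_mode.loc["01", "AAAA"] == pytest.approx(1.0)

    def test_fractions_nonnegative(self):
        rng = np.random.default_rng(2)
        states = np.array(["AAAA", "AAAB", "AABB", "ABBB", "BBBB"])
        labels = pd.DataFrame(
            rng.choice(states, size=(30, 4)),
            index=[f"M{i}" for i in range(30)],
            columns=[f"s{i}" for i in range(4)],
        )
        out = h.unbalanced_fraction(
            self.matrix_from_labels(labels, ["01"] * 15 + ["02"] * 15)
        )
        assert (out.to_numpy() >= 0).all()


class TestTransitionStats:
    def test_chain_of_transitions(self):
        labels = pd.DataFrame(
            {"p": ["AABB"], "c": ["AAAB"], "g": ["AAAA"]},
            index=pd.Index(["M1"], name="marker"),
        )
        cm = h.CompositionMatrix(
            labels=labels,
            positions=pd.DataFrame(
                {"chrom_set": ["01"], "pos_B": [1]}, index=labels.index
            ),
        )
        pedigree = pd.DataFrame(
            {"id": ["p", "c", "g"], "parent_id": [None, "p", "c"], "generation": [0, 1, 2]}
        )
        rec, summary = h.transition_stats(cm, pedigree)
        pairs = set(zip(rec["from_state"], rec["to_state"]))
        assert pairs == {("AABB", "AAAB"), ("AAAB", "AAAA")}

    def test_absorbing_states_stable_on_simulated_lineages(self, parents):
        founder = h.CompositionMap.uniform(parents.chrom_lengths)
        founder.segments["01"] = [
            h.SegmentState("01", 1, parents.chrom_lengths["01"], 4, 0)
        ]
        markers = parents.ab_sites.iloc[::5].reset_index(drop=True)
        lin = h.simulate_lineage(founder, 6, 0.5, 0.5, seed=77, founder_id="LX")
        samples = [
            (ind.id, "tetraploid", ind.composition) for ind in lin.individuals
        ]
        table = h.simulate_array_signals(samples, markers, noise_sd=0.0, seed=78)
        calls = h.call_dosage(table)
        positions = table.markers.reset_index()
        cm = h.build_matrix(calls, positions)
        rec, summary = h.transition_stats(cm, lin.pedigree_frame())
        for state in ("AAAA", "BBBB"):
            rate = summary.loc[summary["from_state"] == state, "stability_rate"]
            if len(rate):
                assert (rate == 1.0).all()

    def test_tetrasomic_selfing_transition_frequencies(self):
        # one parent-child selfing step at 10^4 independent AAAB markers;
        # offspring frequencies follow the gamete-law convolution 1/4,1/2,1/4
        rng = np.random.default_rng(123)
        n = 10_000
        g1 = rng.hypergeometric(3, 1, 2, size=n)
        g2 = rng.hypergeometric(3, 1, 2, size=n)
        child_dosage = g1 + g2
        from hetrack.states import DOSAGE_TO_LABEL

        labels = pd.DataFrame(
            {
                "p": ["AAAB"] * n,
                "c": [DOSAGE_TO_LABEL[d] for d in child_dosage],
            },
            index=pd.Index([f"M{i}" for i in range(n)], name="marker"),
        )
        cm = h.CompositionMatrix(
            labels=labels,
            positions=pd.DataFrame(
                {"chrom_set": ["01"] * n, "pos_B": np.arange(1, n + 1)},
                index=labels.index,
            ),
        )
        pedigree = pd.DataFrame(
            {"id": ["p", "c"], "parent_id": [None, "p"], "generation": [0, 1]}
        )
        rec, _ = h.transition_stats(cm, pedigree)
        observed = rec["to_state"].value_counts()
        from scipy.stats import chisquare

        obs = [observed.get("AAAA", 0), observed.get("AAAB", 0), observed.get("AABB", 0)]
        stat = chisquare(obs, f_exp=[n / 4, n / 2, n / 4])
        assert stat.pvalue > 0.01

    def test_ungenotyped_parent_skipped(self):
        labels = pd.DataFrame(
            {"c": ["AABB"]}, index=pd.Index(["M1"], name="marker")
        )
        cm = h.CompositionMatrix(
            labels=labels,
            positions=pd.DataFrame(
                {"chrom_set": ["01"], "pos_B": [1]}, index=labels.index
            ),
        )
        pedigree = pd.DataFrame(
            {"id": ["c"], "parent_id": ["ghost"], "generation": [1]}
        )
        rec, summary = h.transition_stats(cm, pedigree)
        assert rec.empty


class TestFlowerColorPredict:
    @pytest.mark.parametrize("state", ["AABB", "AAAA", "AAAB", "ABBB"])
    def test_any_a_copy_gives_yellow(self, state):
        assert h.flower_color_predict(state)["yellow"] == 1.0

    def test_bbbb_splits_between_orange_and_white(self):
        dist = h.flower_color_predict("BBBB", silencing_prob=0.0)
        assert dist["orange"] == 1.0
        dist = h.flower_color_predict("BBBB", silencing_prob=0.3)
        assert dist["white"] == pytest.approx(0.3)
        assert dist["orange"] == pytest.approx(0.7)

    def test_invalid_label_rejected(self):
        with pytest.raises(ValueError):
            h.flower_color_predict("ABAB")


class TestPcaScores:
    def dosage_matrix(self):
        rng = np.random.default_rng(5)
        tetra = rng.integers(1, 4, size=(40, 8)).astype(float)
        calls = pd.DataFrame(
            np.column_stack([np.full(40, 4.0), np.full(40, 0.0), tetra]),
            index=pd.Index([f"M{i}" for i in range(40)], name="marker"),
            columns=["dur", "ipa"] + [f"t{i}" for i in range(8)],
        )
        roles = {"dur": "duranensis", "ipa": "ipaensis"}
        roles.update({f"t{i}": "tetraploid" for i in range(8)})
        return h.DosageCallMatrix(calls=calls, roles=roles, markers=None)

    def test_percent_variance_sorted_and_bounded(self):
        _, pct = h.pca_scores(self.dosage_matrix())
        assert (np.diff(pct) <= 1e-9).all()
        assert pct.sum() <= 100 + 1e-6

    def test_duplicated_samples_get_identical_coordinates(self):
        m = self.dosage_matrix()
        m.calls["t_dup"] = m.calls["t0"]
        m.roles["t_dup"] = "tetraploid"
        scores, _ = h.pca_scores(m)
        np.testing.assert_allclose(
            scores.loc["t0"].to_numpy(), scores.loc["t_dup"].to_numpy(), atol=1e-8
        )

    def test_diploids_at_opposite_pc1_extremes(self):
        scores, _ = h.pca_scores(self.dosage_matrix())
        pc1 = scores["PC1"]
        lo, hi = sorted([pc1["dur"], pc1["ipa"]])
        assert (pc1.drop(["dur", "ipa"]) > lo).all()
        assert (pc1.drop(["dur", "ipa"]) < hi).all()

    def test_exclude_diploids_flag(self):
        scores, _ = h.pca_scores(self.dosage_matrix(), include_diploids=False)
        assert set(scores.index) == {f"t{i}" for i in range(8)}

    def test_constant_matrix_rejected(self):
        calls = pd.DataFrame(
            np.full((10, 5), 2.0),
            index=[f"M{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(5)],
        )
        with pytest.raises(ValueError, match="constant|degenerate"):
            h.pca_scores(h.DosageCallMatrix(calls, {c: "tetraploid" for c in calls}, None))
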