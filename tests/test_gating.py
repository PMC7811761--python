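"""Hierarchical gating and lymphocyte-background positivity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import timascan as t
from timascan.gating import (DEFAULT_GATE_CONFIG, ConfigError, GatingError,
                             GateTreeClassifier, default_timascan_tree)
from timascan.io import EventTable

from timascan.simulate import CHANNELS as CH


def _event(**overrides):
    """One event that lands in the classical-monocyte gate by default."""
    base = {"FSC-A": 550.0, "FSC-H": 530.0, "SSC-A": 330.0, "CD45": 4.8,
            "HLA-DR": 4.6, "CD300e": 4.6, "CD14": 5.5, "CD16": 1.2,
            "GFAP": 0.8, "PLP1": 0.8}
    base.update(overrides)
    return [base[c] for c in CH]


def _table(rows):
    return EventTable("t", CH, np.array(rows, dtype=float))


class TestTreeConstruction:
    def test_default_tree_has_all_stages_and_terminals(self, default_tree):
        assert set(default_tree.config) == set(DEFAULT_GATE_CONFIG)
        assert len(default_tree.terminal_populations) == 7
        names = {"root"} | {g.name for g in default_tree.gates}
        assert all(g.parent in names for g in default_tree.gates)

    def test_override_changes_only_that_bound(self, default_tree):
        config = {k: {} for k in DEFAULT_GATE_CONFIG}
        config["subsets"] = {"cd16_split": 2.5}
        tree = default_timascan_tree(config)
        assert tree.config["subsets"]["cd16_split"] == 2.5
        unchanged = {k: v for k, v in tree.config.items() if k != "subsets"}
        assert unchanged == {k: v for k, v in default_tree.config.items()
                             if k != "subsets"}
        assert tree.tree_hash() != default_tree.tree_hash()

    def test_missing_stage_names_the_gate(self):
        config = {k: {} for k in DEFAULT_GATE_CONFIG if k != "cd300e"}
        with pytest.raises(ConfigError, match="missing gate: CD300e"):
            default_timascan_tree(config)


class TestApplyGateTree:
    def test_population_recovery_on_separated_sample(self, gated_sample):
        sample, gating = gated_sample
        mapping = {"debris": "debris_doublets_excluded",
                   "doublet": "debris_doublets_excluded",
                   "other_leukocyte": "ungated"}
        truth = np.array([mapping.get(x, x) for x in sample.truth_labels])
        for pop in ("lymphocyte", "classical_mono", "intermediate_mono",
                    "nonclassical_mono", "dendritic", "debris_doublets_excluded"):
            tp = np.sum((truth == pop) & (gating.labels == pop))
            assert tp / np.sum(truth == pop) >= 0.98          # recall
            assert tp / np.sum(gating.labels == pop) >= 0.98  # precision

    def test_partition_counts_sum_to_total(self, gated_sample):
        _, gating = gated_sample
        c = gating.population_counts
        total = (c["debris_doublets_excluded"] + c["lymphocyte"] + c["dendritic"]
                 + c["monocyte"] + c["ungated"])
        assert total == gating.n_events
        assert c["monocyte"] == (c["classical_mono"] + c["intermediate_mono"]
                                 + c["nonclassical_mono"])

    def test_half_open_bounds_low_in_high_out(self, default_tree):
        split = default_tree.config["subsets"]["cd16_split"]
        on_low = _table([_event(CD16=split)])       # exactly on the low bound
        res = t.apply_gate_tree(on_low, default_tree)
        assert res.labels[0] == "intermediate_mono"
        high = default_tree.config["leukocyte_region"]["fsc_a"][1]
        on_high = _table([_event(**{"FSC-A": high, "FSC-H": 0.95 * high})])
        res = t.apply_gate_tree(on_high, default_tree)
        assert res.labels[0] == "ungated"  # exactly on the high bound: outside

    def test_empty_region_gate_empties_branch_only(self, default_tree):
        config = {k: {} for k in DEFAULT_GATE_CONFIG}
        config["cd14_confirm"] = {"cd14": [0.0, 0.0]}
        tree = default_timascan_tree(config)
        table = _table([_event(), _event(**{"HLA-DR": 1.2, "CD300e": 1.0,
                                            "CD45": 6.0, "SSC-A": 150.0,
                                            "FSC-A": 450.0, "FSC-H": 445.0})])
        res = t.apply_gate_tree(table, tree)
        assert res.population_counts["monocyte"] == 0
        assert res.labels[1] == "lymphocyte"  # other branches unaffected

    def test_missing_channel_named(self, default_tree):
        table = EventTable("x", ["FSC-A"], np.array([[1.0]]))
        with pytest.raises(GatingError, match="missing channel FSC-H"):
            t.apply_gate_tree(table, default_tree)

    def test_gating_invariant_under_monotone_rescaling(self, default_tree):
        """Cubing the CD16 axis (data and bound together) changes nothing."""
        sample = t.simulate_sample(t.default_sample_spec("m", 5_000, seed=13))
        before = t.apply_gate_tree(sample, default_tree).labels
        j = sample.channels.index("CD16")
        values = sample.values.copy()
        values[:, j] = values[:, j] ** 3
        config = {k: {} for k in DEFAULT_GATE_CONFIG}
        config["subsets"] = {
            "cd16_split": DEFAULT_GATE_CONFIG["subsets"]["cd16_split"] ** 3}
        tree = default_timascan_tree(config)
        after = t.apply_gate_tree(
            EventTable("m", sample.channels, values), tree).labels
        assert np.array_equal(before, after)


class TestPositivity:
    def test_constant_background_gives_that_constant(self, default_tree):
        sample = t.simulate_sample(t.default_sample_spec("c", 10_000, seed=1))
        gating = t.apply_gate_tree(sample, default_tree)
        j = sample.channels.index("GFAP")
        sample.values[:, j] = 2.5
        thr = t.lymphocyte_background_threshold(sample, gating, "GFAP", 0.995)
        assert thr == 2.5

    def test_type7_quantile_on_1_to_1000(self, default_tree, gated_sample):
        sample, gating = gated_sample
        lymph = gating.mask("lymphocyte")
        idx = np.where(lymph)[0][:1000]
        table = EventTable("q", sample.channels, sample.values[idx])
        sub_gating = t.apply_gate_tree(table, default_tree)
        j = table.channels.index("GFAP")
        table.values[:, j] = np.arange(1.0, 1001.0)
        thr = t.lymphocyte_background_threshold(table, sub_gating, "GFAP", 0.995)
        assert thr == pytest.approx(995.005, abs=1e-9)

    def test_too_few_lymphocytes_is_a_qc_error(self, default_tree):
        sample = t.simulate_sample(t.default_sample_spec("few", 1_000, seed=2))
        gating = t.apply_gate_tree(sample, default_tree)
        with pytest.raises(GatingError, match="flag sample"):
            t.lymphocyte_background_threshold(sample, gating, "GFAP", 0.995,
                                              min_background_events=5_000)

    def test_boundary_intensity_is_negative(self, gated_sample):
        sample, gating = gated_sample
        thr = float(sample.column("GFAP").max())
        flags = t.label_marker_positive(sample, gating, "GFAP", thr)
        assert flags.sum() == 0  # max value == threshold: not positive

    def test_measured_fraction_matches_truth_plus_background(self, default_tree):
        f, q = 0.02, 0.995
        sample = t.simulate_sample(t.default_sample_spec(
            "m", 100_000, seed=21, gfap_nonclassical=f, gfap_intermediate=f))
        gating = t.apply_gate_tree(sample, default_tree)
        call = t.call_positivity(
            sample, gating, "GFAP", q,
            populations=("intermediate_mono", "nonclassical_mono"))
        n = (gating.population_counts["intermediate_mono"]
             + gating.population_counts["nonclassical_mono"])
        expected = f + (1 - f) * (1 - q)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(call.n_positive / n - expected) < 3 * se

    @settings(max_examples=20, deadline=None)
    @given(st.lists(st.floats(0.5, 0.999), min_size=2, max_size=5))
    def test_raising_quantile_never_increases_positives(self, gated_sample,
                                                        quantiles):
        sample, gating = gated_sample
        counts = []
        for q in sorted(quantiles):
            call = t.call_positivity(sample, gating, "GFAP", q)
            counts.append(call.n_positive)
        assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_sklearn_estimator_protocol():
    from sklearn.base import clone
    clf = GateTreeClassifier()
    clone(clf)  # get_params/set_params round-trip
    sample = t.simulate_sample(t.default_sample_spec("e", 2_000, seed=5))
    labels = clf.fit().predict(sample)
    assert labels.shape == (2_000,)
    arr_labels = GateTreeClassifier().fit().predict(
        sample.values, channels=sample.channels)
    assert np.array_equal(labels, arr_labels)
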