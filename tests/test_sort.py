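"""PCA features, unit clustering, per-unit statistics, cross-session matching."""

import numpy as np
import pytest

from stripmea import (
    SortingParams,
    cluster_units,
    extract_features,
    make_template,
    match_units_across_sessions,
    sort_electrode,
    summarize_units,
)

FS = 30000.0


def cutouts_from_templates(templates, counts, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for k, (tmpl, n) in enumerate(zip(templates, counts)):
        block = np.tile(tmpl, (n, 1))
        if noise_sd:
            block = block + rng.normal(0, noise_sd, block.shape)
        blocks.append(block)
        labels.extend([k] * n)
    return np.vstack(blocks), np.array(labels)


def two_distinct_templates():
    a = make_template(80.0, FS, second_delay_ms=0.5, second_fraction=0.35)
    b = make_template(80.0, FS, second_delay_ms=1.0, second_fraction=0.65,
                      second_width_ms=0.55)
    return a, b


class _Ev:
    def __init__(self, time, cutout=None):
        self.time = time
        self.cutout = cutout if cutout is not None else np.zeros(150)
        self.ptp_amplitude = float(np.ptp(self.cutout))
        self.snr = 10.0


class TestExtractFeatures:
    def test_window_is_42_to_72_at_30khz(self):
        assert SortingParams().window_indices(FS) == (42, 72)

    def test_duplicated_templates_form_two_point_masses(self):
        a, b = two_distinct_templates()
        cutouts, labels = cutouts_from_templates([a, b], [50, 50])
        scores, sortable = extract_features(cutouts, sampling_rate=FS)
        assert sortable
        ca, cb = scores[labels == 0].mean(0), scores[labels == 1].mean(0)
        intra = max(
            scores[labels == 0].std(axis=0).max(),
            scores[labels == 1].std(axis=0).max(),
        )
        assert intra < 1e-9
        assert np.linalg.norm(ca - cb) > 1.0

    def test_identical_cutouts_score_at_origin(self):
        cutouts = np.tile(make_template(80.0), (20, 1))
        scores, sortable = extract_features(cutouts, sampling_rate=FS)
        assert sortable
        assert np.allclose(scores, 0.0)

    def test_scores_are_centered(self, rng):
        cutouts = rng.normal(0, 5, (40, 150))
        scores, _ = extract_features(cutouts, sampling_rate=FS)
        assert np.allclose(scores.mean(axis=0), 0.0, atol=1e-9)

    def test_retained_variance_bounded_by_window_variance(self, rng):
        cutouts = rng.normal(0, 5, (60, 150))
        params = SortingParams(n_components=2)
        scores, _ = extract_features(cutouts, params, FS)
        lo, hi = params.window_indices(FS)
        window = cutouts[:, lo:hi]
        total = ((window - window.mean(0)) ** 2).sum() / (len(window) - 1)
        retained = scores.var(axis=0, ddof=1).sum()
        assert retained <= total + 1e-9
        # with as many components as window samples, equality
        full, _ = extract_features(cutouts, SortingParams(n_components=30), FS)
        assert full.var(axis=0, ddof=1).sum() == pytest.approx(total)

    def test_too_few_cutouts_marks_unsortable(self):
        cutouts = np.tile(make_template(80.0), (5, 1))
        scores, sortable = extract_features(cutouts, sampling_rate=FS)
        assert not sortable
        assert scores.shape == (5, 2)


class TestClusterUnits:
    def test_two_well_separated_clusters_recovered(self, rng):
        a, b = two_distinct_templates()
        cutouts, truth = cutouts_from_templates([a, b], [100, 100], noise_sd=1.0)
        scores, _ = extract_features(cutouts, sampling_rate=FS)
        labels = cluster_units(scores)
        assert len(np.unique(labels)) == 2
        # accuracy after optimal label matching
        acc = max(
            np.mean(labels == truth),
            np.mean(labels == 1 - truth),
        )
        assert acc >= 0.95

    def test_single_cluster_not_oversplit(self):
        # one template + noise must mostly come back as k=1 over replicates
        tmpl = make_template(80.0, FS)
        k_ones = 0
        for seed in range(20):
            cutouts, _ = cutouts_from_templates([tmpl], [150], noise_sd=1.5, seed=seed)
            scores, _ = extract_features(cutouts, sampling_rate=FS)
            labels = cluster_units(scores, SortingParams(seed=seed))
            k_ones += len(np.unique(labels)) == 1
        assert k_ones >= 18

    def test_small_clusters_merged(self, rng):
        scores = np.vstack([
            rng.normal(0, 0.5, (98, 2)),
            rng.normal(20, 0.1, (2, 2)),  # below min_cluster_fraction of 100
        ])
        labels = cluster_units(scores, SortingParams(min_cluster_fraction=0.05))
        assert len(np.unique(labels)) == 1

    def test_determinism(self, rng):
        scores = rng.normal(0, 1, (200, 2))
        scores[100:] += 8.0
        p = SortingParams(seed=7)
        assert np.array_equal(cluster_units(scores, p), cluster_units(scores, p))

    def test_fixed_k_mode(self, rng):
        a, b = two_distinct_templates()
        cutouts, _ = cutouts_from_templates([a, b], [50, 50], noise_sd=0.5)
        scores, _ = extract_features(cutouts, sampling_rate=FS)
        labels = cluster_units(scores, SortingParams(cluster_selection="fixed_k", fixed_k=2))
        assert len(np.unique(labels)) == 2


class TestSortElectrode:
    def test_units_named_by_descending_count(self):
        a, b = two_distinct_templates()
        cutouts, _ = cutouts_from_templates([a, b], [150, 50], noise_sd=1.0)
        events = [_Ev(0.01 * k, c) for k, c in enumerate(cutouts)]
        ua = sort_electrode(events, sampling_rate=FS, electrode_id="E1")
        assert ua.n_units == 2
        counts = {u: ua.unit_labels.count(u) for u in ua.unit_ids}
        assert counts["U1"] >= counts["U2"]

    def test_unsortable_electrode_all_u1(self):
        events = [_Ev(0.1 * k, make_template(80.0)) for k in range(4)]
        ua = sort_electrode(events, sampling_rate=FS)
        assert not ua.sortable
        assert set(ua.unit_labels) == {"U1"}

    def test_templates_have_cutout_length(self):
        a, b = two_distinct_templates()
        cutouts, _ = cutouts_from_templates([a, b], [60, 60], noise_sd=1.0)
        events = [_Ev(0.01 * k, c) for k, c in enumerate(cutouts)]
        ua = sort_electrode(events, sampling_rate=FS)
        for tmpl in ua.templates.values():
            assert tmpl.size == 150


class TestSummarizeUnits:
    def test_unit_frequency_from_count(self):
        # 2,770 spikes over a 30-min frame is a 1.54 Hz unit
        events = [_Ev(t) for t in np.linspace(0, 1799, 2770)]
        table = summarize_units(events, ["U1"] * 2770, 1800.0)
        assert round(float(table.mean_frequency_hz.iloc[0]), 2) == 1.54

    def test_noise_events_excluded_and_counts_partition(self):
        events = [_Ev(0.1 * k) for k in range(100)]
        labels = ["U1"] * 60 + ["U2"] * 30 + ["noise"] * 10
        table = summarize_units(events, labels, 60.0)
        assert table.n_spikes.tolist() == [60, 30]
        assert table.n_spikes.sum() <= len(events)

    def test_empty_units_absent(self):
        events = [_Ev(0.1 * k) for k in range(10)]
        table = summarize_units(events, ["U1"] * 10, 60.0)
        assert table.unit_label.tolist() == ["U1"]


class TestMatchUnitsAcrossSessions:
    def test_identity_on_identical_sets(self):
        a, b = two_distinct_templates()
        ta = {"U1": a, "U2": b}
        pairs, ua, ub = match_units_across_sessions(ta, dict(ta))
        assert {(p[0], p[1]) for p in pairs} == {("U1", "U1"), ("U2", "U2")}
        assert all(p[2] == pytest.approx(1.0) for p in pairs)
        assert ua == ub == []

    def test_scaled_templates_still_pair(self):
        a, b = two_distinct_templates()
        pairs, _, _ = match_units_across_sessions(
            {"U1": a, "U2": b}, {"U1": 0.8 * a, "U2": 0.8 * b}
        )
        assert {(p[0], p[1]) for p in pairs} == {("U1", "U1"), ("U2", "U2")}

    def test_dissimilar_shapes_stay_unmatched(self, rng):
        a, _ = two_distinct_templates()
        noise = rng.normal(0, 1, a.size)
        pairs, ua, ub = match_units_across_sessions({"U1": a}, {"U1": noise})
        assert pairs == []
        assert ua == ["U1"] and ub == ["U1"]


class TestRecoveryGrid:
    def test_k_selection_on_well_separated_units(self):
        """k in {1,2,3} at >=5x separation: correct k in >=80% of replicates."""
        variants = [
            dict(second_delay_ms=0.5, second_fraction=0.35, second_width_ms=0.25),
            dict(second_delay_ms=1.0, second_fraction=0.65, second_width_ms=0.55),
            dict(second_delay_ms=1.5, second_fraction=0.5, second_width_ms=0.7),
        ]
        n_reps = 10
        for true_k in (1, 2, 3):
            hits = 0
            for seed in range(n_reps):
                templates = [make_template(80.0, FS, **variants[i]) for i in range(true_k)]
                cutouts, truth = cutouts_from_templates(
                    templates, [80] * true_k, noise_sd=1.0, seed=seed
                )
                scores, _ = extract_features(cutouts, sampling_rate=FS)
                labels = cluster_units(scores, SortingParams(seed=seed))
                hits += len(np.unique(labels)) == true_k
            assert hits >= 0.8 * n_reps, f"k={true_k}: {hits}/{n_reps}"
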