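"""IS mobilization: assignment, clustering, support index, strain comparison."""

import numpy as np
import pytest

from haloatlas import mobilome, simulate
from haloatlas.io import CoverageTrack, SvRecord


def sv(pos, seq, sv_class="insertion", lib="lib1"):
    return SvRecord("chr", pos, sv_class, seq, lib)


def event(start, element="IS1", sv_class="insertion", lib="lib1"):
    return mobilome.MobilizationEvent(
        library_id=lib, replicon_id="chr", start=start, sv_class=sv_class,
        element_id=element, identity=1.0, q_coverage=1.0, s_coverage=1.0,
    )


@pytest.fixture(scope="module")
def catalog():
    return simulate.random_is_catalog(n_elements=3, length_range=(300, 500), seed=20)


class TestAssignIs:
    def test_exact_copy_assigned_with_full_scores(self, catalog):
        element_id, seq = catalog[0]
        ev = mobilome.assign_is(sv(100, seq), catalog)
        assert ev.element_id == element_id
        assert ev.identity == pytest.approx(1.0)
        assert ev.q_coverage == pytest.approx(1.0)
        assert ev.s_coverage == pytest.approx(1.0)

    def test_decoy_below_identity_threshold_unassigned(self, catalog):
        rng = np.random.default_rng(21)
        _, seq = catalog[0]
        decoy = simulate._mutate(seq, 0.30, rng)  # ~70% identity
        ev = mobilome.assign_is(sv(100, decoy), catalog)
        assert not ev.assigned

    def test_partial_subject_coverage_unassigned(self, catalog):
        element_id, seq = catalog[0]
        fragment = seq[: int(0.6 * len(seq))]  # full identity, 60% of the IS
        ev = mobilome.assign_is(sv(100, fragment), catalog)
        assert not ev.assigned
        assert ev.s_coverage < 0.8

    def test_empty_sequence_rejected(self, catalog):
        record = SvRecord("chr", 100, "other", "", "lib1")
        with pytest.raises(ValueError, match="empty sequence"):
            mobilome.assign_is(record, catalog)

    def test_empty_catalog_rejected(self, catalog):
        with pytest.raises(ValueError, match="catalog"):
            mobilome.assign_is(sv(100, "ACGT"), [])


class TestClusterEvents:
    def test_nearby_pair_forms_one_cluster(self):
        clusters = mobilome.cluster_events([event(100), event(120)])
        (c,) = clusters
        assert c.mean_start == pytest.approx(110.0)
        assert c.e == 2

    def test_distant_events_stay_separate(self):
        clusters = mobilome.cluster_events([event(100), event(200)])
        assert len(clusters) == 2

    def test_single_linkage_chaining(self):
        # pairwise 100-180 exceeds the gap, but chaining joins via 140
        clusters = mobilome.cluster_events([event(100), event(140), event(180)])
        (c,) = clusters
        assert c.mean_start == pytest.approx(140.0)
        assert c.e == 3

    def test_chaining_matches_transitive_closure_oracle(self):
        rng = np.random.default_rng(22)
        starts = sorted(int(s) for s in rng.integers(0, 2000, size=40))
        clusters = mobilome.cluster_events([event(s) for s in starts], max_gap=50)
        # brute-force transitive closure of the <=50 bp adjacency relation
        groups, current = [], [starts[0]]
        for s in starts[1:]:
            if any(abs(s - t) <= 50 for t in current):
                current.append(s)
            else:
                groups.append(current)
                current = [s]
        groups.append(current)
        got = sorted((c.e, c.mean_start) for c in clusters)
        want = sorted((len(g), float(np.mean(g))) for g in groups)
        assert got == want

    def test_different_elements_never_merge(self):
        clusters = mobilome.cluster_events(
            [event(100, "IS1"), event(100, "IS2")]
        )
        assert len(clusters) == 2

    def test_different_classes_never_merge(self):
        clusters = mobilome.cluster_events(
            [event(100, sv_class="insertion"), event(110, sv_class="excision")]
        )
        assert len(clusters) == 2

    def test_unassigned_events_ignored(self):
        unassigned = mobilome.MobilizationEvent(
            "lib1", "chr", 100, "insertion", None, 0.5, 0.5, 0.5
        )
        assert mobilome.cluster_events([unassigned]) == []

    def test_order_invariance(self):
        events = [event(s) for s in [500, 100, 120, 530, 900]]
        forward = mobilome.cluster_events(events)
        backward = mobilome.cluster_events(events[::-1])
        key = lambda c: (c.mean_start, c.e)
        assert sorted(forward, key=key) == sorted(backward, key=key)

    def test_event_count_conserved_across_clusters(self):
        rng = np.random.default_rng(23)
        events = [event(int(s)) for s in rng.integers(0, 5000, size=60)]
        clusters = mobilome.cluster_events(events)
        assert sum(c.e for c in clusters) == len(events)

    def test_raising_max_gap_never_increases_cluster_count(self):
        rng = np.random.default_rng(24)
        events = [event(int(s)) for s in rng.integers(0, 3000, size=50)]
        counts = [
            len(mobilome.cluster_events(events, max_gap=g)) for g in (10, 50, 100, 400)
        ]
        assert counts == sorted(counts, reverse=True)


class TestLocalCoverage:
    def test_uniform_depth(self):
        track = CoverageTrack("chr", "+", np.full(200, 30.0))
        assert mobilome.local_coverage(track, 100) == pytest.approx(30.0)

    def test_window_clipped_at_edge(self):
        values = np.full(100, 10.0)
        values[:5] = 50.0
        track = CoverageTrack("chr", "+", values)
        # window [0, 26) at the left edge: 5 positions of 50, 21 of 10
        assert mobilome.local_coverage(track, 0) == pytest.approx(
            (5 * 50 + 21 * 10) / 26
        )

    def test_zero_coverage_rejected(self):
        track = CoverageTrack("chr", "+", np.zeros(100))
        with pytest.raises(ValueError, match="zero local coverage"):
            mobilome.local_coverage(track, 50)


class TestClassifyCluster:
    @pytest.mark.parametrize(
        "e,c,expected",
        [
            (2, 25, "rare"),       # 0.08 <= 0.1
            (2, 20, "rare"),       # boundary: exactly 0.1
            (10, 20, "common"),    # boundary: exactly 0.5
            (20, 25, "predominant"),
        ],
    )
    def test_threshold_boundaries(self, e, c, expected):
        assert mobilome.classify_cluster(e, c) == expected

    def test_piecewise_constant_in_ratio(self):
        boundaries = []
        previous = None
        for e in range(1, 40):
            cls = mobilome.classify_cluster(e, 40.0)
            if cls != previous:
                boundaries.append(cls)
                previous = cls
        assert boundaries == ["rare", "common", "predominant"]

    def test_zero_coverage_rejected(self):
        with pytest.raises(ValueError):
            mobilome.classify_cluster(1, 0.0)


class TestNormalizeCounts:
    def test_shallower_library_scaled_up(self):
        out = mobilome.normalize_counts(
            {"deep": 10, "shallow": 10}, {"deep": 1000, "shallow": 500}
        )
        assert out == {"deep": 10.0, "shallow": 20.0}

    def test_equal_depths_unchanged(self):
        out = mobilome.normalize_counts({"a": 7, "b": 9}, {"a": 800, "b": 800})
        assert out == {"a": 7.0, "b": 9.0}

    def test_zero_aligned_reads_rejected(self):
        with pytest.raises(ValueError):
            mobilome.normalize_counts({"a": 1}, {"a": 0})


class TestCompareStrains:
    def test_disjoint_intervals_are_different(self):
        out = mobilome.compare_strains({"wt": [10.0, 10.0], "ko": [4.0, 4.0]})
        assert out.verdict == "different"
        assert out.standard_errors["wt"] == 0.0

    def test_identical_replicates_not_different(self):
        out = mobilome.compare_strains({"wt": [5.0, 7.0], "ko": [5.0, 7.0]})
        assert out.verdict == "not_different"

    def test_single_replicate_is_insufficient(self):
        out = mobilome.compare_strains({"wt": [5.0], "ko": [4.0, 6.0]})
        assert out.verdict == "insufficient_replicates"

    def test_ci_is_mean_plus_minus_one_se(self):
        out = mobilome.compare_strains({"wt": [4.0, 6.0], "ko": [1.0, 2.0]})
        se = np.std([4.0, 6.0], ddof=1) / np.sqrt(2)
        assert out.ci["wt"] == pytest.approx((5.0 - se, 5.0 + se))


class TestPlantRecover:
    def test_noise_free_recovery_is_exact(self, catalog):
        records, _, truth = simulate.gen_sv_calls(
            12,
            events_per_cluster_range=(1, 20),
            coverage_per_library=25.0,
            n_noise_events=3,
            is_catalog=catalog,
            jitter_bp=50,
            seed=25,
        )
        events = [mobilome.assign_is(r, catalog) for r in records["lib1"]]
        clusters = mobilome.cluster_events(events)
        tracks = simulate.uniform_depth_tracks(
            ["lib1"], truth.params["coverage"], truth.params["genome_len"]
        )
        clusters = mobilome.annotate_clusters(clusters, tracks)
        planted = [r for r in truth.records if r["label"] == "planted"]
        assert len(clusters) == len(planted)
        got = sorted(
            (c.element_id, c.sv_class, c.mean_start, c.e, c.population_class)
            for c in clusters
        )
        want = sorted(
            (r["element_id"], r["sv_class"], r["mean_start"], r["e"], r["population_class"])
            for r in planted
        )
        assert got == want

    def test_decoys_land_unassigned(self, catalog):
        records, _, truth = simulate.gen_sv_calls(
            0, n_noise_events=4, is_catalog=catalog, seed=26
        )
        events = [mobilome.assign_is(r, catalog) for r in records["lib1"]]
        assert all(not ev.assigned for ev in events)
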