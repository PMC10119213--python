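import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from spheroidquant.calibration import PixelCalibration
from spheroidquant.events import (ApoptosisEvent, assign_event_zones,
                                  death_frequency, detect_apoptosis,
                                  ingest_mitoses, mann_whitney, summarize)
from spheroidquant.image_io import AnnotationTable
from spheroidquant.segmentation import FragmentCandidate, NucleusRecord
from spheroidquant.zones import Ellipse, build_zone_map


def frag(i, row, col, area, s=0):
    return FragmentCandidate(id=i, slice_index=s, centroid=(row, col),
                             area_um2=area, mean_intensity=1.0)


def nucleus(i, zone="invasion", row=10.0, col=10.0):
    return NucleusRecord(id=i, slice_index=0, centroid=(row, col),
                         area_um2=100.0, mean_intensity=1.0, zone=zone)


class TestDetectApoptosis:
    def test_single_fragment_below_area_floor_is_no_event(self, cal):
        assert detect_apoptosis([frag(1, 5, 5, 2.0)], cal) == []

    def test_two_fragments_beyond_twenty_micron_rule_no_event(self, cal):
        frags = [frag(1, 10, 10, 10.0), frag(2, 10, 35, 10.0)]  # 25 µm apart
        assert detect_apoptosis(frags, cal) == []

    def test_four_close_fragments_form_one_event(self, cal):
        frags = [frag(1, 10, 10, 5.0), frag(2, 10, 18, 5.0),
                 frag(3, 17, 10, 5.0), frag(4, 16, 16, 5.0)]
        events = detect_apoptosis(frags, cal)
        assert len(events) == 1
        assert sorted(events[0].member_ids) == [1, 2, 3, 4]
        np.testing.assert_allclose(events[0].center,
                                   np.mean([[10, 10], [10, 18],
                                            [17, 10], [16, 16]], axis=0))

    def test_over_ceiling_fragment_not_clustered(self, cal):
        frags = [frag(1, 10, 10, 30.0), frag(2, 10, 15, 10.0),
                 frag(3, 15, 10, 10.0)]
        events = detect_apoptosis(frags, cal)
        assert len(events) == 1
        assert 1 not in events[0].member_ids

    def test_calibration_scales_linking_distance(self):
        coarse = PixelCalibration(xy_size=2.0, z_step=10.0)
        # 15 px apart = 30 µm at 2 µm/px → no link
        frags = [frag(1, 10, 10, 10.0), frag(2, 10, 25, 10.0)]
        assert detect_apoptosis(frags, coarse) == []

    def test_fragments_on_different_slices_never_cluster(self, cal):
        frags = [frag(1, 10, 10, 10.0, s=0), frag(2, 10, 12, 10.0, s=1)]
        assert detect_apoptosis(frags, cal) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_single_linkage_oracle(self, cal, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 12)
        pts = rng.uniform(0, 80, size=(n, 2))
        areas = rng.uniform(1.0, 30.0, size=n)
        frags = [frag(i + 1, *pts[i], areas[i]) for i in range(n)]
        events = detect_apoptosis(frags, cal)

        # oracle: keep in-band points, then merge-any-pair-within-20 loop
        keep = [i for i in range(n) if 3.0 <= areas[i] <= 25.0]
        clusters = [{i} for i in keep]
        changed = True
        while changed:
            changed = False
            for a, b in itertools.combinations(range(len(clusters)), 2):
                if any(np.hypot(*(pts[i] - pts[j])) <= 20.0
                       for i in clusters[a] for j in clusters[b]):
                    clusters[a] |= clusters[b]
                    del clusters[b]
                    changed = True
                    break
        expected = sorted(sorted(i + 1 for i in c)
                          for c in clusters if len(c) >= 2)
        got = sorted(sorted(e.member_ids) for e in events)
        assert got == expected

    def test_no_fragment_double_counted_across_events(self, cal, rng):
        pts = rng.uniform(0, 200, size=(40, 2))
        frags = [frag(i + 1, *pts[i], 10.0) for i in range(40)]
        events = detect_apoptosis(frags, cal)
        members = [m for e in events for m in e.member_ids]
        assert len(members) == len(set(members))


class TestDeathFrequency:
    @staticmethod
    def _events(n, zone="invasion"):
        return [ApoptosisEvent(id=i, slice_index=0, center=(0, 0),
                               member_ids=[1, 2], zone=zone) for i in range(n)]

    def test_eight_events_ninety_two_nuclei_is_eight_percent(self):
        nuclei = [nucleus(i) for i in range(92)]
        assert death_frequency(self._events(8), nuclei, "invasion") \
            == pytest.approx(0.08)

    def test_zero_events_is_zero(self):
        assert death_frequency([], [nucleus(1)], "invasion") == 0.0

    def test_empty_zone_is_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="spheroidquant"):
            assert death_frequency([], [], "core") == 0.0
        assert "no events or nuclei" in caplog.text

    def test_counts_only_requested_zone(self):
        nuclei = [nucleus(1, zone="core"), nucleus(2, zone="invasion")]
        events = self._events(1, zone="invasion")
        assert death_frequency(events, nuclei, "invasion") == pytest.approx(0.5)
        assert death_frequency(events, nuclei, "core") == 0.0


def simple_zone_map():
    return build_zone_map(Ellipse((50, 50), 10, 10, 0.0),
                          Ellipse((50, 50), 20, 20, 0.0), (100, 100))


class TestIngestMitoses:
    def test_empty_table_gives_zero_frequencies(self, cal):
        table = AnnotationTable(rows=pd.DataFrame(
            columns=["slice", "row", "col", "label"]))
        out = ingest_mitoses(table, simple_zone_map(),
                             [nucleus(1, zone="core")], cal)
        assert out["frequencies"]["core"] == 0.0

    def test_two_mitoses_vs_98_nuclei(self, cal):
        rows = pd.DataFrame({"slice": [0, 0], "row": [50.0, 52.0],
                             "col": [48.0, 55.0], "label": ["mitosis"] * 2})
        nuclei = [nucleus(i, zone="core", row=50, col=50) for i in range(98)]
        out = ingest_mitoses(AnnotationTable(rows=rows), simple_zone_map(),
                             nuclei, cal)
        assert out["frequencies"]["core"] == pytest.approx(2 / 100)

    def test_duplicates_within_five_microns_collapse(self, cal, caplog):
        rows = pd.DataFrame({"slice": [0, 0], "row": [50.0, 51.0],
                             "col": [50.0, 51.0], "label": ["mitosis"] * 2})
        with caplog.at_level("WARNING", logger="spheroidquant"):
            out = ingest_mitoses(AnnotationTable(rows=rows), simple_zone_map(),
                                 [], cal)
        assert out["n_annotations_kept"] == 1

    def test_out_of_bounds_row_rejected_with_warning(self, cal, caplog):
        rows = pd.DataFrame({"slice": [0], "row": [500.0], "col": [50.0],
                             "label": ["mitosis"]})
        with caplog.at_level("WARNING", logger="spheroidquant"):
            out = ingest_mitoses(AnnotationTable(rows=rows), simple_zone_map(),
                                 [], cal)
        assert out["n_annotations_kept"] == 0


class TestSummarize:
    def test_zero_records_give_all_zero_result(self, cal):
        res = summarize([], [], None, simple_zone_map(), None, cal)
        assert res.zone_totals == {"core": 0, "rim": 0, "invasion": 0}
        assert res.invasion_max_distance_um == 0.0
        assert all(v == 0.0 for v in res.death_frequencies.values())

    def test_tables_round_counts_and_frequencies(self, cal):
        nuclei = [nucleus(i, zone="invasion") for i in range(4)]
        for i, n in enumerate(nuclei):
            n.radial_distance_um = 100.0 + i
        events = [ApoptosisEvent(id=1, slice_index=0, center=(1, 1),
                                 member_ids=[1, 2], zone="invasion")]
        res = summarize(nuclei, events, None, simple_zone_map(), None, cal)
        assert res.zone_totals["invasion"] == 4
        assert res.death_frequencies["invasion"] == pytest.approx(1 / 5)
        assert res.invasion_max_distance_um == pytest.approx(103.0)
        table = res.zone_summary_table()
        assert set(table["zone"]) == {"core", "rim", "invasion"}


def mann_whitney_oracle(a, b):
    """Permutation enumeration via U computed from pairwise comparisons."""
    pooled = list(a) + list(b)
    n1 = len(a)

    def u_stat(idx_a):
        ua = 0.0
        idx_b = [i for i in range(len(pooled)) if i not in idx_a]
        for i in idx_a:
            for j in idx_b:
                if pooled[i] > pooled[j]:
                    ua += 1.0
                elif pooled[i] == pooled[j]:
                    ua += 0.5
        return ua

    mid = n1 * (len(pooled) - n1) / 2.0
    obs = abs(u_stat(tuple(range(n1))) - mid)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_stat(combo) - mid) >= obs - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_identical_groups_give_p_one(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_fully_separated_triples(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2 of C(6,3)=20 assignments
        assert "exact" in res.method

    @pytest.mark.parametrize("seed", range(15))
    def test_exact_branch_equals_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1 = int(rng.integers(1, 6))
        n2 = int(rng.integers(1, 6))
        # integer values provoke ties
        a = rng.integers(0, 6, n1).tolist()
        b = rng.integers(0, 6, n2).tolist()
        res = mann_whitney(a, b)
        assert res.p_value == pytest.approx(mann_whitney_oracle(a, b))

    def test_large_sample_branch_close_to_scipy(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.8, 1, 25)
        res = mann_whitney(a, b)
        assert "approximation" in res.method
        ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue, rel=0.02)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_u_bounded_by_product_of_sizes(self, rng):
        for _ in range(20):
            a = rng.normal(size=rng.integers(1, 8))
            b = rng.normal(size=rng.integers(1, 8))
            res = mann_whitney(a, b)
            assert 0 <= res.u_statistic <= len(a) * len(b)
            assert 0 <= res.p_value <= 1


class TestEventZones:
    def test_event_zone_from_center_pixel(self):
        zm = simple_zone_map()
        ev = ApoptosisEvent(id=1, slice_index=0, center=(50, 52),
                            member_ids=[1, 2])
        assign_event_zones([ev], zm)
        assert ev.zone == "core"
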