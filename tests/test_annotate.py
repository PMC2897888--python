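"""Annotation analyses: family counting, induction table, tandems,
compartment enrichment, site classification, conservation profiles."""

import numpy as np
import pytest

from chipgas.annotate import (
    TandemPair,
    average_profile,
    classify_sites,
    compartment_enrichment,
    find_tandem_sites,
    merge_intervals,
    repeat_induction_table,
    spacing_induction_histogram,
    tags_in_annotations,
)
from chipgas.motif import PredictedSite
from chipgas.sga import GenomicInterval, TagRecord


def centered(pos, count, chrom="chr1"):
    return TagRecord(chrom, "c", pos, "0", count)


def iv(start, end, name="fam", class_label=None, chrom="chr1"):
    return GenomicInterval(chrom, start, end, name, class_label)


class TestMergeIntervals:
    def test_overlapping_and_adjacent_merge(self):
        merged = merge_intervals([iv(1, 10), iv(5, 20), iv(21, 30),
                                  iv(50, 60)])
        assert [(m.start, m.end) for m in merged] == [(1, 30), (50, 60)]

    def test_chromosomes_kept_separate(self):
        merged = merge_intervals([iv(1, 10), iv(1, 10, chrom="chr2")])
        assert len(merged) == 2


class TestTagsInAnnotations:
    def test_no_intervals_gives_empty_table(self):
        assert tags_in_annotations([centered(5, 1)], []).empty

    def test_interval_bounds_inclusive(self):
        table = tags_in_annotations(
            [centered(100, 7), centered(200, 3), centered(201, 9)],
            [iv(100, 200)])
        assert table.loc["fam", "tags"] == 10

    def test_nested_same_name_intervals_count_once(self):
        table = tags_in_annotations(
            [centered(150, 5)], [iv(100, 200), iv(140, 160)])
        assert table.loc["fam", "tags"] == 5
        assert table.loc["fam", "coverage_bp"] == 101

    def test_matches_brute_force_membership(self):
        rng = np.random.default_rng(15)
        records = [centered(int(p), int(c)) for p, c in
                   zip(rng.integers(1, 5000, 300), rng.integers(1, 5, 300))]
        intervals = []
        for name in ("A", "B"):
            for _ in range(5):
                s = int(rng.integers(1, 4500))
                intervals.append(iv(s, s + int(rng.integers(10, 400)), name))
        table = tags_in_annotations(records, intervals)
        for name in ("A", "B"):
            merged = merge_intervals([v for v in intervals if v.name == name])
            brute = sum(r.count for r in records
                        if any(m.start <= r.pos <= m.end for m in merged))
            assert table.loc[name, "tags"] == brute

    def test_partition_sums_to_total_count(self):
        records = [centered(p, 2) for p in range(1, 1001, 7)]
        intervals = [iv(1, 500, "left"), iv(501, 1000, "right")]
        table = tags_in_annotations(records, intervals)
        assert table["tags"].sum() == sum(r.count for r in records)


class TestRepeatInductionTable:
    def test_identical_conditions_give_zero_ratios(self):
        records = [centered(p, 3) for p in (100, 200, 300)]
        annotations = [iv(50, 350, "fam", "LTR")]
        table = repeat_induction_table(records, records, annotations,
                                       10_000, 10_000, min_coverage_kb=0.1)
        assert (table["ln_ratio"] == 0.0).all()

    def test_published_family_counts_reproduce(self):
        # one family whose window holds the printed MER41B totals
        stim = [centered(500, 68619)]
        unstim = [centered(500, 3978)]
        table = repeat_induction_table(
            stim, unstim, [iv(1, 150_000, "MER41B", "LTR")],
            15250744, 13019977, min_coverage_kb=100)
        row = table[table["name"] == "MER41B"].iloc[0]
        assert row["ln_ratio"] == 2.69

    def test_coverage_filter_is_strict(self):
        records = [centered(500, 10)]
        annotations = [iv(1, 100_000, "exact", "LTR")]  # exactly 100 kb
        table = repeat_induction_table(records, records, annotations,
                                       1000, 1000, min_coverage_kb=100)
        assert "exact" not in set(table["name"])
        assert "Class" in set(table["name"])  # pooled row still present

    def test_induced_family_ranks_first(self, small_truth, stim_tags,
                                        unstim_tags):
        from chipgas.tagproc import center_tags
        cfg = small_truth.config
        stim_c = center_tags(stim_tags, 70)
        unstim_c = center_tags(unstim_tags, 70)
        table = repeat_induction_table(
            stim_c, unstim_c, small_truth.repeat_intervals,
            cfg.stim_library_total, cfg.unstim_library_total,
            min_coverage_kb=1)
        families = table[table["name"] != "Class"]
        assert families.iloc[0]["name"] == "SynMER41"
        assert families.iloc[0]["ln_ratio"] > 2.0
        control = families[families["name"] == "SynAlu"]
        assert abs(control.iloc[0]["ln_ratio"]) < 1.0

    def test_row_ratio_consistent_with_own_counts(self, small_truth,
                                                  stim_tags, unstim_tags):
        from chipgas.occupancy import induction_log_ratio
        from chipgas.tagproc import center_tags
        stim_c = center_tags(stim_tags, 70)
        unstim_c = center_tags(unstim_tags, 70)
        n_stim = sum(r.count for r in stim_tags)
        n_unstim = sum(r.count for r in unstim_tags)
        table = repeat_induction_table(
            stim_c, unstim_c, small_truth.repeat_intervals,
            n_stim, n_unstim, min_coverage_kb=1)
        for _, row in table.iterrows():
            assert row["ln_ratio_exact"] == pytest.approx(
                induction_log_ratio(row["tags_stim"], row["tags_unstim"],
                                    n_stim, n_unstim))


class TestFindTandemSites:
    def site(self, pos, score, chrom="chr1"):
        return PredictedSite(chrom, pos, "+", score)

    def test_pair_within_spacing_and_score(self):
        pairs = find_tandem_sites([self.site(100, 31), self.site(121, 35)])
        assert len(pairs) == 1
        assert pairs[0].spacing == 21
        assert pairs[0].mean_score == 33.0

    def test_mean_score_gate_is_strict(self):
        assert find_tandem_sites([self.site(100, 31), self.site(121, 28)]) == []
        assert find_tandem_sites([self.site(100, 31), self.site(121, 29)]) == []

    def test_spacing_gate(self):
        assert find_tandem_sites([self.site(100, 40), self.site(201, 40)]) == []
        pairs = find_tandem_sites([self.site(100, 40), self.site(200, 40)])
        assert len(pairs) == 1

    def test_midpoint_repeat_membership(self):
        repeat = [iv(90, 130, "rep")]
        pairs = find_tandem_sites(
            [self.site(100, 40), self.site(121, 40)],
            repeat_intervals=repeat)
        assert pairs[0].in_repeat
        pairs = find_tandem_sites(
            [self.site(500, 40), self.site(521, 40)],
            repeat_intervals=repeat)
        assert not pairs[0].in_repeat

    def test_equals_all_pairs_oracle(self):
        rng = np.random.default_rng(23)
        sites = sorted(
            (self.site(int(p), int(s)) for p, s in
             zip(rng.integers(1, 20_000, 500), rng.integers(20, 45, 500))),
            key=lambda s: s.pos)
        got = {(p.pos1, p.pos2) for p in find_tandem_sites(sites)}
        expected = set()
        for a in sites:
            for b in sites:
                sp = b.pos - a.pos
                if 0 < sp <= 100 and (a.score + b.score) / 2 > 30:
                    expected.add((a.pos, b.pos))
        assert got == expected


class TestSpacingInductionHistogram:
    def test_empty_pairs_give_empty_output(self):
        pair_table, summary = spacing_induction_histogram(
            [], [], [], 1000, 1000)
        assert pair_table.empty and summary.empty

    def test_induced_cutoff_splits_summary(self):
        pairs = [TandemPair("chr1", 1000, 1021, 40.0, True),
                 TandemPair("chr1", 9000, 9019, 40.0, False)]
        stim = [centered(1010, 400), centered(9010, 4)]
        unstim = [centered(1010, 4), centered(9010, 4)]
        pair_table, summary = spacing_induction_histogram(
            pairs, stim, unstim, 10_000, 10_000)
        induced = summary[summary["in_repeat"]]
        assert list(induced["spacing"]) == [21]
        assert not (summary["spacing"] == 19).any()

    def test_window_is_plus_minus_200_around_midpoint(self):
        pairs = [TandemPair("chr1", 1000, 1021, 40.0, False)]
        # midpoint floors to 1010; window [810, 1210] inclusive
        stim = [centered(809, 1), centered(810, 5), centered(1210, 7),
                centered(1211, 2)]
        pair_table, _ = spacing_induction_histogram(
            pairs, stim, [], 1000, 1000)
        assert pair_table.iloc[0]["tags_stim"] == 12


class TestCompartmentEnrichment:
    def test_published_upstream_ratio(self):
        # 7197 genome-wide instances, 1183 overlapping the upstream
        # compartment; compartment/genome sizes as printed in Mb
        inside = [iv(1000 + 400 * i, 1000 + 400 * i + 329, "MER41")
                  for i in range(1183)]
        outside = [iv(400_000_000 + 400 * i, 400_000_000 + 400 * i + 329,
                      "MER41") for i in range(7197 - 1183)]
        compartment = [iv(1, 347_000_000, "upstream")]
        ratio = compartment_enrichment(inside + outside, compartment,
                                       347.0, 3093.0)
        assert ratio == pytest.approx(1.465, abs=0.001)
        assert abs(ratio - 1.46) / 1.46 < 0.01

    def test_compartment_equal_to_genome_gives_unity(self):
        instances = [iv(100, 400), iv(700, 900)]
        compartment = [iv(1, 1000)]
        assert compartment_enrichment(instances, compartment, 1.0, 1.0) \
            == pytest.approx(2 / 2)

    def test_overlap_threshold_boundary(self):
        compartment = [iv(1000, 2000)]
        nine = [iv(900, 1008)]   # overlap 1000..1008 = 9 bp
        ten = [iv(900, 1009)]    # overlap 1000..1009 = 10 bp
        assert compartment_enrichment(nine, compartment, 1.0, 2.0) == 0.0
        assert compartment_enrichment(ten, compartment, 1.0, 2.0) \
            == pytest.approx(2.0)

    def test_zero_lengths_rejected(self):
        with pytest.raises(ValueError):
            compartment_enrichment([iv(1, 2)], [iv(1, 2)], 0.0, 1.0)


class TestClassifySites:
    def site(self, pos, score=35):
        return PredictedSite("chr1", pos, "+", score)

    def test_tagless_distant_site_is_class_one(self):
        per_site, _ = classify_sites([self.site(5000)], [],
                                     [("chr1", 8000)])
        row = per_site.iloc[0]
        assert row["occupation_class"] == 1 and not row["at_tss"]

    @pytest.mark.parametrize("tags, expected", [
        (0, 1), (1, 2), (5, 2), (6, 3), (14, 3), (15, 4),
    ])
    def test_occupation_class_bin_edges(self, tags, expected):
        records = [centered(5000, tags)] if tags else []
        per_site, _ = classify_sites([self.site(5000)], records, [])
        assert per_site.iloc[0]["occupation_class"] == expected

    def test_tss_radius_boundary(self):
        per_site, _ = classify_sites([self.site(5000)], [],
                                     [("chr1", 6000)])
        assert per_site.iloc[0]["at_tss"]
        per_site, _ = classify_sites([self.site(5000)], [],
                                     [("chr1", 6001)])
        assert not per_site.iloc[0]["at_tss"]

    def test_summary_matches_brute_force_classification(self):
        rng = np.random.default_rng(31)
        sites = [self.site(int(p), int(s)) for p, s in
                 zip(rng.integers(1, 30_000, 100), rng.integers(31, 44, 100))]
        records = [centered(int(p), int(c)) for p, c in
                   zip(np.sort(rng.integers(1, 30_000, 400)),
                       rng.integers(1, 8, 400))]
        tss = [("chr1", int(p)) for p in rng.integers(1, 30_000, 10)]
        per_site, summary = classify_sites(sites, records, tss)
        assert summary["n_sites"].sum() == len(sites)
        for _, row in per_site.iterrows():
            n = sum(r.count for r in records
                    if abs(r.pos - row["pos"]) <= 100)
            expected = 1 if n == 0 else 2 if n <= 5 else 3 if n <= 14 else 4
            assert row["occupation_class"] == expected
            assert row["at_tss"] == any(abs(t - row["pos"]) <= 1000
                                        for _, t in tss)


class TestAverageProfile:
    def test_constant_track_gives_constant_profile(self):
        track = [("chr1", p, 0.3) for p in range(1, 2001)]
        profiles = average_profile({"cls": [("chr1", 1000)]}, track,
                                   dmin=-50, dmax=50)
        _, values = profiles["cls"]
        np.testing.assert_allclose(values, 0.3)

    def test_empty_class_skipped(self):
        profiles = average_profile({"empty": [], "full": [("chr1", 100)]},
                                   [("chr1", 100, 1.0)], dmin=-5, dmax=5)
        assert "empty" not in profiles and "full" in profiles

    def test_elevation_at_planted_sites_peaks_at_zero_offset(self, small_truth):
        occupied = [(s.chrom, s.pos) for s in small_truth.sites[:30]]
        track = small_truth.conservation_track()
        profiles = average_profile({"sites": occupied}, track,
                                   dmin=-100, dmax=100)
        offsets, values = profiles["sites"]
        cfg = small_truth.config
        center = values[np.flatnonzero(offsets == 0)][0]
        edge = values[np.abs(offsets) > 50].mean()
        assert center == pytest.approx(cfg.conservation_site_level)
        assert center > edge
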