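"""Tajima's D, window tiling, outlier merging, paralog stratification."""

import numpy as np
import pytest
from scipy import stats

from lowcov import (
    AnnotationSet,
    WindowStat,
    gene_average_d,
    merge_outlier_regions,
    paralog_age_comparison,
    simulate_panel,
    sliding_window_scan,
    tajimas_d,
)
from conftest import tajima_oracle


def _window(start, end, D, chrom="chr1", S=5):
    return WindowStat(chrom, start, end, 21, S, 2.0, D)


class TestTajimasD:
    def test_no_segregating_sites_is_undefined(self):
        m = np.zeros((21, 10), dtype=int)
        m[:, 3] = 1  # fixed column is not segregating
        S, pi, D = tajimas_d(21, m)
        assert S == 0 and D is None

    def test_all_singletons_give_negative_d(self):
        m = np.zeros((21, 12), dtype=int)
        for j in range(12):
            m[j % 21, j] = 1
        S, pi, D = tajimas_d(21, m)
        assert S == 12
        assert D < 0
        oracle = tajima_oracle(m)
        assert D == pytest.approx(oracle[2], abs=1e-12)

    def test_intermediate_frequencies_give_positive_d(self):
        m = np.zeros((10, 8), dtype=int)
        m[:5, :] = 1  # every variant at frequency 0.5
        _, _, D = tajimas_d(10, m)
        assert D > 0

    def test_toy_matrix_matches_straight_line_oracle(self):
        m = np.array([
            [0, 1, 0, 0, 1],
            [0, 0, 0, 1, 1],
            [1, 0, 0, 0, 1],
            [0, 0, 0, 1, 1],
        ])
        S, pi, D = tajimas_d(4, m)
        oS, opi, oD = tajima_oracle(m)
        assert (S, pi) == (oS, pytest.approx(opi))
        assert D == pytest.approx(oD, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_matrices_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(0, 2, size=(21, 30))
        got, want = tajimas_d(21, m), tajima_oracle(m)
        if want[2] is None:
            assert got[2] is None
        else:
            assert got[2] == pytest.approx(want[2], abs=1e-10)
            assert got[1] == pytest.approx(want[1], abs=1e-10)

    def test_fewer_than_two_chromosomes_rejected(self):
        with pytest.raises(ValueError):
            tajimas_d(1, np.zeros((1, 5)))


class TestSlidingWindowScan:
    def test_window_tiling_arithmetic(self):
        positions = np.array([100, 12_000, 24_999])
        counts = np.array([3, 10, 1])
        windows = sliding_window_scan({"chr1": (positions, counts)},
                                      10_000, 5_000, 21)
        starts = [w.start for w in windows]
        assert starts == [1, 5_001, 10_001, 15_001, 20_001]
        assert all(w.length == 10_000 for w in windows)

    def test_boundary_site_inclusive_membership(self):
        """A site at 10,000 belongs to [1,10000] and [5001,15000]."""
        positions = np.array([10_000])
        counts = np.array([7])
        windows = sliding_window_scan({"chr1": (positions, counts)},
                                      10_000, 5_000, 21)
        covering = [w for w in windows if w.S == 1]
        assert [(w.start, w.end) for w in covering] == \
            [(1, 10_000), (5_001, 15_000)]

    def test_site_counts_match_independent_recount(self):
        panel = simulate_panel(21, 400, region_length=120_000, seed=90,
                               recombination_intensity=2.0)
        windows = sliding_window_scan(
            {"chr1": (panel.positions, panel.matrix)}, 10_000, 5_000, 21)
        counts = panel.matrix.sum(axis=0)
        for w in windows:
            inside = (panel.positions >= w.start) & (panel.positions <= w.end)
            seg = ((counts[inside] > 0) & (counts[inside] < 21)).sum()
            assert w.S == seg

    def test_multiple_chromosomes(self):
        v = {
            "chr1": (np.array([5_000]), np.array([4])),
            "chr2": (np.array([2_000, 14_000]), np.array([1, 20])),
        }
        windows = sliding_window_scan(v, 10_000, 5_000, 21)
        assert {w.chromosome for w in windows} == {"chr1", "chr2"}

    def test_bad_geometry_rejected(self):
        with pytest.raises(ValueError):
            sliding_window_scan({}, 0, 5_000)
        with pytest.raises(ValueError):
            sliding_window_scan({}, 10_000, -1)


class TestMergeOutlierRegions:
    def test_no_qualifying_windows(self):
        assert merge_outlier_regions([_window(1, 10_000, -1.5)], -2.0) == []

    def test_overlapping_windows_concatenate(self):
        regions = merge_outlier_regions(
            [_window(1, 10_000, -2.5), _window(5_001, 15_000, -2.2)], -2.0)
        assert regions == [("chr1", 1, 15_000)]

    def test_separated_clusters_stay_apart(self):
        regions = merge_outlier_regions([
            _window(1, 10_000, -2.5),
            _window(5_001, 15_000, -1.0),      # not qualifying
            _window(20_001, 30_000, -2.1),
        ], -2.0)
        assert len(regions) == 2

    def test_positive_cutoff_selects_balancing_windows(self):
        regions = merge_outlier_regions(
            [_window(1, 10_000, 2.5), _window(20_001, 30_000, -2.5)], 2.0)
        assert regions == [("chr1", 1, 10_000)]

    def test_undefined_d_never_qualifies(self):
        assert merge_outlier_regions([_window(1, 10_000, None)], -2.0) == []

    def test_merged_length_equals_union_of_qualifying_windows(self):
        rng = np.random.default_rng(3)
        windows = [
            _window(s, s + 9_999, float(d))
            for s, d in zip(range(1, 200_001, 5_000),
                            rng.normal(-1.8, 0.6, size=40))
        ]
        regions = merge_outlier_regions(windows, -2.0)
        qualifying = [w for w in windows if w.D < -2.0]
        union = set()
        for w in qualifying:
            union.update(range(w.start, w.end + 1))
        merged = sum(end - start + 1 for _, start, end in regions)
        assert merged == len(union)


class TestGeneAverageD:
    def test_single_window_gene(self):
        stats_ = gene_average_d([("g1", 2_000, 3_000)],
                                [_window(1, 10_000, -2.1)])
        assert stats_[0].mean_D == pytest.approx(-2.1)

    def test_two_window_average(self):
        stats_ = gene_average_d(
            [("g1", 8_000, 12_000)],
            [_window(1, 10_000, -1.0), _window(10_001, 20_000, -3.0)])
        assert stats_[0].mean_D == pytest.approx(-2.0)

    def test_no_overlap_flagged_missing(self):
        stats_ = gene_average_d([("g1", 50_000, 60_000)],
                                [_window(1, 10_000, -1.0)])
        assert stats_[0].mean_D is None


def _annotation_fixture(n_per_class=12, spacing=300_000):
    """Genes on a long axis; paralog pairs tagged by age class."""
    genes, pairs = [], []
    classes = ("species_specific", "primate", "eutherian", "vertebrate")
    gid = 0
    pos = 1
    for cls in classes:
        for _ in range(n_per_class):
            g1, g2 = f"g{gid}", f"g{gid + 1}"
            genes.append((g1, pos, pos + 10_000))
            genes.append((g2, pos + spacing, pos + spacing + 10_000))
            pairs.append((g1, g2, cls, spacing < 250_000))
            gid += 2
            pos += 2 * spacing
    for _ in range(40):  # background singletons
        genes.append((f"g{gid}", pos, pos + 10_000))
        gid += 1
        pos += spacing
    return AnnotationSet(genes, pairs, [], set(), classes)


class TestParalogAgeComparison:
    def test_proximal_pairs_excluded(self):
        ann = _annotation_fixture(n_per_class=3, spacing=100_000)
        from lowcov import GeneStat
        gs = [GeneStat(g, s, e, 0.0) for g, s, e in ann.genes]
        res = paralog_age_comparison(gs, ann)
        assert res["n_pairs"] == 0

    def test_recovers_planted_class_ordering_and_kw_statistic(self):
        """Young classes planted 1 unit lower recover the ordering; the
        Kruskal-Wallis statistic matches a direct rank computation."""
        ann = _annotation_fixture()
        rng = np.random.default_rng(8)
        offsets = {"species_specific": -1.5, "primate": -1.0,
                   "eutherian": -0.5, "vertebrate": 0.0}
        from lowcov import GeneStat
        pair_class = {}
        for g1, g2, cls, _ in ann.paralog_pairs:
            pair_class[g1] = pair_class[g2] = cls
        gs = []
        for g, s, e in ann.genes:
            d = rng.normal(offsets.get(pair_class.get(g), 0.0), 0.3)
            gs.append(GeneStat(g, s, e, float(d)))
        res = paralog_age_comparison(gs, ann)
        summary = res["summary"].set_index("age_class")
        means = summary.loc[list(offsets), "mean_D"]
        assert list(means.index[np.argsort(means.to_numpy())]) == \
            list(offsets)
        # independent rank-based Kruskal-Wallis
        groups = []
        for cls in offsets:
            groups.append([g.mean_D for g in gs if pair_class.get(g.gene_id) == cls])
        groups.append([g.mean_D for g in gs if g.gene_id not in pair_class])
        all_vals = np.concatenate(groups)
        ranks = stats.rankdata(all_vals)
        n = len(all_vals)
        start, h = 0, 0.0
        for g in groups:
            r = ranks[start:start + len(g)]
            h += r.sum() ** 2 / len(g)
            start += len(g)
        h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
        assert res["kruskal_statistic"] == pytest.approx(h, rel=1e-9)
        assert res["kruskal_p"] < 1e-6
        assert res["greater_member_p"] < 1e-3

    def test_null_kruskal_p_is_uniform(self):
        """With no class effect, KW p over 200 replicates is uniform."""
        ann = _annotation_fixture(n_per_class=8)
        from lowcov import GeneStat
        pvals = []
        rng = np.random.default_rng(12)
        for _ in range(200):
            gs = [GeneStat(g, s, e, float(rng.normal()))
                  for g, s, e in ann.genes]
            pvals.append(paralog_age_comparison(gs, ann)["kruskal_p"])
        _, p = stats.kstest(pvals, "uniform")
        assert p > 0.01


class TestNeutralCalibration:
    def test_mean_d_near_zero_under_neutral_simulation(self):
        """>=500 neutral 21-chromosome windows: mean D in (-0.5, 0.5),
        |D| > 2 in under 5% of windows."""
        ds = []
        for seed in range(550):
            panel = simulate_panel(21, 12, region_length=10_000,
                                   recombination_intensity=1.0,
                                   seed=5_000 + seed)
            _, _, D = tajimas_d(21, panel.matrix)
            if D is not None:
                ds.append(D)
        ds = np.array(ds)
        assert len(ds) >= 500
        assert -0.5 < ds.mean() < 0.5
        assert np.mean(np.abs(ds) > 2) < 0.05

    def test_frequency_spectrum_direction(self):
        """Enriching singletons lowers D; enriching intermediate
        frequencies raises it, monotonically over three levels."""
        rng = np.random.default_rng(77)

        def mean_d(singleton_weight):
            ds = []
            for _ in range(10):
                m = np.zeros((21, 40), dtype=int)
                for j in range(40):
                    if rng.random() < singleton_weight:
                        m[rng.integers(21), j] = 1
                    else:
                        k = rng.integers(8, 13)
                        m[rng.choice(21, size=k, replace=False), j] = 1
                ds.append(tajimas_d(21, m)[2])
            return np.mean(ds)

        levels = [mean_d(w) for w in (0.9, 0.5, 0.1)]
        assert levels[0] < levels[1] < levels[2]
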