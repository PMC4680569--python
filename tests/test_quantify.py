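"""M-index, concordance, FPR, detection rates, windows, rarefaction."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methylrad as mr


def depth_table(counts: dict, sample="s", library=None):
    series = pd.Series(counts, dtype=float)
    return mr.DepthTable(sample, series, library or int(series.sum()))


def big_table(depths, sample="s"):
    return depth_table({f"site{i}": d for i, d in enumerate(depths)}, sample)


class TestMIndex:
    def _table(self):
        # 100 sites: calibration top 2% = 2 deepest sites (both depth 100)
        depths = [100, 100] + [10] * 49 + [1] * 49
        return big_table(depths)

    def test_depth_max_site_has_m_one(self):
        mt = mr.m_index(self._table())
        assert mt.depth_max == pytest.approx(100.0)
        assert mt.m["site0"] == pytest.approx(1.0)

    def test_depth_one_site_detected_with_m_zero(self):
        mt = mr.m_index(self._table())
        assert mt.m["site99"] == 0.0
        assert "site99" in mt.depth.index  # still detected

    def test_log_ratio_closed_form(self):
        mt = mr.m_index(self._table())
        assert mt.m["site2"] == pytest.approx(math.log(10) / math.log(100))

    def test_zero_depth_sites_absent(self):
        table = big_table([100, 100] + [0] * 30 + [5] * 60)
        mt = mr.m_index(table)
        assert len(mt.m) == 62

    def test_depth_max_le_one_rejected(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.raises(ValueError, match="depth_max"):
                mr.m_index(big_table([1] * 60))

    def test_few_sites_warns(self):
        with pytest.warns(UserWarning, match="detected sites"):
            mr.m_index(big_table([50] * 10 + [5] * 10))

    def test_repetitive_sites_excluded_from_calibration(self):
        depths = [10000] + [100, 100] + [10] * 97
        table = big_table(depths)
        mt = mr.m_index(table, repetitive_ids={"site0"}, source="denovo")
        assert mt.depth_max == pytest.approx(100.0)
        assert mt.m["site0"] == 1.0  # capped

    def test_monotone_in_depth(self):
        mt = mr.m_index(big_table(range(1, 101)))
        ordered = mt.m.loc[[f"site{i}" for i in range(99)]].to_numpy()
        assert (np.diff(ordered) >= 0).all()

    def test_power_rescaling_invariant_with_max_calibration(self):
        # depth -> depth**2 rescales log-depth linearly; with max calibration
        # depth_max transforms the same way, leaving M unchanged
        depths = np.array([100, 80, 40, 10, 3, 2] + [7] * 60)
        a = mr.m_index(big_table(depths), calibration="max")
        b = mr.m_index(big_table(depths.astype(np.int64) ** 2), calibration="max")
        assert np.allclose(a.m.to_numpy(), b.m.to_numpy())


class TestTrinaryCall:
    @pytest.mark.parametrize("m,call", [
        (0.95, "high"), (0.80, "high"), (0.5, "medium"),
        (0.20, "low"), (0.05, "low")])
    def test_cutoffs(self, m, call):
        assert mr.trinary_call(m) == call


class TestConcordance:
    def _mt(self, values, sample="a"):
        s = pd.Series(values)
        return mr.MIndexTable(sample_id=sample, m=s,
                              depth=pd.Series(10.0, index=s.index),
                              depth_max=100.0)

    def test_identical_tables_fully_concordant(self):
        a = self._mt({"x": 0.9, "y": 0.5, "z": 0.1})
        assert mr.concordance(a, a)["concordance_pct"] == 100.0

    def test_divergent_single_site_zero(self):
        res = mr.concordance(self._mt({"x": 0.9}), self._mt({"x": 0.5}, "b"))
        assert res["concordance_pct"] == 0.0

    def test_same_call_or_small_difference_suffices(self):
        a = self._mt({"x": 0.85, "y": 0.45})
        b = self._mt({"x": 0.95, "y": 0.50}, "b")  # same call / small diff
        assert mr.concordance(a, b)["concordance_pct"] == 100.0

    def test_symmetric(self):
        a = self._mt({"x": 0.9, "y": 0.3, "z": 0.15, "w": 0.55})
        b = self._mt({"x": 0.2, "y": 0.35, "z": 0.8, "w": 0.5}, "b")
        assert mr.concordance(a, b) == mr.concordance(b, a)

    def test_no_shared_sites_rejected(self):
        with pytest.raises(ValueError):
            mr.concordance(self._mt({"x": 0.5}), self._mt({"y": 0.5}, "b"))

    def test_replicate_pair_high_concordance(self):
        cfg = mr.SimConfig(seed=31, genome_length=60_000, control_length=0)
        _, catalog = mr.simulate_genome(cfg)
        truth = mr.assign_methylation(catalog, seed=32)
        mts = []
        for s in (33, 34):
            counts = mr.simulate_counts(truth, cfg, seed=s)
            mts.append(mr.m_index(mr.DepthTable(
                f"rep{s}", counts[counts > 0].astype(float),
                int(counts.sum()))))
        res = mr.concordance(*mts)
        assert res["concordance_pct"] >= 90.0


class TestFPR:
    def _setup(self):
        """Catalog whose control contig carries 1948 possible sites, with a
        depth profile matching a 57/18/11/4/2 detection ladder."""
        cat = mr.SiteCatalog(genome_id="g", enzyme=mr.FSPEI)
        for i in range(1948):
            tag = "A" * 32
            cat.add(mr.RestrictionSite(
                contig="chrC", pos=i * 40, site_class="CCGG", top_mC=15,
                bottom_mC=16, tag_span=(i * 40, i * 40 + 32), tag_seq=tag,
                overhang_left=tag[:4], overhang_right=tag[-4:],
                is_control=True))
        depths = [1] * 39 + [2] * 7 + [3] * 7 + [4] * 2 + [5] * 2
        counts = {f"chrC:{i * 40}:CCGG": d for i, d in enumerate(depths)}
        return cat, depth_table(counts, library=10_000)

    def test_detection_ladder(self):
        cat, table = self._setup()
        assert mr.fpr(table, cat, 1)["detected"] == 57
        assert mr.fpr(table, cat, 5)["detected"] == 2
        assert mr.fpr(table, cat, 1)["fpr_pct"] == pytest.approx(100 * 57 / 1948)

    def test_monotone_nonincreasing_in_threshold(self):
        cat, table = self._setup()
        rates = [mr.fpr(table, cat, t)["fpr_pct"] for t in range(1, 8)]
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_zero_detected_is_zero(self):
        cat, _ = self._setup()
        empty = depth_table({}, library=100)
        assert mr.fpr(empty, cat, 1)["fpr_pct"] == 0.0

    def test_no_control_sites_rejected(self, small_catalog):
        cat = mr.SiteCatalog(genome_id="g", enzyme=mr.FSPEI)
        tag = "A" * 32
        cat.add(mr.RestrictionSite("chr1", 0, "CCGG", 15, 16, (0, 32), tag,
                                   tag[:4], tag[-4:]))
        with pytest.raises(ValueError):
            mr.fpr(depth_table({}, library=1), cat, 1)


class TestDetectionRate:
    def test_per_bin_rates(self):
        ref = pd.Series({f"s{i}": (0.1 if i < 10 else 0.5) for i in range(20)})
        detected = [f"s{i}" for i in range(5)] + [f"s{i}" for i in range(10, 20)]
        df = mr.detection_rate(ref, detected)
        low = df[(df.bin_low == 0.0)].iloc[0]
        mid = df[(df.bin_low == 0.5)].iloc[0]
        assert low.total == 10 and low.detected == 5 and low.rate_pct == 50.0
        assert mid.total == 10 and mid.rate_pct == 100.0

    def test_empty_bin_rate_absent(self):
        ref = pd.Series({"a": 0.95})
        df = mr.detection_rate(ref, ["a"])
        assert math.isnan(df[df.bin_low == 0.2].iloc[0].rate_pct)
        assert df[df.bin_low == 0.9].iloc[0].rate_pct == 100.0

    def test_all_detected_is_100_everywhere(self):
        ref = pd.Series(np.linspace(0.01, 1.0, 50),
                        index=[f"s{i}" for i in range(50)])
        df = mr.detection_rate(ref, ref.index)
        rates = df.rate_pct.dropna()
        assert (rates == 100.0).all()


class TestWindowProfile:
    def _mt(self, values):
        s = pd.Series(values)
        return mr.MIndexTable("s", m=s, depth=pd.Series(10.0, index=s.index),
                              depth_max=100.0)

    def _catalog(self, positions, contig_len=1000, window_cls="CCGG"):
        cat = mr.SiteCatalog(genome_id="g", enzyme=mr.FSPEI)
        cat.contig_lengths["chr1"] = contig_len
        cat.genome_length = contig_len
        tag = "A" * 32
        for p in positions:
            cat.add(mr.RestrictionSite("chr1", p, window_cls, p + 15, p + 16,
                                       (p, p + 32), tag, tag[:4], tag[-4:]))
        return cat

    def test_mean_of_window_sites(self):
        cat = self._catalog([10, 50])
        mt = self._mt({"chr1:10:CCGG": 0.2, "chr1:50:CCGG": 0.4})
        (w,) = mr.window_profile(mt, cat, window=1000)
        assert w.mean_m == pytest.approx(0.3)
        assert w.n_sites == 2

    def test_empty_window_missing(self):
        cat = self._catalog([10], contig_len=2500)
        mt = self._mt({"chr1:10:CCGG": 0.6})
        windows = mr.window_profile(mt, cat, window=1000)
        assert len(windows) == 3
        assert math.isnan(windows[1].mean_m) and windows[1].n_sites == 0

    def test_zero_fill_counts_undetected_sites(self):
        cat = self._catalog([10, 50])
        mt = self._mt({"chr1:10:CCGG": 0.8})
        (w,) = mr.window_profile(mt, cat, window=1000, zero_fill=True)
        assert w.mean_m == pytest.approx(0.4)

    def test_planted_high_block_recovered(self):
        cfg = mr.SimConfig(seed=41, genome_length=100_000, control_length=0)
        _, catalog = mr.simulate_genome(cfg)
        # plant: sites in [40k, 60k) fully methylated, others weak
        levels = {}
        for s in catalog:
            levels[s.site_id] = 0.95 if 40_000 <= s.tag_span[0] < 60_000 else 0.2
        truth = mr.MethylomeTruth(levels=pd.Series(levels))
        counts = mr.simulate_counts(truth, cfg, seed=42)
        mt = mr.m_index(mr.DepthTable("s", counts[counts > 0].astype(float),
                                      int(counts.sum())))
        windows = mr.window_profile(mt, catalog, window=20_000)
        means = [w.mean_m for w in windows if w.contig == "chr1"]
        assert np.nanargmax(means) == 2  # the [40k, 60k) window


class TestRarefy:
    def test_full_fraction_reproduces_everything(self):
        table = big_table([50] * 30 + [120, 120])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            df = mr.rarefy(table, [1.0], seed=0)
        assert df.iloc[0].sites_detected == 32
        assert df.iloc[0].pearson_r == 1.0
        assert df.iloc[0].reads_used == int(table.counts.sum())

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mr.rarefy(big_table([5] * 60), [0.0], seed=0)

    def test_depth_two_site_detection_matches_hypergeometric(self):
        """Half of a 10-read library: a depth-2 site stays detected with
        probability 1 - C(8,5)/C(10,5) = 7/9 (checked by simulation)."""
        table = depth_table({"a": 2, "b": 8})
        rng = np.random.default_rng(99)
        hits = 0
        n_rep = 2000
        for _ in range(n_rep):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                df = mr.rarefy(table, [0.5], rng)
            # 'b' (depth 8) is always kept at 5 draws: detected==2 <=> a kept
            hits += int(df.iloc[0].sites_detected == 2)
        p_exact = 1 - math.comb(8, 5) / math.comb(10, 5)
        se = math.sqrt(p_exact * (1 - p_exact) / n_rep)
        assert abs(hits / n_rep - p_exact) < 4 * se

    def test_detection_nondecreasing_in_fraction_on_average(self):
        cfg = mr.SimConfig(seed=51, genome_length=40_000, control_length=0)
        _, catalog = mr.simulate_genome(cfg)
        truth = mr.assign_methylation(catalog, seed=52)
        fractions = [0.1, 0.3, 0.6, 1.0]
        totals = np.zeros(len(fractions))
        for seed in range(20):
            counts = mr.simulate_counts(truth, cfg, seed=100 + seed)
            table = mr.DepthTable("s", counts[counts > 0].astype(float),
                                  int(counts.sum()))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                df = mr.rarefy(table, fractions, seed=seed)
            totals += df.sites_detected.to_numpy()
        means = totals / 20
        assert (np.diff(means) >= 0).all()
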