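"""MA transform, normalization, window statistics, scoring and DMR calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from epimut.medip import (
    MAValues,
    WindowConfig,
    call_dmrs,
    compute_ma,
    ma_to_intensities,
    normalize_ma,
    qpcr_fold_change,
    score_windows,
    summarize_by_chromosome,
    summarize_categories,
    window_statistics,
)
from epimut.simulate import ArrayDesign, generate_array_design


def _channels(cy5, cy3):
    n = len(cy5)
    return pd.DataFrame({"probe_id": [f"p{i}" for i in range(n)], "cy5": cy5, "cy3": cy3})


class TestMATransform:
    def test_log2_arithmetic(self):
        # log2 cy5 = 10, log2 cy3 = 6 -> M = 4, A = 8
        ma = compute_ma(_channels([2.0**10], [2.0**6]))
        assert ma["m"].iloc[0] == pytest.approx(4.0)
        assert ma["a"].iloc[0] == pytest.approx(8.0)

    def test_equal_channels_give_zero_m(self):
        ma = compute_ma(_channels([5.0, 7.0, 100.0], [5.0, 7.0, 100.0]))
        assert np.allclose(ma["m"], 0.0)

    def test_round_trip_recovers_intensities(self):
        rng = np.random.default_rng(0)
        cy5 = rng.uniform(0.5, 5000, 500)
        cy3 = rng.uniform(0.5, 5000, 500)
        table = _channels(cy5, cy3)
        back = ma_to_intensities(compute_ma(table))
        assert np.abs(back["cy5"].to_numpy() - cy5).max() < 1e-9
        assert np.abs(back["cy3"].to_numpy() - cy3).max() < 1e-9

    def test_non_positive_intensity_names_probe(self):
        with pytest.raises(ValueError, match="p1"):
            compute_ma(_channels([1.0, -2.0], [1.0, 1.0]))


class TestNormalization:
    def test_median_center_definition(self):
        ma = pd.DataFrame({"probe_id": list("abc"), "m": [1.0, 2.0, 3.0], "a": [8.0] * 3})
        out = normalize_ma(ma, method="median_center")
        assert out["m"].tolist() == [-1.0, 0.0, 1.0]

    def test_median_center_idempotent(self):
        rng = np.random.default_rng(1)
        ma = pd.DataFrame({"probe_id": range(99), "m": rng.normal(size=99), "a": rng.normal(8, 1, 99)})
        once = normalize_ma(ma)
        twice = normalize_ma(once)
        assert np.abs(once["m"] - twice["m"]).max() < 1e-12

    def test_loess_removes_intensity_dependence(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(6, 12, 5000)
        m = 0.5 * a + rng.normal(0, 0.3, 5000)
        ma = pd.DataFrame({"probe_id": range(5000), "m": m, "a": a})
        out = normalize_ma(ma, method="loess")
        r = np.corrcoef(out["m"], a)[0, 1]
        assert abs(r) < 0.05
        assert abs(np.median(out["m"])) < 1e-9

    def test_unknown_method_rejected(self):
        ma = pd.DataFrame({"probe_id": ["a"], "m": [1.0], "a": [8.0]})
        with pytest.raises(ValueError, match="unknown normalization"):
            normalize_ma(ma, method="quantile")


def _design_from_probes(starts, lengths=50, chrom="chr1", promoter_id="prom0"):
    starts = np.asarray(starts)
    lens = np.full(len(starts), lengths)
    probes = pd.DataFrame(
        {
            "probe_id": [f"{promoter_id}_p{i:03d}" for i in range(len(starts))],
            "chrom": chrom,
            "start": starts,
            "end": starts + lens,
            "promoter_id": promoter_id,
            "gene_id": "g0",
        }
    )
    promoters = pd.DataFrame(
        {
            "promoter_id": [promoter_id],
            "chrom": [chrom],
            "tss": [int(starts.min())],
            "strand": ["+"],
            "region_start": [int(starts.min())],
            "region_end": [int(starts.max() + lengths)],
            "gene_id": ["g0"],
        }
    )
    return ArrayDesign(probes=probes, promoters=promoters)


def _ma_for(design, m_values, cid="c1"):
    frame = pd.DataFrame(
        {"probe_id": design.probes["probe_id"], "m": m_values, "a": 8.0}
    )
    return MAValues({cid: frame})


class TestWindowStatistics:
    def test_three_probe_median(self):
        design = _design_from_probes([0, 100, 200])
        ws = window_statistics(_ma_for(design, [0.5, 1.0, 2.0]), design)
        assert len(ws) == 1
        assert ws["median_m"].iloc[0] == pytest.approx(1.0)
        assert ws["probe_count"].iloc[0] == 3

    def test_fewer_than_min_probes_emits_nothing(self):
        design = _design_from_probes([0, 500])  # never 3 probes within 600 bp
        ws = window_statistics(_ma_for(design, [1.0, 1.0]), design)
        assert len(ws) == 0

    def test_even_count_median_is_mean_of_central_pair(self):
        design = _design_from_probes([0, 100, 200, 300])
        ws = window_statistics(_ma_for(design, [0.0, 1.0, 2.0, 10.0]), design)
        assert (ws["median_m"] == 1.5).any()

    def test_windows_stay_within_promoter_and_span(self):
        design = generate_array_design(n_promoters=3, seed=5)
        rng = np.random.default_rng(6)
        ma = _ma_for(design, rng.normal(size=len(design.probes)))
        ws = window_statistics(ma, design)
        prom = design.promoters.set_index("promoter_id")
        for _, w in ws.iterrows():
            assert w["end"] - w["start"] <= 600
            info = prom.loc[w["promoter_id"]]
            assert info["region_start"] <= w["start"] < w["end"] <= info["region_end"]

    def test_medians_match_brute_force_oracle_on_random_layouts(self):
        rng = np.random.default_rng(7)
        for rep in range(60):
            n = rng.integers(3, 25)
            starts = np.sort(rng.choice(np.arange(0, 4000, 25), size=n, replace=False))
            design = _design_from_probes(starts)
            m = rng.normal(size=n)
            ws = window_statistics(_ma_for(design, m), design)
            by_start = dict(zip(design.probes["start"], m))
            for _, w in ws.iterrows():
                members = [v for s, v in by_start.items() if w["start"] <= s < w["end"]]
                assert len(members) == w["probe_count"]
                assert np.median(members) == pytest.approx(w["median_m"])

    def test_empty_intersection_with_design_rejected(self):
        design = _design_from_probes([0, 100, 200])
        ma = MAValues({"c1": pd.DataFrame({"probe_id": ["zzz"], "m": [0.0], "a": [8.0]})})
        with pytest.raises(ValueError, match="no probes"):
            window_statistics(ma, design)


class TestScoring:
    def _scored(self, medians, cfg=WindowConfig(stratify_null_by_probe_count=False)):
        df = pd.DataFrame(
            {
                "comparison_id": "c1",
                "chrom": "chr1",
                "start": np.arange(len(medians)) * 700,
                "end": np.arange(len(medians)) * 700 + 600,
                "promoter_id": [f"prom{i}" for i in range(len(medians))],
                "gene_id": "g",
                "probe_count": 3,
                "median_m": medians,
                "z": np.nan,
                "p": np.nan,
            }
        )
        return score_windows(df, cfg)

    def test_window_at_experimental_mean_has_z_zero_p_one(self):
        out = self._scored([-1.0, 0.0, 1.0])
        mid = out[out["median_m"] == 0.0].iloc[0]
        assert mid["z"] == pytest.approx(0.0, abs=1e-12)
        assert mid["p"] == pytest.approx(1.0)

    def test_window_at_mean_plus_1_96_sd_has_p_near_0_05(self):
        rng = np.random.default_rng(8)
        base = rng.normal(0, 1.0, 4001)
        base = (base - base.mean()) / base.std(ddof=1)  # exact mean 0, sd 1
        # place one window exactly 1.96 SD above the experimental mean;
        # adding it barely perturbs mean/sd at n=4002
        out = self._scored(np.append(base, 1.959964))
        top = out.iloc[-1]
        assert top["p"] == pytest.approx(0.05, abs=0.001)
        assert np.allclose(out["p"], 2 * sps.norm.sf(np.abs(out["z"])))

    def test_degenerate_null_raises(self):
        with pytest.raises(ValueError, match="degenerate null"):
            self._scored([1.0, 1.0, 1.0])

    def test_null_positive_rate_near_alpha(self):
        rng = np.random.default_rng(9)
        out = self._scored(rng.normal(size=8000))
        rate = (out["p"] < 0.05).mean()
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 8000)


def _multi_comparison_windows(p_by_comp, median=1.0):
    """One shared window universe; p and median set per comparison."""
    rows = []
    for cid, (p, m) in p_by_comp.items():
        rows.append(
            {
                "comparison_id": cid,
                "chrom": "chr1",
                "start": 0,
                "end": 600,
                "promoter_id": "prom0",
                "gene_id": "g0",
                "probe_count": 3,
                "median_m": m,
                "z": 0.0,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


class TestDMRCalling:
    def test_significant_in_only_two_of_three_excluded(self):
        df = _multi_comparison_windows(
            {"c1": (0.01, 1.0), "c2": (0.01, 1.0), "c3": (0.5, 1.0)}
        )
        assert len(call_dmrs(df)) == 0

    def test_significant_everywhere_same_sign_called_once(self):
        df = _multi_comparison_windows(
            {"c1": (0.01, 1.0), "c2": (0.02, 0.8), "c3": (0.001, 1.2)}
        )
        dmrs = call_dmrs(df)
        assert len(dmrs) == 1
        d = dmrs.iloc[0]
        assert d["sign"] == "+"
        assert d["min_p"] == pytest.approx(0.001)
        assert d["per_comparison_p"] == [0.01, 0.02, 0.001]

    def test_sign_flip_across_comparisons_excluded(self):
        df = _multi_comparison_windows(
            {"c1": (0.01, 1.0), "c2": (0.01, -1.0), "c3": (0.01, 1.0)}
        )
        assert len(call_dmrs(df)) == 0
        relaxed = call_dmrs(df, WindowConfig(require_consistent_sign=False))
        assert len(relaxed) == 1

    def test_adjacent_candidates_merge_into_one_region(self):
        rows = []
        for cid in ("c1", "c2"):
            for start in (0, 600):  # touching windows
                rows.append(
                    {
                        "comparison_id": cid, "chrom": "chr1", "start": start,
                        "end": start + 600, "promoter_id": "prom0", "gene_id": "g0",
                        "probe_count": 3, "median_m": 1.0, "z": 3.0, "p": 0.01,
                    }
                )
        dmrs = call_dmrs(pd.DataFrame(rows))
        assert len(dmrs) == 1
        assert dmrs.iloc[0]["start"] == 0 and dmrs.iloc[0]["end"] == 1200
        assert dmrs.iloc[0]["n_windows"] == 2

    def test_mismatched_window_universes_rejected(self):
        rows = [
            {"comparison_id": "c1", "chrom": "chr1", "start": 0, "end": 600,
             "promoter_id": "prom0", "gene_id": "g0", "probe_count": 3,
             "median_m": 1.0, "z": 0.0, "p": 0.5},
            {"comparison_id": "c2", "chrom": "chr1", "start": 700, "end": 1300,
             "promoter_id": "prom0", "gene_id": "g0", "probe_count": 3,
             "median_m": 1.0, "z": 0.0, "p": 0.5},
        ]
        with pytest.raises(ValueError, match="universes differ"):
            call_dmrs(pd.DataFrame(rows))

    def test_intersection_is_subset_of_each_single_comparison_set(self, spiked_setup):
        design, _, hybs = spiked_setup
        cfg = WindowConfig()
        ma = normalize_ma(MAValues.from_hybridizations(hybs))
        scored = score_windows(window_statistics(ma, design, cfg), cfg)
        piv = scored.pivot_table(
            index=["promoter_id", "start", "end"], columns="comparison_id", values="p"
        )
        inter = (piv < cfg.alpha).all(axis=1)
        for cid in piv.columns:
            single = piv[cid] < cfg.alpha
            assert (inter & ~single).sum() == 0


class TestSummaries:
    def test_empty_dmr_list(self):
        empty = call_dmrs(
            _multi_comparison_windows({"c1": (0.9, 1.0), "c2": (0.9, 1.0)})
        )
        assert summarize_by_chromosome(empty).empty
        assert summarize_categories(empty, {}).empty

    def test_counts_per_chromosome_sum_to_total(self):
        dmrs = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr1", "chr2"],
                "start": [0, 1000, 2000, 0],
                "end": [600, 1600, 2600, 600],
                "promoter_id": list("abcd"),
                "gene_id": list("wxyz"),
                "n_windows": 1,
                "min_p": 0.01,
                "mean_median_m": 1.0,
                "sign": "+",
                "per_comparison_p": [[0.01]] * 4,
            }
        )
        table = summarize_by_chromosome(dmrs)
        assert dict(zip(table["chrom"], table["n_dmrs"])) == {"chr1": 3, "chr2": 1}
        assert table["n_dmrs"].sum() == len(dmrs)

    def test_unmapped_genes_binned_unknown(self):
        dmrs = pd.DataFrame(
            {
                "chrom": "chr1", "start": [0, 1, 2], "end": [600, 601, 602],
                "promoter_id": list("abc"), "gene_id": ["g1", "g2", "g3"],
                "n_windows": 1, "min_p": 0.01, "mean_median_m": 1.0, "sign": "+",
                "per_comparison_p": [[0.01]] * 3,
            }
        )
        table = summarize_categories(dmrs, {"g1": "signaling"})
        counts = dict(zip(table["category"], table["n_genes"]))
        assert counts == {"signaling": 1, "unknown": 2}
        assert table["n_genes"].sum() == len(dmrs)


class TestQPCR:
    def test_identical_groups_fold_change_one(self):
        res = qpcr_fold_change([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert res.fold_change == pytest.approx(1.0)

    def test_elementwise_scaling_gives_exact_fold_change(self):
        ctrl = [1.0, 1.5, 2.0, 1.2]
        treat = [38.1 * v for v in ctrl]
        res = qpcr_fold_change(treat, ctrl)
        assert res.fold_change == pytest.approx(38.1)
        assert res.p < 0.05

    def test_mann_whitney_matches_exact_enumeration(self):
        from itertools import combinations

        rng = np.random.default_rng(10)
        for _ in range(5):
            a = rng.normal(0.5, 1, 5) ** 2 + 0.1
            b = rng.normal(0, 1, 4) ** 2 + 0.1
            res = qpcr_fold_change(a, b, test="mann_whitney")
            # exhaustive rank-sum null: all assignments of ranks to group A
            pooled = np.concatenate([a, b])
            ranks = sps.rankdata(pooled)
            obs = ranks[: len(a)].sum()
            na = len(a)
            sums = [sum(c) for c in combinations(ranks, na)]
            mean_sum = np.mean(sums)
            p_exact = np.mean([abs(s - mean_sum) >= abs(obs - mean_sum) - 1e-12 for s in sums])
            assert res.p == pytest.approx(p_exact, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            qpcr_fold_change([], [1.0])
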