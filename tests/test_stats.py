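"""Rank-based comparison machinery against hand formulas and simulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as sstats

from gaitsmooth import (GroupedValues, InputError, compare_complete_vs_stride,
                        compare_locations, kruskal_wallis, posthoc_pairwise,
                        variance_ranking)
from gaitsmooth.smoothness import records_to_dataframe


def hand_kruskal(groups):
    """Rank formula with tie correction, written independently of the package."""
    pooled = np.concatenate(groups)
    ranks = sstats.rankdata(pooled)
    N = len(pooled)
    start, H = 0, 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        H += r.sum() ** 2 / len(g)
        start += len(g)
    H = 12.0 / (N * (N + 1)) * H - 3.0 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (N**3 - N)
    return H / correction


def dunn_oracle(groups, alpha, m):
    """Independent Dunn z computation for one pair of the group dict."""
    names = list(groups)
    pooled = np.concatenate([groups[k] for k in names])
    N = len(pooled)
    ranks = sstats.rankdata(pooled)
    mean_ranks, start = {}, 0
    for k in names:
        mean_ranks[k] = ranks[start:start + len(groups[k])].mean()
        start += len(groups[k])
    _, counts = np.unique(pooled, return_counts=True)
    tie = np.sum(counts**3 - counts) / (12.0 * (N - 1))
    flags = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            se = np.sqrt((N * (N + 1) / 12.0 - tie)
                         * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = min(1.0, 2.0 * sstats.norm.sf(abs(z)) * m)
            flags[(a, b)] = p < alpha
    return flags


class TestKruskalWallis:
    def test_hand_formula_two_groups(self):
        g = GroupedValues("demo", {"a": [1, 2, 3], "b": [4, 5, 6]})
        res = kruskal_wallis(g)
        assert res.H == pytest.approx(27.0 / 7.0, abs=1e-10)
        assert res.df == 1

    def test_identical_groups_give_zero(self):
        g = GroupedValues("demo", {"a": [1, 2, 3], "b": [1, 2, 3]})
        res = kruskal_wallis(g)
        assert res.H == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_all_identical(self):
        g = GroupedValues("demo", {"a": [5.0, 5.0], "b": [5.0, 5.0, 5.0]})
        res = kruskal_wallis(g)
        assert res.H == 0.0 and res.p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            GroupedValues("demo", {"a": [], "b": [1.0]})

    def test_matches_brute_force_on_random_data(self):
        rng = np.random.default_rng(11)
        for rep in range(50):
            k = rng.integers(2, 5)
            if rep % 2:
                groups = [rng.standard_normal(rng.integers(3, 12)) for _ in range(k)]
            else:   # integer data: exercises the tie correction
                groups = [rng.integers(0, 5, rng.integers(3, 12)).astype(float)
                          for _ in range(k)]
            pooled = np.concatenate(groups)
            if np.all(pooled == pooled[0]):
                continue
            g = GroupedValues("demo", {str(i): v for i, v in enumerate(groups)})
            res = kruskal_wallis(g)
            assert res.H == pytest.approx(hand_kruskal(groups), abs=1e-10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(hst.lists(hst.floats(-50, 50), min_size=3, max_size=10, unique=True),
           hst.lists(hst.floats(51, 100), min_size=3, max_size=10, unique=True))
    def test_rank_invariance_under_monotone_transform(self, a, b):
        from hypothesis import assume
        pooled = np.concatenate([a, b])
        transformed = np.exp(pooled / 25.0)
        # the transform must stay injective in floating point to preserve ranks
        assume(len(np.unique(transformed)) == len(pooled))
        g1 = GroupedValues("f", {"a": a, "b": b})
        g2 = GroupedValues("f", {"a": np.exp(np.asarray(a) / 25.0),
                                 "b": np.exp(np.asarray(b) / 25.0)})
        assert kruskal_wallis(g1).H == pytest.approx(kruskal_wallis(g2).H, abs=1e-9)


class TestPosthoc:
    def test_shifted_group_flagged_identical_pair_not(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(20)
        g = GroupedValues("demo", {"a": base, "b": base + 1e-3 * rng.standard_normal(20),
                                   "c": base + 50.0})
        res = {(r.group_a, r.group_b): r.significant for r in posthoc_pairwise(g)}
        assert res[("a", "c")] and res[("b", "c")]
        assert not res[("a", "b")]

    def test_bonferroni_never_below_raw(self):
        rng = np.random.default_rng(5)
        g = GroupedValues("demo", {str(i): rng.standard_normal(10) for i in range(4)})
        for r in posthoc_pairwise(g):
            assert r.p_adjusted >= r.p_raw
            assert 0.0 <= r.p_raw <= 1.0 and 0.0 <= r.p_adjusted <= 1.0

    def test_mannwhitney_variant_agrees_on_obvious_shift(self):
        rng = np.random.default_rng(2)
        g = GroupedValues("demo", {"a": rng.standard_normal(15),
                                   "b": rng.standard_normal(15) + 30.0})
        for method in ("dunn", "mannwhitney"):
            res = posthoc_pairwise(g, method=method)
            assert res[0].significant

    def test_family_wise_error_controlled_under_null(self):
        rng = np.random.default_rng(99)
        false_alarms = 0
        reps = 1000
        for _ in range(reps):
            g = GroupedValues("null", {s: rng.standard_normal(20) for s in "abc"})
            if kruskal_wallis(g).p < 0.05:
                if any(r.significant for r in posthoc_pairwise(g)):
                    false_alarms += 1
        fwer = false_alarms / reps
        # 95% binomial upper bound around the nominal 0.05
        assert fwer <= 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / reps)


@pytest.fixture(scope="module")
def cohort_records(processed_cohort):
    frames = [records_to_dataframe(res.records) for res, _ in processed_cohort
              if res.valid]
    return pd.concat(frames, ignore_index=True)


class TestCompareCompleteVsStride:
    def test_report_covers_metrics_by_segments(self, cohort_records):
        rep = compare_complete_vs_stride(cohort_records)
        assert set(rep["metric"]) == {"SPARC", "PM", "LDLJ"}
        assert set(rep["segment"]) == {"foot", "shank", "thigh", "hip"}
        assert len(rep) == 12
        assert rep["p"].between(0, 1).all()

    def test_identical_scopes_not_significant(self):
        rows = []
        for trial in range(8):
            for scope in ("complete", "stride"):
                rows.append(dict(subject=f"S{trial}", trial=f"T{trial}",
                                 location="foot_L", segment="foot", modality="gyro",
                                 component="magnitude", scope=scope, side="L",
                                 stride_index=0, metric="SPARC", value=-3.0))
        rep = compare_complete_vs_stride(pd.DataFrame(rows))
        assert (rep["p"] == 1.0).all()
        assert not rep["significant"].any()

    def test_rank_difference_sign_tracks_mean_difference(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            shift = rng.uniform(-3, 3)
            rows = []
            for trial in range(10):
                rows.append(dict(subject=f"S{trial}", trial=f"T{trial}",
                                 location="foot_L", segment="foot", modality="gyro",
                                 component="magnitude", scope="complete", side="L",
                                 stride_index=None, metric="SPARC",
                                 value=rng.standard_normal() + shift))
                rows.append(dict(subject=f"S{trial}", trial=f"T{trial}",
                                 location="foot_L", segment="foot", modality="gyro",
                                 component="magnitude", scope="stride", side="L",
                                 stride_index=0, metric="SPARC",
                                 value=rng.standard_normal()))
            rep = compare_complete_vs_stride(pd.DataFrame(rows))
            row = rep.iloc[0]
            if abs(shift) > 1.0:    # away from the noise floor
                assert np.sign(row["mean_rank_diff"]) == np.sign(shift)


class TestVarianceRanking:
    def test_injected_low_sd_metric_wins_everywhere(self):
        rng = np.random.default_rng(1)
        rows = []
        for metric, sd in (("SPARC", 0.1), ("LDLJ", 1.0), ("PM", 2.0)):
            for seg in ("foot", "hip"):
                for comp in ("pitch", "magnitude"):
                    for i in range(10):
                        rows.append(dict(subject="S", trial=f"T{i}", location=seg,
                                         segment=seg, modality="gyro", component=comp,
                                         scope="stride", side="L", stride_index=i,
                                         metric=metric,
                                         value=rng.normal(0.0, sd)))
        ranking = variance_ranking(pd.DataFrame(rows))
        assert ranking.winner == "SPARC"
        sparc_rows = ranking.table[ranking.table["metric"] == "SPARC"]
        assert (sparc_rows["rank"] == 1).all()

    def test_sd_matches_two_pass_formula(self):
        rng = np.random.default_rng(4)
        vals = rng.standard_normal(30)
        rows = [dict(subject="S", trial="T", location="foot_L", segment="foot",
                     modality="gyro", component="pitch", scope="stride", side="L",
                     stride_index=i, metric="SPARC", value=v)
                for i, v in enumerate(vals)]
        ranking = variance_ranking(pd.DataFrame(rows))
        mean = vals.sum() / len(vals)
        two_pass = np.sqrt(np.sum((vals - mean) ** 2) / (len(vals) - 1))
        assert ranking.table["sd"].iloc[0] == pytest.approx(two_pass, abs=1e-12)

    def test_full_cohort_ranking_covers_all_cells(self, cohort_records):
        ranking = variance_ranking(cohort_records)
        cells = ranking.table.groupby(["segment", "component", "scope"]).size()
        assert set(ranking.table["segment"]) == {"foot", "shank", "thigh", "hip"}
        assert set(ranking.table["component"]) == {"yaw", "pitch", "roll", "magnitude"}


class TestCompareLocations:
    @staticmethod
    def _records(shifts, rng, n_trials=12):
        rows = []
        for seg, shift in shifts.items():
            for i in range(n_trials):
                rows.append(dict(subject=f"S{i}", trial=f"T{i}", location=seg,
                                 segment=seg, modality="gyro", component="pitch",
                                 scope="stride", side="L", stride_index=0,
                                 metric="SPARC", value=rng.standard_normal() + shift))
        return pd.DataFrame(rows)

    def test_identical_distributions_no_significant_pairs(self):
        rng = np.random.default_rng(21)
        rep = compare_locations(self._records(
            {"foot": 0.0, "shank": 0.0, "thigh": 0.0, "hip": 0.0}, rng))
        pairs = rep[rep["pair"] != ""]
        assert not pairs["significant"].any()

    def test_shifted_location_all_pairs_significant(self):
        rng = np.random.default_rng(22)
        rep = compare_locations(self._records(
            {"foot": 0.0, "shank": 0.0, "thigh": 0.0, "hip": 5.0}, rng))
        hip_pairs = rep[rep["pair"].str.contains("hip")]
        assert len(hip_pairs) == 3
        assert hip_pairs["significant"].all()

    def test_flags_agree_with_independent_dunn_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            shifts = {s: rng.choice([0.0, 0.0, 4.0]) for s in
                      ("foot", "shank", "thigh", "hip")}
            df = self._records(shifts, rng)
            rep = compare_locations(df)
            groups = {seg: sub["value"].to_numpy()
                      for seg, sub in df.groupby("segment")}
            expected = dunn_oracle(groups, 0.05, m=6)
            for (a, b), flag in expected.items():
                row = rep[rep["pair"] == f"{a}-{b}"]
                assert bool(row["significant"].iloc[0]) == flag

    def test_single_location_rejected(self):
        rng = np.random.default_rng(24)
        with pytest.raises(InputError):
            compare_locations(self._records({"foot": 0.0}, rng))
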