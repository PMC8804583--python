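"""QC cascade: each filter against an independent brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from poolgwas import qc
from poolgwas import simulate as sim


def make_panel(freqs, intensity=100.0, pools=("p1",), groups=None, gain=1.0):
    """Intensity panel from an array of frequencies shaped
    (n_snps, n_pools, n_reps)."""
    freqs = np.asarray(freqs, dtype=float)
    n_snps, n_pools, n_reps = freqs.shape
    groups = groups or ["control"] * n_pools
    rows = []
    for i in range(n_snps):
        for p in range(n_pools):
            for r in range(n_reps):
                f = freqs[i, p, r]
                rows.append(
                    dict(
                        snp_id=f"s{i:03d}", chrom=1, pos=i + 1,
                        pool_id=pools[p], group=groups[p], batch=1,
                        replicate=r + 1,
                        x_raw=intensity * gain * f, y_raw=intensity * (1 - f),
                    )
                )
    return pd.DataFrame(rows)


class TestEstimateFrequency:
    @pytest.mark.parametrize(
        "x,y,expected", [(120, 40, 0.75), (0, 50, 0.0), (100, 100, 0.5)]
    )
    def test_arithmetic(self, x, y, expected):
        assert qc.estimate_frequency(x, y) == expected

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError, match="undefined"):
            qc.estimate_frequency(0.0, 0.0)


class TestNormalizeChannels:
    def test_identity_when_channels_equal(self):
        panel = make_panel(np.full((20, 1, 2), 0.5))
        out = qc.normalize_channels(panel)
        pd.testing.assert_frame_equal(out, panel)

    def test_doubled_x_restored(self):
        panel = make_panel(np.random.default_rng(0).uniform(0.2, 0.8, (50, 1, 1)))
        doubled = panel.assign(x_raw=2 * panel["x_raw"])
        out = qc.normalize_channels(doubled)
        # rescale factor my/mx halves x back to equal-median channels
        assert out["x_raw"].median() == pytest.approx(out["y_raw"].median())

    def test_postcondition_medians_match_per_array(self, null_panel):
        out = qc.normalize_channels(null_panel)
        for _, g in out.groupby(["pool_id", "replicate"]):
            assert g["x_raw"].median() == pytest.approx(g["y_raw"].median())

    def test_all_zero_channel_names_replicate(self):
        panel = make_panel(np.zeros((5, 1, 1)))  # x_raw all zero
        with pytest.raises(ValueError, match="replicate=1"):
            qc.normalize_channels(panel)


class TestReplicateCorrelationFilter:
    def test_identical_replicates_kept(self):
        f = np.random.default_rng(1).uniform(0.1, 0.9, 30)
        panel = make_panel(np.stack([f, f], axis=-1)[:, None, :])
        _, dropped = qc.replicate_correlation_filter(panel)
        assert dropped == []

    def test_shuffled_replicate_dropped(self):
        rng = np.random.default_rng(2)
        f = rng.uniform(0.1, 0.9, 200)
        good1 = f + rng.normal(0, 0.002, 200)
        good2 = f + rng.normal(0, 0.002, 200)
        bad = rng.permutation(f)
        panel = make_panel(np.stack([good1, good2, bad], axis=-1)[:, None, :])
        # brute-force Pearson confirms the shuffled replicate is uncorrelated
        assert abs(np.corrcoef(good1, bad)[0, 1]) < 0.3
        kept, dropped = qc.replicate_correlation_filter(panel, r_min=0.99)
        assert dropped == [("p1", 3)]
        assert set(kept["replicate"]) == {1, 2}

    def test_correlated_but_below_cutoff_all_dropped_to_one(self):
        rng = np.random.default_rng(3)
        f = rng.uniform(0.1, 0.9, 500)
        reps = np.stack([f + rng.normal(0, 0.002, 500) for _ in range(3)], axis=-1)
        panel = make_panel(reps[:, None, :])
        _, dropped = qc.replicate_correlation_filter(panel, r_min=0.99)
        assert dropped == []  # pairwise R ~ 0.999 here


class TestLowIntensityFilter:
    def test_count_rule(self):
        panel = make_panel(np.full((100, 1, 1), 0.5))
        # distinct totals: scale intensity by SNP index
        panel["x_raw"] *= np.repeat(np.arange(1, 101), 1)
        _, removed = qc.low_intensity_filter(panel, 0.05)
        assert len(removed) == 5

    def test_tie_break_lexicographic(self):
        panel = make_panel(np.full((100, 1, 1), 0.5))  # all totals equal
        _, removed = qc.low_intensity_filter(panel, 0.05)
        assert removed == [f"s{i:03d}" for i in range(5)]

    def test_matches_bottom_k_sort_oracle(self):
        rng = np.random.default_rng(4)
        panel = make_panel(rng.uniform(0.2, 0.8, (60, 2, 3)), pools=("a", "b"))
        panel["x_raw"] *= rng.uniform(0.5, 2.0, len(panel))
        totals = (panel["x_raw"] + panel["y_raw"]).groupby(panel["snp_id"]).sum()
        oracle = set(totals.sort_values(kind="mergesort").index[:3])
        _, removed = qc.low_intensity_filter(panel, 0.05)
        assert set(removed) == oracle


class TestDivergenceFilter:
    @pytest.mark.parametrize(
        "reps,removed",
        [
            ((0.10, 0.12, 0.17), True),   # span 0.07 > 0.05
            ((0.10, 0.11, 0.12), False),  # span 0.02
            ((0.10, 0.12, 0.15), False),  # span exactly 0.05: strict rule keeps
        ],
    )
    def test_span_rule(self, reps, removed):
        panel = make_panel(np.array(reps)[None, None, :])
        _, out = qc.divergence_filter(panel, 0.05)
        assert (out == ["s000"]) is removed


class TestMafFilter:
    @pytest.mark.parametrize(
        "f,removed", [(0.005, True), (0.995, True), (0.01, False), (0.3, False)]
    )
    def test_maf_rule(self, f, removed):
        panel = make_panel(np.full((1, 1, 2), f))
        _, out = qc.maf_filter(panel, 0.01)
        assert (out == ["s000"]) is removed

    def test_control_pools_only(self):
        # rare in cases, common in controls -> kept
        panel = make_panel(
            np.stack([np.full((1, 2), 0.001), np.full((1, 2), 0.3)], axis=1),
            pools=("case_p", "ctrl_p"), groups=["case", "control"],
        )
        _, out = qc.maf_filter(panel, 0.01)
        assert out == []


def brute_force_cascade(panel, config):
    """Independent re-implementation of the four QC rules for oracle use."""
    f = panel["x_raw"] / (panel["x_raw"] + panel["y_raw"])
    work = panel.assign(f=f)
    # (panel assumed normalized, no bad replicates in oracle fixtures)
    totals = (work["x_raw"] + work["y_raw"]).groupby(work["snp_id"]).sum()
    k = int(np.floor(config.low_intensity_fraction * totals.size))
    order = sorted(totals.index, key=lambda s: (totals[s], s))
    drop = set(order[:k])
    work = work[~work["snp_id"].isin(drop)]
    span = work.groupby(["snp_id", "pool_id"])["f"].agg(lambda s: s.max() - s.min())
    drop2 = set(span[span > config.max_divergence].index.get_level_values(0))
    work = work[~work["snp_id"].isin(drop2)]
    ctrl = work[work["group"] == "control"]
    fbar = ctrl.groupby(["snp_id", "pool_id"])["f"].mean().groupby("snp_id").mean()
    drop3 = set(fbar[np.minimum(fbar, 1 - fbar) < config.maf_min].index)
    return set(totals.index) - drop - drop2 - drop3


class TestCascade:
    def test_noise_free_fixture_recovers_truth_exactly(self):
        rng = np.random.default_rng(5)
        f = rng.uniform(0.1, 0.9, 40)
        panel = make_panel(np.stack([f, f, f], axis=-1)[:, None, :])
        # gain-free data: normalization is not needed and would distort the
        # scale on a panel whose median frequency is not 0.5
        res = qc.pool_frequencies(
            panel, qc.QCConfig(low_intensity_fraction=0.02), normalize=False
        )
        est = res.table.set_index("snp_id")["f_hat"]
        surviving = est.index
        truth = pd.Series(f, index=[f"s{i:03d}" for i in range(40)])
        assert np.allclose(est, truth[surviving])

    def test_survivors_match_brute_force_oracle(self, null_panel, clean_design):
        config = qc.QCConfig()
        res = qc.pool_frequencies(null_panel, config)
        normalized = qc.normalize_channels(null_panel)
        oracle = brute_force_cascade(normalized, config)
        assert set(res.table["snp_id"]) == oracle

    def test_cascade_is_idempotent(self, null_panel):
        config = qc.QCConfig()
        normalized = qc.normalize_channels(null_panel)
        first = qc.pool_frequencies(normalized, config, normalize=False)
        # re-run the cascade on the surviving (already-normalized) panel
        survivors = set(first.table["snp_id"])
        panel2 = normalized[normalized["snp_id"].isin(survivors)]
        second = qc.pool_frequencies(panel2, config, normalize=False)
        # no replicate drops the second time, and (almost) no new removals:
        # the only possible change is the 5% intensity cut re-applied to an
        # already-cut panel, so survivors shrink by at most that fraction
        assert second.removed["reason"].eq("low_intensity").all()

    def test_filters_never_modify_surviving_values(self, null_panel):
        config = qc.QCConfig()
        normalized = qc.normalize_channels(null_panel)
        res = qc.pool_frequencies(normalized, config, normalize=False)
        f = normalized["x_raw"] / (normalized["x_raw"] + normalized["y_raw"])
        manual = (
            normalized.assign(f=f)
            .groupby(["snp_id", "pool_id"])["f"].mean()
        )
        joined = res.table.set_index(["snp_id", "pool_id"])["f_hat"]
        assert np.allclose(joined, manual.loc[joined.index])

    def test_paper_scale_cascade_strictly_shrinks(self, null_panel):
        res = qc.pool_frequencies(null_panel)
        assert 0 < res.table["snp_id"].nunique() < null_panel["snp_id"].nunique()


class TestBiasReport:
    def test_gain_free_fixture_unbiased(self, null_truth):
        design = sim.default_design(sd_array=0.0, gain_ratio=1.0, bad_array_rate=0.0)
        panel = sim.simulate_pool_intensities(null_truth, design, seed=21)
        res = qc.pool_frequencies(panel, normalize=False)  # gain-free data
        _, bias = qc.frequency_bias_report(res.table, null_truth)
        assert abs(bias) < 0.005  # binomial pool sampling only

    def test_gain_bias_closed_form(self):
        # raw (un-normalized) estimates at f=0.5, g=1.1: bias = 0.55/1.05 - 0.5
        truth = sim.simulate_truth(
            500, maf_sampler=lambda rng, n: np.full(n, 0.5), seed=22
        )
        design = sim.PoolDesign(
            pools=[sim.PoolSpec("p", "control", 1, 100_000)],
            sd_array=0.0, gain_ratio=1.1, bad_array_rate=0.0,
        )
        panel = sim.simulate_pool_intensities(truth, design, seed=23)
        res = qc.pool_frequencies(panel, normalize=False)
        _, bias = qc.frequency_bias_report(res.table, truth)
        assert bias == pytest.approx(0.55 / 1.05 - 0.5, abs=2e-3)

    def test_single_snp_signed_error(self):
        table = pd.DataFrame(
            dict(snp_id=["s0"], pool_id=["p"], group=["control"], f_hat=[0.07])
        )
        truth = sim.simulate_truth(1, maf_sampler=lambda rng, n: np.full(n, 0.05), seed=0)
        truth.variants.loc[0, "snp_id"] = "s0"
        out, bias = qc.frequency_bias_report(table, truth)
        assert out["error"].iloc[0] == pytest.approx(0.02)

    def test_unknown_snp_is_error(self, null_truth):
        table = pd.DataFrame(
            dict(snp_id=["nope"], pool_id=["p"], group=["control"], f_hat=[0.5])
        )
        with pytest.raises(KeyError):
            qc.frequency_bias_report(table, null_truth)
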