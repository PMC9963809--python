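"""Rank statistics against brute-force, scipy, and permutation oracles."""

import numpy as np
import pytest
from scipy import stats

from crpdt.clonostats import (
    dunn_posthoc,
    kruskal_wallis,
    surviving_fraction,
)
from crpdt.synthetic import gen_clone_counts


def _brute_force_h(groups):
    """Independent oracle: ranks by explicit enumeration, textbook formula."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = np.mean(np.arange(i, j) + 1.0)
        i = j
    n = len(pooled)
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    corr = 1 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / corr if corr > 0 else 0.0


class TestKruskalWallis:
    def test_identical_groups_give_zero_h(self):
        res = kruskal_wallis([[5, 5, 5], [5, 5, 5], [5, 5, 5]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_brute_force_rank_oracle(self):
        groups = [np.array([1.0, 2, 3]), np.array([4.0, 5, 6]), np.array([7.0, 8, 9])]
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(_brute_force_h(groups), rel=1e-12)
        assert res.df == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_on_tied_count_data(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.poisson(30, 12).astype(float) for _ in range(4)]
        res = kruskal_wallis(groups)
        ref = stats.kruskal(*groups)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        groups = [rng.poisson(20, 10).astype(float) for _ in range(3)]
        a = kruskal_wallis(groups).statistic
        b = kruskal_wallis([np.exp(g / 10.0) for g in groups]).statistic
        assert a == pytest.approx(b, rel=1e-12)

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])


class TestDunn:
    def test_identical_groups_all_null(self):
        res = dunn_posthoc([[4, 4, 4], [4, 4, 4], [4, 4, 4]])
        assert all(p.z == 0.0 and p.p_adjusted == 1.0 for p in res)

    def test_bonferroni_never_below_unadjusted(self):
        rng = np.random.default_rng(0)
        groups = [rng.poisson(30, 12) for _ in range(4)]
        adj = dunn_posthoc(groups, adjust="bonferroni")
        raw = dunn_posthoc(groups, adjust="none")
        assert all(a.p_adjusted >= r.p_adjusted for a, r in zip(adj, raw))

    def test_shifted_group_agreement_with_permutation_oracle(self):
        """Dunn decisions agree >= 90% with a permutation test on the rank-mean
        difference, across 100 seeded 3-group datasets with one shifted group."""
        agreements = 0
        n_perm = 600
        for seed in range(100):
            rng = np.random.default_rng(seed)
            groups = [
                rng.poisson(150, 12).astype(float),
                rng.poisson(150, 12).astype(float),
                rng.poisson(75, 12).astype(float),
            ]
            dunn = dunn_posthoc(groups, adjust="none")
            pooled = np.concatenate(groups)
            sizes = [len(g) for g in groups]
            ranks = stats.rankdata(pooled)
            # permutation distribution of |mean-rank difference| per pair
            perm_stats = np.empty((n_perm, 3))
            for b in range(n_perm):
                perm = rng.permutation(ranks)
                r0, r1, r2 = (
                    perm[:12].mean(),
                    perm[12:24].mean(),
                    perm[24:].mean(),
                )
                perm_stats[b] = (abs(r0 - r1), abs(r0 - r2), abs(r1 - r2))
            obs = (
                abs(ranks[:12].mean() - ranks[12:24].mean()),
                abs(ranks[:12].mean() - ranks[24:].mean()),
                abs(ranks[12:24].mean() - ranks[24:].mean()),
            )
            ok = True
            for pair_idx, pair in enumerate(dunn):
                p_perm = (perm_stats[:, pair_idx] >= obs[pair_idx]).mean()
                ok &= (pair.p_adjusted < 0.05) == (p_perm < 0.05)
            agreements += ok
        assert agreements >= 90

    def test_only_shifted_group_flagged(self):
        rng = np.random.default_rng(1)
        groups = [
            rng.poisson(150, 12),
            rng.poisson(150, 12),
            rng.poisson(40, 12),
        ]
        res = dunn_posthoc(groups, labels=["a", "b", "c"])
        flags = {(p.group_a, p.group_b): p.significant_at_0_05 for p in res}
        assert not flags[("a", "b")]
        assert flags[("a", "c")] and flags[("b", "c")]


class TestSurvivingFraction:
    def test_reference_against_itself_is_one(self):
        table = gen_clone_counts(seed=0)
        df = surviving_fraction(table, "none @ 0 MBq")
        row = df[df["arm"] == "none @ 0 MBq"].iloc[0]
        assert row["fraction"] == pytest.approx(1.0)

    def test_all_zero_arm_gives_zero_fraction(self):
        table = gen_clone_counts(
            arms=[("ctrl", 0.0, 1.0), ("dead", 3.0, 0.0)], seed=1
        )
        df = surviving_fraction(table, "ctrl")
        assert df[df["arm"] == "dead @ 3 MBq"]["fraction"].iloc[0] == 0.0

    def test_generated_effect_recovered(self):
        table = gen_clone_counts(seed=5)
        df = surviving_fraction(table, "none @ 0 MBq")
        row = df[df["arm"] == "Tb-P1 @ 1 MBq"].iloc[0]
        assert row["fraction"] == pytest.approx(0.5, abs=3 * row["fraction_sd"] / np.sqrt(12))

    def test_missing_reference_rejected(self):
        table = gen_clone_counts(seed=0)
        with pytest.raises(ValueError, match="not found"):
            surviving_fraction(table, "unobtainium")


class TestPipelineCalibration:
    def test_type_i_error_on_null_counts(self):
        """KW at alpha=0.05 on identical-mean Poisson arms rejects 3-7% of the time."""
        rejections = 0
        n_sim = 2000
        rng = np.random.default_rng(2024)
        for _ in range(n_sim):
            groups = [rng.poisson(150, 12) for _ in range(5)]
            rejections += kruskal_wallis(groups).p_value < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07

    def test_default_effect_detected_in_most_simulations(self):
        """The Tb-P1 >= 1 MBq survival deficit is flagged in >= 90% of runs."""
        detected = 0
        n_sim = 500
        for seed in range(n_sim):
            table = gen_clone_counts(seed=seed)
            groups = table.groups()
            tb = [
                groups["Tb-P1 @ 1 MBq"],
                groups["Tb-P1 @ 3 MBq"],
                groups["Tb-P1 @ 0 MBq"],
            ]
            res = dunn_posthoc(tb, labels=["1", "3", "0"])
            flags = {(p.group_a, p.group_b): p.significant_at_0_05 for p in res}
            detected += flags[("1", "0")] and flags[("3", "0")]
        assert detected / n_sim >= 0.90
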