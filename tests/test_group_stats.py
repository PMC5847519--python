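import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm, rankdata

from natriq.group_stats import (
    bonferroni_alpha,
    metrics_long_table,
    pairwise_rank_z,
    run_anova,
    steel_dwass,
    steel_dwass_critical_z,
    steel_dwass_zmatrix,
)


def brute_force_z(a, b):
    """Independent oracle: z from pairwise win/tie counting (Mann-Whitney U)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    u = sum(1.0 for x, y in itertools.product(a, b) if y > x) + 0.5 * sum(
        1.0 for x, y in itertools.product(a, b) if y == x
    )
    # rank-sum of b = U + nb(nb+1)/2; expectation nb(N+1)/2
    na, nb = a.size, b.size
    n = na + nb
    w = u + nb * (nb + 1) / 2.0
    d = w - nb * (n + 1) / 2.0
    ranks = rankdata(np.concatenate([a, b]))
    var = na * nb / (n * (n - 1.0)) * np.sum((ranks - (n + 1) / 2.0) ** 2)
    d = np.sign(d) * max(abs(d) - 0.5, 0.0)
    return d / np.sqrt(var)


class TestPairwiseZ:
    def test_identical_samples_give_zero(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pairwise_rank_z(x, x) == 0.0

    def test_full_separation_n13_saturates(self):
        a = np.arange(13, dtype=float)
        b = a + 100.0
        z = pairwise_rank_z(a, b)
        # hand arithmetic: (260 - 175.5 - 0.5) / sqrt(13*13*27/12)
        assert z == pytest.approx(84.0 / np.sqrt(380.25), abs=1e-12)
        assert round(abs(z), 2) == 4.31

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_oracle_small_samples(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 6, size=3).astype(float)  # small, ties likely
        b = rng.integers(0, 6, size=3).astype(float)
        assert pairwise_rank_z(a, b) == pytest.approx(brute_force_z(a, b), abs=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(size=13) for _ in range(4)]
        z = steel_dwass_zmatrix(groups)
        np.testing.assert_allclose(z, -z.T, atol=1e-12)


class TestSteelDwass:
    def test_k2_reduces_to_wilcoxon_normal_approximation(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=13), rng.normal(0.8, size=13)
        res = steel_dwass([a, b])
        (_, _, z, p) = res.pairs[0]
        assert p == pytest.approx(2 * norm.sf(abs(z)), abs=1e-6)

    def test_z_bounded_by_saturation_ceiling(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(loc, size=13) for loc in (0, 5, 10, 50)]
        zmax = 84.0 / np.sqrt(380.25)
        for _, _, z, p in steel_dwass(groups).pairs:
            assert abs(z) <= zmax + 1e-12
            assert 0.0 <= p <= 1.0

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            steel_dwass([[1.0, 2.0], [3.0, 4.0, 5.0]])

    def test_familywise_calibration_short_run(self):
        # conservative but near-nominal under the null (see acceptance test
        # for the full 2000-simulation check at k=8)
        rng = np.random.default_rng(21)
        crit = steel_dwass_critical_z(3, 0.05)
        rej = sum(
            np.abs(
                steel_dwass_zmatrix([rng.normal(size=13) for _ in range(3)])
            ).max()
            > crit
            for _ in range(400)
        )
        assert 0.01 <= rej / 400 <= 0.09


class TestBonferroni:
    @pytest.mark.parametrize(
        "n, alpha, exact, rounded",
        [(6, 0.05, 0.05 / 6, 0.008), (1, 0.05, 0.05, 0.05), (2, 0.05, 0.025, 0.025)],
    )
    def test_values(self, n, alpha, exact, rounded):
        res = bonferroni_alpha(n, alpha)
        assert res.exact == pytest.approx(exact, rel=1e-12)
        assert res.rounded == rounded

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0)


def _toy_table(effect=0.0, seed=0, n=12):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        sex = "female" if i % 2 == 0 else "male"
        age = 20 + (i % 6)
        for group, delta in (("GM", 0.0), ("WM", effect)):
            rows.append(
                (f"sub-{i:02d}", sex, age, group, "tsc",
                 10.0 + delta + rng.normal(0, 1.0))
            )
    return pd.DataFrame(
        rows,
        columns=["subject_id", "sex", "age", "group_label", "metric_name", "value"],
    )


class TestAnova:
    def test_null_effect_f_near_zero(self):
        table = _toy_table(effect=0.0, seed=1)
        # make the two groups exactly identical per subject
        piv = table.pivot(index="subject_id", columns="group_label", values="value")
        table.loc[table["group_label"] == "WM", "value"] = piv["GM"].to_numpy()
        res = run_anova(table, "tsc")
        assert res.f_per_factor["group"] == pytest.approx(0.0, abs=1e-20)

    def test_large_injected_effect_detected(self):
        table = _toy_table(effect=5.0, seed=2, n=13)
        res = run_anova(table, "tsc")
        assert res.p_values["group"] < 0.008
        assert res.df_per_factor["group"] == 1

    def test_matches_projection_oracle(self):
        """F statistics agree with OLS sums of squares computed by hand."""
        table = _toy_table(effect=2.0, seed=3)
        res = run_anova(table, "tsc")

        def ssr(columns):
            x = np.column_stack(columns)
            y = table["value"].to_numpy()
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            return float(np.sum((y - x @ beta) ** 2))

        ones = np.ones(len(table))
        g = (table["group_label"] == "WM").to_numpy(float)
        s = (table["sex"] == "male").to_numpy(float)
        age = table["age"].to_numpy(float)
        ss_full = ssr([ones, g, s, age])
        df_resid = len(table) - 4
        # Type II F for the group factor: drop it from the full model
        f_group = ((ssr([ones, s, age]) - ss_full) / 1) / (ss_full / df_resid)
        assert res.f_per_factor["group"] == pytest.approx(f_group, rel=1e-8)
        # whole-model F against the intercept-only null
        f_whole = ((ssr([ones]) - ss_full) / 3) / (ss_full / df_resid)
        assert res.f_whole_model == pytest.approx(f_whole, rel=1e-8)

    def test_permuted_labels_are_null(self):
        # permuting group labels kills the injected effect
        rng = np.random.default_rng(8)
        table = _toy_table(effect=5.0, seed=4, n=13)
        table["group_label"] = rng.permutation(table["group_label"].to_numpy())
        while (table.groupby(["subject_id", "group_label"]).size() != 1).any():
            table["group_label"] = rng.permutation(table["group_label"].to_numpy())
        res = run_anova(table, "tsc")
        assert res.p_values["group"] > 0.008

    def test_missing_metric_rejected(self):
        with pytest.raises(ValueError):
            run_anova(_toy_table(), "ecf")


class TestLongTable:
    def test_reshape_contract(self):
        quant = pd.DataFrame(
            {
                "subject_id": ["s1", "s1"],
                "roi": ["GM", "WM"],
                "t2s_ms": [4.9, 4.4],
                "t2l_ms": [31.5, 38.2],
                "f": [0.46, 0.6],
                "r2": [0.99, 0.99],
                "na_sf_mM": [21.0, 22.0],
                "na_lf_mM": [25.0, 16.0],
                "tsc_mM": [46.0, 38.0],
                "ecf": [0.18, 0.11],
            }
        )
        subjects = pd.DataFrame(
            {"subject_id": ["s1"], "sex": ["female"], "age": [25]}
        )
        long = metrics_long_table(quant, subjects)
        assert set(long["metric_name"]) == {"t2s", "t2l", "na_sf", "na_lf", "tsc", "ecf"}
        assert long.shape[0] == 12
        row = long[(long["metric_name"] == "tsc") & (long["group_label"] == "GM")]
        assert row["value"].iloc[0] == 46.0
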