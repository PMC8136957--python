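"""z-factor screening, pooling, family-wise normalization, and the
one-hold-out stability ranking."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from biodyn.biomarkers import BiomarkerPanel
from biodyn.errors import DataError, StatisticsError
from biodyn.selection import (
    normalize_panel,
    pool_biomarkers,
    rank_one_hold_out,
    z_factor,
    z_factor_record,
)


def make_panel(values: dict, families=None, index=None):
    df = pd.DataFrame(values, index=index)
    if index is None:
        df.index = [f"S{i + 1}" for i in range(len(df))]
    fams = families or {c: "local" for c in df.columns}
    return BiomarkerPanel(values=df, families=fams)


class TestZFactor:
    def test_worked_arithmetic(self):
        """mu_A=1, mu_B=0, sigma=0.1 each: Z = 1 - 3(0.2)/1 = 0.4."""
        rng = np.random.default_rng(0)
        # construct groups with exactly the target means and SDs
        base = rng.standard_normal(20)
        base = (base - base.mean()) / base.std(ddof=1)
        a = 1.0 + 0.1 * base
        b = 0.0 + 0.1 * base
        assert z_factor(a, b) == pytest.approx(0.4, abs=1e-12)

    def test_zero_spread_perfect_assay(self):
        assert z_factor([1.0, 1.0, 1.0], [0.0, 0.0, 0.0]) == 1.0

    def test_wide_overlap_goes_negative(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 5.0, 50)
        b = rng.normal(0.1, 5.0, 50)
        assert z_factor(a, b) < 0

    def test_equal_means_flagged_undefined(self):
        rec = z_factor_record("b", [1.0, 2.0], [2.0, 1.0])
        assert rec.undefined
        assert np.isnan(rec.z_factor)

    def test_singleton_group_warns_sd_zero(self):
        with pytest.warns(UserWarning, match="single value"):
            z = z_factor([1.0], [0.0, 0.1, -0.1])
        assert z <= 1.0

    def test_empty_group_raises(self):
        with pytest.raises(StatisticsError):
            z_factor([], [1.0])

    @given(
        scale=st.floats(min_value=0.01, max_value=50.0),
        shift=st.floats(min_value=-10.0, max_value=10.0),
    )
    def test_affine_invariance(self, scale, shift):
        rng = np.random.default_rng(3)
        a = rng.normal(1.0, 0.2, 10)
        b = rng.normal(0.0, 0.3, 10)
        z0 = z_factor(a, b)
        z1 = z_factor(scale * a + shift, scale * b + shift)
        assert z1 == pytest.approx(z0, rel=1e-9, abs=1e-9)


class TestPooling:
    def test_perfectly_correlated_pair_pools_to_mean(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        panel = make_panel({"A": x, "B": 2 * x + 1, "C": [5, 1, 4, 2]})
        pooled, mapping = pool_biomarkers(panel, 0.9)
        pool_name = next(k for k, v in mapping.items() if len(v) > 1)
        assert sorted(mapping[pool_name]) == ["A", "B"]
        np.testing.assert_allclose(
            pooled.values[pool_name], (x + (2 * x + 1)) / 2
        )
        assert mapping["C"] == ["C"]

    def test_uncorrelated_panel_identity_map(self):
        rng = np.random.default_rng(5)
        panel = make_panel({f"B{i}": rng.standard_normal(12) for i in range(4)})
        pooled, mapping = pool_biomarkers(panel, 0.95)
        assert all(v == [k] for k, v in mapping.items())
        assert sorted(pooled.biomarkers) == sorted(panel.biomarkers)

    def test_constant_biomarker_excluded_with_warning(self):
        panel = make_panel({"A": [1.0, 2.0, 3.0], "K": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            pooled, mapping = pool_biomarkers(panel, 0.9)
        assert mapping["K"] == ["K"]

    def test_pooling_respects_families(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        panel = make_panel(
            {"L": x, "G": x.copy()},
            families={"L": "local", "G": "global"},
        )
        _, mapping = pool_biomarkers(panel, 0.9)
        # perfectly correlated but different families: not pooled
        assert mapping["L"] == ["L"] and mapping["G"] == ["G"]

    def test_pooled_members_partition(self):
        rng = np.random.default_rng(6)
        latent = rng.standard_normal(10)
        panel = make_panel(
            {f"B{i}": latent + rng.normal(0, 0.05, 10) for i in range(3)}
            | {"N": rng.standard_normal(10)}
        )
        _, mapping = pool_biomarkers(panel, 0.9)
        members = [m for v in mapping.values() for m in v]
        assert sorted(members) == sorted(panel.biomarkers)

    def test_pooling_improves_z_factor(self):
        """Three noisy copies of one latent signal: the pooled biomarker
        separates the outcome groups better than any member."""
        rng = np.random.default_rng(11)
        n = 20
        label = np.array([True] * 10 + [False] * 10)
        latent = 2.0 * label + rng.normal(0, 0.5, n)
        panel = make_panel(
            {f"B{i}": latent + rng.normal(0, 0.5, n) for i in range(3)}
        )
        pooled, mapping = pool_biomarkers(panel, 0.5)
        pool_name = next(k for k, v in mapping.items() if len(v) > 1)
        z_members = [
            z_factor(panel.values[c][label], panel.values[c][~label])
            for c in mapping[pool_name]
        ]
        z_pooled = z_factor(
            pooled.values[pool_name][label], pooled.values[pool_name][~label]
        )
        assert z_pooled > max(z_members)


class TestNormalization:
    def test_divides_by_family_minimum_sd(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 0.2, 30)
        b = rng.normal(0, 0.5, 30)
        panel = make_panel({"A": a, "B": b})
        normed = normalize_panel(panel)
        min_sd = min(a.std(ddof=1), b.std(ddof=1))
        np.testing.assert_allclose(normed.values["A"], a / min_sd)
        np.testing.assert_allclose(normed.values["B"], b / min_sd)
        assert min(normed.values.std(ddof=1)) == pytest.approx(1.0)

    def test_families_normalized_independently(self):
        rng = np.random.default_rng(9)
        local = rng.normal(0, 0.3, 20)
        glob = rng.normal(0, 0.7, 20)
        panel = make_panel(
            {"L": local, "G": glob}, families={"L": "local", "G": "global"}
        )
        scaled = make_panel(
            {"L": local, "G": 10 * glob}, families={"L": "local", "G": "global"}
        )
        np.testing.assert_allclose(
            normalize_panel(panel).values["L"],
            normalize_panel(scaled).values["L"],
        )

    def test_z_factor_invariant_under_normalization(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(0, 0.4, 20)
        label = np.array([True] * 10 + [False] * 10)
        panel = make_panel({"A": vals + label, "B": rng.normal(0, 2.0, 20)})
        normed = normalize_panel(panel)
        z0 = z_factor(panel.values["A"][label], panel.values["A"][~label])
        z1 = z_factor(normed.values["A"][label], normed.values["A"][~label])
        assert z1 == pytest.approx(z0)

    def test_all_zero_sd_family_raises(self):
        panel = make_panel({"A": [1.0, 1.0, 1.0]})
        with pytest.raises(StatisticsError, match="local"):
            normalize_panel(panel)


class TestOneHoldOut:
    @staticmethod
    def planted_panel(n=20, n_noise=7, seed=15):
        rng = np.random.default_rng(seed)
        labels = pd.Series(
            [True] * (n // 2) + [False] * (n // 2),
            index=[f"S{i + 1}" for i in range(n)],
        )
        cols = {"Signal": labels.to_numpy() * 1.0 + rng.normal(0, 0.01, n)}
        for i in range(n_noise):
            cols[f"Noise {i + 1}"] = rng.standard_normal(n)
        return make_panel(cols, index=labels.index), labels

    def test_planted_signal_recovered_with_full_stability(self):
        panel, labels = self.planted_panel()
        result = rank_one_hold_out(panel, labels, k=1)
        assert result.ranking[0] == "Signal"
        assert result.stability["Signal"] == 1.0
        assert result.stable == ["Signal"]

    def test_null_panels_rarely_produce_stable_winner(self):
        """Pure-noise panels (10 subjects x 40 biomarkers): at least 90%
        have no stability-1 biomarker at k=1. Folds share 9 of 10
        subjects, so per-fold rankings are correlated and occasional
        stable noise winners are expected."""
        rng = np.random.default_rng(20260921)
        hits = 0
        for _ in range(100):
            vals = pd.DataFrame(
                rng.standard_normal((10, 40)),
                index=[f"S{j}" for j in range(10)],
                columns=[f"B{j}" for j in range(40)],
            )
            panel = BiomarkerPanel(
                values=vals, families={c: "local" for c in vals.columns}
            )
            labels = pd.Series(
                rng.permutation([True] * 5 + [False] * 5), index=vals.index
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if rank_one_hold_out(panel, labels, k=1).stable:
                    hits += 1
        assert hits <= 10

    def test_recovery_probability_monotone_in_effect_size(self):
        """Planted-signal recovery rate grows with effect size (ladder of
        3 effect sizes x 100 panels)."""
        rng = np.random.default_rng(33)
        rates = []
        for effect in (0.5, 1.5, 4.0):
            wins = 0
            for _ in range(100):
                n = 10
                labels = pd.Series(
                    rng.permutation([True] * 5 + [False] * 5),
                    index=[f"S{i}" for i in range(n)],
                )
                cols = {
                    "Signal": effect * labels.to_numpy() + rng.standard_normal(n)
                }
                for i in range(5):
                    cols[f"Noise {i}"] = rng.standard_normal(n)
                panel = make_panel(cols, index=labels.index)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = rank_one_hold_out(panel, labels, k=1)
                wins += res.ranking[0] == "Signal"
            rates.append(wins / 100)
        assert rates[0] < rates[1] < rates[2]

    def test_duplicated_subjects_keep_ranking(self):
        """Duplicating every subject leaves the ranking of well-separated
        biomarkers unchanged (fold invariance up to fold count; near-tied
        pure-noise biomarkers are excluded because their ordering is a
        knife edge by construction)."""
        rng = np.random.default_rng(16)
        n = 10
        labels = pd.Series(
            [True] * 5 + [False] * 5, index=[f"S{i + 1}" for i in range(n)]
        )
        cols = {
            f"Effect {i}": eff * labels.to_numpy() + rng.normal(0, 0.05, n)
            for i, eff in enumerate((2.0, 1.0, 0.5, 0.25))
        }
        panel = make_panel(cols, index=labels.index)
        dup_values = pd.concat(
            [panel.values, panel.values.set_axis([f"D{i}" for i in range(n)])]
        )
        dup_labels = pd.concat(
            [labels, labels.set_axis([f"D{i}" for i in range(n)])]
        )
        dup_panel = BiomarkerPanel(values=dup_values, families=panel.families)
        r1 = rank_one_hold_out(panel, labels, k=1)
        r2 = rank_one_hold_out(dup_panel, dup_labels, k=1)
        assert r1.ranking == r2.ranking
        assert r1.stable == r2.stable

    def test_fold_losing_class_skipped_with_warning(self):
        panel, _ = self.planted_panel(n=4, n_noise=1, seed=17)
        labels = pd.Series(
            [True, False, False, False], index=panel.values.index
        )
        with pytest.warns(UserWarning, match="lost a label class"):
            result = rank_one_hold_out(panel, labels, k=1)
        assert result.skipped_folds == ["S1"]

    def test_too_few_subjects_or_single_class(self):
        panel, labels = self.planted_panel(n=4, n_noise=1)
        with pytest.raises(StatisticsError):
            rank_one_hold_out(
                BiomarkerPanel(
                    values=panel.values.iloc[:2], families=panel.families
                ),
                labels.iloc[:2],
                k=1,
            )
        with pytest.raises(StatisticsError):
            rank_one_hold_out(panel, labels * 0 + True, k=1)

    def test_paper_scale_reduction_structure(self):
        """A 13-biomarker panel with 4 planted discriminating biomarkers
        reduces to exactly those 4 under one-hold-out stability at k=4
        (structural reproduction of the screening funnel)."""
        rng = np.random.default_rng(99)
        n = 10
        labels = pd.Series(
            [True] * 7 + [False] * 3, index=[f"S{i + 1}" for i in range(n)]
        )
        cols = {}
        for i in range(4):
            cols[f"Planted {i + 1}"] = (
                2.0 * labels.to_numpy() + rng.normal(0, 0.05, n)
            )
        for i in range(9):
            cols[f"Noise {i + 1}"] = rng.standard_normal(n)
        panel = make_panel(cols, index=labels.index)
        result = rank_one_hold_out(panel, labels, k=4)
        assert sorted(result.stable) == [f"Planted {i + 1}" for i in range(4)]
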