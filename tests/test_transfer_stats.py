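"""Transfer difference/strength, the 2x3 ANOVA and the power analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from facedcm.model_comparison import entry_label
from facedcm.network_model import MODULATORY_INPUTS, region_index
from facedcm.transfer_stats import (
    TransferMeasures,
    extract_measures,
    power_paired_t,
    power_sample_size,
    rm_anova_2x3,
    transfer_difference,
    transfer_strength,
)

finite = st.floats(min_value=-10, max_value=10, allow_nan=False)


class TestTransferMeasures:
    def test_central_condition_worked_examples(self):
        # printed group-average homotopic modulations under central faces
        assert transfer_difference(0.27, 0.23) == pytest.approx(0.04)
        assert transfer_difference(0.02, -0.12) == pytest.approx(0.14)
        assert transfer_strength(0.27, 0.23) == pytest.approx(0.25)
        assert transfer_strength(0.0, 0.0) == 0.0

    @given(x=finite)
    @settings(max_examples=50, deadline=None)
    def test_equal_transfer_has_zero_difference(self, x):
        assert transfer_difference(x, x) == 0.0

    @given(a=st.floats(min_value=0, max_value=10, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_transfer_strength(self, a):
        assert transfer_strength(-a, a) == pytest.approx(a)

    @given(b_lr=finite, b_rl=finite)
    @settings(max_examples=100, deadline=None)
    def test_strength_dominates_half_difference(self, b_lr, b_rl):
        d = transfer_difference(b_lr, b_rl)
        s = transfer_strength(b_lr, b_rl)
        assert s >= abs(d) / 2 - 1e-12
        assert s >= 0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            transfer_difference(np.nan, 0.0)
        with pytest.raises(ValueError):
            transfer_strength(np.inf, 0.0)


def _param_map(values):
    """values: {(mod, src, tgt): b} -> labelled parameter dict."""
    out = {}
    for (mod, src, tgt), v in values.items():
        m = MODULATORY_INPUTS.index(mod)
        out[entry_label(("B", m, region_index(tgt), region_index(src)))] = v
    return out


def _full_subject(offset=0.0):
    values = {}
    for mod in MODULATORY_INPUTS:
        for pair in ("OFA", "FFA"):
            values[(mod, f"l{pair}", f"r{pair}")] = 0.3 + offset
            values[(mod, f"r{pair}", f"l{pair}")] = 0.1 + offset
    return _param_map(values)


class TestExtractMeasures:
    def test_hand_computed_table(self):
        measures = extract_measures([_full_subject()])
        df = measures.table
        assert len(df) == 6  # 2 pairs x 3 locations
        assert np.allclose(df["difference"], 0.2)
        assert np.allclose(df["strength"], 0.2)

    def test_mirror_swap_negates_difference_keeps_strength(self):
        values = {("CF", "lFFA", "rFFA"): 0.4, ("CF", "rFFA", "lFFA"): -0.1,
                  ("CF", "lOFA", "rOFA"): 0.2, ("CF", "rOFA", "lOFA"): 0.3,
                  ("LF", "lFFA", "rFFA"): 0.1, ("LF", "rFFA", "lFFA"): 0.2,
                  ("LF", "lOFA", "rOFA"): 0.0, ("LF", "rOFA", "lOFA"): 0.1,
                  ("RF", "lFFA", "rFFA"): -0.2, ("RF", "rFFA", "lFFA"): 0.2,
                  ("RF", "lOFA", "rOFA"): 0.5, ("RF", "rOFA", "lOFA"): 0.1}
        swapped = {
            (mod, src.translate(str.maketrans("lr", "rl")),
             tgt.translate(str.maketrans("lr", "rl"))): v
            for (mod, src, tgt), v in values.items()
        }
        t1 = extract_measures([_param_map(values)]).table
        t2 = extract_measures([_param_map(swapped)]).table
        merged = t1.merge(t2, on=["subject", "region_pair", "location"])
        assert np.allclose(merged["difference_x"], -merged["difference_y"])
        assert np.allclose(merged["strength_x"], merged["strength_y"])

    def test_cohort_row_count(self):
        measures = extract_measures([_full_subject(0.01 * s) for s in range(17)])
        assert len(measures.table) == 17 * 2 * 3

    def test_missing_parameter_named(self):
        incomplete = _full_subject()
        key = next(iter(incomplete))
        del incomplete[key]
        with pytest.raises(KeyError, match="missing homotopic"):
            extract_measures([incomplete])


def _cohort(n=17, loc_shift=(0.0, 0.0, 0.0), noise=0.3, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    shift = dict(zip(("left", "central", "right"), loc_shift))
    for s in range(n):
        base = rng.normal(0, 0.2)
        for pair in ("OFA", "FFA"):
            for loc in ("left", "central", "right"):
                d = base + shift[loc] + rng.normal(0, noise)
                rows.append({"subject": s, "region_pair": pair,
                             "location": loc, "b_lr": d, "b_rl": 0.0,
                             "difference": d, "strength": abs(d)})
    return TransferMeasures(pd.DataFrame(rows))


class TestRmAnova:
    def test_no_location_variation_gives_null_location_effect(self):
        """Subject and region effects without any location structure must
        not produce a location effect."""
        measures = _cohort(n=17, loc_shift=(0.0, 0.0, 0.0), seed=1)
        res = rm_anova_2x3(measures, "difference")
        assert res.effects.loc["location", "p"] > 0.1
        assert res.effects.loc["location", "F"] < 3.0

    def test_large_location_shift_detected_at_n17(self):
        measures = _cohort(n=17, loc_shift=(0.8, 0.0, 0.7), seed=2)
        res = rm_anova_2x3(measures, "difference")
        assert res.effects.loc["location", "p"] < 0.001
        assert all(row["p"] < 0.05 for _, row in res.posthoc.iterrows()
                   if {row["a"], row["b"]} != {"left", "right"})

    def test_matches_textbook_sums_of_squares(self):
        measures = _cohort(n=10, loc_shift=(0.2, 0.0, 0.4), seed=5)
        res = rm_anova_2x3(measures, "difference")

        df = measures.table
        pairs = sorted(df["region_pair"].unique())
        locs = sorted(df["location"].unique())
        arr = np.zeros((10, len(pairs), len(locs)))
        for s in range(10):
            for ri, rp in enumerate(pairs):
                for li, loc in enumerate(locs):
                    arr[s, ri, li] = df[(df.subject == s)
                                        & (df.region_pair == rp)
                                        & (df.location == loc)]["difference"].iloc[0]
        n, a, b = arr.shape
        gm = arr.mean()
        ma = arr.mean(axis=(0, 2))
        mb = arr.mean(axis=(0, 1))
        ms = arr.mean(axis=(1, 2))
        mab = arr.mean(axis=0)
        mas = arr.mean(axis=2)
        mbs = arr.mean(axis=1)
        ss_a = n * b * np.sum((ma - gm) ** 2)
        ss_b = n * a * np.sum((mb - gm) ** 2)
        ss_ab = n * np.sum((mab - ma[:, None] - mb[None, :] + gm) ** 2)
        ss_as = b * np.sum((mas - ma[None, :] - ms[:, None] + gm) ** 2)
        ss_bs = a * np.sum((mbs - mb[None, :] - ms[:, None] + gm) ** 2)
        ss_abs = np.sum((arr - mab[None] - mas[:, :, None] - mbs[:, None, :]
                         + ma[None, :, None] + mb[None, None, :]
                         + ms[:, None, None] - gm) ** 2)
        f_a = (ss_a / (a - 1)) / (ss_as / ((a - 1) * (n - 1)))
        f_b = (ss_b / (b - 1)) / (ss_bs / ((b - 1) * (n - 1)))
        f_ab = (ss_ab / ((a - 1) * (b - 1))) / (
            ss_abs / ((a - 1) * (b - 1) * (n - 1)))
        assert res.effects.loc["region", "F"] == pytest.approx(f_a, abs=1e-6)
        assert res.effects.loc["location", "F"] == pytest.approx(f_b, abs=1e-6)
        assert res.effects.loc["region x location", "F"] == pytest.approx(
            f_ab, abs=1e-6)

    def test_location_f_near_one_under_permutation_null(self):
        """Permuting location labels within subject destroys the effect;
        the location F statistic should average about 1."""
        measures = _cohort(n=12, loc_shift=(0.5, 0.0, 0.4), seed=7)
        df = measures.table
        rng = np.random.default_rng(0)
        fs = []
        locs = np.array(["left", "central", "right"])
        for _ in range(200):
            shuffled = df.copy()
            for s in shuffled["subject"].unique():
                perm = rng.permutation(3)
                mask = shuffled["subject"] == s
                mapping = dict(zip(locs, locs[perm]))
                shuffled.loc[mask, "location"] = shuffled.loc[
                    mask, "location"].map(mapping)
            res = rm_anova_2x3(TransferMeasures(shuffled), "difference")
            fs.append(res.effects.loc["location", "F"])
        assert 0.6 < np.mean(fs) < 1.5

    def test_incomplete_design_rejected(self):
        measures = _cohort(n=5)
        broken = TransferMeasures(measures.table.iloc[:-1])
        with pytest.raises(ValueError, match="incomplete|unbalanced"):
            rm_anova_2x3(broken, "difference")

    def test_report_serialisation(self, tmp_path):
        res = rm_anova_2x3(_cohort(n=6, seed=3), "strength")
        text = res.to_json(tmp_path / "anova.json")
        assert "location" in text
        assert "ANOVA" in res.summary()


class TestPowerAnalysis:
    def test_study_design_sample_size(self):
        # d = 1.17, Bonferroni alpha 0.05/4, power 0.95 -> 16 participants
        assert power_sample_size(1.17, 0.0125, 0.95) == 16

    def test_power_monotone_in_n(self):
        powers = [power_paired_t(0.8, 0.05, n) for n in range(3, 40)]
        assert all(b >= a for a, b in zip(powers, powers[1:]))

    def test_monte_carlo_rejection_rates_bracket_the_answer(self):
        """At n-1 the simulated rejection rate falls short of the target;
        at the returned n it reaches it (within binomial error)."""
        d, alpha, target = 1.17, 0.0125, 0.95
        n_star = power_sample_size(d, alpha, target)
        rng = np.random.default_rng(123)
        reps = 200_000
        from scipy import stats as sps

        for n, expect_reach in ((n_star - 1, False), (n_star, True)):
            x = rng.standard_normal((reps, n)) + d
            t = x.mean(axis=1) / (x.std(axis=1, ddof=1) / np.sqrt(n))
            crit = sps.t.ppf(1 - alpha / 2, n - 1)
            rate = np.mean(np.abs(t) > crit)
            se = 3 * np.sqrt(target * (1 - target) / reps)
            if expect_reach:
                assert rate >= target - se
            else:
                assert rate < target - se
            # MC agrees with the exact noncentral-t power
            assert rate == pytest.approx(power_paired_t(d, alpha, n), abs=0.005)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            power_sample_size(-1.0, 0.05, 0.9)
        with pytest.raises(ValueError):
            power_sample_size(0.5, 1.5, 0.9)
        with pytest.raises(ValueError):
            power_sample_size(0.5, 0.05, 0.0)
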