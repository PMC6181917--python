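"""Tau specificity, group aggregation, the LRT, and FDR control."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicescape.specificity_differential import (
    aggregate_groups,
    bh_fdr,
    call_specific,
    coverage_filter,
    differential_lrt,
    differential_table,
    specificity_profiles,
    tau,
)


class TestTau:
    def test_single_group_expression_is_one(self):
        assert tau([10, 0, 0, 0, 0]) == pytest.approx(1.0)

    def test_uniform_expression_is_zero(self):
        assert tau([4, 4, 4, 4]) == pytest.approx(0.0)

    def test_two_group_halfway(self):
        # x_hat = (1, 0.5) -> (0 + 0.5) / 1
        assert tau([8, 4]) == pytest.approx(0.5)

    def test_near_specific_profile(self):
        # hand arithmetic: ((1-1) + (1-1/9) + 3*1) / 4 = 0.9722...
        assert tau([9, 1, 0, 0, 0]) == pytest.approx(35 / 36)

    def test_all_zero_is_undefined(self):
        assert math.isnan(tau([0, 0, 0]))

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            tau([5.0])

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(st.floats(0, 1e6, allow_nan=False), min_size=2, max_size=8),
        st.floats(0.01, 1e3),
    )
    def test_scale_invariant_and_permutation_equivariant(self, x, c):
        if max(x) == 0:
            return
        t0 = tau(x)
        assert tau([c * v for v in x]) == pytest.approx(t0, abs=1e-9)
        assert tau(list(reversed(x))) == pytest.approx(t0, abs=1e-9)
        assert 0.0 <= t0 <= 1.0


def _quants(rows):
    return pd.DataFrame(rows, columns=["event_key", "sample_id", "counts_eii", "counts_eei"])


def _sheet(samples):
    return pd.DataFrame(samples, columns=["sample_id", "tissue", "stage", "replicate"])


class TestAggregateGroups:
    def test_tissue_mode_pools_stages_and_replicates(self):
        samples, rows = [], []
        for stage in ("fetus", "m2", "y1", "adult"):
            for rep in (1, 2, 3):
                sid = f"muscle_{stage}_r{rep}"
                samples.append((sid, "muscle", stage, rep))
                rows.append(("ev1", sid, 2, 1))
        agg = aggregate_groups(_quants(rows), _sheet(samples))
        eii = agg[(agg.side == "EII")]
        assert len(eii) == 1
        assert eii.iloc[0]["raw_count"] == 24  # 12 samples x 2

    def test_cpm_normalizes_by_library_size(self):
        samples = [("s1", "heart", "adult", 1), ("s2", "liver", "adult", 1)]
        rows = [("ev1", "s1", 10, 0), ("ev1", "s2", 20, 0)]
        agg = aggregate_groups(
            _quants(rows),
            _sheet(samples),
            library_sizes={"s1": 1_000_000, "s2": 2_000_000},
        )
        eii = agg[agg.side == "EII"].set_index("group")
        assert eii.loc["heart", "cpm"] == pytest.approx(eii.loc["liver", "cpm"])

    def test_unknown_sample_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            aggregate_groups(
                _quants([("ev1", "mystery", 1, 1)]),
                _sheet([("s1", "heart", "adult", 1)]),
            )

    def test_stage_mode_requires_tissue_and_groups_by_stage(self):
        samples = [
            ("m_f_r1", "muscle", "fetus", 1),
            ("m_a_r1", "muscle", "adult", 1),
            ("h_f_r1", "heart", "fetus", 1),
        ]
        rows = [("ev1", s, 3, 1) for s, *_ in samples]
        agg = aggregate_groups(_quants(rows), _sheet(samples), mode="stage", tissue="muscle")
        assert set(agg["group"]) == {"fetus", "adult"}
        with pytest.raises(ValueError):
            aggregate_groups(_quants(rows), _sheet(samples), mode="stage")


class TestCoverageFilter:
    def _agg(self, raw_counts):
        return pd.DataFrame(
            {
                "event_key": "ev1",
                "group": [f"g{i}" for i in range(len(raw_counts))],
                "side": "EII",
                "raw_count": raw_counts,
                "cpm": raw_counts,
            }
        )

    def test_max_count_below_three_removed(self):
        assert coverage_filter(self._agg([2, 1, 0])).empty

    def test_boundary_count_three_kept(self):
        assert len(coverage_filter(self._agg([3, 0, 0]))) == 3

    def test_all_zero_removed(self):
        assert coverage_filter(self._agg([0, 0, 0])).empty


def _profiles_from_counts(counts_by_group, side="EII", event="ev1"):
    agg = pd.DataFrame(
        {
            "event_key": event,
            "group": list(counts_by_group),
            "side": side,
            "raw_count": list(counts_by_group.values()),
            "cpm": list(counts_by_group.values()),
        }
    )
    return specificity_profiles(agg)


class TestCallSpecific:
    def test_single_tissue_expression_is_specific(self):
        profiles = _profiles_from_counts(
            {"muscle": 9, "heart": 0, "kidney": 0, "liver": 0, "spleen": 0}
        )
        calls = call_specific(profiles)
        assert calls.iloc[0]["specific"]
        assert calls.iloc[0]["specific_group"] == "muscle"

    def test_any_leakage_blocks_strict_call(self):
        profiles = _profiles_from_counts(
            {"muscle": 9, "heart": 1, "kidney": 0, "liver": 0, "spleen": 0}
        )
        assert not call_specific(profiles, tau_threshold=1.0).iloc[0]["specific"]

    def test_relaxed_threshold_admits_near_specific(self):
        profiles = _profiles_from_counts(
            {"muscle": 9, "heart": 1, "kidney": 0, "liver": 0, "spleen": 0}
        )
        calls = call_specific(profiles, tau_threshold=0.9)
        assert calls.iloc[0]["tau"] == pytest.approx(35 / 36)
        assert calls.iloc[0]["specific"]

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.integers(0, 20), min_size=2, max_size=6))
    def test_strict_call_equals_brute_force_single_group_rule(self, counts):
        if max(counts) == 0:
            return
        profiles = _profiles_from_counts(
            {f"g{i}": c for i, c in enumerate(counts)}
        )
        call = bool(call_specific(profiles, tau_threshold=1.0).iloc[0]["specific"])
        assert call == (sum(1 for c in counts if c > 0) == 1)


class TestDifferentialLRT:
    def test_identical_counts_give_null_result(self):
        res = differential_lrt([(50, 50)] * 3, [(50, 50)] * 3)
        assert res.lr_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_opposite_extreme_counts_highly_significant(self):
        res = differential_lrt([(90, 10)] * 3, [(10, 90)] * 3)
        assert res.p_value < 1e-6

    def test_closed_form_matches_direct_loglik_arithmetic(self):
        ca, cb = [(30, 10), (28, 12)], [(15, 25), (18, 22)]
        res = differential_lrt(ca, cb)
        ia, ea = 58.0, 22.0
        ib, eb = 33.0, 47.0
        pa, pb = ia / (ia + ea), ib / (ib + eb)
        p0 = (ia + ib) / (ia + ea + ib + eb)

        def ll(i, e, p):
            return i * math.log(p) + e * math.log(1 - p)

        lr = 2 * (ll(ia, ea, pa) + ll(ib, eb, pb) - ll(ia, ea, p0) - ll(ib, eb, p0))
        assert res.lr_statistic == pytest.approx(lr)

    def test_untestable_zero_condition_skipped(self):
        assert differential_lrt([(0, 0)] * 3, [(10, 10)] * 3) is None

    def test_separation_flagged_not_crashed(self):
        res = differential_lrt([(20, 0)] * 3, [(0, 20)] * 3)
        assert res.boundary
        assert res.p_value < 1e-6

    def test_type_i_error_controlled_under_null(self):
        rng = np.random.default_rng(7)
        n, reps, events = 100, 3, 2000
        rejections = 0
        for _ in range(events):
            ca = [(int(i), n - int(i)) for i in rng.binomial(n, 0.5, reps)]
            cb = [(int(i), n - int(i)) for i in rng.binomial(n, 0.5, reps)]
            if differential_lrt(ca, cb).p_value < 0.05:
                rejections += 1
        assert abs(rejections / events - 0.05) <= 0.015

    def test_power_increases_with_effect_size(self):
        rng = np.random.default_rng(8)
        n, sims = 100, 1000
        powers = []
        for dpsi in (0.1, 0.3, 0.5):
            hits = 0
            for _ in range(sims):
                ca = [(int(i), n - int(i)) for i in rng.binomial(n, 0.5 - dpsi / 2, 3)]
                cb = [(int(i), n - int(i)) for i in rng.binomial(n, 0.5 + dpsi / 2, 3)]
                res = differential_lrt(ca, cb)
                hits += res is not None and res.p_value < 0.05
            powers.append(hits / sims)
        # power saturates at 1 for large effects; require monotone
        # non-decreasing with a strict rise over the full effect range
        assert powers[0] <= powers[1] <= powers[2]
        assert powers[0] < powers[2]
        assert powers[2] > 0.99


class TestBhFdr:
    def test_step_up_arithmetic(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2]), [0.2])

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0]), [1.0, 1.0])

    def test_empty_input(self):
        assert bh_fdr([]).size == 0

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(1e-9, 1.0, allow_nan=False), min_size=1, max_size=30))
    def test_q_dominates_p_and_is_monotone_in_rank(self, ps):
        q = bh_fdr(ps)
        assert (q >= np.asarray(ps) - 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(np.asarray(q)[order]) >= -1e-12).all()


def test_differential_table_integration():
    samples = [
        (f"{t}_r{r}", t, "adult", r) for t in ("heart", "muscle") for r in (1, 2, 3)
    ]
    rows = []
    for r in (1, 2, 3):
        rows += [("shifted", f"heart_r{r}", 90, 10), ("shifted", f"muscle_r{r}", 10, 90)]
        rows += [("flat", f"heart_r{r}", 40, 60), ("flat", f"muscle_r{r}", 40, 60)]
    diff = differential_table(_quants(rows), _sheet(samples), "heart", "muscle")
    diff = diff.set_index("event_key")
    assert bool(diff.loc["shifted", "significant"])
    assert not bool(diff.loc["flat", "significant"])
    assert (diff["q_value"] >= diff["p_value"] - 1e-12).all()
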