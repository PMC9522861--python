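"""Asymmetry index, significance A, credibility floor, AEP/unilateral/shared calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import latproteo as lp
from latproteo.asymmetry import AEP_CLASSES, UNILATERAL_CLASSES

from conftest import make_dm


class TestAsymmetryIndex:
    def test_endpoints_and_arithmetic(self):
        assert lp.asymmetry_index(100, 0) == 1.0
        assert lp.asymmetry_index(0, 100) == -1.0
        assert lp.asymmetry_index(7.3, 7.3) == 0.0
        assert lp.asymmetry_index(300, 100) == 0.5

    def test_undefined_and_negative(self):
        with pytest.raises(lp.DataError):
            lp.asymmetry_index(0, 0)
        with pytest.raises(lp.DataError):
            lp.asymmetry_index(-1, 2)

    @given(st.floats(0, 1e9), st.floats(0, 1e9))
    def test_antisymmetric_and_bounded(self, L, R):
        if L + R == 0:
            return
        ai = lp.asymmetry_index(L, R)
        assert -1.0 <= ai <= 1.0
        assert ai == -lp.asymmetry_index(R, L)


class TestSignificanceA:
    def test_median_point_has_p_half(self):
        rng = np.random.default_rng(0)
        q, p = lp.significance_a(rng.normal(0, 1, 500))
        assert lp.sig_a_p(q.r0, q)[0] == pytest.approx(0.5)

    def test_constant_ratios_are_degenerate(self):
        q, p = lp.significance_a(np.zeros(50))
        assert q.r_minus1 == q.r0 == q.r1
        assert np.all(p == 1.0)

    def test_upper_quantile_point_matches_normal_tail(self):
        """At x = r1 the robust z is 1 by construction, so p = P(Z > 1) = 0.1587."""
        rng = np.random.default_rng(1)
        q, _ = lp.significance_a(rng.normal(0, 1, 5000))
        assert lp.sig_a_p(q.r1, q)[0] == pytest.approx(0.15866, abs=1e-4)

    def test_each_tail_flags_about_five_percent(self):
        """One-sided construction: ~5% of a symmetric null falls under 0.05 per tail."""
        rng = np.random.default_rng(2)
        _, p = lp.significance_a(rng.normal(0, 1, 5000))
        frac = (p < 0.05).mean()
        assert 0.08 <= frac <= 0.12

    def test_low_power_warning(self, caplog):
        with caplog.at_level("WARNING", logger="latproteo.asymmetry"):
            lp.significance_a(np.arange(10.0))
        assert any("low-power" in r.message for r in caplog.records)


class TestIntensityFloor:
    def test_examples(self):
        assert lp.intensity_floor(np.full(100, 3.5)) == 3.5
        assert lp.intensity_floor(np.arange(1.0, 101.0), 1) == pytest.approx(1.99)

    def test_monotone_in_percentile(self):
        rng = np.random.default_rng(3)
        vals = rng.lognormal(3, 1, 400)
        floors = [lp.intensity_floor(vals, q) for q in (0.5, 1, 2, 5, 10)]
        assert all(b >= a for a, b in zip(floors[:-1], floors[1:]))


def no_noise_study(effect=1.5, seed=4):
    return lp.generate(
        lp.SimParams(
            n_proteins=600, frac_aep=0.08, aep_log2_effect=effect, frac_unilateral=0.05,
            noise_log2_sd=0.02, dropout_midpoint=None, seed=seed,
        )
    )


class TestCallAeps:
    def test_tight_null_recovers_exactly_the_planted_set(self):
        """Planted 2^1.5-fold left effects against a near-zero null spread."""
        m, d, truth = no_noise_study()
        dm = lp.join_design(m, d)
        for gw in (9, 11, 13):
            rec = lp.call_aeps(dm, gw)
            called = set(rec.loc[rec["class"] == "aep_left", "protein"])
            low = set(rec.loc[rec["class"] == "low_intensity", "protein"])
            planted = truth.proteins_with_label("aep_left", gw)
            assert called <= planted
            # misses are exactly the planted proteins under the credibility floor
            assert planted - called == planted & low

    def test_fold_change_boundary_is_strict(self):
        vals = np.ones((40, 6))
        vals[0, 0] = 2.0  # L/R exactly 2 at gw 9
        rng = np.random.default_rng(5)
        vals[1:, :] *= rng.lognormal(0, 0.05, size=(39, 6))
        rec = lp.call_aeps(make_dm(vals * 100), 9)
        assert rec.set_index("protein").loc["P000", "class"] == "bilateral_ns"

    def test_low_intensity_candidate_excluded(self):
        """An above-threshold ratio at trace intensity is not a credible AEP."""
        rng = np.random.default_rng(6)
        vals = 1000 * rng.lognormal(0, 0.1, size=(200, 6))
        vals[0, 0], vals[0, 1] = 0.9, 0.1  # 9-fold left at ~1/2000 of typical intensity
        rec = lp.call_aeps(make_dm(vals), 9)
        row = rec.set_index("protein").loc["P000"]
        assert row["fold_change"] > 2
        assert row["class"] == "low_intensity"


class TestCallUnilateral:
    def test_floor_splits_unilateral_calls(self):
        rng = np.random.default_rng(7)
        vals = 1000 * rng.lognormal(0, 0.1, size=(300, 6))
        vals[0, 0], vals[0, 1] = 20000.0, 0.0  # left-only, well above the floor
        vals[1, 0], vals[1, 1] = 0.01, 0.0  # left-only, trace intensity
        rec = lp.call_unilateral(make_dm(vals), 9).set_index("protein")
        assert rec.loc["P000", "class"] == "unilateral_left"
        assert rec.loc["P000", "ai"] == 1.0
        assert rec.loc["P001", "class"] == "low_intensity"

    def test_planted_unilateral_recovered_in_no_noise_limit(self):
        m, d, truth = no_noise_study()
        dm = lp.join_design(m, d)
        for gw in (9, 11, 13):
            rec = lp.call_unilateral(dm, gw)
            called_left = set(rec.loc[rec["class"] == "unilateral_left", "protein"])
            low = set(rec.loc[rec["class"] == "low_intensity", "protein"])
            planted = truth.proteins_with_label("unilateral_left", gw)
            assert called_left <= planted
            assert planted - called_left == planted & low


class TestClassesPartitionAndAntisymmetry:
    def test_classes_partition_detected_proteins(self, small_dm):
        for gw in (9, 11, 13):
            rec = lp.asymmetry_records(small_dm, gw)
            detected = (small_dm.column("L", gw) + small_dm.column("R", gw)) > 0
            assert len(rec) == int(detected.sum())
            assert rec["protein"].is_unique
            allowed = set(AEP_CLASSES) | set(UNILATERAL_CLASSES) | {"bilateral_ns", "low_intensity"}
            assert set(rec["class"]) <= allowed

    def test_swapping_sides_mirrors_everything(self, small_dm):
        swap_cols = {f"L{g:02d}": f"R{g:02d}" for g in (9, 11, 13)}
        swap_cols.update({v: k for k, v in swap_cols.items()})
        swapped_intens = small_dm.matrix.intensities.rename(columns=swap_cols)
        swapped = lp.join_design(
            lp.QuantMatrix(swapped_intens, small_dm.matrix.meta), small_dm.design
        )
        mirror = {
            "aep_left": "aep_right", "aep_right": "aep_left",
            "unilateral_left": "unilateral_right", "unilateral_right": "unilateral_left",
            "bilateral_ns": "bilateral_ns", "low_intensity": "low_intensity",
        }
        for gw in (9, 11, 13):
            a = lp.asymmetry_records(small_dm, gw).set_index("protein")
            b = lp.asymmetry_records(swapped, gw).set_index("protein")
            assert np.allclose(a["ai"], -b.loc[a.index, "ai"])
            assert (b.loc[a.index, "class"] == a["class"].map(mirror)).all()


class TestSharedAsymmetric:
    @staticmethod
    def toy_records():
        """Five proteins with hand-built per-week classes and folds."""
        def rec(gw, rows):
            return pd.DataFrame(
                [
                    {
                        "protein": pid, "gw": gw, "L": L, "R": R,
                        "mean_intensity": (L + R) / 2,
                        "ai": (L - R) / (L + R),
                        "log2_ratio": np.log2(L / R) if L > 0 and R > 0 else np.nan,
                        "sig_a_p": 0.01 if cls in AEP_CLASSES else 0.5,
                        "fold_change": max(L / R, R / L) if L > 0 and R > 0 else np.inf,
                        "class": cls,
                    }
                    for pid, L, R, cls in rows
                ]
            )

        return {
            9: rec(9, [("a", 300, 100, "aep_left"), ("b", 100, 330, "aep_right"),
                       ("c", 500, 100, "aep_left"), ("d", 160, 100, "bilateral_ns"),
                       ("e", 100, 100, "bilateral_ns")]),
            11: rec(11, [("a", 250, 100, "aep_left"), ("b", 100, 100, "bilateral_ns"),
                         ("c", 400, 100, "aep_left"), ("d", 100, 155, "bilateral_ns"),
                         ("e", 100, 100, "bilateral_ns")]),
            13: rec(13, [("a", 100, 104, "bilateral_ns"), ("b", 100, 290, "aep_right"),
                         ("c", 450, 100, "aep_left"), ("d", 170, 100, "bilateral_ns"),
                         ("e", 100, 100, "bilateral_ns")]),
        }

    def test_buckets_match_hand_enumeration(self):
        shared = lp.shared_asymmetric(self.toy_records(), min_gws=2, fc_threshold=1.5)
        assert set(shared.shared["protein"]) == {"a", "b", "c"}
        pair = shared.pairwise_counts.set_index(["gw_a", "gw_b"])["n_exactly_two"]
        assert pair[(9, 11)] == 1  # a: AEP at 9 and 11 only
        assert pair[(9, 13)] == 1  # b: AEP at 9 and 13 only
        assert pair[(11, 13)] == 0
        # c is asymmetric at all three weeks, so it sits in no exactly-two bucket
        assert shared.shared.set_index("protein").loc["c", "n_gws_aep"] == 3

    def test_relaxed_fold_rule_every_week(self):
        shared = lp.shared_asymmetric(self.toy_records(), fc_threshold=1.5)
        # c exceeds 1.5-fold at every week; d reaches it at every week (>= inclusive,
        # direction not required consistent); a fails at gw 13
        assert set(shared.consistent_fold["protein"]) == {"c", "d"}
        d_row = shared.consistent_fold.set_index("protein").loc["d"]
        assert d_row["direction_gw11"] == "right" and d_row["direction_gw9"] == "left"

    def test_min_gws_validation(self):
        with pytest.raises(lp.ParameterError):
            lp.shared_asymmetric(self.toy_records(), min_gws=4)
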