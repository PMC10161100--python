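"""Gamma-index engine: closed forms, brute-force oracle equivalence, masks."""

import numpy as np
import pytest

from gkdosim.gamma import (
    GammaCriteria,
    gamma_map,
    gamma_profile_1d,
    passing_rate,
    resample_map,
)


def brute_force_gamma(ref, ref_sp, ev, ev_sp, criteria, ref_origin=0.0, ev_origin=0.0):
    """Exhaustive γ oracle: linear resample of the evaluated map, then a
    full search over every resampled point for every reference point."""
    ref = np.asarray(ref, float)
    ev = np.asarray(ev, float)
    nd = ref.ndim
    fine, step = resample_map(ev, ev_sp, criteria.resample_step_mm)
    idx = np.stack(
        np.meshgrid(*[np.arange(s) for s in fine.shape], indexing="ij"), axis=-1
    ).reshape(-1, nd)
    pos_e = np.asarray(ev_origin) + idx * step
    out = np.full(ref.shape, np.nan)
    f = criteria.dd_percent / 100.0
    for i in np.ndindex(ref.shape):
        d_r = ref[i]
        if d_r < criteria.cutoff_gy:
            continue
        pos_r = np.asarray(ref_origin) + np.asarray(i) * np.asarray(ref_sp)
        d2 = np.sum((pos_e - pos_r) ** 2, axis=-1)
        g2 = d2 / criteria.dta_mm**2 + ((fine.ravel() - d_r) / (f * d_r)) ** 2
        out[i] = np.sqrt(g2.min())
    return out


class TestResampleMap:
    def test_native_pitch_preserves_samples(self):
        vals = np.array([[1.0, 2.0], [3.0, 4.0]])
        fine, _ = resample_map(vals, 1.0, 1.0)
        assert np.array_equal(fine, vals)

    def test_linear_ramp_exact(self):
        ramp = np.arange(11, dtype=float)
        fine, _ = resample_map(ramp, 1.0, 0.25)
        assert np.allclose(fine, np.arange(0, 10.001, 0.25), atol=1e-12)

    def test_smooth_map_close_to_dense_linear_oracle(self, rng):
        x = np.linspace(0, 2 * np.pi, 21)
        vals = 2.0 + np.sin(x)
        fine, _ = resample_map(vals, x[1] - x[0], (x[1] - x[0]) / 10)
        oracle = np.interp(
            np.linspace(0, 20, len(fine)), np.arange(21), vals
        )
        assert np.allclose(fine, oracle, rtol=5e-3)

    def test_step_exceeding_extent_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            resample_map(np.ones((4, 4)), 1.0, 100.0)


class TestGammaClosedForms:
    def test_self_comparison_zero_everywhere(self, rng):
        vals = rng.uniform(2.0, 8.0, (15, 15))
        crit = GammaCriteria(resample_step_mm=0.5)
        res = gamma_map((vals, 1.0), (vals, 1.0), crit)
        assert np.nanmax(res.gamma) <= 1e-9
        assert res.passing_rate == 100.0

    def test_uniform_six_percent_offset_gives_gamma_two(self):
        """No gradients: only the dose term acts; 6% against 3% local → γ = 2."""
        ref = np.full((12, 12), 5.0)
        ev = 1.06 * ref
        crit = GammaCriteria(dd_percent=3.0, resample_step_mm=0.5)
        res = gamma_map((ref, 1.0), (ev, 1.0), crit)
        assert np.allclose(res.gamma[res.mask], 2.0, atol=1e-9)
        assert res.passing_rate == 0.0

    def test_small_translation_bounded_by_dta(self):
        """0.5 mm shift of any gradient: γ ≤ 0.5 + resampling tolerance."""
        x = np.arange(40) * 0.5
        ref = 2.0 + np.sin(x / 3.0)
        ev = 2.0 + np.sin((x - 0.5) / 3.0)
        crit = GammaCriteria(dta_mm=1.0, resample_step_mm=0.1, cutoff_gy=0.5)
        res = gamma_map((ref, 0.5), (ev, 0.5), crit)
        # interior points only: at the profile ends the matching value falls
        # outside the evaluated extent and the bound does not apply
        assert np.nanmax(res.gamma[3:-3]) <= 0.5 + 0.1

    def test_1d_ramp_shifted_one_mm_hits_criteria_boundary(self):
        x = np.arange(60) * 0.5
        ref = 1.0 + 0.2 * x
        ev = 1.0 + 0.2 * (x - 1.0)
        crit = GammaCriteria(dta_mm=1.0, dd_percent=3.0, resample_step_mm=0.1,
                             cutoff_gy=0.5)
        g = gamma_profile_1d(ref, ev, crit, spacing=0.5)
        interior = g[10:-10]
        # a pure 1 mm spatial shift of a shallow ramp: γ ≈ min over the
        # trade-off curve, bounded by the pure-DTA solution γ = 1
        assert np.nanmax(interior) <= 1.0 + 0.05
        assert np.nanmax(interior) >= 0.5

    def test_identical_profiles_zero(self):
        p = np.linspace(2, 4, 30)
        g = gamma_profile_1d(p, p, GammaCriteria(resample_step_mm=0.5))
        assert np.nanmax(g) <= 1e-9


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_pairs(self, rng):
        """Windowed/early-exit search ≡ exhaustive oracle on 50 random pairs."""
        crit = GammaCriteria(
            dd_percent=3.0, dta_mm=1.0, cutoff_gy=1.0,
            resample_step_mm=0.5, search_radius_mm=np.inf,  # uncapped
        )
        for _ in range(50):
            ref = rng.uniform(0.5, 6.0, (20, 20))
            ev = ref * rng.uniform(0.9, 1.1, (20, 20))
            res = gamma_map((ref, 1.0), (ev, 1.0), crit)
            oracle = brute_force_gamma(ref, (1.0, 1.0), ev, (1.0, 1.0), crit)
            sel = res.mask
            assert np.allclose(res.gamma[sel], oracle[sel], atol=1e-9)

    def test_windowed_search_matches_oracle_when_radius_suffices(self, rng):
        """The capped search agrees with the oracle when the true minimum
        lies inside the window (the practical regime)."""
        ref = rng.uniform(2.0, 6.0, (15, 15))
        ev = ref * rng.uniform(0.98, 1.02, (15, 15))
        capped = GammaCriteria(resample_step_mm=0.5, search_radius_mm=4.0)
        uncapped = GammaCriteria(resample_step_mm=0.5, search_radius_mm=np.inf)
        a = gamma_map((ref, 1.0), (ev, 1.0), capped)
        b = gamma_map((ref, 1.0), (ev, 1.0), uncapped)
        assert np.allclose(a.gamma[a.mask], b.gamma[b.mask], atol=1e-9)

    def test_1d_oracle(self, rng):
        crit = GammaCriteria(resample_step_mm=0.25, cutoff_gy=0.5,
                             search_radius_mm=np.inf)
        ref = rng.uniform(1.0, 4.0, 30)
        ev = ref * rng.uniform(0.95, 1.05, 30)
        g = gamma_profile_1d(ref, ev, crit, spacing=1.0)
        oracle = brute_force_gamma(ref, (1.0,), ev, (1.0,), crit)
        sel = np.isfinite(g)
        assert np.allclose(g[sel], oracle[sel], atol=1e-9)


class TestProperties:
    def test_loosening_criteria_never_increases_gamma(self, rng):
        ref = rng.uniform(1.5, 6.0, (12, 12))
        ev = ref * rng.uniform(0.92, 1.08, (12, 12))
        tight = GammaCriteria(dd_percent=2.0, dta_mm=1.0, resample_step_mm=0.5)
        loose_dd = GammaCriteria(dd_percent=4.0, dta_mm=1.0, resample_step_mm=0.5)
        loose_dta = GammaCriteria(dd_percent=2.0, dta_mm=2.0, resample_step_mm=0.5)
        g0 = gamma_map((ref, 1.0), (ev, 1.0), tight)
        for crit in (loose_dd, loose_dta):
            g1 = gamma_map((ref, 1.0), (ev, 1.0), crit)
            assert np.all(g1.gamma[g1.mask] <= g0.gamma[g0.mask] + 1e-12)

    def test_asymmetry_regression_pair(self):
        """γ(A, B) ≠ γ(B, A) in general; this fixture pins one such pair."""
        ref = np.array([[2.0, 2.0, 2.0], [2.0, 4.0, 2.0], [2.0, 2.0, 2.0]])
        ev = np.full((3, 3), 2.0)
        crit = GammaCriteria(resample_step_mm=1.0, search_radius_mm=np.inf)
        ab = gamma_map((ref, 3.0), (ev, 3.0), crit)
        ba = gamma_map((ev, 3.0), (ref, 3.0), crit)
        # the 4 Gy spike has no dose match anywhere in the flat map: its γ is
        # the pure dose term |2−4|/(3% · 4) = 50/3.  In the reverse direction
        # the flat center point finds an exact dose match 3 mm away (γ = 3),
        # so the comparison is genuinely asymmetric.
        assert np.nanmax(ab.gamma) > np.nanmax(ba.gamma)
        assert np.nanmax(ab.gamma) == pytest.approx(50.0 / 3.0, rel=1e-6)
        assert np.nanmax(ba.gamma) == pytest.approx(3.0, rel=1e-6)

    def test_cutoff_monotone_on_low_dose_failures(self):
        """Raising the cut-off removes low-dose failures, never adds any."""
        x = np.arange(30) * 1.0
        ref = 0.5 + 0.2 * x
        ev = ref.copy()
        ev[ref < 2.0] *= 1.2  # 20% error only at low dose
        rates = []
        for cutoff in (1.0, 2.5):
            crit = GammaCriteria(cutoff_gy=cutoff, resample_step_mm=0.5)
            res = gamma_map((ref, 1.0), (ev, 1.0), crit)
            rates.append(res.passing_rate)
        assert rates[1] >= rates[0]

    def test_mismatched_dims_rejected(self):
        with pytest.raises(ValueError, match="mismatched frames"):
            gamma_map((np.ones(5), 1.0), (np.ones((5, 5)), 1.0))

    def test_all_below_cutoff_rejected(self):
        with pytest.raises(ValueError, match="empty evaluation set"):
            gamma_map((np.full((4, 4), 0.1), 1.0), (np.full((4, 4), 0.1), 1.0))


class TestPassingRate:
    def test_self_comparison_100_with_and_without_masks(self, rng):
        vals = rng.uniform(2.0, 8.0, (10, 10))
        res = gamma_map((vals, 1.0), (vals, 1.0),
                        GammaCriteria(resample_step_mm=0.5))
        air = np.zeros((10, 10), bool)
        air[:3] = True
        assert passing_rate(res, exclude_mask=air) == 100.0
        assert passing_rate(res) == 100.0

    def test_constructed_half_failures(self):
        """Exactly half the evaluated points fail → 50%."""
        ref = np.full((10, 10), 4.0)
        ev = ref.copy()
        ev[:5] *= 1.10  # 10% error with 3% local → γ > 3 for rows 0–4
        crit = GammaCriteria(resample_step_mm=0.5)
        res = gamma_map((ref, 10.0), (ev, 10.0), crit)  # 10 mm pitch: no DTA rescue
        assert res.passing_rate == pytest.approx(50.0)

    def test_excluding_failure_region_restores_100(self):
        ref = np.full((10, 10), 4.0)
        ev = ref.copy()
        ev[:5] *= 1.10
        crit = GammaCriteria(resample_step_mm=0.5)
        res = gamma_map((ref, 10.0), (ev, 10.0), crit)
        bad = np.zeros((10, 10), bool)
        bad[:5] = True
        assert passing_rate(res, exclude_mask=bad) == 100.0

    def test_empty_after_masking_rejected(self):
        vals = np.full((4, 4), 4.0)
        res = gamma_map((vals, 1.0), (vals, 1.0),
                        GammaCriteria(resample_step_mm=0.5))
        with pytest.raises(ValueError, match="empty"):
            passing_rate(res, exclude_mask=np.ones((4, 4), bool))
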