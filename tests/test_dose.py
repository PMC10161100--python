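"""Dose engines: path integrals, beam model, calibration closure, MC-lite."""

import numpy as np
import pytest

from gkdosim.dose import (
    aligned_grid,
    beam_dose,
    compute_plan_dose,
    mc_lite_dose,
    radiological_depth,
    reference_relative_dose,
    water_sphere_density,
)
from gkdosim.grids import UCP, VoxelGrid
from gkdosim.machine import Plan, Shot, reference_plan, sector_probabilities


def _uniform_rho(value=1.0, shape=(40, 40, 40), origin=(0, 0, 0), spacing=(5, 5, 5)):
    return VoxelGrid(np.full(shape, float(value)), origin, spacing)


class TestRadiologicalDepth:
    def test_uniform_water_chord(self):
        rho = _uniform_rho(1.0)
        # 10 cm chord inside the grid
        assert radiological_depth(rho, (10, 100, 100), (110, 100, 100)) == pytest.approx(
            10.0, rel=1e-12
        )

    def test_half_water_half_bone(self):
        rho = _uniform_rho(1.0, shape=(40, 8, 8), spacing=(5, 5, 5))
        rho.data[20:, :, :] = 1.72  # second half (x ≥ 97.5 mm) is bone
        d = radiological_depth(rho, (47.5, 10, 10), (147.5, 10, 10))
        # 5 cm water + 5 cm bone
        assert d == pytest.approx(5.0 + 5.0 * 1.72, rel=1e-9)

    def test_zero_length_segment(self):
        assert radiological_depth(_uniform_rho(), (7, 7, 7), (7, 7, 7)) == 0.0

    def test_segment_missing_grid(self):
        assert radiological_depth(_uniform_rho(), (-50, -50, -50), (-40, -50, -50)) == 0.0

    def test_matches_midpoint_quadrature_oracle(self, rng):
        """Siddon traversal vs 10⁴-step midpoint quadrature on random grids."""
        for _ in range(5):
            rho = VoxelGrid(
                rng.uniform(0.2, 2.0, (15, 12, 10)), (0, 0, 0), (2.0, 3.0, 2.5)
            )
            p0 = rng.uniform(-5, 30, 3)
            p1 = rng.uniform(-5, 30, 3)
            exact = radiological_depth(rho, p0, p1)
            # oracle: dense midpoint sampling with nearest-voxel lookup
            n = 10_000
            t = (np.arange(n) + 0.5) / n
            pos = p0 + t[:, None] * (p1 - p0)
            idx = np.round((pos - np.array(rho.origin)) / np.array(rho.spacing))
            ok = np.all((idx >= 0) & (idx < np.array(rho.shape)), axis=1)
            ii = idx[ok].astype(int)
            vals = rho.data[ii[:, 0], ii[:, 1], ii[:, 2]]
            oracle = vals.sum() / n * np.linalg.norm(p1 - p0) * 0.1
            assert exact == pytest.approx(oracle, rel=1e-3, abs=1e-4)


class TestBeamDose:
    def test_focus_value_in_water(self, machine, water_maps):
        """On-axis at the focus: OF·exp(−μ·d_rad), unit profile and inverse-square."""
        src = machine.sector_sources(0)[2]
        d_rad = radiological_depth(water_maps.rho, src.position, UCP)
        expected = machine.output_factors[16] * np.exp(-machine.mu * d_rad)
        got = beam_dose(UCP, src, 16, water_maps.rho, machine)
        # profile at the exact center of a 16 mm field is 1 to erfc precision
        assert got == pytest.approx(expected, rel=1e-6)

    def test_far_off_axis_is_negligible(self, machine, water_maps):
        src = machine.sector_sources(0)[2]
        on_axis = beam_dose(UCP, src, 4, water_maps.rho, machine)
        # a point 30 mm off the beam axis, same depth scale
        axis = (UCP - src.position) / np.linalg.norm(UCP - src.position)
        perp = np.cross(axis, [0.0, 0.0, 1.0])
        perp /= np.linalg.norm(perp)
        off = beam_dose(UCP + 30 * perp, src, 4, water_maps.rho, machine)
        assert off < 0.01 * on_axis

    def test_bone_attenuation_ratio(self, machine):
        """Replacing 3 cm of water by bone lowers primary by exp(−μ·3·0.72)."""
        shape = (40, 16, 16)
        water = VoxelGrid(np.ones(shape), (60.0, 84.0, 84.0), (2.0, 2.0, 2.0))
        boned = water.copy_with(water.data.copy())
        # 30 mm slab of bone perpendicular to x, upstream of the UCP
        x = boned.axis_centers(0)
        sel = (x >= 70.0) & (x < 100.0)
        boned.data[sel, :, :] = 1.72
        src_pos = np.array([-300.0, 100.0, 100.0])  # source on the -x axis

        class SrcStub:
            position = src_pos

        point = np.array([105.0, 100.0, 100.0])  # beyond the slab
        d_w = beam_dose(point, SrcStub, 16, water, machine, focus=point)
        d_b = beam_dose(point, SrcStub, 16, boned, machine, focus=point)
        expected = np.exp(-machine.mu * 3.0 * 0.72)
        assert d_b / d_w == pytest.approx(expected, rel=1e-3)


class TestPlanDose:
    def test_calibration_closure_at_ucp(self, machine, water_maps):
        """Reference configuration: UCP dose equals Ḋ_ref · BOT within 0.1%."""
        plan = reference_plan()
        dose = compute_plan_dose(
            plan, water_maps, machine, spacing=(2.5, 2.5, 2.5), n_samples=24
        )
        ucp = dose.grid.sample(UCP)
        assert ucp == pytest.approx(plan.reference_dose_rate * dose.bot, rel=1e-3)

    def test_prescription_normalisation(self, machine, water_maps):
        plan = reference_plan()  # 4 Gy at the 50% isodose
        dose = compute_plan_dose(
            plan, water_maps, machine, spacing=(2.5, 2.5, 2.5), n_samples=24
        )
        assert dose.data.max() == pytest.approx(8.0, rel=1e-9)
        assert dose.medium == "dose_to_medium"

    def test_rotation_invariance_about_z(self, machine, water_maps):
        """90° rotation of an off-center shot maps the dose field accordingly."""
        spacing = (2.5, 2.5, 2.5)
        grid = aligned_grid(UCP - 25.0, UCP + 25.0, spacing)
        d_ref = reference_relative_dose(
            machine, spacing=spacing, n_samples=24, half_extent=(25.0, 25.0, 25.0)
        )
        p1 = Plan(shots=[Shot(center=(108.0, 100.0, 100.0))])
        p2 = Plan(shots=[Shot(center=(100.0, 108.0, 100.0))])
        d1 = compute_plan_dose(p1, water_maps, machine, grid=grid,
                               n_samples=24, d_ref=d_ref)
        d2 = compute_plan_dose(p2, water_maps, machine, grid=grid,
                               n_samples=24, d_ref=d_ref)
        # compare at matched points: x-profile of plan 1 vs y-profile of plan 2
        t = np.linspace(-15, 15, 31)
        pts1 = np.column_stack([108 + t, np.full_like(t, 100), np.full_like(t, 100)])
        pts2 = np.column_stack([np.full_like(t, 100), 108 + t, np.full_like(t, 100)])
        v1 = d1.grid.sample(pts1)
        v2 = d2.grid.sample(pts2)
        assert np.allclose(v1, v2, rtol=5e-3)

    def test_air_cavity_raises_downstream_dose(self, machine):
        """Less attenuation behind an air gap: on-axis dose beyond the cavity
        is higher than in the mirrored water-only phantom by ≈ exp(μ·ρ_w·L)."""
        shape = (50, 20, 20)
        water = VoxelGrid(np.ones(shape), (50.0, 81.0, 81.0), (2.0, 2.0, 2.0))
        gapped = water.copy_with(water.data.copy())
        x = gapped.axis_centers(0)
        sel = (x >= 80.0) & (x < 95.0)  # ~15 mm air gap upstream
        gapped.data[sel, :, :] = 0.0012
        gap_cm = sel.sum() * gapped.spacing[0] * 0.1  # voxelised gap length
        src_pos = np.array([-300.0, 100.0, 100.0])

        class SrcStub:
            position = src_pos

        point = np.array([110.0, 100.0, 100.0])
        d_w = beam_dose(point, SrcStub, 16, water, machine, focus=point)
        d_a = beam_dose(point, SrcStub, 16, gapped, machine, focus=point)
        expected = np.exp(machine.mu * gap_cm * (1 - 0.0012))
        assert d_a / d_w == pytest.approx(expected, rel=1e-3)

    def test_monotone_attenuation_along_axis(self, machine, water_maps):
        """Primary dose falls with added radiological depth along one beam."""
        src = machine.sector_sources(3)[10]
        axis = (UCP - src.position) / np.linalg.norm(UCP - src.position)
        depths = np.linspace(-20, 20, 9)  # mm along the axis around the UCP
        vals = [
            beam_dose(UCP + t * axis, src, 16, water_maps.rho, machine)
            for t in depths
        ]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_empty_plan_rejected(self):
        with pytest.raises(ValueError):
            Plan(shots=[])


class TestMCLite:
    def test_sector_sampling_frequencies(self, rng):
        """Observed category fractions within 3 sd of the binomial."""
        shots = [Shot(sector_states=(16, 4) + ("blocked",) * 6)]
        plan = Plan(shots=shots)
        s = sector_probabilities(plan, phsp_counts={16: 100, 4: 300, 8: 1})
        n = 100_000
        draws = rng.choice(len(s.p), size=n, p=s.p)
        for k, p in enumerate(s.p):
            obs = float(np.mean(draws == k))
            sd = np.sqrt(p * (1 - p) / n)
            assert abs(obs - p) < 3 * sd

    def test_seed_reproducibility(self, machine, water_maps):
        kw = dict(n_histories=5_000, n_batches=2, seed=9, spacing=(4.0, 4.0, 4.0))
        a = mc_lite_dose(reference_plan(), water_maps, machine, **kw)
        b = mc_lite_dose(reference_plan(), water_maps, machine, **kw)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(a.uncertainty, b.uncertainty)

    def test_agrees_with_deterministic_at_ucp(self, machine, water_maps):
        """Both engines are anchored to Ḋ_ref·BOT at the UCP in the
        reference configuration; MC-lite must agree within 2 batch SE."""
        plan = reference_plan()
        mc = mc_lite_dose(
            plan, water_maps, machine,
            n_histories=60_000, n_batches=6, seed=4, spacing=(2.5, 2.5, 2.5),
        )
        det = compute_plan_dose(
            plan, water_maps, machine, spacing=(2.5, 2.5, 2.5), n_samples=24
        )
        # compare dose rates (Gy/min): divide out each engine's own BOT
        ucp_mc = mc.grid.sample(UCP) / mc.bot
        ucp_det = det.grid.sample(UCP) / det.bot
        idx = tuple(
            np.round((UCP - np.array(mc.grid.origin)) / np.array(mc.grid.spacing)).astype(int)
        )
        se = mc.uncertainty[idx] * ucp_mc
        # two independent MC estimates enter (plan run and reference run)
        assert abs(ucp_mc - ucp_det) < 2.0 * np.sqrt(2.0) * se

    def test_uncertainty_scales_as_inverse_sqrt_histories(self, machine, water_maps):
        """log–log slope of batch SE vs history count ≈ −0.5 ± 0.1."""
        sizes = [4_000, 16_000, 64_000]
        uncs = []
        for n in sizes:
            mc = mc_lite_dose(
                reference_plan(), water_maps, machine,
                n_histories=n, n_batches=6, seed=12, spacing=(4.0, 4.0, 4.0),
                d_ref=1.0,
            )
            # aggregate over the high-dose core so the estimate is not
            # dominated by single-voxel noise in the SE itself
            core = mc.data > 0.2 * mc.data.max()
            uncs.append(float(np.median(mc.uncertainty[core])))
        slope = np.polyfit(np.log(sizes), np.log(uncs), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)

    def test_invalid_batching_rejected(self, machine, water_maps):
        with pytest.raises(ValueError):
            mc_lite_dose(reference_plan(), water_maps, machine,
                         n_histories=10, n_batches=1)
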