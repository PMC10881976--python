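import math

import numpy as np
import pandas as pd
import pytest

import bicarbenv as bv


@pytest.fixture(scope="module")
def core_grid(request):
    model = bv.add_3hp_pathway(bv.build_core_model())
    spec = bv.EnvelopeSpec(ratios=[0.0, 0.25, 0.5, math.inf], n_growth_points=9)
    return bv.compute_envelope(model, spec)


class TestToyOracle:
    def test_envelope_matches_closed_form(self, toy_branch):
        """The branch model's envelope is the exact line from
        (max biomass yield, 0) to (0, max product yield)."""
        spec = bv.EnvelopeSpec(ratios=[0.0], mode="none", n_growth_points=11)
        grid = bv.compute_envelope(toy_branch, spec)
        exact = bv.analytic_envelope_toy(uptake=1.0)
        sweep = grid.sweeps[0]
        assert sweep.mu_max == pytest.approx(exact.mu_max, abs=1e-12)
        for pt in sweep.points:
            assert pt.product_max == pytest.approx(
                exact.product_max_flux(pt.growth_rate), abs=1e-9)
            assert pt.yield_product == pytest.approx(
                exact.yield_product(pt.growth_fraction), abs=1e-9)

    def test_grid_refinement_consistent(self, toy_branch):
        """A finer growth grid agrees exactly at shared grid points."""
        coarse = bv.compute_envelope(
            toy_branch, bv.EnvelopeSpec(ratios=[0.0], mode="none", n_growth_points=21))
        fine = bv.compute_envelope(
            toy_branch, bv.EnvelopeSpec(ratios=[0.0], mode="none", n_growth_points=41))
        cpts, fpts = coarse.sweeps[0].points, fine.sweeps[0].points
        for i, cp in enumerate(cpts):
            fp = fpts[2 * i]
            assert fp.product_max == pytest.approx(cp.product_max, abs=1e-9)


class TestCoreEnvelope:
    def test_ratio_zero_kills_production(self, core_grid):
        sweep = next(s for s in core_grid.sweeps if s.ratio == 0.0)
        for pt in sweep.points:
            if pt.feasible:
                assert pt.product_max == pytest.approx(0.0, abs=1e-8)

    def test_upper_envelope_concave(self, core_grid):
        for sweep in core_grid.sweeps:
            ys = [p.product_max for p in sweep.points if p.feasible]
            if len(ys) >= 3:
                assert np.all(np.diff(ys, 2) <= 1e-6)

    def test_product_monotone_in_ratio(self, core_grid):
        finite = sorted((s for s in core_grid.sweeps if s.ratio > 0),
                        key=lambda s: s.ratio)
        for lo_sw, hi_sw in zip(finite, finite[1:]):
            for lo_pt, hi_pt in zip(lo_sw.points, hi_sw.points):
                if lo_pt.feasible and hi_pt.feasible:
                    assert hi_pt.product_max >= lo_pt.product_max - 1e-7

    def test_tidy_dataframe_schema(self, core_grid):
        df = core_grid.to_dataframe()
        assert {"ratio", "mode", "mu", "growth_fraction", "product_min",
                "product_max", "yield_product", "yield_biomass"} <= set(df.columns)
        feasible = df[df.feasible]
        assert (feasible.product_min <= feasible.product_max + 1e-9).all()
        assert (feasible.yield_product >= -1e-9).all()


class TestTheoreticalYield:
    def test_mass_molar_consistency(self, core_with_pathway):
        y = bv.max_theoretical_yield(core_with_pathway)
        assert y.g_per_g == pytest.approx(
            bv.molar_to_mass_yield(y.mol_per_mol, 90.08, 180.16), rel=1e-3)

    def test_closed_bicarbonate_zero_yield(self, core_with_pathway):
        m = bv.cap_bicarbonate_formation(core_with_pathway, 0.0, 1.0)
        assert bv.max_theoretical_yield(m).mol_per_mol == pytest.approx(0.0, abs=1e-9)

    def test_demand_ratio_equals_molar_yield(self, core_with_pathway):
        """1:1 carboxylation makes the bicarbonate:glucose flux ratio at the
        optimum equal the molar product yield."""
        y = bv.max_theoretical_yield(core_with_pathway)
        demand = bv.bicarbonate_ratio_at_optimum(core_with_pathway)
        assert demand.ratio == pytest.approx(y.mol_per_mol, abs=1e-6)
        assert demand.fva_min == pytest.approx(demand.fva_max, abs=1e-6)

    def test_binding_cap_returns_cap(self, core_with_pathway):
        capped = bv.cap_bicarbonate_formation(core_with_pathway, 0.4, 1.0)
        demand = bv.bicarbonate_ratio_at_optimum(capped)
        assert demand.ratio == pytest.approx(0.4, abs=1e-6)


class TestOverlay:
    def _grid(self, toy_branch):
        return bv.compute_envelope(
            toy_branch, bv.EnvelopeSpec(ratios=[0.0], mode="none", n_growth_points=11))

    def test_published_endpoint_yield(self):
        assert bv.mass_yield(11.25, 20.0) == 0.5625

    def test_inside_point_classified_inside(self, toy_branch):
        grid = self._grid(toy_branch)
        table = pd.DataFrame([{"strain": "inside", "titre_g_l": 4.0,
                               "glucose_g_l": 20.0, "dcw_g_l": 4.0}])
        report = bv.overlay_strains(grid, table)
        assert report.placements[0].classification[(0.0, "none")] == "inside"
        assert report.placements[0].yield_product == pytest.approx(0.2)

    def test_outside_point_warns(self, toy_branch):
        grid = self._grid(toy_branch)
        table = pd.DataFrame([{"strain": "super", "titre_g_l": 18.0,
                               "glucose_g_l": 20.0, "dcw_g_l": 6.0}])
        with pytest.warns(UserWarning, match="outside"):
            report = bv.overlay_strains(grid, table)
        assert report.placements[0].classification[(0.0, "none")] == "outside"

    def test_on_boundary_classified_on(self, toy_branch):
        grid = self._grid(toy_branch)
        table = pd.DataFrame([{"strain": "edge", "titre_g_l": 10.0,
                               "glucose_g_l": 20.0, "dcw_g_l": 10.0}])
        report = bv.overlay_strains(grid, table)
        assert report.placements[0].classification[(0.0, "none")] == "on"

    def test_od600_imputed(self, toy_branch):
        grid = self._grid(toy_branch)
        table = pd.DataFrame([{"strain": "od", "titre_g_l": 2.0,
                               "glucose_g_l": 20.0, "od600": 10.0}])
        report = bv.overlay_strains(grid, table)
        assert report.placements[0].yield_biomass == pytest.approx(0.35)

    def test_nonpositive_glucose_rejected(self, toy_branch):
        grid = self._grid(toy_branch)
        table = pd.DataFrame([{"strain": "bad", "titre_g_l": 1.0,
                               "glucose_g_l": 0.0, "dcw_g_l": 1.0}])
        with pytest.raises(ValueError, match="bad"):
            bv.overlay_strains(grid, table)

    def test_noiseless_synthetic_recovery(self, toy_branch):
        grid = self._grid(toy_branch)
        truth = [(0.3, 0.1), (0.6, 0.2)]
        table = bv.generate_strain_table(truth, glucose=20.0, noise_cv=0.0, seed=7)
        report = bv.overlay_strains(grid, table)
        for placement, (yp, yb) in zip(report.placements, truth):
            assert placement.yield_product == pytest.approx(yp, abs=1e-12)
            assert placement.yield_biomass == pytest.approx(yb, abs=1e-12)

    def test_plot_writes_file(self, toy_branch, tmp_path):
        grid = self._grid(toy_branch)
        out = tmp_path / "env.png"
        bv.plot_envelope(grid, path=out)
        assert out.stat().st_size > 0
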