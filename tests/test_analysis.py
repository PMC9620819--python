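"""FBA, FVA, yield optimization and flux-space projections."""

import numpy as np
import pytest

from metadesign import (InfeasibleError, ModelError, ObjSense, RatioExpression,
                        UnboundedError, fba, flux_space_projection, fva,
                        plot_projection, yield_opt)
from metadesign.model import fixture, parse_linear_constraints


class TestFba:
    def test_chain_bottleneck(self, chain3):
        sol = fba(chain3, {"R3": 1})
        assert sol.objective_value == pytest.approx(5)
        assert sol["R2"] == pytest.approx(5)

    def test_coupler_max_growth(self, coupler6):
        assert fba(coupler6, {"R_bio": 1}).objective_value == pytest.approx(10)

    def test_infeasible_extra(self, chain3):
        with pytest.raises(InfeasibleError):
            fba(chain3, {"R3": 1}, extra="R3 >= 20")

    def test_unknown_objective(self, chain3):
        with pytest.raises(ModelError):
            fba(chain3, {"Rnope": 1})

    def test_steady_state_and_bounds_hold(self, coupler6):
        sol = fba(coupler6, {"R_pex": 1})
        S = coupler6.stoichiometric_matrix()
        v = np.array([sol[r.id] for r in coupler6.reactions])
        assert np.abs(S @ v).max() < 1e-6
        lb, ub = coupler6.bounds()
        assert (v >= lb - 1e-6).all() and (v <= ub + 1e-6).all()

    def test_optimum_dominates_random_feasible_points(self, coupler6):
        """LP optimum >= objective at feasible points found by random objectives."""
        rng = np.random.default_rng(0)
        opt = fba(coupler6, {"R_bio": 1}).objective_value
        for _ in range(25):
            w = {r.id: float(c) for r, c in
                 zip(coupler6.reactions, rng.normal(size=5))}
            pt = fba(coupler6, w)
            assert pt.values["R_bio"] <= opt + 1e-6

    def test_matches_cobrapy(self, coupler6):
        """Independent cross-check against the COBRApy solver stack."""
        from metadesign.io import to_cobra
        cm = to_cobra(coupler6)
        cm.objective = cm.reactions.get_by_id("R_bio").flux_expression
        assert fba(coupler6, {"R_bio": 1}).objective_value == \
            pytest.approx(cm.optimize().objective_value)


class TestFva:
    def test_chain_coupling(self, chain3):
        res = fva(chain3, ["R2"], extra="R3 >= 1")
        assert res["R2"] == (pytest.approx(1), pytest.approx(5))

    def test_bottleneck_propagation(self, chain3):
        assert fva(chain3, ["R1"])["R1"] == (pytest.approx(0), pytest.approx(5))

    def test_coupler_essentials_signature(self, coupler6):
        res = fva(coupler6, extra="R_bio >= 1")
        assert res["R_up"][0] == pytest.approx(1)
        assert res["R_1"][0] == pytest.approx(0)
        assert res["R_3"][0] == pytest.approx(0)

    def test_infeasible_before_any_solve(self, chain3):
        with pytest.raises(InfeasibleError):
            fva(chain3, extra="R3 >= 20")

    def test_intervals_contain_fba_optimum(self, coupler6):
        sol = fba(coupler6, {"R_pex": 1})
        res = fva(coupler6)
        for rid, (lo, hi) in res.items():
            assert lo - 1e-6 <= sol[rid] <= hi + 1e-6

    def test_monotone_under_extra_constraints(self, coupler6):
        wide = fva(coupler6)
        narrow = fva(coupler6, extra="R_bio >= 1, R_pex >= 1")
        for rid in wide:
            assert narrow[rid][0] >= wide[rid][0] - 1e-6
            assert narrow[rid][1] <= wide[rid][1] + 1e-6

    def test_matches_cobrapy(self, coupler6):
        from cobra.flux_analysis import flux_variability_analysis
        from metadesign.io import to_cobra
        cm = to_cobra(coupler6)
        cm.objective = cm.reactions.get_by_id("R_bio").flux_expression
        ref = flux_variability_analysis(cm, fraction_of_optimum=0)
        ours = fva(coupler6)
        for rid in ours:
            assert ours[rid][0] == pytest.approx(ref.loc[rid, "minimum"], abs=1e-6)
            assert ours[rid][1] == pytest.approx(ref.loc[rid, "maximum"], abs=1e-6)


class TestYieldOpt:
    def test_product_yield(self, coupler6):
        val, flux = yield_opt(coupler6,
                              RatioExpression({"R_pex": 1}, {"R_up": 1}),
                              extra="R_bio >= 1")
        assert val == pytest.approx(0.5)
        assert flux["R_pex"] / flux["R_up"] == pytest.approx(0.5)
        assert flux["R_1"] == pytest.approx(0, abs=1e-6)

    def test_conservation_identity(self, chain3):
        val, _ = yield_opt(chain3, RatioExpression({"R3": 1}, {"R1": 1}),
                           extra="R1 >= 1")
        assert val == pytest.approx(1)

    def test_degenerate_denominator_rejected(self, chain3):
        with pytest.raises(ModelError, match="zero"):
            yield_opt(chain3, RatioExpression({"R3": 1}, {"R1": 1}),
                      extra="R1 = 0")

    def test_missing_denominator_rejected(self, chain3):
        with pytest.raises(ModelError):
            yield_opt(chain3, RatioExpression({"R3": 1}))

    def test_matches_dense_grid_oracle(self, coupler6):
        """Charnes-Cooper optimum equals a dense grid search over (R_1, R_3)."""
        best = 0.0
        for x in np.linspace(0, 10, 101):
            for y in np.linspace(0, 10, 101):
                if x + 2 * y <= 10 and x + y >= 1 and x + 2 * y > 0:
                    best = max(best, y / (x + 2 * y))
        val, _ = yield_opt(coupler6, RatioExpression({"R_pex": 1}, {"R_up": 1}),
                           extra="R_bio >= 1")
        assert val == pytest.approx(best, abs=1e-6)


class TestProjection:
    def test_production_envelope_triangle(self, coupler6):
        reg = flux_space_projection(
            coupler6, [RatioExpression.rate("R_bio"), RatioExpression.rate("R_pex")])
        assert sorted(reg.boundary) == [(0, 0), (5, 5), (10, 0)]

    def test_conservation_segment(self, chain3):
        reg = flux_space_projection(
            chain3, [RatioExpression.rate("R1"), RatioExpression.rate("R3")])
        assert sorted(reg.boundary) == [(0, 0), (5, 5)]

    def test_identical_axes_diagonal(self, coupler6):
        reg = flux_space_projection(
            coupler6, [RatioExpression.rate("R_bio"), RatioExpression.rate("R_bio")])
        assert sorted(reg.boundary) == [(0, 0), (10, 10)]

    def test_infeasible_region_flagged(self, chain3):
        reg = flux_space_projection(
            chain3, [RatioExpression.rate("R1"), RatioExpression.rate("R3")],
            extra="R3 >= 20")
        assert reg.feasible is False and reg.boundary == []

    def test_grid_refinement_invariance(self, coupler6):
        axes = [RatioExpression.rate("R_bio"), RatioExpression.rate("R_pex")]
        a = flux_space_projection(coupler6, axes, n_grid=11, method="grid")
        b = flux_space_projection(coupler6, axes, n_grid=21, method="grid")
        for v in a.boundary:
            assert min(abs(v[0] - w[0]) + abs(v[1] - w[1])
                       for w in b.boundary) < 1e-6

    def test_yield_space_axes(self, coupler6):
        axes = [RatioExpression({"R_bio": 1}, {"R_up": 1}),
                RatioExpression({"R_pex": 1}, {"R_up": 1})]
        reg = flux_space_projection(coupler6, axes, extra="R_up >= 1")
        # biomass yield in [0.5, 1]; product yield up to 0.5 at biomass yield 0.5
        xs = [v[0] for v in reg.boundary]
        ys = [v[1] for v in reg.boundary]
        assert max(xs) == pytest.approx(1.0)
        assert max(ys) == pytest.approx(0.5)

    def test_mixed_denominators_rejected(self, coupler6):
        axes = [RatioExpression({"R_bio": 1}, {"R_up": 1}),
                RatioExpression({"R_pex": 1}, {"R_bio": 1})]
        with pytest.raises(ModelError, match="denominator"):
            flux_space_projection(coupler6, axes)

    def test_3d_projection_and_exports(self, coupler6, tmp_path):
        axes = [RatioExpression.rate("R_bio"), RatioExpression.rate("R_pex"),
                RatioExpression.rate("R_up")]
        reg = flux_space_projection(coupler6, axes, n_grid=5)
        assert reg.boundary, "3D projection should produce facets"
        reg.to_tsv(str(tmp_path / "facets.tsv"))
        reg2 = flux_space_projection(
            coupler6, [RatioExpression.rate("R_bio"), RatioExpression.rate("R_pex")])
        reg2.to_tsv(str(tmp_path / "poly.tsv"))
        plot_projection(reg2, str(tmp_path / "poly.svg"))
        assert (tmp_path / "poly.svg").exists()
        assert (tmp_path / "poly.tsv").read_text().startswith("axis1")
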