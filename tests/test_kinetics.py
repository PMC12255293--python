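import math

import numpy as np
import pytest

from mcsdr import reference, thermo
from mcsdr.kinetics import (
    KineticParams,
    apparent_second_order_rate,
    derive_rates,
    effective_rate_from_toehold,
    fit_time_grid,
    second_order_solution,
    simulate_mcsdr,
    simulate_multiclosure,
    simulate_tsdr,
    _chain_rhs,
    _integrate,
)

CONC = reference.DEFAULT_CONC


class TestOneStepModel:
    def test_matches_equal_concentration_closed_form(self, t_grid):
        """c0^2 k t / (1 + c0 k t) to 1e-6 relative at every grid time."""
        tr = simulate_tsdr(1e4, CONC, CONC, t_grid)
        x = CONC * 1e4 * t_grid
        expected = CONC * x / (1 + x)
        assert np.max(np.abs(tr.values - expected) / expected) < 1e-6

    def test_yield_at_1000s_is_2p5_over_3p5(self):
        tr = simulate_tsdr(1e4, CONC, CONC, [1000.0])
        assert tr.endpoint / CONC == pytest.approx(2.5 / 3.5, rel=1e-6)

    def test_unequal_concentrations_match_closed_form(self, t_grid):
        tr = simulate_tsdr(5e4, 2 * CONC, CONC / 2, t_grid)
        expected = second_order_solution(5e4, 2 * CONC, CONC / 2, t_grid)
        assert np.max(np.abs(tr.values - expected)) < 1e-6 * CONC

    @pytest.mark.parametrize("k1,A0", [(0.0, CONC), (1e4, 0.0)])
    def test_no_reaction_without_rate_or_reactant(self, k1, A0, t_grid):
        assert np.all(simulate_tsdr(k1, A0, CONC, t_grid).values == 0)

    def test_rejects_negative_inputs(self, t_grid):
        with pytest.raises(ValueError):
            simulate_tsdr(-1.0, CONC, CONC, t_grid)


class TestTwoStepModel:
    def test_mass_conservation_is_exact(self, system, kparams, t_grid):
        """A + I + I* + C stays at A0 (and B likewise) to <= 1e-9 relative."""
        for variant in ("PM", "MM"):
            tr = simulate_mcsdr(system, variant, kparams, CONC, CONC, t_grid)
            sp = tr.species
            total = sp["A"] + sum(v for k, v in sp.items() if k.startswith("I")) + sp["C"]
            assert np.max(np.abs(total - CONC)) <= 1e-9 * CONC
            assert sp["A"].min() >= -1e-12 * CONC and sp["B"].min() >= -1e-12 * CONC

    def test_docking_step_obeys_detailed_balance(self, system):
        """With alignment and breathing off, [I]/([A][B]) equilibrates to
        exp(-dG_toehold/RT)/C0."""
        params = KineticParams(k_align=0.0, nu_breathe=0.0)
        rates = derive_rates(system, "PM", params)
        tr = simulate_mcsdr(system, "PM", params, CONC, CONC, np.linspace(10.0, 2000.0, 5))
        sp = tr.species
        ratio = sp["I0"][-1] / (sp["A"][-1] * sp["B"][-1])
        expected = math.exp(-rates.dG_toehold / (thermo.GAS_CONSTANT_KCAL * params.temperature))
        assert ratio == pytest.approx(expected, rel=1e-5)

    def test_blocked_breathing_blocks_the_mismatch_path(self, system, t_grid):
        tr = simulate_mcsdr(system, "MM", KineticParams(nu_breathe=0.0), CONC, CONC, t_grid)
        assert np.all(tr.values == 0)

    def test_matched_trace_dominates_mismatched_pointwise(self, system, kparams, t_grid):
        pm = simulate_mcsdr(system, "PM", kparams, CONC, CONC, t_grid)
        mm = simulate_mcsdr(system, "MM", kparams, CONC, CONC, t_grid)
        assert np.all(pm.values >= mm.values)
        assert pm.endpoint > 10 * mm.endpoint

    def test_breathed_state_dominant_limit_recovers_open_pathway(self, system, t_grid):
        """When opening is strongly favorable and fast, the mismatch chain
        collapses onto the same two-state pathway with the shortened
        toehold."""
        params = KineticParams(nu_breathe=1e6, dG_open=-6.0)
        rates = derive_rates(system, "MM", params)
        mm = simulate_mcsdr(system, "MM", params, CONC, CONC, t_grid)
        scale = CONC
        rhs, n = _chain_rhs(rates, 0, 1.0, 1.0, scale)
        open_path = _integrate(rhs, n, t_grid)[-1] * scale
        assert np.max(np.abs(mm.values - open_path)) < 2e-3 * CONC


class TestEffectiveRate:
    def test_saturates_at_docking_rate_for_strong_toeholds(self, kparams):
        assert effective_rate_from_toehold(-1e3, kparams) == pytest.approx(kparams.k_dock, rel=1e-9)
        assert effective_rate_from_toehold(float("-inf"), kparams) == kparams.k_dock

    def test_zero_energy_plug_in(self, kparams):
        expected = kparams.k_dock * kparams.k_align / (kparams.k_align + kparams.k_dock * 1.0)
        assert effective_rate_from_toehold(0.0, kparams) == pytest.approx(expected)

    def test_monotone_non_increasing_in_toehold_energy(self, kparams):
        grid = np.linspace(-15.0, 5.0, 41)
        vals = [effective_rate_from_toehold(g, kparams) for g in grid]
        assert all(b <= a * (1 + 1e-12) for a, b in zip(vals, vals[1:]))


class TestMultiClosure:
    def test_single_closure_nests_the_two_step_model(self, system, kparams, t_grid):
        a = simulate_mcsdr(system, "MM", kparams, CONC, CONC, t_grid)
        b = simulate_multiclosure(system, kparams, CONC, CONC, t_grid, "MM")
        assert np.allclose(a.values, b.values, rtol=1e-10, atol=1e-20)

    def test_mismatch_yield_non_increasing_in_closures(self, kparams, t_grid):
        ends = []
        for n in range(1, 6):
            sysn = reference.reference_system(n_close=n)
            ends.append(simulate_multiclosure(sysn, kparams, CONC, CONC, t_grid, "MM").endpoint)
        assert all(b <= a for a, b in zip(ends, ends[1:]))

    def test_matched_yield_insensitive_to_closures(self, kparams, t_grid):
        """The helper mismatches the matched target, so its pathway (and
        yield) does not depend on how many bases the closure spans."""
        ends = [
            simulate_multiclosure(reference.reference_system(toehold_len=11, n_close=n), kparams, CONC, CONC, t_grid, "PM").endpoint
            for n in range(1, 6)
        ]
        assert max(ends) <= 1.1 * min(ends)


class TestApparentRate:
    def test_round_trip_recovery(self, t_grid):
        tr = simulate_tsdr(5e4, CONC, CONC, t_grid)
        k = apparent_second_order_rate(tr, CONC, CONC)
        assert abs(k - 5e4) / 5e4 < 1e-3

    def test_flat_zero_trace_is_degenerate(self, t_grid):
        tr = simulate_tsdr(0.0, CONC, CONC, t_grid)
        k, info = apparent_second_order_rate(tr, CONC, CONC, full=True)
        assert k == 0.0 and info["degenerate"]

    def test_fast_alignment_limit_matches_toehold_prediction(self, system):
        """With alignment much faster than undocking the two-step model is an
        effective one-step reaction at the dock-commit rate."""
        params = KineticParams(k_align=500.0)
        rates = derive_rates(system, "PM", params)
        pred = effective_rate_from_toehold(rates.dG_toehold, params, k_commit=500.0)
        t = np.geomspace(0.01, 40.0, 60)
        tr = simulate_mcsdr(system, "PM", params, CONC, CONC, t)
        k = apparent_second_order_rate(tr, CONC, CONC)
        assert abs(k - pred) / pred < 0.05


class TestSweepGrid:
    def test_grid_shape_and_columns(self, grid):
        assert len(grid) == 30
        assert set(grid.columns) >= {"toehold_len", "n_close", "yield_pm", "yield_mm", "rate_pm", "rate_mm", "df", "ddf"}
        assert grid["yield_pm"].between(0, 1 + 1e-9).all()
        assert (grid["rate_pm"] >= 0).all()

    def test_df_non_decreasing_in_closures(self, grid):
        for _, sub in grid.groupby("toehold_len"):
            vals = sub.sort_values("n_close")["df"].dropna().to_list()
            assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_rate_ratio_spans_three_orders_of_magnitude(self, grid):
        ok = grid[grid["rate_mm"] > 0]
        assert (ok["rate_pm"] / ok["rate_mm"]).max() >= 1e3

    def test_ddf_has_interior_optimum_where_resolvable(self, grid):
        """DDF peaks at an intermediate toehold length; rows where the
        mismatch yield falls below the metric floor (flagged NaN) cannot
        exhibit the full shape and are excluded."""
        full_rows = 0
        argmaxes = {}
        for nc, sub in grid.groupby("n_close"):
            sub = sub.sort_values("toehold_len")
            if sub["ddf"].notna().all():
                full_rows += 1
                am = sub.loc[sub["ddf"].idxmax(), "toehold_len"]
                assert sub["toehold_len"].iloc[0] < am < sub["toehold_len"].iloc[-1]
            defined = sub.dropna(subset=["ddf"])
            if len(defined):
                argmaxes[nc] = defined.loc[defined["ddf"].idxmax(), "toehold_len"]
        assert full_rows >= 1
        # different closure counts prefer different toehold lengths
        assert len(set(argmaxes.values())) > 1
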