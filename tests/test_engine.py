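import numpy as np
import pytest

import hepatocal as hc
from hepatocal.engine import basal_catecholamine_profile, run_comparison, run_scenario
from hepatocal.params import (
    CalciumParams, InnervationPattern, MetabolismParams, ScenarioConfig,
    TransportParams, preset,
)


def short(name="human", gij=5.0, t_end=1200.0, **kw):
    cfg = preset(name, gij)
    cfg.t_end = t_end
    for k, v in kw.items():
        setattr(cfg, k, v)
    return cfg


class TestDeterminism:
    def test_identical_configs_give_bit_identical_trajectories(self):
        r1 = run_scenario(short(t_end=700.0))
        r2 = run_scenario(short(t_end=700.0))
        assert np.array_equal(r1.y, r2.y)
        assert r1.provenance["config_hash"] == r2.provenance["config_hash"]


class TestExerciseEvent:
    def test_uptake_step_lands_exactly_at_exercise_start(self, short_human):
        res = short_human
        t, gb = res.t, res.body("GB")
        assert 500.0 in t
        i = int(np.searchsorted(t, 500.0))
        # flat control before the step, immediate decline after it
        assert abs(gb[i] - gb[i - 2]) < 0.05
        assert gb[i + 2] - gb[i] < -0.05

    def test_no_exercise_control_is_stationary(self, bank):
        res = bank("no_exercise", 5.0)
        gb = res.body("GB")
        assert abs(gb[-1] - gb[0]) < 0.02 * gb[0]
        assert float(res.cns_activation.max()) < 1e-6
        # catecholamines hold their basal steady state
        epn0, nepn0, _, _ = basal_catecholamine_profile(res.config)
        assert res.body("Epn_B")[-1] == pytest.approx(epn0, rel=0.02)
        assert res.body("NEpn_B")[-1] == pytest.approx(nepn0, rel=0.02)


class TestInvariants:
    def test_state_bounds_hold_on_the_output_grid(self, short_human):
        res = short_human
        tol = 1e-6
        for name in ("r", "g"):
            block = res.cell(name)
            assert block.min() >= -tol and block.max() <= 1 + tol
        for name in ("IP3", "CaI", "Glyc", "Gc"):
            assert res.cell(name).min() >= -tol
        for sp in ("glucose", "insulin", "glucagon", "epinephrine",
                   "norepinephrine"):
            assert res.blood(sp).min() >= -tol
        assert np.all(np.diff(res.t) > 0)

    def test_glycogen_is_monotonically_consumed(self, short_human):
        glyc = short_human.cell("Glyc")
        assert np.all(np.diff(glyc, axis=1) <= 1e-9)

    def test_glucose_mass_balance_closes(self, short_human):
        # d/dt [Σ Gc + Σ G_blood + s·GB] = Σ glycogenolysis − s·uptake
        res = short_human
        cfg = res.config
        s = cfg.transport.s
        t = res.t
        store = (res.cell("Gc").sum(axis=0) + res.blood("glucose").sum(axis=0)
                 + s * res.body("GB"))
        flux = res.glycogenolysis_flux.sum(axis=0)
        mult = cfg.systemic.exercise_multiplier
        in_ex = (t >= cfg.exercise_start) & (t < cfg.exercise_start + cfg.exercise_duration)
        u = res.u_G_basal * np.where(in_ex, mult, 1.0)
        lhs = store[-1] - store[0]
        rhs = np.trapezoid(flux - s * u, t)
        assert lhs == pytest.approx(rhs, rel=2e-3)

    def test_cumulative_export_equals_glycogen_consumed(self, short_human):
        res = short_human
        exported = np.trapezoid(res.glucose_export.sum(axis=0), res.t)
        consumed = -1e3 * (res.cell("Glyc").sum(axis=0)[-1]
                           - res.cell("Glyc").sum(axis=0)[0])
        stored = res.cell("Gc").sum(axis=0)[-1] - res.cell("Gc").sum(axis=0)[0]
        assert exported + stored == pytest.approx(consumed, rel=2e-3)


class TestCouplingAndConvergence:
    def test_disabling_ca_potentiation_removes_gap_junction_dependence(self):
        totals = []
        for gij in (0.0, 5.0):
            cfg = short(gij=gij)
            cfg.metabolism.v_CaI_max = 0.0
            totals.append(hc.glucose_outputs(run_scenario(cfg))[0])
        assert totals[0] == pytest.approx(totals[1], rel=1e-4)

    def test_halving_tolerances_changes_totals_below_a_tenth_percent(self):
        base = hc.glucose_outputs(run_scenario(short()))[0]
        tight = short()
        tight.rtol, tight.atol = 5e-7, 5e-10
        refined = hc.glucose_outputs(run_scenario(tight))[0]
        assert abs(refined - base) / base < 1e-3


class TestTwoCellSymmetry:
    def test_identical_uncoupled_cells_trace_identically(self):
        N = 2
        cfg = ScenarioConfig(
            innervation=InnervationPattern(np.ones(N, dtype=bool), 2.0),
            G_ij=0.0,
            transport=TransportParams(N=N),
            calcium=CalciumParams(k_r_i=np.full(N, 0.75), k_IP3_i=np.full(N, 0.55)),
            metabolism=MetabolismParams(zonation_weight_i=np.full(N, 0.75)),
            exercise_start=100.0, exercise_duration=500.0, t_end=600.0,
        )
        # freeze the catecholamine field (no secretion, no clearance) so both
        # compartments carry an identical stimulus and the two cells are
        # exact mirror images
        cfg.systemic.k_clear_cat = 1e-12
        cfg.systemic.v_Epn = 0.0
        cfg.systemic.v_NEpn = 0.0
        cfg.initial.Epn_B0 = 1.5
        cfg.initial.NEpn_B0 = 3.0
        res = run_scenario(cfg)
        for name in ("r", "IP3", "CaI", "g"):
            block = res.cell(name)
            np.testing.assert_allclose(block[0], block[1], rtol=1e-5, atol=1e-7)


class TestComparison:
    def test_comparison_requires_matching_grids(self):
        a, b = short(t_end=700.0), short(t_end=800.0)
        with pytest.raises(ValueError):
            run_comparison([a, b])

    def test_comparison_returns_aligned_results(self):
        a, b = short("human", 5.0, t_end=700.0), short("denervated", 5.0, t_end=700.0)
        ra, rb = run_comparison([a, b])
        np.testing.assert_array_equal(ra.t, rb.t)


class TestSerializationOutputs:
    def test_save_writes_trajectory_and_summary(self, tmp_path):
        res = run_scenario(short(t_end=600.0))
        res.save(tmp_path / "out")
        import json
        assert (tmp_path / "out" / "trajectory.csv").exists()
        summary = json.loads((tmp_path / "out" / "summary.json").read_text())
        assert summary["config_hash"] == res.provenance["config_hash"]
        assert len(summary["per_layer_glucose_output"]) == res.N

    def test_long_dataframe_shape(self):
        res = run_scenario(short(t_end=600.0))
        df = res.to_long_dataframe()
        T = len(res.t)
        # 6 cell states ×15 + 5 species ×15 + 5 body states
        assert len(df) == T * (6 * 15 + 5 * 15 + 5)
        assert set(df.columns) == {"time", "entity", "variable", "value"}
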