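"""Phase segmentation, perturbations, sweeps and the chemostat."""

import dataclasses

import numpy as np
import pytest

import agesim as ag
from agesim.boolean import BooleanState
from agesim.dynamics import CellState, Timeline
from agesim.experiments import (PerturbationSpec, PhaseTracker,
                                critical_dilution, cumulative_usage,
                                segment_phases)


def _timeline(rows, params=None):
    tl = Timeline(params=params)
    tl.steps = rows
    return tl


class TestPhaseSegmentation:
    def test_constant_growth_is_all_phase_one(self):
        rows = [{"t": 0.1 * i, "g": 0.3, "ethanol_exchange": 0.5}
                for i in range(20)]
        ann = segment_phases(_timeline(rows))
        assert set(ann.labels) == {"I"}
        assert ann.t_I_II is None and ann.t_II_III is None

    def test_growth_drop_without_ethanol_uptake_stops_at_phase_two(self):
        # mirrors low-maintenance deaths that never reach ethanol uptake
        rows = [{"t": 0.1 * i, "g": 0.3 if i < 10 else 0.1,
                 "ethanol_exchange": 0.2} for i in range(20)]
        ann = segment_phases(_timeline(rows))
        assert set(ann.labels) == {"I", "II"}
        assert ann.t_II_III is None

    def test_single_step_dip_is_not_sustained(self):
        g = [0.3] * 5 + [0.1] + [0.3] * 10
        rows = [{"t": 0.1 * i, "g": gi, "ethanol_exchange": 0.2}
                for i, gi in enumerate(g)]
        assert set(segment_phases(_timeline(rows)).labels) == {"I"}

    def test_labels_monotone_even_for_recovering_growth(self):
        g = [0.3] * 5 + [0.1] * 5 + [0.3] * 5
        rows = [{"t": 0.1 * i, "g": gi, "ethanol_exchange": 0.2}
                for i, gi in enumerate(g)]
        labels = segment_phases(_timeline(rows)).labels
        assert list(labels) == sorted(labels, key="I II III".split().index)

    def test_empty_timeline_rejected(self):
        with pytest.raises(ValueError):
            segment_phases(_timeline([]))

    def test_wildtype_passes_through_all_three_phases(self, wildtype,
                                                      wildtype_phases):
        ann = wildtype_phases
        counts = {p: ann.labels.count(p) for p in ("I", "II", "III")}
        assert all(c > 0 for c in counts.values())
        assert 0 < ann.t_I_II < ann.t_II_III < wildtype.death_time
        # live labels recorded during the run agree with offline segmentation
        df = wildtype.to_dataframe()
        assert list(df["phase"]) == list(ann.labels)

    def test_phase_division_counts_sum_to_lifespan(self, wildtype,
                                                   wildtype_phases):
        per_phase = wildtype_phases.divisions_per_phase(wildtype)
        assert sum(per_phase.values()) == wildtype.n_divisions

    def test_tracker_is_causal(self):
        tr = PhaseTracker()
        assert tr.phase == "I"
        for _ in range(3):
            tr.step(0.3, 0.5)
        assert tr.phase == "I"
        for _ in range(3):
            tr.step(0.1, 0.5)
        assert tr.phase == "II"
        tr.step(0.1, -0.01)
        assert tr.phase == "III"


class TestPerturbations:
    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PerturbationSpec(("E",), mode="silencing")
        with pytest.raises(ValueError):
            PerturbationSpec(("E",), scope="IV")

    def test_deleting_all_maintenance_routes_kills_immediately(self, toy):
        """Without any mitochondrial ATP source the first maintenance
        demand is unpayable: zero completed divisions."""
        spec = PerturbationSpec(("Cit1", "Adh2"), mode="deletion",
                                scope="life")
        p = dataclasses.replace(toy.params, t_max=5.0)
        tl = ag.simulate_lifespan(toy.model, toy.network, toy.table, p,
                                  perturbation=spec)
        assert tl.died and tl.n_divisions == 0

    def test_overexpression_of_unused_enzyme_pins_usage_to_zero(self, toy):
        # 1.5 x an optimal usage of 0 is still 0
        spec = PerturbationSpec(("Cit1",), mode="overexpression",
                                scope="life")
        p = dataclasses.replace(toy.params, t_max=2.0)
        tl = ag.simulate_lifespan(toy.model, toy.network, toy.table, p,
                                  perturbation=spec)
        df = tl.to_dataframe()
        assert (df["u_Cit1"].abs() <= 1e-12).all()

    def test_unknown_enzyme_reported(self, toy):
        spec = PerturbationSpec(("Sod5",), mode="deletion", scope="life")
        p = dataclasses.replace(toy.params, t_max=1.0)
        with pytest.raises(KeyError):
            ag.simulate_lifespan(toy.model, toy.network, toy.table, p,
                                 perturbation=spec)

    def test_superoxide_dismutase_loss_raises_damage_formation(self, toy,
                                                               wildtype):
        """Direction check on the ROS chain: at a stressed mid-life
        state, removing the forced detox capacity increases the damage
        formation flux at unchanged oxidative activity."""
        df = wildtype.to_dataframe()
        row = df[df["in_H2O2"] == 1].iloc[len(df) // 8]
        state = CellState(M=row["M"], P=row["P"], D=row["D"])
        coupled = ag.set_cell_coupling(toy.model, state, toy.params)
        sol = ag.solve(coupled)
        stress = BooleanState({"Yap1": 1, "Skn7": 1, "Msn2/4": 1, "Cat8": 0,
                               "PKA": 1, "Snf1": 0, "Rim15": 0, "Sln1": 1,
                               "Glucose": 1, "H2O2": 1, "Trx12": 0})
        var = ag.enzyme_variability(coupled, sol, toy.params.gamma,
                                    enzymes=["Sod1", "Trx1", "Ctt1", "Adh2",
                                             "Cit1"])
        regulated = ag.regulate(coupled, stress, toy.table, var,
                                toy.params.epsilon)
        with_detox = ag.solve(regulated)
        deleted = ag.solve(regulated.with_enzyme_bounds(
            {"Sod1": (0.0, 0.0), "Trx1": (0.0, 0.0), "Ctt1": (0.0, 0.0)}))
        assert deleted.feasible and with_detox.feasible
        assert deleted.damage_formation > with_detox.damage_formation
        assert deleted.flux["ETOH_RESP"] == pytest.approx(
            with_detox.flux["ETOH_RESP"], rel=0.05)

    def test_phase_three_deletion_leaves_earlier_life_untouched(self, toy,
                                                                wildtype,
                                                                wildtype_phases):
        spec = PerturbationSpec(("Sod1", "Trx1", "Ctt1"), mode="deletion",
                                scope="III")
        tl = ag.simulate_lifespan(toy.model, toy.network, toy.table,
                                  toy.params, perturbation=spec)
        a = wildtype.to_dataframe()
        b = tl.to_dataframe()
        cut = wildtype_phases.t_II_III
        pre_a = a[a["t"] < cut].reset_index(drop=True)
        pre_b = b[b["t"] < cut].reset_index(drop=True)
        assert len(pre_b) == len(pre_a)
        for col in ("g", "f_m", "D", "M", "o2_uptake"):
            assert np.allclose(pre_a[col], pre_b[col], atol=1e-12)


class TestCumulativeUsage:
    def test_per_phase_usages_sum_to_whole_life(self, wildtype,
                                                wildtype_phases):
        total = cumulative_usage(wildtype)
        by_phase = [cumulative_usage(wildtype, wildtype_phases, phase)
                    for phase in ("I", "II", "III")]
        for enzyme, value in total.items():
            split = sum(part.get(enzyme, 0.0) for part in by_phase)
            assert split == pytest.approx(value, abs=1e-12)

    def test_phase_filter_requires_annotation(self, wildtype):
        with pytest.raises(ValueError):
            cumulative_usage(wildtype, phase="I")


class TestSweep:
    def test_single_point_grid_matches_direct_simulation(self, toy):
        p = dataclasses.replace(toy.params, f0=2e-3, r0=1e-3, t_max=40.0)
        df = ag.sweep(toy.model, toy.network, toy.table,
                      [2e-3], [1e-3], [toy.params.epsilon], p)
        tl = ag.simulate_lifespan(toy.model, toy.network, toy.table, p)
        assert len(df) == 1
        row = df.iloc[0]
        assert row["lifespan"] == tl.n_divisions
        gen = tl.generation_times
        assert row["mean_generation_time"] == pytest.approx(
            sum(gen) / len(gen))
        assert not row["censored"]

    def test_errors_are_flagged_and_sweep_continues(self, toy):
        p = dataclasses.replace(toy.params, t_max=2.0)
        df = ag.sweep(toy.model, toy.network, toy.table,
                      [-1.0, 1e-3], [1e-3], [0.04], p)
        assert df["error"].notna().iloc[0]
        assert df["error"].isna().iloc[1]


class TestChemostat:
    def test_zero_dilution_runs_maintenance_only(self, toy):
        df = ag.chemostat(toy.model, [0.0])
        row = df.iloc[0]
        assert row["feasible"]
        # basal maintenance keeps a small oxidative flux alive
        assert 0 < row["glucose_uptake"] < 0.05
        assert row["o2_uptake"] > 0

    def test_rate_above_maximal_growth_flagged_infeasible(self, toy):
        g_max = ag.solve(toy.model).growth_rate
        df = ag.chemostat(toy.model, [g_max + 0.1])
        assert not df["feasible"].iloc[0]

    def test_overflow_switch_exists(self, toy):
        """Crabtree-like behaviour: respiration only at low dilution,
        ethanol production switching on above a critical rate."""
        crit = critical_dilution(toy.model, 0.0, 0.35)
        assert crit is not None and 0.02 < crit < 0.33
        below = ag.solve_chemostat(toy.model, crit - 0.02)
        above = ag.solve_chemostat(toy.model, crit + 0.02)
        etoh = toy.model.special("ethanol_exchange")
        assert below.flux[etoh] <= 1e-6
        assert above.flux[etoh] > 1e-4
        # below the switch the cell respires: high O2 per glucose
        assert below.flux["O2_UP"] / below.flux["GLC_UP"] > \
            above.flux["O2_UP"] / above.flux["GLC_UP"]

    def test_negative_rate_rejected(self, toy):
        with pytest.raises(ValueError):
            ag.solve_chemostat(toy.model, -0.1)
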