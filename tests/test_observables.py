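"""Measurement-like outputs: phase percentages, generation counts, BrdU, F(Tc)."""

from dataclasses import replace

import numpy as np
import pytest

from cyclesim import (
    CycleState,
    PerturbationSpec,
    compile_model,
    simulate,
)
from cyclesim.engine import PHASES
from cyclesim.observables import (
    brdu_series,
    death_fraction_per_generation,
    generation_counts,
    observable_table,
    phase_percentages,
    tc_distribution,
)
from cyclesim.phase_kinetics import (
    AgeGrid,
    PhaseDurationSpec,
    build_duration_distribution,
    mass_mean_h,
)
from cyclesim.engine import Trajectory


def _hand_state(model, g1=200.0, s=300.0, g2m=500.0):
    st = CycleState.empty(model)
    st.a["G1"][0, 0] = g1
    st.a["S"][0, 0] = s
    st.a["G2M"][0, 0] = g2m
    st.entered[0] = g1 + s + g2m
    return st


class TestPhasePercentages:
    def test_hand_state(self, plain_config):
        model = compile_model(plain_config)
        traj = Trajectory(states=[_hand_state(model)], model=model)
        pct = phase_percentages(traj)
        assert pct.iloc[0][["pct_g1", "pct_s", "pct_g2m"]].to_numpy() == pytest.approx(
            [20.0, 30.0, 50.0]
        )

    def test_all_g1(self, plain_config):
        model = compile_model(plain_config)
        traj = Trajectory(states=[_hand_state(model, 100.0, 0.0, 0.0)], model=model)
        pct = phase_percentages(traj)
        assert pct.iloc[0]["pct_g1"] == 100.0

    def test_sum_to_100_and_pol_exclusion(self, plain_config, plain_start):
        perts = (
            PerturbationSpec(kind="polyploid", cycles=(1, 2),
                             params={"p_pol": 0.3, "dr_pol": 0.0}),
        )
        traj = simulate(replace(plain_config, perturbations=perts), 48.0,
                        start=plain_start)
        pct = phase_percentages(traj)
        total = pct[["pct_g1", "pct_s", "pct_g2m"]].sum(axis=1).to_numpy()
        assert total == pytest.approx(100.0, abs=1e-6)
        incl = phase_percentages(traj, include_polyploid=True)
        assert incl[["pct_g1", "pct_s", "pct_g2m"]].sum(axis=1).iloc[-1] < 100.0

    def test_empty_population_reported(self, plain_config):
        model = compile_model(plain_config)
        traj = Trajectory(states=[CycleState.empty(model)], model=model)
        with pytest.raises(ValueError, match="empty population"):
            phase_percentages(traj)


class TestGenerationCounts:
    def test_partition_and_normalization(self, plain_config, plain_start):
        perts = (
            PerturbationSpec(kind="polyploid", cycles=(1,),
                             params={"p_pol": 0.2, "dr_pol": 0.0}),
        )
        traj = simulate(replace(plain_config, perturbations=perts), 48.0,
                        start=plain_start)
        gen = generation_counts(traj, n0_norm=1000.0)
        assert gen["n_gen0"].iloc[0] == pytest.approx(1000.0)
        cols = [c for c in gen.columns if c.startswith("n_gen")] + ["n_pol"]
        assert gen[cols].sum(axis=1).to_numpy() == pytest.approx(
            gen["n"].to_numpy(), rel=1e-12
        )

    def test_gen1_rises_then_falls(self, plain_config, plain_start):
        traj = simulate(plain_config, 72.0, start=plain_start)
        g1 = generation_counts(traj)["n_gen1"].to_numpy()
        peak = g1.argmax()
        assert 0 < peak < g1.size - 1
        assert g1[-1] < g1[peak] * 0.5


class TestBrdUSeries:
    def test_t0_equals_s_percentage(self, plain_config, plain_start):
        # exact without S quiescence; quiescent-in-S cells are unlabelled
        # (they do not synthesize DNA) and go to the BrdU- cycle
        pair = simulate(plain_config, 6.0, brdu_pulse=True, start=plain_start)
        bs = brdu_series(*pair)
        pct = phase_percentages(pair)
        assert bs["pct_brdu_pos"].iloc[0] == pytest.approx(pct["pct_s"].iloc[0])
        assert bs["pct_und_pos"].iloc[0] == pytest.approx(bs["pct_brdu_pos"].iloc[0])

    def test_und_cells_nonincreasing_without_death(self, plain_config, plain_start):
        neg, pos = simulate(plain_config, 48.0, brdu_pulse=True, start=plain_start)
        und_cells = np.array([s.cycle_totals()[0] for s in pos.states])
        assert np.all(np.diff(und_cells) <= 1e-9)

    def test_rejects_unpaired(self, plain_config, plain_start):
        traj = simulate(plain_config, 6.0, start=plain_start)
        with pytest.raises(ValueError):
            brdu_series(traj, traj)


class TestTcDistribution:
    @pytest.fixture(scope="class")
    def dists(self, grid):
        return {
            ph: build_duration_distribution(spec, AgeGrid(delta_h=0.5, n_max=4096))
            for ph, spec in {
                "G1": PhaseDurationSpec(10.0, 0.0),
                "S": PhaseDurationSpec(8.0, 0.0),
                "G2M": PhaseDurationSpec(6.0, 0.0),
            }.items()
        }

    def test_delta_sum(self, dists):
        f, mean = tc_distribution(dists)
        assert mean == pytest.approx(24.0)
        assert f[47] == pytest.approx(1.0)  # compartment 48 = 24 h

    def test_mean_additivity_random_cvs(self, grid):
        dists = {
            "G1": build_duration_distribution(PhaseDurationSpec(11.0, 0.25), grid),
            "S": build_duration_distribution(PhaseDurationSpec(9.0, 0.15), grid),
            "G2M": build_duration_distribution(PhaseDurationSpec(4.0, 0.25), grid),
        }
        f, mean = tc_distribution(dists)
        expect = sum(mass_mean_h(dists[ph].mass, 0.5) for ph in PHASES)
        assert mean == pytest.approx(expect, rel=1e-9)
        assert mass_mean_h(f, 0.5) == pytest.approx(expect, rel=1e-9)

    def test_delay_stretches_mean(self, dists):
        # S delay of 0.5 doubles the S contribution to the mean cycle time
        f, mean = tc_distribution(dists, delays={"S": 0.5})
        assert mean == pytest.approx(10.0 + 16.0 + 6.0)


class TestDeathFractions:
    def test_zero_without_death_modules(self, plain_config, plain_start):
        traj = simulate(plain_config, 48.0, start=plain_start)
        df = death_fraction_per_generation(traj)
        assert df["pct_died"].dropna().to_numpy() == pytest.approx(0.0, abs=1e-12)
        assert np.all(df["died"] <= df["entered"] + 1e-12)

    def test_gen0_g1_block_eventual_fate(self, plain_config):
        """All-G1 starting cohort with a lethal G1 block: the gen0 death
        fraction tends to p_bl x (eventual death share among blocked)."""
        p_bl, dr = 0.4, 0.05
        config = replace(
            plain_config,
            p_q={},
            dr_q={},
            perturbations=(
                PerturbationSpec(kind="block", phase="G1", cycles=(0,),
                                 params={"p_bl": p_bl, "dr_bl": dr}),
            ),
        )
        model = compile_model(config)
        s = CycleState.empty(model)
        s.a["G1"][0, 0] = 1000.0
        s.entered[0] = 1000.0
        for _ in range(800):  # 400 h: blocked pool fully drained by death
            s = step_cached(s, model)
        df_frac = s.dead[0] / s.entered[0]
        assert df_frac == pytest.approx(p_bl, rel=1e-3)


def step_cached(s, model):
    from cyclesim import step

    return step(s, model)


class TestObservableTable:
    def test_tidy_long_format(self, base_config, base_start):
        pair = simulate(base_config, 6.0, brdu_pulse=True, start=base_start)
        table = observable_table(pair, dose=2.5)
        assert set(table.columns) == {"dose", "time_h", "quantity", "value"}
        assert (table["dose"] == 2.5).all()
        assert {"pct_g1", "n_gen0", "pct_brdu_pos"} <= set(table["quantity"])
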