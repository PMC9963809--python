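"""Scenario assembly, weighted transport, tallies, and their invariants."""

import dataclasses

import numpy as np
import pytest

from crpdt.engine import (
    Geometry,
    NanoparticleModel,
    PhysicsSwitches,
    ScenarioConfig,
    SourceConfig,
    TransportParams,
    force_capture,
    run_scenario,
    scenario_config,
    track_primary,
)
from crpdt.physics import ChargedParticleState, Photon


def _gamma(weight=1.0):
    return Photon(
        position_um=np.zeros(3),
        direction=np.array([0.0, 0.0, 1.0]),
        weight=weight,
        origin="annihilation",
        energy_kev=511.0,
    )


class TestConfigValidation:
    def test_inconsistent_scenario_rejected_before_tracking(self):
        with pytest.raises(ValueError, match="requires"):
            ScenarioConfig(
                scenario_id="water_only",
                nanoparticle=NanoparticleModel(lanthanide="Tb", has_ps=True),
            )

    def test_source_inside_cell_rejected(self):
        with pytest.raises(ValueError, match="source sphere"):
            Geometry(source_center_um=(0.0, 0.0, -4.0))

    def test_geometry_nesting_enforced(self):
        with pytest.raises(ValueError, match="nest"):
            Geometry(cluster_radius_um=6.0)

    def test_capture_probability_bounds(self):
        with pytest.raises(ValueError, match="capture"):
            TransportParams(gamma_capture_prob=1.0)

    def test_factory_builds_consistent_models(self):
        for sid, (lan, ps) in {
            "water_only": ("none", False),
            "tb_ps": ("Tb", True),
            "gd_ps": ("Gd", True),
        }.items():
            cfg = scenario_config(sid, primaries=10, seed=0)
            assert cfg.nanoparticle.lanthanide == lan
            assert cfg.nanoparticle.has_ps == ps


class TestForceCapture:
    def test_zero_probability_passes_all_weight(self):
        inter, surv = force_capture(_gamma(), 0.0)
        assert inter == 0.0 and surv == 1.0

    def test_weight_split_conserves_exactly(self):
        inter, surv = force_capture(_gamma(1.0), 0.3)
        assert inter == pytest.approx(0.3) and surv == pytest.approx(0.7)
        assert inter + surv == 1.0

    def test_repeated_traversals_decay_geometrically(self):
        w = 1.0
        for k in range(1, 6):
            _, w = force_capture(_gamma(w), 0.3)
            assert w == pytest.approx(0.7**k, rel=1e-12)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            force_capture(_gamma(), 1.0)


class TestTrackPrimary:
    def test_track_produces_cerenkov_then_annihilates(self, rng):
        cfg = scenario_config("water_only", primaries=1, seed=0)
        state = ChargedParticleState(
            kinetic_energy_kev=844.0,
            position_um=np.array([0.0, 0.0, -6.5]),
            direction=np.array([0.0, 0.0, 1.0]),
        )
        events = track_primary(state, cfg, rng)
        # 844 keV is far above the 264 keV water threshold
        assert len(events["cerenkov_photons"]) > 0
        g1, g2 = events["annihilation_pair"]
        assert g1.energy_kev == g2.energy_kev == 511.0
        assert events["final_state"].kinetic_energy_kev == 0.0

    def test_cerenkov_switch_off_emits_no_optical_photons(self, rng):
        cfg = scenario_config(
            "water_only", primaries=1, seed=0, switches=PhysicsSwitches(cerenkov=False)
        )
        state = ChargedParticleState(
            kinetic_energy_kev=844.0,
            position_um=np.zeros(3) - np.array([0, 0, 6.5]),
            direction=np.array([0.0, 0.0, 1.0]),
        )
        events = track_primary(state, cfg, rng)
        assert events["cerenkov_photons"] == []


class TestRunScenario:
    def test_water_only_contains_only_cerenkov_origin(self, scenario_runs):
        tally, _ = scenario_runs["water_only"]
        assert set(tally.hist["emitted"]) == {"cerenkov"}

    def test_seeded_determinism_bit_identical(self):
        cfg = scenario_config("tb_ps", primaries=5_000, seed=11)
        t1, _ = run_scenario(cfg)
        t2, _ = run_scenario(scenario_config("tb_ps", primaries=5_000, seed=11))
        for surface in t1.SURFACES:
            assert set(t1.hist[surface]) == set(t2.hist[surface])
            for origin in t1.hist[surface]:
                assert np.array_equal(t1.hist[surface][origin], t2.hist[surface][origin])
        assert t1.ps_excitation == t2.ps_excitation

    @pytest.mark.parametrize("sid", ["ps_only", "tb_ps", "tb_only", "gd_ps"])
    def test_weight_conservation(self, scenario_runs, sid):
        tally, _ = scenario_runs[sid]
        assert tally.conservation_residual() < 1e-9

    def test_all_optical_physics_off_gives_empty_tallies(self):
        cfg = scenario_config(
            "tb_ps",
            primaries=2_000,
            seed=3,
            switches=PhysicsSwitches(
                cerenkov=False, scintillation=False, uv_fluorescence=False,
                ps_fluorescence=False,
            ),
        )
        tally, _ = run_scenario(cfg)
        assert all(not tally.hist[s] for s in tally.SURFACES)
        assert sum(tally.ps_excitation.values()) == 0.0

    def test_scintillation_switch_controls_annihilation_pathway(self):
        cfg = scenario_config(
            "tb_ps", primaries=5_000, seed=4,
            switches=PhysicsSwitches(scintillation=False),
        )
        tally, _ = run_scenario(cfg)
        assert tally.ps_excitation["annihilation_scintillation"] == 0.0
        assert tally.ps_excitation["direct_cerenkov"] > 0.0

    def test_pathway_weights_partition_total_excitation(self, scenario_runs):
        tally, _ = scenario_runs["tb_ps"]
        total_abs = sum(tally.absorbed_ps.values())
        assert sum(tally.ps_excitation.values()) == pytest.approx(total_abs, rel=1e-12)

    def test_adding_tb_never_decreases_ps_excitation(self):
        """Paired seeds: tb_ps excitation >= ps_only excitation, 10 replicates."""
        wins = 0
        for seed in range(10):
            t_ps, _ = run_scenario(scenario_config("ps_only", primaries=20_000, seed=seed))
            t_tb, _ = run_scenario(scenario_config("tb_ps", primaries=20_000, seed=seed))
            wins += sum(t_tb.ps_excitation.values()) >= sum(t_ps.ps_excitation.values())
        assert wins == 10

    def test_manifest_records_reproducibility_data(self, scenario_runs):
        _, manifest = scenario_runs["tb_ps"]
        assert manifest["seed"] == 7
        assert manifest["primaries"] == 100_000
        assert manifest["transport"]["gamma_importance"] > 0
        assert "scintillator_emission" in manifest["fixture_hashes"]

    def test_gamma_bookkeeping(self, scenario_runs):
        tally, _ = scenario_runs["tb_ps"]
        assert tally.gamma_created == 2.0 * 100_000
        assert tally.gamma_captured > 0
        assert tally.gamma_created == pytest.approx(
            tally.gamma_captured + tally.gamma_escaped
        )


class TestScaledDownEquivalence:
    def test_fold_change_stable_between_scales(self):
        """tb_ps/ps_only fluorescence fold at 10^5 vs 4x10^5 primaries agrees
        within 3 combined Monte Carlo sigma."""
        from crpdt.analysis import fold_change, summarize

        folds = []
        for n in (100_000, 400_000):
            s = {}
            for sid in ("ps_only", "tb_ps"):
                t, _ = run_scenario(scenario_config(sid, primaries=n, seed=21))
                s[sid] = summarize(t, sid)
            folds.append(fold_change(s["tb_ps"], s["ps_only"], "ps_fluor"))
        diff = abs(folds[0].ratio - folds[1].ratio)
        sigma = np.hypot(folds[0].sigma, folds[1].sigma)
        assert diff < 3 * sigma
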