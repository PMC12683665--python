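"""Generator validity, reproducibility and parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from germscreen.data import InspectionSchedule, validate_panel
from germscreen.indices import panel_sti_matrix, seedling_sti_table
from germscreen.synth import (
    ArchetypeParams,
    SimulationConfig,
    default_screening_config,
    simulate_dish,
    simulate_gradient,
    simulate_panel,
    simulate_seedlings,
)


def plain_params(**over):
    base = dict(
        name="T", mu0=np.log(1.0), sigma=0.5, delta=1.5, pi0=0.95, rho=0.8,
        alpha0=0.05, alpha_salt=0.1, length_means=(30.0, 45.0, 20.0),
        length_sti=(0.5, 0.3, 0.2), tau=0.05,
    )
    base.update(over)
    return ArchetypeParams(**base)


class TestArchetypeParams:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            plain_params(pi0=1.4)
        with pytest.raises(ValueError):
            plain_params(delta=0.8)
        with pytest.raises(ValueError):
            plain_params(length_sti=(0.5, -0.1, 0.2))

    def test_dose_interpolation_anchored_at_200(self):
        p = plain_params()
        assert p.delta_at(0.0) == 1.0
        assert p.delta_at(200.0) == p.delta
        assert p.delta_at(100.0) == pytest.approx(1 + (p.delta - 1) / 2)
        assert p.pi_at(200.0) == pytest.approx(p.pi0 * p.rho)


class TestSimulateDish:
    def test_deterministic_limit_all_in_one_interval(self, schedule):
        p = plain_params(mu0=np.log(1.5), sigma=0.0, tau=0.0, pi0=1.0,
                         alpha0=0.0, alpha_salt=0.0)
        dish = simulate_dish(p, 0.0, schedule, 50, np.random.default_rng(0))
        assert dish.new_germ == {1: 0, 2: 50, 3: 0, 6: 0}

    def test_zero_viability_gives_empty_dish(self, schedule):
        p = plain_params(pi0=0.0)
        dish = simulate_dish(p, 0.0, schedule, 50, np.random.default_rng(0))
        assert dish.g_final == 0

    def test_delay_recovery_from_many_dishes(self, schedule):
        """T50 ratio over simulated dishes approaches the configured delay."""
        from germscreen.timetoevent import (
            SeedIntervals, counts_to_intervals, fit_npmle, t50_germinated,
        )

        p = plain_params(mu0=np.log(0.8), sigma=0.6, delta=2.0, tau=0.0,
                         rho=1.0, pi0=0.97)
        rng = np.random.default_rng(17)
        t50 = {}
        for trt in (0.0, 200.0):
            dishes = [
                simulate_dish(p, trt, schedule, 50, rng, replicate=f"r{i}")
                for i in range(200)
            ]
            iv = SeedIntervals.concat(
                [counts_to_intervals(d, schedule) for d in dishes]
            )
            t50[trt] = t50_germinated(fit_npmle(iv)).time
        assert t50[200.0] / t50[0.0] == pytest.approx(2.0, rel=0.10)


class TestSimulatePanel:
    def test_emitted_panel_is_valid_with_truth(self):
        panel, truth = simulate_panel(default_screening_config(rng_seed=5))
        assert validate_panel(panel) == []
        assert len(truth) == 32 + 9 + 14
        assert truth["archetype"].value_counts().to_dict() == {
            "C1": 32, "C3": 14, "C2": 9,
        }

    def test_reproducible_byte_identical(self, tmp_path):
        from germscreen.io import write_germination_table

        cfg = default_screening_config(rng_seed=9)
        for name in ("a", "b"):
            panel, truth = simulate_panel(cfg)
            write_germination_table(panel, tmp_path / f"{name}.csv")
            truth.to_csv(tmp_path / f"truth_{name}.csv", index=False)
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()
        assert (
            (tmp_path / "truth_a.csv").read_bytes()
            == (tmp_path / "truth_b.csv").read_bytes()
        )

    def test_archetype_sti_tg_means_match_targets(self):
        """Panel-level STI_TG grand means land on the cluster phenotypes."""
        panel, truth = simulate_panel(default_screening_config(rng_seed=2))
        sti = panel_sti_matrix(panel)
        arch = truth.set_index("accession")["archetype"]
        means = sti.join(arch).groupby("archetype")["TG"].mean()
        assert means["C1"] == pytest.approx(0.90, abs=0.05)
        assert means["C2"] == pytest.approx(0.62, abs=0.05)
        assert means["C3"] == pytest.approx(0.90, abs=0.05)

    def test_identical_archetypes_give_chance_level_clustering(self):
        from sklearn.metrics import adjusted_rand_score

        from germscreen.screening import hkmeans

        p = plain_params()
        cfg = SimulationConfig(
            archetypes={"X": (p, 20), "Y": (p, 20), "Z": (p, 17)},
            rng_seed=3,
        )
        panel, truth = simulate_panel(cfg)
        sti = panel_sti_matrix(panel)
        labels = hkmeans(sti, k=3, seed=0).labels
        ari = adjusted_rand_score(
            truth.set_index("accession").loc[sti.index, "archetype"], labels
        )
        assert abs(ari) < 0.15

    def test_consistency_at_large_n_with_fine_schedule(self):
        """STI_TG approaches rho and the T50 ratio approaches delta."""
        from germscreen.timetoevent import (
            SeedIntervals, counts_to_intervals, fit_npmle, t50_germinated,
        )

        fine = InspectionSchedule(tuple(np.round(np.arange(0.2, 6.01, 0.2), 2)))
        p = plain_params(mu0=np.log(0.8), sigma=0.6, delta=2.0, rho=0.6,
                         pi0=0.97, tau=0.0, alpha0=0.0, alpha_salt=0.0,
                         sigma_salt_mult=1.0)
        rng = np.random.default_rng(23)
        t50 = {}
        tg = {}
        for trt in (0.0, 200.0):
            dishes = [
                simulate_dish(p, trt, fine, 3000, rng, replicate=f"r{i}")
                for i in range(10)
            ]
            iv = SeedIntervals.concat(
                [counts_to_intervals(d, fine) for d in dishes]
            )
            fit = fit_npmle(iv)
            t50[trt] = t50_germinated(fit).time
            tg[trt] = sum(d.g_final for d in dishes) / sum(d.n_sown for d in dishes)
        assert t50[200.0] / t50[0.0] == pytest.approx(2.0, rel=0.02)
        # completion by day 6 is near-total in both arms, so TG ratio ~ rho
        assert tg[200.0] / tg[0.0] == pytest.approx(0.6, abs=0.02)

    def test_increasing_delay_increases_mean_germination_time(self, schedule):
        from germscreen.indices import compute_indices

        rng = np.random.default_rng(31)
        mgts = []
        for delta in (1.0, 1.5, 2.0):
            p = plain_params(delta=delta, tau=0.0, rho=1.0)
            vals = [
                compute_indices(
                    simulate_dish(p, 200.0, schedule, 400, rng), schedule
                ).mgt
                for _ in range(30)
            ]
            mgts.append(np.mean(vals))
        assert mgts[0] < mgts[1] < mgts[2]


class TestSimulateSeedlings:
    def test_valid_panel_and_design(self):
        panel, truth = simulate_seedlings(default_screening_config(rng_seed=4))
        assert validate_panel(panel) == []
        assert len(truth) == 7 + 3 + 4  # per-cluster representative counts
        assert len(panel) == 14 * 2 * 5  # genotypes x treatments x boxes

    def test_unit_multipliers_give_unit_stis(self):
        p = plain_params(length_sti=(1.0, 1.0, 1.0))
        cfg = SimulationConfig(archetypes={"X": (p, 3)}, rng_seed=6)
        acc = pd.DataFrame({"accession": ["G1", "G2"], "archetype": ["X", "X"]})
        panel, _ = simulate_seedlings(cfg, accessions=acc)
        sti = seedling_sti_table(panel)
        for trait in ("shoot", "main_root", "lateral_root"):
            np.testing.assert_allclose(sti[trait], 1.0, atol=0.12)

    def test_zero_variance_lengths_recover_exact_multipliers(self):
        p = plain_params(length_sti=(0.53, 0.29, 0.17))
        cfg = SimulationConfig(archetypes={"X": (p, 1)}, length_cv=0.0, rng_seed=0)
        acc = pd.DataFrame({"accession": ["G1"], "archetype": ["X"]})
        panel, _ = simulate_seedlings(cfg, accessions=acc)
        sti = seedling_sti_table(panel)
        assert sti.loc["G1", "shoot"] == pytest.approx(0.53, abs=1e-12)
        assert sti.loc["G1", "main_root"] == pytest.approx(0.29, abs=1e-12)
        assert sti.loc["G1", "lateral_root"] == pytest.approx(0.17, abs=1e-12)

    def test_default_config_orders_trait_impacts(self):
        """Shoot length is least impacted, lateral roots most."""
        panel, _ = simulate_seedlings(default_screening_config(rng_seed=8))
        sti = seedling_sti_table(panel)
        means = sti.mean()
        assert means["shoot"] > means["main_root"] > means["lateral_root"]


class TestGradientAndConfig:
    def test_gradient_panel_valid(self):
        panel, truth = simulate_gradient(rng_seed=12)
        assert validate_panel(panel) == []
        assert len(panel) == 2 * 7 * 3
        assert set(truth["accession"]) == {"VAR-C1", "VAR-C3"}

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = default_screening_config(rng_seed=99)
        path = tmp_path / "config.yaml"
        cfg.to_yaml(path)
        back = SimulationConfig.from_yaml(path)
        assert back.rng_seed == 99
        assert back.schedule.times == cfg.schedule.times
        assert back.archetypes.keys() == cfg.archetypes.keys()
        for name in cfg.archetypes:
            assert back.archetypes[name] == cfg.archetypes[name]

    def test_control_required_in_treatments(self):
        with pytest.raises(ValueError, match="control"):
            SimulationConfig(treatments=(50.0, 200.0))
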