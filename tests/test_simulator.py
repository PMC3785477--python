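import numpy as np
import pytest

import tfocc
from conftest import single_molecule_config, toy_landscape
from oracles import single_molecule_stationary


class TestBasics:
    def test_zero_abundance_gives_empty_record(self):
        lsc = toy_landscape([0.0, 1.0])
        cfg = single_molecule_config(lsc, dna_length=2, t_end=100.0)
        cfg.species[0].abundance = 0
        rec = tfocc.simulate(cfg)
        assert rec.residence["tf"].sum() == 0
        assert sum(rec.event_counts["tf"].values()) == 0
        assert rec.final_positions["tf"].size == 0

    def test_no_species_is_valid(self):
        rec = tfocc.simulate(tfocc.SimConfig(dna_length=10, species=[],
                                             t_end=5.0))
        assert rec.residence == {}

    def test_two_equal_sites_split_evenly(self):
        lsc = toy_landscape([0.0, 0.0])
        cfg = single_molecule_config(lsc, dna_length=2,
                                     move_probs=(0.5, 0.5, 0.0, 0.0),
                                     hop_range=1, t_end=4e4, seed=5)
        rec = tfocc.simulate(cfg)
        frac = rec.residence["tf"][0] / rec.residence["tf"].sum()
        assert frac == pytest.approx([0.5, 0.5], abs=0.05)

    def test_three_state_slide_only_matches_boltzmann(self):
        lsc = toy_landscape([0.0, 1.0, 0.0])
        cfg = single_molecule_config(lsc, dna_length=3,
                                     move_probs=(0.5, 0.5, 0.0, 0.0),
                                     hop_range=1, t_end=1e5, seed=6)
        rec = tfocc.simulate(cfg)
        tau = np.array([1.0, np.e, 1.0])
        frac = rec.residence["tf"][0] / rec.residence["tf"].sum()
        np.testing.assert_allclose(frac, tau / tau.sum(), atol=0.02)

    def test_footprint_demand_warning(self):
        lsc = toy_landscape(np.zeros(10), footprint=5)
        sp = tfocc.SpeciesParams(name="a", footprint=5, abundance=4,
                                 k_assoc=1.0, landscape=lsc)
        with pytest.warns(UserWarning, match="footprint demand"):
            tfocc.SimConfig(dna_length=14, species=[sp], t_end=1.0)


@pytest.fixture(scope="module")
def crowded_record():
    lsc = toy_landscape(np.linspace(0, 2, 181), footprint=20)
    cognate = tfocc.SpeciesParams(name="tf", footprint=20, abundance=3,
                                  k_assoc=1.0, landscape=lsc, hop_range=10)
    crowder = tfocc.SpeciesParams(name="nc", footprint=15, abundance=6,
                                  k_assoc=0.5, tau0=4.0, hop_range=10)
    cfg = tfocc.SimConfig(dna_length=200, species=[cognate, crowder],
                          t_end=5e3, seed=17)
    return tfocc.simulate(cfg), cfg


class TestConservation:

    def test_bound_plus_free_equals_t_end(self, crowded_record):
        rec, cfg = crowded_record
        for name in ("tf", "nc"):
            total = rec.bound_time[name] + rec.free_time[name]
            np.testing.assert_allclose(total, cfg.t_end, atol=1e-6)

    def test_molecule_conservation(self, crowded_record):
        rec, cfg = crowded_record
        for sp in cfg.species:
            assert rec.final_positions[sp.name].size == sp.abundance

    def test_residence_bounded_by_abundance_times_t(self, crowded_record):
        rec, cfg = crowded_record
        for sp in cfg.species:
            assert rec.residence[sp.name].sum() <= sp.abundance * cfg.t_end + 1e-6

    def test_steric_hindrance_no_basepair_double_covered(self, crowded_record):
        """Summed per-bp covered time across all species cannot exceed t_end,
        and end-of-run footprints must be pairwise disjoint."""
        rec, cfg = crowded_record
        total_cov = sum(rec.coverage_seconds(sp.name) for sp in cfg.species)
        assert total_cov.max() <= cfg.t_end * (1 + 1e-9)
        covered = np.zeros(cfg.dna_length, dtype=int)
        for sp in cfg.species:
            n_starts = cfg.dna_length - sp.footprint + 1
            for st in rec.final_positions[sp.name]:
                if st >= 0:
                    p = st % n_starts
                    covered[p: p + sp.footprint] += 1
        assert covered.max() <= 1


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        lsc = toy_landscape(np.linspace(0, 1.5, 50), footprint=3)
        sp = tfocc.SpeciesParams(name="tf", footprint=3, abundance=4,
                                 k_assoc=1.0, landscape=lsc, hop_range=8)
        cfg = tfocc.SimConfig(dna_length=52, species=[sp], t_end=2e3, seed=99)
        a, b = tfocc.simulate(cfg), tfocc.simulate(cfg)
        np.testing.assert_array_equal(a.residence["tf"], b.residence["tf"])
        np.testing.assert_array_equal(a.final_positions["tf"],
                                      b.final_positions["tf"])
        assert a.event_counts == b.event_counts

    def test_different_seed_differs(self):
        lsc = toy_landscape(np.zeros(20))
        cfg1 = single_molecule_config(lsc, 20, t_end=1e3, seed=1)
        cfg2 = single_molecule_config(lsc, 20, t_end=1e3, seed=2)
        a, b = tfocc.simulate(cfg1), tfocc.simulate(cfg2)
        assert not np.array_equal(a.residence["tf"], b.residence["tf"])


class TestEnsemble:
    def test_single_replicate_matches_simulate(self):
        lsc = toy_landscape(np.zeros(10))
        cfg = single_molecule_config(lsc, 10, t_end=500.0, seed=42)
        snaps = tfocc.ensemble_snapshots(cfg, 1, base_seed=42)
        rec = tfocc.simulate(cfg)
        np.testing.assert_array_equal(snaps.positions["tf"][0],
                                      rec.final_positions["tf"])

    def test_zero_abundance_snapshots_empty(self):
        lsc = toy_landscape(np.zeros(5))
        cfg = single_molecule_config(lsc, 5, t_end=10.0)
        cfg.species[0].abundance = 0
        snaps = tfocc.ensemble_snapshots(cfg, 3, base_seed=0)
        assert snaps.positions["tf"].shape == (3, 0)

    def test_two_equal_sites_binomial_split(self):
        lsc = toy_landscape([0.0, 0.0])
        cfg = single_molecule_config(lsc, 2, move_probs=(0.4, 0.4, 0.0, 0.2),
                                     hop_range=1, t_end=50.0, seed=0)
        snaps = tfocc.ensemble_snapshots(cfg, 4000, base_seed=7)
        ens = tfocc.sdo_ensemble(snaps, "tf")
        # ~Binomial(4000, ~0.47); 4 sigma ~ 0.032
        assert ens.values[0] == pytest.approx(ens.values[1], abs=0.04)


class TestBoundTimeFraction:
    def test_zero_k_assoc_never_binds(self):
        lsc = toy_landscape(np.zeros(5))
        cfg = single_molecule_config(lsc, 5, k_assoc=0.0, t_end=100.0)
        assert tfocc.bound_time_fraction(tfocc.simulate(cfg), "tf") == 0.0

    def test_no_unbinding_approaches_one(self):
        lsc = toy_landscape(np.zeros(5))
        cfg = single_molecule_config(lsc, 5, k_assoc=50.0,
                                     move_probs=(0.5, 0.5, 0.0, 0.0),
                                     t_end=1e4, seed=3)
        assert tfocc.bound_time_fraction(tfocc.simulate(cfg), "tf") > 0.99

    def test_two_state_closed_form(self):
        # pure bind/unbind: f = k / (k + u) with u = 1/tau0
        lsc = toy_landscape(np.zeros(50))
        cfg = single_molecule_config(lsc, 50, k_assoc=2.0,
                                     move_probs=(0.0, 0.0, 0.0, 1.0),
                                     t_end=4e4, seed=8)
        f = tfocc.bound_time_fraction(tfocc.simulate(cfg), "tf")
        assert f == pytest.approx(2.0 / 3.0, abs=0.02)

    def test_unknown_species_rejected(self):
        lsc = toy_landscape(np.zeros(5))
        rec = tfocc.simulate(single_molecule_config(lsc, 5, t_end=10.0))
        with pytest.raises(KeyError):
            tfocc.bound_time_fraction(rec, "nope")


class TestStationaryOracle:
    """The simulator against the explicit CTMC solved by linear algebra."""

    @pytest.mark.parametrize("seed,footprint,hop_range,move_probs", [
        (21, 1, 5, (0.4, 0.4, 0.1, 0.1)),
        (22, 3, 8, (0.45, 0.45, 0.05, 0.05)),
    ])
    def test_time_average_matches_stationary(self, seed, footprint, hop_range,
                                             move_probs):
        rng = np.random.default_rng(seed)
        L = 40
        n_starts = L - footprint + 1
        energies = rng.uniform(0, 2, size=(n_starts, 1))
        lsc = tfocc.EnergyLandscape(energies=energies, tau0=1.0, scaling=1.0,
                                    footprint=footprint)
        cfg = single_molecule_config(lsc, L, move_probs=move_probs,
                                     hop_range=hop_range, t_end=3e5,
                                     seed=seed, footprint=footprint)
        rec = tfocc.simulate(cfg)
        pi_free, pi_bound = single_molecule_stationary(
            lsc.waiting_times.T, 1.0, move_probs, hop_range)
        emp_bound = rec.residence["tf"] / cfg.t_end
        emp_free = rec.free_time["tf"][0] / cfg.t_end
        tv = 0.5 * (abs(emp_free - pi_free) +
                    np.abs(emp_bound - pi_bound).sum())
        assert tv < 0.02

    def test_oracle_bound_distribution_equals_ado(self):
        """Reversibility: the oracle's bound distribution is Boltzmann,
        i.e. exactly the affinity-derived occupancy."""
        rng = np.random.default_rng(30)
        energies = rng.uniform(0, 3, size=(25, 1))
        lsc = tfocc.EnergyLandscape(energies=energies, tau0=1.0, scaling=1.0,
                                    footprint=1)
        _, pi_bound = single_molecule_stationary(
            lsc.waiting_times.T, 1.0, (0.4, 0.4, 0.1, 0.1), 6)
        ado = tfocc.ado(lsc)
        np.testing.assert_allclose(pi_bound[0] / pi_bound.sum(), ado.values,
                                   rtol=1e-8)


class TestSnapshotTimes:
    def test_mid_run_snapshots_recorded(self):
        lsc = toy_landscape(np.zeros(10))
        sp = tfocc.SpeciesParams(name="tf", footprint=1, abundance=2,
                                 k_assoc=5.0, landscape=lsc)
        cfg = tfocc.SimConfig(dna_length=10, species=[sp], t_end=100.0,
                              seed=4, snapshot_times=[25.0, 50.0, 75.0])
        rec = tfocc.simulate(cfg)
        assert rec.snapshots["states"].shape == (3, 2)


class TestConfigIO:
    def test_yaml_round_trip(self, tmp_path):
        lsc = toy_landscape(np.linspace(0, 1, 10))
        cfg = single_molecule_config(lsc, 10, t_end=50.0, seed=12)
        path = tmp_path / "cfg.yaml"
        tfocc.save_config(cfg, path)
        back = tfocc.load_config(path, landscapes={"tf": lsc})
        assert back.dna_length == cfg.dna_length
        assert back.t_end == cfg.t_end
        assert back.species[0].name == "tf"
        rec_a = tfocc.simulate(cfg)
        rec_b = tfocc.simulate(back)
        np.testing.assert_array_equal(rec_a.residence["tf"],
                                      rec_b.residence["tf"])


class TestSingleMoleculeFastPath:
    def test_fast_ensemble_identical_to_general_kernel(self):
        """The single-molecule ensemble path reproduces the general
        event-queue kernel draw for draw: same seeds, same end states."""
        rng = np.random.default_rng(60)
        energies = rng.uniform(0, 2, size=(44, 2))
        lsc = tfocc.EnergyLandscape(energies=energies, tau0=1.0, scaling=1.0,
                                    footprint=7)
        cfg = single_molecule_config(lsc, 50, t_end=300.0, footprint=7,
                                     hop_range=9)
        snaps = tfocc.ensemble_snapshots(cfg, 300, base_seed=500)
        for i in (0, 17, 123, 299):
            cfg_i = tfocc.SimConfig(dna_length=50, species=cfg.species,
                                    t_end=300.0, seed=500 + i)
            rec = tfocc.simulate(cfg_i)
            assert snaps.positions["tf"][i, 0] == rec.final_positions["tf"][0]
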