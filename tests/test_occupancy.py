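import math

import numpy as np
import pytest

import tfocc
from tfocc.occupancy import OccupancyTrack
from conftest import single_molecule_config, toy_landscape


def track(values, estimator="time", **kw):
    return OccupancyTrack(values=np.asarray(values, dtype=float),
                          estimator=estimator, **kw)


class TestAdo:
    def test_flat_landscape_uniform(self):
        lsc = toy_landscape(np.zeros(8))
        np.testing.assert_allclose(tfocc.ado(lsc).values, 1 / 8)

    def test_boltzmann_weights(self):
        lsc = toy_landscape([0.0, 1.0, 2.0])
        expected = np.array([1.0, math.e, math.e**2])
        expected /= expected.sum()
        np.testing.assert_allclose(tfocc.ado(lsc).values, expected, atol=1e-4)
        # spot values of the normalized Boltzmann law
        np.testing.assert_allclose(tfocc.ado(lsc).values,
                                   [0.09003057, 0.24472847, 0.66524096],
                                   atol=1e-6)

    def test_tau0_cancels(self):
        e = np.array([[0.0], [1.5], [0.7]])
        a = tfocc.EnergyLandscape(energies=e, tau0=1.0, scaling=1.0, footprint=1)
        b = tfocc.EnergyLandscape(energies=e, tau0=2.0, scaling=1.0, footprint=1)
        np.testing.assert_allclose(tfocc.ado(a).values, tfocc.ado(b).values)

    def test_strands_summed_per_start(self):
        e = np.array([[0.0, 1.0], [1.0, 0.0]])
        lsc = tfocc.EnergyLandscape(energies=e, tau0=1.0, scaling=1.0,
                                    footprint=1)
        np.testing.assert_allclose(tfocc.ado(lsc).values, [0.5, 0.5])


class TestSdoEstimators:
    def test_time_average_is_residence_over_t(self):
        lsc = toy_landscape(np.zeros(4))
        cfg = single_molecule_config(lsc, 4, t_end=100.0, seed=1)
        rec = tfocc.simulate(cfg)
        t = tfocc.sdo_time(rec, "tf")
        np.testing.assert_allclose(
            t.values, rec.residence["tf"].sum(axis=0) / 100.0)
        assert t.values.sum() == pytest.approx(
            tfocc.bound_time_fraction(rec, "tf"), abs=1e-9)

    def test_time_average_matches_stationary_oracle(self):
        lsc = toy_landscape([0.0, 1.0, 0.0])
        cfg = single_molecule_config(lsc, 3, move_probs=(0.5, 0.5, 0.0, 0.0),
                                     hop_range=1, t_end=2e5, seed=2)
        t = tfocc.sdo_time(tfocc.simulate(cfg), "tf")
        tau = np.array([1.0, np.e, 1.0])
        np.testing.assert_allclose(t.values / t.values.sum(),
                                   tau / tau.sum(), atol=0.02)

    def test_ensemble_sticky_molecule_always_bound(self):
        # k huge, dwell huge: every replicate sticks where it first lands,
        # so the ensemble track is a probability distribution over starts
        lsc = toy_landscape(np.zeros(10), tau0=1e9)
        cfg = single_molecule_config(lsc, 10, k_assoc=100.0, t_end=10.0, seed=3)
        snaps = tfocc.ensemble_snapshots(cfg, 50, base_seed=11)
        ens = tfocc.sdo_ensemble(snaps, "tf")
        assert ens.values.sum() == pytest.approx(1.0)
        assert ens.values.max() <= 1.0

    def test_ensemble_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tfocc.sdo_ensemble([], "tf")

    def test_hybrid_of_single_record_is_time_average(self):
        lsc = toy_landscape(np.zeros(6))
        cfg = single_molecule_config(lsc, 6, t_end=200.0, seed=4)
        rec = tfocc.simulate(cfg)
        np.testing.assert_allclose(tfocc.sdo_hybrid([rec], "tf").values,
                                   tfocc.sdo_time(rec, "tf").values)

    def test_hybrid_is_mean_of_tracks(self):
        lsc = toy_landscape(np.zeros(5))
        cfg = single_molecule_config(lsc, 5, t_end=300.0, seed=5)
        recs = tfocc.simulate_replicates(cfg, 3, base_seed=100)
        hybrid = tfocc.sdo_hybrid(recs, "tf")
        manual = np.mean([tfocc.sdo_time(r, "tf").values for r in recs], axis=0)
        np.testing.assert_allclose(hybrid.values, manual)

    def test_hybrid_mismatched_t_sim_rejected(self):
        lsc = toy_landscape(np.zeros(5))
        r1 = tfocc.simulate(single_molecule_config(lsc, 5, t_end=100.0))
        r2 = tfocc.simulate(single_molecule_config(lsc, 5, t_end=200.0))
        with pytest.raises(ValueError, match="t_sim"):
            tfocc.sdo_hybrid([r1, r2], "tf")


class TestNormalization:
    def test_log_max_by_construction(self):
        np.testing.assert_allclose(
            tfocc.normalize_log_max(track([1.0, math.exp(-1)])), [0.0, -1.0])

    def test_constant_track_all_zeros(self):
        np.testing.assert_allclose(tfocc.normalize_log_max(track([3, 3, 3])),
                                   0.0)

    def test_hand_values(self):
        np.testing.assert_allclose(
            tfocc.normalize_log_max(track([4.0, 2.0, 1.0])),
            [0.0, -math.log(2), -math.log(4)])

    def test_zeros_map_to_sentinel(self):
        out = tfocc.normalize_log_max(track([2.0, 0.0]))
        assert out[1] == -np.inf

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            tfocc.normalize_log_max(track([0.0, 0.0]))


class TestStrongSites:
    def test_fraction_one_selects_argmax(self):
        lsc = toy_landscape([1.0, 3.0, 2.0])
        assert tfocc.select_strong_sites(lsc, 1.0).tolist() == [1]

    def test_flat_landscape_selects_everything(self):
        lsc = toy_landscape(np.zeros(6))
        assert tfocc.select_strong_sites(lsc, 0.5).size == 6

    def test_half_max_filter(self):
        lsc = toy_landscape([10.0, 6.0, 2.0, 0.0])
        assert tfocc.select_strong_sites(lsc, 0.5).tolist() == [0, 1]

    def test_realized_percentage(self):
        lsc = toy_landscape([10.0, 6.0, 2.0, 0.0])
        assert tfocc.strong_site_percentage(lsc, 0.5) == pytest.approx(50.0)


class TestCompare:
    def test_identity_gives_unit_ratios(self):
        a = track([0.5, 0.2, 0.1], estimator="ado")
        res = tfocc.compare(a, a, sites=np.array([0, 1, 2]))
        np.testing.assert_allclose(res.ratios, 1.0)
        assert res.mean_ratio == pytest.approx(1.0)
        np.testing.assert_allclose(res.log_ratios, 0.0, atol=1e-12)

    def test_scaling_invariance(self):
        a = track([0.5, 0.2, 0.1])
        b = track([1.0, 0.4, 0.2])
        res = tfocc.compare(b, a, sites=np.array([0, 1, 2]))
        np.testing.assert_allclose(res.ratios, 1.0)

    def test_hand_vectors(self):
        ado_t = track([1.0, 0.5])
        sdo_t = track([1.0, 0.8])
        res = tfocc.compare(sdo_t, ado_t, sites=np.array([0, 1]))
        np.testing.assert_allclose(res.ratios, [1.0, 1.6])
        assert res.mean_ratio == pytest.approx(1.3)

    def test_zero_sdo_sites_excluded(self):
        res = tfocc.compare(track([1.0, 0.0, 0.5]), track([1.0, 0.5, 0.5]),
                            sites=np.array([0, 1, 2]))
        assert res.n_excluded == 1
        assert res.ratios.size == 2

    def test_all_zero_sdo_rejected(self):
        with pytest.raises(ValueError, match="non-zero"):
            tfocc.compare(track([1.0, 0.0]), track([1.0, 1.0]),
                          sites=np.array([1]))


class TestCounts:
    def test_no_exceedance_at_identity(self):
        a = track([1.0, 0.3, 0.2])
        assert tfocc.count_exceeding(a, a, phi=1.5) == 0

    def test_single_exceeding_site(self):
        sdo = track([1.0, 0.6])
        ado_t = track([1.0, 0.2])
        assert tfocc.count_exceeding(sdo, ado_t, phi=2.0) == 1

    def test_phi_to_zero_counts_nonzero_sdo(self):
        sdo = track([1.0, 0.0, 0.4])
        ado_t = track([1.0, 0.5, 0.5])
        assert tfocc.count_exceeding(sdo, ado_t, phi=1e-12) == 2

    def test_high_occupancy_examples(self):
        assert tfocc.count_high_occupancy(track([1.0, 0.6, 0.2]), 0.5) == 2
        assert tfocc.count_high_occupancy(track([1.0, 0.6, 0.2]), 1.0) == 1
        assert tfocc.count_high_occupancy(track([2.0, 2.0, 2.0]), 0.9) == 3

    def test_high_occupancy_all_zero_rejected(self):
        with pytest.raises(ValueError):
            tfocc.count_high_occupancy(track([0.0, 0.0]), 0.5)


class TestAffinityBands:
    def test_three_band_classification(self):
        lsc = toy_landscape([10.0, 5.0, 1.0])
        labels = tfocc.affinity_band_classification(
            np.array([0, 1, 2]), lsc, band_edges=(0.7, 0.3))
        assert labels == ["high", "medium", "non-specific"]

    def test_argmax_is_high_and_zero_is_nonspecific(self):
        lsc = toy_landscape([4.0, 0.0])
        labels = tfocc.affinity_band_classification(np.array([0, 1]), lsc)
        assert labels == ["high", "non-specific"]


class TestTrackInvariants:
    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            track([-0.1, 0.5])

    def test_tsv_round_trip(self, tmp_path):
        t = track([0.25, 0.5, 0.25])
        path = tmp_path / "t.tsv"
        t.to_tsv(path)
        import pandas as pd
        back = pd.read_csv(path, sep="\t")
        np.testing.assert_allclose(back["value"], t.values)
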