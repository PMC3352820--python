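"""Generator ground truth: invariants, determinism, and closed forms."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecoevo.growth import IsolateLabel
from ecoevo.synthetic import (
    evolve_isolates,
    evolved_configs,
    logistic_density,
    make_default_community,
    resource_fraction,
    simulate_dataset,
    simulate_growth_curve,
    simulate_null_dataset,
    simulate_serial_transfer,
    simulate_used_tea,
)


def mean_row_distance(U):
    return np.mean(
        [np.linalg.norm(U[i] - U[j])
         for i, j in itertools.combinations(range(U.shape[0]), 2)]
    )


class TestMakeDefaultCommunity:
    def test_overlap_guaranteed(self):
        cfg = make_default_community(4, 10, seed=1)
        shared = ((cfg.U > 0).sum(axis=0) >= 2).sum()
        assert shared >= 1

    def test_invariants_hold_small_case(self):
        cfg = make_default_community(2, 2, seed=7)
        assert cfg.U.min() >= 0 and cfg.U.max() <= 1
        assert cfg.P.min() >= 0 and cfg.base_medium.min() >= 0
        assert len(set(cfg.species_ids)) == 2

    def test_deterministic_for_same_seed(self):
        a = make_default_community(3, 8, seed=5)
        b = make_default_community(3, 8, seed=5)
        np.testing.assert_array_equal(a.U, b.U)
        np.testing.assert_array_equal(a.P, b.P)
        np.testing.assert_array_equal(a.base_medium, b.base_medium)

    @pytest.mark.parametrize("n_species,n_compounds", [(1, 5), (3, 1), (0, 0)])
    def test_rejects_degenerate_counts(self, n_species, n_compounds):
        with pytest.raises(ValueError):
            make_default_community(n_species, n_compounds)


class TestEvolveIsolates:
    def test_zero_effect_is_identity_for_all_treatments(self, community):
        for tr in ("ancestral", "monoculture", "polyculture"):
            out = evolve_isolates(community, tr, effect_size=0.0)
            np.testing.assert_array_equal(out.U, community.U)
            np.testing.assert_array_equal(out.P, community.P)
            np.testing.assert_array_equal(out.r, community.r)

    def test_polyculture_rows_diverge(self, community):
        poly = evolve_isolates(community, "polyculture", effect_size=1.0)
        assert mean_row_distance(poly.U) > mean_row_distance(community.U)

    def test_monoculture_rows_converge(self, community):
        mono = evolve_isolates(community, "monoculture", effect_size=1.0)
        sub = community.substrate_mask
        assert mean_row_distance(mono.U[:, sub]) <= mean_row_distance(
            community.U[:, sub]
        )

    def test_unknown_treatment_rejected(self, community):
        with pytest.raises(ValueError):
            evolve_isolates(community, "coculture")

    def test_ancestral_reference_rows_preserved(self, community):
        poly = evolve_isolates(community, "polyculture", effect_size=1.0)
        np.testing.assert_array_equal(poly.U_ref, community.U)


class TestUsedTea:
    def test_inactive_species_leaves_medium_unchanged(self, tiny_config):
        cfg = tiny_config
        cfg.U[0] = 0.0
        cfg.P[0] = 0.0
        out = simulate_used_tea(cfg, "A", cfg.base_medium)
        np.testing.assert_allclose(out, cfg.base_medium)

    def test_full_consumption_leaves_only_production(self, tiny_config):
        cfg = tiny_config
        cfg.U[0] = 1.0
        out = simulate_used_tea(cfg, "A", cfg.base_medium)
        np.testing.assert_allclose(out, cfg.P[0])

    def test_chaining_equals_double_application(self, tiny_config):
        cfg = tiny_config
        once = simulate_used_tea(cfg, "A", cfg.base_medium)
        chained = simulate_used_tea(cfg, "B", once)
        expected = once * (1.0 - cfg.U[1]) + cfg.P[1]
        np.testing.assert_allclose(chained, expected)

    def test_unknown_isolate_rejected(self, tiny_config):
        with pytest.raises(KeyError):
            simulate_used_tea(tiny_config, "Z", tiny_config.base_medium)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_output_nonnegative_for_random_configs(self, seed):
        cfg = make_default_community(3, 6, seed=seed)
        for sp in cfg.species_ids:
            assert simulate_used_tea(cfg, sp, cfg.base_medium).min() >= 0


class TestGrowthCurves:
    def test_infinite_capacity_gives_exact_exponential(self, tiny_config):
        cfg = tiny_config
        cfg.K = np.array([np.inf, np.inf])
        rows = simulate_growth_curve(
            cfg, IsolateLabel("A", "ancestral", 1), times_h=np.arange(0.0, 97.0, 24.0)
        )
        sample = rows[~rows.is_control].sort_values("time_h")
        od = sample.od600.to_numpy() - cfg.blank_od
        log2n = (od * cfg.cal_slope + cfg.cal_intercepts[0]) * np.log2(10.0)
        slopes = np.diff(log2n) / 1.0  # per day
        np.testing.assert_allclose(slopes, cfg.r[0], atol=1e-9)

    def test_no_consumable_resource_means_no_growth(self, tiny_config):
        cfg = tiny_config
        empty = np.zeros_like(cfg.base_medium)
        rows = simulate_growth_curve(cfg, IsolateLabel("A", "ancestral", 1), medium=empty)
        sample = rows[~rows.is_control]
        assert sample.od600.std() == pytest.approx(0.0, abs=1e-12)

    def test_fixed_seed_reproducible(self, community):
        kw = dict(isolate=IsolateLabel("A", "ancestral", 1), seed=3)
        pd.testing.assert_frame_equal(
            simulate_growth_curve(community, **kw),
            simulate_growth_curve(community, **kw),
        )

    def test_negative_medium_rejected(self, community):
        bad = community.base_medium.copy()
        bad[0] = -1.0
        with pytest.raises(ValueError):
            simulate_growth_curve(community, IsolateLabel("A", "ancestral", 1), medium=bad)

    def test_phi_monotone_in_consumed_compounds(self, community):
        med = community.base_medium.copy()
        base_phi = resource_fraction(community, 0, med * 0.5)
        med2 = med * 0.5
        consumed = np.argmax(community.U[0])
        med2[consumed] += 0.1
        assert resource_fraction(community, 0, med2) >= base_phi

    def test_logistic_saturates_at_capacity(self):
        n = logistic_density(1e6, 1e8, 5.0, np.array([100.0]))
        assert n[0] == pytest.approx(1e8, rel=1e-6)


class TestSerialTransfer:
    def test_full_regrowth_without_noise_is_fixed_point(self, tiny_config):
        log = simulate_serial_transfer(tiny_config, 10, 20.0, noise_sd=0.0)
        np.testing.assert_allclose(
            log.pre_density_per_ml, tiny_config.K[0], rtol=1e-12
        )

    def test_seed_determinism(self, community):
        a = simulate_serial_transfer(community, 15, 20.0, seed=2)
        b = simulate_serial_transfer(community, 15, 20.0, seed=2)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_dilution_rejected(self, community):
        with pytest.raises(ValueError):
            simulate_serial_transfer(community, 5, 1.0)


class TestNullDataset:
    def test_all_treatments_identical_truth(self, community):
        configs = evolved_configs(community, effect_size=0.0)
        for tr in ("monoculture", "polyculture"):
            np.testing.assert_array_equal(configs[tr].U, configs["ancestral"].U)
            np.testing.assert_array_equal(configs[tr].P, configs["ancestral"].P)

    def test_dataset_deterministic(self, community):
        a = simulate_null_dataset(
            community, seed=4, n_growth_replicates=2, n_peak_replicates=2,
            include_used_growth=False,
        )
        b = simulate_null_dataset(
            community, seed=4, n_growth_replicates=2, n_peak_replicates=2,
            include_used_growth=False,
        )
        for name in ("growth", "calibration", "peaks", "transfers", "respiration"):
            pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))


def test_dataset_write_round_trip(tmp_path, community):
    ds = simulate_dataset(
        community, effect_size=1.0, seed=1,
        n_growth_replicates=2, n_peak_replicates=2, include_used_growth=False,
    )
    paths = ds.write(tmp_path)
    assert sorted(p.name for p in paths.values()) == [
        "calibration.csv", "growth.csv", "manifest.txt", "peaks.csv",
        "respiration.csv", "transfers.csv",
    ]
    back = pd.read_csv(paths["peaks"])
    assert set(back.sample_id) == set(ds.peaks.sample_id)
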