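"""Peak-table processing, PCA, distance statistics, Monte Carlo tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecoevo.metabolomics import (
    DeltaProfile,
    PeakProfile,
    collapse_correlated_peaks,
    divergence_distance,
    evolution_distance,
    load_peak_table,
    net_change,
    pca_unscaled,
    permutation_test,
    profiles_to_frame,
    remove_contaminants,
)
from ecoevo.synthetic import evolved_configs, simulate_peak_table


def _delta(sid, values, species, treatment="ancestral", peaks=None):
    peaks = peaks or [f"p{i}" for i in range(len(values))]
    return DeltaProfile(sid, pd.Series(values, index=peaks, dtype=float),
                        species=species, treatment=treatment)


class TestLoadPeakTable:
    def test_minimal_table(self, small_peak_table):
        profiles = load_peak_table(small_peak_table)
        assert len(profiles) == 2
        assert list(profiles[0].peaks.index) == ["p1", "p2", "p3"]

    def test_duplicate_rows_rejected(self, small_peak_table):
        dup = pd.concat([small_peak_table, small_peak_table.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            load_peak_table(dup)

    def test_missing_peak_requires_zero_fill(self, small_peak_table):
        partial = small_peak_table.iloc[:-1]
        with pytest.raises(ValueError, match="missing"):
            load_peak_table(partial)
        profiles = load_peak_table(partial, zero_fill=True)
        assert profiles[1].peaks["p3"] == 0.0

    def test_generator_table_round_trips(self, community):
        configs = evolved_configs(community, effect_size=1.0, seed=3)
        table = simulate_peak_table(configs, n_replicates=2, seed=3,
                                    include_sequential=False)
        profiles = load_peak_table(table)
        frame = profiles_to_frame(profiles)
        assert frame.shape[0] == table.sample_id.nunique()
        back = frame.loc["A-ancestral-r1"]
        want = table[table.sample_id == "A-ancestral-r1"].set_index("peak_id")
        np.testing.assert_allclose(back[want.index], want.integral)


class TestContaminantRemoval:
    def test_named_peaks_removed(self, community):
        configs = evolved_configs(community, effect_size=0.0)
        profiles = load_peak_table(
            simulate_peak_table(configs, n_replicates=2, include_sequential=False)
        )
        n0 = profiles[0].peaks.size
        out = remove_contaminants(profiles, ["methanol", "acetonitrile"])
        assert out[0].peaks.size == n0 - 2

    def test_empty_list_is_identity(self, small_peak_table):
        profiles = load_peak_table(small_peak_table)
        out = remove_contaminants(profiles, [])
        assert out[0].peaks.equals(profiles[0].peaks)

    def test_cannot_empty_axis(self, small_peak_table):
        profiles = load_peak_table(small_peak_table)
        with pytest.raises(ValueError):
            remove_contaminants(profiles, ["p1", "p2", "p3"])


class TestCollapseCorrelated:
    def _profiles(self, X, peaks):
        return [
            PeakProfile(f"s{i}", pd.Series(row, index=peaks))
            for i, row in enumerate(X)
        ]

    def test_proportional_pair_merges(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(1, 2, size=6)
        X = np.column_stack([a, 0.5 * a, rng.uniform(1, 2, size=6)])
        out, groups = collapse_correlated_peaks(self._profiles(X, ["x", "y", "z"]))
        assert groups == [["x", "y"]]
        assert "x+y" in out[0].peaks.index
        np.testing.assert_allclose(out[0].peaks["x+y"], X[0, 0] + X[0, 1])

    def test_uncorrelated_table_unchanged(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(size=(8, 4))
        out, groups = collapse_correlated_peaks(
            self._profiles(X, list("abcd")), r_threshold=0.95
        )
        assert groups == []
        assert out[0].peaks.equals(self._profiles(X, list("abcd"))[0].peaks)

    def test_planted_three_peak_group_found(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(1, 3, size=10)
        X = np.column_stack(
            [a, 2.0 * a, 0.3 * a, rng.uniform(1, 3, size=10),
             rng.uniform(1, 3, size=10)]
        )
        _, groups = collapse_correlated_peaks(
            self._profiles(X, list("abcde"))
        )
        assert groups == [["a", "b", "c"]]

    def test_needs_three_samples(self):
        with pytest.raises(ValueError):
            collapse_correlated_peaks(
                self._profiles(np.ones((2, 3)), list("abc"))
            )


class TestNetChange:
    def test_zero_when_identical(self):
        p = PeakProfile("s", pd.Series({"a": 1.0, "b": 2.0}))
        assert (net_change(p, p).values == 0).all()

    def test_subtraction_sign_convention(self):
        before = PeakProfile("b", pd.Series({"a": 2.0, "b": 1.0}))
        after = PeakProfile("a", pd.Series({"a": 1.0, "b": 3.0}))
        delta = net_change(after, before)
        np.testing.assert_allclose(delta.values, [-1.0, 2.0])

    def test_generator_closed_form(self, tiny_config):
        from ecoevo.synthetic import simulate_used_tea

        cfg = tiny_config
        used = simulate_used_tea(cfg, "A", cfg.base_medium)
        after = PeakProfile("u", pd.Series(used, index=cfg.compound_ids))
        before = PeakProfile("b", pd.Series(cfg.base_medium, index=cfg.compound_ids))
        delta = net_change(after, before)
        np.testing.assert_allclose(
            delta.values, cfg.P[0] - cfg.U[0] * cfg.base_medium
        )

    def test_axis_mismatch_rejected(self):
        a = PeakProfile("a", pd.Series({"x": 1.0}))
        b = PeakProfile("b", pd.Series({"y": 1.0}))
        with pytest.raises(ValueError):
            net_change(a, b)


class TestPCA:
    def test_planted_direction_recovered(self):
        rng = np.random.default_rng(0)
        direction = np.array([3.0, 0.0, 4.0]) / 5.0
        t = rng.normal(size=20)
        X = np.outer(t, direction)
        deltas = [_delta(f"s{i}", row, "A") for i, row in enumerate(X)]
        res = pca_unscaled(deltas)
        cosine = abs(res.loadings["PC1"].to_numpy() @ direction)
        assert cosine > 0.999

    def test_isotropic_eigenvalues_close(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(4000, 2))
        deltas = [_delta(f"s{i}", row, "A") for i, row in enumerate(X)]
        res = pca_unscaled(deltas)
        assert res.eigenvalues[0] / res.eigenvalues[1] < 1.15

    def test_eigenvalue_sum_equals_total_variance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 6))
        deltas = [_delta(f"s{i}", row, "A") for i, row in enumerate(X)]
        res = pca_unscaled(deltas)
        total = X.var(axis=0, ddof=1).sum()
        assert res.eigenvalues.sum() == pytest.approx(total, abs=1e-8)

    def test_reconstruction_from_all_components(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 4))
        deltas = [_delta(f"s{i}", row, "A") for i, row in enumerate(X)]
        res = pca_unscaled(deltas)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(recon, X - X.mean(axis=0), atol=1e-8)


class TestDistances:
    def test_evolution_zero_for_identical_sets(self):
        anc = [_delta("a", [1.0, 2.0], "A"), _delta("b", [0.0, 1.0], "B")]
        evo = [_delta("a2", [1.0, 2.0], "A", "monoculture"),
               _delta("b2", [0.0, 1.0], "B", "monoculture")]
        assert evolution_distance(anc, evo) == 0.0

    def test_evolution_hand_case(self):
        anc = [_delta("a", [0.0, 0.0], "A"), _delta("b", [1.0, 1.0], "B")]
        evo = [_delta("a2", [3.0, 4.0], "A", "monoculture"),
               _delta("b2", [1.0, 1.0], "B", "monoculture")]
        assert evolution_distance(anc, evo) == pytest.approx(2.5)

    def test_species_sets_must_match(self):
        anc = [_delta("a", [0.0], "A")]
        evo = [_delta("b", [0.0], "B", "monoculture")]
        with pytest.raises(ValueError):
            evolution_distance(anc, evo)

    def test_divergence_zero_when_identical(self):
        profs = [_delta(s, [2.0, 2.0], s) for s in "ABC"]
        assert divergence_distance(profs) == 0.0

    def test_divergence_hand_case(self):
        profs = [_delta("a", [0.0, 0.0], "A"), _delta("b", [3.0, 0.0], "B"),
                 _delta("c", [0.0, 4.0], "C")]
        assert divergence_distance(profs) == pytest.approx(4.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(shift=st.floats(-50, 50))
    def test_translation_invariance(self, shift):
        profs = [_delta("a", [0.0, 1.0], "A"), _delta("b", [3.0, 2.0], "B"),
                 _delta("c", [1.0, 4.0], "C")]
        shifted = [_delta(p.sample_id, p.values.to_numpy() + shift, p.species)
                   for p in profs]
        assert divergence_distance(shifted) == pytest.approx(
            divergence_distance(profs), abs=1e-9
        )


def oracle_exhaustive_p(profiles, stat):
    """Independent enumeration oracle over all within-species orders.

    Species are the blocking factor: profiles move only among the treatment
    slots of their own species, matching the restricted shuffle the test
    uses.
    """
    X = np.array([p.values.to_numpy() for p in profiles])
    labels = [(p.species, p.treatment) for p in profiles]
    species = [p.species for p in profiles]
    obs = stat(X, labels)
    groups = [
        [i for i, s in enumerate(species) if s == sp]
        for sp in sorted(set(species))
    ]
    draws = []
    for combo in itertools.product(
        *(itertools.permutations(g) for g in groups)
    ):
        order = np.empty(len(profiles), dtype=int)
        for g, perm in zip(groups, combo):
            order[g] = perm
        draws.append(stat(X[order], labels))
    draws = np.array(draws)
    eps = 1e-9 * max(1.0, abs(obs))
    ge = np.sum(draws >= obs - eps)
    le = np.sum(draws <= obs + eps)
    return min(1.0, 2.0 * min(ge, le) / draws.size)


def _mean_by(X, labels, want):
    rows = [x for x, lab in zip(X, labels) if lab == want]
    return np.mean(rows, axis=0)


class TestPermutationTest:
    def test_identical_profiles_give_p_one(self):
        profs = [_delta(f"s{i}", [1.0, 1.0], sp, tr)
                 for i, (sp, tr) in enumerate(
                     itertools.product("AB", ["ancestral", "monoculture"]))]
        res = permutation_test("evolution_distance", profs, B=50, seed=0)
        assert res.p_two_tailed == 1.0

    def test_enumeration_mode_matches_oracle_exactly(self):
        # 2 species x (2 ancestral + 1 evolved replicate) = 6 profiles;
        # within-species enumeration space is 3! * 3! = 36 orders
        rng = np.random.default_rng(5)
        profs = []
        for sp in "AB":
            for tr, reps in (("ancestral", 2), ("monoculture", 1)):
                for i in range(reps):
                    profs.append(
                        _delta(f"{sp}-{tr}-{i}", rng.normal(size=3), sp, tr)
                    )

        def stat(X, labels):
            species = sorted({s for s, _ in labels})
            return np.mean(
                [np.linalg.norm(_mean_by(X, labels, (s, "ancestral"))
                                - _mean_by(X, labels, (s, "monoculture")))
                 for s in species]
            )

        res = permutation_test("evolution_distance", profs, exhaustive=True)
        assert res.p_two_tailed == pytest.approx(
            oracle_exhaustive_p(profs, stat), abs=0
        )
        assert res.B == 36

    def test_null_draw_count_and_p_bounds(self):
        rng = np.random.default_rng(6)
        profs = [
            _delta(f"{sp}{tr}{i}", rng.normal(size=4), sp, tr)
            for sp in "ABC" for tr in ("ancestral", "polyculture")
            for i in (1, 2)
        ]
        res = permutation_test("divergence_distance", profs, B=199, seed=1,
                               focal_treatment="polyculture")
        assert res.B == 199 and len(res.null_draws) == 199
        assert 1.0 / 200.0 <= res.p_two_tailed <= 1.0

    def test_pairwise_distance_multiset_is_permutation_invariant(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(6, 3))
        d0 = sorted(
            np.linalg.norm(X[i] - X[j])
            for i, j in itertools.combinations(range(6), 2)
        )
        order = rng.permutation(6)
        d1 = sorted(
            np.linalg.norm(X[order][i] - X[order][j])
            for i, j in itertools.combinations(range(6), 2)
        )
        np.testing.assert_allclose(d0, d1)

    def test_unknown_statistic_rejected(self):
        profs = [_delta("a", [0.0], "A"), _delta("b", [1.0], "B")]
        with pytest.raises(ValueError):
            permutation_test("median_shift", profs)
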