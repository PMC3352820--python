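"""Repeated-simulation studies: calibration of the statistical machinery.

Each function runs many independent synthetic experiments against the
generator's ground truth and reports an operating characteristic — type-I
error of the Monte Carlo tests under the null generator, power of the
divergence test, sign recovery of the interaction network and cross-feeding
correlation, and recovery error of the V_MAX and OD-calibration estimators.
These are the package's own validation experiments; the same functions back
the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._seeding import child_seed
from .crossfeeding import build_crossfeed_table, correlation_by_treatment
from .growth import IsolateLabel, blank_correct, vmax_table
from .interactions import interaction_table
from .metabolomics import permutation_test
from .synthetic import (
    evolved_configs,
    make_default_community,
    resource_fraction,
    simulate_calibration_table,
    simulate_delta_profiles,
    simulate_growth_curve,
    simulate_sequential_assays,
    simulate_used_tea,
)

__all__ = [
    "type_i_error_study",
    "divergence_power_study",
    "crossfeed_sign_study",
    "vmax_recovery_study",
    "calibration_coverage_study",
    "network_sign_recovery_study",
]

_STUDY_SPECIES = 4
_STUDY_COMPOUNDS = 10


def _null_profiles(seed: int, n_replicates: int = 3):
    cfg = make_default_community(_STUDY_SPECIES, _STUDY_COMPOUNDS,
                                 seed=child_seed(seed, "community"))
    configs = evolved_configs(cfg, effect_size=0.0)
    pool = {tr: configs[tr] for tr in ("ancestral", "polyculture")}
    return simulate_delta_profiles(pool, n_replicates=n_replicates,
                                   seed=child_seed(seed, "profiles"))


def type_i_error_study(
    n_datasets: int = 500, B: int = 999, alpha: float = 0.05, seed: int = 0
) -> dict[str, float]:
    """Rejection rates of both Monte Carlo tests under the null generator.

    Every dataset is drawn with effect_size = 0 (all treatments share the
    ground truth), so rejections are false positives; calibrated tests land
    near ``alpha``.
    """
    rejections = {"evolution_distance": 0, "divergence_distance": 0}
    for i in range(n_datasets):
        profiles = _null_profiles(child_seed(seed, "t1", i))
        for stat in rejections:
            res = permutation_test(
                stat, profiles, B=B, seed=child_seed(seed, "t1", i, stat),
                focal_treatment="polyculture",
            )
            rejections[stat] += res.p_two_tailed < alpha
    return {k: v / n_datasets for k, v in rejections.items()}


def divergence_power_study(
    n_reps: int = 200, B: int = 999, alpha: float = 0.05,
    effect_size: float = 1.0, seed: int = 0,
) -> float:
    """Fraction of synthetic experiments where the divergence test rejects.

    Polyculture evolution at the default effect size drives between-species
    divergence well above the ancestral level; the study reports how often
    the permutation test detects it.
    """
    hits = 0
    for i in range(n_reps):
        s = child_seed(seed, "power", i)
        cfg = make_default_community(_STUDY_SPECIES, _STUDY_COMPOUNDS,
                                     seed=child_seed(s, "community"))
        configs = evolved_configs(cfg, effect_size=effect_size)
        pool = {tr: configs[tr] for tr in ("ancestral", "polyculture")}
        profiles = simulate_delta_profiles(pool, n_replicates=3,
                                           seed=child_seed(s, "profiles"))
        res = permutation_test(
            "divergence_distance", profiles, B=B,
            seed=child_seed(s, "test"), focal_treatment="polyculture",
        )
        hits += res.p_two_tailed < alpha
    return hits / n_reps


def crossfeed_sign_study(
    n_reps: int = 100, effect_size: float = 1.0, seed: int = 0
) -> dict[str, float]:
    """Sign stability of the polyculture production-consumption correlation."""
    rs = []
    for i in range(n_reps):
        s = child_seed(seed, "crossfeed", i)
        cfg = make_default_community(_STUDY_SPECIES, _STUDY_COMPOUNDS,
                                     seed=child_seed(s, "community"))
        configs = evolved_configs(cfg, effect_size=effect_size)
        assays = simulate_sequential_assays(configs, n_replicates=5,
                                            seed=child_seed(s, "assays"))
        evolved = [a for a in assays if a.treatment != "ancestral"]
        ancestral = [a for a in assays if a.treatment == "ancestral"]
        records = build_crossfeed_table(evolved, ancestral)
        corr = correlation_by_treatment(records).set_index("treatment")
        rs.append(float(corr.loc["polyculture", "r"]))
    rs = np.array(rs)
    return {
        "fraction_negative": float(np.mean(rs < 0)),
        "mean_r": float(rs.mean()),
    }


def vmax_recovery_study(
    n_curves: int = 200, seed: int = 0
) -> dict[str, float]:
    """V_MAX estimator recovery against the generator's growth-rate truth.

    Noiseless exponential curves must return the generating rate to
    numerical precision; curves with the default OD noise are summarised by
    the median absolute relative error.
    """
    cfg = make_default_community(_STUDY_SPECIES, _STUDY_COMPOUNDS,
                                 seed=child_seed(seed, "community"))
    model = cfg.calibration_model()
    times = np.array([0.0, 24.0, 48.0])

    # exact branch: no noise, no density ceiling
    exact = cfg.copy()
    exact.noise_od = 0.0
    exact.K = np.full(len(cfg.species_ids), np.inf)
    worst = 0.0
    for j, sp in enumerate(exact.species_ids):
        rows = simulate_growth_curve(exact, IsolateLabel(sp, "ancestral", 1),
                                     times_h=times)
        table = vmax_table(blank_correct(rows, epsilon=1e-12), model)
        worst = max(worst, abs(table.loc[0, "vmax"] - exact.r[j]))

    errors = []
    noisy = cfg.copy()
    noisy.K = np.full(len(cfg.species_ids), np.inf)
    for i in range(n_curves):
        sp = noisy.species_ids[i % len(noisy.species_ids)]
        j = noisy.index(sp)
        rows = simulate_growth_curve(
            noisy, IsolateLabel(sp, "ancestral", 1 + i), times_h=times,
            seed=child_seed(seed, "noisy", i),
        )
        table = vmax_table(blank_correct(rows, epsilon=1e-12), model)
        errors.append(abs(table.loc[0, "vmax"] - noisy.r[j]) / noisy.r[j])
    return {
        "noiseless_max_abs_error": float(worst),
        "median_abs_relative_error": float(np.median(errors)),
    }


def calibration_coverage_study(
    n_reps: int = 500, seed: int = 0, level: float = 0.95
) -> float:
    """Coverage of the shared-slope confidence interval over noisy refits."""
    cfg = make_default_community(_STUDY_SPECIES, _STUDY_COMPOUNDS,
                                 seed=child_seed(seed, "community"))
    import statsmodels.formula.api as smf

    hits = 0
    for i in range(n_reps):
        rows = simulate_calibration_table(cfg, seed=child_seed(seed, "cal", i))
        df = rows.copy()
        df["_y"] = np.log10(df["colonies_per_ml"])
        fit = smf.ols("_y ~ C(species) + od600", data=df).fit()
        lo, hi = fit.conf_int(alpha=1 - level).loc["od600"]
        hits += lo <= cfg.cal_slope <= hi
    return hits / n_reps


def _true_edge_sign(cfg_anc, cfg_tr, donor: str, recipient: str,
                    min_effect: float = 0.1) -> str | None:
    """Noiseless expected edge sign; None when truly near-neutral."""
    i = cfg_tr.index(recipient)
    used = simulate_used_tea(cfg_tr, donor, cfg_tr.base_medium)
    phi_used = resource_fraction(cfg_tr, i, used)
    phi_fresh = resource_fraction(cfg_tr, i, cfg_tr.base_medium)
    diff = cfg_tr.r[i] * (phi_used - phi_fresh)
    if abs(diff) < min_effect:
        return None
    return "negative" if diff < 0 else "positive"


def network_sign_recovery_study(
    n_reps: int = 100, n_replicates: int = 9, B: int = 999,
    effect_size: float = 1.0, seed: int = 0,
) -> dict[str, float]:
    """Edge-sign recovery of the interaction network at default noise.

    For each replicate community the recovered edge signs (ancestral and
    polyculture treatments) are compared against the noiseless expected
    signs; edges whose true growth-rate effect is within 0.1 doublings/day
    of zero have no defined truth and are excluded from scoring.
    """
    times = np.array([0.0, 24.0, 48.0])
    correct = total = 0
    for rep in range(n_reps):
        s = child_seed(seed, "network", rep)
        cfg = make_default_community(_STUDY_SPECIES, _STUDY_COMPOUNDS,
                                     seed=child_seed(s, "community"))
        configs = evolved_configs(cfg, effect_size=effect_size)
        for tr in ("ancestral", "polyculture"):
            c = configs[tr]
            frames = []
            media = [("unused", c.base_medium)] + [
                (f"used_by:{d}", simulate_used_tea(c, d, c.base_medium))
                for d in c.species_ids
            ]
            for sub_name, medium in media:
                for k in range(1, n_replicates + 1):
                    for col, sp in enumerate(c.species_ids, start=1):
                        if sub_name == f"used_by:{sp}":
                            continue
                        frames.append(
                            simulate_growth_curve(
                                c, IsolateLabel(sp, tr, k), medium=medium,
                                times_h=times, seed=child_seed(s, tr),
                                substrate=sub_name,
                                plate=f"{sub_name}-{k}", column=col,
                            )
                        )
            table = vmax_table(
                blank_correct(pd.concat(frames, ignore_index=True)),
                cfg.calibration_model(),
            )
            edges = interaction_table(table, tr, B=B,
                                      seed=child_seed(s, tr, "edges"),
                                      n_boot=0)
            for e in edges:
                truth = _true_edge_sign(configs["ancestral"], c,
                                        e.donor, e.recipient)
                if truth is None:
                    continue
                total += 1
                correct += e.sign == truth
    return {
        "fraction_correct": correct / total if total else float("nan"),
        "n_scored_edges": float(total),
    }
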