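"""Synthetic experiment generator.

Emulates a serial-transfer evolution experiment with heterotrophic bacteria
on a leaf-extract medium: a ground-truth community (growth parameters,
per-compound consumption/production) produces all five analysis inputs —
growth-assay OD600 plates, an OD/colony-count calibration table, NMR-style
peak tables of spent media, serial-transfer logs, and colorimetric
respiration plates. Nothing here is an estimate of any real system; the
generator exists so that every downstream statistic can be tested against a
known truth.

Model sketch
------------
* The medium is a vector of compound amounts. The first ~half are substrates
  present in the base medium; the rest are waste products absent from it.
* Species ``i`` consumes fraction ``U[i, c]`` of compound ``c`` and adds
  ``P[i, c]`` of it per growth cycle: spent ("used") medium is
  ``medium * (1 - U[i]) + P[i]``.
* Growth is logistic with rate ``rho = r * ln2 * phi(medium)`` where
  ``phi = sum_c U[i, c] * medium[c] / sum_c U_ref[i, c] * base[c]`` clamped
  to [0, 1]; ``U_ref`` is the species' ancestral consumption row, so evolved
  isolates that shifted consumption onto other species' waste products can
  grow *faster* on spent medium than on fresh medium (facilitation) while
  growing slower on fresh medium (the adaptation trade-off).
* Evolution treatments transform (U, P, r): monoculture isolates converge in
  consumption and speed up; polyculture isolates specialise (each substrate
  is kept by its strongest consumer, dropped by the rest), gain consumption
  of other species' waste products with weight ``coupling * effect_size``,
  and produce more waste. ``effect_size = 0`` is an exact identity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeding import child_rng
from .growth import TREATMENTS, CalibrationModel, IsolateLabel

__all__ = [
    "CommunityConfig",
    "SyntheticDataset",
    "make_default_community",
    "evolve_isolates",
    "resource_fraction",
    "logistic_density",
    "simulate_growth_curve",
    "simulate_used_tea",
    "simulate_serial_transfer",
    "simulate_delta_profiles",
    "simulate_dataset",
    "simulate_null_dataset",
]

BASE_SPECIES_LABEL = "none"
BASE_TREATMENT_LABEL = "base_medium"

_SUBSTRATE_NAMES = [
    "glucose", "choline", "formate", "succinate", "trehalose",
    "xylose", "maltose", "arabinose", "fructose", "mannose",
]
_WASTE_NAMES = [
    "acetate", "lactate", "pyruvate", "ethanol", "propionate",
    "butyrate", "glycerol", "citrate", "malate", "fumarate",
]

#: default MicroResp-style indicator calibration (A, B, D); configuration,
#: not an assertion about any instrument
DEFAULT_RESPIRATION_CALIBRATION = (-0.2265, -1.606, -6.771)


@dataclass
class CommunityConfig:
    """Ground truth for one community (one evolutionary state)."""

    species_ids: list[str]
    compound_ids: list[str]
    base_medium: np.ndarray          # amount of each compound in fresh medium
    r: np.ndarray                    # intrinsic growth rate, doublings/day
    K: np.ndarray                    # carrying capacity, cells/ml
    U: np.ndarray                    # consumption fractions, species x compound
    P: np.ndarray                    # production amounts, species x compound
    coupling: float = 1.0            # kappa: cross-feeding uptake weight
    noise_od: float = 0.01           # sd of OD600 measurement noise
    noise_peak: float = 0.05         # sd of peak-integral noise
    seed: int = 0
    # measurement-layer truth (enough to invert every assay)
    cal_slope: float = 3.0
    cal_intercepts: np.ndarray | None = None   # log10 cells/ml at OD 0
    n0: float = 1e6                  # inoculation density, cells/ml
    blank_od: float = 0.05           # sterile-medium OD600
    U_ref: np.ndarray | None = None  # ancestral consumption rows (phi denominator)
    is_substrate: np.ndarray | None = None  # compounds natively in the medium

    def __post_init__(self) -> None:
        self.base_medium = np.asarray(self.base_medium, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        self.K = np.asarray(self.K, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        s, c = len(self.species_ids), len(self.compound_ids)
        if len(set(self.species_ids)) != s:
            raise ValueError("species_ids must be unique")
        if self.U.shape != (s, c) or self.P.shape != (s, c):
            raise ValueError("U and P must be species x compound")
        if self.base_medium.shape != (c,):
            raise ValueError("base_medium must have one entry per compound")
        if np.any(self.U < 0) or np.any(self.U > 1):
            raise ValueError("U entries must lie in [0, 1]")
        for name in ("P", "base_medium", "r", "K"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be non-negative")
        if min(self.coupling, self.noise_od, self.noise_peak) < 0:
            raise ValueError("coupling and noise terms must be non-negative")
        if self.cal_intercepts is None:
            self.cal_intercepts = 5.5 + 0.15 * np.arange(s)
        self.cal_intercepts = np.asarray(self.cal_intercepts, dtype=float)
        if self.U_ref is None:
            self.U_ref = self.U.copy()
        self.U_ref = np.asarray(self.U_ref, dtype=float)
        if self.is_substrate is None:
            self.is_substrate = self.base_medium > 0
        self.is_substrate = np.asarray(self.is_substrate, dtype=bool)

    # -- helpers -----------------------------------------------------------
    def index(self, species: str) -> int:
        try:
            return self.species_ids.index(species)
        except ValueError:
            raise KeyError(f"species {species!r} not in config") from None

    def copy(self) -> "CommunityConfig":
        return dataclasses.replace(
            self,
            species_ids=list(self.species_ids),
            compound_ids=list(self.compound_ids),
            base_medium=self.base_medium.copy(),
            r=self.r.copy(),
            K=self.K.copy(),
            U=self.U.copy(),
            P=self.P.copy(),
            cal_intercepts=self.cal_intercepts.copy(),
            U_ref=self.U_ref.copy(),
            is_substrate=self.is_substrate.copy(),
        )

    @property
    def substrate_mask(self) -> np.ndarray:
        return self.is_substrate

    def calibration_model(self) -> CalibrationModel:
        """The generator's own OD calibration as an analysis-layer model."""
        return CalibrationModel(
            slope=self.cal_slope,
            intercepts={
                sp: float(a) for sp, a in zip(self.species_ids, self.cal_intercepts)
            },
        )


@dataclass
class SyntheticDataset:
    """The five input tables plus the ground truth that generated them."""

    growth: pd.DataFrame
    calibration: pd.DataFrame
    peaks: pd.DataFrame
    transfers: pd.DataFrame
    respiration: pd.DataFrame
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the five CSVs plus a key-value manifest; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("growth", "calibration", "peaks", "transfers", "respiration"):
            p = outdir / f"{name}.csv"
            getattr(self, name).to_csv(p, index=False)
            paths[name] = p
        manifest = outdir / "manifest.txt"
        cfg: CommunityConfig = self.truth["ancestral"]
        lines = [
            f"seed: {self.truth['seed']}",
            f"effect_size: {self.truth['effect_size']}",
            f"species: {','.join(cfg.species_ids)}",
            f"compounds: {','.join(cfg.compound_ids)}",
            f"coupling: {cfg.coupling}",
            f"noise_od: {cfg.noise_od}",
            f"noise_peak: {cfg.noise_peak}",
        ]
        manifest.write_text("\n".join(lines) + "\n", encoding="utf-8")
        paths["manifest"] = manifest
        return paths


# ---------------------------------------------------------------------------
# community construction and in-silico evolution


def make_default_community(
    n_species: int, n_compounds: int, seed: int = 0
) -> CommunityConfig:
    """A random community with guaranteed consumption overlap among species.

    Substrates (present in the base medium) make up at least half of the
    compounds; every species consumes substrate 0, so ancestral spent-medium
    interactions are negative. Each species produces one characteristic
    waste compound that is absent from the base medium.
    """
    if n_species < 2 or n_compounds < 2:
        raise ValueError("need at least 2 species and 2 compounds")
    rng = child_rng(seed, "community")
    n_sub = max(1, (n_compounds + 1) // 2)
    n_waste = n_compounds - n_sub

    def _names(pool, n, prefix):
        return [pool[i] if i < len(pool) else f"{prefix}{i + 1:02d}" for i in range(n)]

    compounds = _names(_SUBSTRATE_NAMES, n_sub, "substrate") + _names(
        _WASTE_NAMES, n_waste, "waste"
    )
    species = [chr(ord("A") + i) if i < 26 else f"S{i}" for i in range(n_species)]

    U = np.zeros((n_species, n_compounds))
    U[:, 0] = rng.uniform(0.4, 0.9, size=n_species)  # shared core substrate
    for c in range(1, n_sub):
        consumers = rng.random(n_species) < 0.6
        U[consumers, c] = rng.uniform(0.3, 0.9, size=int(consumers.sum()))

    # one characteristic waste product per species (distinct while enough
    # waste compounds exist), so metabolic footprints are species-resolved
    P = np.zeros((n_species, n_compounds))
    if n_waste > 0:
        for i in range(n_species):
            w = n_sub + (i % n_waste)
            P[i, w] = rng.uniform(0.4, 0.9)

    base = np.zeros(n_compounds)
    base[:n_sub] = rng.uniform(0.8, 1.5, size=n_sub)
    base[n_sub:] = 0.05  # trace fermentation products in the leaf extract
    is_substrate = np.zeros(n_compounds, dtype=bool)
    is_substrate[:n_sub] = True

    return CommunityConfig(
        species_ids=species,
        compound_ids=compounds,
        base_medium=base,
        r=rng.uniform(1.5, 2.5, size=n_species),
        K=10 ** rng.uniform(8.3, 9.0, size=n_species),
        U=U,
        P=P,
        seed=int(seed),
        is_substrate=is_substrate,
    )


def evolve_isolates(
    config: CommunityConfig,
    treatment: str,
    effect_size: float = 1.0,
    seed: int = 0,
) -> CommunityConfig:
    """Ground-truth parameters of isolates after evolution under a treatment.

    ancestral    -> unchanged copy.
    monoculture  -> growth rate increased; consumption rows pulled toward the
                    community mean (convergence).
    polyculture  -> substrate specialisation (the strongest consumer of each
                    substrate keeps/raises it, the rest largely drop it),
                    cross-feeding uptake added on compounds other species
                    produce (weight ``coupling * effect_size``), and waste
                    production increased.

    ``effect_size = 0`` returns the input unchanged for every treatment; the
    ancestral consumption rows are preserved in ``U_ref``.
    """
    if treatment not in TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}")
    if effect_size < 0:
        raise ValueError("effect_size must be non-negative")
    out = config.copy()
    out.U_ref = config.U.copy()
    if treatment == "ancestral" or effect_size == 0:
        return out

    e = float(effect_size)
    w = min(1.0, 0.4 * e)
    if treatment == "monoculture":
        mean_row = config.U.mean(axis=0, keepdims=True)
        U = np.clip((1 - w) * config.U + w * mean_row, 0.0, 1.0)
        # weak waste economy: monoculture isolates also gain a little
        # production and uptake of by-products, far below polyculture
        gain = min(0.9, 0.15 * config.coupling * e)
        if gain > 0:
            for i in range(len(config.species_ids)):
                others = np.delete(config.P, i, axis=0)
                produced = others.max(axis=0) > 0
                U[i, produced] = np.clip(U[i, produced] + gain, 0.0, 1.0)
        out.U = U
        out.P = config.P * (1.0 + 0.2 * min(1.0, e))
        out.r = config.r * (1.0 + 0.25 * e)
        return out

    # polyculture
    sub = config.substrate_mask
    U = config.U.copy()
    if sub.any():
        cols = np.where(sub)[0]
        winners = np.argmax(config.U[:, cols], axis=0)
        boost = 0.3 * min(1.0, e)
        drop = 1.0 - 0.9 * min(1.0, e)
        for c, win in zip(cols, winners):
            keep = U[win, c]
            U[:, c] *= drop
            U[win, c] = min(1.0, keep + boost)
    # consumption of other species' waste products (cross-feeding)
    gain = min(0.9, 0.7 * config.coupling * e)
    if gain > 0:
        for i in range(len(config.species_ids)):
            others = np.delete(config.P, i, axis=0)
            produced = others.max(axis=0) > 0
            U[i, produced] = np.clip(U[i, produced] + gain, 0.0, 1.0)
    out.U = U
    out.P = config.P * (1.0 + 0.8 * min(1.0, e))
    return out


# ---------------------------------------------------------------------------
# growth curves


def resource_fraction(
    config: CommunityConfig, species_index: int, medium: np.ndarray
) -> float:
    """phi: consumable resource in ``medium`` relative to the ancestral
    consumable budget on fresh base medium, clamped to [0, 1]."""
    medium = np.asarray(medium, dtype=float)
    if np.any(medium < 0):
        raise ValueError("medium amounts must be non-negative")
    denom = float(config.U_ref[species_index] @ config.base_medium)
    if denom <= 0:
        return 0.0
    return float(np.clip(config.U[species_index] @ medium / denom, 0.0, 1.0))


def logistic_density(
    n0: float, K: float, rho: float, t_days: np.ndarray
) -> np.ndarray:
    """N(t) = K n0 e^{rho t} / (K + n0 (e^{rho t} - 1)); exponential if K = inf."""
    t_days = np.asarray(t_days, dtype=float)
    if not np.isfinite(K):
        return n0 * np.exp(rho * t_days)
    g = np.exp(rho * t_days)
    return K * n0 * g / (K + n0 * (g - 1.0))


def simulate_growth_curve(
    config: CommunityConfig,
    isolate: IsolateLabel,
    medium: np.ndarray | None = None,
    times_h: np.ndarray = (0.0, 24.0, 48.0, 72.0, 96.0),
    seed: int = 0,
    *,
    substrate: str = "unused",
    plate: str = "P1",
    column: int = 1,
    include_controls: bool = True,
) -> pd.DataFrame:
    """Assay rows (sample well + matched sterile control) for one isolate.

    ``config`` must already carry the isolate's evolved parameters; growth
    is logistic with rate ``r * ln2 * phi(medium)`` and the OD600 readout
    inverts the calibration line and adds the sterile-medium blank plus
    Gaussian noise.
    """
    times_h = np.asarray(times_h, dtype=float)
    if np.any(times_h < 0) or np.any(np.diff(times_h) <= 0):
        raise ValueError("times must be non-negative and sorted")
    if medium is None:
        medium = config.base_medium
    medium = np.asarray(medium, dtype=float)
    if medium.shape != config.base_medium.shape:
        raise ValueError("medium must have one entry per compound")
    i = config.index(isolate.species)
    phi = resource_fraction(config, i, medium)
    rho = float(config.r[i]) * np.log(2.0) * phi
    dens = logistic_density(config.n0, float(config.K[i]), rho, times_h / 24.0)
    od_true = (np.log10(dens) - config.cal_intercepts[i]) / config.cal_slope

    rng = child_rng(
        seed, "growth", isolate.species, isolate.treatment, isolate.replicate,
        substrate, plate, column,
    )
    rows = []
    noise = rng.normal(0.0, config.noise_od, size=times_h.size)
    for t, od, eps in zip(times_h, od_true, noise):
        rows.append(
            {
                "plate": plate,
                "well": f"A{column}",
                "column": column,
                "species": isolate.species,
                "treatment": isolate.treatment,
                "replicate": isolate.replicate,
                "substrate": substrate,
                "time_h": float(t),
                "od600": float(od + config.blank_od + eps),
                "is_control": False,
            }
        )
    if include_controls:
        cnoise = rng.normal(0.0, config.noise_od, size=times_h.size)
        for t, eps in zip(times_h, cnoise):
            rows.append(
                {
                    "plate": plate,
                    "well": f"H{column}",
                    "column": column,
                    "species": "sterile",
                    "treatment": isolate.treatment,
                    "replicate": 0,
                    "substrate": substrate,
                    "time_h": float(t),
                    "od600": float(config.blank_od + eps),
                    "is_control": True,
                }
            )
    return pd.DataFrame.from_records(rows)


# ---------------------------------------------------------------------------
# spent medium and peak tables


def simulate_used_tea(
    config: CommunityConfig, isolate: IsolateLabel | str, medium: np.ndarray
) -> np.ndarray:
    """Medium after growth of one isolate: ``medium * (1 - U[i]) + P[i]``."""
    medium = np.asarray(medium, dtype=float)
    if np.any(medium < 0):
        raise ValueError("medium amounts must be non-negative")
    species = isolate.species if isinstance(isolate, IsolateLabel) else isolate
    i = config.index(species)
    return medium * (1.0 - config.U[i]) + config.P[i]


def _noisy(values: np.ndarray, rng: np.random.Generator, sd: float) -> np.ndarray:
    return np.maximum(values + rng.normal(0.0, sd, size=values.shape), 0.0)


def simulate_delta_profiles(
    configs: dict[str, CommunityConfig],
    n_replicates: int = 3,
    seed: int = 0,
):
    """Net-change profiles (spent minus fresh medium) per isolate.

    Returns a list of :class:`ecoevo.metabolomics.DeltaProfile`; the
    noiseless truth for species ``i`` is ``P[i] - U[i] * base``. This is the
    light-weight path used by the repeated-simulation studies.
    """
    from .metabolomics import DeltaProfile

    profiles = []
    for tr, cfg in configs.items():
        base = cfg.base_medium
        for i, sp in enumerate(cfg.species_ids):
            truth = cfg.P[i] - cfg.U[i] * base
            for rep in range(1, n_replicates + 1):
                rng = child_rng(seed, "delta", tr, sp, rep)
                noisy = truth + rng.normal(0.0, cfg.noise_peak, size=truth.shape)
                profiles.append(
                    DeltaProfile(
                        sample_id=f"{sp}-{tr}-r{rep}",
                        values=pd.Series(noisy, index=cfg.compound_ids),
                        species=sp,
                        treatment=tr,
                        replicate=rep,
                    )
                )
    return profiles


def _peak_rows(
    sample_id: str,
    values: pd.Series,
    meta: dict,
    rng: np.random.Generator,
    sd: float,
    *,
    contaminants: bool,
    split_peak_of: str | None,
) -> list[dict]:
    vals = pd.Series(_noisy(values.to_numpy(), rng, sd), index=values.index)
    if split_peak_of is not None and split_peak_of in vals.index:
        # a second resonance of the same compound: proportional + tiny noise
        vals[f"{split_peak_of}_b"] = max(
            0.0, 0.65 * vals[split_peak_of] + rng.normal(0.0, 0.005)
        )
    if contaminants:
        vals["methanol"] = max(0.0, 0.30 + rng.normal(0.0, 0.03))
        vals["acetonitrile"] = max(0.0, 0.22 + rng.normal(0.0, 0.03))
    return [
        {"sample_id": sample_id, "peak_id": pk, "integral": float(v), **meta}
        for pk, v in vals.items()
    ]


def simulate_peak_table(
    configs: dict[str, CommunityConfig],
    n_replicates: int = 3,
    seed: int = 0,
    *,
    include_sequential: bool = True,
    contaminants: bool = True,
    split_peak: bool = True,
) -> pd.DataFrame:
    """Long-format peak table: fresh medium, singly and doubly used medium.

    Sample lineages: ``unused`` (fresh tea), ``used_by:<sp>`` (one isolate),
    and ``used_by:<sp1>,<sp2>`` (sequential growth, same treatment — the
    cross-feeding design). Optional contaminant peaks (methanol,
    acetonitrile) and a proportional split resonance of the first substrate
    exercise the preprocessing steps.
    """
    anc = configs["ancestral"]
    split_of = anc.compound_ids[0] if split_peak else None
    rows: list[dict] = []
    base = pd.Series(anc.base_medium, index=anc.compound_ids)
    for rep in range(1, n_replicates + 1):
        rng = child_rng(seed, "peaks", "base", rep)
        rows += _peak_rows(
            f"base-r{rep}", base,
            {
                "species": BASE_SPECIES_LABEL,
                "treatment": BASE_TREATMENT_LABEL,
                "substrate": "unused",
                "replicate": rep,
            },
            rng, anc.noise_peak,
            contaminants=contaminants, split_peak_of=split_of,
        )
    for tr, cfg in configs.items():
        for sp in cfg.species_ids:
            used1 = pd.Series(
                simulate_used_tea(cfg, sp, cfg.base_medium), index=cfg.compound_ids
            )
            for rep in range(1, n_replicates + 1):
                rng = child_rng(seed, "peaks", tr, sp, rep)
                rows += _peak_rows(
                    f"{sp}-{tr}-r{rep}", used1,
                    {
                        "species": sp,
                        "treatment": tr,
                        "substrate": f"used_by:{sp}",
                        "replicate": rep,
                    },
                    rng, cfg.noise_peak,
                    contaminants=contaminants, split_peak_of=split_of,
                )
            if include_sequential:
                for sp2 in cfg.species_ids:
                    if sp2 == sp:
                        continue
                    used2 = pd.Series(
                        simulate_used_tea(cfg, sp2, used1.to_numpy()),
                        index=cfg.compound_ids,
                    )
                    for rep in range(1, n_replicates + 1):
                        rng = child_rng(seed, "peaks", tr, sp, sp2, rep)
                        rows += _peak_rows(
                            f"{sp}+{sp2}-{tr}-r{rep}", used2,
                            {
                                "species": sp2,
                                "treatment": tr,
                                "substrate": f"used_by:{sp},{sp2}",
                                "replicate": rep,
                            },
                            rng, cfg.noise_peak,
                            contaminants=contaminants, split_peak_of=split_of,
                        )
    return pd.DataFrame.from_records(rows)


def simulate_sequential_assays(
    configs: dict[str, CommunityConfig],
    n_replicates: int = 5,
    seed: int = 0,
):
    """Replicate-mean sequential spent-medium assays per (pair, treatment).

    Returns a list of :class:`ecoevo.crossfeeding.SequentialAssay` built
    from noisy base, first-filtrate, and second-filtrate profiles — the
    direct route into the cross-feeding statistics without a full peak
    table.
    """
    from .crossfeeding import SequentialAssay

    def _mean_noisy(truth: np.ndarray, key: tuple, sd: float) -> np.ndarray:
        draws = [
            _noisy(truth, child_rng(seed, *key, rep), sd)
            for rep in range(1, n_replicates + 1)
        ]
        return np.mean(draws, axis=0)

    anc = configs["ancestral"]
    idx = anc.compound_ids
    base_mean = pd.Series(
        _mean_noisy(anc.base_medium, ("seq", "base"), anc.noise_peak), index=idx
    )
    assays = []
    for tr, cfg in configs.items():
        for sp1 in cfg.species_ids:
            f1_truth = simulate_used_tea(cfg, sp1, cfg.base_medium)
            f1 = pd.Series(
                _mean_noisy(f1_truth, ("seq", tr, sp1), cfg.noise_peak), index=idx
            )
            for sp2 in cfg.species_ids:
                if sp2 == sp1:
                    continue
                f2_truth = simulate_used_tea(cfg, sp2, f1_truth)
                f2 = pd.Series(
                    _mean_noisy(f2_truth, ("seq", tr, sp1, sp2), cfg.noise_peak),
                    index=idx,
                )
                assays.append(
                    SequentialAssay(
                        first_species=sp1, second_species=sp2, treatment=tr,
                        base=base_mean, filtrate1=f1, filtrate2=f2,
                    )
                )
    return assays


# ---------------------------------------------------------------------------
# serial transfers and respiration plates


def simulate_serial_transfer(
    config: CommunityConfig,
    n_transfers: int = 15,
    dilution: float = 20.0,
    seed: int = 0,
    *,
    culture_id: str = "culture-1",
    species_index: int = 0,
    volume_ml: float = 2.0,
    stationary_density: float | None = None,
    noise_sd: float = 0.1,
    growth_days: float = 3.5,
) -> pd.DataFrame:
    """Transfer log: pre-transfer densities under dilute-and-regrow cycles.

    Each cycle divides the density by ``dilution`` and regrows exponentially
    toward the stationary density (default: the species' K) for
    ``growth_days``; lognormal noise perturbs the attained density. With
    ``noise_sd = 0`` and full regrowth the pre-transfer density is constant.
    """
    if n_transfers < 1:
        raise ValueError("need at least one transfer")
    if dilution <= 1:
        raise ValueError("dilution factor must exceed 1")
    rng = child_rng(seed, "transfer", culture_id)
    ceiling = (
        float(config.K[species_index])
        if stationary_density is None
        else float(stationary_density)
    )
    rate = float(config.r[species_index])
    rows = []
    pre = ceiling * (np.exp(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 1.0)
    for t in range(1, n_transfers + 1):
        if t > 1:
            post = pre / dilution
            regrown = min(ceiling, post * 2.0 ** (rate * growth_days))
            pre = regrown * (np.exp(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 1.0)
        rows.append(
            {
                "culture_id": culture_id,
                "transfer": t,
                "pre_density_per_ml": float(pre),
                "dilution": float(dilution),
                "volume_ml": float(volume_ml),
            }
        )
    return pd.DataFrame.from_records(rows)


def community_respiration_score(config: CommunityConfig) -> float:
    """Fraction-like productivity score of a community's ground truth.

    Substrate term: how much of the base medium the community's best
    consumer of each compound removes. Chain term: waste produced that some
    *other* member consumes (cross-feeding adds respiration). Normalised by
    total base-medium content.
    """
    sub = config.substrate_mask
    covered = (config.base_medium[sub] * config.U[:, sub].max(axis=0)).sum()
    chain = 0.0
    n = len(config.species_ids)
    for c in np.where(~sub)[0]:
        for i in range(n):
            if config.P[i, c] > 0:
                others = [config.U[j, c] for j in range(n) if j != i]
                chain += config.P[i, c] * max(others) if others else 0.0
    total = config.base_medium.sum()
    return float((covered + chain) / total) if total > 0 else 0.0


def pct_to_absorbance(
    pct: float, calibration=DEFAULT_RESPIRATION_CALIBRATION
) -> float:
    """Invert %CO2 = A + B / (1 + D * Ai) for the normalized absorbance Ai."""
    A, B, D = calibration
    return (B / (pct - A) - 1.0) / D


def simulate_respiration_plate(
    configs: dict[str, CommunityConfig],
    histories: tuple[str, ...] = ("monoculture", "polyculture"),
    n_replicates: int = 10,
    n_blanks: int = 4,
    seed: int = 0,
    *,
    calibration=DEFAULT_RESPIRATION_CALIBRATION,
    pct_scale: float = 1.5,
    blank_ratio: float = 0.92,
    od_t0: float = 0.35,
    noise_sd: float = 0.01,
    plate: str = "R1",
) -> pd.DataFrame:
    """Cresol-red indicator plate for communities reassembled per history.

    Each community's planted net %CO2 is ``pct_scale`` times its respiration
    score; wells encode it through the indicator curve relative to blank
    wells, which carry only the ambient drift ``blank_ratio``.
    """
    A, B, D = calibration
    pct_blank = A + B / (1.0 + D)  # indicator reading at zero net respiration
    rows = []
    well = 1
    for history in histories:
        cfg = configs[history]
        planted = pct_scale * community_respiration_score(cfg)
        for rep in range(1, n_replicates + 1):
            rng = child_rng(seed, "respiration", history, rep)
            ai = pct_to_absorbance(planted + pct_blank, calibration)
            t0 = od_t0 * (1.0 + rng.normal(0.0, noise_sd))
            t6 = t0 * ai * blank_ratio * (1.0 + rng.normal(0.0, noise_sd))
            rows.append(
                {
                    "plate": plate,
                    "well": f"W{well}",
                    "community_id": f"{history}-assembly-{rep}",
                    "history": history,
                    "od570_t0": float(t0),
                    "od570_t6": float(max(t6, 1e-6)),
                    "is_blank": False,
                }
            )
            well += 1
    for b in range(1, n_blanks + 1):
        rng = child_rng(seed, "respiration", "blank", b)
        t0 = od_t0 * (1.0 + rng.normal(0.0, noise_sd))
        t6 = t0 * blank_ratio * (1.0 + rng.normal(0.0, noise_sd))
        rows.append(
            {
                "plate": plate,
                "well": f"B{b}",
                "community_id": "blank",
                "history": "blank",
                "od570_t0": float(t0),
                "od570_t6": float(t6),
                "is_blank": True,
            }
        )
        well += 1
    return pd.DataFrame.from_records(rows)


# ---------------------------------------------------------------------------
# full datasets


def evolved_configs(
    config: CommunityConfig, effect_size: float = 1.0, seed: int = 0
) -> dict[str, CommunityConfig]:
    """Ground-truth parameters for all three treatments."""
    return {
        tr: evolve_isolates(config, tr, effect_size=effect_size, seed=seed)
        for tr in TREATMENTS
    }


def simulate_growth_table(
    configs: dict[str, CommunityConfig],
    n_replicates: int = 9,
    times_h=(0.0, 24.0, 48.0, 72.0, 96.0),
    seed: int = 0,
    *,
    include_used: bool = True,
) -> pd.DataFrame:
    """Growth-assay plate rows for every species x treatment x substrate.

    Substrates are fresh medium plus, when ``include_used`` is set, medium
    previously used by each *other* species of the same treatment (donor and
    recipient always share a treatment).
    """
    frames = []
    for tr, cfg in configs.items():
        media: list[tuple[str, np.ndarray]] = [("unused", cfg.base_medium)]
        if include_used:
            for donor in cfg.species_ids:
                media.append(
                    (f"used_by:{donor}", simulate_used_tea(cfg, donor, cfg.base_medium))
                )
        for sub_name, medium in media:
            for rep in range(1, n_replicates + 1):
                plate = f"{tr[:4]}-{sub_name}-{rep}"
                for col, sp in enumerate(cfg.species_ids, start=1):
                    donor = sub_name.removeprefix("used_by:")
                    if sub_name != "unused" and donor == sp:
                        continue  # no self-conditioned assays
                    frames.append(
                        simulate_growth_curve(
                            cfg,
                            IsolateLabel(sp, tr, rep),
                            medium=medium,
                            times_h=np.asarray(times_h, dtype=float),
                            seed=seed,
                            substrate=sub_name,
                            plate=plate,
                            column=col,
                        )
                    )
    return pd.concat(frames, ignore_index=True)


def simulate_calibration_table(
    config: CommunityConfig,
    od_grid=(0.1, 0.32, 0.54, 0.76, 0.98, 1.2),
    n_per_od: int = 3,
    noise_sd: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Colony-count calibration rows: per-species lines with a shared slope."""
    rows = []
    for i, sp in enumerate(config.species_ids):
        rng = child_rng(seed, "calibration", sp)
        for od in od_grid:
            for _ in range(n_per_od):
                log10c = (
                    config.cal_intercepts[i]
                    + config.cal_slope * od
                    + rng.normal(0.0, noise_sd)
                )
                rows.append(
                    {
                        "species": sp,
                        "treatment": "ancestral",
                        "od600": float(od),
                        "colonies_per_ml": float(10.0 ** log10c),
                    }
                )
    return pd.DataFrame.from_records(rows)


def simulate_transfer_table(
    configs: dict[str, CommunityConfig],
    n_cultures: int = 3,
    n_transfers: int = 15,
    dilution: float = 20.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Transfer logs for monoculture lineages and polyculture communities."""
    anc = configs["ancestral"]
    frames = []
    for i, sp in enumerate(anc.species_ids):
        for k in range(1, n_cultures + 1):
            frames.append(
                simulate_serial_transfer(
                    anc, n_transfers, dilution, seed,
                    culture_id=f"mono-{sp}-{k}", species_index=i,
                )
            )
    for k in range(1, n_cultures + 1):
        frames.append(
            simulate_serial_transfer(
                anc, n_transfers, dilution, seed,
                culture_id=f"poly-{k}", species_index=int(np.argmax(anc.K)),
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_dataset(
    config: CommunityConfig,
    effect_size: float = 1.0,
    seed: int = 0,
    *,
    n_growth_replicates: int = 9,
    n_peak_replicates: int = 3,
    n_transfers: int = 15,
    dilution: float = 20.0,
    include_used_growth: bool = True,
) -> SyntheticDataset:
    """The full synthetic experiment: all five input tables plus the truth."""
    configs = evolved_configs(config, effect_size=effect_size, seed=seed)
    growth = simulate_growth_table(
        configs, n_replicates=n_growth_replicates, seed=seed,
        include_used=include_used_growth,
    )
    calibration = simulate_calibration_table(config, seed=seed)
    peaks = simulate_peak_table(configs, n_replicates=n_peak_replicates, seed=seed)
    transfers = simulate_transfer_table(configs, n_transfers=n_transfers,
                                        dilution=dilution, seed=seed)
    respiration = simulate_respiration_plate(configs, seed=seed)
    truth = {**configs, "effect_size": float(effect_size), "seed": int(seed)}
    return SyntheticDataset(
        growth=growth,
        calibration=calibration,
        peaks=peaks,
        transfers=transfers,
        respiration=respiration,
        truth=truth,
    )


def simulate_null_dataset(config: CommunityConfig, seed: int = 0, **kw) -> SyntheticDataset:
    """Dataset with ``effect_size = 0``: no true difference between treatments."""
    return simulate_dataset(config, effect_size=0.0, seed=seed, **kw)
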