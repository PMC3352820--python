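"""End-to-end analysis pipeline and run configuration.

Wires the modules in the order of the experiment's logic: growth assays ->
interaction networks -> metabolic footprints -> cross-feeding -> demography
-> community respiration. A run is driven by a :class:`RunConfig` that
either points at the five input CSVs or carries a synthesis block for the
generator; every stage writes tidy CSV outputs plus a machine-readable run
log. Same config and seed means byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._seeding import child_seed
from .growth import (
    TREATMENTS,
    blank_correct,
    fit_od_calibration,
    treatment_contrast,
    vmax_table,
)
from .interactions import build_network, interaction_table, write_network
from .metabolomics import (
    DeltaProfile,
    collapse_correlated_peaks,
    load_peak_table,
    pca_unscaled,
    permutation_test,
    profiles_to_frame,
    remove_contaminants,
)
from .crossfeeding import (
    SequentialAssay,
    build_crossfeed_table,
    correlation_by_treatment,
    interaction_model,
)
from .demography import TransferLog, effective_size
from .respiration import RespirationSettings, community_rates, compare_assemblies
from .synthetic import (
    BASE_TREATMENT_LABEL,
    make_default_community,
    simulate_dataset,
)

__all__ = ["RunConfig", "run_pipeline", "demo"]

CONTAMINANT_PEAKS = ("methanol", "acetonitrile")


@dataclass
class RunConfig:
    """Inputs (paths or a synthesis block) plus statistical settings."""

    inputs: dict | None = None          # growth/calibration/peaks/transfers/respiration
    synthesis: dict | None = None       # generator parameters
    seed: int = 0
    B: int = 10_000
    alpha: float = 0.05
    window_h: float = 48.0
    epsilon: float = 1e-3
    collapse_r: float = 0.95
    capacity_h: float = 96.0
    capacity_tol_h: float = 4.0
    ne_method: str = "bottleneck_times_generations"
    respiration: dict = field(default_factory=dict)
    schema_version: int = 1

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.synthesis is None):
            raise ValueError("provide either input paths or a synthesis block")
        if not float(self.seed).is_integer():
            raise ValueError("seed must be an integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True),
            encoding="utf-8",
        )


def default_demo_config(seed: int = 0) -> RunConfig:
    """The demo's study conditions: a 4-species, 10-compound community."""
    return RunConfig(
        synthesis={
            "n_species": 4,
            "n_compounds": 10,
            "effect_size": 1.0,
            "n_growth_replicates": 9,
            "n_peak_replicates": 5,
            "n_transfers": 15,
            "dilution": 20.0,
        },
        seed=seed,
    )


def _load_tables(config: RunConfig):
    if config.synthesis is not None:
        syn = dict(config.synthesis)
        community = make_default_community(
            syn.pop("n_species", 4), syn.pop("n_compounds", 10), seed=config.seed
        )
        ds = simulate_dataset(community, seed=config.seed, **syn)
        return {
            "growth": ds.growth,
            "calibration": ds.calibration,
            "peaks": ds.peaks,
            "transfers": ds.transfers,
            "respiration": ds.respiration,
        }
    names = ("growth", "calibration", "peaks", "transfers", "respiration")
    missing = [n for n in names if n not in config.inputs]
    if missing:
        raise ValueError(f"missing input table path: {missing}")
    return {n: pd.read_csv(config.inputs[n]) for n in names}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _write(df: pd.DataFrame, outdir: Path, name: str, log: dict) -> None:
    path = outdir / name
    df.to_csv(path, index=False, float_format="%.10g")
    log["outputs"].append(name)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage; returns the run log (also written as run_log.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "version": __version__,
        "seed": config.seed,
        "settings": {
            "B": config.B,
            "alpha": config.alpha,
            "window_h": config.window_h,
            "epsilon": config.epsilon,
            "collapse_r": config.collapse_r,
            "ne_method": config.ne_method,
        },
        "outputs": [],
        "stages": {},
    }

    tables = _load_tables(config)

    # ------------------------------------------------------------- growth
    try:
        corrected = blank_correct(tables["growth"], epsilon=config.epsilon)
        model = fit_od_calibration(tables["calibration"])
        vmax = vmax_table(corrected, model, window_h=config.window_h)
        vmax = vmax.sort_values(
            ["treatment", "species", "substrate", "replicate"]
        ).reset_index(drop=True)
        _write(vmax, outdir, "vmax_estimates.csv", log)

        contrasts = []
        unused = vmax[vmax["substrate"] == "unused"]
        pairs = [("ancestral", "monoculture"), ("ancestral", "polyculture"),
                 ("monoculture", "polyculture")]
        for sp, grp in unused.groupby("species"):
            for a, b in pairs:
                va = grp[grp["treatment"] == a]["vmax"].to_numpy()
                vb = grp[grp["treatment"] == b]["vmax"].to_numpy()
                if va.size < 2 or vb.size < 2:
                    continue
                c = treatment_contrast(
                    vb, va, B=config.B,
                    seed=child_seed(config.seed, "contrast", sp, a, b),
                )
                contrasts.append(
                    {"species": sp, "reference": a, "treatment": b,
                     "difference": c.difference, "ratio": c.ratio, "p": c.p,
                     "n_ref": c.n_b, "n_evolved": c.n_a, "B": c.B}
                )
        _write(pd.DataFrame.from_records(contrasts), outdir,
               "growth_contrasts.csv", log)
        log["stages"]["growth"] = {
            "calibration_slope": model.slope,
            "calibration_r2": model.r2,
            "n_curves": int(len(vmax)),
        }
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise StageError("growth", e) from e

    # ------------------------------------------------------- interactions
    try:
        edge_frames = []
        for tr in TREATMENTS:
            if tr not in set(vmax["treatment"]):
                continue
            edges = interaction_table(
                vmax, tr, alpha=config.alpha, B=min(config.B, 9999),
                seed=child_seed(config.seed, "edges", tr),
            )
            if not edges:
                continue
            G = build_network(edges)
            write_network(G, outdir / f"network_{tr}.csv", "csv")
            write_network(G, outdir / f"network_{tr}.dot", "dot")
            write_network(G, outdir / f"network_{tr}.graphml", "graphml")
            log["outputs"] += [f"network_{tr}.csv", f"network_{tr}.dot",
                               f"network_{tr}.graphml"]
            edge_frames.append(
                pd.DataFrame.from_records(
                    [dataclasses.asdict(e) for e in edges]
                )
            )
        if edge_frames:
            _write(pd.concat(edge_frames, ignore_index=True), outdir,
                   "interaction_edges.csv", log)
    except Exception as e:  # noqa: BLE001
        raise StageError("interactions", e) from e

    # ------------------------------------------------------- metabolomics
    try:
        profiles = load_peak_table(tables["peaks"])
        profiles = remove_contaminants(profiles, CONTAMINANT_PEAKS)
        profiles, groups = collapse_correlated_peaks(profiles, config.collapse_r)
        _write(
            pd.DataFrame(
                [{"group": i + 1, "peaks": "+".join(g)} for i, g in enumerate(groups)]
            ),
            outdir, "peak_groups.csv", log,
        )
        base = [p for p in profiles if p.treatment == BASE_TREATMENT_LABEL]
        if not base:
            raise ValueError("peak table has no fresh-medium samples")
        base_mean = profiles_to_frame(base).mean(axis=0)
        singles = [
            p for p in profiles
            if p.treatment in TREATMENTS and p.substrate == f"used_by:{p.species}"
        ]
        deltas = [
            DeltaProfile(
                sample_id=p.sample_id, values=p.peaks - base_mean,
                species=p.species, treatment=p.treatment, replicate=p.replicate,
            )
            for p in singles
        ]
        pca = pca_unscaled(deltas)
        meta = pd.DataFrame(
            {"species": [d.species for d in deltas],
             "treatment": [d.treatment for d in deltas]},
            index=[d.sample_id for d in deltas],
        )
        scores = pca.scores.join(meta)
        scores.index.name = "sample_id"
        _write(scores.reset_index(), outdir, "pca_scores.csv", log)
        loadings = pca.loadings.copy()
        loadings.index.name = "peak_id"
        _write(loadings.reset_index(), outdir, "pca_loadings.csv", log)

        tests = []
        summary: dict[str, float] = {}
        for tr in ("monoculture", "polyculture"):
            pool = [d for d in deltas if d.treatment in ("ancestral", tr)]
            for statname in ("evolution_distance", "divergence_distance"):
                res = permutation_test(
                    statname, pool, B=config.B,
                    seed=child_seed(config.seed, "nmr", statname, tr),
                    focal_treatment=tr,
                )
                tests.append(
                    {"statistic": statname, "treatment": tr,
                     "observed": res.observed, "p_two_tailed": res.p_two_tailed,
                     "B": res.B}
                )
                summary[f"{statname}:{tr}"] = res.observed
        _write(pd.DataFrame.from_records(tests), outdir, "nmr_tests.csv", log)
        log["stages"]["metabolomics"] = {
            "n_profiles": len(profiles),
            "n_collapsed_groups": len(groups),
            "observed": summary,
            "pc_variance_fractions": [float(v) for v in pca.variance_fractions[:4]],
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("metabolomics", e) from e

    # ------------------------------------------------------- cross-feeding
    try:
        assays = _sequential_assays(profiles, base_mean)
        evolved = [a for a in assays if a.treatment in ("monoculture", "polyculture")]
        ancestral = [a for a in assays if a.treatment == "ancestral"]
        records = build_crossfeed_table(evolved, ancestral)
        _write(records, outdir, "crossfeed_records.csv", log)
        if not records.empty and records["treatment"].nunique() >= 2:
            corr = correlation_by_treatment(records)
            _write(corr, outdir, "crossfeed_correlations.csv", log)
            model_rec = interaction_model(records)
            _write(pd.DataFrame([model_rec]), outdir, "crossfeed_model.csv", log)
            log["stages"]["crossfeeding"] = {
                "interaction_coefficient": model_rec["interaction_coefficient"],
                "r_by_treatment": dict(zip(corr["treatment"], corr["r"])),
            }
    except Exception as e:  # noqa: BLE001
        raise StageError("crossfeeding", e) from e

    # ----------------------------------------------------------- demography
    try:
        rows = []
        for cid in sorted(tables["transfers"]["culture_id"].unique()):
            stats = effective_size(
                TransferLog.from_frame(tables["transfers"], cid),
                method=config.ne_method,
            )
            rows.append(
                {"culture_id": cid,
                 "total_generations": stats.total_generations,
                 "mean_generations_per_transfer": float(
                     np.mean(stats.generations_per_transfer)),
                 "bottleneck_size": stats.bottleneck_size,
                 "ne": stats.ne, "ne_method": stats.ne_method,
                 "n_clipped": stats.n_clipped}
            )
        demo_df = pd.DataFrame.from_records(rows)
        _write(demo_df, outdir, "demography.csv", log)
        log["stages"]["demography"] = {
            "total_generations_range": [float(demo_df["total_generations"].min()),
                                        float(demo_df["total_generations"].max())],
            "ne_range": [float(demo_df["ne"].min()), float(demo_df["ne"].max())],
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("demography", e) from e

    # ----------------------------------------------------------- respiration
    try:
        settings = RespirationSettings(**config.respiration)
        rates = community_rates(tables["respiration"], settings)
        rates = rates.sort_values(["history", "community_id"]).reset_index(drop=True)
        _write(rates, outdir, "respiration_rates.csv", log)
        hist = rates.groupby("history")["rate_ug_per_ml_per_h"]
        if {"monoculture", "polyculture"} <= set(rates["history"]):
            c = compare_assemblies(
                hist.get_group("polyculture").to_numpy(),
                hist.get_group("monoculture").to_numpy(),
                B=min(config.B, 9999),
                seed=child_seed(config.seed, "respiration"),
            )
            _write(
                pd.DataFrame(
                    [{"group_a": "polyculture", "group_b": "monoculture",
                      "mean_a": c.mean_a, "mean_b": c.mean_b,
                      "difference": c.difference, "p": c.p, "B": c.B}]
                ),
                outdir, "respiration_contrast.csv", log,
            )
            log["stages"]["respiration"] = {
                "polyculture_mean": c.mean_a, "monoculture_mean": c.mean_b,
                "difference": c.difference, "p": c.p,
            }
    except Exception as e:  # noqa: BLE001
        raise StageError("respiration", e) from e

    (outdir / "run_log.json").write_text(
        json.dumps(log, indent=2, sort_keys=True), encoding="utf-8"
    )
    return log


def _sequential_assays(profiles, base_mean: pd.Series) -> list[SequentialAssay]:
    """Replicate-mean assay chains from the peak table's lineage labels."""
    frame = profiles_to_frame(profiles)
    meta = pd.DataFrame(
        {"substrate": [p.substrate for p in profiles],
         "treatment": [p.treatment for p in profiles]},
        index=frame.index,
    )
    assays = []
    seq = meta[meta["substrate"].str.contains(",", na=False)]
    for (sub, tr), grp in seq.groupby(["substrate", "treatment"]):
        sp1, sp2 = sub.removeprefix("used_by:").split(",")
        f2 = frame.loc[grp.index].mean(axis=0)
        first_mask = (meta["substrate"] == f"used_by:{sp1}") & (meta["treatment"] == tr)
        if not first_mask.any():
            continue
        f1 = frame.loc[first_mask[first_mask].index].mean(axis=0)
        assays.append(
            SequentialAssay(
                first_species=sp1, second_species=sp2, treatment=tr,
                base=base_mean, filtrate1=f1, filtrate2=f2,
            )
        )
    return assays


def demo(outdir: str | Path, seed: int = 0) -> dict:
    """Synthesize the default community and run the full pipeline on it."""
    config = default_demo_config(seed=seed)
    return run_pipeline(config, outdir)
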