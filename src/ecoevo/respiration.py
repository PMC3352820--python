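"""Community respiration from colorimetric CO2 indicator plates.

Respired CO2 acidifies a cresol-red gel whose 570 nm absorbance drops; each
well's end/start ratio, normalised by blank wells (medium without cells,
carrying only ambient drift), gives a normalised absorbance Ai with Ai = 1
at zero net respiration. An indicator calibration curve
%CO2 = A + B / (1 + D * Ai) converts Ai to headspace CO2; the blank reading
(Ai = 1) is subtracted as the zero-respiration baseline. Ideal-gas
bookkeeping then yields micrograms of CO2 and a rate per ml of medium per
hour. Calibration constants are instrument configuration, never asserted as
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import ContrastResult, permute_two_sample

__all__ = [
    "RespirationSettings",
    "CO2Rate",
    "normalize_indicator",
    "pct_co2",
    "co2_rate",
    "community_rates",
    "compare_assemblies",
]

#: g/mol of CO2 over l/mol of ideal gas at 0 degrees C
_CO2_DENSITY = 44.0 / 22.4


@dataclass
class RespirationSettings:
    """Assay geometry and indicator calibration."""

    incubation_h: float = 6.0
    medium_volume_ml: float = 1.0
    headspace_volume_ml: float = 1.0
    temperature_c: float = 25.0
    calibration: tuple[float, float, float] = (-0.2265, -1.606, -6.771)

    def __post_init__(self) -> None:
        if self.incubation_h <= 0:
            raise ValueError("incubation time must be positive")
        if min(self.medium_volume_ml, self.headspace_volume_ml) <= 0:
            raise ValueError("volumes must be positive")


@dataclass
class CO2Rate:
    community_id: str
    rate: float                 # ug CO2 / ml medium / h
    mean: float
    se: float
    n: int
    clipped: bool = False       # negative baseline-corrected reading set to 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("need at least one replicate")


def normalize_indicator(assay_rows: pd.DataFrame) -> pd.DataFrame:
    """Per-well normalised absorbance Ai, blank-referenced per plate.

    Ai = (od570_t6 / od570_t0) / mean over the plate's blank wells of the
    same ratio, so blanks average Ai = 1 (the zero-respiration baseline) and
    ambient drift divides out.
    """
    df = assay_rows.copy()
    if (df[["od570_t0", "od570_t6"]] <= 0).any().any():
        raise ValueError("OD readings must be positive")
    df["_ratio"] = df["od570_t6"] / df["od570_t0"]
    out = []
    for plate, grp in df.groupby("plate"):
        blanks = grp[grp["is_blank"].astype(bool)]
        if blanks.empty:
            raise ValueError(f"plate {plate!r} has no blank wells")
        baseline = blanks["_ratio"].mean()
        grp = grp.copy()
        grp["ai"] = grp["_ratio"] / baseline
        out.append(grp)
    return pd.concat(out, ignore_index=True).drop(columns="_ratio")


def pct_co2(ai, calibration=(-0.2265, -1.606, -6.771)):
    """Headspace %CO2 from normalised absorbance: A + B / (1 + D * Ai)."""
    A, B, D = calibration
    ai = np.asarray(ai, dtype=float)
    denom = 1.0 + D * ai
    if np.any(np.abs(denom) < 1e-12):
        raise ZeroDivisionError("indicator curve singular at 1 + D*Ai = 0")
    return A + B / denom


def co2_rate(
    pct: float,
    settings: RespirationSettings,
    *,
    community_id: str = "",
) -> tuple[float, bool]:
    """Rate in ug CO2 per ml medium per hour from a net %CO2 reading.

    ug CO2 = pct/100 * headspace_ml * (44/22.4) * 273/(273+T) * 1000;
    negative baseline-corrected readings are clipped to 0 and flagged.
    """
    clipped = pct < 0
    pct = max(float(pct), 0.0)
    micrograms = (
        pct / 100.0
        * settings.headspace_volume_ml
        * _CO2_DENSITY
        * (273.0 / (273.0 + settings.temperature_c))
        * 1000.0
    )
    rate = micrograms / settings.medium_volume_ml / settings.incubation_h
    return rate, bool(clipped)


def community_rates(
    assay_rows: pd.DataFrame,
    settings: RespirationSettings | None = None,
) -> pd.DataFrame:
    """Tidy per-well and per-community CO2 rates from raw indicator readings."""
    settings = settings or RespirationSettings()
    df = normalize_indicator(assay_rows)
    A, B, D = settings.calibration
    baseline = pct_co2(1.0, settings.calibration)  # blank reading, Ai = 1
    wells = df[~df["is_blank"].astype(bool)].copy()
    net = pct_co2(wells["ai"].to_numpy(), settings.calibration) - baseline
    rates, flags = zip(*(co2_rate(p, settings) for p in net)) if len(wells) else ((), ())
    wells["net_pct_co2"] = net
    wells["rate_ug_per_ml_per_h"] = rates
    wells["clipped"] = flags
    return wells[
        ["plate", "well", "community_id", "history", "ai",
         "net_pct_co2", "rate_ug_per_ml_per_h", "clipped"]
        if "history" in wells.columns
        else ["plate", "well", "community_id", "ai",
              "net_pct_co2", "rate_ug_per_ml_per_h", "clipped"]
    ]


def compare_assemblies(
    rates_a,
    rates_b,
    B: int = 9999,
    seed: int | None = None,
    exhaustive: bool | None = None,
) -> ContrastResult:
    """Permutation contrast of mean CO2 rate between two community groups."""
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >=2 replicates per group")
    return permute_two_sample(a, b, B=B, seed=seed, exhaustive=exhaustive)
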