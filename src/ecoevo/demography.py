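"""Serial-transfer demography: generations and effective population size.

A batch culture diluted 1:dilution and regrown each cycle doubles
log2(regrowth factor) times per cycle. With the pre-transfer density series
N(t), generations per transfer are g_t = log2(N(t) / (N(t-1)/dilution)); the
founding density before the first recorded transfer is taken as
N(1)/dilution (a culture started by the same dilution from an equal-density
stock), so a constant-density log over T transfers totals T*log2(dilution).
The effective population size uses the classic serial-transfer
approximation Ne = N0 * g (bottleneck census times generations per cycle);
a harmonic-mean census alternative is provided because the estimator choice
is a convention, recorded in the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TransferLog", "DemographyStats", "generations", "effective_size"]


@dataclass
class TransferLog:
    """Pre-transfer densities for one culture across consecutive transfers."""

    culture_id: str
    transfers: np.ndarray          # 1..T consecutive
    pre_density_per_ml: np.ndarray
    dilution: np.ndarray           # per-transfer dilution factor (> 1)
    volume_ml: np.ndarray

    def __post_init__(self) -> None:
        for name in ("transfers", "pre_density_per_ml", "dilution", "volume_ml"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        t = self.transfers.astype(int)
        if not np.array_equal(t, np.arange(1, t.size + 1)):
            raise ValueError("transfer indices must be consecutive from 1")
        if np.any(self.pre_density_per_ml <= 0):
            raise ValueError("densities must be positive")
        if np.any(self.dilution <= 1):
            raise ValueError("dilution factors must exceed 1")
        if np.any(self.volume_ml <= 0):
            raise ValueError("culture volume must be positive")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, culture_id: str | None = None) -> "TransferLog":
        if culture_id is not None:
            df = df[df["culture_id"] == culture_id]
        elif df["culture_id"].nunique() != 1:
            raise ValueError("frame holds several cultures; pass culture_id")
        df = df.sort_values("transfer")
        return cls(
            culture_id=str(df["culture_id"].iloc[0]),
            transfers=df["transfer"].to_numpy(),
            pre_density_per_ml=df["pre_density_per_ml"].to_numpy(),
            dilution=df["dilution"].to_numpy(),
            volume_ml=df["volume_ml"].to_numpy(),
        )


@dataclass
class DemographyStats:
    culture_id: str
    generations_per_transfer: np.ndarray
    total_generations: float
    bottleneck_size: float          # mean post-dilution census, cells
    ne: float
    ne_method: str
    n_clipped: int                  # transfers with decline below replacement

    def __post_init__(self) -> None:
        if self.ne <= 0:
            raise ValueError("Ne must be positive")
        total = float(np.sum(self.generations_per_transfer))
        if not np.isclose(total, self.total_generations):
            raise ValueError("total generations must equal the per-transfer sum")


def generations(log: TransferLog) -> DemographyStats:
    """Per-transfer and total generations (Ne filled in by effective_size)."""
    N = log.pre_density_per_ml
    prev = np.concatenate([[N[0]], N[:-1]])
    post = prev / log.dilution
    g = np.log2(N / post)
    clipped = g < 0
    g = np.where(clipped, 0.0, g)
    bottleneck = float(np.mean(post * log.volume_ml))
    stats = DemographyStats(
        culture_id=log.culture_id,
        generations_per_transfer=g,
        total_generations=float(g.sum()),
        bottleneck_size=bottleneck,
        ne=max(bottleneck * float(g.mean()), np.finfo(float).tiny),
        ne_method="bottleneck_times_generations",
        n_clipped=int(clipped.sum()),
    )
    return stats


def effective_size(log: TransferLog, method: str = "bottleneck_times_generations") -> DemographyStats:
    """Demography stats with Ne under the chosen convention.

    ``bottleneck_times_generations``: Ne = N0 * g with N0 the mean
    post-dilution census (cells) and g the mean generations per transfer.
    ``harmonic_mean``: harmonic mean of post-dilution and pre-transfer
    census sizes across the log.
    """
    stats = generations(log)
    if method == "bottleneck_times_generations":
        return stats
    if method == "harmonic_mean":
        N = log.pre_density_per_ml * log.volume_ml
        prev = np.concatenate([[N[0]], N[:-1]])
        post = prev / log.dilution
        census = np.concatenate([post, N])
        stats.ne = float(census.size / np.sum(1.0 / census))
        stats.ne_method = "harmonic_mean"
        return stats
    raise ValueError(f"unknown Ne method {method!r}")
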