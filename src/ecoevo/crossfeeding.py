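"""Cross-feeding statistics from sequential spent-medium assays.

Two per-compound deltas describe a pair of species grown in sequence on the
same medium: delta_01 = (filtrate of species 1) - (fresh medium) and
delta_12 = (filtrate of species 2 grown on that filtrate) - (filtrate of
species 1). Positive deltas are production, negative consumption; the two
telescope to (filtrate 2 - fresh medium) exactly.

Evolved cross-feeding is detected by comparing evolved against ancestral
pairs: for each compound the evolved first species *produced* (evolved
delta_01 > 0), x = the evolution of production by species 1 and y = the
evolution of consumption by species 2. A negative x-y correlation means
compounds produced in greater amounts are also consumed in greater amounts.
A linear model y ~ x * treatment (monoculture reference) tests whether that
coupling is stronger in polyculture-evolved pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

from .metabolomics import DeltaProfile, PeakProfile

__all__ = [
    "SequentialAssay",
    "delta_01",
    "delta_12",
    "build_crossfeed_table",
    "correlation_by_treatment",
    "interaction_model",
]


@dataclass
class SequentialAssay:
    """Profiles from one base -> species1 -> species2 assay chain."""

    first_species: str
    second_species: str
    treatment: str
    base: pd.Series
    filtrate1: pd.Series
    filtrate2: pd.Series

    def __post_init__(self) -> None:
        if self.first_species == self.second_species:
            raise ValueError("first and second species must differ")
        for name in ("filtrate1", "filtrate2"):
            s = getattr(self, name)
            if not s.index.equals(self.base.index):
                raise ValueError(f"{name} peak axis differs from base")


def _series(profile) -> pd.Series:
    if isinstance(profile, PeakProfile):
        return profile.peaks
    if isinstance(profile, DeltaProfile):
        return profile.values
    return pd.Series(profile, dtype=float)


def delta_01(filtrate1, base) -> pd.Series:
    """Per-compound change after the first species: filtrate1 - fresh medium."""
    f, b = _series(filtrate1), _series(base)
    if not f.index.equals(b.index):
        raise ValueError("profiles must share a peak axis")
    return f - b


def delta_12(filtrate2, filtrate1) -> pd.Series:
    """Change after the second species: filtrate2 - filtrate1."""
    return delta_01(filtrate2, filtrate1)


def build_crossfeed_table(
    evolved: list[SequentialAssay],
    ancestral: list[SequentialAssay],
) -> pd.DataFrame:
    """One record per (species pair, produced compound).

    x = delta_01(evolved) - delta_01(ancestral)  (evolution of production)
    y = delta_12(evolved) - delta_12(ancestral)  (evolution of consumption
    change by the second species). Only compounds the evolved first species
    produced (delta_01 > 0) are kept. Evolved assays lacking an ancestral
    counterpart for the same (first, second) pair are skipped with a warning.
    """
    anc = {(a.first_species, a.second_species): a for a in ancestral}
    records = []
    skipped = []
    for ev in evolved:
        key = (ev.first_species, ev.second_species)
        if key not in anc:
            skipped.append(key + (ev.treatment,))
            continue
        an = anc[key]
        d01_e = delta_01(ev.filtrate1, ev.base)
        d01_a = delta_01(an.filtrate1, an.base)
        d12_e = delta_12(ev.filtrate2, ev.filtrate1)
        d12_a = delta_12(an.filtrate2, an.filtrate1)
        produced = d01_e > 0  # produced-compound filter (evolved isolate)
        for compound in d01_e.index[produced]:
            records.append(
                {
                    "first_species": ev.first_species,
                    "second_species": ev.second_species,
                    "treatment": ev.treatment,
                    "compound": compound,
                    "x": float(d01_e[compound] - d01_a[compound]),
                    "y": float(d12_e[compound] - d12_a[compound]),
                }
            )
    if skipped:
        warnings.warn(
            f"no ancestral counterpart for pairs: {sorted(set(skipped))}",
            stacklevel=2,
        )
    return pd.DataFrame.from_records(
        records,
        columns=["first_species", "second_species", "treatment", "compound", "x", "y"],
    )


def correlation_by_treatment(records: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between x and y within each treatment (two-sided t-test p)."""
    out = []
    for tr, grp in records.groupby("treatment"):
        if len(grp) < 3:
            raise ValueError(f"treatment {tr!r} has fewer than 3 records")
        if grp["x"].std() == 0 or grp["y"].std() == 0:
            raise ValueError(f"zero variance in x or y for treatment {tr!r}")
        r, p = sps.pearsonr(grp["x"], grp["y"])
        out.append({"treatment": tr, "r": float(r), "p": float(p), "n": len(grp)})
    return pd.DataFrame.from_records(out)


def interaction_model(records: pd.DataFrame) -> dict:
    """OLS fit of y ~ x * treatment with monoculture as the reference level.

    The interaction coefficient is slope(polyculture) - slope(monoculture);
    a negative value means production-consumption coupling is stronger in
    polyculture-evolved pairs.
    """
    treatments = sorted(records["treatment"].unique())
    if len(treatments) < 2:
        raise ValueError("interaction model needs both treatments")
    for tr, grp in records.groupby("treatment"):
        if len(grp) < 3:
            raise ValueError(f"treatment {tr!r} has fewer than 3 records")
    df = records.copy()
    fit = smf.ols(
        "y ~ x * C(treatment, Treatment(reference='monoculture'))", data=df
    ).fit()
    inter_key = [k for k in fit.params.index if k.startswith("x:")]
    if len(inter_key) != 1:
        raise ValueError("expected exactly two treatment levels")
    inter_key = inter_key[0]
    slope_mono = float(fit.params["x"])
    coef = float(fit.params[inter_key])
    return {
        "slope_monoculture": slope_mono,
        "slope_polyculture": slope_mono + coef,
        "interaction_coefficient": coef,
        "interaction_t": float(fit.tvalues[inter_key]),
        "interaction_p": float(fit.pvalues[inter_key]),
        "n": int(fit.nobs),
        "r2": float(fit.rsquared),
    }
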