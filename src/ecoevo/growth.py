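"""Growth-assay analysis: blank correction, OD calibration, V_MAX, contrasts.

Plate-reader OD600 time series are blank-corrected against sterile control
wells on the same plate column, calibrated to cell densities with a linear
model sharing one OD slope across species (per-species intercepts), and
summarised by V_MAX — the ordinary least-squares slope of log2 cell density
against time over the first 48 h, in doublings per day. Treatment contrasts
use a two-sided label-permutation test on the difference of group means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .stats import ContrastResult, permute_two_sample

__all__ = [
    "TREATMENTS",
    "IsolateLabel",
    "GrowthCurve",
    "CalibrationModel",
    "VmaxEstimate",
    "blank_correct",
    "fit_od_calibration",
    "od_to_log_density",
    "curves_from_table",
    "estimate_vmax",
    "carrying_capacity",
    "vmax_table",
    "treatment_contrast",
]

TREATMENTS = ("ancestral", "monoculture", "polyculture")
LOG2_10 = math.log2(10.0)

#: default floor applied to blank-corrected OD before log-calibration
DEFAULT_OD_FLOOR = 1e-3


@dataclass(frozen=True)
class IsolateLabel:
    """One isolate: species, evolutionary treatment, replicate index."""

    species: str
    treatment: str
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(
                f"treatment must be one of {TREATMENTS}, got {self.treatment!r}"
            )
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")


@dataclass
class GrowthCurve:
    """Blank-corrected, calibrated OD trajectory for one assay well."""

    isolate: IsolateLabel
    substrate: str
    times_h: np.ndarray
    od_raw: np.ndarray | None = None
    od_corrected: np.ndarray | None = None
    log2_density: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")
        for name in ("od_raw", "od_corrected", "log2_density"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.times_h.shape:
                    raise ValueError(f"{name} must align with times")
                setattr(self, name, v)


@dataclass
class CalibrationModel:
    """log10(cells/ml) = intercept[species] + slope * OD600."""

    slope: float
    intercepts: dict[str, float]
    fstat: float = math.nan
    df_model: int = 0
    df_resid: int = 0
    r2: float = math.nan

    def predict_log10(self, od: float | np.ndarray, species: str) -> float | np.ndarray:
        if species not in self.intercepts:
            raise KeyError(f"no calibration intercept for species {species!r}")
        return self.intercepts[species] + self.slope * np.asarray(od, dtype=float)


@dataclass
class VmaxEstimate:
    """Maximum growth rate: OLS slope of log2 density vs time (doublings/day)."""

    isolate: IsolateLabel
    substrate: str
    vmax: float
    se: float
    n_points: int
    window_h: float

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("vmax needs at least 2 points")
        if self.window_h <= 0:
            raise ValueError("window must be positive")


# ---------------------------------------------------------------------------
# blank correction


def blank_correct(
    plate_rows: pd.DataFrame,
    epsilon: float = DEFAULT_OD_FLOOR,
    *,
    od_col: str = "od600",
    control_col: str = "is_control",
) -> pd.DataFrame:
    """Subtract each well's matched sterile control, flooring at ``epsilon``.

    Controls are matched on (plate, column, time_h); the column is parsed
    from the well name (digits) when no explicit ``column`` field exists.
    Measurement wells without a control raise with the offenders listed.
    """
    df = plate_rows.copy()
    if "column" not in df.columns:
        df["column"] = df["well"].astype(str).str.extract(r"(\d+)$")[0].astype(int)
    ctrl = df[df[control_col].astype(bool)]
    meas = df[~df[control_col].astype(bool)].copy()
    key = ["plate", "column", "time_h"]
    blanks = ctrl.groupby(key)[od_col].mean().rename("_blank")
    meas = meas.join(blanks, on=key)
    missing = meas[meas["_blank"].isna()]
    if not missing.empty:
        offenders = missing[key].drop_duplicates().to_records(index=False).tolist()
        raise ValueError(f"no sterile control for (plate, column, time): {offenders}")
    meas["od_corrected"] = np.maximum(meas[od_col] - meas["_blank"], epsilon)
    return meas.drop(columns="_blank")


# ---------------------------------------------------------------------------
# OD -> cell density calibration


def fit_od_calibration(
    calibration_rows: pd.DataFrame,
    *,
    od_col: str = "od600",
    count_col: str = "colonies_per_ml",
    species_col: str = "species",
) -> CalibrationModel:
    """Fit log10(colonies/ml) ~ species + OD600 with one shared slope.

    Mirrors a common-slope / per-species-intercept calibration design; the
    overall regression F, degrees of freedom and r² are reported alongside
    the coefficients.
    """
    df = calibration_rows[[species_col, od_col, count_col]].dropna().copy()
    if (df[count_col] <= 0).any():
        raise ValueError("colony counts must be positive")
    df["_y"] = np.log10(df[count_col])
    per_species_od = df.groupby(species_col)[od_col].nunique()
    if (per_species_od < 2).any():
        bad = per_species_od[per_species_od < 2].index.tolist()
        raise ValueError(f"need >=2 distinct OD values per species; offenders: {bad}")
    df = df.rename(columns={species_col: "_sp", od_col: "_od"})
    fit = smf.ols("_y ~ C(_sp) + _od", data=df).fit()
    if not np.isfinite(fit.params["_od"]):
        raise ValueError("rank-deficient calibration design")
    base = df["_sp"].astype("category").cat.categories[0]
    intercepts = {str(base): float(fit.params["Intercept"])}
    for sp in df["_sp"].unique():
        key = f"C(_sp)[T.{sp}]"
        if key in fit.params:
            intercepts[str(sp)] = float(fit.params["Intercept"] + fit.params[key])
    return CalibrationModel(
        slope=float(fit.params["_od"]),
        intercepts=intercepts,
        fstat=float(fit.fvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        r2=float(fit.rsquared),
    )


def od_to_log_density(
    model: CalibrationModel, od: float | np.ndarray, species: str
) -> float | np.ndarray:
    """Calibrated cell density in log2 cells/ml for a blank-corrected OD."""
    return model.predict_log10(od, species) * LOG2_10


def curves_from_table(
    corrected_rows: pd.DataFrame, model: CalibrationModel
) -> list[GrowthCurve]:
    """Assemble calibrated :class:`GrowthCurve` objects from tidy assay rows."""
    curves = []
    keys = ["species", "treatment", "replicate", "substrate"]
    for (sp, tr, rep, sub), grp in corrected_rows.groupby(keys, sort=True):
        grp = grp.sort_values("time_h")
        od = grp["od_corrected"].to_numpy()
        curves.append(
            GrowthCurve(
                isolate=IsolateLabel(str(sp), str(tr), int(rep)),
                substrate=str(sub),
                times_h=grp["time_h"].to_numpy(),
                od_corrected=od,
                log2_density=np.asarray(od_to_log_density(model, od, str(sp))),
            )
        )
    return curves


# ---------------------------------------------------------------------------
# growth summaries


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and its standard error (0 when the fit is saturated)."""
    n = x.size
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValueError("time points are degenerate")
    slope = float(xc @ y) / sxx
    if n == 2:
        return slope, 0.0
    resid = y - (y.mean() + slope * xc)
    s2 = float(resid @ resid) / (n - 2)
    return slope, math.sqrt(s2 / sxx)


def estimate_vmax(curve: GrowthCurve, window_h: float = 48.0) -> VmaxEstimate:
    """V_MAX: OLS slope of log2 density on time (days) over t <= ``window_h``."""
    if curve.log2_density is None:
        raise ValueError("curve has no calibrated log2 densities")
    mask = curve.times_h <= window_h + 1e-9
    t = curve.times_h[mask] / 24.0
    y = curve.log2_density[mask]
    if t.size < 2:
        raise ValueError(f"need >=2 points within the first {window_h} h")
    slope, se = _ols_slope(t, y)
    return VmaxEstimate(
        isolate=curve.isolate,
        substrate=curve.substrate,
        vmax=slope,
        se=se,
        n_points=int(t.size),
        window_h=float(window_h),
    )


def carrying_capacity(
    curve: GrowthCurve, at_h: float = 96.0, tol_h: float = 4.0
) -> float:
    """Calibrated density (log10 cells/ml) at the reading nearest ``at_h``."""
    if curve.log2_density is None:
        raise ValueError("curve has no calibrated log2 densities")
    d = np.abs(curve.times_h - at_h)
    i = int(np.argmin(d))
    if d[i] > tol_h:
        raise ValueError(f"no reading within {tol_h} h of {at_h} h")
    return float(curve.log2_density[i] / LOG2_10)


def vmax_table(
    corrected_rows: pd.DataFrame,
    model: CalibrationModel,
    window_h: float = 48.0,
) -> pd.DataFrame:
    """Tidy V_MAX per isolate x substrate from blank-corrected assay rows."""
    records = []
    for c in curves_from_table(corrected_rows, model):
        est = estimate_vmax(c, window_h=window_h)
        records.append(
            {
                "species": c.isolate.species,
                "treatment": c.isolate.treatment,
                "replicate": c.isolate.replicate,
                "substrate": c.substrate,
                "vmax": est.vmax,
                "se": est.se,
                "n_points": est.n_points,
                "window_h": est.window_h,
            }
        )
    return pd.DataFrame.from_records(records)


def treatment_contrast(
    estimates_a: list[VmaxEstimate] | np.ndarray,
    estimates_b: list[VmaxEstimate] | np.ndarray,
    B: int = 9999,
    seed: int | None = None,
    exhaustive: bool | None = None,
) -> ContrastResult:
    """Permutation contrast of mean V_MAX between two isolate groups."""
    a = _as_values(estimates_a)
    b = _as_values(estimates_b)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >=2 estimates per group")
    return permute_two_sample(a, b, B=B, seed=seed, exhaustive=exhaustive)


def _as_values(estimates) -> np.ndarray:
    if len(estimates) and isinstance(estimates[0], VmaxEstimate):
        return np.array([e.vmax for e in estimates], dtype=float)
    return np.asarray(estimates, dtype=float)
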