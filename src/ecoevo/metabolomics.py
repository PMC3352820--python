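"""Metabolic-footprint statistics on NMR-style peak tables.

Peak integrals (dimensionless, relative to an internal standard such as DSS)
are loaded into per-sample profiles; net use/production is the difference
between spent and fresh medium (positive = production). Preprocessing
removes named contaminant peaks and collapses groups of near-perfectly
correlated peaks (multiple resonances of one compound). Multivariate
structure is summarised by covariance-based (unscaled) PCA, and treatment
effects are tested by Monte Carlo permutation: whole profiles are shuffled
among (species, treatment) labels with group sizes fixed, and Euclidean
distance statistics are recomputed under each relabelling.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import PermutationTestResult, grouped_permutation

__all__ = [
    "PeakProfile",
    "DeltaProfile",
    "PCAResult",
    "load_peak_table",
    "profiles_to_frame",
    "remove_contaminants",
    "collapse_correlated_peaks",
    "net_change",
    "pca_unscaled",
    "evolution_distance",
    "divergence_distance",
    "permutation_test",
]


@dataclass
class PeakProfile:
    """One sample's peak integrals with its metadata."""

    sample_id: str
    peaks: pd.Series
    species: str = ""
    treatment: str = ""
    substrate: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        self.peaks = pd.Series(self.peaks, dtype=float)
        if self.peaks.index.has_duplicates:
            raise ValueError(f"duplicate peak names in sample {self.sample_id!r}")
        if (self.peaks < 0).any():
            raise ValueError(f"negative integrals in sample {self.sample_id!r}")


@dataclass
class DeltaProfile:
    """Net change of each peak between two media (positive = production)."""

    sample_id: str
    values: pd.Series
    species: str = ""
    treatment: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        self.values = pd.Series(self.values, dtype=float)
        if self.values.index.has_duplicates:
            raise ValueError(f"duplicate peak names in delta {self.sample_id!r}")


@dataclass
class PCAResult:
    """Covariance-based PCA: loadings, scores, eigenvalues."""

    loadings: pd.DataFrame      # peaks x components
    scores: pd.DataFrame        # samples x components
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    mean: pd.Series


# ---------------------------------------------------------------------------
# loading and preprocessing


def load_peak_table(
    source, *, zero_fill: bool = False
) -> list[PeakProfile]:
    """Read a long-format peak table (CSV path or DataFrame) into profiles.

    Requires columns sample_id, peak_id, integral; optional metadata columns
    species, treatment, substrate, replicate. Every sample must report every
    peak unless ``zero_fill`` is set; duplicate (sample, peak) rows error.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    required = {"sample_id", "peak_id", "integral"}
    if not required.issubset(df.columns):
        raise ValueError(f"peak table must have columns {sorted(required)}")
    if df.duplicated(["sample_id", "peak_id"]).any():
        dup = df[df.duplicated(["sample_id", "peak_id"], keep=False)]
        raise ValueError(
            "duplicate (sample, peak) rows: "
            f"{dup[['sample_id', 'peak_id']].drop_duplicates().values.tolist()[:5]}"
        )
    wide = df.pivot(index="sample_id", columns="peak_id", values="integral")
    if wide.isna().any().any():
        if zero_fill:
            wide = wide.fillna(0.0)
        else:
            missing = wide.isna().stack()
            offenders = missing[missing].index.tolist()[:5]
            raise ValueError(f"missing peaks (sample, peak): {offenders}")
    meta_cols = [c for c in ("species", "treatment", "substrate", "replicate")
                 if c in df.columns]
    meta = df.drop_duplicates("sample_id").set_index("sample_id")
    profiles = []
    for sid in wide.index:
        kw = {c: meta.loc[sid, c] for c in meta_cols}
        if "replicate" in kw:
            kw["replicate"] = int(kw["replicate"])
        profiles.append(PeakProfile(sample_id=str(sid), peaks=wide.loc[sid], **kw))
    return profiles


def profiles_to_frame(profiles) -> pd.DataFrame:
    """Stack profiles into a samples x peaks DataFrame (axes must agree)."""
    if not profiles:
        raise ValueError("no profiles given")
    series = [p.peaks if isinstance(p, PeakProfile) else p.values for p in profiles]
    axis = series[0].index
    for p, s in zip(profiles, series):
        if not s.index.equals(axis):
            raise ValueError(f"peak axis mismatch at sample {p.sample_id!r}")
    return pd.DataFrame(
        np.vstack([s.to_numpy() for s in series]),
        index=[p.sample_id for p in profiles],
        columns=axis,
    )


def _replace_axis(profile, new: pd.Series):
    out = type(profile)(
        sample_id=profile.sample_id,
        **{("peaks" if isinstance(profile, PeakProfile) else "values"): new},
        species=profile.species,
        treatment=profile.treatment,
        replicate=profile.replicate,
        **({"substrate": profile.substrate} if isinstance(profile, PeakProfile) else {}),
    )
    return out


def remove_contaminants(profiles, names) -> list:
    """Drop named contaminant peaks (e.g. methanol, acetonitrile) everywhere.

    Absent names are tolerated (the sample set may already lack them);
    removing every peak errors.
    """
    if not profiles:
        return []
    axis = (profiles[0].peaks if isinstance(profiles[0], PeakProfile)
            else profiles[0].values).index
    present = [n for n in names if n in axis]
    keep = axis.difference(present, sort=False)
    if len(keep) == 0:
        raise ValueError("contaminant removal would empty the peak axis")
    out = []
    for p in profiles:
        s = p.peaks if isinstance(p, PeakProfile) else p.values
        out.append(_replace_axis(p, s[keep]))
    return out


def collapse_correlated_peaks(
    profiles, r_threshold: float = 0.95
) -> tuple[list, list[list[str]]]:
    """Merge groups of peaks with pairwise Pearson r above the threshold.

    Peaks whose integrals are near-proportional across samples usually are
    multiple resonances of one compound; single-linkage groups over pairs
    with r > ``r_threshold`` are each replaced by the sum of their members
    (named ``first+second+...``). Returns (profiles, groups).
    """
    frame = profiles_to_frame(profiles)
    if frame.shape[0] < 3:
        raise ValueError("correlation grouping needs at least 3 samples")
    corr = frame.corr().to_numpy()
    peaks = list(frame.columns)
    n = len(peaks)
    # single linkage = connected components of the r > threshold graph
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(n), 2):
        if np.isfinite(corr[i, j]) and corr[i, j] > r_threshold:
            parent[find(i)] = find(j)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    groups = [sorted(peaks[i] for i in members)
              for members in comps.values() if len(members) > 1]
    groups.sort()
    if not groups:
        return list(profiles), []
    merged = frame.copy()
    for grp in groups:
        merged["+".join(grp)] = merged[grp].sum(axis=1)
        merged = merged.drop(columns=grp)
    out = []
    for p in profiles:
        out.append(_replace_axis(p, merged.loc[p.sample_id]))
    return out, groups


def net_change(after: PeakProfile, before: PeakProfile) -> DeltaProfile:
    """Spent-minus-fresh profile: positive values mean net production."""
    if not after.peaks.index.equals(before.peaks.index):
        raise ValueError("profiles must share an identical peak axis")
    return DeltaProfile(
        sample_id=after.sample_id,
        values=after.peaks - before.peaks,
        species=after.species,
        treatment=after.treatment,
        replicate=after.replicate,
    )


# ---------------------------------------------------------------------------
# PCA


def pca_unscaled(deltas, center: bool = True) -> PCAResult:
    """PCA of the covariance (unscaled variances, centered, not standardised).

    Eigenvalues use the n-1 divisor, so their sum equals the total variance
    of the input. Component signs are fixed by making each component's
    largest-magnitude loading positive.
    """
    frame = profiles_to_frame(deltas)
    if frame.shape[0] < 2 or frame.shape[1] < 2:
        raise ValueError("need >=2 samples and >=2 peaks")
    X = frame.to_numpy(dtype=float)
    mean = X.mean(axis=0)
    Xc = X - mean if center else X.copy()
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (X.shape[0] - 1)
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    scores = u * s
    names = [f"PC{k + 1}" for k in range(len(eig))]
    total = eig.sum()
    return PCAResult(
        loadings=pd.DataFrame(vt.T, index=frame.columns, columns=names),
        scores=pd.DataFrame(scores, index=frame.index, columns=names),
        eigenvalues=eig,
        variance_fractions=eig / total if total > 0 else eig,
        mean=pd.Series(mean, index=frame.columns),
    )


# ---------------------------------------------------------------------------
# distance statistics


def _species_means(profiles) -> tuple[np.ndarray, list[str]]:
    frame = profiles_to_frame(profiles)
    sp = pd.Index([p.species for p in profiles], name="species")
    means = frame.groupby(sp).mean()
    return means.to_numpy(), list(means.index)


def evolution_distance(ancestral, evolved) -> float:
    """Mean per-species Euclidean distance between ancestral and evolved
    footprints (replicates averaged within species first)."""
    ma, sa = _species_means(ancestral)
    me, se = _species_means(evolved)
    if sa != se:
        raise ValueError(f"species sets differ: {sa} vs {se}")
    return float(np.linalg.norm(ma - me, axis=1).mean())


def divergence_distance(profiles) -> float:
    """Mean Euclidean distance between species' footprints within one
    treatment (all unordered species pairs, replicates averaged first)."""
    means, species = _species_means(profiles)
    if len(species) < 2:
        raise ValueError("divergence needs at least 2 species")
    dists = [
        np.linalg.norm(means[i] - means[j])
        for i, j in itertools.combinations(range(len(species)), 2)
    ]
    return float(np.mean(dists))


# ---------------------------------------------------------------------------
# Monte Carlo permutation tests


def _group_setup(profiles):
    labels = [(p.species, p.treatment) for p in profiles]
    uniq = sorted(set(labels))
    code = {lab: k for k, lab in enumerate(uniq)}
    g = np.array([code[lab] for lab in labels], dtype=np.intp)
    return g, uniq


def _evolution_stat_fn(uniq, reference: str, focal: str):
    by_species: dict[str, dict[str, int]] = {}
    for k, (sp, tr) in enumerate(uniq):
        by_species.setdefault(sp, {})[tr] = k
    ia, ie = [], []
    for sp, trs in sorted(by_species.items()):
        if reference in trs and focal in trs:
            ia.append(trs[reference])
            ie.append(trs[focal])
    if not ia:
        raise ValueError(
            f"no species carries both {reference!r} and {focal!r} profiles"
        )
    ia, ie = np.array(ia), np.array(ie)

    def stat(means: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(means[..., ia, :] - means[..., ie, :], axis=-1)
        return d.mean(axis=-1)

    return stat


def _divergence_pairs(uniq, treatment: str):
    idx = [k for k, (_, tr) in enumerate(uniq) if tr == treatment]
    if len(idx) < 2:
        raise ValueError(f"treatment {treatment!r} has fewer than 2 species groups")
    pairs = np.array(list(itertools.combinations(idx, 2)))
    return pairs[:, 0], pairs[:, 1]


def _divergence_stat_fn(uniq, focal: str, reference: str | None):
    fi, fj = _divergence_pairs(uniq, focal)
    if reference is None:
        def stat(means):
            return np.linalg.norm(
                means[..., fi, :] - means[..., fj, :], axis=-1
            ).mean(axis=-1)
        return stat
    ri, rj = _divergence_pairs(uniq, reference)

    def stat(means):
        df = np.linalg.norm(means[..., fi, :] - means[..., fj, :], axis=-1).mean(axis=-1)
        dr = np.linalg.norm(means[..., ri, :] - means[..., rj, :], axis=-1).mean(axis=-1)
        return df - dr

    return stat


def permutation_test(
    statistic,
    profiles,
    B: int = 10_000,
    seed: int | None = None,
    *,
    focal_treatment: str | None = None,
    reference_treatment: str = "ancestral",
    exhaustive: bool = False,
    block_by_species: bool = True,
) -> PermutationTestResult:
    """Monte Carlo test shuffling whole profiles among treatment labels.

    ``statistic`` is ``"evolution_distance"`` (mean paired distance between
    the reference and focal treatment, per species), ``"divergence_distance"``
    (between-species divergence within the focal treatment, minus the same
    quantity in the reference treatment when the pool contains it — a shuffle
    confined to one treatment with one profile per species would leave plain
    divergence invariant), or a callable receiving group means of shape
    (..., G, n_peaks).

    By default species act as a blocking factor: profiles are shuffled among
    treatment labels *within* each species, which keeps every group's size
    fixed and makes the null distribution reflect treatment assignment
    rather than between-species differences (an unrestricted shuffle mixes
    species and is dominated by them; set ``block_by_species=False`` to get
    that scheme). Two-tailed p doubles the smaller tail with the add-one
    correction; ``exhaustive=True`` enumerates every distinct order (the
    observed one included, so no correction is added).
    """
    g, uniq = _group_setup(profiles)
    treatments = {tr for _, tr in uniq}
    if focal_treatment is None:
        evolved = sorted(treatments - {reference_treatment})
        if len(evolved) != 1 and callable(statistic) is False:
            raise ValueError(
                "focal_treatment is required when several non-reference "
                f"treatments are present: {sorted(treatments)}"
            )
        focal_treatment = evolved[0] if evolved else reference_treatment

    if callable(statistic):
        stat_fn, name = statistic, getattr(statistic, "__name__", "custom")
    elif statistic == "evolution_distance":
        stat_fn = _evolution_stat_fn(uniq, reference_treatment, focal_treatment)
        name = "evolution_distance"
    elif statistic == "divergence_distance":
        ref = reference_treatment if reference_treatment in treatments else None
        ref = None if ref == focal_treatment else ref
        stat_fn = _divergence_stat_fn(uniq, focal_treatment, ref)
        name = "divergence_distance"
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    X = profiles_to_frame(profiles).to_numpy(dtype=float)
    blocks = None
    if block_by_species:
        species = sorted({p.species for p in profiles})
        code = {s: k for k, s in enumerate(species)}
        blocks = np.array([code[p.species] for p in profiles], dtype=np.intp)
    return grouped_permutation(
        X, g, stat_fn, name, B=B, seed=seed, exhaustive=exhaustive,
        blocks=blocks,
    )
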