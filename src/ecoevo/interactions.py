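"""Spent-medium interaction networks.

The interaction of a donor species on a recipient is read off growth assays:
the recipient's maximum growth rate on medium previously used by the donor
(then filter-sterilised) minus its rate on fresh medium. Negative effects
indicate niche overlap (the donor consumed shared resources), positive
effects facilitation/cross-feeding (the donor produced usable by-products).
Significance is a two-sided label-permutation test; the relative growth
ratio carries a percentile-bootstrap interval. Edges assemble into a
directed network per treatment.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from ._seeding import child_seed
from .growth import TREATMENTS, VmaxEstimate
from .stats import permute_two_sample

__all__ = [
    "InteractionEdge",
    "interaction_effect",
    "interaction_table",
    "build_network",
    "write_network",
    "read_network_csv",
]

SIGNS = ("negative", "neutral", "positive")


@dataclass
class InteractionEdge:
    """Donor -> recipient effect on maximum growth rate."""

    donor: str
    recipient: str
    treatment: str
    effect: float                  # mean vmax(used) - mean vmax(unused)
    relative: float | None         # mean vmax(used) / mean vmax(unused)
    ci_low: float | None
    ci_high: float | None
    p: float
    sign: str
    n_used: int
    n_unused: int

    def __post_init__(self) -> None:
        if self.donor == self.recipient:
            raise ValueError("donor and recipient must differ")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.sign not in SIGNS:
            raise ValueError(f"sign must be one of {SIGNS}")


def _values(estimates) -> np.ndarray:
    if len(estimates) and isinstance(estimates[0], VmaxEstimate):
        return np.array([e.vmax for e in estimates], dtype=float)
    return np.asarray(estimates, dtype=float)


def interaction_effect(
    used,
    unused,
    donor: str,
    recipient: str,
    treatment: str,
    alpha: float = 0.05,
    B: int = 9999,
    n_boot: int = 1000,
    seed: int | None = None,
) -> InteractionEdge:
    """One network edge from replicate V_MAX values on used vs unused medium.

    The effect and the relative ratio are computed on group means; p is a
    two-sided permutation test of the group labels and the ratio interval a
    percentile bootstrap over replicates. When the mean unused rate is not
    positive the ratio is undefined and reported missing.
    """
    u = _values(used)
    f = _values(unused)
    if u.size < 2 or f.size < 2:
        raise ValueError("need >=2 replicates on each medium")
    contrast = permute_two_sample(u, f, B=B, seed=seed)
    effect = contrast.difference
    relative = contrast.ratio

    ci_low = ci_high = None
    if relative is not None and n_boot > 0:
        rng = np.random.default_rng(None if seed is None else seed + 1)
        iu = rng.integers(0, u.size, size=(n_boot, u.size))
        if_ = rng.integers(0, f.size, size=(n_boot, f.size))
        denom = f[if_].mean(axis=1)
        ok = denom > 0
        if ok.sum() >= max(10, n_boot // 2):
            ratios = u[iu].mean(axis=1)[ok] / denom[ok]
            ci_low, ci_high = (float(q) for q in np.quantile(ratios, [0.025, 0.975]))

    if contrast.p < alpha:
        sign = "negative" if effect < 0 else "positive"
    else:
        sign = "neutral"
    return InteractionEdge(
        donor=donor,
        recipient=recipient,
        treatment=treatment,
        effect=float(effect),
        relative=relative,
        ci_low=ci_low,
        ci_high=ci_high,
        p=float(contrast.p),
        sign=sign,
        n_used=int(u.size),
        n_unused=int(f.size),
    )


def interaction_table(
    vmax_rows: pd.DataFrame,
    treatment: str,
    alpha: float = 0.05,
    B: int = 9999,
    seed: int | None = None,
    n_boot: int = 1000,
) -> list[InteractionEdge]:
    """All donor -> recipient edges of one treatment from a tidy V_MAX table.

    Expects columns species / treatment / substrate / vmax with substrates
    ``unused`` and ``used_by:<donor>``; donor and recipient always share the
    treatment (cross-treatment conditioning is rejected upstream by the
    generator and the pipeline).
    """
    df = vmax_rows[vmax_rows["treatment"] == treatment]
    edges = []
    species = sorted(df["species"].unique())
    for recipient in species:
        unused = df[(df["species"] == recipient) & (df["substrate"] == "unused")][
            "vmax"
        ].to_numpy()
        for donor in species:
            if donor == recipient:
                continue
            used = df[
                (df["species"] == recipient)
                & (df["substrate"] == f"used_by:{donor}")
            ]["vmax"].to_numpy()
            if used.size == 0:
                continue
            edge_seed = None if seed is None else child_seed(seed, donor, recipient)
            edges.append(
                interaction_effect(
                    used, unused, donor, recipient, treatment,
                    alpha=alpha, B=B, n_boot=n_boot, seed=edge_seed,
                )
            )
    return edges


def build_network(edges: list[InteractionEdge]) -> nx.DiGraph:
    """Directed interaction graph; edge attributes carry effect/sign/p."""
    if not edges:
        raise ValueError("no edges")
    treatments = {e.treatment for e in edges}
    if len(treatments) > 1:
        raise ValueError(f"edges mix treatments: {sorted(treatments)}")
    G = nx.DiGraph(treatment=edges[0].treatment)
    for e in edges:
        if G.has_edge(e.donor, e.recipient):
            raise ValueError(f"duplicate edge {e.donor}->{e.recipient}")
        G.add_edge(
            e.donor,
            e.recipient,
            effect=e.effect,
            sign=e.sign,
            p=e.p,
            relative=np.nan if e.relative is None else e.relative,
            dashed=e.sign == "neutral",
        )
    return G


_EDGE_FIELDS = ("donor", "recipient", "effect", "sign", "p", "relative", "dashed")


def write_network(G: nx.DiGraph, path: str | Path, format: str = "csv") -> Path:
    """Write the network as a round-trippable CSV edge list, DOT, or GraphML."""
    path = Path(path)
    if format == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(_EDGE_FIELDS)
            for u, v, d in sorted(G.edges(data=True)):
                w.writerow([u, v, d["effect"], d["sign"], d["p"],
                            d["relative"], d["dashed"]])
    elif format == "dot":
        colour = {"negative": "blue", "positive": "red", "neutral": "grey"}
        lines = ["digraph interactions {"]
        for u, v, d in sorted(G.edges(data=True)):
            style = "dashed" if d["dashed"] else "solid"
            lines.append(
                f'  "{u}" -> "{v}" [color={colour[d["sign"]]}, style={style}, '
                f'penwidth={max(0.5, abs(d["effect"]) * 3):.2f}, '
                f'label="{d["effect"]:+.2f}"];'
            )
        lines.append("}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format == "graphml":
        nx.write_graphml(G, path)
    else:
        raise ValueError(f"unsupported format {format!r}")
    return path


def read_network_csv(path: str | Path) -> nx.DiGraph:
    """Rebuild a network from the CSV edge list written by write_network."""
    df = pd.read_csv(path)
    G = nx.DiGraph()
    for _, row in df.iterrows():
        G.add_edge(
            row["donor"], row["recipient"],
            effect=float(row["effect"]), sign=row["sign"], p=float(row["p"]),
            relative=float(row["relative"]),
            dashed=bool(row["dashed"]) if not isinstance(row["dashed"], str)
            else row["dashed"].lower() == "true",
        )
    return G
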