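"""Dice-coefficient overlap between region sets, permutation null, FDR.

Networks and parcels are sets of region labels drawn from a declared
universe (typically the 34 Desikan-Killiany cortical regions).  The
permutation null repopulates the *network* with uniform draws from the
universe, holding the parcel fixed, and uses the add-one Monte-Carlo
p-value (1 + #{null >= observed}) / (1 + n_iter).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


def normalize_region(name: str) -> str:
    """Case-, whitespace-, underscore- and hyphen-insensitive region key."""
    return re.sub(r"[\s_\-\.]+", "", name.strip().lower())


@dataclass(frozen=True)
class RegionSet:
    """A named set of region labels with optional per-region size weights."""

    name: str
    regions: frozenset[str]
    weights: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValueError(f"region set {self.name!r} is empty")

    @classmethod
    def from_labels(cls, name: str, labels: Iterable[str],
                    universe: Sequence[str] | None = None,
                    weights: Mapping[str, float] | None = None) -> "RegionSet":
        """Build a set, validating labels against a universe when given.

        Unknown names are errors, never silent drops.
        """
        if universe is not None:
            canon = {normalize_region(u): u for u in universe}
            resolved = []
            for lab in labels:
                key = normalize_region(lab)
                if key not in canon:
                    raise KeyError(f"region {lab!r} not in the declared universe")
                resolved.append(canon[key])
            labels = resolved
        return cls(name=name, regions=frozenset(labels), weights=weights)


@dataclass
class OverlapResult:
    """Observed Dice for a (network, parcel) pair with its permutation p."""

    pair: tuple[str, str]
    dice: float
    p_perm: float
    q_fdr: float | None = None
    n_iter: int = 0
    seed: int | None = None


def dice_coefficient(a: RegionSet, b: RegionSet) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); weighted analogue when both carry weights."""
    inter = a.regions & b.regions
    if a.weights is not None and b.weights is not None:
        w = {**b.weights, **a.weights}
        num = 2.0 * sum(w[r] for r in inter)
        den = sum(a.weights[r] for r in a.regions) + sum(b.weights[r] for r in b.regions)
    else:
        num = 2.0 * len(inter)
        den = len(a.regions) + len(b.regions)
    return num / den if den else 0.0


def permutation_pvalue(
    network: RegionSet,
    parcel: RegionSet,
    universe: Sequence[str],
    n_iter: int = 1000,
    seed: int | None = None,
) -> OverlapResult:
    """Permutation significance of the observed Dice coefficient.

    Each iteration redraws |network| regions uniformly without replacement
    from the universe and recomputes Dice against the fixed parcel.  When
    both sets carry weights, the weighted Dice is used for the observed and
    the null values alike (null networks inherit the network's weights,
    falling back to the parcel's for regions outside it).
    """
    universe = list(universe)
    k = len(network.regions)
    if k > len(universe):
        raise ValueError(
            f"network {network.name!r} ({k} regions) larger than the universe ({len(universe)})"
        )
    weighted = network.weights is not None and parcel.weights is not None
    observed = dice_coefficient(network, parcel)
    rng = np.random.default_rng(seed)
    uni = np.array(universe, dtype=object)
    null_w = dict(parcel.weights or {}) | dict(network.weights or {}) if weighted else None
    parcel_set = parcel.regions
    nb = len(parcel.regions)
    count = 0
    for _ in range(n_iter):
        draw = rng.choice(uni, size=k, replace=False)
        if weighted:
            null_net = RegionSet("null", frozenset(draw), null_w)
            null_dice = dice_coefficient(null_net, parcel)
        else:
            inter = sum(1 for r in draw if r in parcel_set)
            null_dice = 2.0 * inter / (k + nb)
        if null_dice >= observed:
            count += 1
    p = (1.0 + count) / (1.0 + n_iter)
    return OverlapResult(pair=(network.name, parcel.name), dice=observed,
                         p_perm=p, n_iter=n_iter, seed=seed)


def fdr_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg q-values (length- and order-preserving)."""
    pvalues = np.asarray(pvalues, float)
    if pvalues.size == 0:
        return pvalues
    return multipletests(pvalues, method="fdr_bh")[1]


def region_union_count(sets: Sequence[RegionSet]) -> int:
    """Number of distinct regions covered by a collection of region sets."""
    out: set[str] = set()
    for s in sets:
        out |= s.regions
    return len(out)


def overlap_table(results: Sequence[OverlapResult], adjust: bool = True) -> pd.DataFrame:
    """Tabulate overlap results; fills q_fdr across the batch when adjust=True."""
    df = pd.DataFrame(
        {
            "network": [r.pair[0] for r in results],
            "parcel": [r.pair[1] for r in results],
            "dice": [r.dice for r in results],
            "p_perm": [r.p_perm for r in results],
            "n_iter": [r.n_iter for r in results],
            "seed": [r.seed for r in results],
        }
    )
    if adjust and len(df):
        q = fdr_adjust(df["p_perm"].to_numpy())
        df.insert(4, "q_fdr", q)
        for r, qv in zip(results, q):
            r.q_fdr = float(qv)
    return df


def load_region_sets(path: str | Path,
                     universe: Sequence[str] | None = None) -> dict[str, RegionSet]:
    """Read region sets from two-column TSV (set_name, region) or JSON {name: [regions]}."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            raw = json.load(fh)
        items = raw.items()
    else:
        df = pd.read_csv(path, sep="\t", header=None, names=["set_name", "region"],
                         comment="#", skip_blank_lines=True)
        items = ((name, grp["region"].tolist()) for name, grp in df.groupby("set_name", sort=False))
    return {name: RegionSet.from_labels(name, labels, universe) for name, labels in items}
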