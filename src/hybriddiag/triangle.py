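"""Ancestry-informative markers, hybrid index and interclass heterozygosity.

AIMs are biallelic sites whose allele frequencies differ between two
parental groups by at least a threshold delta; at delta = 1.0 with a single
diploid per parent this admits exactly the sites fixed for alternate
alleles.  For a sample genotyped at the AIMs, the hybrid index h is the
proportion of its alleles derived from parent 2, and the interclass
heterozygosity H the proportion of AIMs carrying one allele from each
parental class.  (h, H) pairs live in the triangle with vertices P1 =
(0, 0), P2 = (1, 0) and F1 = (0.5, 1.0): a true F1 sits at the apex,
backcrosses along the edges.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "AIM",
    "AIMSet",
    "TriangleStats",
    "TRIANGLE_VERTICES",
    "discover_aims",
    "hybrid_index",
    "interclass_heterozygosity",
    "triangle_stats_for_sample",
    "triangle_coordinates",
    "plot_triangle",
]

Genotypes = Mapping[int, tuple[str, str]]

TRIANGLE_VERTICES = {"P1": (0.0, 0.0), "P2": (1.0, 0.0), "F1": (0.5, 1.0)}

_MISSING = {None, "N", ".", ""}


@dataclass(frozen=True)
class AIM:
    scaffold: str
    position: int
    allele_p1: str
    allele_p2: str
    delta: float


@dataclass
class AIMSet:
    """Sites passing the allele-frequency-difference filter, parent-oriented."""

    sites: list[AIM]
    delta_threshold: float
    n_skipped_missing: int = 0
    n_skipped_multiallelic: int = 0

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def positions(self) -> list[int]:
        return [a.position for a in self.sites]


@dataclass
class TriangleStats:
    """(hybrid index, interclass heterozygosity) for one sample."""

    sample_id: str
    hybrid_index: float
    interclass_het: float
    n_aims_used: int

    @property
    def in_triangle(self) -> bool:
        h, H = self.hybrid_index, self.interclass_het
        return H <= 2.0 * min(h, 1.0 - h) + 1e-12


def _allele_counts(samples: Sequence[Genotypes], pos: int) -> Counter:
    counts: Counter = Counter()
    for gt_map in samples:
        gt = gt_map.get(pos)
        if gt is None:
            continue
        for allele in gt:
            if allele not in _MISSING:
                counts[allele] += 1
    return counts


def discover_aims(
    genotypes_p1: Sequence[Genotypes],
    genotypes_p2: Sequence[Genotypes],
    delta: float = 1.0,
    scaffold: str = "scaffold_1",
) -> AIMSet:
    """Find ancestry-informative markers from parental genotype sets.

    Per-site allele frequencies are computed within each parental group;
    sites are kept when the frequency difference of the parent-2-oriented
    allele is at least ``delta`` (closed threshold, so delta = 1.0 admits
    exactly fixed differences).  Sites missing in every sample of a group
    or with more than two alleles overall are skipped and counted.

    Parental genotypes are mappings position -> (allele, allele); a single
    diploid per parent (frequencies in {0, 0.5, 1}) is the minimal input,
    but any number of samples per group is accepted.
    """
    if not genotypes_p1 or not genotypes_p2:
        raise ValueError("parental genotype sets must be non-empty")
    positions = sorted(
        {p for s in genotypes_p1 for p in s} | {p for s in genotypes_p2 for p in s}
    )
    sites: list[AIM] = []
    n_missing = 0
    n_multi = 0
    for pos in positions:
        c1 = _allele_counts(genotypes_p1, pos)
        c2 = _allele_counts(genotypes_p2, pos)
        if not c1 or not c2:
            n_missing += 1
            continue
        alleles = set(c1) | set(c2)
        if len(alleles) > 2:
            n_multi += 1
            continue
        a2 = c2.most_common(1)[0][0]  # parent-2 orientation allele
        f1 = c1[a2] / sum(c1.values())
        f2 = c2[a2] / sum(c2.values())
        d = abs(f2 - f1)
        if d >= delta:
            a1 = c1.most_common(1)[0][0]
            if a1 == a2:
                continue
            sites.append(AIM(scaffold=scaffold, position=pos, allele_p1=a1, allele_p2=a2, delta=d))
    return AIMSet(
        sites=sites,
        delta_threshold=delta,
        n_skipped_missing=n_missing,
        n_skipped_multiallelic=n_multi,
    )


def _usable(sample_genotypes: Genotypes, aims: AIMSet) -> list[tuple[AIM, tuple[str, str]]]:
    used = []
    for aim in aims:
        gt = sample_genotypes.get(aim.position)
        if gt is None or any(a in _MISSING for a in gt):
            continue
        used.append((aim, gt))
    return used


def hybrid_index(sample_genotypes: Genotypes, aims: AIMSet) -> float:
    """Proportion of the sample's alleles at genotyped AIMs that carry the
    parent-2 allele; 0 for pure P1, 1 for pure P2, 0.5 for equal ancestry.
    AIMs missing in the sample are excluded."""
    used = _usable(sample_genotypes, aims)
    if not used:
        raise ValueError("sample genotyped at zero AIMs")
    n_p2 = sum(1 for aim, gt in used for allele in gt if allele == aim.allele_p2)
    return n_p2 / (2 * len(used))


def interclass_heterozygosity(sample_genotypes: Genotypes, aims: AIMSet) -> float:
    """Proportion of genotyped AIMs carrying exactly one parent-1 and one
    parent-2 allele; 1.0 for a true F1, 0 for pure parents."""
    used = _usable(sample_genotypes, aims)
    if not used:
        raise ValueError("sample genotyped at zero AIMs")
    n_het = sum(
        1
        for aim, gt in used
        if {aim.allele_p1, aim.allele_p2} == set(gt) and gt[0] != gt[1]
    )
    return n_het / len(used)


def triangle_stats_for_sample(
    sample_id: str, sample_genotypes: Genotypes, aims: AIMSet
) -> TriangleStats:
    used = _usable(sample_genotypes, aims)
    if not used:
        raise ValueError("sample genotyped at zero AIMs")
    return TriangleStats(
        sample_id=sample_id,
        hybrid_index=hybrid_index(sample_genotypes, aims),
        interclass_het=interclass_heterozygosity(sample_genotypes, aims),
        n_aims_used=len(used),
    )


def triangle_coordinates(stats: Sequence[TriangleStats]) -> pd.DataFrame:
    """Plot table of (h, H) pairs with per-sample triangle-feasibility flags."""
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in stats],
            "hybrid_index": [s.hybrid_index for s in stats],
            "interclass_het": [s.interclass_het for s in stats],
            "n_aims_used": [s.n_aims_used for s in stats],
            "in_triangle": [s.in_triangle for s in stats],
        }
    )


def plot_triangle(stats: Sequence[TriangleStats], path=None, ax=None):
    """Render a triangle plot; returns the matplotlib Axes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    xs = [0.0, 1.0, 0.5, 0.0]
    ys = [0.0, 0.0, 1.0, 0.0]
    ax.plot(xs, ys, color="0.6", lw=1)
    df = triangle_coordinates(stats)
    ax.scatter(df["hybrid_index"], df["interclass_het"], zorder=3)
    for _, row in df.iterrows():
        ax.annotate(row["sample_id"], (row["hybrid_index"], row["interclass_het"]),
                    fontsize=7, xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("hybrid index (h)")
    ax.set_ylabel("interclass heterozygosity (H)")
    ax.set_xlim(-0.05, 1.05)
    ax.set_ylim(-0.05, 1.05)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
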