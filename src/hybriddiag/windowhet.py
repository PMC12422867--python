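"""Per-site heterozygosity in a genomic window and synthetic-hybrid diploids.

Heterozygosity of a phased diploid window is the fraction of comparable
sites (both haplotypes called, no gap) at which the haplotypes differ.  A
"synthetic hybrid" pairs one haplotype from each of two species into an
artificial diploid whose window heterozygosity estimates the cross-species
divergence — the level a true F1 should show, providing a yardstick for a
putative natural hybrid.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from .simulate import DiploidIndividual

__all__ = [
    "DiploidWindow",
    "per_site_heterozygosity",
    "make_synthetic_hybrid",
    "window_from_individual",
]

_CALLED = set("ACGT")


@dataclass
class DiploidWindow:
    """Two aligned haplotype sequences over one genomic window.

    Sequences may contain ``N`` (masked) and ``-`` (alignment gap); both are
    excluded from heterozygosity numerator and denominator.
    """

    sample_id: str
    scaffold: str
    start: int
    end: int
    hap1: str
    hap2: str

    def __post_init__(self) -> None:
        if len(self.hap1) != len(self.hap2):
            raise ValueError("haplotypes must be aligned to a common length")

    def __len__(self) -> int:
        return len(self.hap1)

    @property
    def het_sites(self) -> int:
        return sum(
            1
            for a, b in zip(self.hap1, self.hap2)
            if a in _CALLED and b in _CALLED and a != b
        )


def per_site_heterozygosity(win: DiploidWindow) -> float:
    """Differing sites / comparable sites, where a site is comparable when
    both haplotypes carry a called base (not N, not a gap)."""
    comparable = sum(
        1 for a, b in zip(win.hap1, win.hap2) if a in _CALLED and b in _CALLED
    )
    if comparable == 0:
        raise ValueError("window has no comparable sites")
    return win.het_sites / comparable


def _end_gap_free_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -7.0
    aligner.extend_gap_score = -2.0
    # homologous windows may start/end offset; end gaps are free
    aligner.end_gap_score = 0.0
    return aligner


def make_synthetic_hybrid(
    hap_from_species_a: str,
    hap_from_species_b: str,
    sample_id: str = "synthetic_hybrid",
    scaffold: str = "window",
    gap_tolerance: float = 0.1,
) -> DiploidWindow:
    """Pair one haplotype from each species into an artificial F1-like diploid.

    The two haplotypes are globally aligned (end gaps free); indel columns
    remain in the aligned strings but are excluded from the heterozygosity
    site count.  If the gapped fraction of the alignment exceeds
    ``gap_tolerance`` the windows are considered non-homologous.
    """
    a, b = hap_from_species_a.upper(), hap_from_species_b.upper()
    if not a or not b:
        raise ValueError("empty haplotype")
    if len(a) == len(b) and "-" not in a and "-" not in b:
        aligned_a, aligned_b = a, b
    else:
        aligner = _end_gap_free_aligner()
        alignment = aligner.align(a.replace("-", ""), b.replace("-", ""))[0]
        aligned_a, aligned_b = str(alignment[0]), str(alignment[1])
        gap_cols = sum(
            1 for x, y in zip(aligned_a, aligned_b) if x == "-" or y == "-"
        )
        if gap_cols / len(aligned_a) > gap_tolerance:
            raise ValueError(
                f"alignment has {gap_cols}/{len(aligned_a)} gapped columns, "
                f"beyond the configured tolerance {gap_tolerance}"
            )
    return DiploidWindow(
        sample_id=sample_id,
        scaffold=scaffold,
        start=0,
        end=len(aligned_a),
        hap1=aligned_a,
        hap2=aligned_b,
    )


def window_from_individual(
    ind: DiploidIndividual, start: int = 0, end: int | None = None, scaffold: str = "scaffold_1"
) -> DiploidWindow:
    """Extract a diploid window directly from a simulated individual."""
    if end is None:
        end = ind.L
    return DiploidWindow(
        sample_id=ind.sample_id,
        scaffold=scaffold,
        start=start,
        end=end,
        hap1=ind.hap1[start:end],
        hap2=ind.hap2[start:end],
    )
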