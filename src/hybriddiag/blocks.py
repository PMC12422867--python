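"""Phase-block filtering and parental assignment against a candidate panel.

Each phased haplotype block carries two consensus haplotype sequences; both
are scored against every candidate parental reference with a local
aligner whose decision semantics follow nucleotide-BLAST ranking (rank by
alignment score, equal top scores form a tie-set, hits below an identity
gate are excluded).  For a true F1 the two parental lineages are expected
to receive roughly equal numbers of top hits, which is tested with an
exact binomial test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from scipy import stats

__all__ = [
    "PhaseBlock",
    "CandidatePanel",
    "Hit",
    "HitReport",
    "HitTally",
    "filter_blocks",
    "block_summary",
    "make_aligner",
    "score_haplotype",
    "tally_top_hits",
    "f1_balance_test",
]


@dataclass
class PhaseBlock:
    """A contiguous run of phased variants with two haplotype consensus sequences.

    The block length convention is pinned as (last variant - first variant
    + 1): phase blocks are defined by the span of their phased variants.
    Haplotype sequences cover ``[start, end)`` and may contain ``N`` at
    masked sites.
    """

    scaffold: str
    start: int
    end: int
    variant_positions: list[int]
    hap1_seq: str
    hap2_seq: str

    def __post_init__(self) -> None:
        if len(self.hap1_seq) != len(self.hap2_seq):
            raise ValueError("haplotype sequences must have equal length")
        if not self.variant_positions:
            raise ValueError("a phase block needs at least one variant position")
        vp = self.variant_positions
        if any(p < self.start or p >= self.end for p in vp):
            raise ValueError("variant positions must lie within the block span")

    @property
    def n_variants(self) -> int:
        return len(self.variant_positions)

    @property
    def length(self) -> int:
        vp = self.variant_positions
        return vp[-1] - vp[0] + 1

    @property
    def haplotypes(self) -> tuple[str, str]:
        return (self.hap1_seq, self.hap2_seq)


class CandidatePanel(dict):
    """Labeled candidate-parent reference sequences, homologous to the query scaffold.

    A thin mapping label -> sequence with uniqueness and size validation;
    sequences may be full scaffolds (queries are sliced to the block span)
    or pre-extracted homologous regions.
    """

    def __init__(self, entries: Mapping[str, str]):
        if len(entries) < 2:
            raise ValueError("a candidate panel needs at least two labeled sequences")
        super().__init__(entries)

    @classmethod
    def from_fasta(cls, path) -> "CandidatePanel":
        entries = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        return cls(entries)

    def region(self, label: str, start: int, end: int) -> str:
        """Homologous region of a candidate; falls back to the whole sequence
        when the candidate is shorter than the requested span (pre-extracted
        panels)."""
        seq = self[label]
        if len(seq) >= end:
            return seq[start:end]
        return seq


@dataclass(frozen=True)
class Hit:
    label: str
    score: float
    identity: float


@dataclass
class HitReport:
    """Ranked candidate hits for one query haplotype.

    ``top_category`` is a single label, a frozenset of labels for an exact
    score tie, or ``"none"`` when no candidate survives the identity gate.
    """

    hits: list[Hit]
    top_category: str | frozenset

    @property
    def resolved(self) -> bool:
        return isinstance(self.top_category, str) and self.top_category != "none"


@dataclass
class HitTally:
    """Counts of top-hit categories over all scored block haplotypes."""

    counts: dict
    n_blocks: int
    n_queries: int
    n_dropped: int = 0
    assignments: list = field(default_factory=list)  # (block_index, hap_index, category)

    def count(self, category) -> int:
        return self.counts.get(category, 0)

    def grouped(self, groups: Mapping[str, Iterable[str]]) -> dict:
        """Merge labels for reporting (e.g. congeneric candidates plus their
        tie-set into one named group); tie-sets fully inside a group count
        for it, every other category falls into ``"other"``."""
        mapping = {}
        for gname, labels in groups.items():
            for lab in labels:
                mapping[lab] = gname
        out: dict = {}
        for cat, n in self.counts.items():
            if isinstance(cat, frozenset):
                gs = {mapping.get(lab) for lab in cat}
                key = gs.pop() if len(gs) == 1 and None not in gs else "other"
            else:
                key = mapping.get(cat, "other" if cat != "none" else "none")
            out[key] = out.get(key, 0) + n
        return out


def filter_blocks(
    blocks: Sequence[PhaseBlock], min_variants: int = 10, min_length: int = 100
) -> list[PhaseBlock]:
    """Retain informative blocks: at least ``min_variants`` phased variants
    and a span of at least ``min_length`` bp.  Order is preserved."""
    if min_variants < 0 or min_length < 0:
        raise ValueError("thresholds must be >= 0")
    return [
        b for b in blocks if b.n_variants >= min_variants and b.length >= min_length
    ]


def block_summary(blocks: Sequence[PhaseBlock]):
    """(n, mean_variants, sd_variants, mean_length, sd_length) with sample SD."""
    n = len(blocks)
    if n < 2:
        raise ValueError("need at least two blocks for a sample SD")
    nv = np.array([b.n_variants for b in blocks], dtype=float)
    ln = np.array([b.length for b in blocks], dtype=float)
    return (
        n,
        float(nv.mean()),
        float(nv.std(ddof=1)),
        float(ln.mean()),
        float(ln.std(ddof=1)),
    )


def make_aligner() -> Align.PairwiseAligner:
    """Local aligner with nucleotide-BLAST-like scoring (+2/-3, gap open 5,
    extend 2); ``N`` is scored neutrally against everything."""
    matrix = substitution_matrices.Array("ACGTN", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            matrix[a, b] = 2.0 if a == b else -3.0
    # N row/column stays 0: masked bases neither reward nor penalize
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -7.0  # first gapped base: open(5) + extend(2)
    aligner.extend_gap_score = -2.0
    return aligner


def _alignment_identity(alignment) -> float:
    c = alignment.counts()
    total = c.gaps + c.identities + c.mismatches
    return c.identities / total if total else 0.0


def score_haplotype(
    query: str,
    panel: Mapping[str, str],
    min_identity: float = 0.97,
    aligner: Align.PairwiseAligner | None = None,
) -> HitReport:
    """Score one haplotype against every candidate and rank by alignment score.

    Hits with identity (matches / alignment columns, gaps counting against)
    below ``min_identity`` are excluded before ranking; an exact tie for the
    top score yields a frozenset tie category.
    """
    if not query:
        raise ValueError("empty query")
    if set(query) <= {"N"}:
        raise ValueError("query is all-N")
    if aligner is None:
        aligner = make_aligner()
    hits = []
    for label, candidate in panel.items():
        alignments = aligner.align(query, candidate)
        try:
            best = alignments[0]
        except IndexError:
            # no positive-scoring local alignment exists
            hits.append(Hit(label=label, score=0.0, identity=0.0))
            continue
        hits.append(Hit(label=label, score=float(best.score), identity=_alignment_identity(best)))
    hits.sort(key=lambda h: (-h.score, h.label))
    surviving = [h for h in hits if h.identity >= min_identity]
    if not surviving:
        top: str | frozenset = "none"
    else:
        top_score = surviving[0].score
        top_labels = [h.label for h in surviving if h.score == top_score]
        top = top_labels[0] if len(top_labels) == 1 else frozenset(top_labels)
    return HitReport(hits=hits, top_category=top)


def tally_top_hits(
    blocks: Sequence[PhaseBlock],
    panel: CandidatePanel,
    min_identity: float = 0.97,
    max_n_fraction: float = 0.5,
) -> HitTally:
    """Score both haplotypes of every block and tally top-hit categories.

    Queries whose sequence is more than ``max_n_fraction`` N are dropped and
    counted separately; candidate sequences longer than the block span are
    sliced to the homologous region before alignment.
    """
    aligner = make_aligner()
    counts: dict = {}
    assignments = []
    n_queries = 0
    n_dropped = 0
    for bi, block in enumerate(blocks):
        local = {
            label: panel.region(label, block.start, block.end)
            if isinstance(panel, CandidatePanel)
            else panel[label]
            for label in panel
        }
        for hi, hap in enumerate(block.haplotypes):
            n_queries += 1
            n_frac = hap.count("N") / len(hap) if hap else 1.0
            if n_frac > max_n_fraction:
                n_dropped += 1
                counts["dropped"] = counts.get("dropped", 0) + 1
                assignments.append((bi, hi, "dropped"))
                continue
            report = score_haplotype(hap, local, min_identity=min_identity, aligner=aligner)
            cat = report.top_category
            counts[cat] = counts.get(cat, 0) + 1
            assignments.append((bi, hi, cat))
    return HitTally(
        counts=counts,
        n_blocks=len(blocks),
        n_queries=n_queries,
        n_dropped=n_dropped,
        assignments=assignments,
    )


def f1_balance_test(
    tally: HitTally, label_parent1: str, label_parent2: str
) -> tuple[float, float]:
    """Proportion of parent-1 top hits among the two parents, with an exact
    two-sided binomial test against the F1 expectation of 0.5."""
    c1 = tally.count(label_parent1)
    c2 = tally.count(label_parent2)
    if c1 + c2 == 0:
        raise ValueError("no queries assigned to either parental label")
    proportion = c1 / (c1 + c2)
    p = stats.binomtest(c1, c1 + c2, 0.5, alternative="two-sided").pvalue
    return proportion, float(p)
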