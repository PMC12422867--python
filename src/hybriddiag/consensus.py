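"""Masked consensus calling from per-position read evidence.

A consensus base is called only where the read evidence survives base- and
mapping-quality thresholds; everything else becomes ``N`` with an explicit
per-position mask reason, and the surviving fraction of the region is
reported as the coverage fraction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .simulate import Pileup

__all__ = ["MaskedSequence", "masked_consensus", "coverage_fraction"]

MASK_REASONS = ("pass", "low_bq", "low_mq", "no_depth", "tie")


@dataclass
class MaskedSequence:
    """A consensus string over {A,C,G,T,N} with a per-position mask reason.

    ``mask_reason[i]`` is ``"pass"`` exactly when ``seq[i]`` is a called
    base; masked positions record why: no reads (``no_depth``), all reads
    failing the base-quality (``low_bq``) or mapping-quality (``low_mq``)
    threshold, or a majority tie among contributing reads (``tie``).
    """

    seq: str
    mask_reason: list[str]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.mask_reason):
            raise ValueError("sequence and mask_reason lengths differ")
        for base, reason in zip(self.seq, self.mask_reason):
            if (reason == "pass") != (base != "N"):
                raise ValueError("position must be N iff its reason is not 'pass'")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def coverage_fraction(self) -> float:
        return coverage_fraction(self)


def masked_consensus(pileup: Pileup, bq_min: int = 20, mq_min: int = 20) -> MaskedSequence:
    """Call a majority-rule consensus, masking positions that fail quality screening.

    A read contributes to a position only if its base quality is at least
    ``bq_min`` AND its mapping quality is at least ``mq_min`` (the threshold
    is strict below: a read exactly at the threshold passes).  A position
    with zero reads is masked ``no_depth``; a position whose reads all fail
    is masked ``low_bq`` if any read failed the base-quality screen, else
    ``low_mq``.  Ties for the majority base are masked ``tie`` rather than
    fabricating a call.
    """
    if bq_min < 0 or mq_min < 0:
        raise ValueError("quality thresholds must be >= 0")
    bases: list[str] = []
    reasons: list[str] = []
    for column in pileup.columns:
        if not column:
            bases.append("N")
            reasons.append("no_depth")
            continue
        contributing = [b for b, bq, mq in column if bq >= bq_min and mq >= mq_min]
        if not contributing:
            if any(bq < bq_min for _, bq, _ in column):
                reasons.append("low_bq")
            else:
                reasons.append("low_mq")
            bases.append("N")
            continue
        counts = Counter(contributing).most_common()
        if len(counts) > 1 and counts[0][1] == counts[1][1]:
            bases.append("N")
            reasons.append("tie")
        else:
            bases.append(counts[0][0])
            reasons.append("pass")
    return MaskedSequence(seq="".join(bases), mask_reason=reasons)


def coverage_fraction(seq: MaskedSequence) -> float:
    """Fraction of positions with a called (non-masked) consensus base."""
    if len(seq) == 0:
        raise ValueError("empty sequence")
    n_pass = sum(1 for r in seq.mask_reason if r == "pass")
    return n_pass / len(seq)
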