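"""Genetic↔behavioural polyandry correction.

Paternity-based ("genetic") polyandry underestimates behavioural polyandry:
when a female mates with two males, one of them may sire every pup of a small
litter, so the litter is misclassified as monandrous.  This module computes
the misclassification probability from the litter-size distribution and the
paternity-share structure, and converts a genetic polyandry rate G into a
behavioural rate B.

Model: within a two-mate litter of size k, each pup independently takes mate
1 with a fixed probability s (the expected paternity share), so the litter
shows a single genetic sire with probability s**k + (1-s)**k.  Shares follow
the sire-pair genotypes under random mating: two +/+ or two +/t males split
evenly (s = 1/2); in a mixed pair the +/t male's share is the sperm
competitiveness c.

Litters of size one are excluded throughout — a singleton cannot reveal
multiple sires.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "MisclassSpec",
    "PolyandryCorrection",
    "single_sire_prob_given_k",
    "mean_single_sire_prob",
    "behavioural_from_genetic",
]


@dataclass(frozen=True)
class MisclassSpec:
    """Inputs of the misclassification model.

    Parameters
    ----------
    litter_size_dist
        Mapping litter size k (k >= 2) -> proportion, summing to 1.
    wt_freq
        Adult +/t frequency y; weights the sire-pair genotype mixture.
    c
        Sperm competitiveness of a +/t male against a +/+ male.
    d
        Drive strength; carried for genotype bookkeeping only — shares do
        not depend on it.
    """

    litter_size_dist: Mapping[int, float]
    wt_freq: float
    c: float
    d: float = 0.9

    def __post_init__(self) -> None:
        if not self.litter_size_dist:
            raise ValueError("litter_size_dist must be nonempty")
        total = 0.0
        for k, p in self.litter_size_dist.items():
            if k < 2:
                raise ValueError(
                    f"litter sizes below 2 are excluded from polyandry analysis (got k={k})"
                )
            if p < 0:
                raise ValueError(f"negative proportion for k={k}")
            total += p
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"litter-size proportions must sum to 1, got {total}")
        for name in ("wt_freq", "c", "d"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class PolyandryCorrection:
    """A genetic rate G, the single-sire probability m̄ of a behaviourally
    polyandrous litter, and the implied behavioural rate B = G / (1 − m̄)
    with misclassified fraction M = B·m̄ (so B = G + M)."""

    genetic_rate: float
    single_sire_prob: float
    behavioural_rate: float
    misclassified_fraction: float

    @classmethod
    def from_genetic_and_misclassified(cls, G: float, M: float) -> "PolyandryCorrection":
        """Build the correction from a genetic rate and a misclassified
        fraction (B = G + M; m̄ = M / B)."""
        if not 0.0 <= G <= 1.0 or not 0.0 <= M <= 1.0:
            raise ValueError("G and M must lie in [0, 1]")
        B = G + M
        if B > 1.0:
            raise ValueError(f"G + M = {B} exceeds 1")
        mbar = 0.0 if B == 0.0 else M / B
        return cls(
            genetic_rate=G,
            single_sire_prob=mbar,
            behavioural_rate=B,
            misclassified_fraction=M,
        )


def single_sire_prob_given_k(k: int, s: float) -> float:
    """Probability that all k pups of a two-mate litter share one sire, when
    each pup independently takes mate 1 with probability s."""
    if k < 1:
        raise ValueError(f"litter size must be >= 1, got {k}")
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"share must lie in [0, 1], got {s}")
    return s**k + (1.0 - s) ** k


def mean_single_sire_prob(spec: MisclassSpec) -> float:
    """Mean single-sire probability m̄ of a behaviourally polyandrous litter.

    Averages ``single_sire_prob_given_k`` over the litter-size distribution
    and over the sire-pair genotype composition under random mating with
    adult +/t frequency y: (+/+, +/+) with probability (1−y)² and share 1/2,
    mixed with probability 2y(1−y) and share c, (+/t, +/t) with probability
    y² and share 1/2.
    """
    y, c = spec.wt_freq, spec.c
    pair_weights = ((1.0 - y) ** 2, 0.5), (2.0 * y * (1.0 - y), c), (y**2, 0.5)
    mbar = 0.0
    for k, pk in spec.litter_size_dist.items():
        mbar += pk * sum(w * single_sire_prob_given_k(k, s) for w, s in pair_weights)
    return mbar


def behavioural_from_genetic(G: float, mbar: float) -> PolyandryCorrection:
    """Convert a genetic polyandry rate G into a behavioural rate.

    B = G / (1 − m̄): of the behaviourally polyandrous litters, a fraction
    m̄ shows a single genetic sire and is misclassified as monandrous, so
    the observed genetic rate is B·(1 − m̄).
    """
    if not 0.0 <= G <= 1.0:
        raise ValueError(f"G must lie in [0, 1], got {G}")
    if not 0.0 <= mbar < 1.0:
        raise ValueError(f"mbar must lie in [0, 1), got {mbar}")
    B = G / (1.0 - mbar)
    if B > 1.0 + 1e-12:
        raise ValueError(
            f"inconsistent inputs: G={G} with mbar={mbar} implies behavioural rate {B} > 1"
        )
    B = min(B, 1.0)
    return PolyandryCorrection(
        genetic_rate=G,
        single_sire_prob=mbar,
        behavioural_rate=B,
        misclassified_fraction=B * mbar,
    )
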