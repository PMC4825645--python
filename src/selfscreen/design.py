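"""Detection probability and cohort sizing for recessive-mutant screens.

Compares the selfing design, where each screened F2 individual is
homozygous for a target recessive allele with probability 1/4, with the
gonochoristic intercross design (zebrafish-style), where a random
F2 x F2 intracross requires both parents to be carriers (1/2 each) and
the offspring to be homozygous (1/4), i.e. 1/16 per screened individual.
Detecting at least one homozygote among n independent individuals
succeeds with probability 1 - (1 - p)**n.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "BreedingSystem",
    "Convention",
    "DesignSpec",
    "per_individual_probability",
    "detection_probability",
    "min_individuals",
    "design_comparison",
]


class BreedingSystem(str, enum.Enum):
    SELFING = "SELFING"
    GONOCHORISTIC_INTERCROSS = "GONOCHORISTIC_INTERCROSS"


class Convention(str, enum.Enum):
    STRICT = "STRICT"  # exact probability must reach the target
    NEAREST_PERCENT = "NEAREST_PERCENT"  # probabilities compared after rounding to 1%


_SYSTEM_P = {
    BreedingSystem.SELFING: 0.25,
    BreedingSystem.GONOCHORISTIC_INTERCROSS: 1.0 / 16.0,
}
# selfing yields homozygotes in F2; a gonochoristic screen needs F3 intracrosses
_SYSTEM_GENERATIONS = {
    BreedingSystem.SELFING: 2,
    BreedingSystem.GONOCHORISTIC_INTERCROSS: 3,
}


@dataclass(frozen=True)
class DesignSpec:
    breeding_system: BreedingSystem
    per_individual_probability: float
    generations_to_homozygote: int

    @classmethod
    def for_system(cls, system: BreedingSystem | str) -> "DesignSpec":
        system = BreedingSystem(system)
        return cls(system, _SYSTEM_P[system], _SYSTEM_GENERATIONS[system])


def per_individual_probability(system: BreedingSystem | str) -> float:
    """Probability one screened individual is homozygous for the target
    recessive: 1/4 under selfing, (1/2)(1/2)(1/4) = 1/16 under random
    gonochoristic intercrosses."""
    return _SYSTEM_P[BreedingSystem(system)]


def detection_probability(n: int, p: float) -> float:
    """Probability of at least one homozygote among ``n`` individuals."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must be in (0, 1], got {p}")
    return 1.0 - (1.0 - p) ** n


def min_individuals(
    target: float, p: float, convention: Convention | str = Convention.STRICT
) -> int:
    """Smallest cohort size reaching a target detection probability.

    STRICT requires ``detection_probability(n, p) >= target`` exactly.
    NEAREST_PERCENT compares probabilities after rounding to the nearest
    percent, the convention under which a selfing screen needs 8 fish and
    a gonochoristic one 35 intracrosses at the 90% level (their exact
    probabilities, 0.8999 and 0.8959, both round to 90%).
    """
    convention = Convention(convention)
    if not 0.0 < target < 1.0:
        raise ValueError(f"target must be in (0, 1), got {target}")
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must be in (0, 1], got {p}")
    if convention is Convention.STRICT:
        if p == 1.0:
            return 1
        return max(1, math.ceil(math.log(1.0 - target) / math.log(1.0 - p)))
    target_pct = round(target * 100)
    n = 1
    while round(detection_probability(n, p) * 100) < target_pct:
        n += 1
    return n


def design_comparison(target: float = 0.90) -> pd.DataFrame:
    """Side-by-side cohort requirements for both breeding systems."""
    rows = []
    for system in BreedingSystem:
        spec = DesignSpec.for_system(system)
        for convention in Convention:
            n = min_individuals(target, spec.per_individual_probability, convention)
            rows.append(
                {
                    "system": system.value,
                    "convention": convention.value,
                    "p_per_individual": spec.per_individual_probability,
                    "target": target,
                    "n_required": n,
                    "detection_probability": detection_probability(
                        n, spec.per_individual_probability
                    ),
                    "generations_to_homozygote": spec.generations_to_homozygote,
                }
            )
    return pd.DataFrame(rows)
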