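"""Genotype representation and exact Mendelian transmission under selfing.

A self-fertilizing hermaphrodite transmits both gametes itself, so a
heterozygous locus segregates 1:2:1 among offspring and the familiar
"two carriers : one wild-type" ratio appears once homozygous lethals are
removed.  Loci are treated as unlinked and independent, and genotypes are
unordered (parental origin is meaningless under selfing).
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np

__all__ = [
    "AlleleClass",
    "MutantAllele",
    "Genotype",
    "GenotypeDistribution",
    "self_cross_distribution",
    "survivor_distribution",
    "sample_offspring",
]

_PROB_TOL = 1e-12


class AlleleClass(str, enum.Enum):
    """Functional class of an induced recessive allele."""

    ZYGOTIC_LETHAL = "ZYGOTIC_LETHAL"  # homozygous embryos arrest/die before scoring
    STERILE_TYPE_I = "STERILE_TYPE_I"  # maternal-effect: homozygous mothers lay nonviable eggs
    STERILE_TYPE_II = "STERILE_TYPE_II"  # non-egg-layer: ovotestis/anatomical defect
    VISIBLE_VIABLE = "VISIBLE_VIABLE"  # visible homozygous phenotype, viable and fertile


@dataclass(frozen=True)
class MutantAllele:
    """One ENU-induced recessive allele.

    Parameters
    ----------
    allele_id
        Unique identifier within a screen.
    allele_class
        Functional class of the allele.
    phenotype_label
        Free-text phenotype, e.g. ``"curly tail"`` or ``"golden yolk"``.
    penetrance
        Fraction of homozygotes expressing the phenotype (lethality for
        zygotic lethals, sterility for sterile classes).
    maternal_dominance
        Fraction of *heterozygous* mothers expressing a maternal effect.
        Non-zero values model partial dominant maternal effects, which
        push the sterile fraction among offspring of carriers above the
        Mendelian 25%.
    """

    allele_id: str
    allele_class: AlleleClass
    phenotype_label: str = ""
    penetrance: float = 1.0
    maternal_dominance: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError(f"penetrance must be in [0, 1], got {self.penetrance}")
        if not 0.0 <= self.maternal_dominance <= 1.0:
            raise ValueError(
                f"maternal_dominance must be in [0, 1], got {self.maternal_dominance}"
            )


@dataclass(frozen=True)
class Genotype:
    """Unordered multi-locus genotype as allele dosages.

    Stores only non-zero dosages; an absent allele has dosage 0 (``+/+``).
    Dosage 1 is a carrier (``m/+``), dosage 2 a homozygote (``m/m``).
    """

    _dosages: tuple[tuple[str, int], ...] = field(default=())

    @classmethod
    def from_dosages(cls, dosages: Mapping[str, int]) -> "Genotype":
        for allele_id, d in dosages.items():
            if d not in (0, 1, 2):
                raise ValueError(f"dosage for {allele_id!r} must be 0, 1 or 2, got {d}")
        return cls(tuple(sorted((a, d) for a, d in dosages.items() if d != 0)))

    @classmethod
    def wild_type(cls) -> "Genotype":
        return cls(())

    def dosage(self, allele_id: str) -> int:
        for a, d in self._dosages:
            if a == allele_id:
                return d
        return 0

    @property
    def dosages(self) -> dict[str, int]:
        return dict(self._dosages)

    @property
    def allele_ids(self) -> tuple[str, ...]:
        return tuple(a for a, _ in self._dosages)

    def is_wild_type(self) -> bool:
        return not self._dosages

    def is_homozygous(self, allele_id: str) -> bool:
        return self.dosage(allele_id) == 2

    def is_carrier(self, allele_id: str) -> bool:
        return self.dosage(allele_id) == 1

    def __str__(self) -> str:
        if not self._dosages:
            return "+/+"
        parts = []
        for a, d in self._dosages:
            parts.append(f"{a}/{a}" if d == 2 else f"{a}/+")
        return ";".join(parts)

    @classmethod
    def parse(cls, text: str) -> "Genotype":
        """Inverse of ``str``: ``"a/+;b/b"`` -> dosages {a: 1, b: 2}."""
        text = text.strip()
        if text in ("+/+", "", "."):
            return cls.wild_type()
        dosages: dict[str, int] = {}
        for part in text.split(";"):
            left, _, right = part.partition("/")
            if right == "+":
                dosages[left] = 1
            elif right == left:
                dosages[left] = 2
            else:
                raise ValueError(f"cannot parse genotype component {part!r}")
        return cls.from_dosages(dosages)


@dataclass(frozen=True)
class GenotypeDistribution:
    """Probability distribution over genotypes; probabilities sum to one."""

    entries: tuple[tuple[Genotype, float], ...]

    @classmethod
    def from_dict(cls, probs: Mapping[Genotype, float]) -> "GenotypeDistribution":
        total = sum(probs.values())
        if abs(total - 1.0) > _PROB_TOL:
            raise ValueError(f"probabilities must sum to 1, got {total}")
        if any(p < 0 for p in probs.values()):
            raise ValueError("probabilities must be nonnegative")
        return cls(tuple(sorted(probs.items(), key=lambda kv: str(kv[0]))))

    def as_dict(self) -> dict[Genotype, float]:
        return dict(self.entries)

    def probability(self, genotype: Genotype) -> float:
        return self.as_dict().get(genotype, 0.0)

    def __len__(self) -> int:
        return len(self.entries)


# Offspring dosage marginals under selfing, per parental dosage.
_SELFING_MARGINALS: dict[int, dict[int, float]] = {
    0: {0: 1.0},
    1: {2: 0.25, 1: 0.5, 0: 0.25},
    2: {2: 1.0},
}


def self_cross_distribution(parent: Genotype) -> GenotypeDistribution:
    """Exact offspring genotype distribution when ``parent`` self-crosses.

    Each heterozygous locus segregates 1:2:1 (quarter homozygous mutant,
    half carrier, quarter wild-type); homozygous loci transmit
    deterministically.  Loci are unlinked, so multi-locus probabilities
    are products of the per-locus marginals.
    """
    probs: dict[Genotype, float] = {Genotype.wild_type(): 1.0}
    for allele_id, parent_dosage in parent.dosages.items():
        marginal = _SELFING_MARGINALS[parent_dosage]
        new_probs: dict[Genotype, float] = {}
        for genotype, p in probs.items():
            for child_dosage, q in marginal.items():
                d = genotype.dosages
                if child_dosage:
                    d[allele_id] = child_dosage
                g = Genotype.from_dosages(d)
                new_probs[g] = new_probs.get(g, 0.0) + p * q
        probs = new_probs
    return GenotypeDistribution.from_dict(probs)


def survivor_distribution(
    dist: GenotypeDistribution, lethal: Callable[[Genotype], bool]
) -> GenotypeDistribution:
    """Condition a genotype distribution on survival.

    ``lethal`` is a predicate marking genotypes that die before scoring;
    the surviving classes are renormalized, preserving their relative
    ratios.  Selfing a carrier of an embryonic lethal and conditioning on
    survival yields the screen's 2 carrier : 1 wild-type adult ratio.
    """
    survivors = {g: p for g, p in dist.entries if not lethal(g)}
    total = sum(survivors.values())
    if total <= 0.0:
        raise ValueError("no surviving genotypes: all probability mass is lethal")
    return GenotypeDistribution.from_dict({g: p / total for g, p in survivors.items()})


def sample_offspring(parent: Genotype, rng: np.random.Generator) -> Genotype:
    """Draw one selfed offspring genotype, distributed per
    :func:`self_cross_distribution`."""
    dosages: dict[str, int] = {}
    for allele_id, parent_dosage in parent.dosages.items():
        if parent_dosage == 2:
            dosages[allele_id] = 2
        else:
            # two independent gametes from a heterozygote
            child = int(rng.integers(0, 2)) + int(rng.integers(0, 2))
            if child:
                dosages[allele_id] = child
    return Genotype.from_dosages(dosages)


def enumerate_gamete_pairs(parent: Genotype) -> Iterable[Genotype]:
    """Enumerate all ordered gamete pairs of a selfing parent.

    Yields one offspring genotype per ordered pair of ordered gametes
    (``4**L`` outcomes for L loci, counting homozygous loci as a single
    gamete type repeated); tallying the yields reproduces
    :func:`self_cross_distribution` exactly.  Exposed for verification.
    """
    loci = list(parent.dosages.items())
    # per locus, the two allele copies a gamete can carry (1 = mutant copy)
    copy_options = [(1, 1) if d == 2 else (1, 0) for _, d in loci]
    for egg in itertools.product(*[range(2) for _ in loci]):
        for sperm in itertools.product(*[range(2) for _ in loci]):
            dosages = {}
            for (allele_id, _), opts, e, s in zip(loci, copy_options, egg, sperm):
                d = opts[e] + opts[s]
                if d:
                    dosages[allele_id] = d
            yield Genotype.from_dosages(dosages)
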