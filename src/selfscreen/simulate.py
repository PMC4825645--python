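"""Forward gene-drop simulation of a selfing hermaphrodite mutagenesis screen.

Simulates the full four-generation design (P -> F1 -> F2 -> F3 -> F4):
mutagenized founders carry a Poisson number of induced recessive alleles,
every F1 is heterozygous for its genome's alleles, and each later
generation arises by self-fertilization.  Homozygous zygotic lethals die
as embryos (with probability equal to their penetrance), maternal-effect
(Type I) sterile homozygous mothers lay fertilized but nonviable eggs,
and non-egg-layer (Type II) sterile mothers lay nothing.  Clutches are
collected over discrete sessions, embryos are reared with imperfect
survival, and a small fraction of reared fish are primary males that
never produce clutches.

The output — a pedigree, per-embryo clutch records, and a truth map of
each fish's real genotype class — has exactly the statistical structure
the classification stage assumes, so classifier parameter recovery can be
measured against ground truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genetics import (
    AlleleClass,
    Genotype,
    MutantAllele,
    sample_offspring,
)

__all__ = [
    "ScreenConfig",
    "Fish",
    "Embryo",
    "Clutch",
    "ScreenResult",
    "simulate_screen",
    "simulate_clutch",
    "rear_cohort",
]

logger = logging.getLogger(__name__)

GENERATIONS = ("P", "F1", "F2", "F3", "F4")

# phenotype label pool per allele class, cycled over alleles
_LABEL_POOL = {
    AlleleClass.ZYGOTIC_LETHAL: (
        "curly tail",
        "short tail",
        "no trunk",
        "dwarf",
        "eye defects",
        "skull defects",
        "gastrula defects",
        "embryonic lethal",
    ),
    AlleleClass.STERILE_TYPE_I: ("maternal effect",),
    AlleleClass.STERILE_TYPE_II: ("nonegg layer",),
    AlleleClass.VISIBLE_VIABLE: ("hyper-pigmentation", "golden yolk"),
}

_DEFAULT_CLASS_PROBABILITIES = {
    AlleleClass.ZYGOTIC_LETHAL: 0.5,
    AlleleClass.STERILE_TYPE_I: 0.2,
    AlleleClass.STERILE_TYPE_II: 0.1,
    AlleleClass.VISIBLE_VIABLE: 0.2,
}


@dataclass
class ScreenConfig:
    """All simulator parameters.

    Defaults describe a screen of 47 mutagenized founder families: the
    allele load per genome is Poisson with mean 0.575 split over four
    functional classes, so that ~25% of F1 genomes carry at least one
    zygotic lethal; two to 13 F2 fish are screened per family; 3.6% of
    reared fish are primary males; clutches are truncated-Poisson(4)
    embryos per collection session, three sessions per week; a fish with
    no eggs over 24 consecutive sessions (~2 months) is a candidate
    non-egg-layer.
    """

    n_f1_families: int = 47
    alleles_per_genome_mean: float = 0.575
    class_probabilities: dict[AlleleClass, float] = field(
        default_factory=lambda: dict(_DEFAULT_CLASS_PROBABILITIES)
    )
    penetrance_range: tuple[float, float] = (1.0, 1.0)
    maternal_dominance: float = 0.0
    f2_cohort_size_range: tuple[int, int] = (2, 13)
    primary_male_rate: float = 0.036
    clutch_size_mean: float = 4.0
    clutch_size_max: int = 25
    sessions_per_week: int = 3
    min_sessions_to_maturity: int = 12
    eggless_window_sessions: int = 24
    rearing_survival: float = 0.9
    background_nonviable_rate: float = 0.0
    unfertilized_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.class_probabilities = {
            AlleleClass(k): float(v) for k, v in self.class_probabilities.items()
        }
        probs = list(self.class_probabilities.values())
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("class probabilities must be in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(f"class_probabilities must sum to 1, got {sum(probs)}")
        for name in ("primary_male_rate", "rearing_survival",
                     "background_nonviable_rate", "unfertilized_rate",
                     "maternal_dominance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.penetrance_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"penetrance_range must be ordered within [0, 1]")
        lo, hi = self.f2_cohort_size_range
        if not (1 <= lo <= hi):
            raise ValueError("f2_cohort_size_range must be positive and ordered")
        if self.alleles_per_genome_mean < 0:
            raise ValueError("alleles_per_genome_mean must be nonnegative")
        for name in ("n_f1_families", "clutch_size_max", "sessions_per_week",
                     "min_sessions_to_maturity", "eggless_window_sessions"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")

    @classmethod
    def from_json(cls, path_or_text) -> "ScreenConfig":
        """Load a configuration from a JSON file path or JSON text.

        Unknown keys are rejected so that typos do not silently fall back
        to defaults.
        """
        import os

        if isinstance(path_or_text, (str, os.PathLike)) and os.path.exists(path_or_text):
            with open(path_or_text) as fh:
                data = json.load(fh)
        else:
            data = json.loads(path_or_text)
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        for key in ("penetrance_range", "f2_cohort_size_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_json(self) -> str:
        data = asdict(self)
        data["class_probabilities"] = {
            k.value: v for k, v in self.class_probabilities.items()
        }
        data["penetrance_range"] = list(self.penetrance_range)
        data["f2_cohort_size_range"] = list(self.f2_cohort_size_range)
        return json.dumps(data, indent=2)


@dataclass
class Fish:
    """One individual in the pedigree.

    ``expressed_sterile`` records which sterility phenotype (if any) this
    fish actually expresses once adult, after penetrance and maternal
    dominance draws; it is simulator-internal ground truth, not part of
    the pedigree file format.
    """

    fish_id: str
    family_id: str
    generation: str
    parent_id: str | None
    genotype: Genotype
    role: str = "HERMAPHRODITE"  # or PRIMARY_MALE
    status: str = "ADULT"  # EMBRYO_LETHAL, JUVENILE_DEATH, ADULT, CENSORED
    sessions_observed: int = 0
    expressed_sterile: str | None = None  # "STERILE_I" | "STERILE_II" | None

    def is_adult_hermaphrodite(self) -> bool:
        return self.role == "HERMAPHRODITE" and self.status == "ADULT"


@dataclass
class Embryo:
    embryo_id: str
    parent_id: str
    session_index: int
    genotype: Genotype
    fertilized: bool
    viable_at_score: bool
    phenotype_labels: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.fertilized and self.viable_at_score:
            raise ValueError("an unfertilized embryo cannot be viable")


@dataclass
class Clutch:
    """All embryos collected from one parent in one session (may be empty)."""

    parent_id: str
    session_index: int
    embryos: list[Embryo] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.embryos)

    @property
    def n_viable(self) -> int:
        return sum(e.viable_at_score for e in self.embryos)


@dataclass
class ScreenResult:
    pedigree: list[Fish]
    clutches: list[Clutch]
    truth: dict[str, str]
    config: ScreenConfig
    alleles: dict[str, MutantAllele]


def _true_class(fish: Fish, alleles: Mapping[str, MutantAllele]) -> str:
    if fish.role == "PRIMARY_MALE":
        return "PRIMARY_MALE"
    if fish.expressed_sterile is not None:
        return fish.expressed_sterile
    if any(fish.genotype.is_carrier(a) for a in alleles):
        return "CARRIER"
    if any(fish.genotype.is_homozygous(a) for a in alleles):
        return "HOMOZYGOUS_VIABLE"
    return "WILD_TYPE"


def _draw_clutch_size(config: ScreenConfig, rng: np.random.Generator) -> int:
    return int(min(rng.poisson(config.clutch_size_mean), config.clutch_size_max))


def simulate_clutch(
    mother: Fish,
    session: int,
    alleles: Mapping[str, MutantAllele],
    config: ScreenConfig,
    rng: np.random.Generator,
) -> Clutch:
    """Simulate one collection session from an adult hermaphrodite.

    A mother expressing Type II sterility lays nothing; one expressing a
    Type I maternal effect lays fertilized eggs that are all nonviable
    regardless of embryo genotype.  Otherwise each embryo's viability
    follows its own genotype: homozygous zygotic lethals express (and
    die) with probability equal to the allele's penetrance, visible
    viable homozygotes express their label but survive, and background
    unfertilized/nonviable rates apply on top.
    """
    if not mother.is_adult_hermaphrodite():
        raise ValueError(f"{mother.fish_id} is not an adult hermaphrodite")
    if mother.expressed_sterile == "STERILE_II":
        return Clutch(mother.fish_id, session, [])
    size = _draw_clutch_size(config, rng)
    maternal_kill = mother.expressed_sterile == "STERILE_I"
    embryos = []
    for i in range(size):
        genotype = sample_offspring(mother.genotype, rng)
        fertilized = bool(rng.random() >= config.unfertilized_rate)
        labels: set[str] = set()
        if not fertilized:
            viable = False
        elif maternal_kill:
            viable = False
        else:
            viable = True
            for allele_id in genotype.allele_ids:
                if not genotype.is_homozygous(allele_id):
                    continue
                allele = alleles[allele_id]
                if allele.allele_class is AlleleClass.ZYGOTIC_LETHAL:
                    if rng.random() < allele.penetrance:
                        labels.add(allele.phenotype_label)
                        viable = False
                elif allele.allele_class is AlleleClass.VISIBLE_VIABLE:
                    if rng.random() < allele.penetrance:
                        labels.add(allele.phenotype_label)
            if viable and rng.random() < config.background_nonviable_rate:
                viable = False
        embryos.append(
            Embryo(
                embryo_id=f"{mother.fish_id}-s{session}-e{i}",
                parent_id=mother.fish_id,
                session_index=session,
                genotype=genotype,
                fertilized=fertilized,
                viable_at_score=viable,
                phenotype_labels=frozenset(labels),
            )
        )
    return Clutch(mother.fish_id, session, embryos)


def _draw_expression(
    genotype: Genotype,
    alleles: Mapping[str, MutantAllele],
    rng: np.random.Generator,
) -> str | None:
    """Decide at maturity which sterility phenotype (if any) a fish expresses."""
    # Type II (no eggs at all) masks Type I if both would express.
    expressed: str | None = None
    for allele_id in genotype.allele_ids:
        allele = alleles[allele_id]
        if allele.allele_class is AlleleClass.STERILE_TYPE_II:
            if genotype.is_homozygous(allele_id) and rng.random() < allele.penetrance:
                return "STERILE_II"
        elif allele.allele_class is AlleleClass.STERILE_TYPE_I:
            if genotype.is_homozygous(allele_id):
                if rng.random() < allele.penetrance:
                    expressed = "STERILE_I"
            elif rng.random() < allele.maternal_dominance:
                # partial dominant maternal effect in a heterozygous mother
                expressed = "STERILE_I"
    return expressed


def rear_cohort(
    clutches: Iterable[Clutch],
    alleles: Mapping[str, MutantAllele],
    config: ScreenConfig,
    rng: np.random.Generator,
    *,
    family_id: str,
    generation: str,
    id_prefix: str,
) -> list[Fish]:
    """Raise the viable embryos of a set of clutches to adulthood.

    Each viable embryo survives rearing with probability
    ``rearing_survival`` (otherwise JUVENILE_DEATH) and, if it survives,
    is a primary male with probability ``primary_male_rate``.  Sterility
    expression is drawn here, once per adult.  An input with no viable
    embryos yields an empty cohort (the allele is lost), with a warning.
    """
    viable = [e for c in clutches for e in c.embryos if e.viable_at_score]
    if not viable:
        logger.warning("no viable embryos to rear for family %s (%s)",
                       family_id, generation)
        return []
    fish: list[Fish] = []
    for k, embryo in enumerate(viable):
        if rng.random() >= config.rearing_survival:
            fish.append(
                Fish(f"{id_prefix}-{k}", family_id, generation, embryo.parent_id,
                     embryo.genotype, status="JUVENILE_DEATH")
            )
            continue
        if rng.random() < config.primary_male_rate:
            fish.append(
                Fish(f"{id_prefix}-{k}", family_id, generation, embryo.parent_id,
                     embryo.genotype, role="PRIMARY_MALE")
            )
            continue
        fish.append(
            Fish(
                f"{id_prefix}-{k}", family_id, generation, embryo.parent_id,
                embryo.genotype,
                expressed_sterile=_draw_expression(embryo.genotype, alleles, rng),
            )
        )
    return fish


def _draw_family_alleles(
    family_id: str, config: ScreenConfig, rng: np.random.Generator
) -> dict[str, MutantAllele]:
    n = int(rng.poisson(config.alleles_per_genome_mean))
    classes = list(config.class_probabilities)
    probs = np.array([config.class_probabilities[c] for c in classes])
    lo, hi = config.penetrance_range
    alleles: dict[str, MutantAllele] = {}
    for k in range(n):
        cls = classes[int(rng.choice(len(classes), p=probs))]
        pool = _LABEL_POOL[cls]
        allele_id = f"{family_id}a{k}"
        alleles[allele_id] = MutantAllele(
            allele_id=allele_id,
            allele_class=cls,
            phenotype_label=pool[k % len(pool)],
            penetrance=float(lo if lo == hi else rng.uniform(lo, hi)),
            maternal_dominance=(
                config.maternal_dominance
                if cls is AlleleClass.STERILE_TYPE_I
                else 0.0
            ),
        )
    return alleles


def _collect_and_rear(
    mother: Fish,
    target: int,
    alleles: Mapping[str, MutantAllele],
    config: ScreenConfig,
    rng: np.random.Generator,
    *,
    generation: str,
    id_prefix: str,
    max_sessions: int = 120,
) -> list[Fish]:
    """Collect clutches from one mother until ~target fish can be reared."""
    clutches: list[Clutch] = []
    n_viable = 0
    session = 0
    # oversample embryos so rearing losses rarely undershoot the target
    need = max(int(np.ceil(target / max(config.rearing_survival, 1e-9))) + 4, target)
    while n_viable < need and session < max_sessions:
        clutch = simulate_clutch(mother, session, alleles, config, rng)
        clutches.append(clutch)
        n_viable += clutch.n_viable
        session += 1
    reared = rear_cohort(clutches, alleles, config, rng,
                         family_id=mother.family_id, generation=generation,
                         id_prefix=id_prefix)
    # the screen only scores `target` fish per family; surplus is not reared
    kept: list[Fish] = []
    n_screened = 0
    for f in reared:
        kept.append(f)
        if f.status in ("ADULT",):
            n_screened += 1
        if n_screened >= target:
            break
    return kept


def simulate_screen(config: ScreenConfig) -> ScreenResult:
    """Run the full four-generation screen.

    Returns the pedigree, all clutch records (the F3 embryos scored from
    F2 mothers and the F4 embryos scored from F3 mothers of families
    segregating a sterile allele), and a truth map from fish id to true
    genotype class, for parameter-recovery testing.  Fully reproducible
    from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    pedigree: list[Fish] = []
    clutches: list[Clutch] = []
    alleles_all: dict[str, MutantAllele] = {}

    for i in range(config.n_f1_families):
        family_id = f"R{i + 1:03d}"
        family_alleles = _draw_family_alleles(family_id, config, rng)
        alleles_all.update(family_alleles)

        founder = Fish(f"{family_id}-P", family_id, "P", None,
                       Genotype.from_dosages({a: 1 for a in family_alleles}))
        # screened lineages are by construction founded by fertile F1 fish
        f1 = Fish(f"{family_id}-F1", family_id, "F1", founder.fish_id,
                  founder.genotype)
        pedigree.extend([founder, f1])

        lo, hi = config.f2_cohort_size_range
        f2_target = int(rng.integers(lo, hi + 1))
        f2 = _collect_and_rear(f1, f2_target, family_alleles, config, rng,
                               generation="F2", id_prefix=f"{family_id}-F2")
        pedigree.extend(f2)

        # F3 embryo scoring: every adult F2 hermaphrodite is collected
        # over the full eggless window so Type II sterility is observable
        f2_adults = [f for f in f2 if f.is_adult_hermaphrodite()]
        for fish in f2_adults:
            fish.sessions_observed = config.eggless_window_sessions
            for s in range(config.eggless_window_sessions):
                clutches.append(simulate_clutch(fish, s, family_alleles, config, rng))

        # sterile confirmation: rear F3 from the fertile siblings of any
        # sterile F2, then score their F4 clutches
        has_sterile_f2 = any(f.expressed_sterile for f in f2_adults)
        if has_sterile_f2:
            for fish in f2_adults:
                if fish.expressed_sterile:
                    continue
                f3_target = int(rng.integers(lo, hi + 1))
                f3 = _collect_and_rear(
                    fish, f3_target, family_alleles, config, rng,
                    generation="F3", id_prefix=f"{fish.fish_id}-F3")
                pedigree.extend(f3)
                for f3_fish in f3:
                    if not f3_fish.is_adult_hermaphrodite():
                        continue
                    f3_fish.sessions_observed = config.eggless_window_sessions
                    for s in range(config.eggless_window_sessions):
                        clutches.append(
                            simulate_clutch(f3_fish, s, family_alleles, config, rng))

    truth = {
        f.fish_id: _true_class(f, alleles_all)
        for f in pedigree
        if f.status == "ADULT"
    }
    return ScreenResult(pedigree, clutches, truth, config, alleles_all)
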