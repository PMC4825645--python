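"""Decision rules of the simultaneous zygotic/sterile screen.

Clutch records are reduced to per-parent summaries, from which each adult
hermaphrodite is called: a Type I (maternal-effect) sterile when at least
90% of a minimum of 20 scored embryos are nonviable or unfertilized; a
Type II (non-egg-layer) sterile when no eggs appear over a two-month
observation window; a zygotic carrier when its clutches contain embryos
with the family's mutant phenotype; wild-type otherwise.  Fish whose
genotype cannot be resolved from the evidence stay honest: the */+ class
marks individuals whose descendants were never reared, and INDETERMINATE
marks insufficient clutch data.

Backward genotyping infers an adult's genotype from the phenotypes of its
reared offspring: a parent with at least one sterile offspring must be a
carrier of the sterile allele, while one whose reared offspring are all
fertile is called wild-type only once enough offspring have been checked
for the residual miss probability (0.75 per fertile offspring of a true
carrier) to be small.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .simulate import Clutch, Fish

__all__ = [
    "Call",
    "ClassificationRules",
    "ClutchSummary",
    "FishCall",
    "summarize_clutches",
    "call_sterility",
    "call_zygotic_carrier",
    "backward_genotype",
    "categorize_family",
    "classify_screen",
]


class Call(str, enum.Enum):
    WILD_TYPE = "WILD_TYPE"
    CARRIER = "CARRIER"
    STERILE_I = "STERILE_I"
    STERILE_II = "STERILE_II"
    STAR_PLUS = "STAR_PLUS"  # */+ : wild-type or carrier, undetermined
    PRIMARY_MALE = "PRIMARY_MALE"
    INDETERMINATE = "INDETERMINATE"
    FERTILE = "FERTILE"  # intermediate: passed sterility screen, carrier call pending

    def is_sterile(self) -> bool:
        return self in (Call.STERILE_I, Call.STERILE_II)


@dataclass(frozen=True)
class ClassificationRules:
    """All decision thresholds of the screen.

    ``min_embryos_scored``: embryos required before any fertility call.
    ``nonviable_fraction_threshold``: pooled nonviable+unfertilized
    fraction at or above which a fish is Type I sterile (default 0.90).
    ``eggless_window_sessions``: zero-egg sessions required for a Type II
    call (24 = three sessions/week for ~2 months).
    ``carrier_min_mutant_embryos``: mutant-labelled embryos required to
    call a fertile fish a zygotic carrier.
    ``backward_sterile_fraction``: expected sterile fraction among
    offspring of a carrier (reported with the evidence; the carrier call
    itself needs only one sterile descendant).
    ``wildtype_min_fertile_offspring``: fully fertile reared offspring
    required before a backward wild-type call (8 leaves a 0.75**8 = 10%
    residual miss probability).
    ``confirm_total_embryos``: embryos accumulated to confirm a sterile
    call and assess penetrance.
    """

    min_embryos_scored: int = 20
    nonviable_fraction_threshold: float = 0.90
    eggless_window_sessions: int = 24
    carrier_min_mutant_embryos: int = 2
    backward_sterile_fraction: float = 0.25
    wildtype_min_fertile_offspring: int = 8
    confirm_total_embryos: int = 100

    def __post_init__(self) -> None:
        if self.min_embryos_scored < 1:
            raise ValueError("min_embryos_scored must be >= 1")
        if not 0.0 < self.nonviable_fraction_threshold <= 1.0:
            raise ValueError("nonviable_fraction_threshold must be in (0, 1]")
        if not 0.0 < self.backward_sterile_fraction <= 1.0:
            raise ValueError("backward_sterile_fraction must be in (0, 1]")
        for name in ("eggless_window_sessions", "carrier_min_mutant_embryos",
                     "wildtype_min_fertile_offspring", "confirm_total_embryos"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_json(cls, path_or_text) -> "ClassificationRules":
        import json
        import os

        if isinstance(path_or_text, (str, os.PathLike)) and os.path.exists(path_or_text):
            with open(path_or_text) as fh:
                data = json.load(fh)
        else:
            data = json.loads(path_or_text)
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown rule keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class ClutchSummary:
    """Aggregated clutch evidence for one parent across sessions."""

    parent_id: str
    n_scored: int = 0
    n_viable: int = 0
    n_nonviable: int = 0
    n_unfertilized: int = 0
    n_mutant_by_label: dict[str, int] = field(default_factory=dict)
    sessions_spanned: int = 0
    sessions_with_zero_eggs: int = 0

    def __post_init__(self) -> None:
        if self.n_viable + self.n_nonviable != self.n_scored:
            raise ValueError("n_viable + n_nonviable must equal n_scored")
        if min(self.n_scored, self.n_viable, self.n_nonviable,
               self.n_unfertilized) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def nonviable_fraction(self) -> float:
        # unfertilized eggs are part of n_nonviable already; the sterility
        # criterion pools nonviable and nonfertilized
        return self.n_nonviable / self.n_scored if self.n_scored else 0.0

    def n_mutant(self, labels: Iterable[str] | None = None) -> int:
        if labels is None:
            return sum(self.n_mutant_by_label.values())
        return sum(self.n_mutant_by_label.get(l, 0) for l in set(labels))


@dataclass
class FishCall:
    fish_id: str
    call: Call
    evidence: ClutchSummary | None = None
    notes: str = ""


def summarize_clutches(
    clutches: Sequence[Clutch], sessions_observed: int | None = None
) -> ClutchSummary:
    """Aggregate all clutches of one parent into scoring counts.

    ``sessions_observed`` overrides the session count inferred from the
    clutch list, which matters when empty sessions were not recorded as
    explicit empty clutches.
    """
    if not clutches and sessions_observed is None:
        raise ValueError("no clutches and no observation window given")
    parents = {c.parent_id for c in clutches}
    if len(parents) > 1:
        raise ValueError(f"clutches from multiple parents: {sorted(parents)}")
    parent_id = clutches[0].parent_id if clutches else ""
    summary = ClutchSummary(parent_id=parent_id)
    nonempty_sessions = set()
    for clutch in clutches:
        if clutch.size:
            nonempty_sessions.add(clutch.session_index)
        for e in clutch.embryos:
            summary.n_scored += 1
            if e.viable_at_score:
                summary.n_viable += 1
            else:
                summary.n_nonviable += 1
                if not e.fertilized:
                    summary.n_unfertilized += 1
            for label in e.phenotype_labels:
                summary.n_mutant_by_label[label] = (
                    summary.n_mutant_by_label.get(label, 0) + 1
                )
    n_sessions = sessions_observed if sessions_observed is not None else len(clutches)
    summary.sessions_spanned = n_sessions
    summary.sessions_with_zero_eggs = n_sessions - len(nonempty_sessions)
    return summary


def call_sterility(
    summary: ClutchSummary, fish: Fish, rules: ClassificationRules
) -> FishCall:
    """Apply the sterility criteria to one adult hermaphrodite.

    Type I: at least ``min_embryos_scored`` embryos scored and 90%+ of
    them nonviable or unfertilized.  Type II: zero embryos over the full
    eggless window.  Fish with some data but not enough for either
    criterion are INDETERMINATE; all others proceed to carrier calling as
    FERTILE.
    """
    if not fish.is_adult_hermaphrodite():
        raise ValueError(f"{fish.fish_id} is not an adult hermaphrodite")
    if summary.n_scored == 0:
        if summary.sessions_with_zero_eggs >= rules.eggless_window_sessions:
            return FishCall(fish.fish_id, Call.STERILE_II, summary,
                            notes="no eggs over the full observation window")
        return FishCall(fish.fish_id, Call.INDETERMINATE, summary,
                        notes="no eggs but observation window incomplete")
    if summary.n_scored < rules.min_embryos_scored:
        return FishCall(fish.fish_id, Call.INDETERMINATE, summary,
                        notes=f"only {summary.n_scored} embryos scored")
    frac = (summary.n_nonviable) / summary.n_scored
    if frac >= rules.nonviable_fraction_threshold:
        return FishCall(fish.fish_id, Call.STERILE_I, summary,
                        notes=f"nonviable fraction {frac:.2f}")
    return FishCall(fish.fish_id, Call.FERTILE, summary)


def call_zygotic_carrier(
    summary: ClutchSummary,
    family_phenotype_labels: Iterable[str],
    rules: ClassificationRules,
) -> FishCall:
    """Call a fertile fish a zygotic carrier from its mutant embryos.

    A fish is a CARRIER when at least ``carrier_min_mutant_embryos`` of
    its scored embryos show one of the family's mutant phenotypes, and
    WILD_TYPE otherwise; with fewer than ``min_embryos_scored`` embryos
    the call is INDETERMINATE.
    """
    if summary.n_scored < rules.min_embryos_scored:
        return FishCall(summary.parent_id, Call.INDETERMINATE, summary,
                        notes=f"only {summary.n_scored} embryos scored")
    n_mutant = summary.n_mutant(family_phenotype_labels)
    if n_mutant >= rules.carrier_min_mutant_embryos:
        return FishCall(summary.parent_id, Call.CARRIER, summary,
                        notes=f"{n_mutant} mutant embryos")
    return FishCall(summary.parent_id, Call.WILD_TYPE, summary)


def backward_genotype(
    f2_fish: Fish,
    reared_offspring_calls: Sequence[FishCall],
    rules: ClassificationRules,
) -> FishCall:
    """Infer a parent's genotype from its reared offspring's calls.

    CARRIER as soon as one reared offspring is sterile (the sterile
    allele must have come from the parent); WILD_TYPE when all of at
    least ``wildtype_min_fertile_offspring`` reared offspring are fully
    fertile; */+ otherwise — too few offspring were reared to decide.
    """
    n_sterile = sum(c.call.is_sterile() for c in reared_offspring_calls)
    fertile_calls = (Call.WILD_TYPE, Call.CARRIER, Call.FERTILE)
    n_fertile = sum(c.call in fertile_calls for c in reared_offspring_calls)
    if n_sterile >= 1:
        return FishCall(
            f2_fish.fish_id, Call.CARRIER,
            notes=f"{n_sterile}/{len(reared_offspring_calls)} reared offspring sterile")
    if n_fertile >= rules.wildtype_min_fertile_offspring:
        return FishCall(
            f2_fish.fish_id, Call.WILD_TYPE,
            notes=f"all {n_fertile} reared offspring fertile")
    return FishCall(f2_fish.fish_id, Call.STAR_PLUS,
                    notes="insufficient reared offspring")


def categorize_family(
    member_calls: Sequence[FishCall], phenotype_labels: Iterable[str] = ()
) -> str:
    """Summarize a family by the union of its confirmed mutation types.

    Mirrors the screen's family categories: a sterile part ("Sterile I",
    "Sterile II" or "Sterile I and II") when sterile fish were found, and
    a zygotic part ("Zygotic" when carriers were confirmed, "Zygotic not
    confirmed" otherwise).
    """
    calls = {c.call for c in member_calls}
    has_i = Call.STERILE_I in calls
    has_ii = Call.STERILE_II in calls
    has_carrier = Call.CARRIER in calls
    # was any member even screened for zygotic transmission?
    has_fertile_data = calls & {Call.CARRIER, Call.WILD_TYPE, Call.FERTILE}
    if has_i and has_ii:
        sterile_part = "Sterile I and II"
    elif has_i:
        sterile_part = "Sterile I"
    elif has_ii:
        sterile_part = "Sterile II"
    else:
        sterile_part = ""
    if sterile_part:
        if has_carrier:
            return f"{sterile_part}/zygotic"
        if has_fertile_data:
            return f"{sterile_part}/zygotic not confirmed"
        return sterile_part
    return "Zygotic" if has_carrier else "Zygotic not confirmed"


def _family_labels(
    clutches_by_parent: Mapping[str, list[Clutch]], parents: Iterable[str]
) -> set[str]:
    labels: set[str] = set()
    for p in parents:
        for clutch in clutches_by_parent.get(p, []):
            for e in clutch.embryos:
                labels |= set(e.phenotype_labels)
    return labels


def classify_screen(
    pedigree: Sequence[Fish],
    clutches: Sequence[Clutch],
    rules: ClassificationRules | None = None,
) -> tuple[dict[str, FishCall], dict[str, str]]:
    """Run the whole decision pipeline on a pedigree plus clutch records.

    Returns (calls by fish id, category by family id).  F2 and F3 adults
    are called from their own clutches; F2 fish of sterile families whose
    reared F3 offspring were classified are then backward-genotyped,
    which can upgrade a WILD_TYPE/CARRIER call or resolve a */+ one.
    Primary males are set aside with their own call.
    """
    rules = rules or ClassificationRules()
    by_id = {f.fish_id: f for f in pedigree}
    clutches_by_parent: dict[str, list[Clutch]] = defaultdict(list)
    for c in clutches:
        clutches_by_parent[c.parent_id].append(c)
    children: dict[str, list[Fish]] = defaultdict(list)
    for f in pedigree:
        if f.parent_id:
            children[f.parent_id].append(f)

    families: dict[str, list[Fish]] = defaultdict(list)
    for f in pedigree:
        families[f.family_id].append(f)

    calls: dict[str, FishCall] = {}
    for family_id, members in families.items():
        scorable = [f for f in members
                    if f.generation in ("F2", "F3") and f.status == "ADULT"]
        labels = _family_labels(
            clutches_by_parent, (f.fish_id for f in scorable))
        # first pass: own-clutch calls for every adult
        for f in scorable:
            if f.role == "PRIMARY_MALE":
                calls[f.fish_id] = FishCall(f.fish_id, Call.PRIMARY_MALE)
                continue
            own = clutches_by_parent.get(f.fish_id, [])
            summary = summarize_clutches(own, sessions_observed=f.sessions_observed) \
                if (own or f.sessions_observed) else None
            if summary is None:
                calls[f.fish_id] = FishCall(f.fish_id, Call.INDETERMINATE,
                                            notes="never scored")
                continue
            call = call_sterility(summary, f, rules)
            if call.call is Call.FERTILE:
                call = call_zygotic_carrier(summary, labels, rules)
            calls[f.fish_id] = call
        # primary males among members regardless of generation bucket
        for f in members:
            if f.role == "PRIMARY_MALE" and f.fish_id not in calls:
                calls[f.fish_id] = FishCall(f.fish_id, Call.PRIMARY_MALE)
        # backward genotyping: F2 parents with reared, classified F3
        for f in scorable:
            if f.generation != "F2" or f.role == "PRIMARY_MALE":
                continue
            f3 = [c for c in children.get(f.fish_id, [])
                  if c.generation == "F3" and c.status == "ADULT"
                  and c.role != "PRIMARY_MALE"]
            f3_calls = [calls[c.fish_id] for c in f3 if c.fish_id in calls]
            if not f3_calls:
                continue
            back = backward_genotype(f, f3_calls, rules)
            own_call = calls[f.fish_id]
            if back.call is Call.CARRIER or (
                back.call is Call.WILD_TYPE
                and own_call.call in (Call.INDETERMINATE, Call.WILD_TYPE)
            ):
                back.evidence = own_call.evidence
                calls[f.fish_id] = back
            # fertile offspring of a sterile-allele carrier cannot be told
            # apart from carriers without rearing their own progeny: they
            # stay in the */+ class.  Offspring of a backward-confirmed
            # wild-type parent keep their WILD_TYPE call.
            if back.call is Call.CARRIER and any(
                fc.call.is_sterile() for fc in f3_calls
            ):
                for child in f3:
                    if calls[child.fish_id].call is Call.WILD_TYPE:
                        old = calls[child.fish_id]
                        calls[child.fish_id] = FishCall(
                            child.fish_id, Call.STAR_PLUS, old.evidence,
                            notes="fertile offspring of a sterile-allele carrier")

    categories = {}
    for family_id, members in families.items():
        member_calls = [calls[f.fish_id] for f in members if f.fish_id in calls]
        if member_calls:
            categories[family_id] = categorize_family(member_calls)
    return calls, categories
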