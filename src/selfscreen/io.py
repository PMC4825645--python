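"""File formats, validation, and the end-to-end pipeline.

Pedigree and clutch tables use a small TSV dialect (tab-separated, header
row, UTF-8, ``.`` for missing values).  Standard pedigree formats assume
two distinct parents per individual; a selfing pedigree has one, so the
pedigree table carries a single ``parent_id`` column.

Pedigree columns: fish_id, family_id, generation, parent_id, role,
status, sessions_observed [, true_genotype].
Clutch columns (one row per embryo): embryo_id, parent_id,
session_index, fertilized (0/1), viable (0/1), phenotype_labels
(semicolon-joined).
Calls columns: fish_id, call, n_scored, n_viable, n_nonviable, n_mutant,
evidence_notes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .classify import ClassificationRules, FishCall, classify_screen
from .genetics import Genotype
from .simulate import Clutch, Embryo, Fish, ScreenConfig, ScreenResult, simulate_screen
from .stats import cohort_summary, segregation_test, Rounding

__all__ = [
    "MISSING",
    "read_pedigree",
    "write_pedigree",
    "read_clutches",
    "write_clutches",
    "write_calls",
    "RunManifest",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

MISSING = "."

PEDIGREE_COLUMNS = ["fish_id", "family_id", "generation", "parent_id",
                    "role", "status", "sessions_observed"]
CLUTCH_COLUMNS = ["embryo_id", "parent_id", "session_index",
                  "fertilized", "viable", "phenotype_labels"]


class ValidationError(ValueError):
    pass


def write_pedigree(pedigree: Sequence[Fish], path, truth: dict | None = None) -> None:
    """Write a pedigree TSV; pass ``truth`` to append a true_genotype column."""
    rows = []
    for f in pedigree:
        row = {
            "fish_id": f.fish_id,
            "family_id": f.family_id,
            "generation": f.generation,
            "parent_id": f.parent_id or MISSING,
            "role": f.role,
            "status": f.status,
            "sessions_observed": f.sessions_observed,
        }
        if truth is not None:
            row["true_genotype"] = str(f.genotype)
            row["true_class"] = truth.get(f.fish_id, MISSING)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> list[Fish]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(PEDIGREE_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValidationError(f"pedigree file missing columns: {sorted(missing_cols)}")
    fish: list[Fish] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.fish_id in seen:
            raise ValidationError(f"row {i}: duplicate fish_id {row.fish_id!r}")
        seen.add(row.fish_id)
        genotype = Genotype.parse(getattr(row, "true_genotype", MISSING))
        fish.append(
            Fish(
                fish_id=row.fish_id,
                family_id=row.family_id,
                generation=row.generation,
                parent_id=None if row.parent_id == MISSING else row.parent_id,
                genotype=genotype,
                role=row.role,
                status=row.status,
                sessions_observed=int(row.sessions_observed),
            )
        )
    ids = {f.fish_id for f in fish}
    for i, f in enumerate(fish, start=2):
        if f.parent_id is not None and f.parent_id not in ids:
            raise ValidationError(
                f"row {i}: dangling parent_id {f.parent_id!r} for {f.fish_id}")
    return fish


def write_clutches(clutches: Sequence[Clutch], path) -> None:
    rows = []
    for c in clutches:
        for e in c.embryos:
            rows.append(
                {
                    "embryo_id": e.embryo_id,
                    "parent_id": e.parent_id,
                    "session_index": e.session_index,
                    "fertilized": int(e.fertilized),
                    "viable": int(e.viable_at_score),
                    "phenotype_labels": ";".join(sorted(e.phenotype_labels)) or MISSING,
                }
            )
    pd.DataFrame(rows, columns=CLUTCH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_clutches(path) -> list[Clutch]:
    """Read per-embryo clutch rows back into per-session Clutch objects.

    Empty sessions leave no rows; callers recover them from each fish's
    ``sessions_observed`` in the pedigree.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(CLUTCH_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValidationError(f"clutch file missing columns: {sorted(missing_cols)}")
    grouped: dict[tuple[str, int], list[Embryo]] = defaultdict(list)
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.embryo_id in seen:
            raise ValidationError(f"row {i}: duplicate embryo_id {row.embryo_id!r}")
        seen.add(row.embryo_id)
        fertilized = row.fertilized == "1"
        viable = row.viable == "1"
        if viable and not fertilized:
            raise ValidationError(
                f"row {i}: embryo {row.embryo_id} viable but unfertilized")
        labels = frozenset(
            l for l in row.phenotype_labels.split(";") if l and l != MISSING)
        session = int(row.session_index)
        grouped[(row.parent_id, session)].append(
            Embryo(row.embryo_id, row.parent_id, session, Genotype.wild_type(),
                   fertilized, viable, labels)
        )
    return [
        Clutch(parent_id, session, embryos)
        for (parent_id, session), embryos in sorted(grouped.items())
    ]


def write_calls(calls: dict[str, FishCall], path) -> None:
    rows = []
    for fish_id in sorted(calls):
        call = calls[fish_id]
        ev = call.evidence
        rows.append(
            {
                "fish_id": fish_id,
                "call": call.call.value,
                "n_scored": ev.n_scored if ev else MISSING,
                "n_viable": ev.n_viable if ev else MISSING,
                "n_nonviable": ev.n_nonviable if ev else MISSING,
                "n_mutant": ev.n_mutant() if ev else MISSING,
                "evidence_notes": call.notes or MISSING,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    outputs: list[str] = field(default_factory=list)
    timestamp: str = ""

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def run_pipeline(
    config: ScreenConfig | str | Path,
    outdir: str | Path,
    rules: ClassificationRules | None = None,
    seed: int | None = None,
    write_truth: bool = True,
) -> RunManifest:
    """Simulate, classify, summarize: the whole pipeline in one call.

    Writes pedigree, clutch, calls and family-category TSVs, a
    segregation goodness-of-fit JSON, cohort summary tables, and a run
    manifest into ``outdir``.  Reruns with the same configuration and
    seed produce byte-identical tables (the manifest's timestamp aside).
    """
    if not isinstance(config, ScreenConfig):
        config = ScreenConfig.from_json(config)
    if seed is not None:
        config.seed = seed
    rules = rules or ClassificationRules()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    result = simulate_screen(config)
    calls, categories = classify_screen(result.pedigree, result.clutches, rules)

    outputs = []

    def _out(name: str) -> Path:
        outputs.append(name)
        return outdir / name

    write_pedigree(result.pedigree, _out("pedigree.tsv"),
                   truth=result.truth if write_truth else None)
    write_clutches(result.clutches, _out("clutches.tsv"))
    write_calls(calls, _out("calls.tsv"))

    fam_rows = []
    for family_id in sorted(categories):
        members = [f for f in result.pedigree
                   if f.family_id == family_id and f.generation == "F2"
                   and f.status == "ADULT"]
        n_carrier = sum(
            calls[f.fish_id].call.value == "CARRIER"
            for f in members if f.fish_id in calls)
        fam_rows.append({
            "family_id": family_id,
            "category": categories[family_id],
            "n_f2_scored": len(members),
            "n_f2_carriers": n_carrier,
        })
        logger.info("family %s: %s (%d/%d carriers)", family_id,
                    categories[family_id], n_carrier, len(members))
    pd.DataFrame(fam_rows).to_csv(_out("families.tsv"), sep="\t", index=False)

    # F2 segregation goodness of fit on the simulated calls (1 wild-type :
    # 2 carriers among non-male, non-sterile F2 adults), when both classes occur
    f2_calls = [calls[f.fish_id].call.value for f in result.pedigree
                if f.generation == "F2" and f.fish_id in calls]
    n_wt = f2_calls.count("WILD_TYPE")
    n_carrier = f2_calls.count("CARRIER")
    gof: dict = {"n_wild_type": n_wt, "n_carrier": n_carrier}
    if n_wt and n_carrier:
        gof["segregation_1_2"] = segregation_test(
            [n_wt, n_carrier], [1, 2], Rounding.EXACT).to_dict()
    with open(_out("segregation_gof.json"), "w") as fh:
        json.dump(gof, fh, indent=2)

    # embryo counts per F2 fish by called class (cohort summary table)
    clutch_counts = defaultdict(int)
    for c in result.clutches:
        clutch_counts[c.parent_id] += c.size
    records = pd.DataFrame(
        [
            {"fish_id": fid, "call": calls[fid].call.value,
             "n_embryos": clutch_counts.get(fid, 0)}
            for fid in sorted(calls)
            if calls[fid].call.value != "PRIMARY_MALE"
        ]
    )
    if not records.empty:
        cohort_summary(records, "n_embryos", "call", decimals=0).to_csv(
            _out("embryo_summary.tsv"), sep="\t")

    manifest = RunManifest(
        config_hash=hashlib.sha256(config.to_json().encode()).hexdigest()[:16],
        seed=config.seed,
        version=__version__,
        outputs=outputs,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    manifest.write(outdir / "manifest.json")
    return manifest
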