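"""Reporting-odds-ratio disproportionality analysis.

Aggregates spontaneous-report drug–event pair records into case-level
2x2 contingency tables, computes the reporting odds ratio

    ROR = (a/c) / (b/d) = a*d / (b*c)

with a Wald 95% confidence interval on the log scale, ranks drugs by
point ROR and builds ROR-ranked top-N subsets plus an ATC-matched
independent test set. Cells: a = cases with the drug and the adverse
event, b = drug without event, c = event without drug, d = neither.

When any cell is zero the Haldane–Anscombe correction (add 0.5 to every
cell) keeps the ratio defined; corrected results are flagged.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chem_io import CompoundCohort

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class RorResult:
    drug_id: str
    ror: float
    log_se: float
    ci95: tuple[float, float]
    corrected: bool
    table: ContingencyTable

    def __post_init__(self) -> None:
        low, high = self.ci95
        if not (low <= self.ror <= high):
            raise ValueError("point ROR must lie inside its CI")


def build_contingency(records: pd.DataFrame, drug: str, event: str) -> ContingencyTable:
    """Case-level 2x2 table for one drug and one event.

    ``records`` has columns case_id, drug_id, event_id; a case may list
    many drugs and events and each case counts once per cell regardless
    of repeated mentions.
    """
    required = {"case_id", "drug_id", "event_id"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns {sorted(missing)}")
    cases = records["case_id"].unique()
    with_drug = set(records.loc[records["drug_id"] == drug, "case_id"])
    with_event = set(records.loc[records["event_id"] == event, "case_id"])
    a = len(with_drug & with_event)
    b = len(with_drug) - a
    c = len(with_event) - a
    d = len(cases) - a - b - c
    return ContingencyTable(a, b, c, d)


def compute_ror(
    table: ContingencyTable, drug_id: str = "", correction: bool = True
) -> RorResult:
    """Point ROR with Wald 95% CI on ln(ROR).

    A zero cell triggers the Haldane–Anscombe correction (0.5 added to
    all four cells) when ``correction`` is enabled, otherwise an error.
    """
    a, b, c, d = (float(x) for x in table.as_tuple())
    corrected = False
    if min(a, b, c, d) == 0:
        if not correction:
            raise ZeroDivisionError(
                f"ROR undefined for cells {table.as_tuple()} without continuity correction"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    ror = (a * d) / (b * c)
    log_se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_ror = math.log(ror)
    ci = (math.exp(log_ror - Z_95 * log_se), math.exp(log_ror + Z_95 * log_se))
    return RorResult(
        drug_id=drug_id, ror=ror, log_se=log_se, ci95=ci, corrected=corrected, table=table
    )


@dataclass
class RankedDrugList:
    """Drugs sorted by point ROR descending; ties broken by drug id."""

    entries: list[RorResult]

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda r: (-r.ror, r.drug_id))

    def top_n(self, n: int) -> list[RorResult]:
        return self.entries[: max(0, n)]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def ids(self) -> list[str]:
        return [r.drug_id for r in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "drug_id": [r.drug_id for r in self.entries],
                "ror": [r.ror for r in self.entries],
                "ci_low": [r.ci95[0] for r in self.entries],
                "ci_high": [r.ci95[1] for r in self.entries],
                "corrected": [r.corrected for r in self.entries],
            }
        )


def rank_by_ror(results: list[RorResult]) -> RankedDrugList:
    return RankedDrugList(list(results))


def ror_from_records(
    records: pd.DataFrame, event: str, drugs: list[str] | None = None, correction: bool = True
) -> RankedDrugList:
    """Compute and rank RORs for every drug (or a given subset) against
    one event."""
    if drugs is None:
        drugs = sorted(
            d for d in records["drug_id"].unique() if not str(d).startswith("__")
        )
    results = [
        compute_ror(build_contingency(records, drug, event), drug_id=drug, correction=correction)
        for drug in drugs
    ]
    return rank_by_ror(results)


def build_matched_test_set(
    positives: RankedDrugList,
    positive_atc: dict[str, list[str]],
    negative_pool: CompoundCohort,
    k: int,
    seed: int = 0,
) -> tuple[list[str], list[str], int]:
    """Top-k positives plus k ATC-matched negatives.

    Greedy ATC level-1 frequency matching: for each level-1 letter of
    the positives' histogram, take as many pool negatives of that letter
    as available; deficits are reallocated to the letters most frequent
    in the remaining pool, with residual ties filled deterministically
    from the given seed. Returns (positive ids, negative ids, L1
    histogram distance between the matched sets).
    """
    if k > len(positives) or k > negative_pool.size:
        raise ValueError(
            f"k={k} exceeds a pool size ({len(positives)} positives, "
            f"{negative_pool.size} negatives)"
        )
    top = [r.drug_id for r in positives.top_n(k)]
    target = Counter()
    for drug in top:
        letters = sorted({c.strip()[0].upper() for c in positive_atc.get(drug, []) if c.strip()})
        target[letters[0] if letters else "unassigned"] += 1

    rng = np.random.default_rng(seed)
    by_letter: dict[str, list[str]] = {}
    for rec in negative_pool:
        letters = rec.atc_level1()
        letter = letters[0] if letters else "unassigned"
        by_letter.setdefault(letter, []).append(rec.id)
    for ids in by_letter.values():
        ids.sort()

    chosen: list[str] = []
    deficit = 0
    for letter, want in sorted(target.items()):
        have = by_letter.get(letter, [])
        take = min(want, len(have))
        chosen.extend(have[:take])
        by_letter[letter] = have[take:]
        deficit += want - take
    if deficit:
        logger.warning(
            "ATC matching: %d slot(s) could not be matched by letter; "
            "filling from the most frequent remaining pool letters",
            deficit,
        )
    while deficit and any(by_letter.values()):
        letter = max(by_letter, key=lambda l: (len(by_letter[l]), l))
        pool = by_letter[letter]
        idx = int(rng.integers(len(pool)))
        chosen.append(pool.pop(idx))
        deficit -= 1
    if len(chosen) < k:
        raise ValueError("negative pool exhausted before reaching k matches")

    matched = Counter()
    id_to_letter = {
        rec.id: (rec.atc_level1()[0] if rec.atc_level1() else "unassigned")
        for rec in negative_pool
    }
    for cid in chosen:
        matched[id_to_letter[cid]] += 1
    l1 = sum(abs(target[l] - matched[l]) for l in set(target) | set(matched))
    return top, sorted(chosen), l1


def read_records_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"case_id": str, "drug_id": str, "event_id": str})
    return df


def read_aggregated_csv(path: str | Path) -> dict[str, ContingencyTable]:
    """Read a pre-aggregated table CSV: drug_id,a,b,c,d."""
    df = pd.read_csv(path, dtype={"drug_id": str})
    return {
        str(r.drug_id): ContingencyTable(int(r.a), int(r.b), int(r.c), int(r.d))
        for r in df.itertuples(index=False)
    }
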