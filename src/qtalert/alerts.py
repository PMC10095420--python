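"""Structural-alert screening.

Matches a dictionary of named SMARTS alerts against two labeled cohorts
(QT-prolonging vs no-DIQT-concern) and computes the per-alert
proportion-difference screen: for every alert, the fraction of each
cohort carrying at least one embedding of the pattern, and the
difference of those fractions. Alerts whose proportion in the positive
cohort exceeds the negative-cohort proportion by more than a threshold
(default 0.20) are retained.

Counting is per molecule, not per occurrence: a drug with five tertiary
amines contributes one to the tertiary-amine count. Overlapping alert
classes are screened independently.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from rdkit import Chem

from .chem_io import CompoundCohort

#: name of the packaged default dictionary
DEFAULT_DICTIONARY = "alert_dictionary.tsv"


class AlertConfigError(ValueError):
    """An alert definition is unusable (bad SMARTS, duplicate id)."""


@dataclass
class AlertDefinition:
    """A named substructure alert with its compiled SMARTS query."""

    alert_id: int
    name: str
    class_group: str
    smarts: str
    query: Chem.Mol = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        query = Chem.MolFromSmarts(self.smarts)
        if query is None:
            raise AlertConfigError(
                f"alert {self.alert_id} ({self.name!r}): invalid SMARTS {self.smarts!r}"
            )
        self.query = query


@dataclass(frozen=True)
class AlertScreenRow:
    """Two-cohort presence counts and proportions for one alert."""

    alert_id: int
    name: str
    class_group: str
    n_pos: int
    total_pos: int
    n_neg: int
    total_neg: int

    @property
    def p_pos(self) -> float:
        return self.n_pos / self.total_pos

    @property
    def p_neg(self) -> float:
        return self.n_neg / self.total_neg

    @property
    def difference(self) -> float:
        return self.p_pos - self.p_neg


@dataclass
class ScreenReport:
    """All screen rows plus the retained subset."""

    rows: list[AlertScreenRow]
    threshold: float

    @property
    def retained(self) -> list[AlertScreenRow]:
        return apply_retention_filter(self.rows, self.threshold)

    def to_frame(self) -> pd.DataFrame:
        """Tabular report; proportions rendered to 4 decimals, sorted by
        difference descending within class group."""
        df = pd.DataFrame(
            {
                "alert_id": [r.alert_id for r in self.rows],
                "class_group": [r.class_group for r in self.rows],
                "name": [r.name for r in self.rows],
                "n_pos": [r.n_pos for r in self.rows],
                "p_pos": [round(r.p_pos, 4) for r in self.rows],
                "n_neg": [r.n_neg for r in self.rows],
                "p_neg": [round(r.p_neg, 4) for r in self.rows],
                "difference": [round(r.difference, 4) for r in self.rows],
                "retained": [r.difference > self.threshold for r in self.rows],
            }
        )
        df["_diff_full"] = [r.difference for r in self.rows]
        df = df.sort_values(
            ["class_group", "_diff_full"], ascending=[True, False], kind="stable"
        ).drop(columns="_diff_full")
        return df.reset_index(drop=True)


def load_alert_dictionary(path: str | Path | None = None) -> list[AlertDefinition]:
    """Load an alert dictionary TSV (columns alert_id, name, class_group,
    smarts; ``#`` comment lines allowed). ``None`` loads the packaged
    default dictionary."""
    if path is None:
        ref = importlib.resources.files("qtalert") / "data" / DEFAULT_DICTIONARY
        with importlib.resources.as_file(ref) as p:
            return load_alert_dictionary(p)
    df = _read_tsv(path)
    required = {"alert_id", "name", "class_group", "smarts"}
    missing = required - set(df.columns)
    if missing:
        raise AlertConfigError(f"{path}: dictionary missing columns {sorted(missing)}")
    alerts = [
        AlertDefinition(
            alert_id=int(row.alert_id),
            name=str(row.name),
            class_group=str(row.class_group),
            smarts=str(row.smarts),
        )
        for row in df.itertuples(index=False)
    ]
    ids = [a.alert_id for a in alerts]
    if len(ids) != len(set(ids)):
        raise AlertConfigError(f"{path}: duplicate alert_id in dictionary")
    return alerts


def match_alert(mol: Chem.Mol, alert: AlertDefinition) -> bool:
    """True iff the molecule contains at least one embedding of the alert."""
    return mol.HasSubstructMatch(alert.query)


def screen_alerts(
    pos: CompoundCohort,
    neg: CompoundCohort,
    dictionary: list[AlertDefinition],
    threshold: float = 0.20,
) -> ScreenReport:
    """Run the two-cohort proportion-difference screen."""
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both cohorts must be non-empty")
    if not 0 <= threshold < 1:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    rows = []
    for alert in dictionary:
        n_pos = sum(match_alert(rec.mol, alert) for rec in pos)
        n_neg = sum(match_alert(rec.mol, alert) for rec in neg)
        rows.append(
            AlertScreenRow(
                alert_id=alert.alert_id,
                name=alert.name,
                class_group=alert.class_group,
                n_pos=n_pos,
                total_pos=pos.size,
                n_neg=n_neg,
                total_neg=neg.size,
            )
        )
    return ScreenReport(rows=rows, threshold=threshold)


def screen_from_counts(
    counts: pd.DataFrame,
    total_pos: int,
    total_neg: int,
    threshold: float = 0.20,
) -> ScreenReport:
    """Build a screen report from pre-tabulated per-alert counts
    (columns alert_id, name, class_group, n_pos, n_neg) — for published
    count tables where the structures themselves are not available."""
    rows = [
        AlertScreenRow(
            alert_id=int(r.alert_id),
            name=str(r.name),
            class_group=str(r.class_group),
            n_pos=int(r.n_pos),
            total_pos=total_pos,
            n_neg=int(r.n_neg),
            total_neg=total_neg,
        )
        for r in counts.itertuples(index=False)
    ]
    return ScreenReport(rows=rows, threshold=threshold)


def load_reference_counts() -> pd.DataFrame:
    """The packaged DIQTA screen count table (24 retained alerts,
    cohort sizes 144 and 95)."""
    ref = importlib.resources.files("qtalert") / "data" / "diqta_screen_counts.tsv"
    with importlib.resources.as_file(ref) as p:
        return _read_tsv(p)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    """TSV reader that drops full-line ``#`` comments only — ``#`` is a
    meaningful character inside SMARTS atom primitives."""
    import io

    with open(path) as fh:
        body = "".join(line for line in fh if not line.lstrip().startswith("#"))
    return pd.read_csv(io.StringIO(body), sep="\t")


def apply_retention_filter(
    rows: list[AlertScreenRow], threshold: float = 0.20
) -> list[AlertScreenRow]:
    """Rows with difference strictly above the threshold, sorted by
    difference descending (ties by alert_id)."""
    kept = [r for r in rows if r.difference > threshold]
    return sorted(kept, key=lambda r: (-r.difference, r.alert_id))


def tabulate_by_category(cohort: CompoundCohort, alert: AlertDefinition) -> dict[str, int]:
    """Count alert-carrying molecules per ATC level-1 letter.

    A drug with codes in several anatomical classes counts once per
    class; matching records without any ATC code are binned under
    ``unassigned``.
    """
    counts: dict[str, int] = {}
    for rec in cohort:
        if not match_alert(rec.mol, alert):
            continue
        letters = rec.atc_level1() or ["unassigned"]
        for letter in letters:
            counts[letter] = counts.get(letter, 0) + 1
    return dict(sorted(counts.items()))


def write_screen_report(report: ScreenReport, path: str | Path) -> None:
    report.to_frame().to_csv(path, sep="\t", index=False)
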