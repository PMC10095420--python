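"""SA-linked substructure-count descriptors.

Implements the ten count descriptors tied to the retained structural
alerts (codes D718, D756, D661, D759, D627, D130, D647, D626, D757,
D598 in the Mold2 numbering), assembles per-cohort descriptor matrices
and applies the low-variance column filter.

Each descriptor counts symmetry-unique occurrences of a functional
group, anchored on the group-defining atom so that one group never
counts twice (e.g. one NR3 nitrogen is one tertiary amine regardless of
how its substituents are enumerated). The counting rules are this
package's documented readings of the published one-line descriptions;
externally computed full descriptor matrices can be imported instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem_io import CompoundCohort


@dataclass(frozen=True)
class DescriptorDefinition:
    """A named counting rule: SMARTS pattern(s) plus the index of the
    anchor atom within each pattern."""

    code: str
    description: str
    patterns: tuple[tuple[str, int], ...]  # (smarts, anchor atom index)

    def count(self, mol: Chem.Mol) -> int:
        anchors: set[int] = set()
        for smarts, anchor_idx in self.patterns:
            query = _compiled(smarts)
            for match in mol.GetSubstructMatches(query, uniquify=True):
                anchors.add(match[anchor_idx])
        return len(anchors)


_QUERY_CACHE: dict[str, Chem.Mol] = {}


def _compiled(smarts: str) -> Chem.Mol:
    query = _QUERY_CACHE.get(smarts)
    if query is None:
        query = Chem.MolFromSmarts(smarts)
        if query is None:
            raise ValueError(f"invalid SMARTS {smarts!r}")
        _QUERY_CACHE[smarts] = query
    return query


# Shared with the alert dictionary where the same group is screened, so
# count >= 1 is equivalent to the corresponding alert matching.
_TERT_ALIPHATIC_AMINE = "[NX3;H0;!$([NX3][CX3]=[OX1,SX1,NX2])]([CX4])([CX4])[CX4]"
_HALOGEN = "[F,Cl,Br,I]"

SA_DESCRIPTORS: tuple[DescriptorDefinition, ...] = (
    DescriptorDefinition(
        "D718",
        "number of CH3X groups (methyl bound to a heteroatom)",
        (("[CX4;H3][!#6;!#1]", 0),),
    ),
    DescriptorDefinition(
        "D756",
        "number of Al-O-Ar, Ar-O-Ar or R-O-C=X (X in O,S,N) oxygens",
        (
            ("[CX4][OX2]c", 1),
            ("c[OX2]c", 1),
            ("[#6][OX2][CX3]=[OX1,SX1,NX2]", 1),
        ),
    ),
    DescriptorDefinition(
        "D661",
        "number of quaternary ammonium (aliphatic) groups",
        (("[NX4+]([CX4])([CX4])([CX4])[CX4]", 0),),
    ),
    DescriptorDefinition(
        "D759",
        "number of tertiary aliphatic amine groups",
        ((_TERT_ALIPHATIC_AMINE, 0),),
    ),
    DescriptorDefinition(
        "D627",
        "number of tertiary amide (aliphatic) groups",
        (("[NX3;H0]([CX4])([CX4])[CX3]=[OX1]", 0),),
    ),
    DescriptorDefinition(
        "D130",
        "number of halogen atoms",
        ((_HALOGEN, 0),),
    ),
    DescriptorDefinition(
        "D647",
        "number of primary aliphatic amine groups (NH2 on sp3 carbon)",
        (("[NX3;H2][CX4]", 0),),
    ),
    DescriptorDefinition(
        "D626",
        "number of secondary amide (aromatic) groups (N-aryl anilide NH)",
        (("[NX3;H1](c)[CX3]=[OX1]", 0),),
    ),
    DescriptorDefinition(
        "D757",
        "number of Al-NH2 groups",
        (("[NX3;H2][CX4]", 0),),
    ),
    DescriptorDefinition(
        "D598",
        "number of tertiary sp3 carbons (CH bound to three carbons)",
        (("[CX4;H1]([#6])([#6])[#6]", 0),),
    ),
)

SA_DESCRIPTOR_CODES: tuple[str, ...] = tuple(d.code for d in SA_DESCRIPTORS)


def compute_sa_descriptors(mol: Chem.Mol) -> dict[str, int]:
    """The ten SA-linked counts for one standardized molecule."""
    return {d.code: d.count(mol) for d in SA_DESCRIPTORS}


@dataclass
class DescriptorMatrix:
    """A labeled descriptor table: one row per molecule, one column per
    descriptor code."""

    values: pd.DataFrame  # index: molecule ids; columns: descriptor codes
    labels: pd.Series  # aligned to values.index; "positive"/"negative"/"unknown"

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.labels.index):
            raise ValueError("labels must be indexed exactly like the matrix rows")
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()].tolist()
            raise ValueError(f"matrix contains missing values in columns {bad}")
        if not self.values.index.is_unique:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate molecule ids: {dupes}")

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def codes(self) -> list[str]:
        return list(self.values.columns)

    def X(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def y(self) -> np.ndarray:
        """Binary label vector: positive -> 1, negative -> 0. Errors on
        unknown labels."""
        mapping = {"positive": 1, "negative": 0}
        unknown = [l for l in self.labels.unique() if l not in mapping]
        if unknown:
            raise ValueError(f"cannot binarize labels {unknown}")
        return self.labels.map(mapping).to_numpy(dtype=int)

    def select(self, codes: list[str]) -> "DescriptorMatrix":
        missing = [c for c in codes if c not in self.values.columns]
        if missing:
            raise KeyError(f"descriptor column(s) not present: {missing}")
        return DescriptorMatrix(self.values[list(codes)].copy(), self.labels.copy())

    def to_csv(self, path: str | Path, label_column: str = "label") -> None:
        out = self.values.copy()
        out.insert(0, label_column, self.labels)
        out.to_csv(path, index_label="id")


def assemble_matrix(
    cohorts: list[CompoundCohort],
    descriptors: tuple[DescriptorDefinition, ...] = SA_DESCRIPTORS,
) -> DescriptorMatrix:
    """Compute a descriptor matrix over one or more cohorts; row order is
    input order, duplicate ids across cohorts are an error."""
    if not cohorts or all(c.size == 0 for c in cohorts):
        raise ValueError("need at least one non-empty cohort")
    ids: list[str] = []
    labels: list[str] = []
    rows: list[dict[str, int]] = []
    for cohort in cohorts:
        for rec in cohort:
            try:
                row = {d.code: d.count(rec.mol) for d in descriptors}
            except Exception as exc:
                raise RuntimeError(
                    f"descriptor computation failed for molecule {rec.id!r}: {exc}"
                ) from exc
            ids.append(rec.id)
            labels.append(rec.label)
            rows.append(row)
    values = pd.DataFrame(rows, index=pd.Index(ids, name="id"))
    return DescriptorMatrix(values, pd.Series(labels, index=values.index, name="label"))


def import_matrix(
    path: str | Path, label_column: str = "label", labels: pd.Series | None = None
) -> DescriptorMatrix:
    """Import an externally computed descriptor matrix (CSV, first column
    molecule id). Labels come from ``label_column`` if present, else from
    the ``labels`` series."""
    df = pd.read_csv(path, index_col=0)
    if label_column in df.columns:
        lab = df[label_column].astype(str)
        df = df.drop(columns=[label_column])
    elif labels is not None:
        lab = labels.reindex(df.index)
        if lab.isna().any():
            missing = df.index[lab.isna()].tolist()
            raise ValueError(f"no label provided for molecule ids {missing}")
    else:
        lab = pd.Series("unknown", index=df.index)
    return DescriptorMatrix(df, pd.Series(lab, index=df.index, name="label"))


def variance_filter(matrix: DescriptorMatrix, threshold: float = 0.001) -> DescriptorMatrix:
    """Drop columns whose population variance (ddof=0, raw unscaled
    values) is <= threshold. Idempotent; erroring if nothing survives."""
    variances = matrix.values.var(axis=0, ddof=0)
    keep = variances[variances > threshold].index.tolist()
    if not keep:
        raise ValueError(
            f"variance filter at {threshold} removed every column "
            f"({len(variances)} input columns)"
        )
    return DescriptorMatrix(matrix.values[keep].copy(), matrix.labels.copy())
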