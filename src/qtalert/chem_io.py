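"""Compound input/output and structure standardization.

Reads labeled compound sets from SMILES-CSV or SDF, standardizes every
structure (largest organic fragment, neutralized charges, one fixed
aromaticity model) and exposes the in-memory cohort consumed by the
alert screen, the descriptor calculator and the SAR models.

Standardization convention: RDKit's default aromaticity perception,
salt/counter-ion stripping by keeping the largest covalent fragment,
charge neutralization where chemically possible, stereochemistry
discarded (every downstream feature is a 2D substructure count).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

Label = Literal["positive", "negative", "unknown"]
VALID_LABELS = ("positive", "negative", "unknown")


class StructureError(ValueError):
    """Raised when a structure cannot be parsed or standardized."""

    def __init__(self, record_id: str, message: str):
        self.record_id = record_id
        super().__init__(f"record {record_id!r}: {message}")


@dataclass
class MoleculeRecord:
    """One drug: identifier, standardized structure, label, ATC codes."""

    id: str
    name: str
    mol: Chem.Mol
    label: Label = "unknown"
    atc_codes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {VALID_LABELS}, got {self.label!r}")
        if self.mol is None or self.mol.GetNumHeavyAtoms() < 1:
            raise StructureError(self.id, "structure has no heavy atoms")

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)

    def atc_level1(self) -> list[str]:
        """Distinct ATC level-1 letters carried by this record."""
        letters = {c.strip()[0].upper() for c in self.atc_codes if c.strip()}
        return sorted(letters)


@dataclass
class CompoundCohort:
    """An ordered, id-unique collection of molecule records."""

    records: list[MoleculeRecord]
    cohort_label: Literal["positive", "negative", "unlabeled"] = "unlabeled"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate record id {rec.id!r} in cohort")
            seen.add(rec.id)
        if self.cohort_label != "unlabeled":
            for rec in self.records:
                if rec.label != self.cohort_label:
                    raise ValueError(
                        f"record {rec.id!r} has label {rec.label!r}, "
                        f"cohort is {self.cohort_label!r}"
                    )

    @property
    def size(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return self.size

    def __iter__(self) -> Iterator[MoleculeRecord]:
        return iter(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]


_uncharger = rdMolStandardize.Uncharger()


def normalize_structure(mol: Chem.Mol, record_id: str = "<anonymous>") -> Chem.Mol:
    """Standardize a parsed molecule.

    Keeps the largest covalent fragment (salt stripping), neutralizes
    charges where chemically possible, removes stereochemistry and
    re-perceives aromaticity under RDKit's default model. Idempotent.
    """
    if mol is None:
        raise StructureError(record_id, "cannot normalize a missing structure")
    try:
        frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
        if len(frags) > 1:
            # largest organic fragment: most heavy atoms, carbon-containing
            # fragments preferred over bare counter-ions
            def key(f: Chem.Mol) -> tuple[int, int]:
                has_c = any(a.GetAtomicNum() == 6 for a in f.GetAtoms())
                return (int(has_c), f.GetNumHeavyAtoms())

            mol = max(frags, key=key)
        mol = Chem.Mol(mol)
        Chem.SanitizeMol(mol)
        mol = _uncharger.uncharge(mol)
        Chem.RemoveStereochemistry(mol)
        Chem.SanitizeMol(mol)
    except StructureError:
        raise
    except Exception as exc:  # rdkit raises plain Exceptions on sanitize failure
        raise StructureError(record_id, f"standardization failed: {exc}") from exc
    if mol.GetNumHeavyAtoms() < 1:
        raise StructureError(record_id, "no heavy atoms after standardization")
    return mol


def mol_from_smiles(smiles: str, record_id: str = "<anonymous>") -> Chem.Mol:
    """Parse and standardize a SMILES string."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(record_id, f"unparsable SMILES {smiles!r}")
    return normalize_structure(mol, record_id)


def _parse_atc(raw: str | None) -> list[str]:
    if not raw:
        return []
    return [tok.strip() for tok in str(raw).split(";") if tok.strip()]


def load_compounds(
    path: str | Path,
    fmt: Literal["smiles-csv", "sdf"],
    label: Label | None = None,
) -> CompoundCohort:
    """Load a cohort from a SMILES CSV or an SDF file.

    CSV columns: ``id,name,smiles,label,atc`` (``atc`` semicolon-separated;
    ``name``, ``label`` and ``atc`` optional). SDF molecules carry
    properties ``ID``, ``NAME``, ``LABEL``, ``ATC``.

    Records whose structure fails to parse or standardize are excluded
    with a logged warning; the file itself being unreadable is an error.
    When ``label`` is given it overrides per-record labels and sets the
    cohort label.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "smiles-csv":
        raw = list(_iter_csv(path))
    elif fmt == "sdf":
        raw = list(_iter_sdf(path))
    else:
        raise ValueError(f"unknown format {fmt!r}")

    records: list[MoleculeRecord] = []
    n_excluded = 0
    for rec_id, name, make_mol, rec_label, atc in raw:
        use_label: Label = label if label is not None else (rec_label or "unknown")
        try:
            mol = make_mol()
            records.append(
                MoleculeRecord(id=rec_id, name=name, mol=mol, label=use_label, atc_codes=atc)
            )
        except StructureError as exc:
            n_excluded += 1
            logger.warning("excluding record: %s", exc)
    if n_excluded:
        logger.warning("%s: excluded %d unparsable record(s)", path.name, n_excluded)
    cohort_label = label if label in ("positive", "negative") else "unlabeled"
    return CompoundCohort(records=records, cohort_label=cohort_label)


def _iter_csv(path: Path):
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "smiles" not in [f.lower() for f in reader.fieldnames]:
            raise ValueError(f"{path}: expected a header with a 'smiles' column")
        for i, row in enumerate(reader):
            row = {k.lower(): v for k, v in row.items() if k}
            rec_id = (row.get("id") or f"row{i + 1}").strip()
            smiles = (row.get("smiles") or "").strip()
            rec_label = (row.get("label") or "").strip().lower() or None
            if rec_label is not None and rec_label not in VALID_LABELS:
                raise ValueError(f"{path}: invalid label {rec_label!r} for record {rec_id!r}")
            yield (
                rec_id,
                (row.get("name") or "").strip(),
                lambda s=smiles, r=rec_id: mol_from_smiles(s, r),
                rec_label,
                _parse_atc(row.get("atc")),
            )


def _iter_sdf(path: Path):
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    for i, mol in enumerate(supplier):
        if mol is None:
            rec_id = f"sdf{i + 1}"
            yield (rec_id, "", lambda r=rec_id: _raise_unparsable(r), None, [])
            continue
        props = {k.upper(): mol.GetProp(k) for k in mol.GetPropNames()}
        if mol.HasProp("_Name") and mol.GetProp("_Name").strip():
            default_id = mol.GetProp("_Name").strip()
        else:
            default_id = f"sdf{i + 1}"
        rec_id = props.get("ID", default_id)
        rec_label = props.get("LABEL", "").strip().lower() or None
        if rec_label is not None and rec_label not in VALID_LABELS:
            raise ValueError(f"{path}: invalid label {rec_label!r} for record {rec_id!r}")
        yield (
            rec_id,
            props.get("NAME", ""),
            lambda m=mol, r=rec_id: _sdf_mol(m, r),
            rec_label,
            _parse_atc(props.get("ATC")),
        )


def _raise_unparsable(record_id: str) -> Chem.Mol:
    raise StructureError(record_id, "unparsable SDF block")


def _sdf_mol(mol: Chem.Mol, record_id: str) -> Chem.Mol:
    mol = Chem.Mol(mol)
    try:
        Chem.SanitizeMol(mol)
        mol = Chem.RemoveHs(mol)
    except Exception as exc:
        raise StructureError(record_id, f"sanitization failed: {exc}") from exc
    return normalize_structure(mol, record_id)


def write_smiles_csv(cohort: CompoundCohort, path: str | Path) -> None:
    """Write a cohort as a ``id,name,smiles,label,atc`` CSV."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "name", "smiles", "label", "atc"])
        for rec in cohort:
            writer.writerow(
                [rec.id, rec.name, rec.smiles, rec.label, ";".join(rec.atc_codes)]
            )


def cohort_from_smiles(
    pairs: Iterable[tuple[str, str]],
    label: Label = "unknown",
    atc: Sequence[Sequence[str]] | None = None,
) -> CompoundCohort:
    """Build a cohort from ``(id, smiles)`` pairs — convenience for tests
    and the synthetic generator."""
    pairs = list(pairs)
    atc_lists = [list(a) for a in atc] if atc is not None else [[] for _ in pairs]
    records = [
        MoleculeRecord(id=i, name="", mol=mol_from_smiles(s, i), label=label, atc_codes=a)
        for (i, s), a in zip(pairs, atc_lists, strict=True)
    ]
    cohort_label = label if label in ("positive", "negative") else "unlabeled"
    return CompoundCohort(records=records, cohort_label=cohort_label)
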