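"""Compound table I/O, canonicalization, and library cleansing.

Raw compound tables (CSV or SDF) are turned into a unique, refined library of
organic, single-component, isotope-free structures.  Every rejected record is
accounted for under exactly one reason, applied in a fixed precedence order,
so the report always balances: ``n_input = n_kept + sum(rejects)``.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

#: Rejection reasons in precedence order: the first matching reason is recorded.
REJECT_REASONS = (
    "unparseable",
    "missing_structure",
    "multicomponent",
    "isotope",
    "inorganic",
    "duplicate",
    "ambiguous_label",
)


class CompoundFormatError(ValueError):
    """Raised when an input table violates the expected schema."""


@dataclass
class RawRecord:
    """One row of an input compound table, prior to any cleansing."""

    id: str
    smiles_raw: str
    name: str = ""
    labels: dict[str, int] = field(default_factory=dict)
    source_tag: str = ""


@dataclass(frozen=True)
class CompoundRecord:
    """A curated chemical structure.

    ``structure_key`` is a deterministic hash of the canonical SMILES, so two
    records describing the same structure share the same key regardless of
    how the input SMILES was written.
    """

    id: str
    name: str
    smiles_raw: str
    smiles_canonical: str
    structure_key: str
    source_tag: str = ""
    labels: dict[str, int] = field(default_factory=dict, hash=False, compare=False)


@dataclass
class CurationReport:
    n_input: int
    n_kept: int
    rejects: dict[str, int]

    def __post_init__(self) -> None:
        assert self.n_input == self.n_kept + sum(self.rejects.values())

    def to_dict(self) -> dict:
        return {"n_input": self.n_input, "n_kept": self.n_kept, "rejects": dict(self.rejects)}


def structure_key(smiles_canonical: str) -> str:
    """Deterministic 16-hex-digit key of a canonical SMILES string."""
    return hashlib.sha256(smiles_canonical.encode()).hexdigest()[:16]


def read_compound_table(path: str | Path, format: str | None = None) -> list[RawRecord]:
    """Read a compound table from CSV or SDF into raw records, order preserved.

    CSV files must carry ``id`` and ``smiles`` columns (``name`` and any label
    columns are optional; every column other than id/name/smiles whose values
    are 0/1/empty is treated as a per-module label column).  SDF entries use
    the molecule title as id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "sdf" if path.suffix.lower() == ".sdf" else "csv"
    if format == "csv":
        return _read_csv(path)
    if format == "sdf":
        return _read_sdf(path)
    raise CompoundFormatError(f"unknown format {format!r}; expected 'csv' or 'sdf'")


def _read_csv(path: Path) -> list[RawRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("id", "smiles"):
        if col not in df.columns:
            raise CompoundFormatError(f"missing mandatory column {col!r} in {path}")
    if df.empty:
        warnings.warn(f"{path} contains no compound rows", stacklevel=2)
        return []
    label_cols = [c for c in df.columns if c not in ("id", "smiles", "name", "source_tag")]
    records = []
    for row in df.itertuples(index=False):
        row = row._asdict()
        labels = {}
        for col in label_cols:
            value = str(row[col]).strip()
            if value in ("0", "1"):
                labels[col] = int(value)
        records.append(
            RawRecord(
                id=str(row["id"]),
                smiles_raw=str(row["smiles"]),
                name=str(row.get("name", "")),
                labels=labels,
                source_tag=str(row.get("source_tag", "")),
            )
        )
    return records


def _read_sdf(path: Path) -> list[RawRecord]:
    records = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            # keep a placeholder so curation can count it as unparseable
            records.append(RawRecord(id=f"sdf_{i}", smiles_raw="", name=""))
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"sdf_{i}"
        records.append(RawRecord(id=name or f"sdf_{i}", smiles_raw=Chem.MolToSmiles(mol), name=name))
    if not records:
        warnings.warn(f"{path} contains no molecules", stacklevel=2)
    return records


def _first_reject_reason(raw: RawRecord) -> tuple[str | None, Chem.Mol | None]:
    """Apply the structural cleansing rules in precedence order."""
    if not raw.smiles_raw or not raw.smiles_raw.strip():
        return "missing_structure", None
    mol = Chem.MolFromSmiles(raw.smiles_raw)
    if mol is None:
        return "unparseable", None
    if "." in Chem.MolToSmiles(mol):
        return "multicomponent", None
    if any(atom.GetIsotope() != 0 for atom in mol.GetAtoms()):
        return "isotope", None
    if not any(atom.GetAtomicNum() == 6 for atom in mol.GetAtoms()):
        return "inorganic", None
    return None, mol


def curate(records: list[RawRecord]) -> tuple[list[CompoundRecord], CurationReport]:
    """Cleanse a raw compound list into a unique curated library.

    Rule precedence (first match wins): unparseable > missing_structure >
    multicomponent > isotope > inorganic > duplicate > ambiguous_label.
    Duplicate structures keep the first occurrence in input order; structures
    whose copies carry conflicting labels for the same module are dropped
    entirely (every copy) as ``ambiguous_label``.
    """
    rejects = {reason: 0 for reason in REJECT_REASONS}
    # single structural pass: (raw, structural reason or None, key or None)
    triaged: list[tuple[RawRecord, str | None, str | None, str | None]] = []
    for raw in records:
        reason, mol = _first_reject_reason(raw)
        if reason is not None:
            triaged.append((raw, reason, None, None))
            continue
        canonical = Chem.MolToSmiles(mol)
        triaged.append((raw, None, canonical, structure_key(canonical)))

    # a structure is label-ambiguous when its copies disagree on any module
    label_sets: dict[str, dict[str, set[int]]] = {}
    for raw, reason, _, key in triaged:
        if reason is not None:
            continue
        per_module = label_sets.setdefault(key, {})
        for module, value in raw.labels.items():
            per_module.setdefault(module, set()).add(value)
    ambiguous_keys = {
        key
        for key, per_module in label_sets.items()
        if any(len(values) > 1 for values in per_module.values())
    }

    survivors: list[CompoundRecord] = []
    seen_keys: set[str] = set()
    for raw, reason, canonical, key in triaged:
        if reason is not None:
            rejects[reason] += 1
            continue
        if key in ambiguous_keys:
            # every copy of a conflicting structure is dropped under this reason
            rejects["ambiguous_label"] += 1
            continue
        if key in seen_keys:
            rejects["duplicate"] += 1
            continue
        seen_keys.add(key)
        survivors.append(
            CompoundRecord(
                id=raw.id,
                name=raw.name,
                smiles_raw=raw.smiles_raw,
                smiles_canonical=canonical,
                structure_key=key,
                source_tag=raw.source_tag,
                labels=dict(raw.labels),
            )
        )

    report = CurationReport(
        n_input=len(records),
        n_kept=len(survivors),
        rejects={reason: count for reason, count in rejects.items()},
    )
    return survivors, report


def write_library_csv(library: list[CompoundRecord], path: str | Path) -> None:
    """Persist a curated library (id, name, smiles_canonical, structure_key + labels)."""
    modules = sorted({module for rec in library for module in rec.labels})
    rows = []
    for rec in library:
        row = {
            "id": rec.id,
            "name": rec.name,
            "smiles_canonical": rec.smiles_canonical,
            "structure_key": rec.structure_key,
        }
        for module in modules:
            row[module] = rec.labels.get(module, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
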