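"""Seeded synthetic compound libraries with planted structure–activity signal.

Molecules are assembled by concatenating valence-safe SMILES units from a
small linear grammar (alkyl, aryl, ether, ester, amine); no ring is formed
during assembly beyond whole aromatic units, which keeps every string
chemically valid without a full chemistry engine.  For each regulator module
a fraction of compounds ("carriers") receives that module's planted motif
spliced at a random chain position, and the module label is the favorable
direction value iff the compound is a carrier, then flipped independently
with the configured label noise.  Rejection sampling guarantees that at
noise 0 a molecule matches its module's motif iff it is a carrier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

from epiqsar.curation import CompoundRecord, structure_key
from epiqsar.datasets import RegulatorModule

#: Chain units; each concatenates on both sides without valence violations.
DEFAULT_UNITS = ("C", "CC", "CCC", "c1ccccc1", "OC", "C(=O)OC", "NC", "C=C")

#: Planted motif per module, drawn from the alert-vocabulary of interest:
#: short acyl chains, amides, dienes, gem-dimethyl carbinols, hexyl ethers.
DEFAULT_MOTIFS: dict[RegulatorModule, str] = {
    RegulatorModule.MIR34A: "CC(CCC(=O))",
    RegulatorModule.DNMT3A: "C(=O)N",
    RegulatorModule.HDAC: "OCCCCCC",
    RegulatorModule.MIR125B: "C=CC=C",
    RegulatorModule.MIR135A: "C(C)(C)O",
}


class GeneratorError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    seed: int
    n_per_module: int = 250
    active_fraction: float = 0.4
    label_noise: float = 0.1
    planted_fragment: dict[RegulatorModule, str] = field(
        default_factory=lambda: dict(DEFAULT_MOTIFS)
    )
    units: tuple[str, ...] = DEFAULT_UNITS
    min_units: int = 2
    max_units: int = 5

    def __post_init__(self) -> None:
        if not (0.0 <= self.active_fraction <= 1.0):
            raise GeneratorError("active_fraction must be in [0, 1]")
        if not (0.0 <= self.label_noise <= 1.0):
            raise GeneratorError("label_noise must be in [0, 1]")
        for module, motif in self.planted_fragment.items():
            if Chem.MolFromSmiles(motif) is None:
                raise GeneratorError(f"motif {motif!r} for {module} does not parse")


@dataclass
class SyntheticLibrary:
    """Per-module labeled libraries plus the planted ground truth."""

    config: GeneratorConfig
    libraries: dict[RegulatorModule, list[CompoundRecord]]
    labels: dict[RegulatorModule, np.ndarray]
    ground_truth: dict[RegulatorModule, dict]

    def write_csv(self, directory: str | Path) -> dict[RegulatorModule, Path]:
        """Emit one curation-schema CSV per module plus a ground-truth JSON."""
        import pandas as pd

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for module, records in self.libraries.items():
            rows = [
                {
                    "id": rec.id,
                    "name": rec.name,
                    "smiles": rec.smiles_canonical,
                    module.value: int(self.labels[module][i]),
                }
                for i, rec in enumerate(records)
            ]
            path = directory / f"library_{module.value}.csv"
            pd.DataFrame(rows).to_csv(path, index=False)
            paths[module] = path
        truth_path = directory / "ground_truth.json"
        truth_path.write_text(
            json.dumps(
                {m.value: truth for m, truth in self.ground_truth.items()}, indent=1
            )
        )
        return paths


def _assemble(
    rng: np.random.Generator,
    units: tuple[str, ...],
    n_units: int,
    motif: str | None,
) -> str:
    parts = [units[i] for i in rng.integers(0, len(units), size=n_units)]
    if motif is not None:
        parts.insert(int(rng.integers(0, n_units + 1)), motif)
    return "".join(parts)


def _sample_molecule(
    rng: np.random.Generator,
    config: GeneratorConfig,
    motif_query: Chem.Mol,
    motif: str,
    carrier: bool,
    taken_keys: set[str],
    max_attempts: int = 2000,
) -> tuple[str, str]:
    """One unique molecule that matches the motif iff it is a carrier."""
    for _ in range(max_attempts):
        n_units = int(rng.integers(config.min_units, config.max_units + 1))
        smiles = _assemble(rng, config.units, n_units, motif if carrier else None)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            continue
        if mol.HasSubstructMatch(motif_query) != carrier:
            continue
        canonical = Chem.MolToSmiles(mol)
        key = structure_key(canonical)
        if key in taken_keys:
            continue
        return smiles, canonical
    raise GeneratorError(
        f"could not assemble a {'carrier' if carrier else 'non-carrier'} for motif "
        f"{motif!r} in {max_attempts} attempts; check grammar/motif compatibility"
    )


def generate_library(config: GeneratorConfig) -> SyntheticLibrary:
    """Generate one labeled library per regulator module (byte-deterministic)."""
    libraries: dict[RegulatorModule, list[CompoundRecord]] = {}
    labels: dict[RegulatorModule, np.ndarray] = {}
    ground_truth: dict[RegulatorModule, dict] = {}
    for module in RegulatorModule:
        motif = config.planted_fragment.get(module, DEFAULT_MOTIFS[module])
        motif_query = Chem.MolFromSmiles(motif)
        # independent, reproducible stream per module
        rng = np.random.default_rng([config.seed, _module_stream(module)])
        n = config.n_per_module
        carrier_flags = rng.random(n) < config.active_fraction
        taken: set[str] = set()
        records: list[CompoundRecord] = []
        module_labels = np.empty(n, dtype=int)
        carrier_ids: list[str] = []
        favorable = module.favorable_label
        for i in range(n):
            carrier = bool(carrier_flags[i])
            raw, canonical = _sample_molecule(
                rng, config, motif_query, motif, carrier, taken
            )
            key = structure_key(canonical)
            taken.add(key)
            cid = f"{module.value}_{i:04d}"
            label = favorable if carrier else 1 - favorable
            if rng.random() < config.label_noise:
                label = 1 - label
            records.append(
                CompoundRecord(
                    id=cid,
                    name=cid,
                    smiles_raw=raw,
                    smiles_canonical=canonical,
                    structure_key=key,
                    source_tag="synthetic",
                    labels={module.value: int(label)},
                )
            )
            module_labels[i] = label
            if carrier:
                carrier_ids.append(cid)
        libraries[module] = records
        labels[module] = module_labels
        ground_truth[module] = {
            "motif": motif,
            "carriers": carrier_ids,
            "favorable_label": favorable,
        }
    return SyntheticLibrary(
        config=config, libraries=libraries, labels=labels, ground_truth=ground_truth
    )


def _module_stream(module: RegulatorModule) -> int:
    return list(RegulatorModule).index(module) + 1


def generate_prediction_library(
    config: GeneratorConfig, n: int = 200, motif_probability: float = 0.25
) -> list[CompoundRecord]:
    """An unlabeled screening library from the same grammar.

    Each compound independently carries each module's motif with
    ``motif_probability``, so the library spans the full range of
    directional rank scores.  Deterministic for a fixed config.
    """
    rng = np.random.default_rng([config.seed, 1000])
    motifs = [config.planted_fragment.get(m, DEFAULT_MOTIFS[m]) for m in RegulatorModule]
    taken: set[str] = set()
    records: list[CompoundRecord] = []
    attempts_per_compound = 2000
    for i in range(n):
        for _ in range(attempts_per_compound):
            n_units = int(rng.integers(config.min_units, config.max_units + 1))
            parts = [config.units[j] for j in rng.integers(0, len(config.units), size=n_units)]
            for motif in motifs:
                if rng.random() < motif_probability:
                    parts.insert(int(rng.integers(0, len(parts) + 1)), motif)
            smiles = "".join(parts)
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                continue
            canonical = Chem.MolToSmiles(mol)
            key = structure_key(canonical)
            if key in taken:
                continue
            taken.add(key)
            cid = f"PRED_{i:04d}"
            records.append(
                CompoundRecord(
                    id=cid,
                    name=cid,
                    smiles_raw=smiles,
                    smiles_canonical=canonical,
                    structure_key=key,
                    source_tag="synthetic-prediction",
                )
            )
            break
        else:
            raise GeneratorError("could not assemble a unique prediction compound")
    return records
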