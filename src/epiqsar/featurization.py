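"""Descriptor sets and the pluggable featurization provider layer.

Six descriptor sets drive the benchmarking grid: five binary fingerprint
families (E-state, MACCS, PubChem-style hashed circular, graph-topology
path, and Klekota–Roth-style substructure keys) plus a real-valued block of
1D/2D whole-molecule descriptors.  The exact bit definitions are provider
semantics, not part of the modeling contract, so each provider records its
name, version, and matrix width in the provenance of every matrix it emits.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
import json

import numpy as np
import pandas as pd
import rdkit
from rdkit import Chem
from rdkit.Chem import Descriptors, MACCSkeys, rdFingerprintGenerator
from rdkit.Chem.EState import Fingerprinter as EStateFingerprinter


class DescriptorSet(str, Enum):
    """The six descriptor sets of the benchmarking grid."""

    ESTATE_FP = "ESTATE_FP"
    MACCS_FP = "MACCS_FP"
    PUBCHEM_FP = "PUBCHEM_FP"
    GRAPH_FP = "GRAPH_FP"
    KLEKOTA_ROTH_FP = "KLEKOTA_ROTH_FP"
    DESC_1D2D = "DESC_1D2D"

    @property
    def is_binary(self) -> bool:
        return self is not DescriptorSet.DESC_1D2D


class ProviderError(ValueError):
    """Raised when a featurization provider is missing or unsupported."""


class DegenerateFeaturesError(ValueError):
    """Raised when feature cleaning removes every column."""


@dataclass
class FeatureMatrix:
    """Compounds x descriptors for one descriptor set.

    ``values`` is a dense float array with one row per compound in library
    order; binary sets contain only 0.0/1.0.
    """

    compound_ids: list[str]
    descriptor_set: DescriptorSet
    column_names: list[str]
    values: np.ndarray
    provenance: dict

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.compound_ids),
            len(self.column_names),
        ):
            raise ValueError("feature matrix shape does not match ids/columns")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.compound_ids, columns=self.column_names)

    def write_csv(self, path: str | Path) -> None:
        """Persist as CSV (ids in the first column) with a sidecar provenance JSON."""
        path = Path(path)
        frame = self.to_frame()
        frame.index.name = "id"
        frame.to_csv(path)
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        sidecar.write_text(
            json.dumps({"descriptor_set": self.descriptor_set.value, **self.provenance}, indent=1)
        )


# Substructure keys for the Klekota-Roth-style set: functional groups and
# small motifs recurrent in bioactive molecules, expressed as SMARTS.
_KR_SMARTS = [
    ("amide", "C(=O)N"),
    ("carboxylic_acid", "C(=O)[OX2H1]"),
    ("ester", "C(=O)O[#6]"),
    ("ketone", "[#6]C(=O)[#6]"),
    ("aldehyde", "[CX3H1]=O"),
    ("carbonyl", "C=O"),
    ("hydroxyl", "[OX2H]"),
    ("phenol", "c[OX2H]"),
    ("ether", "[#6][OX2][#6]"),
    ("primary_amine", "[NX3H2]"),
    ("secondary_amine", "[NX3H1]([#6])[#6]"),
    ("tertiary_amine", "[NX3]([#6])([#6])[#6]"),
    ("c_n_single", "C[NX3]"),
    ("nitrile", "C#N"),
    ("nitro", "[N+](=O)[O-]"),
    ("imine", "C=N"),
    ("guanidine", "NC(=N)N"),
    ("urea", "NC(=O)N"),
    ("carbamate", "NC(=O)O"),
    ("sulfide", "[#6]S[#6]"),
    ("thiol", "[SX2H]"),
    ("sulfoxide", "S(=O)"),
    ("sulfone", "S(=O)(=O)"),
    ("sulfonamide", "S(=O)(=O)N"),
    ("thiocarbonyl", "C=S"),
    ("isothiocyanate", "N=C=S"),
    ("halogen_f", "[F]"),
    ("halogen_cl", "[Cl]"),
    ("halogen_br", "[Br]"),
    ("halogen_i", "[I]"),
    ("benzene", "c1ccccc1"),
    ("arene_any", "a1aaaaa1"),
    ("pyridine", "n1ccccc1"),
    ("five_ring_arom", "a1aaaa1"),
    ("furan", "o1cccc1"),
    ("thiophene", "s1cccc1"),
    ("pyrrole", "[nH]1cccc1"),
    ("cyclohexane", "C1CCCCC1"),
    ("cyclopentane", "C1CCCC1"),
    ("ring_sulfur_sat", "[#16;R]"),
    ("ring_oxygen_sat", "[#8;R]"),
    ("ring_nitrogen_sat", "[#7;R]"),
    ("alkene", "C=C"),
    ("conjugated_diene", "C=CC=C"),
    ("alkyne", "C#C"),
    ("allylic_chain", "C=CC"),
    ("styrene_like", "cC=C"),
    ("methyl", "[CH3]"),
    ("gem_dimethyl", "C(C)(C)"),
    ("tert_butyl", "C(C)(C)C"),
    ("isopropyl", "[CH](C)C"),
    ("ethyl_chain", "CC"),
    ("propyl_chain", "CCC"),
    ("butyl_chain", "CCCC"),
    ("pentyl_chain", "CCCCC"),
    ("hexyl_ether", "OCCCCCC"),
    ("alkoxy_ethyl", "OCC"),
    ("glycol_ether", "OCCO"),
    ("acetal", "OC(O)"),
    ("alpha_branch_acyl", "CC(CCC=O)"),
    ("acyl_chain", "CCC=O"),
    ("hydroxy_gem_dimethyl", "C(C)(C)O"),
    ("benzyl", "cC"),
    ("aniline_like", "cN"),
    ("aryl_ether", "cO[#6]"),
    ("aryl_carbonyl", "cC=O"),
    ("aryl_halide", "c[F,Cl,Br,I]"),
    ("phosphate", "P(=O)(O)O"),
    ("quaternary_n", "[N+X4]"),
    ("hydroxylamine", "NO"),
    ("hydrazine", "NN"),
    ("azo", "N=N"),
    ("cyclohexyl_sulfur", "C1CCCCC1S"),
    ("thioether_ring", "S1CCCC1"),
    ("lactone", "O=C1OCCC1"),
    ("lactam", "O=C1NCCC1"),
    ("enol_ether", "C=CO"),
    ("vinyl_amine", "C=CN"),
    ("amidine", "NC=N"),
    ("aromatic_n2_ring", "a1aana1"),
    ("biphenyl", "c1ccccc1-c1ccccc1"),
    ("fused_arene", "c1ccc2ccccc2c1"),
    ("trifluoromethyl", "C(F)(F)F"),
    ("dichloro_carbon", "C(Cl)Cl"),
    ("long_chain8", "CCCCCCCC"),
    ("ester_of_aryl", "cC(=O)O"),
    ("amide_of_aryl", "cC(=O)N"),
    ("n_acyl", "NC=O"),
    ("o_acyl", "OC=O"),
    ("beta_keto", "C(=O)CC=O"),
    ("michael_acceptor", "C=CC=O"),
]


class RDKitProvider:
    """Toolkit-native featurization backend built on RDKit."""

    name = "rdkit"

    def __init__(self) -> None:
        self.version = rdkit.__version__
        self._morgan = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=881)
        self._kr_queries = [
            (label, Chem.MolFromSmarts(smarts)) for label, smarts in _KR_SMARTS
        ]
        assert all(query is not None for _, query in self._kr_queries)
        self._desc_names = [name for name, _ in Descriptors.descList]

    def supports(self, descriptor_set: DescriptorSet) -> bool:
        return True

    def column_names(self, descriptor_set: DescriptorSet) -> list[str]:
        if descriptor_set is DescriptorSet.ESTATE_FP:
            return [f"EStateFP{i}" for i in range(79)]
        if descriptor_set is DescriptorSet.MACCS_FP:
            return [f"MACCSFP{i}" for i in range(167)]
        if descriptor_set is DescriptorSet.PUBCHEM_FP:
            return [f"SubFP{i}" for i in range(881)]
        if descriptor_set is DescriptorSet.GRAPH_FP:
            return [f"GraphFP{i}" for i in range(2048)]
        if descriptor_set is DescriptorSet.KLEKOTA_ROTH_FP:
            return [f"KRFP_{label}" for label, _ in self._kr_queries]
        return list(self._desc_names)

    def compute_row(self, mol: Chem.Mol, descriptor_set: DescriptorSet) -> np.ndarray:
        if descriptor_set is DescriptorSet.ESTATE_FP:
            counts, _ = EStateFingerprinter.FingerprintMol(mol)
            return (np.asarray(counts) > 0).astype(float)
        if descriptor_set is DescriptorSet.MACCS_FP:
            return np.array(MACCSkeys.GenMACCSKeys(mol), dtype=float)
        if descriptor_set is DescriptorSet.PUBCHEM_FP:
            return np.array(self._morgan.GetFingerprint(mol), dtype=float)
        if descriptor_set is DescriptorSet.GRAPH_FP:
            # bond orders ignored: captures the molecular graph topology only
            fp = Chem.RDKFingerprint(mol, useBondOrder=False, fpSize=2048)
            return np.array(fp, dtype=float)
        if descriptor_set is DescriptorSet.KLEKOTA_ROTH_FP:
            return np.array(
                [float(mol.HasSubstructMatch(query)) for _, query in self._kr_queries]
            )
        row = np.array(
            [_safe_descriptor(fn, mol) for _, fn in Descriptors.descList], dtype=float
        )
        return row


def _safe_descriptor(fn, mol) -> float:
    try:
        value = float(fn(mol))
    except (ValueError, ZeroDivisionError, OverflowError):
        return float("nan")
    if not np.isfinite(value):
        return float("nan")
    return value


_PROVIDERS: dict[str, object] = {}


def get_provider(name: str = "rdkit"):
    if name not in _PROVIDERS:
        if name == "rdkit":
            _PROVIDERS[name] = RDKitProvider()
        else:
            raise ProviderError(
                f"no featurization provider {name!r}; available: ['rdkit']"
            )
    return _PROVIDERS[name]


def register_provider(name: str, provider) -> None:
    """Register an alternative descriptor backend (e.g., an external calculator)."""
    _PROVIDERS[name] = provider


def featurize(library, descriptor_set: DescriptorSet, provider: str = "rdkit") -> FeatureMatrix:
    """Compute one descriptor set for a curated library.

    ``library`` is a list of curated compound records (``smiles_canonical``
    attribute) or plain SMILES strings.  Row order follows library order and
    repeated featurization of the same input is byte-identical for a fixed
    provider version.
    """
    descriptor_set = DescriptorSet(descriptor_set)
    backend = get_provider(provider)
    if not backend.supports(descriptor_set):
        raise ProviderError(
            f"provider {provider!r} does not support {descriptor_set.value}"
        )
    ids, smiles = [], []
    for i, item in enumerate(library):
        if hasattr(item, "smiles_canonical"):
            ids.append(item.id)
            smiles.append(item.smiles_canonical)
        else:
            ids.append(str(i))
            smiles.append(str(item))
    columns = backend.column_names(descriptor_set)
    rows = np.empty((len(smiles), len(columns)), dtype=float)
    for i, smi in enumerate(smiles):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:  # curation guarantees parseability
            raise RuntimeError(f"internal error: unparseable curated SMILES {smi!r}")
        rows[i] = backend.compute_row(mol, descriptor_set)
    return FeatureMatrix(
        compound_ids=ids,
        descriptor_set=descriptor_set,
        column_names=columns,
        values=rows,
        provenance={
            "provider": backend.name,
            "provider_version": backend.version,
            "n_columns": len(columns),
        },
    )


def clean_features(matrix: FeatureMatrix) -> tuple[FeatureMatrix, list[str]]:
    """Drop constant columns and columns containing missing values.

    Column order is otherwise preserved.  Raises if nothing survives.
    """
    values = matrix.values
    with np.errstate(invalid="ignore"):
        has_nan = np.isnan(values).any(axis=0)
        constant = np.all(values == values[0:1, :], axis=0) if len(values) else np.zeros(
            values.shape[1], dtype=bool
        )
    drop = has_nan | constant
    if drop.all() and values.shape[1] > 0:
        raise DegenerateFeaturesError("feature cleaning removed every column")
    kept_idx = np.flatnonzero(~drop)
    dropped = [matrix.column_names[j] for j in np.flatnonzero(drop)]
    cleaned = FeatureMatrix(
        compound_ids=list(matrix.compound_ids),
        descriptor_set=matrix.descriptor_set,
        column_names=[matrix.column_names[j] for j in kept_idx],
        values=values[:, kept_idx],
        provenance={**matrix.provenance, "dropped_columns": len(dropped)},
    )
    return cleaned, dropped


class FeatureCleaner:
    """Leakage-free train/test feature cleaning.

    Fitted on training rows only: records which columns are constant or carry
    missing values there, then removes the same columns from any matrix it
    transforms (test folds, prediction libraries).
    """

    def __init__(self) -> None:
        self.keep_idx_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "FeatureCleaner":
        X = np.asarray(X, dtype=float)
        with np.errstate(invalid="ignore"):
            has_nan = np.isnan(X).any(axis=0)
            constant = np.all(X == X[0:1, :], axis=0)
        keep = ~(has_nan | constant)
        if not keep.any():
            raise DegenerateFeaturesError("all training columns constant or missing")
        self.keep_idx_ = np.flatnonzero(keep)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.keep_idx_ is None:
            raise RuntimeError("FeatureCleaner used before fit")
        X = np.asarray(X, dtype=float)
        out = X[:, self.keep_idx_]
        # residual missing values in non-training rows are zero-filled
        return np.nan_to_num(out, nan=0.0, posinf=0.0, neginf=0.0)
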