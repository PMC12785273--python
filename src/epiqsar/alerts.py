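"""Structural-alert mining from SMILES fragments.

Molecules are broken recursively at every acyclic, non-directional single
bond (rings stay intact) and every connected fragment within the atom
bounds is collected.  Fragments are scored against a binary-labeled library
with a smoothed likelihood ratio (match rate among actives over match rate
among inactives, Haldane–Anscombe +0.5 correction) and an information gain
filter, then selected greedily with coverage-based redundancy removal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from rdkit import Chem


class FragmentationError(ValueError):
    pass


@dataclass(frozen=True)
class Fragment:
    """A connected substructure pattern (canonical SMILES, usable as a query)."""

    pattern: str
    heavy_atoms: int


@dataclass(frozen=True)
class AlertRule:
    fragment: Fragment
    a: int  # actives matched
    b: int  # inactives matched
    P: int  # total actives
    N: int  # total inactives
    LR: float
    IG: float


@dataclass
class AlertSet:
    rules: list[AlertRule]  # in selection order
    coverage: float  # fraction of actives matched by >= 1 selected rule

    def __len__(self) -> int:
        return len(self.rules)


def _breakable_bonds(mol: Chem.Mol) -> list[int]:
    bonds = []
    for bond in mol.GetBonds():
        if (
            bond.GetBondType() == Chem.BondType.SINGLE
            and not bond.IsInRing()
            and bond.GetBondDir() == Chem.BondDir.NONE
            and bond.GetStereo() == Chem.BondStereo.STEREONONE
        ):
            bonds.append(bond.GetIdx())
    return bonds


def enumerate_fragments(
    smiles: str, min_atoms: int = 2, max_atoms: int = 18, cap: int = 5000
) -> set[Fragment]:
    """All connected fragments reachable by breaking acyclic single bonds.

    Includes the intact molecule when it fits the atom bounds.  Fragments
    are canonicalized and deduplicated; exceeding ``cap`` distinct patterns
    for one molecule raises, advising tighter bounds.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FragmentationError(f"invalid SMILES {smiles!r}")
    collected: dict[str, int] = {}
    seen: set[str] = set()
    stack = [mol]
    seen.add(Chem.MolToSmiles(mol))
    while stack:
        current = stack.pop()
        n_heavy = current.GetNumHeavyAtoms()
        if min_atoms <= n_heavy <= max_atoms:
            collected[Chem.MolToSmiles(current)] = n_heavy
            if len(collected) > cap:
                raise FragmentationError(
                    f"fragment cap {cap} exceeded for {smiles!r}; tighten the atom bounds"
                )
        if n_heavy <= min_atoms:  # nothing smaller can qualify
            continue
        for bond_idx in _breakable_bonds(current):
            try:
                pieces = Chem.GetMolFrags(
                    Chem.FragmentOnBonds(current, [bond_idx], addDummies=False),
                    asMols=True,
                    sanitizeFrags=True,
                )
            except Exception:
                continue
            for piece in pieces:
                key = Chem.MolToSmiles(piece)
                if key not in seen:
                    seen.add(key)
                    stack.append(piece)
    return {Fragment(pattern=p, heavy_atoms=h) for p, h in collected.items()}


def _entropy_bits(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _match_vector(pattern: str, mols: list[Chem.Mol]) -> np.ndarray:
    query = Chem.MolFromSmiles(pattern)
    if query is None:
        query = Chem.MolFromSmarts(pattern)
    if query is None:
        raise FragmentationError(f"pattern {pattern!r} does not parse as a query")
    return np.array([mol.HasSubstructMatch(query) for mol in mols], dtype=bool)


def _library_mols(library) -> list[Chem.Mol]:
    mols = []
    for item in library:
        smi = item.smiles_canonical if hasattr(item, "smiles_canonical") else str(item)
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise FragmentationError(f"invalid library SMILES {smi!r}")
        mols.append(mol)
    return mols


def _score(fragment: Fragment, matches: np.ndarray, y: np.ndarray) -> AlertRule:
    P = int((y == 1).sum())
    N = int((y == 0).sum())
    a = int(matches[y == 1].sum())
    b = int(matches[y == 0].sum())
    lr = ((a + 0.5) / (P + 1)) / ((b + 0.5) / (N + 1))
    h_prior = _entropy_bits(np.array([P, N], dtype=float))
    n = P + N
    h_cond = 0.0
    for mask in (matches, ~matches):
        weight = mask.sum() / n
        if weight > 0:
            h_cond += weight * _entropy_bits(
                np.array([(y[mask] == 1).sum(), (y[mask] == 0).sum()], dtype=float)
            )
    return AlertRule(fragment=fragment, a=a, b=b, P=P, N=N, LR=float(lr), IG=float(h_prior - h_cond))


def score_fragment(fragment: Fragment | str, library, labels) -> AlertRule:
    """Score one fragment against a labeled library (labels: 1 = active)."""
    if isinstance(fragment, str):
        query = Chem.MolFromSmiles(fragment)
        if query is None:
            raise FragmentationError(f"invalid fragment SMILES {fragment!r}")
        fragment = Fragment(pattern=Chem.MolToSmiles(query), heavy_atoms=query.GetNumHeavyAtoms())
    mols = _library_mols(library)
    y = np.asarray(labels, dtype=int)
    if len(y) != len(mols):
        raise ValueError("labels length does not match library size")
    matches = _match_vector(fragment.pattern, mols)
    return _score(fragment, matches, y)


def mine_alerts(
    library,
    labels,
    min_support: int = 3,
    min_IG: float = 0.05,
    max_rules: int = 20,
    min_atoms: int = 2,
    max_atoms: int = 18,
) -> AlertSet:
    """Mine an ordered set of structural alerts for the active class.

    Fragments pooled over the whole library are scored (LR, IG) by true
    substructure matching; rules below ``min_support`` matched actives or
    below ``min_IG`` are dropped.  Selection is greedy by descending LR
    (ties: higher IG, fewer heavy atoms, lexicographic pattern); the actives
    matched by a selected rule no longer count toward the support of later
    rules, which removes redundant sub/super-structure variants.

    Candidate fragments are pre-screened by how many library molecules'
    own fragment pools contain them (cheap containment screen before the
    substructure matching pass).
    """
    library = list(library)
    if not library:
        return AlertSet(rules=[], coverage=0.0)
    mols = _library_mols(library)
    y = np.asarray(labels, dtype=int)
    if len(y) != len(mols):
        raise ValueError("labels length does not match library size")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to mine alerts")

    pool_count: dict[Fragment, int] = {}
    for mol in mols:
        for fragment in enumerate_fragments(
            Chem.MolToSmiles(mol), min_atoms=min_atoms, max_atoms=max_atoms
        ):
            pool_count[fragment] = pool_count.get(fragment, 0) + 1
    candidates = [f for f, c in pool_count.items() if c >= min_support]

    scored: list[tuple[AlertRule, np.ndarray]] = []
    for fragment in candidates:
        matches = _match_vector(fragment.pattern, mols)
        rule = _score(fragment, matches, y)
        if rule.a >= min_support and rule.IG >= min_IG:
            scored.append((rule, matches))
    scored.sort(
        key=lambda rm: (
            -rm[0].LR,
            -rm[0].IG,
            rm[0].fragment.heavy_atoms,
            rm[0].fragment.pattern,
        )
    )

    active_idx = np.flatnonzero(y == 1)
    uncovered = set(active_idx.tolist())
    selected: list[AlertRule] = []
    covered_any = np.zeros(len(mols), dtype=bool)
    for rule, matches in scored:
        if len(selected) >= max_rules:
            break
        support_remaining = sum(1 for i in active_idx if i in uncovered and matches[i])
        if support_remaining < min_support:
            continue
        selected.append(rule)
        covered_any |= matches
        uncovered -= set(np.flatnonzero(matches).tolist())
    n_actives = len(active_idx)
    coverage = (
        float(covered_any[active_idx].sum() / n_actives) if n_actives else 0.0
    )
    return AlertSet(rules=selected, coverage=coverage)


def permutation_importance(
    model,
    features: np.ndarray,
    labels: np.ndarray,
    metric: str = "ACC",
    repeats: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Mean accuracy drop per feature column under independent shuffling.

    ``model`` exposes ``predict_label`` (package classifiers) or ``predict``
    (bare scikit-learn estimators).  A column that never changes under
    permutation (constant) has importance exactly 0.
    """
    if metric != "ACC":
        raise ValueError("only the accuracy metric is supported")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    predict = getattr(model, "predict_label", None) or model.predict
    baseline = float((np.asarray(predict(X)) == y).mean())
    rng = np.random.default_rng(seed)
    importances = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        drops = []
        for _ in range(repeats):
            X_perm = X.copy()
            X_perm[:, j] = X_perm[rng.permutation(len(X)), j]
            acc = float((np.asarray(predict(X_perm)) == y).mean())
            drops.append(baseline - acc)
        importances[j] = np.mean(drops)
    return importances
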