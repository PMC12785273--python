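"""Directional mitigation scoring and compound prioritization.

A predicted label only "mitigates" if it points in the module's favorable
direction: down (label 0) for miR-34a, DNMT3a and HDAC; up (label 1) for
miR-125b and miR-135a.  Each compound gets one binary indicator per module
and an equal-weight rank score — the mean of its five indicators — used to
order the library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from epiqsar.datasets import RegulatorModule

MODULES = tuple(RegulatorModule)
_MIR_MODULES = (RegulatorModule.MIR34A, RegulatorModule.MIR125B, RegulatorModule.MIR135A)


@dataclass(frozen=True)
class ModulePrediction:
    compound_id: str
    module: RegulatorModule
    predicted_label: int
    score: float = float("nan")
    in_domain: bool = True


@dataclass
class MitigationProfile:
    compound_id: str
    indicators: dict[RegulatorModule, int]
    rank_score: float
    out_of_domain: frozenset = field(default_factory=frozenset)


def mitigation_indicator(module: RegulatorModule, predicted_label: int) -> int:
    """1 iff the predicted label is the module's favorable direction."""
    if predicted_label not in (0, 1):
        raise ValueError(f"predicted_label must be 0 or 1, got {predicted_label!r}")
    return int(predicted_label == RegulatorModule(module).favorable_label)


def rank_score(indicators: dict[RegulatorModule, int]) -> float:
    """Equal-weight mean of the five module indicators (multiples of 0.2)."""
    missing = [m.value for m in MODULES if m not in indicators]
    if missing:
        raise ValueError(f"missing module indicator(s): {', '.join(missing)}")
    return sum(indicators[m] for m in MODULES) / len(MODULES)


def build_profile(predictions: list[ModulePrediction]) -> MitigationProfile:
    """Fold one compound's five module predictions into a profile.

    Out-of-domain predictions contribute indicator 0 and are flagged, so an
    unreliable module can never raise a compound's rank.
    """
    ids = {p.compound_id for p in predictions}
    if len(ids) != 1:
        raise ValueError(f"predictions span multiple compounds: {sorted(ids)}")
    indicators: dict[RegulatorModule, int] = {}
    out_of_domain = set()
    for p in predictions:
        if p.module in indicators:
            raise ValueError(f"duplicate prediction for module {p.module.value}")
        if p.in_domain:
            indicators[p.module] = mitigation_indicator(p.module, p.predicted_label)
        else:
            indicators[p.module] = 0
            out_of_domain.add(p.module)
    return MitigationProfile(
        compound_id=ids.pop(),
        indicators=indicators,
        rank_score=rank_score(indicators),
        out_of_domain=frozenset(out_of_domain),
    )


@dataclass
class RankTable:
    profiles: list[MitigationProfile]  # descending rank_score, ties by id

    def __len__(self) -> int:
        return len(self.profiles)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.profiles:
            row = {"id": p.compound_id, "rank_score": p.rank_score}
            for m in MODULES:
                row[f"indicator_{m.value}"] = p.indicators[m]
            for m in MODULES:
                row[f"in_domain_{m.value}"] = int(m not in p.out_of_domain)
            rows.append(row)
        return pd.DataFrame(rows)


def rank_library(predictions: list[ModulePrediction]) -> RankTable:
    """Rank a library from its complete 5-module prediction matrix.

    Sorted by descending rank score; ties broken alphabetically by compound
    id (stable and deterministic).
    """
    by_compound: dict[str, list[ModulePrediction]] = {}
    for p in predictions:
        by_compound.setdefault(p.compound_id, []).append(p)
    incomplete = {
        cid: sorted({m.value for m in MODULES} - {p.module.value for p in preds})
        for cid, preds in by_compound.items()
        if len(preds) != len(MODULES)
    }
    if incomplete:
        cid, missing = next(iter(incomplete.items()))
        raise ValueError(f"compound {cid!r} lacks predictions for: {', '.join(missing)}")
    profiles = [build_profile(preds) for preds in by_compound.values()]
    profiles.sort(key=lambda p: (-p.rank_score, p.compound_id))
    return RankTable(profiles=profiles)


def _round2(value: float) -> float:
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summarize_module_coverage(rank_table: RankTable) -> dict[str, float]:
    """Percentage of the library flagged favorable per module, plus the
    microRNA umbrella (favorable for at least one of miR-34a/miR-125b/miR-135a;
    compounds hitting several miR modules are counted once)."""
    if not rank_table.profiles:
        raise ValueError("empty rank table")
    n = len(rank_table.profiles)
    coverage = {}
    for m in MODULES:
        hits = sum(p.indicators[m] for p in rank_table.profiles)
        coverage[m.value] = _round2(100.0 * hits / n)
    mir_hits = sum(
        1
        for p in rank_table.profiles
        if any(p.indicators[m] for m in _MIR_MODULES)
    )
    coverage["microRNA"] = _round2(100.0 * mir_hits / n)
    return coverage
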