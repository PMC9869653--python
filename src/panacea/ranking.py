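"""Tie-aware top-n selection and clinical drug-tier evaluation.

Selected drug lists are evaluated against a 10-level clinical-support
taxonomy supplied as a local table:

    1A approved for the cancer type under study, 1B approved for other
    cancer types, 2A/2B in clinical trial(s) (this type / other types),
    3A/3B curated in CTD (this type / other types), 4A/4B inferred in CTD,
    5 repurposed for cancer, 6 no support.

"Supported" drugs are those in Tiers 1–5; "indicated for the cancer type"
means Tiers 1A, 2A, 3A or 4A. Drugs absent from the table default to
Tier 6; merged drugs take the best (most clinically advanced) tier among
their members.

Top-n selection is tie-inclusive: the set of top n drugs additionally
contains every drug tying the n-th score, e.g. if the sixth and seventh
drugs' scores equal the fifth one, they are included in the Top 5. Score
ties use exact floating equality — the distance method genuinely produces
exact ties for drugs with identical distance/driverness patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .distance import DrugScoreVector

TIER_LABELS: tuple[str, ...] = (
    "1A", "1B", "2A", "2B", "3A", "3B", "4A", "4B", "5", "6")
SUPPORTED_TIERS = frozenset(TIER_LABELS[:-1])            # Tiers 1–5
APPROVED_OR_TRIAL_TIERS = frozenset(("1A", "1B", "2A", "2B"))  # Tiers 1–2
INDICATED_TIERS = frozenset(("1A", "2A", "3A", "4A"))
DEFAULT_TIER = "6"

_TIER_ORDER = {t: i for i, t in enumerate(TIER_LABELS)}


@dataclass
class TierTable:
    """Drug → tier lookup with merged-drug resolution.

    ``merge_ledger`` (merged name → original member names, as produced by
    :func:`panacea.network_io.merge_equivalent_drugs`) lets a merged drug
    like ``"D1/D2"`` resolve to the best tier among its members; a merged
    node represents any of its member drugs being prescribable.
    """

    tiers: dict[str, str]
    merge_ledger: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {t for t in self.tiers.values() if t not in _TIER_ORDER}
        if bad:
            raise ValueError(f"unknown tier labels {sorted(bad)}; "
                             f"expected one of {list(TIER_LABELS)}")

    @classmethod
    def from_tsv(cls, path, merge_ledger: dict[str, tuple[str, ...]] | None = None,
                 drug_column: str = "drug", tier_column: str = "tier") -> "TierTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        tiers = {
            str(d).strip(): str(t).strip().upper()
            for d, t in zip(df[drug_column], df[tier_column])
        }
        return cls(tiers=tiers, merge_ledger=dict(merge_ledger or {}))

    def tier_of(self, drug: str) -> str:
        """Tier for one (possibly merged) drug; unknown drugs are Tier 6."""
        members = self.merge_ledger.get(drug)
        if members is None and "/" in drug and drug not in self.tiers:
            members = tuple(drug.split("/"))
        if members:
            return min(
                (self.tiers.get(m, DEFAULT_TIER) for m in members),
                key=_TIER_ORDER.__getitem__,
            )
        return self.tiers.get(drug, DEFAULT_TIER)


@dataclass
class TierSummary:
    """Per-tier proportions of a selected drug set, plus headline rollups."""

    proportions: dict[str, float]
    supported: float           # Tiers 1–5
    approved_or_trial: float   # Tiers 1–2
    indicated_for_type: float  # Tiers 1A, 2A, 3A, 4A
    n_drugs: int

    def to_frame(self) -> pd.DataFrame:
        rows = [{"tier": t, "proportion": self.proportions[t]}
                for t in TIER_LABELS]
        return pd.DataFrame(rows)


def top_n_with_ties(scores: DrugScoreVector | Mapping[str, float],
                    n: int) -> list[str]:
    """Top n drugs by descending score, plus every drug tying the n-th score.

    Within the returned list drugs are ordered by descending score with a
    lexicographic name tie-break. If fewer than n drugs exist, all are
    returned.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    mapping = scores.scores if isinstance(scores, DrugScoreVector) else dict(scores)
    ordered = sorted(mapping.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ordered) <= n:
        return [d for d, _ in ordered]
    cutoff = ordered[n - 1][1]
    return [d for d, s in ordered if s >= cutoff]


def annotate_tiers(selected: Sequence[str],
                   tiers: TierTable) -> list[tuple[str, str]]:
    """Attach a tier to every selected drug (missing → Tier 6)."""
    return [(drug, tiers.tier_of(drug)) for drug in selected]


def tier_proportions(annotated: Sequence[tuple[str, str]]) -> TierSummary:
    """Proportion of a selected drug set falling in each tier.

    Raises ``ValueError`` on an empty selection (proportions are undefined).
    """
    if not annotated:
        raise ValueError("cannot summarize an empty drug selection")
    n = len(annotated)
    counts = {t: 0 for t in TIER_LABELS}
    for drug, tier in annotated:
        if tier not in counts:
            raise ValueError(f"unknown tier {tier!r} for drug {drug!r}")
        counts[tier] += 1
    props = {t: c / n for t, c in counts.items()}
    supported = sum(props[t] for t in TIER_LABELS if t in SUPPORTED_TIERS)
    return TierSummary(
        proportions=props,
        supported=supported,
        approved_or_trial=sum(props[t] for t in APPROVED_OR_TRIAL_TIERS),
        indicated_for_type=sum(props[t] for t in INDICATED_TIERS),
        n_drugs=n,
    )
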