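"""Credible-causal-variant (CCV) selection from GWAS summary statistics.

Per risk signal the CCV set is the inclusive union of three routes:

* a likelihood-ratio filter against the lead variant (ratio >= 1/100,
  asymptotic approximation ``exp((z_i^2 - z_lead^2) / 2)``),
* LD expansion around the lead (r^2 strictly > 0.8), used alone for
  secondary signals and for variants absent from the summary data,
* externally supplied Bayesian credible-set membership.

Source flags are tracked per variant so set bookkeeping follows
inclusion-exclusion exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

SOURCE_LLR = "LLR"
SOURCE_LD = "LD"
SOURCE_BAYES = "BAYES"

#: VEP consequence strings treated as protein-altering.
PROTEIN_ALTERING = frozenset({"missense_variant", "frameshift_variant"})


@dataclass(frozen=True)
class SummaryStatRecord:
    variant_id: str
    chrom: str
    pos: int  # 1-based
    beta: float
    se: float
    p: float

    @property
    def z(self) -> float:
        return self.beta / self.se

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.variant_id}: se must be > 0")
        if not (0 < self.p <= 1):
            raise ValueError(f"{self.variant_id}: p must be in (0,1]")


@dataclass(frozen=True)
class RiskSignal:
    signal_id: int
    locus_id: int
    lead_variant_id: str
    is_secondary: bool = False


@dataclass
class CredibleVariant:
    variant_id: str
    signal_id: int
    sources: set[str] = field(default_factory=set)
    lr_vs_lead: Optional[float] = None
    r2_to_lead: Optional[float] = None


class LdTable:
    """Symmetric r^2 lookup keyed by variant-id pairs."""

    def __init__(self, pairs: Iterable[tuple[str, str, float]]):
        self._r2: dict[frozenset[str], float] = {}
        self._ids: set[str] = set()
        for a, b, r2 in pairs:
            if not (0.0 <= r2 <= 1.0):
                raise ValueError(f"r2 out of [0,1]: {a},{b}={r2}")
            self._ids.update((a, b))
            if a != b:
                self._r2[frozenset((a, b))] = r2

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LdTable":
        return cls(
            (str(r.id_a), str(r.id_b), float(r.r2)) for r in df.itertuples()
        )

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)), 0.0)

    def __contains__(self, vid: str) -> bool:
        return vid in self._ids

    def partners(self, vid: str) -> set[str]:
        return {
            next(iter(key - {vid}))
            for key in self._r2
            if vid in key and len(key - {vid}) == 1
        }


def likelihood_ratio_vs_lead(z_i: float, z_lead: float) -> float:
    """Likelihood ratio of variant i versus the lead, from Z-scores."""
    if not (math.isfinite(z_i) and math.isfinite(z_lead)):
        raise ValueError("Z-scores must be finite")
    return math.exp((z_i * z_i - z_lead * z_lead) / 2.0)


def select_llr_set(
    records: Sequence[SummaryStatRecord],
    lead: str,
    threshold: float = 0.01,
) -> set[str]:
    """Variants whose likelihood ratio against the lead is >= threshold.

    Inclusive boundary; the lead is always a member.
    """
    if not records:
        raise ValueError("no summary-statistic records supplied")
    by_id = {r.variant_id: r for r in records}
    if lead not in by_id:
        raise KeyError(f"lead variant {lead} absent from summary statistics")
    z_lead = by_id[lead].z
    kept = {
        r.variant_id
        for r in records
        if likelihood_ratio_vs_lead(r.z, z_lead) >= threshold
    }
    kept.add(lead)
    return kept


def ld_expand(
    lead: str,
    ld: LdTable,
    r2_threshold: float = 0.8,
    restrict_to: Optional[set[str]] = None,
) -> set[str]:
    """Lead plus every variant with r^2 strictly above ``r2_threshold``."""
    if lead not in ld:
        raise KeyError(f"lead variant {lead} absent from LD table")
    out = {
        v
        for v in ld.partners(lead)
        if ld.r2(lead, v) > r2_threshold
        and (restrict_to is None or v in restrict_to)
    }
    out.add(lead)
    return out


def union_credible(
    signal_id: int,
    llr_set: set[str],
    ld_set: set[str],
    bayes_set: set[str],
    records_by_id: Optional[Mapping[str, SummaryStatRecord]] = None,
    lead: Optional[str] = None,
    ld: Optional[LdTable] = None,
) -> list[CredibleVariant]:
    """Union of the three routes with per-variant source flags.

    Cardinality obeys inclusion-exclusion by construction. When summary
    stats / LD context is supplied, lr_vs_lead and r2_to_lead are filled in.
    """
    z_lead = None
    if records_by_id is not None and lead is not None and lead in records_by_id:
        z_lead = records_by_id[lead].z
    out: dict[str, CredibleVariant] = {}
    for vid in sorted(llr_set | ld_set | bayes_set):
        cv = CredibleVariant(variant_id=vid, signal_id=signal_id)
        if vid in llr_set:
            cv.sources.add(SOURCE_LLR)
        if vid in ld_set:
            cv.sources.add(SOURCE_LD)
        if vid in bayes_set:
            cv.sources.add(SOURCE_BAYES)
        if z_lead is not None and records_by_id is not None and vid in records_by_id:
            cv.lr_vs_lead = min(
                1.0, likelihood_ratio_vs_lead(records_by_id[vid].z, z_lead)
            )
        if ld is not None and lead is not None and vid in ld:
            cv.r2_to_lead = ld.r2(lead, vid)
        out[vid] = cv
    return list(out.values())


def classify_protein_altering(
    consequence_table: Mapping[str, str],
) -> set[str]:
    """Variants whose comma-separated consequence string contains a
    protein-altering term. Missing variants count as non-altering."""
    out = set()
    for vid, cons in consequence_table.items():
        terms = {t.strip() for t in str(cons).split(",")}
        if terms & PROTEIN_ALTERING:
            out.add(vid)
    return out


def finemap_signal(
    signal: RiskSignal,
    records: Sequence[SummaryStatRecord],
    ld: Optional[LdTable],
    bayes_members: Optional[set[str]] = None,
    llr_threshold: float = 0.01,
    r2_threshold: float = 0.8,
    not_genotyped: Optional[set[str]] = None,
) -> list[CredibleVariant]:
    """Full per-signal CCV selection.

    Primary signals: LLR filter, plus LD expansion restricted to variants
    absent from the summary data (``not_genotyped``). Secondary signals:
    LD expansion only. Bayesian membership unions in regardless.
    """
    bayes_members = bayes_members or set()
    by_id = {r.variant_id: r for r in records}
    llr_set: set[str] = set()
    ld_set: set[str] = set()
    if signal.is_secondary:
        if ld is not None and signal.lead_variant_id in ld:
            ld_set = ld_expand(signal.lead_variant_id, ld, r2_threshold)
    else:
        if records:
            llr_set = select_llr_set(records, signal.lead_variant_id, llr_threshold)
        if ld is not None and signal.lead_variant_id in ld:
            restrict = not_genotyped
            if restrict is None:
                restrict = {v for v in ld.partners(signal.lead_variant_id) if v not in by_id}
            ld_set = ld_expand(
                signal.lead_variant_id, ld, r2_threshold, restrict_to=restrict
            )
    return union_credible(
        signal.signal_id,
        llr_set,
        ld_set,
        bayes_members,
        records_by_id=by_id,
        lead=signal.lead_variant_id,
        ld=ld,
    )


def ccvs_to_frame(ccvs: Sequence[CredibleVariant]) -> pd.DataFrame:
    rows = [
        {
            "variant_id": c.variant_id,
            "signal_id": c.signal_id,
            "sources": ",".join(sorted(c.sources)),
            "lr_vs_lead": c.lr_vs_lead,
            "r2_to_lead": c.r2_to_lead,
        }
        for c in ccvs
    ]
    return pd.DataFrame(
        rows, columns=["variant_id", "signal_id", "sources", "lr_vs_lead", "r2_to_lead"]
    )
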