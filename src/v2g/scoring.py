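"""Integrative 0-8 candidate-gene score and per-signal rankings.

An eQTL/TWAS-supported gene takes a base of 6 points (the chromatin ladder
and methylation points do not stack on it); otherwise the base is the
4-level nested chromatin ladder plus 2 for meQTL/MWAS support. Driver-list
membership adds 1 point each (melanoma, pan-cancer) for every gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .evidence import EvidenceRecord

EQTL_TWAS_POINTS = 6
MEQTL_MWAS_POINTS = 2
MAX_SCORE = 8


@dataclass(frozen=True)
class GeneScore:
    signal_id: int
    gene_id: str
    total: int
    components: dict

    def __post_init__(self) -> None:
        assert 0 <= self.total <= MAX_SCORE
        assert self.total == sum(self.components.values())


def score_gene(record: EvidenceRecord) -> GeneScore:
    """Score one evidence record; rejects ladder-nesting violations."""
    record.check_nesting()
    ladder = (
        int(record.linked)
        + int(record.var_regulatory)
        + int(record.var_mpra_sig)
        + int(record.var_marginal_eqtl)
    )
    if record.eqtl_or_twas:
        components = {
            "eqtl_twas": EQTL_TWAS_POINTS,
            "ladder": 0,
            "meqtl_mwas": 0,
        }
    else:
        components = {
            "eqtl_twas": 0,
            "ladder": ladder,
            "meqtl_mwas": MEQTL_MWAS_POINTS if record.meqtl_or_mwas else 0,
        }
    components["driver_melanoma"] = int(record.driver_melanoma)
    components["driver_pancancer"] = int(record.driver_pancancer)
    return GeneScore(
        signal_id=record.signal_id,
        gene_id=record.gene_id,
        total=sum(components.values()),
        components=components,
    )


def score_records(records: Sequence[EvidenceRecord]) -> list[GeneScore]:
    return [score_gene(r) for r in records]


def rank_genes(
    scores: Sequence[GeneScore], thresholds: Sequence[int] = (7, 6, 4)
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Rank genes per signal (score desc, ties by gene id) and count
    signals whose best gene reaches each threshold."""
    rows = [
        {
            "signal_id": s.signal_id,
            "gene_id": s.gene_id,
            "total": s.total,
            **{k: v for k, v in s.components.items()},
        }
        for s in scores
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "signal_id",
            "gene_id",
            "total",
            "eqtl_twas",
            "ladder",
            "meqtl_mwas",
            "driver_melanoma",
            "driver_pancancer",
        ],
    )
    if df.empty:
        return df, {f"signals_max_ge_{t}": 0 for t in thresholds}
    df = df.sort_values(
        ["signal_id", "total", "gene_id"], ascending=[True, False, True]
    ).reset_index(drop=True)
    df["rank"] = df.groupby("signal_id").cumcount() + 1
    per_signal_max = df.groupby("signal_id")["total"].max()
    counts = {
        f"signals_max_ge_{t}": int((per_signal_max >= t).sum()) for t in thresholds
    }
    return df, counts
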