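"""Promoter-region construction under three definitions and gene assignment.

Definitions: chromatin-state promoters per cell context (melanocyte or
melanoma state calls, merged across samples), and a global definition of
TSS +/- 2.5 kb over protein-coding transcripts. Promoter intervals are
held 1-based closed; BED input is converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from . import vocab

logger = logging.getLogger(__name__)

GLOBAL = "global"
DEFAULT_FLANK = 2500


@dataclass(frozen=True)
class TranscriptModel:
    gene_id: str
    gene_name: str
    transcript_id: str
    chrom: str
    strand: str
    tss: int  # 1-based
    biotype: str = "protein_coding"

    @property
    def is_coding(self) -> bool:
        return self.biotype == "protein_coding"


@dataclass
class PromoterRegion:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    source: str  # melanocyte | melanoma | global
    gene_ids: set[str] = field(default_factory=set)
    transcript_ids: set[str] = field(default_factory=set)

    def overlaps_point(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and self.end >= start


def transcripts_from_frame(df: pd.DataFrame) -> list[TranscriptModel]:
    """Build transcript models from a GTF frame (see io.read_gtf).

    TSS is the transcript start on + strand and the transcript end on -.
    """
    out = []
    for r in df.itertuples():
        tss = int(r.start) if r.strand == "+" else int(r.end)
        out.append(
            TranscriptModel(
                gene_id=str(r.gene_id),
                gene_name=str(r.gene_name),
                transcript_id=str(r.transcript_id),
                chrom=str(r.chrom),
                strand=str(r.strand),
                tss=tss,
                biotype=str(r.biotype),
            )
        )
    return out


def merge_intervals(
    intervals: Sequence[tuple[str, int, int]],
) -> list[tuple[str, int, int]]:
    """Merge overlapping or book-ended 1-based closed intervals per chrom."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    out: list[tuple[str, int, int]] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e + 1:  # adjacent intervals merge
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return out


def build_chromhmm_promoters(
    segments: pd.DataFrame, context: str
) -> list[PromoterRegion]:
    """Merged promoter intervals from state segments of one cell context.

    ``segments`` is a BED4-style frame (chrom, start, end, state;
    0-based half-open), possibly pooled across samples. Segments whose
    label is not in the context's promoter vocabulary are ignored;
    labels outside the whole registry are counted in the log.
    """
    known = vocab.REGULATORY_STATES[context]
    promoter_states = vocab.PROMOTER_STATES[context]
    unknown = 0
    kept: list[tuple[str, int, int]] = []
    for r in segments.itertuples():
        label = str(r.state)
        if label in promoter_states:
            kept.append((str(r.chrom), int(r.start) + 1, int(r.end)))
        elif label not in known:
            unknown += 1
    if unknown:
        logger.info("build_chromhmm_promoters(%s): %d unknown-label segments ignored",
                    context, unknown)
    return [
        PromoterRegion(chrom, s, e, source=context)
        for chrom, s, e in merge_intervals(kept)
    ]


def build_global_promoters(
    transcripts: Sequence[TranscriptModel],
    flank: int = DEFAULT_FLANK,
    chrom_lengths: Optional[dict[str, int]] = None,
) -> list[PromoterRegion]:
    """TSS +/- flank (1-based closed) per protein-coding transcript,
    clamped to chromosome bounds; the gene is assigned by construction."""
    out = []
    for t in transcripts:
        if not t.is_coding:
            continue
        start = max(1, t.tss - flank)
        end = t.tss + flank
        if chrom_lengths and t.chrom in chrom_lengths:
            end = min(end, chrom_lengths[t.chrom])
        out.append(
            PromoterRegion(
                t.chrom,
                start,
                end,
                source=GLOBAL,
                gene_ids={t.gene_id},
                transcript_ids={t.transcript_id},
            )
        )
    return out


def assign_genes_to_promoters(
    promoters: Sequence[PromoterRegion],
    transcripts: Sequence[TranscriptModel],
    reach: int = DEFAULT_FLANK,
    coding_only: bool = False,
) -> list[PromoterRegion]:
    """Assign genes whose TSS +/- reach window overlaps the promoter.

    Chromatin-state promoters may assign to non-coding transcripts; pass
    ``coding_only=True`` to restrict. Promoters ending with an empty gene
    set are retained but flagged unassigned (empty set).
    """
    for p in promoters:
        for t in transcripts:
            if coding_only and not t.is_coding:
                continue
            if t.chrom != p.chrom:
                continue
            if p.overlaps(t.tss - reach, t.tss + reach):
                p.gene_ids.add(t.gene_id)
                p.transcript_ids.add(t.transcript_id)
    return list(promoters)


def promoters_to_frame(promoters: Sequence[PromoterRegion]) -> pd.DataFrame:
    rows = [
        {
            "chrom": p.chrom,
            "start": p.start,
            "end": p.end,
            "source": p.source,
            "gene_ids": ",".join(sorted(p.gene_ids)),
            "transcript_ids": ",".join(sorted(p.transcript_ids)),
        }
        for p in promoters
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "source", "gene_ids", "transcript_ids"]
    )
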