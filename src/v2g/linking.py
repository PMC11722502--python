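"""Variant-to-gene nomination through chromatin loops or promoter overlap.

High-confidence loops (score >= 5) connect a CCV's primary/adjacent bins to
bins overlapping gene promoters; CCVs sitting directly inside a promoter
link by overlap. Links carry a distance class and an alternative-promoter
flag for loops reaching a distant promoter of an overlap-linked gene.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .fragments import FragmentMap, VariantBinAssignment
from .promoters import PromoterRegion, TranscriptModel

logger = logging.getLogger(__name__)

MECH_LOOP = "loop"
MECH_PROMOTER_OVERLAP = "promoter_overlap"

CLASS_OVERLAP = "overlap"
CLASS_LT_100KB = "lt_100kb"
CLASS_100KB_1MB = "kb100_to_1Mb"
CLASS_GT_1MB = "gt_1Mb"

DEFAULT_SCORE_THRESHOLD = 5.0
DEFAULT_ALT_PROMOTER_SEP = 10_000


@dataclass(frozen=True)
class InteractionLoop:
    loop_id: str
    bait_bin_id: int
    other_end_bin_id: int
    score: float

    def touches(self, bin_id: int) -> bool:
        return bin_id in (self.bait_bin_id, self.other_end_bin_id)

    def other(self, bin_id: int) -> int:
        if bin_id == self.bait_bin_id:
            return self.other_end_bin_id
        if bin_id == self.other_end_bin_id:
            return self.bait_bin_id
        raise ValueError(f"bin {bin_id} not an end of loop {self.loop_id}")


@dataclass
class VariantGeneLink:
    variant_id: str
    signal_id: int
    gene_id: str
    mechanism: str
    via_bin_ids: tuple[int, ...] = ()
    promoter_source: str = ""
    distance: int = 0  # variant position to nearest linked-gene TSS
    edge_distance: int = 0  # variant position to nearest promoter edge
    distance_class: str = CLASS_OVERLAP
    alt_promoter: bool = False
    promoter_interval: tuple[str, int, int] = ("", 0, 0)
    loop_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class CcvPlacement:
    """A credible variant with its genomic position and bin assignment."""

    variant_id: str
    signal_id: int
    chrom: str
    pos: int  # 1-based
    assignment: VariantBinAssignment


def classify_distance(distance: int, mechanism: str = MECH_LOOP) -> str:
    """Distance bins: overlap (0), (0, 100 kb), [100 kb, 1 Mb], > 1 Mb."""
    if mechanism == MECH_PROMOTER_OVERLAP or distance == 0:
        return CLASS_OVERLAP
    if distance < 100_000:
        return CLASS_LT_100KB
    if distance <= 1_000_000:
        return CLASS_100KB_1MB
    return CLASS_GT_1MB


def _resolve_bin(fmap: FragmentMap, chrom: str, start1: int, end1: int) -> Optional[int]:
    """Map a 1-based inclusive interval to the bin it covers (by midpoint)."""
    mid0 = (start1 - 1 + end1) // 2
    try:
        return fmap.bin_at(chrom, mid0).bin_id
    except KeyError:
        return None


def load_interactions(
    path: str,
    fmap: FragmentMap,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> list[InteractionLoop]:
    """Read ibed-dialect interaction calls and keep score >= threshold.

    Columns: bait chrom/start/end/name, other-end chrom/start/end/name,
    N_reads, score; an optional header line starting with 'bait' is
    skipped. Trans-chromosomal records and records whose coordinates do
    not resolve to a bin are dropped with a log entry.
    """
    loops: list[InteractionLoop] = []
    skipped = trans = 0
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if f[0].startswith("bait"):
                continue
            (bc, bs, be, bn, oc, os_, oe, _on, _n, score) = f[:10]
            if float(score) < score_threshold:
                continue
            if bc != oc:
                trans += 1
                continue
            bait = _resolve_bin(fmap, bc, int(bs), int(be))
            other = _resolve_bin(fmap, oc, int(os_), int(oe))
            if bait is None or other is None:
                skipped += 1
                continue
            loop_id = bn if bn and bn != "." else f"loop_{i}"
            loops.append(InteractionLoop(loop_id, bait, other, float(score)))
    if skipped or trans:
        logger.info(
            "load_interactions: %d unresolvable and %d trans records dropped",
            skipped,
            trans,
        )
    return loops


def filter_loops(
    loops: Iterable[InteractionLoop], score_threshold: float = DEFAULT_SCORE_THRESHOLD
) -> list[InteractionLoop]:
    return [lp for lp in loops if lp.score >= score_threshold]


class _GeneTss:
    def __init__(self, transcripts: Sequence[TranscriptModel]):
        self.by_gene: dict[str, list[TranscriptModel]] = {}
        self.by_tid: dict[str, TranscriptModel] = {}
        for t in transcripts:
            self.by_gene.setdefault(t.gene_id, []).append(t)
            self.by_tid[t.transcript_id] = t

    def nearest_tss_distance(
        self, gene_id: str, pos: int, transcript_ids: Optional[set[str]] = None
    ) -> int:
        cands = []
        if transcript_ids:
            cands = [
                self.by_tid[tid]
                for tid in transcript_ids
                if tid in self.by_tid and self.by_tid[tid].gene_id == gene_id
            ]
        if not cands:
            cands = self.by_gene.get(gene_id, [])
        if not cands:
            return 0
        return min(abs(pos - t.tss) for t in cands)


def link_variants_to_genes(
    ccvs: Sequence[CcvPlacement],
    loops: Sequence[InteractionLoop],
    promoters: Sequence[PromoterRegion],
    fmap: FragmentMap,
    transcripts: Sequence[TranscriptModel] = (),
) -> list[VariantGeneLink]:
    """Nominate (variant, gene) pairs via loops and via promoter overlap.

    Loop route: every loop touching any of the variant's bins links the
    variant to every gene of every promoter overlapping the loop's other
    end. Overlap route: the variant position lies inside a promoter.
    Duplicate nominations collapse per (variant, gene, mechanism), keeping
    the two mechanisms as separate records.
    """
    tss_index = _GeneTss(transcripts)
    # promoter lookup per bin is cheap at desk scale: test hull overlap
    links: dict[tuple[str, str, str], VariantGeneLink] = {}

    def add(
        ccv: CcvPlacement,
        gene_id: str,
        mechanism: str,
        promoter: PromoterRegion,
        via_bins: tuple[int, ...],
        loop_id: str = "",
    ) -> None:
        if mechanism == MECH_PROMOTER_OVERLAP:
            dist = 0
            edge = 0
        else:
            dist = tss_index.nearest_tss_distance(
                gene_id, ccv.pos, promoter.transcript_ids
            )
            edge = min(abs(ccv.pos - promoter.start), abs(ccv.pos - promoter.end))
            if promoter.overlaps_point(ccv.pos):
                edge = 0
        key = (ccv.variant_id, gene_id, mechanism)
        if key in links:
            lk = links[key]
            lk.via_bin_ids = tuple(sorted(set(lk.via_bin_ids) | set(via_bins)))
            if loop_id:
                lk.loop_ids = tuple(sorted(set(lk.loop_ids) | {loop_id}))
            if dist < lk.distance:
                lk.distance = dist
                lk.edge_distance = edge
                lk.distance_class = classify_distance(dist, mechanism)
                lk.promoter_interval = (promoter.chrom, promoter.start, promoter.end)
                lk.promoter_source = promoter.source
        else:
            links[key] = VariantGeneLink(
                variant_id=ccv.variant_id,
                signal_id=ccv.signal_id,
                gene_id=gene_id,
                mechanism=mechanism,
                via_bin_ids=via_bins,
                promoter_source=promoter.source,
                distance=dist,
                edge_distance=edge,
                distance_class=classify_distance(dist, mechanism),
                promoter_interval=(promoter.chrom, promoter.start, promoter.end),
                loop_ids=(loop_id,) if loop_id else (),
            )

    for ccv in ccvs:
        # (a) loop mechanism over primary + adjacent bins
        for bin_id in ccv.assignment.bin_ids:
            for lp in loops:
                if not lp.touches(bin_id):
                    continue
                other = fmap.bin(lp.other(bin_id))
                for p in promoters:
                    if not p.gene_ids:
                        continue
                    if p.chrom != other.chrom:
                        continue
                    # bin hull 0-based half-open vs promoter 1-based closed
                    if p.start <= other.end and p.end >= other.start + 1:
                        for gene_id in p.gene_ids:
                            add(ccv, gene_id, MECH_LOOP, p, (bin_id,), lp.loop_id)
        # (b) direct promoter overlap
        for p in promoters:
            if p.gene_ids and p.chrom == ccv.chrom and p.overlaps_point(ccv.pos):
                for gene_id in p.gene_ids:
                    add(ccv, gene_id, MECH_PROMOTER_OVERLAP, p, ())
    return list(links.values())


def flag_alternative_promoter(
    links: Sequence[VariantGeneLink],
    min_separation: int = DEFAULT_ALT_PROMOTER_SEP,
) -> list[VariantGeneLink]:
    """Flag loop links whose target promoter lies >= min_separation away
    (nearest edges) from an overlap-linked promoter of the same gene for
    the same variant."""
    overlap_by_pair: dict[tuple[str, str], list[tuple[str, int, int]]] = {}
    for lk in links:
        if lk.mechanism == MECH_PROMOTER_OVERLAP:
            overlap_by_pair.setdefault((lk.variant_id, lk.gene_id), []).append(
                lk.promoter_interval
            )
    for lk in links:
        if lk.mechanism != MECH_LOOP:
            continue
        for chrom, s, e in overlap_by_pair.get((lk.variant_id, lk.gene_id), []):
            pc, ps, pe = lk.promoter_interval
            if pc != chrom:
                continue
            if ps > e:
                sep = ps - e
            elif s > pe:
                sep = s - pe
            else:
                sep = 0
            if sep >= min_separation:
                lk.alt_promoter = True
    return list(links)


def summarize_signals(
    links: Sequence[VariantGeneLink],
    all_signal_ids: Optional[Sequence[int]] = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-signal gene / linked-variant counts plus global medians."""
    signal_ids = sorted(
        set(all_signal_ids or []) | {lk.signal_id for lk in links}
    )
    rows = []
    for sid in signal_ids:
        sl = [lk for lk in links if lk.signal_id == sid]
        genes = {lk.gene_id for lk in sl}
        variants = {lk.variant_id for lk in sl}
        classes = {lk.distance_class for lk in sl}
        rows.append(
            {
                "signal_id": sid,
                "n_genes": len(genes),
                "n_linked_variants": len(variants),
                "has_overlap": CLASS_OVERLAP in classes,
                "has_lt_100kb": CLASS_LT_100KB in classes,
                "has_100kb_1Mb": CLASS_100KB_1MB in classes,
                "has_gt_1Mb": CLASS_GT_1MB in classes,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "signal_id",
            "n_genes",
            "n_linked_variants",
            "has_overlap",
            "has_lt_100kb",
            "has_100kb_1Mb",
            "has_gt_1Mb",
        ],
    )
    summary = {
        "median_genes_per_signal": float(statistics.median(df.n_genes)) if len(df) else 0.0,
        "median_linked_variants_per_signal": (
            float(statistics.median(df.n_linked_variants)) if len(df) else 0.0
        ),
        "n_signals_no_nomination": int((df.n_genes == 0).sum()) if len(df) else 0,
    }
    return df, summary


def links_to_frame(links: Sequence[VariantGeneLink]) -> pd.DataFrame:
    rows = [
        {
            "variant_id": lk.variant_id,
            "signal_id": lk.signal_id,
            "gene_id": lk.gene_id,
            "mechanism": lk.mechanism,
            "via_bin_ids": ",".join(map(str, lk.via_bin_ids)),
            "promoter_source": lk.promoter_source,
            "distance": lk.distance,
            "edge_distance": lk.edge_distance,
            "distance_class": lk.distance_class,
            "alt_promoter": lk.alt_promoter,
        }
        for lk in links
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "variant_id",
            "signal_id",
            "gene_id",
            "mechanism",
            "via_bin_ids",
            "promoter_source",
            "distance",
            "edge_distance",
            "distance_class",
            "alt_promoter",
        ],
    )


def write_washu_track(
    links: Sequence[VariantGeneLink],
    ccvs: Mapping[str, CcvPlacement],
    fmap: FragmentMap,
    path: str,
) -> None:
    """WashU long-range text: chrom start end chrom2:start2-end2,score."""
    with open(path, "w") as fh:
        for lk in links:
            if lk.mechanism != MECH_LOOP or lk.variant_id not in ccvs:
                continue
            ccv = ccvs[lk.variant_id]
            b = fmap.bin(ccv.assignment.primary_bin_id)
            pc, ps, pe = lk.promoter_interval
            fh.write(
                f"{b.chrom}\t{b.start}\t{b.end}\t{pc}:{ps - 1}-{pe},1\n"
            )
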