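"""Restriction-fragment map, k-fragment binning and variant-to-bin assignment.

Models a dual-enzyme digestion (``^GATC`` and ``G^ANTC``), groups consecutive
fragments into analysis bins, flags baited bins from target regions, and
assigns variants to their harbouring bin plus any adjacent-fragment bin that
overlaps a +/- window around the variant.

Coordinates are 0-based half-open internally; rmap/baitmap files are emitted
1-based inclusive (CHiCAGO dialect); variant positions are ingested 1-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: (motif regex with N expanded, cut offset from match start)
DEFAULT_MOTIFS: tuple[tuple[str, int], ...] = (("GATC", 0), ("GANTC", 1))


@dataclass(frozen=True)
class RestrictionFragment:
    frag_id: int
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class FragmentBin:
    bin_id: int
    chrom: str
    start: int
    end: int
    member_frag_ids: list[int]
    baited: bool = False


@dataclass(frozen=True)
class VariantBinAssignment:
    variant_id: str
    primary_bin_id: int
    adjacent_bin_ids: tuple[int, ...]
    window: int = 500

    @property
    def bin_ids(self) -> tuple[int, ...]:
        return (self.primary_bin_id,) + self.adjacent_bin_ids


def _motif_pattern(motif: str) -> re.Pattern[str]:
    # N in the recognition sequence matches any base, but never N in the
    # subject; overlapping sites are found with a lookahead.
    return re.compile("(?=" + motif.replace("N", "[ACGT]") + ")")


def find_cut_sites(
    sequence: str, motifs: Sequence[tuple[str, int]] = DEFAULT_MOTIFS
) -> list[int]:
    """Return sorted, deduplicated cut positions in ``sequence``.

    A cut position is ``match_start + offset`` for every motif occurrence.
    Cuts at 0 or at the sequence end are dropped (they would create empty
    fragments).
    """
    seq = sequence.upper()
    cuts: set[int] = set()
    for motif, offset in motifs:
        pat = _motif_pattern(motif)
        for m in pat.finditer(seq):
            cuts.add(m.start() + offset)
    return sorted(c for c in cuts if 0 < c < len(seq))


def digest(
    sequence: str,
    chrom: str = "chr1",
    motifs: Sequence[tuple[str, int]] = DEFAULT_MOTIFS,
    first_frag_id: int = 1,
) -> list[RestrictionFragment]:
    """Digest ``sequence`` into restriction fragments tiling it exactly."""
    if not sequence:
        return []
    cuts = find_cut_sites(sequence, motifs)
    bounds = [0, *cuts, len(sequence)]
    return [
        RestrictionFragment(first_frag_id + i, chrom, bounds[i], bounds[i + 1])
        for i in range(len(bounds) - 1)
    ]


def digest_genome(
    sequences: Mapping[str, str],
    motifs: Sequence[tuple[str, int]] = DEFAULT_MOTIFS,
) -> list[RestrictionFragment]:
    """Digest every chromosome; fragment ids ascend along the genome."""
    frags: list[RestrictionFragment] = []
    next_id = 1
    for chrom in sequences:
        chrom_frags = digest(sequences[chrom], chrom, motifs, first_frag_id=next_id)
        frags.extend(chrom_frags)
        next_id += len(chrom_frags)
    return frags


def make_bins(fragments: Sequence[RestrictionFragment], k: int = 4) -> list[FragmentBin]:
    """Group k consecutive same-chromosome fragments into bins.

    Grouping restarts at each chromosome; a trailing partial bin is kept.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    bins: list[FragmentBin] = []
    by_chrom: dict[str, list[RestrictionFragment]] = {}
    for f in fragments:
        by_chrom.setdefault(f.chrom, []).append(f)
    bin_id = 1
    for chrom, frags in by_chrom.items():
        frags = sorted(frags, key=lambda f: f.start)
        for i in range(0, len(frags), k):
            group = frags[i : i + k]
            bins.append(
                FragmentBin(
                    bin_id=bin_id,
                    chrom=chrom,
                    start=group[0].start,
                    end=group[-1].end,
                    member_frag_ids=[f.frag_id for f in group],
                )
            )
            bin_id += 1
    return bins


@dataclass
class FragmentMap:
    """Indexed view over fragments and bins for one genome."""

    fragments: list[RestrictionFragment]
    bins: list[FragmentBin]
    _frag_by_id: dict[int, RestrictionFragment] = field(init=False, repr=False)
    _bin_by_id: dict[int, FragmentBin] = field(init=False, repr=False)
    _bin_of_frag: dict[int, int] = field(init=False, repr=False)
    _frags_by_chrom: dict[str, list[RestrictionFragment]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._frag_by_id = {f.frag_id: f for f in self.fragments}
        self._bin_by_id = {b.bin_id: b for b in self.bins}
        self._bin_of_frag = {
            fid: b.bin_id for b in self.bins for fid in b.member_frag_ids
        }
        self._frags_by_chrom = {}
        for f in self.fragments:
            self._frags_by_chrom.setdefault(f.chrom, []).append(f)
        for frags in self._frags_by_chrom.values():
            frags.sort(key=lambda f: f.start)

    @classmethod
    def from_sequences(
        cls,
        sequences: Mapping[str, str],
        k: int = 4,
        motifs: Sequence[tuple[str, int]] = DEFAULT_MOTIFS,
    ) -> "FragmentMap":
        frags = digest_genome(sequences, motifs)
        return cls(frags, make_bins(frags, k))

    def fragment(self, frag_id: int) -> RestrictionFragment:
        return self._frag_by_id[frag_id]

    def bin(self, bin_id: int) -> FragmentBin:
        return self._bin_by_id[bin_id]

    def bin_of_fragment(self, frag_id: int) -> int:
        return self._bin_of_frag[frag_id]

    def fragment_at(self, chrom: str, pos0: int) -> RestrictionFragment:
        """Fragment containing 0-based position ``pos0``."""
        frags = self._frags_by_chrom.get(chrom)
        if not frags:
            raise KeyError(f"no fragments on {chrom}")
        lo, hi = 0, len(frags) - 1
        while lo <= hi:
            mid = (lo + hi) // 2
            f = frags[mid]
            if pos0 < f.start:
                hi = mid - 1
            elif pos0 >= f.end:
                lo = mid + 1
            else:
                return f
        raise KeyError(f"position {chrom}:{pos0} outside all fragments")

    def bin_at(self, chrom: str, pos0: int) -> FragmentBin:
        return self.bin(self.bin_of_fragment(self.fragment_at(chrom, pos0).frag_id))

    def bins_overlapping(self, chrom: str, start0: int, end0: int) -> list[FragmentBin]:
        return [
            b
            for b in self.bins
            if b.chrom == chrom and b.start < end0 and b.end > start0
        ]

    def neighbors(self, frag: RestrictionFragment) -> list[RestrictionFragment]:
        """Immediate same-chromosome neighbours of ``frag``."""
        frags = self._frags_by_chrom[frag.chrom]
        idx = next(i for i, f in enumerate(frags) if f.frag_id == frag.frag_id)
        out = []
        if idx > 0:
            out.append(frags[idx - 1])
        if idx + 1 < len(frags):
            out.append(frags[idx + 1])
        return out


def build_baitmap(
    bins: Sequence[FragmentBin],
    fragments: Sequence[RestrictionFragment],
    target_regions: Iterable[tuple[str, int, int]],
) -> list[FragmentBin]:
    """Flag a bin baited iff any member fragment overlaps any target region.

    ``target_regions`` are (chrom, start, end) 0-based half-open. Mutates
    and returns ``bins``.
    """
    regions = list(target_regions)
    frag_by_id = {f.frag_id: f for f in fragments}
    for b in bins:
        b.baited = False
        for fid in b.member_frag_ids:
            f = frag_by_id[fid]
            if any(
                f.chrom == chrom and f.start < end and f.end > start
                for chrom, start, end in regions
            ):
                b.baited = True
                break
    return list(bins)


def assign_variant_bins(
    variant_id: str,
    chrom: str,
    pos: int,
    fmap: FragmentMap,
    window: int = 500,
) -> VariantBinAssignment:
    """Assign a 1-based variant position to its primary bin and any adjacent
    bins whose neighbouring fragment overlaps ``pos +/- window`` (inclusive).

    Adjacency is tested on fragments (immediate neighbours of the variant's
    fragment), then mapped to bins; a neighbour inside the primary bin adds
    nothing.
    """
    pos0 = pos - 1
    frag = fmap.fragment_at(chrom, pos0)
    primary = fmap.bin_of_fragment(frag.frag_id)
    win_lo, win_hi = pos0 - window, pos0 + window  # inclusive bounds
    adjacent: list[int] = []
    for nb in fmap.neighbors(frag):
        if nb.start <= win_hi and nb.end - 1 >= win_lo:
            b = fmap.bin_of_fragment(nb.frag_id)
            if b != primary and b not in adjacent:
                adjacent.append(b)
    return VariantBinAssignment(variant_id, primary, tuple(sorted(adjacent)), window)


# ---------------------------------------------------------------------------
# CHiCAGO-dialect I/O (1-based inclusive, tab-separated, no header)
# ---------------------------------------------------------------------------


def write_rmap(fragments: Sequence[RestrictionFragment], path: str) -> None:
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(f"{f.chrom}\t{f.start + 1}\t{f.end}\t{f.frag_id}\n")


def read_rmap(path: str) -> list[RestrictionFragment]:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "frag_id"]
    )
    return [
        RestrictionFragment(int(r.frag_id), str(r.chrom), int(r.start) - 1, int(r.end))
        for r in df.itertuples()
    ]


def write_baitmap(
    bins: Sequence[FragmentBin], path: str, annotation: str = "bait"
) -> None:
    """Emit baited bins in baitmap dialect (rmap columns + annotation)."""
    with open(path, "w") as fh:
        for b in bins:
            if b.baited:
                fh.write(f"{b.chrom}\t{b.start + 1}\t{b.end}\t{b.bin_id}\t{annotation}\n")


def read_baitmap(path: str) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "bin_id", "annotation"],
    )


def write_bin_rmap(bins: Sequence[FragmentBin], path: str) -> None:
    """Emit the binned map itself in rmap dialect (bin ids as fragment ids)."""
    with open(path, "w") as fh:
        for b in bins:
            fh.write(f"{b.chrom}\t{b.start + 1}\t{b.end}\t{b.bin_id}\n")


def coverage_report(
    assignments: Sequence[VariantBinAssignment], fmap: FragmentMap
) -> dict[str, float]:
    """Fraction of variants in a baited bin, and baited-or-adjacent."""
    n = len(assignments)
    if n == 0:
        return {"n_variants": 0, "frac_baited": 0.0, "frac_baited_or_adjacent": 0.0}
    in_bait = sum(1 for a in assignments if fmap.bin(a.primary_bin_id).baited)
    in_any = sum(
        1
        for a in assignments
        if any(fmap.bin(b).baited for b in a.bin_ids)
    )
    return {
        "n_variants": n,
        "frac_baited": in_bait / n,
        "frac_baited_or_adjacent": in_any / n,
    }
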