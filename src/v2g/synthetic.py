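"""Self-consistent toy universe generator with a planted-truth ledger.

Generates a genome (FASTA + GTF), GWAS summary statistics with
LD-correlated Z-scores around planted causal variants, chromatin-state and
ATAC tracks, CHiCAGO-style interaction calls connecting planted enhancer
bins to target-gene promoter bins, MPRA/QTL/driver tables, and a ledger of
the planted truth so every downstream stage can be validated exactly.

Layout guarantees used by the tests: each chromosome is divided into one
slot per gene; the gene sits in the first quarter of its slot and the
signal's enhancer anchor in the second half, far from every TSS, so the
only links a noise-free run can produce are the planted ones.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import io as vio
from .fragments import FragmentMap

logger = logging.getLogger(__name__)

GENE_LENGTH = 2_000
ENHANCER_HALFWIDTH = 250
PROMOTER_STATE_HALFWIDTH = 500
VARIANT_CLUSTER_HALFWIDTH = 1_500
FRAGMENT_EDGE_MARGIN = 5

FILENAMES = {
    "fasta": "genome.fa",
    "gtf": "genes.gtf",
    "sumstats": "sumstats.tsv",
    "ld": "ld.tsv",
    "bayes": "bayes.tsv",
    "signals": "signals.tsv",
    "targets": "target_regions.bed",
    "chromhmm_melanocyte": "chromhmm_melanocyte.bed",
    "chromhmm_melanoma": "chromhmm_melanoma.bed",
    "atac_melanocyte": "atac_melanocyte.bed",
    "atac_melanoma": "atac_melanoma.bed",
    "interactions": "interactions.ibed",
    "mpra": "mpra.tsv",
    "qtl": "qtl.tsv",
    "drivers": "drivers.tsv",
    "expression": "expression.tsv",
    "ledger": "ledger.json",
}


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    n_chromosomes: int = 1
    chrom_length: int = 200_000
    n_genes: int = 5
    n_signals: int = 3
    n_variants_per_signal: int = 5
    causal_effect_lambda: float = 6.0
    ld_decay_rate: float = 2e-3
    fraction_regulatory: float = 1.0
    loop_true_score_range: tuple[float, float] = (6.0, 12.0)
    loop_noise_rate: float = 0.0
    bin_k: int = 4
    se: float = 0.02  # beta = z * se; only z matters downstream
    n_expression_samples: int = 10

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length < 1:
            raise ValueError("chromosome counts/lengths must be >= 1")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.n_signals < 1 or self.n_variants_per_signal < 1:
            raise ValueError("signal counts must be >= 1")
        if not (0.0 <= self.fraction_regulatory <= 1.0):
            raise ValueError("fraction_regulatory must be in [0,1]")
        if not (0.0 <= self.loop_noise_rate <= 1.0):
            raise ValueError("loop_noise_rate must be in [0,1]")
        if self.loop_true_score_range[0] > self.loop_true_score_range[1]:
            raise ValueError("loop_true_score_range must be ordered")


@dataclass
class PlantedTruth:
    causal_variants: dict[int, str] = field(default_factory=dict)  # signal -> id
    true_links: set[tuple[str, str]] = field(default_factory=set)
    true_genes: dict[int, str] = field(default_factory=dict)  # signal -> gene
    true_regulatory_elements: list[tuple[str, int, int]] = field(default_factory=list)
    decoy_loops: list[str] = field(default_factory=list)
    driver_genes: dict[str, tuple[bool, bool]] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "causal_variants": {str(k): v for k, v in self.causal_variants.items()},
            "true_links": sorted(list(t) for t in self.true_links),
            "true_genes": {str(k): v for k, v in self.true_genes.items()},
            "true_regulatory_elements": [list(t) for t in self.true_regulatory_elements],
            "decoy_loops": self.decoy_loops,
            "driver_genes": {
                g: list(v) for g, v in sorted(self.driver_genes.items())
            },
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        d = json.loads(text)
        return cls(
            causal_variants={int(k): v for k, v in d["causal_variants"].items()},
            true_links={tuple(t) for t in d["true_links"]},
            true_genes={int(k): v for k, v in d["true_genes"].items()},
            true_regulatory_elements=[tuple(t) for t in d["true_regulatory_elements"]],
            decoy_loops=list(d["decoy_loops"]),
            driver_genes={g: tuple(v) for g, v in d["driver_genes"].items()},
        )


def _sub_rng(seed: int, role: str) -> np.random.Generator:
    """Per-file sub-seed derived from the global seed and a role hash, so
    adding outputs does not reshuffle existing ones."""
    digest = hashlib.sha256(role.encode()).digest()
    return np.random.default_rng([seed, int.from_bytes(digest[:4], "big")])


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


@dataclass
class GenomeBundle:
    sequences: dict[str, str]
    transcripts: list[dict]  # io.write_gtf rows

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


def generate_genome(config: SyntheticConfig) -> GenomeBundle:
    """Random A/C/G/T chromosomes with non-overlapping slotted genes."""
    config.validate()
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    rng_seq = _sub_rng(config.seed, "genome.sequence")
    bases = np.array(list("ACGT"))
    sequences = {
        c: "".join(bases[rng_seq.integers(0, 4, size=config.chrom_length)])
        for c in chroms
    }

    # round-robin gene assignment to chromosomes
    genes_per_chrom = [0] * config.n_chromosomes
    for i in range(config.n_genes):
        genes_per_chrom[i % config.n_chromosomes] += 1
    rng_gene = _sub_rng(config.seed, "genome.genes")
    transcripts: list[dict] = []
    gene_idx = 0
    for ci, chrom in enumerate(chroms):
        n = genes_per_chrom[ci]
        if n == 0:
            continue
        slot = config.chrom_length // n
        if slot < 4 * GENE_LENGTH:
            raise ValueError(
                f"chromosome {chrom} too short to host {n} genes "
                f"(slot {slot} < {4 * GENE_LENGTH})"
            )
        for gi in range(n):
            slot_start = gi * slot
            # gene in the first quarter of its slot
            lo = slot_start + slot // 16
            hi = slot_start + slot // 4 - GENE_LENGTH
            start0 = int(rng_gene.integers(lo, max(lo + 1, hi)))
            strand = "+" if rng_gene.random() < 0.5 else "-"
            gene_idx += 1
            transcripts.append(
                {
                    "chrom": chrom,
                    "start": start0 + 1,  # GTF 1-based
                    "end": start0 + GENE_LENGTH,
                    "strand": strand,
                    "gene_id": f"G{gene_idx:04d}",
                    "gene_name": f"GENE{gene_idx}",
                    "transcript_id": f"T{gene_idx:04d}",
                    "biotype": "protein_coding",
                }
            )
    return GenomeBundle(sequences=sequences, transcripts=transcripts)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------


def ld_correlation(positions: np.ndarray, decay_rate: float) -> np.ndarray:
    """Signed r matrix with exponential distance decay."""
    d = np.abs(positions[:, None] - positions[None, :])
    return np.exp(-decay_rate * d)


def _nearest_pd(corr: np.ndarray) -> np.ndarray:
    """Repair a non-positive-definite matrix by diagonal loading."""
    eps = 1e-10
    for _ in range(20):
        try:
            np.linalg.cholesky(corr)
            return corr
        except np.linalg.LinAlgError:
            logger.info("correlation not PD; diagonal loading eps=%g", eps)
            corr = (corr + eps * np.eye(len(corr))) / (1 + eps)
            eps *= 10
    raise np.linalg.LinAlgError("could not repair correlation matrix")


def simulate_summary_stats(
    variant_ids: list[str],
    corr: np.ndarray,
    causal_index: int,
    effect_lambda: float,
    rng: np.random.Generator,
    chrom: str,
    positions: np.ndarray,
    se: float = 0.02,
) -> pd.DataFrame:
    """Z-scores from MVN(mean = r_.,causal * lambda, cov = corr);
    beta/se back-filled so z = beta / se."""
    corr = np.asarray(corr, dtype=float)
    if np.any(np.abs(corr) > 1 + 1e-9):
        raise ValueError("correlations must lie in [-1, 1]")
    if not (0 <= causal_index < len(variant_ids)):
        raise IndexError("causal index out of range")
    corr = _nearest_pd(corr)
    mean = corr[:, causal_index] * effect_lambda
    z = rng.multivariate_normal(mean, corr, method="cholesky")
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    return pd.DataFrame(
        {
            "variant_id": variant_ids,
            "chrom": chrom,
            "pos": positions.astype(int),
            "beta": z * se,
            "se": se,
            "p": p,
        }
    )


# ---------------------------------------------------------------------------
# architecture planting
# ---------------------------------------------------------------------------


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    genome: GenomeBundle
    sumstats: pd.DataFrame
    ld: pd.DataFrame
    bayes: pd.DataFrame
    signals: pd.DataFrame
    targets: pd.DataFrame  # BED3, 0-based half-open
    chromhmm: dict[str, pd.DataFrame]  # context -> BED4
    atac: dict[str, pd.DataFrame]  # context -> BED3
    interactions: pd.DataFrame  # ibed rows
    mpra: pd.DataFrame
    qtl: pd.DataFrame
    drivers: pd.DataFrame
    expression: pd.DataFrame
    truth: PlantedTruth

    def write(self, outdir: str) -> dict[str, str]:
        os.makedirs(outdir, exist_ok=True)
        paths = {k: os.path.join(outdir, v) for k, v in FILENAMES.items()}
        vio.write_fasta(self.genome.sequences, paths["fasta"])
        vio.write_gtf(self.genome.transcripts, paths["gtf"])
        vio.write_tsv(self.sumstats, paths["sumstats"])
        vio.write_tsv(self.ld, paths["ld"])
        vio.write_tsv(self.bayes, paths["bayes"])
        vio.write_tsv(self.signals, paths["signals"])
        vio.write_bed(self.targets, paths["targets"])
        for ctx in ("melanocyte", "melanoma"):
            vio.write_bed(self.chromhmm[ctx], paths[f"chromhmm_{ctx}"])
            vio.write_bed(self.atac[ctx], paths[f"atac_{ctx}"])
        self.interactions.to_csv(paths["interactions"], sep="\t", index=False)
        vio.write_tsv(self.mpra, paths["mpra"])
        vio.write_tsv(self.qtl, paths["qtl"])
        vio.write_tsv(self.drivers, paths["drivers"])
        self.expression.to_csv(paths["expression"], sep="\t")
        with open(paths["ledger"], "w") as fh:
            fh.write(self.truth.to_json() + "\n")
        return paths


def _sample_variant_position(
    anchor0: int, chrom: str, fmap: FragmentMap, rng: np.random.Generator,
    taken: set[int],
) -> int:
    """0-based variant position near the anchor, on a fragment body (never
    within the edge margin, so digestion and variants cannot interact)."""
    for _ in range(200):
        pos0 = int(
            rng.integers(
                anchor0 - VARIANT_CLUSTER_HALFWIDTH,
                anchor0 + VARIANT_CLUSTER_HALFWIDTH + 1,
            )
        )
        if pos0 in taken:
            continue
        try:
            frag = fmap.fragment_at(chrom, pos0)
        except KeyError:
            continue
        if (
            pos0 - frag.start >= FRAGMENT_EDGE_MARGIN
            and frag.end - pos0 > FRAGMENT_EDGE_MARGIN
        ):
            taken.add(pos0)
            return pos0
    raise RuntimeError("could not place variant on a fragment body")


def plant_architecture(
    genome: GenomeBundle,
    config: SyntheticConfig,
    fmap: FragmentMap,
) -> SyntheticBundle:
    """Plant one true (causal variant -> gene) regulatory link per signal,
    with the enhancer element, ATAC peak, loop, and MPRA record implied by
    it; decoy loops are added at ``loop_noise_rate``."""
    config.validate()
    if config.n_signals > len(genome.transcripts):
        raise ValueError("need at least one gene per signal")
    truth = PlantedTruth()
    rng_pos = _sub_rng(config.seed, "architecture.positions")
    rng_z = _sub_rng(config.seed, "architecture.zscores")
    rng_loop = _sub_rng(config.seed, "architecture.loops")
    rng_expr = _sub_rng(config.seed, "architecture.expression")

    n_regulatory = round(config.fraction_regulatory * config.n_signals)

    tss_of = {}
    for t in genome.transcripts:
        tss_of[t["gene_id"]] = (
            t["chrom"],
            t["start"] if t["strand"] == "+" else t["end"],
        )
    all_tss = list(tss_of.values())

    sumstats_frames = []
    ld_rows = []
    bayes_rows = []
    signal_rows = []
    target_rows = []
    hmm: dict[str, list] = {"melanocyte": [], "melanoma": []}
    atac: dict[str, list] = {"melanocyte": [], "melanoma": []}
    ibed_rows = []
    mpra_rows = []
    qtl_rows = []

    # background promoter-state segments over every TSS
    for gene_id, (chrom, tss) in tss_of.items():
        s0 = max(0, tss - 1 - PROMOTER_STATE_HALFWIDTH)
        e0 = tss + PROMOTER_STATE_HALFWIDTH
        hmm["melanocyte"].append((chrom, s0, e0, "TssA"))
        hmm["melanoma"].append((chrom, s0, e0, "1_TssA"))

    loop_counter = 0

    def bin_hull_1based(bin_id: int) -> tuple[str, int, int]:
        b = fmap.bin(bin_id)
        return b.chrom, b.start + 1, b.end

    slot_by_chrom = {}
    genes_by_chrom: dict[str, list[dict]] = {}
    for t in genome.transcripts:
        genes_by_chrom.setdefault(t["chrom"], []).append(t)
    for chrom, genes in genes_by_chrom.items():
        slot_by_chrom[chrom] = len(genome.sequences[chrom]) // len(genes)

    for s in range(1, config.n_signals + 1):
        gene = genome.transcripts[s - 1]
        gene_id = gene["gene_id"]
        chrom, tss = tss_of[gene_id]
        slot = slot_by_chrom[chrom]
        genes_on_chrom = genes_by_chrom[chrom]
        slot_index = genes_on_chrom.index(gene)
        slot_start = slot_index * slot

        # enhancer anchor in the second half of the gene's slot
        anchor0 = None
        for _ in range(100):
            cand = int(
                rng_pos.integers(
                    slot_start + slot // 2,
                    slot_start + slot - VARIANT_CLUSTER_HALFWIDTH - 1_000,
                )
            )
            if all(
                c != chrom or abs(cand - (t - 1)) > 6_000 for c, t in all_tss
            ):
                anchor0 = cand
                break
        if anchor0 is None:
            raise RuntimeError("could not place enhancer anchor away from TSSs")

        # bins: causal bin must differ from the target promoter's bin
        promoter_bin = fmap.bin_at(chrom, tss - 1).bin_id
        causal_bin = fmap.bin_at(chrom, anchor0).bin_id
        while causal_bin == promoter_bin:
            logger.info("signal %d: re-planting link at greater distance", s)
            anchor0 += fmap.bin(causal_bin).end - fmap.bin(causal_bin).start
            causal_bin = fmap.bin_at(chrom, anchor0).bin_id

        taken: set[int] = set()
        causal_pos0 = _sample_variant_position(anchor0, chrom, fmap, rng_pos, taken)
        causal_bin = fmap.bin_at(chrom, causal_pos0).bin_id
        positions0 = [causal_pos0]
        for _ in range(config.n_variants_per_signal - 1):
            positions0.append(
                _sample_variant_position(anchor0, chrom, fmap, rng_pos, taken)
            )
        order = np.argsort(positions0)
        positions0 = [positions0[i] for i in order]
        causal_idx = positions0.index(causal_pos0)
        vids = [f"rs{s}_{i + 1}" for i in range(len(positions0))]
        causal_id = vids[causal_idx]
        positions1 = np.asarray(positions0) + 1

        corr = ld_correlation(positions1.astype(float), config.ld_decay_rate)
        ss = simulate_summary_stats(
            vids, corr, causal_idx, config.causal_effect_lambda, rng_z,
            chrom, positions1, se=config.se,
        )
        sumstats_frames.append(ss)
        for i in range(len(vids)):
            for j in range(i + 1, len(vids)):
                ld_rows.append(
                    {"id_a": vids[i], "id_b": vids[j], "r2": corr[i, j] ** 2}
                )
        bayes_rows.append(
            {"variant_id": causal_id, "signal_id": s, "pip": 0.95}
        )
        signal_rows.append(
            {
                "signal_id": s,
                "locus_id": s,
                "lead_variant_id": causal_id,
                "is_secondary": False,
            }
        )
        # association region: variant span extended by one fragment each way
        lo_frag = fmap.fragment_at(chrom, min(positions0))
        hi_frag = fmap.fragment_at(chrom, max(positions0))
        region_lo = max(0, lo_frag.start - (lo_frag.end - lo_frag.start))
        region_hi = hi_frag.end + (hi_frag.end - hi_frag.start)
        target_rows.append((chrom, region_lo, region_hi))

        regulatory = s <= n_regulatory
        if regulatory:
            enh_lo = causal_pos0 - ENHANCER_HALFWIDTH
            enh_hi = causal_pos0 + ENHANCER_HALFWIDTH + 1
            hmm["melanocyte"].append((chrom, enh_lo, enh_hi, "EnhA1"))
            hmm["melanoma"].append((chrom, enh_lo, enh_hi, "4_EnhA"))
            atac["melanocyte"].append((chrom, enh_lo, enh_hi))
            atac["melanoma"].append((chrom, enh_lo, enh_hi))
            truth.true_regulatory_elements.append((chrom, enh_lo, enh_hi))

        loop_counter += 1
        score = float(
            rng_loop.uniform(*config.loop_true_score_range)
        )
        bc, bs, be = bin_hull_1based(causal_bin)
        oc, os_, oe = bin_hull_1based(promoter_bin)
        ibed_rows.append(
            {
                "bait_chr": bc,
                "bait_start": bs,
                "bait_end": be,
                "bait_name": f"signal{s}_enh",
                "otherEnd_chr": oc,
                "otherEnd_start": os_,
                "otherEnd_end": oe,
                "otherEnd_name": gene_id,
                "N_reads": int(rng_loop.integers(20, 200)),
                "score": round(score, 2),
            }
        )
        for i, vid in enumerate(vids):
            is_causal = vid == causal_id
            mpra_rows.append(
                {
                    "variant_id": vid,
                    "tested": True,
                    "fdr_sig_melanocyte": bool(is_causal and regulatory),
                    "fdr_sig_melanoma": bool(is_causal and regulatory),
                }
            )
        qtl_rows.append(
            {
                "signal_id": s,
                "gene_id": gene_id,
                "eqtl_or_twas": False,
                "meqtl_or_mwas": False,
            }
        )
        truth.causal_variants[s] = causal_id
        truth.true_genes[s] = gene_id
        truth.true_links.add((causal_id, gene_id))

    # decoy loops: from a causal's bin to a different signal's gene promoter
    n_decoys = round(config.loop_noise_rate * config.n_signals)
    decoy_seen: set[tuple[int, int]] = set()
    attempts = 0
    while len(truth.decoy_loops) < n_decoys and attempts < 50 * max(1, n_decoys):
        attempts += 1
        s = int(rng_loop.integers(1, config.n_signals + 1))
        g = int(rng_loop.integers(1, config.n_signals + 1))
        if config.n_signals > 1 and g == s:
            continue
        if config.n_signals == 1:
            break  # no wrong gene available
        causal_id = truth.causal_variants[s]
        wrong_gene = truth.true_genes[g]
        crow = [
            r for f in sumstats_frames for r in f.itertuples()
            if r.variant_id == causal_id
        ][0]
        causal_bin = fmap.bin_at(crow.chrom, int(crow.pos) - 1).bin_id
        wc, wt = tss_of[wrong_gene]
        wrong_bin = fmap.bin_at(wc, wt - 1).bin_id
        if crow.chrom != wc:
            continue  # cis only
        if (causal_bin, wrong_bin) in decoy_seen:
            continue
        decoy_seen.add((causal_bin, wrong_bin))
        loop_counter += 1
        loop_name = f"decoy_{loop_counter}"
        bc, bs, be = bin_hull_1based(causal_bin)
        oc, os_, oe = bin_hull_1based(wrong_bin)
        ibed_rows.append(
            {
                "bait_chr": bc,
                "bait_start": bs,
                "bait_end": be,
                "bait_name": loop_name,
                "otherEnd_chr": oc,
                "otherEnd_start": os_,
                "otherEnd_end": oe,
                "otherEnd_name": wrong_gene,
                "N_reads": int(rng_loop.integers(20, 200)),
                "score": round(float(rng_loop.uniform(5.0, 10.0)), 2),
            }
        )
        truth.decoy_loops.append(loop_name)

    # decoy ATAC peaks on empty ground, away from variants and TSSs
    for _ in range(n_decoys):
        chrom = list(genome.sequences)[0]
        pos = int(rng_loop.integers(0, len(genome.sequences[chrom]) - 400))
        atac["melanocyte"].append((chrom, pos, pos + 200))

    # one planted driver gene for scoring exercises
    if truth.true_genes:
        first_gene = truth.true_genes[1]
        truth.driver_genes[first_gene] = (True, False)

    # expression: every gene comfortably above the low-expression cutoff
    gene_ids = [t["gene_id"] for t in genome.transcripts]
    expr = pd.DataFrame(
        rng_expr.lognormal(mean=2.0, sigma=0.5,
                           size=(len(gene_ids), config.n_expression_samples)),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=[f"S{i + 1}" for i in range(config.n_expression_samples)],
    ).round(4)

    sumstats = (
        pd.concat(sumstats_frames, ignore_index=True)
        if sumstats_frames
        else pd.DataFrame(columns=["variant_id", "chrom", "pos", "beta", "se", "p"])
    )
    sumstats["beta"] = sumstats["beta"].round(6)
    sumstats["p"] = sumstats["p"].apply(lambda x: float(f"{x:.6g}"))

    drivers = pd.DataFrame(
        [
            {"gene_id": g, "melanoma_driver": v[0], "pancancer_driver": v[1]}
            for g, v in sorted(truth.driver_genes.items())
        ],
        columns=["gene_id", "melanoma_driver", "pancancer_driver"],
    )

    return SyntheticBundle(
        config=config,
        genome=genome,
        sumstats=sumstats,
        ld=pd.DataFrame(ld_rows, columns=["id_a", "id_b", "r2"]).round(6),
        bayes=pd.DataFrame(bayes_rows, columns=["variant_id", "signal_id", "pip"]),
        signals=pd.DataFrame(
            signal_rows,
            columns=["signal_id", "locus_id", "lead_variant_id", "is_secondary"],
        ),
        targets=pd.DataFrame(target_rows, columns=["chrom", "start", "end"]),
        chromhmm={
            ctx: pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
            for ctx, rows in hmm.items()
        },
        atac={
            ctx: pd.DataFrame(rows, columns=["chrom", "start", "end"])
            for ctx, rows in atac.items()
        },
        interactions=pd.DataFrame(
            ibed_rows,
            columns=[
                "bait_chr",
                "bait_start",
                "bait_end",
                "bait_name",
                "otherEnd_chr",
                "otherEnd_start",
                "otherEnd_end",
                "otherEnd_name",
                "N_reads",
                "score",
            ],
        ),
        mpra=pd.DataFrame(
            mpra_rows,
            columns=["variant_id", "tested", "fdr_sig_melanocyte", "fdr_sig_melanoma"],
        ),
        qtl=pd.DataFrame(
            qtl_rows, columns=["signal_id", "gene_id", "eqtl_or_twas", "meqtl_or_mwas"]
        ),
        drivers=drivers,
        expression=expr,
        truth=truth,
    )


def generate(config: SyntheticConfig, outdir: Optional[str] = None) -> SyntheticBundle:
    """Full universe: genome, fragment map, planted architecture; optionally
    written to ``outdir``."""
    genome = generate_genome(config)
    fmap = FragmentMap.from_sequences(genome.sequences, k=config.bin_k)
    bundle = plant_architecture(genome, config, fmap)
    if outdir is not None:
        bundle.write(outdir)
    return bundle
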