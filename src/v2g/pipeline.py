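"""End-to-end orchestration: finemap -> fragments -> promoters -> linking ->
evidence -> scoring, from a structured config, with a deterministic output
bundle and a run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import evidence as ev
from . import finemap as fm
from . import fragments as fr
from . import io as vio
from . import linking as lk
from . import promoters as pm
from . import scoring as sc
from .synthetic import FILENAMES

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    input_dir: str
    out_dir: str
    seed: int = 0
    # paper-constant thresholds, all overridable
    llr_ratio: float = 0.01
    r2: float = 0.8
    chicago_score: float = 5.0
    adjacency_window: int = 500
    promoter_flank: int = 2_500
    alt_promoter_sep: int = 10_000
    bin_k: int = 4
    marginal_p: float = 0.05
    rsem_low: float = 0.1
    low_fraction: float = 0.20
    finemap_window: int = 10_000  # summary-stat window around each lead
    files: dict = field(default_factory=dict)  # overrides for FILENAMES

    def path(self, key: str) -> str:
        return os.path.join(self.input_dir, self.files.get(key, FILENAMES[key]))

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        """Hash of the run parameters (paths excluded, so the same analysis
        in a different location hashes identically)."""
        params = dataclasses.asdict(self)
        params.pop("input_dir")
        params.pop("out_dir")
        return hashlib.sha256(
            json.dumps(params, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    ccvs: pd.DataFrame
    links: pd.DataFrame
    link_objs: list
    evidence: pd.DataFrame
    scores: pd.DataFrame
    rank_counts: dict
    signal_summary: pd.DataFrame
    signal_medians: dict
    high_confidence: dict
    coverage: dict
    manifest: dict


def _file_sha(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"[{stage}] {err}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    os.makedirs(config.out_dir, exist_ok=True)
    outputs: dict[str, str] = {}

    def out(name: str) -> str:
        p = os.path.join(config.out_dir, name)
        outputs[name] = p
        return p

    # ---------------------------------------------------------------- finemap
    try:
        sumstats = vio.read_tsv(config.path("sumstats"))
        signals_df = vio.read_tsv(config.path("signals"))
        ld = fm.LdTable.from_frame(vio.read_tsv(config.path("ld")))
        bayes_path = config.path("bayes")
        bayes = (
            vio.read_tsv(bayes_path) if os.path.exists(bayes_path) else pd.DataFrame(
                columns=["variant_id", "signal_id", "pip"])
        )
        records = [
            fm.SummaryStatRecord(
                str(r.variant_id), str(r.chrom), int(r.pos),
                float(r.beta), float(r.se), float(r.p),
            )
            for r in sumstats.itertuples()
        ]
        by_id = {r.variant_id: r for r in records}
        all_ccvs: list[fm.CredibleVariant] = []
        for srow in signals_df.itertuples():
            sig = fm.RiskSignal(
                int(srow.signal_id), int(srow.locus_id),
                str(srow.lead_variant_id), bool(srow.is_secondary),
            )
            lead_rec = by_id.get(sig.lead_variant_id)
            if lead_rec is not None:
                window_records = [
                    r
                    for r in records
                    if r.chrom == lead_rec.chrom
                    and abs(r.pos - lead_rec.pos) <= config.finemap_window
                ]
            else:
                window_records = []
            bayes_members = set(
                bayes.loc[bayes.signal_id == sig.signal_id, "variant_id"].astype(str)
            )
            all_ccvs.extend(
                fm.finemap_signal(
                    sig, window_records, ld, bayes_members,
                    llr_threshold=config.llr_ratio, r2_threshold=config.r2,
                )
            )
        ccvs_df = fm.ccvs_to_frame(all_ccvs)
        vio.write_tsv(ccvs_df, out("ccvs.tsv"))
    except Exception as e:  # noqa: BLE001
        raise StageError("finemap", e) from e

    # -------------------------------------------------------------- fragments
    try:
        sequences = vio.read_fasta(config.path("fasta"))
        fmap = fr.FragmentMap.from_sequences(sequences, k=config.bin_k)
        targets = vio.read_bed(config.path("targets"))
        fr.build_baitmap(
            fmap.bins,
            fmap.fragments,
            [(str(r.chrom), int(r.start), int(r.end)) for r in targets.itertuples()],
        )
        fr.write_rmap(fmap.fragments, out("rmap.txt"))
        fr.write_baitmap(fmap.bins, out("baitmap.txt"))
        placements: dict[str, lk.CcvPlacement] = {}
        for cv in all_ccvs:
            rec = by_id.get(cv.variant_id)
            if rec is None:
                logger.warning("CCV %s has no summary record; skipped in linking",
                               cv.variant_id)
                continue
            assignment = fr.assign_variant_bins(
                cv.variant_id, rec.chrom, rec.pos, fmap,
                window=config.adjacency_window,
            )
            placements[cv.variant_id + f"@{cv.signal_id}"] = lk.CcvPlacement(
                cv.variant_id, cv.signal_id, rec.chrom, rec.pos, assignment
            )
        coverage = fr.coverage_report(
            [p.assignment for p in placements.values()], fmap
        )
        pd.DataFrame([coverage]).to_csv(out("coverage.tsv"), sep="\t", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError("fragments", e) from e

    # -------------------------------------------------------------- promoters
    try:
        gtf = vio.read_gtf(config.path("gtf"))
        transcripts = pm.transcripts_from_frame(gtf)
        chrom_lengths = {c: len(s) for c, s in sequences.items()}
        all_promoters: list[pm.PromoterRegion] = []
        for ctx in ("melanocyte", "melanoma"):
            seg = vio.read_bed(
                config.path(f"chromhmm_{ctx}"),
                names=("chrom", "start", "end", "state"),
            )
            proms = pm.build_chromhmm_promoters(seg, ctx)
            pm.assign_genes_to_promoters(proms, transcripts, reach=config.promoter_flank)
            all_promoters.extend(proms)
        all_promoters.extend(
            pm.build_global_promoters(
                transcripts, flank=config.promoter_flank, chrom_lengths=chrom_lengths
            )
        )
        vio.write_tsv(pm.promoters_to_frame(all_promoters), out("promoters.tsv"))
    except Exception as e:  # noqa: BLE001
        raise StageError("promoters", e) from e

    # ---------------------------------------------------------------- linking
    try:
        loops = lk.load_interactions(
            config.path("interactions"), fmap, score_threshold=config.chicago_score
        )
        links = lk.link_variants_to_genes(
            list(placements.values()), loops, all_promoters, fmap, transcripts
        )
        lk.flag_alternative_promoter(links, min_separation=config.alt_promoter_sep)
        links_df = lk.links_to_frame(links)
        vio.write_tsv(links_df, out("links.tsv"))
        sig_summary, medians = lk.summarize_signals(
            links, signals_df.signal_id.tolist()
        )
        vio.write_tsv(sig_summary, out("signal_summary.tsv"))
        lk.write_washu_track(
            links,
            {p.variant_id: p for p in placements.values()},
            fmap,
            out("links_washu.txt"),
        )
    except Exception as e:  # noqa: BLE001
        raise StageError("linking", e) from e

    # --------------------------------------------------------------- evidence
    try:
        atac = {
            ctx: vio.read_bed(config.path(f"atac_{ctx}"))
            for ctx in ("melanocyte", "melanoma")
        }
        hmm = {
            ctx: vio.read_bed(
                config.path(f"chromhmm_{ctx}"),
                names=("chrom", "start", "end", "state"),
            )
            for ctx in ("melanocyte", "melanoma")
        }
        reg = ev.annotate_regulatory(list(placements.values()), atac, hmm)
        mpra_path = config.path("mpra")
        mpra: dict[str, ev.MpraResult] = {}
        if os.path.exists(mpra_path):
            for r in vio.read_tsv(mpra_path).itertuples():
                mpra[str(r.variant_id)] = ev.MpraResult(
                    str(r.variant_id), bool(r.tested),
                    bool(r.fdr_sig_melanocyte), bool(r.fdr_sig_melanoma),
                )
        else:
            logger.warning("MPRA file missing; high-confidence set will be empty")
        qtl: dict[tuple[int, str], ev.QtlEvidence] = {}
        qtl_path = config.path("qtl")
        if os.path.exists(qtl_path):
            for r in vio.read_tsv(qtl_path).itertuples():
                qtl[(int(r.signal_id), str(r.gene_id))] = ev.QtlEvidence(
                    int(r.signal_id), str(r.gene_id),
                    bool(r.eqtl_or_twas), bool(r.meqtl_or_mwas),
                )
        drivers: dict[str, tuple[bool, bool]] = {}
        drv_path = config.path("drivers")
        if os.path.exists(drv_path):
            for r in vio.read_tsv(drv_path).itertuples():
                drivers[str(r.gene_id)] = (
                    bool(r.melanoma_driver), bool(r.pancancer_driver)
                )
        expression: dict[str, tuple[bool, bool]] = {}
        expr_path = config.path("expression")
        if os.path.exists(expr_path):
            matrix = pd.read_csv(expr_path, sep="\t", index_col=0)
            retained, _pct = ev.expression_filter(
                matrix, threshold=config.rsem_low,
                max_low_fraction=config.low_fraction,
            )
            for g in matrix.index:
                keep = g in retained
                expression[str(g)] = (keep, keep)
        gwas_p = {r.variant_id: r.p for r in records}
        ev_records = ev.build_evidence_records(
            links, reg, mpra, qtl, drivers, expression, gwas_p
        )
        ev_df = ev.records_to_frame(ev_records)
        vio.write_tsv(ev_df, out("evidence.tsv"))
        hc_variants, hc_genes, hc_signals = ev.high_confidence_set(
            ev_records, links, reg, mpra
        )
        hc = {
            "variants": sorted(hc_variants),
            "genes": sorted(hc_genes),
            "signals": sorted(hc_signals),
        }
        with open(out("high_confidence.json"), "w") as fh:
            json.dump(hc, fh, indent=1, sort_keys=True)
    except Exception as e:  # noqa: BLE001
        raise StageError("evidence", e) from e

    # ---------------------------------------------------------------- scoring
    try:
        scores = sc.score_records(ev_records)
        ranking, counts = sc.rank_genes(scores)
        vio.write_tsv(ranking, out("scores.tsv"))
    except Exception as e:  # noqa: BLE001
        raise StageError("scoring", e) from e

    # --------------------------------------------------------------- manifest
    manifest = {
        "config_hash": config.digest(),
        "row_counts": {
            "ccvs": int(len(ccvs_df)),
            "links": int(len(links_df)),
            "evidence": int(len(ev_df)),
            "scores": int(len(ranking)),
            "high_confidence_genes": len(hc["genes"]),
            "high_confidence_variants": len(hc["variants"]),
            "high_confidence_signals": len(hc["signals"]),
        },
        "funnel": {
            "n_variants": int(ccvs_df.variant_id.nunique()),
            "n_linked_variants": int(links_df.variant_id.nunique()) if len(links_df) else 0,
            "n_regulatory_variants": sum(
                1 for a in reg.values() if a.any_regulatory
            ),
            "n_high_confidence_variants": len(hc["variants"]),
        },
        "rank_counts": counts,
        "coverage": coverage,
        "outputs": {},
    }
    manifest_path = os.path.join(config.out_dir, "manifest.json")
    for name, path in sorted(outputs.items()):
        manifest["outputs"][name] = _file_sha(path)
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return PipelineResult(
        ccvs=ccvs_df,
        links=links_df,
        link_objs=links,
        evidence=ev_df,
        scores=ranking,
        rank_counts=counts,
        signal_summary=sig_summary,
        signal_medians=medians,
        high_confidence=hc,
        coverage=coverage,
        manifest=manifest,
    )
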