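"""Evidence overlay: regulatory regions, MPRA, QTL flags, expression, drivers.

Aggregates per-(signal, gene) evidence over the variants that link them,
with a strictly nested variant ladder: linked => regulatory => MPRA
significant => marginal eQTL. The high-confidence set is every gene linked
by a regulatory, MPRA-significant variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import vocab
from .linking import CcvPlacement, VariantGeneLink

MARGINAL_P = 0.05
RSEM_LOW = 0.1
LOW_FRACTION = 0.20


@dataclass
class RegulatoryAnnotation:
    variant_id: str
    atac_melanocyte: bool = False
    atac_melanoma: bool = False
    chromhmm_regulatory_melanocyte: bool = False
    chromhmm_regulatory_melanoma: bool = False

    @property
    def any_regulatory(self) -> bool:
        return (
            self.atac_melanocyte
            or self.atac_melanoma
            or self.chromhmm_regulatory_melanocyte
            or self.chromhmm_regulatory_melanoma
        )

    @property
    def both_assays(self) -> bool:
        """Regulatory by ATAC and by ChromHMM (stricter AND set)."""
        return (self.atac_melanocyte or self.atac_melanoma) and (
            self.chromhmm_regulatory_melanocyte or self.chromhmm_regulatory_melanoma
        )

    def regulatory_in(self, context: str) -> bool:
        if context == vocab.MELANOCYTE:
            return self.atac_melanocyte or self.chromhmm_regulatory_melanocyte
        return self.atac_melanoma or self.chromhmm_regulatory_melanoma


@dataclass(frozen=True)
class MpraResult:
    variant_id: str
    tested: bool
    fdr_sig_melanocyte: bool = False
    fdr_sig_melanoma: bool = False

    def __post_init__(self) -> None:
        if not self.tested and (self.fdr_sig_melanocyte or self.fdr_sig_melanoma):
            raise ValueError(f"{self.variant_id}: untested yet significant")

    @property
    def significant(self) -> bool:
        return self.fdr_sig_melanocyte or self.fdr_sig_melanoma

    def significant_in(self, context: str) -> bool:
        if context == vocab.MELANOCYTE:
            return self.fdr_sig_melanocyte
        return self.fdr_sig_melanoma


@dataclass(frozen=True)
class QtlEvidence:
    signal_id: int
    gene_id: str
    eqtl_or_twas: bool = False
    meqtl_or_mwas: bool = False


@dataclass
class EvidenceRecord:
    signal_id: int
    gene_id: str
    linked: bool = False
    best_variant_id: str = ""
    var_regulatory: bool = False
    var_mpra_sig: bool = False
    var_marginal_eqtl: bool = False
    meqtl_or_mwas: bool = False
    eqtl_or_twas: bool = False
    driver_melanoma: bool = False
    driver_pancancer: bool = False
    expressed_melanocyte: bool = True
    expressed_melanoma: bool = True
    protein_coding_nomination: bool = False

    def check_nesting(self) -> None:
        if self.var_marginal_eqtl and not self.var_mpra_sig:
            raise ValueError("var_marginal_eqtl requires var_mpra_sig")
        if self.var_mpra_sig and not self.var_regulatory:
            raise ValueError("var_mpra_sig requires var_regulatory")
        if self.var_regulatory and not self.linked:
            raise ValueError("var_regulatory requires linked")


def _point_in_bed(chrom: str, pos: int, bed: pd.DataFrame) -> bool:
    # bed is 0-based half-open; pos is 1-based
    if bed is None or bed.empty:
        return False
    sub = bed[bed.chrom == chrom]
    return bool(((sub.start < pos) & (sub.end >= pos)).any())


def annotate_regulatory(
    ccvs: Sequence[CcvPlacement],
    atac_by_context: Mapping[str, pd.DataFrame],
    chromhmm_by_context: Mapping[str, pd.DataFrame],
) -> dict[str, RegulatoryAnnotation]:
    """Point-overlap of each variant with ATAC peaks and regulatory-state
    ChromHMM segments, per cell context."""
    out: dict[str, RegulatoryAnnotation] = {}
    reg_segments = {}
    for ctx, seg in chromhmm_by_context.items():
        if seg is None or seg.empty:
            reg_segments[ctx] = seg
        else:
            reg_segments[ctx] = seg[
                seg.state.isin(vocab.REGULATORY_STATES[ctx])
            ].reset_index(drop=True)
    for ccv in ccvs:
        ann = RegulatoryAnnotation(ccv.variant_id)
        ann.atac_melanocyte = _point_in_bed(
            ccv.chrom, ccv.pos, atac_by_context.get(vocab.MELANOCYTE)
        )
        ann.atac_melanoma = _point_in_bed(
            ccv.chrom, ccv.pos, atac_by_context.get(vocab.MELANOMA)
        )
        ann.chromhmm_regulatory_melanocyte = _point_in_bed(
            ccv.chrom, ccv.pos, reg_segments.get(vocab.MELANOCYTE)
        )
        ann.chromhmm_regulatory_melanoma = _point_in_bed(
            ccv.chrom, ccv.pos, reg_segments.get(vocab.MELANOMA)
        )
        out[ccv.variant_id] = ann
    return out


def marginal_eqtl_test(
    dosage: np.ndarray,
    expression: np.ndarray,
    covariates: Optional[np.ndarray] = None,
) -> Optional[tuple[float, float]]:
    """OLS of expression on dosage (+ covariates + intercept); returns
    (beta, two-sided p) for the dosage coefficient, or None when the
    dosage is constant (no test possible)."""
    dosage = np.asarray(dosage, dtype=float)
    expression = np.asarray(expression, dtype=float)
    n = len(dosage)
    if np.allclose(dosage, dosage[0]):
        return None
    cols = [np.ones(n), dosage]
    if covariates is not None and covariates.size:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.extend(cov.T)
    X = np.column_stack(cols)
    k = X.shape[1]
    if n <= k:
        raise ValueError("need more samples than parameters")
    coef, _, rank, _ = np.linalg.lstsq(X, expression, rcond=None)
    resid = expression - X @ coef
    dof = n - rank
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    beta = float(coef[1])
    if se == 0.0:
        return beta, 0.0
    t = beta / se
    p = float(2.0 * stats.t.sf(abs(t), dof))
    return beta, p


def expression_filter(
    matrix: pd.DataFrame,
    threshold: float = RSEM_LOW,
    max_low_fraction: float = LOW_FRACTION,
) -> tuple[list[str], pd.Series]:
    """Drop genes with value < threshold in strictly more than
    ``max_low_fraction`` of samples; return retained genes and each
    retained gene's median expression percentile across samples.

    ``matrix`` is genes x samples. Percentiles (0-100) are rank-based per
    sample among retained genes, with 100 for the top gene.
    """
    low_frac = (matrix < threshold).mean(axis=1)
    retained = matrix.index[low_frac <= max_low_fraction].tolist()
    kept = matrix.loc[retained]
    if kept.empty:
        return retained, pd.Series(dtype=float)
    pct = kept.rank(axis=0, pct=True) * 100.0
    return retained, pct.median(axis=1)


def _ladder_level(
    variant_id: str,
    gene_id: str,
    reg: Mapping[str, RegulatoryAnnotation],
    mpra: Mapping[str, MpraResult],
    marginal_p: Mapping[tuple[str, str], float],
    context: Optional[str] = None,
) -> int:
    """Depth 1-4 of the nested variant ladder for a linking variant."""
    level = 1  # linked by construction
    ann = reg.get(variant_id)
    if ann is None:
        return level
    regulatory = ann.regulatory_in(context) if context else ann.any_regulatory
    if not regulatory:
        return level
    level = 2
    mp = mpra.get(variant_id)
    sig = (
        mp is not None
        and mp.tested
        and (mp.significant_in(context) if context else mp.significant)
    )
    if not sig:
        return level
    level = 3
    p = marginal_p.get((variant_id, gene_id))
    if p is not None and p < MARGINAL_P:
        level = 4
    return level


def build_evidence_records(
    links: Sequence[VariantGeneLink],
    reg: Mapping[str, RegulatoryAnnotation],
    mpra: Mapping[str, MpraResult],
    qtl: Mapping[tuple[int, str], QtlEvidence] = {},
    drivers: Mapping[str, tuple[bool, bool]] = {},
    expression: Mapping[str, tuple[bool, bool]] = {},
    gwas_p: Mapping[str, float] = {},
    marginal_p: Mapping[tuple[str, str], float] = {},
    context: Optional[str] = None,
    protein_coding: Mapping[tuple[int, str], bool] = {},
) -> list[EvidenceRecord]:
    """One EvidenceRecord per (signal, gene), with variant flags computed
    over the same linking variant (ladder nesting enforced).

    Pass ``context`` to restrict regulatory/MPRA evidence to one cell
    context (used for cell-type-specificity re-runs).
    """
    by_pair: dict[tuple[int, str], list[VariantGeneLink]] = {}
    for lk in links:
        by_pair.setdefault((lk.signal_id, lk.gene_id), []).append(lk)
    records: list[EvidenceRecord] = []
    pairs = set(by_pair) | set(protein_coding)
    for sid, gid in sorted(pairs, key=lambda p: (p[0], p[1])):
        pair_links = by_pair.get((sid, gid), [])
        rec = EvidenceRecord(signal_id=sid, gene_id=gid, linked=bool(pair_links))
        rec.protein_coding_nomination = bool(protein_coding.get((sid, gid), False))
        variants = sorted({lk.variant_id for lk in pair_links})
        best_level, best_var = 0, ""
        for vid in variants:
            level = _ladder_level(vid, gid, reg, mpra, marginal_p, context)
            key = (-level, gwas_p.get(vid, 1.0), vid)
            if best_var == "" or key < (
                -best_level,
                gwas_p.get(best_var, 1.0),
                best_var,
            ):
                best_level, best_var = level, vid
        rec.best_variant_id = best_var
        rec.var_regulatory = best_level >= 2
        rec.var_mpra_sig = best_level >= 3
        rec.var_marginal_eqtl = best_level >= 4
        q = qtl.get((sid, gid))
        if q is not None:
            rec.eqtl_or_twas = q.eqtl_or_twas
            rec.meqtl_or_mwas = q.meqtl_or_mwas
        if gid in drivers:
            rec.driver_melanoma, rec.driver_pancancer = drivers[gid]
        if gid in expression:
            rec.expressed_melanocyte, rec.expressed_melanoma = expression[gid]
        rec.check_nesting()
        records.append(rec)
    return records


def high_confidence_set(
    records: Sequence[EvidenceRecord],
    links: Sequence[VariantGeneLink] = (),
    reg: Mapping[str, RegulatoryAnnotation] = {},
    mpra: Mapping[str, MpraResult] = {},
    context: Optional[str] = None,
) -> tuple[set[str], set[str], set[int]]:
    """(variant set, gene set, signal set) for genes linked by a
    regulatory, MPRA-significant variant."""
    genes = {r.gene_id for r in records if r.var_mpra_sig}
    signals = {r.signal_id for r in records if r.var_mpra_sig}
    hc_pairs = {(r.signal_id, r.gene_id) for r in records if r.var_mpra_sig}
    variants: set[str] = set()
    for lk in links:
        if (lk.signal_id, lk.gene_id) not in hc_pairs:
            continue
        ann = reg.get(lk.variant_id)
        mp = mpra.get(lk.variant_id)
        if ann is None or mp is None or not mp.tested:
            continue
        regulatory = ann.regulatory_in(context) if context else ann.any_regulatory
        sig = mp.significant_in(context) if context else mp.significant
        if regulatory and sig:
            variants.add(lk.variant_id)
    return variants, genes, signals


def cell_type_specificity(
    links: Sequence[VariantGeneLink],
    reg: Mapping[str, RegulatoryAnnotation],
    mpra: Mapping[str, MpraResult],
    **kwargs,
) -> dict[str, set[str]]:
    """Classify high-confidence genes as melanocyte-only, melanoma-only or
    shared by re-running the evidence filter per single context."""
    sets = {}
    for ctx in vocab.CONTEXTS:
        recs = build_evidence_records(links, reg, mpra, context=ctx, **kwargs)
        _, genes, _ = high_confidence_set(recs, links, reg, mpra, context=ctx)
        sets[ctx] = genes
    return {
        "melanocyte_only": sets[vocab.MELANOCYTE] - sets[vocab.MELANOMA],
        "melanoma_only": sets[vocab.MELANOMA] - sets[vocab.MELANOCYTE],
        "shared": sets[vocab.MELANOCYTE] & sets[vocab.MELANOMA],
    }


def records_to_frame(records: Sequence[EvidenceRecord]) -> pd.DataFrame:
    rows = [vars(r).copy() for r in records]
    return pd.DataFrame(rows)
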