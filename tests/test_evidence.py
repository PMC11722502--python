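import numpy as np
import pandas as pd
import pytest

from v2g import vocab
from v2g.evidence import (
    EvidenceRecord,
    MpraResult,
    QtlEvidence,
    RegulatoryAnnotation,
    annotate_regulatory,
    build_evidence_records,
    cell_type_specificity,
    expression_filter,
    high_confidence_set,
    marginal_eqtl_test,
)
from v2g.fragments import VariantBinAssignment
from v2g.linking import CcvPlacement, VariantGeneLink


def ccv(vid, chrom="chr1", pos=150):
    return CcvPlacement(vid, 1, chrom, pos, VariantBinAssignment(vid, 1, ()))


def link(vid, gene, sid=1):
    return VariantGeneLink(vid, sid, gene, "loop")


def bed(rows, cols=("chrom", "start", "end")):
    return pd.DataFrame(rows, columns=list(cols))


class TestAnnotateRegulatory:
    def test_atac_overlap(self):
        reg = annotate_regulatory(
            [ccv("v")],
            {vocab.MELANOCYTE: bed([("chr1", 100, 200)]), vocab.MELANOMA: bed([])},
            {vocab.MELANOCYTE: bed([], ("chrom", "start", "end", "state")),
             vocab.MELANOMA: bed([], ("chrom", "start", "end", "state"))},
        )
        assert reg["v"].atac_melanocyte and not reg["v"].atac_melanoma
        assert reg["v"].any_regulatory

    def test_enhancer_state_lookup(self):
        reg = annotate_regulatory(
            [ccv("v")],
            {vocab.MELANOCYTE: bed([]), vocab.MELANOMA: bed([])},
            {
                vocab.MELANOCYTE: bed(
                    [("chr1", 100, 200, "EnhWk")], ("chrom", "start", "end", "state")
                ),
                vocab.MELANOMA: bed([], ("chrom", "start", "end", "state")),
            },
        )
        assert reg["v"].chromhmm_regulatory_melanocyte
        assert not reg["v"].chromhmm_regulatory_melanoma

    def test_quies_all_false(self):
        reg = annotate_regulatory(
            [ccv("v")],
            {vocab.MELANOCYTE: bed([]), vocab.MELANOMA: bed([])},
            {
                vocab.MELANOCYTE: bed(
                    [("chr1", 100, 200, "Quies")], ("chrom", "start", "end", "state")
                ),
                vocab.MELANOMA: bed([], ("chrom", "start", "end", "state")),
            },
        )
        assert not reg["v"].any_regulatory


class TestMarginalEqtl:
    def test_noiseless_slope(self):
        dosage = np.array([0, 1, 2, 0, 1, 2, 0, 1.0])
        beta, p = marginal_eqtl_test(dosage, 2 * dosage)
        assert beta == pytest.approx(2.0)
        assert p < 1e-10

    def test_constant_dosage_no_test(self):
        assert marginal_eqtl_test(np.ones(10), np.arange(10.0)) is None

    def test_normal_equations_oracle(self, rng):
        n = 8
        dosage = rng.integers(0, 3, n).astype(float)
        dosage[0] = 0; dosage[1] = 2  # ensure variation
        cov = rng.normal(size=(n, 2))
        y = rng.normal(size=n)
        beta, p = marginal_eqtl_test(dosage, y, cov)
        X = np.column_stack([np.ones(n), dosage, cov])
        oracle = np.linalg.solve(X.T @ X, X.T @ y)[1]
        assert beta == pytest.approx(oracle, abs=1e-10)

    def test_type_one_error_calibration(self):
        # null simulations: dosage independent of expression
        rng = np.random.default_rng(1)
        n, n_cov, sims = 100, 5, 1000
        rejections = 0
        for _ in range(sims):
            dosage = rng.integers(0, 3, n).astype(float)
            cov = rng.normal(size=(n, n_cov))
            y = rng.normal(size=n)
            res = marginal_eqtl_test(dosage, y, cov)
            if res is not None and res[1] < 0.05:
                rejections += 1
        rate = rejections / sims
        assert 0.03 <= rate <= 0.07


class TestExpressionFilter:
    def test_all_zero_gene_excluded(self):
        m = pd.DataFrame(
            {"s1": [0.0, 5.0], "s2": [0.0, 6.0]}, index=["dead", "alive"]
        )
        retained, _ = expression_filter(m)
        assert retained == ["alive"]

    def test_boundary_exactly_20pct_retained(self):
        vals = [0.05, 0.05] + [1.0] * 8  # exactly 2/10 below threshold
        m = pd.DataFrame([vals, [0.05] * 3 + [1.0] * 7],
                         index=["edge", "out"],
                         columns=[f"s{i}" for i in range(10)])
        retained, _ = expression_filter(m)
        assert retained == ["edge"]

    def test_top_gene_percentile_100(self):
        m = pd.DataFrame(
            {"s1": [9.0, 1.0, 2.0], "s2": [8.0, 1.0, 2.0]},
            index=["top", "low", "mid"],
        )
        _, pct = expression_filter(m)
        assert pct["top"] == pytest.approx(100.0)


def _reg(vid, on=True):
    ann = RegulatoryAnnotation(vid)
    ann.chromhmm_regulatory_melanocyte = on
    return ann


class TestBuildEvidence:
    def test_full_ladder_gene(self):
        links = [link("v", "G")]
        reg = {"v": _reg("v")}
        mpra = {"v": MpraResult("v", True, True, False)}
        recs = build_evidence_records(
            links, reg, mpra, marginal_p={("v", "G"): 0.01}
        )
        (r,) = recs
        assert r.linked and r.var_regulatory and r.var_mpra_sig and r.var_marginal_eqtl
        assert r.best_variant_id == "v"

    def test_untested_mpra_breaks_ladder(self):
        links = [link("v", "G")]
        reg = {"v": _reg("v")}
        mpra = {"v": MpraResult("v", tested=False)}
        (r,) = build_evidence_records(links, reg, mpra)
        assert r.var_regulatory and not r.var_mpra_sig

    def test_deeper_variant_wins(self):
        links = [link("a", "G"), link("b", "G")]
        reg = {"a": _reg("a"), "b": _reg("b")}
        mpra = {
            "a": MpraResult("a", True, False, False),
            "b": MpraResult("b", True, True, False),
        }
        (r,) = build_evidence_records(links, reg, mpra)
        assert r.best_variant_id == "b" and r.var_mpra_sig

    def test_tie_breaks_by_gwas_p_then_id(self):
        links = [link("a", "G"), link("b", "G")]
        reg = {"a": _reg("a"), "b": _reg("b")}
        mpra = {}
        (r,) = build_evidence_records(
            links, reg, mpra, gwas_p={"a": 0.5, "b": 1e-8}
        )
        assert r.best_variant_id == "b"

    def test_nesting_invariant_holds(self):
        rng = np.random.default_rng(9)
        links, reg, mpra = [], {}, {}
        for i in range(30):
            vid = f"v{i}"
            links.append(link(vid, f"G{i % 5}"))
            reg[vid] = _reg(vid, on=bool(rng.integers(0, 2)))
            tested = bool(rng.integers(0, 2))
            mpra[vid] = MpraResult(
                vid, tested, tested and bool(rng.integers(0, 2)), False
            )
        for r in build_evidence_records(links, reg, mpra):
            r.check_nesting()  # raises on violation

    def test_marginal_eqtl_requires_p_below_005(self):
        links = [link("v", "G")]
        reg = {"v": _reg("v")}
        mpra = {"v": MpraResult("v", True, True, False)}
        (r,) = build_evidence_records(links, reg, mpra, marginal_p={("v", "G"): 0.05})
        assert not r.var_marginal_eqtl  # strict <


class TestHighConfidence:
    def test_no_mpra_empty(self):
        links = [link("v", "G")]
        recs = build_evidence_records(links, {"v": _reg("v")}, {})
        variants, genes, signals = high_confidence_set(recs, links, {"v": _reg("v")}, {})
        assert genes == set() and variants == set() and signals == set()

    def test_one_gene_per_signal(self):
        links, reg, mpra = [], {}, {}
        for sid in (1, 2, 3):
            vid = f"v{sid}"
            links.append(link(vid, f"G{sid}", sid=sid))
            reg[vid] = _reg(vid)
            mpra[vid] = MpraResult(vid, True, True, False)
        recs = build_evidence_records(links, reg, mpra)
        variants, genes, signals = high_confidence_set(recs, links, reg, mpra)
        assert len(signals) == 3 and len(genes) == 3 and len(variants) == 3

    def test_monotone_adding_evidence(self):
        links = [link("v", "G")]
        reg = {"v": _reg("v", on=False)}
        mpra = {"v": MpraResult("v", True, True, False)}
        recs = build_evidence_records(links, reg, mpra)
        _, genes0, _ = high_confidence_set(recs, links, reg, mpra)
        reg2 = {"v": _reg("v", on=True)}
        recs2 = build_evidence_records(links, reg2, mpra)
        _, genes1, _ = high_confidence_set(recs2, links, reg2, mpra)
        assert genes0 <= genes1

    def test_planted_universe_matches_ledger(self, noise_free_bundle):
        truth = noise_free_bundle.truth
        assert {g for _, g in truth.true_links} == set(truth.true_genes.values())


class TestCellTypeSpecificity:
    def test_melanocyte_only_gene(self):
        links = [link("v", "G")]
        ann = RegulatoryAnnotation("v")
        ann.chromhmm_regulatory_melanocyte = True
        reg = {"v": ann}
        mpra = {"v": MpraResult("v", True, fdr_sig_melanocyte=True)}
        out = cell_type_specificity(links, reg, mpra)
        assert out["melanocyte_only"] == {"G"}
        assert out["melanoma_only"] == set() and out["shared"] == set()

    def test_shared_gene(self):
        links = [link("v", "G")]
        ann = RegulatoryAnnotation("v")
        ann.chromhmm_regulatory_melanocyte = True
        ann.atac_melanoma = True
        reg = {"v": ann}
        mpra = {"v": MpraResult("v", True, True, True)}
        out = cell_type_specificity(links, reg, mpra)
        assert out["shared"] == {"G"}


class TestMpraResult:
    def test_untested_cannot_be_significant(self):
        with pytest.raises(ValueError):
            MpraResult("v", tested=False, fdr_sig_melanocyte=True)


class TestEvidenceRecordNesting:
    def test_violation_rejected(self):
        r = EvidenceRecord(1, "G", linked=False, var_regulatory=True)
        with pytest.raises(ValueError):
            r.check_nesting()
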