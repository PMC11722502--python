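# v2g — capture-HiC variant-to-gene mapping

Post-GWAS variant-to-gene analysis as a reusable pipeline: fine-map risk
signals from summary statistics, model dual-enzyme restriction fragments and
4-fragment bins, link credible variants to gene promoters through
high-confidence chromatin loops or direct promoter overlap, filter with
cell-type-specific regulatory and reporter-assay evidence, and rank candidate
genes with an integrative 0–8 score. A synthetic-data generator emulates
every input (genome, GWAS, LD, chromatin states, ATAC, loops, MPRA, QTL
flags) with a planted-truth ledger so the whole analysis runs and validates
at desk scale.

## Modules

| module | role |
| --- | --- |
| `v2g.synthetic` | toy universe generator with planted-truth ledger |
| `v2g.finemap` | CCV selection: LLR filter, LD expansion, Bayesian union |
| `v2g.fragments` | ^GATC / G^ANTC digestion, k-fragment bins, baitmap, ±500 b adjacency |
| `v2g.promoters` | chromatin-state and TSS±2.5 kb promoter definitions, gene assignment |
| `v2g.linking` | loop / promoter-overlap nomination, distance classes, alt-promoter flags |
| `v2g.evidence` | ATAC/ChromHMM/MPRA/QTL/driver/expression overlay, high-confidence set |
| `v2g.scoring` | integrative 0–8 gene score and per-signal ranking |
| `v2g.pipeline` + `v2g.cli` | end-to-end orchestration, manifest, CLI |

## CLI

```bash
v2g demo --seed 42 --out demo_inputs          # synthetic input bundle + ledger
# write a config pointing at the bundle:
python - <<'EOF'
from v2g.pipeline import PipelineConfig
PipelineConfig(input_dir="demo_inputs", out_dir="demo_out", seed=42).to_yaml("config.yaml")
EOF
v2g run --config config.yaml                  # full pipeline run
v2g score --evidence demo_out/evidence.tsv    # (re-)score an evidence table
```

Outputs (TSV/JSON plus CHiCAGO-dialect rmap/baitmap and a WashU long-range
track) land in the configured output directory together with a
`manifest.json` recording config hash, row counts and checksums; reruns with
the same seed are byte-identical.

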