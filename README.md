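# sigsearch

Signature search methods for transcriptomic drug repurposing.

Given an **oncogenic signature** — a ranked list of differentially
expressed genes with signed statistics (log fold changes) describing a
disease state — and a **pharmacotranscriptomic reference panel** — a
genes × drugs matrix of perturbation statistics in the style of LINCS
L1000 — `sigsearch` answers three questions a repurposing screen asks:

1. **Which scoring method, and which signature size, work best here?**
   Five signature search methods (SSMs) are implemented — XSum, CMap,
   GSEA, ZhangScore, XCos — each scoring the tailored TopN up/down tag
   sets of the signature against every drug column. Negative scores mean
   the drug *reverses* the signature (potentially therapeutic); positive
   scores mean it *mimics* it (agonistic). Method × TopN cells are
   benchmarked with two annotation-based indices (ROC **AUC** of
   Effective vs Ineffective drugs, higher is better; running-sum
   enrichment **ES** of known-effective drugs in the score ordering,
   lower is better), or — when annotations are scarce — with an
   annotation-free **drug self-retrieval** performance score.
2. **Which drugs should I shortlist?** Single-method queries, multi-method
   consensus via robust rank aggregation (each drug scored
   −log₁₀ of its aggregated rank P-value), and cross-signature quadrant
   analysis (drugs negative under two independent signatures are the
   promising lower-left corner).
3. **Can I trust the pipeline?** A seeded synthetic-data module plants
   known reversers into noise panels at a controlled effect size, so every
   stage is testable end to end without downloading anything.

## Worked example

```bash
sigsearch simulate --out demo/sim --n-genes 500 --n-drugs 50 \
    --n-effective 4 --n-deg 100 --effect-size 5 --seed 11
sigsearch benchmark --panel demo/sim/panel.gct \
    --signature demo/sim/signature.tsv \
    --auc-annotation demo/sim/annotation_auc.csv \
    --es-annotation demo/sim/annotation_es.csv \
    --topn-grid 25,50,100 --out demo/bench
```

which logs

```
INFO sigsearch: optimal AUC cell: CMap at TopN=25
INFO sigsearch: optimal ES cell: CMap at TopN=25
```

`demo/bench/benchmark_grid.tsv` holds one row per (method, TopN, index):
all 15 cells reach AUC 1.0 and ES −1.0 here because the planted effect
(5 noise standard deviations on 200 signature genes) overwhelms the
noise — the 4 planted reversers are the 4 most negative scores under
every method. Querying with the selected cell:

```bash
sigsearch query --panel demo/sim/panel.gct --signature demo/sim/signature.tsv \
    --method CMap --topn 25 --out demo/query
```

writes `demo/query/top.json`, whose `negative` block lists the four
planted drugs (compare `demo/sim/truth.json`) with scores −1.00 … −0.98,
i.e. the strongest predicted reversers (the fifth list entry is a
background drug trailing far behind at −0.29); `demo/query/scores.tsv`
has the full table with rank 1 = most negative. The same workflow runs purely in
Python via `sigsearch.simulate`, `benchmark_sweep`, `query_single`,
`ss_all`, `ss_cross`.

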