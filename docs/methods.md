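# Methods

## The scoring problem

A disease state is summarized as a gene signature: every gene carries a
signed differential-expression statistic (here generically "stat",
typically a log2 fold change). A reference panel records, for the same
gene universe, the expression shift each drug induces. A signature search
method (SSM) quantifies the concordance between the two: a drug that
pushes the signature's up-genes down and down-genes up *reverses* the
disease pattern and is a repurposing candidate. All five methods in this
package use the convention **negative = reversal (therapeutic), positive
= mimic (agonistic)**; the library never flips signs downstream, so a
score's sign can always be read directly.

## Tailored TopN filtration

Querying with the full signature dilutes the strongest biology, so the
signature is tailored to the TopN most up-regulated genes (descending
stat) and TopN most down-regulated genes (ascending stat). The two tag
sets are forced to equal size — a balanced representation of both
transcriptional directions — and ties in stat are broken by gene id so
results are identical across platforms and input orderings. A boolean
significance flag, when the input carries one, can restrict eligibility
(`require_significant`); no p-value threshold is imposed internally
because significance is an upstream decision. Selection is prefix-stable:
the TopN−1 tags are always a prefix of the TopN tags.

Signature genes absent from a panel are dropped per method with the
coverage reported (`validate_against_panel`); only a signature with zero
overlap is an error. The ZhangScore denominator shrinks accordingly, so
partial coverage never inflates a score.

## The five methods

With a drug's genes ranked by stat descending (position 1 = most
up-regulated) and t tags at sorted positions V(1..t) among n genes:

- **CMap.** The Kolmogorov–Smirnov running statistic per tag set is
  `a = max_j(j/t − V(j)/n)`, `b = max_j(V(j)/n − (j−1)/t)`, returning
  `a` if `a > b` else `−b`. The raw connectivity is `ks_up − ks_down`
  when the two statistics deviate in opposite directions, else 0 (the
  null rule). Raw scores are then panel-scaled: positives divided by the
  maximum positive, negatives by |minimum negative|, giving [−1, 1].
- **GSEA.** Per tag set, the weighted running-sum enrichment score: a
  hit at position p adds `|stat(p)|^w / Σ_hits |stat|^w`, a miss
  subtracts `1/(n−t)`; the score is the signed maximum deviation of the
  walk. Connectivity is `(ES_up − ES_down)/2` when the two enrichment
  scores disagree in sign, else 0. The weight exponent defaults to 1
  (stat-weighted); 0 gives the classic unweighted KS-like sum. An exact
  peak/−trough tie resolves to the positive branch, with a 1e−12
  tolerance so float rounding cannot flip the convention.
- **ZhangScore.** Tags get signed magnitude-ranks on both sides
  (signature: rank of |sig stat| among tags, signed by direction;
  reference: rank of |drug stat| among the same genes, signed by the
  drug stat). The score is the inner product normalized by the maximum
  achievable pairing `Σ k²`, hence exactly ±1 for perfect
  (anti)concordance.
- **XSum.** Sum of drug stats over up-tags minus down-tags, restricted
  to the drug's own extreme genes (top/bottom `extreme_n` by stat); tags
  outside the extremes contribute nothing. Unbounded, scale-carrying.
- **XCos.** Cosine similarity between signature stats and drug stats on
  the tag genes inside the extremes; an empty or zero-norm overlap
  yields 0 with a warning rather than an error, since a cosine of an
  empty set is undefined but harmless in a panel sweep.

`extreme_n` defaults to 500 genes per tail when the panel has ≥ 1000
genes (the customary eXtreme restriction at L1000 scale), otherwise half
the gene universe. Only CMap receives panel-wide rescaling; the other
methods are already bounded or deliberately scale-carrying.

## Benchmark indices

**AUC** is the ROC area of the *negated* score predicting the Effective
label (therapeutic drugs are expected to score negative); ties count 1/2,
so AUC is invariant under any strictly monotone transform of the scores
and `AUC + AUC(swapped labels) = 1` exactly. **ES** applies the same
running-sum machinery at the drug level: drugs sorted by score
descending, hits = the known-effective set, unweighted increments by
default (a drug-level stat weight has no natural default). Effective
drugs concentrated at the reversal end give ES near −1; *lower is
better*, mirroring the AUC's *higher is better*. The optimal cell is the
grid argmax (AUC) / argmin (ES), ties to smaller TopN then method name.
The default TopN grid is 50–500 in steps of 50, a span covering
customary signature sizes; it is user-overridable and infeasible cells
are recorded with their reason rather than aborting a sweep.

## Self-retrieval robustness

Without annotations, each drug's own column is tailored into a TopN
query and scored against the whole panel; the drug's rank in the
descending (mimic) ordering measures how sharply the method recognizes
its own profile. Ties share the mean rank. The summary is the normalized
mean rank `PS = mean((M − rank)/(M − 1))` in [0, 1]: 1 when every drug
self-retrieves first, 0.5 under random ranking, strictly decreasing in
any single rank. The formula is isolated in `performance_score` so an
alternative summary (top-k recall, AUC-style) can be swapped in one
place. Degradation is modeled by adding seeded Gaussian noise to the
column *before* deriving the query (replicate noise), scoring against
the clean panel. Ranked profiles are cached on the panel object, so the
M × M scoring loop and repeated (method, TopN) evaluations share the
expensive sort.

## Query strategies

**Single method** returns the full score table plus the top-k (default
5) drugs per sign. **Consensus** runs K ≥ 2 methods; per direction a
drug's normalized rank under a method is its rank among same-direction
drugs divided by the panel size M, and a method that does not place the
drug in that direction contributes the worst rank 1 (the unobserved-item
convention; a strict all-methods-agree mode is available). The
aggregated P-value is the minimum over k of the binomial tail
`P(k-th smallest of K uniforms ≤ r_(k))`, Bonferroni-corrected by K —
conservative under the null, monotone in every rank. The overall score
is −log₁₀(P) (base 10 is the conventional significance display).
**Cross-signature** scores two signatures with one shared method and
classifies drugs by sign pair into quadrants; an exactly zero score sits
on an axis and joins no quadrant. The promising list is the −− quadrant
ordered by the sum of the two scores.

## Annotation building

IC50 tables (micromolar) are collapsed per drug by the median (even
counts: mean of the middle two) and thresholded at 10 μM by default:
strictly below → Effective, at or above → Ineffective (the boundary case
is resolved to Ineffective because effectiveness is defined as *below*
the threshold). Identifier conversion maps through a unique-key table
and keeps only ids present in the panel's gene ∪ drug universe,
reporting unmapped and absent ids separately.

## Synthetic data

The generator emulates a desk-scale L1000-style screen. The signature
has `n_deg` up- and `n_deg` down-regulated genes at random positions
with shifted-exponential magnitudes (sorted decreasing within each
block, strongest first) over a near-zero background, plus a significance
flag marking the differential blocks. The panel is iid Gaussian noise
(`noise_sd`); `n_effective` randomly placed drugs are planted as
reversers — shifted by `effect_size · noise_sd` *against* the signature
direction on its differential genes — and an optional fraction of
planted mimics is shifted *with* it. Ground truth is exported in both
annotation modes. Defaults (1000 genes × 100 drugs, 5 reversers, 250
differential genes per direction, effect size 5, unit noise) are the
study conditions used throughout the tests and the acceptance script.

What the generator does **not** emulate: L1000 moderated z-score
marginals, gene–gene correlation, plate/batch structure, or
dose–response heterogeneity. Passing tests therefore demonstrate
correctness of the statistics and the planted-signal recovery contract,
not performance on real screens, where effect sizes are far smaller and
noise is structured.

## Numerical and design choices

- All randomness flows through `numpy.random.default_rng` seeded from a
  single integer; signature and panel draws use distinct child streams
  of that seed. Reruns are byte-identical (fixed 6-significant-digit
  serialization, sorted JSON keys, no timestamps in manifests).
- Deterministic tie-breaks everywhere: gene id for stat ties, drug id
  for score ties, smaller TopN then method name for grid optima, mean
  rank for self-retrieval ties.
- Problem sizes in the test-suite and acceptance runs (panels up to
  1000 × 100, 20 null replicates, a 40-drug self-retrieval panel) were
  chosen so the full pipeline exercises every path in seconds while
  keeping Monte-Carlo error well inside the asserted bands; the null ES
  band (±0.1 at 20 replicates) is the widest relative to its sampling
  noise (sd of the replicate mean ≈ 0.09), which is why those replicate
  seeds are fixed.
- The ES/GSEA positive-branch tie rule and the CMap null rule mean
  antisymmetry under stat negation holds exactly for XSum/XCos and up to
  null-rule zeroing for the other methods; the property tests encode
  exactly that contract.

## Limitations

- GCT support covers the 1.2/1.3 text formats (the text subset of
  L1000-style distributions), not binary GCTX/HDF5 archives.
- The robustness module's performance score is one defensible summary of
  self-retrieval ranks; alternatives exist and would change absolute
  values (not orderings of clearly separated methods).
- Consensus treats methods as exchangeable rankers; it does not model
  correlation between methods, so its P-values are screening scores, not
  calibrated significance levels.
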