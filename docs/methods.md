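# Methods

## Vote-counting meta-analysis

The unit of evidence is the *study report*: one study saying one gene moved
in one direction at adjusted *p* < 0.05. This suits literature corpora where
effect sizes are not comparable across platforms, tissues and species, at
the cost of ignoring magnitude entirely — no pooled log-fold-change or
random-effects model is attempted, deliberately.

Assumptions baked into the tally:

- **One report per gene per study.** Studies publishing several timepoints
  are collapsed to the single record with the smallest adjusted p-value
  (ties: larger |log2FC|, then up-regulation). The collapse choice is echoed
  in the run manifest; alternatives (latest timepoint, any-direction union)
  would change scores for multi-timepoint studies only.
- **Symbol-identity matching.** Cross-species harmonization is case-folded
  string equality (`Icam1` ≡ `ICAM1`), optionally composed with a
  user-supplied synonym map. No ortholog inference: a gene renamed between
  annotation releases counts as two genes. This mirrors how published DEG
  tables are actually cross-referenced and keeps the operation deterministic.
- **Strict significance boundary.** `adj_p < alpha`, so a table row at
  exactly 0.05 is excluded.

Thresholds and their defaults:

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | adjusted-p cutoff at ingest (strict `<`) |
| `min_consistency` | 0.75 | fraction of reports agreeing on direction (inclusive `>=`); 50/50 ties always fail |
| `min_reports` | 4 | score needed to enter the commonly-reported lists (with the default 7-study corpus: 4 of 7) |
| `max_fdr` | 0.05 | BH q cutoff for enriched terms (strict `<`) |
| `top_n` | 20 | terms kept per collection after the q filter |

Ranking ties (equal score) are broken by descending consistency then
ascending symbol purely so that outputs are byte-reproducible; the
underlying evidence cannot distinguish tied genes.

## Over-representation analysis

For a query of *n* genes inside a universe of *N*, a term with *K* members
in the universe and *k* query hits is scored with the hypergeometric upper
tail *P(X ≥ k)* (computed via `scipy.stats.hypergeom.sf`; identical to the
one-sided Fisher exact test of the 2×2 table). Choices a user should know:

- **Universe.** Defaults to the union of all collection members, since a
  curated reference list is rarely distributable with the collection;
  overridable with a background file. Query symbols outside the universe are
  dropped with a logged count — they cannot be scored.
- **BH scope.** The correction runs over terms with *k ≥ 1* only.
  Zero-overlap terms have p = 1 and carry no evidence; including them would
  only inflate *m* and dilute every q-value. Recorded in the manifest.
- **One-sided only.** Depletion is not tested.
- Degenerate inputs: an empty effective query is fatal with a diagnostic of
  how many symbols matched; a query overlapping no set returns an empty,
  valid result.

No gene-ontology graph topology is used (no parent propagation or
elim-style decorrelation): terms are treated as flat sets, so enriched
parent/child pairs will co-occur in the output.

## Venn partition

Organ sets are undirected symbol sets by default — a gene up in liver and
down in kidney still co-occurs — matching how published organ Venn diagrams
are drawn; `directional=true` keeps `SYM/up` and `SYM/down` distinct.
Signatures are ordered spinal cord, cerebral, hepatic, renal, myocardial.
The partition is exact (every gene in exactly one of the 2^k − 1 cells),
so cell counts always sum to the union and per-organ marginals to the organ
set sizes; tests enforce both identities.

## Synthetic corpus generator

`simulate_corpus` emulates a seven-study, five-organ acute-IRI DEG
literature: a planted pan-organ signature (38 up, 20 down — the scale of
curated highly-repeated lists in this field), per-organ private DEGs
(30/organ), and 150 background genes reported by 1–3 random studies.
Signature and organ-specific genes are reported by each eligible study
independently with `report_prob` (default 0.8) and each report's direction
flips with `flip_prob` (default 0.1) — values chosen so that a typical
corpus exhibits the full score range 1..7 with mixed consistency, the
regime the thresholds are designed for. Adjusted p-values are uniform on
(1e-6, 0.049) so the significance filter is the identity on clean corpora;
`n_contaminant_rows_per_study` adds p ≥ 0.05 rows to exercise it. log2FC
magnitudes are log-normal(0, 0.5) and cosmetic — only the sign matters
downstream, but they exercise table parsing.

What the generator does *not* model: read counts and differential-testing
noise (the unit is the reported DEG, not the measurement), correlated genes,
study-specific significance criteria, annotation drift between species, or
symbol synonymy. Passing recovery tests therefore demonstrates the
correctness of the tallying/selection machinery under the stated reporting
model, not robustness to those real-data pathologies.

Under this model a planted gene is recovered (correct list) with probability

&nbsp;&nbsp;Σ_{r≥4} B(r; S, report_prob) · P(Binom(r, 1−flip_prob) ≥ ⌈0.75·r⌉),

which the test suite evaluates in closed form and compares against observed
recall over 200 replicate corpora (3-standard-error band). All randomness
flows through a single seeded `numpy.random.default_rng` (PCG64, named in
the manifest), so corpora are byte-identical across runs and platforms.

`simulate_gmt` plants enriched terms that draw a fixed fraction of their
members from a query (the remainder from outside it, so the overlap is
exact) among decoys sampled uniformly from the universe; overlap equal to
the uniform expectation makes planted terms indistinguishable from decoys,
giving a null construction for calibration tests.

## Numerical and design notes

- BH is implemented directly (sort, cumulative minimum from the largest
  rank, clip at 1); tests cross-check it against a quadratic-time
  step-up reference and `statsmodels.multipletests`.
- The hypergeometric tail is validated against exhaustive enumeration of all
  C(N, n) draws for every universe up to N = 12 at 1e-12.
- Problem sizes in the test suite and acceptance script (corpus of ~360
  genes, 200 noisy replicates, 1000 null enrichment replicates, 100 power
  seeds) were chosen as the smallest designs whose Monte-Carlo error is well
  inside the asserted bands.
- Exit codes of the CLI: 0 ok, 1 usage error, 2 data error.

## Known limitations

- Vote counting weights a small underpowered study equally with a large
  well-powered one; the score is a popularity measure, not an effect
  estimate.
- With `min_reports` fixed at 4 while the number of studies varies, the
  implied stringency changes; callers comparing corpora of different sizes
  should scale `min_reports` themselves (the pipeline only validates
  `min_reports ≤ S`).
- Headline gene counts from any specific published corpus depend on that
  corpus's supplementary tables and annotation versions and are not
  recomputable from simulation; the package documents them as fixtures
  (`crossdeg.signatures`) rather than asserting them.
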