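# Methods

This note documents the statistical model behind `cdmkit`, the default
parameters and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical choices that make runs reproducible.
Empirical statements here are limited to quantities computed by the test
suite (`tests/`) or by `scripts/acceptance.py`.

## 1. Consistency scoring

**Input model.** An expression dataset is a probe × sample intensity
matrix with per-sample condition (`control`/`disease`) and subset labels.
Two designs are supported: *within* (each subset contains both conditions,
e.g. tissue regions of the same cohort) and *split* (each subset is
condition-pure, e.g. random sample splits). Mixing the two in one dataset
is rejected.

**Intensity filter.** Only probes in the upper 40% of pooled mean
intensity are scored (`intensity_fraction = 0.40`). Rationale: on log-
normal intensity distributions the lower ranks are dominated by
background, where fold changes are unstable; the cutoff also induces the
intensity–detectability correlation the tiering exploits. The count is
`ceil(0.40 · n_probes)`; ties at the boundary break lexicographically by
probe id so the retained set is deterministic.

**Welch tests.** Per probe, a two-tailed unequal-variance t-test per
subset (within design) or per control-subset × disease-subset pair (split
design — a 2×2 split yields four tests). Welch rather than pooled-variance
because case and control groups routinely differ in dispersion. Each group
needs n ≥ 2; zero-variance degenerate cases return p = 1 for equal means
and p = 0 otherwise. p-values are floored at 1e−300 before taking logs.

**PCS and direction.** The Primary Consistency Score is the mean of
−log10 p over a probe's tests: a probe must be consistently, not
occasionally, differential to score high. Direction is the sign of the
mean log disease/control ratio across tests (0 when exactly balanced).
`estimate_recall(N, m, P) = C(N, m) · P(m)` and `compute_pec(q, n) = q^n`
expose the design arithmetic relating split counts to recall and to the
probability that a consistent call is correct.

## 2. Tier assignment

The top 10% of PCS per platform (`top_fraction = 0.10`, `ceil`,
deterministic tie-break) are "high-PCS". Rules, evaluated per gene over
its high-PCS probes:

- **T2a** — ≥2 probes on the same platform, concordant direction.
- **T2b** — probes on both primary platforms, concordant.
- **T1a** — T2b and the multi-probe platform itself has ≥2 concordant
  probes. The multi-probe platform defaults to the platform with the
  highest mean probes-per-gene.
- **T1b** — Tier 2 and Tier 3 simultaneously.
- **T1c** — ≥3 concordant probes on one platform.
- **T3** — a high-PCS gene sharing a functional gene set of ≤500 members
  (`tier3_max_set_size`) with another high-PCS gene. The size cap keeps
  generic, uninformative categories from linking everything.
- **Tier 0** — (Tier 1 ∪ Tier 2) ∩ high-PCS on the auxiliary multi-disease
  platform; the most stringent, cross-pathology list.

Direction consensus is by majority sign over supporting probes; an exact
tie disqualifies Tier 1/2 membership (evidence contradicts itself). A gene
receives its best (numerically smallest) tier. Reports use the
differences Tier 1−0, Tier 2−1, Tier 3−2 so each list adds only new genes.

## 3. Ontology enrichment

For a changed list of size L against a background of size T containing TG
genes of a category, with CG of them in the list:

- `ENR = (CG/L)/(TG/T)`;
- one-sided Fisher p = hypergeometric upper tail
  `P(X ≥ CG)` (`scipy.stats.hypergeom.sf(CG−1, T, TG, L)`).

**Expression-matched background.** Enrichment lists are intensity-biased,
so comparing them to the whole genome inflates every "expressed" category.
The background is the largest intensity-descending prefix of the measured
genes whose mean intensity still reaches the changed list's mean
(computed via the non-increasing cumulative mean and a binary search),
always including the changed genes themselves. Genes absent from the
ontology stay in T and dilute it, matching "total file" semantics of
GoMiner-style tools.

**Permutation FDR.** For each of `cycles = 100` permutation cycles a
random list of size L is drawn from the background and all categories are
re-tested; for an observed p-value cutoff p_c,
`FDR(p_c) = mean over cycles of #{random p ≤ p_c} / #{observed p ≤ p_c}`,
clipped to [0, 1]. 100 cycles is the default because the estimator pools
counts over all categories per cycle; `tests/test_enrichment.py` checks
its stability against 1,000 cycles. Reports keep categories with TG ≥ 5
(`min_category_size`) and FDR < 0.2 (`fdr_cutoff`), sorted by FDR, then
descending ENR, then term id.

## 4. Literature semantic enrichment

The corpus is an offline gene–document–tag table. A tier list acts as a
Boolean OR query; a *delimiter* is a Boolean tag expression (AND/OR/NOT,
parentheses) parsed by a small recursive-descent parser. The statistic is
the delimited/total hit ratio, compared as a fold against a control: the
mean ratio of `n_control_resamples = 50` size-matched random gene lists
drawn from the measured background. Subset variance (the list split into
k random parts, sample variance of per-part ratios) measures how evenly
the association is spread; the oncogene/tumor-suppressor ratio uses two
fixed tags and flags division by zero as `inf` rather than failing.

Size-matched random controls are the method's own validation statistic,
but they *attenuate* strong associations: control lists hit documents
that also cross-mention associated genes, and contain associated genes at
the base rate. For recovering a planted association strength the package
therefore also provides `semantic.background_tag_rate` (tag rate among
documents mentioning none of the listed genes); the rate ratio
list-documents / non-list-documents is the unbiased estimator used by the
acceptance criterion (recovered mean 10.07 for a planted 10× association
at seed 1, `corpus_fold_recovered_mean`).

## 5. Interaction sub-networks

The tier list seeds an induced subgraph of a global interaction network,
optionally with first-order neighbors. Connected components are split by
greedy modularity maximization, refined by single-node shifts (modularity
is asserted never to decrease), and recursively re-split when larger than
`max_size = 35` — about the largest sub-network that is still readable as
a mechanism diagram. A sub-network of n molecules containing k focus
(tier) molecules scores `−log10 P(X ≥ k)` under the hypergeometric null
of drawing n molecules from the background network. Hub statistics
compare the fraction of high-connectivity genes in a list against random
size-matched draws.

## 6. The synthetic generator

`generate_multiplatform_study` emulates, in log2 space, the structure the
method was designed for; the defaults *are* the study conditions and were
fixed a priori:

| parameter | default | rationale |
|---|---|---|
| `n_genes` | 5000 | compendium scale that still runs in seconds |
| platforms | AFFY1 (1–3 probes/gene), ILMN1, ILMN2 (auxiliary) | multi-probe + single-probe primary pair, multi-disease auxiliary |
| `n_subsets`, `n_per_group` | 3, 10 | typical cohort subset structure |
| `baseline_log2_mean/sd` | 8, 2 | log-normal intensities, wide dynamic range so the upper-40% cut is meaningful |
| `noise_sd` | 0.5 | ≈40% CV per-sample noise, typical for arrays |
| `batch_sd` | 0.25 | gene × subset × condition hybridization offsets — the false-positive source for naive pooled tests |
| `probe_offset_sd` | 0.5 | probe affinity; constant per probe, cancels in tests |
| `crosshyb_fraction` | 0.03 | probes with platform-consistent spurious signal — rejected by cross-platform/multi-probe concordance |
| `sporadic_fraction`, `sporadic_scale` | 0.10, 1.5 | single-subset, single-platform artifacts — rejected by consistency averaging |
| `planted_fraction` | 0.02 | disease genes, intensity-rank-weighted sampling (signal rides on expressed genes) |
| `effect_size` | 1.5 | planted shift in noise-sd units |
| `downregulated_fraction` | 0.8 | predominance of down-regulation |
| `aux_shared_fraction` | 0.5 | auxiliary platform carries half the disease signal |

It does **not** emulate spatial array artifacts, probe-sequence effects,
normalization pipelines, or missing-data mechanisms beyond the reader's
handling. Companion generators produce gene sets (a few terms planted
from the disease genes), corpora (per-document tag probability = base
rate × the largest association fold over mentioned genes, capped at 1)
and interaction networks (Chung–Lu expected-degree graphs with power-law
weights `w_i ∝ i^{−1/(γ−1)}`, γ = 2.5, plus a planted dense module). All
export their ground truth.

**Benchmark definitions** (acceptance criterion 4): *Tier 1* precision is
measured against the planted genes; *top-PCS* is the size-matched gene
list from the pooled primary-platform PCS ranking (the method's selection
stage without the concordance rules); *single-test* is the size-matched
list from one Welch test on the first subset of the multi-probe platform,
genes ranked by their best probe. At seed 1 the acceptance script
measures mean precisions 0.640 / 0.236 / 0.118 with the strict ordering
holding in 9 of 10 seeds; the test suite asserts the ordering in ≥80% of
25 seeds.

## 7. Numerical and reproducibility choices

- All randomness flows from one integer seed through
  `numpy.random.SeedSequence` spawning; derived integer seeds are < 2³¹.
- Sorts that define selections (intensity filter, high-PCS cut, report
  ordering) are stable (`mergesort`) with explicit lexicographic
  tie-breaks, so outputs are bit-reproducible.
- p-values are floored at 1e−300 before −log10; hypergeometric tails come
  from `scipy.stats.hypergeom.sf` rather than factorial ratios.
- Welch tests are vectorized over probes (`scipy.stats.ttest_ind`,
  `axis=1`, `equal_var=False`).
- The pipeline manifest records every parameter and an SHA-256 checksum
  of every output (elapsed time excluded), so identical configs and seeds
  produce identical manifests.

## 8. Limitations

- Tier rules are hard thresholds; a probe just below the top-10% PCS cut
  contributes nothing. No soft evidence weighting is attempted.
- The permutation FDR is a pooled-count estimator: accurate and cheap at
  100 cycles for dense category collections, coarse for single categories
  in small collections.
- The semantic stage's size-matched control attenuates strong
  associations (section 4); folds it reports are conservative.
- Sub-network scoring treats the interaction network as undirected,
  untyped presence/absence evidence.
- The generator's artifacts are the structured ones the tier rules target
  (batch, cross-hybridization, sporadic cohort effects); performance
  numbers measured on it quantify behaviour under this model, not under
  any particular real compendium.
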