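# Methods

`labelsafe` implements a section-aware pipeline for mining adverse drug
reactions (ADRs) from structured drug labeling.  The pipeline has six
stages, run in order: terminology loading, corpus parsing/selection,
dictionary matching, occurrence statistics, organ-class enrichment, and
therapeutic-class clustering, plus a gold-standard evaluator and a
synthetic-data generator that makes every stage testable without licensed
inputs.

## Terminology model

The terminology is a strict three-level hierarchy in the style of
regulatory ADR dictionaries: Low Level Terms (LLTs, the granular coding
level) group under exactly one Preferred Term (PT, the analysis level),
and each PT carries one *primary* System Organ Class (SOC).  Multi-axial
SOC links beyond the primary are not modeled; all roll-ups use the primary
SOC only.  Five SOCs that do not describe medical disorders
(Investigations; Injury, poisoning and procedural complications; Social
circumstances; Surgical and medical procedures; Product issues) are
excluded from ADR statistics by name (configurable), leaving the
"disorder" SOCs.  PTs whose primary SOC is excluded are dropped from all
counts at extraction time and noted in the logs.  Dictionary files use the
`$`-delimited ASCII dialect with the standard column positions, so a
licensed distribution drops in unchanged.

## Corpus model and selection

Labels are SPL-style XML; each section is identified by a LOINC code.
The three ADR-bearing sections are Boxed Warning (BW, `34066-1`),
Warnings and Precautions (WP, `43685-7`) and Adverse Reactions (AR,
`34084-4`).  Only the BW code and the WP code are fixed by convention in
the source material we follow; the AR code is the standard SPL assignment
and is configurable (`sections.loinc_map`) in case of drift.  Section text
is the whitespace-normalized concatenation of all text nodes under the
section's `text` content in document order (table cells included), with
nested subsections folded into their coded ancestor.  A fourth
pseudo-section, `whole`, is the concatenation of all sections.

Corpus selection applies four sequential criteria: (I) human prescription
drug — over-the-counter and unclassifiable labels removed; we key this on
the marketing-category element, an assumption since the data standard
offers more than one signal; (II) NDA approval pathway; (III) single
active-ingredient UNII; (IV) most recent label per UNII by effective date.
Labels without an effective date are excluded at step IV with a warning;
date ties break to the lexicographically greater set id so selection is
deterministic.  The selection log records exclusions per criterion and
always satisfies `survivors + Σ exclusions = inputs`.

## Matching engine

The matcher reproduces the behavior of classic full-text indexing engines
used for this task.  Normalization lowercases, Unicode-compatibility-folds
and tokenizes on non-alphanumerics (hyphens and slashes split), removes
stop words, and stems with a self-contained Porter (1980) stemmer.  The
same normalizer is applied to dictionary terms and label text, so the
specific stemmer is immaterial as long as it is consistent.  The default
stop list is a small fixed English list that includes the single letters
`a` and `d`; this is what makes "Hepatitis A", "Hepatitis D" and
"Hepatitis" index identically — the documented stop-word collision.  Each
surviving token keeps its raw-text character span (0-based, half-open), so
every match records exact provenance.

An LLT matches where its normalized token sequence occurs contiguously in
the section's normalized token stream.  Two policies:

* `all_matches` (default, "oracle-compat"): every index entry matching at
  any position is reported, including entries nested inside longer
  matches ("myocardial infarction" also yields "infarction") and whole
  collision groups.  High recall, low precision.
* `longest_match`: at each position the longest entry wins and scanning
  resumes after it; nested false positives are suppressed.

Both policies miss non-contiguous rewordings ("suicidal thinking and
behavior" does not match "suicidal behavior") — the documented
false-negative mode.  Matches roll up LLT → PT and each PT is counted at
most once per section per document.

## Statistics

**Occurrence.** The binary drug × PT × section tensor underlies all
statistics.  Percentages in the section-accounting table are computed
with half-even rounding at one decimal (shares of the whole-document
count) or two decimals (per-PT section rates, kept as exact rationals
internally).  Top-N rankings break count ties by PT name ascending, then
code, so results are deterministic.

**Enrichment.** For each disorder SOC, a 2×2 table partitions the PT
universe U by SOC membership and by presence in any Boxed Warning.  U
defaults to the PTs observed anywhere in the corpus
(`enrichment.universe = observed`); the full-dictionary alternative is a
flag.  PT counts (not drug counts) are tested, matching the framing of
the enrichment question; a drug-count mode is deliberately not
implemented.  The two-sided Fisher p-value sums hypergeometric point
probabilities over the attainable tables whose probability does not
exceed the observed table's, with a 1e-7 relative tolerance on the
comparison, accumulated in log space for stability.  Bonferroni uses the
number of SOCs actually tested as the divisor (0.05/22 reported to one
significant digit as 0.002).  Tests verify exact agreement (≤1e-12) with
integer enumeration and with an independent reference implementation.

**Clustering.** Cell (PT, ATC) counts BW-bearing drugs of a second-level
ATC class whose Boxed Warning mentions the PT; drugs with several ATC
codes count in each.  Classes with fewer than 5 BW drugs and PTs in fewer
than 5 distinct BW drugs are dropped (filters act on raw counts; the
"5 drugs" PT filter counts distinct drugs, not drug–ATC pairs), then
cells transform as log2(count + 1) — the +1 pseudocount resolves zero
cells, which a bare log2 of frequencies cannot.  Rows and columns are
clustered independently by agglomerative clustering, Euclidean distance
and complete linkage by default (the classic heatmap defaults; both
configurable).  Dendrograms are emitted as Newick text; column clusters at
a requested cut are reported with member classes and PTs whose
within-cluster mean exceeds the global mean by a configurable margin.

**Evaluation.** Scoring is set-based at PT granularity per drug per
section: recall = tp/(tp+fn), precision = tp/(tp+fp), macro averages are
unweighted means over drugs.  Drugs with empty gold and empty prediction
score 1.0/1.0 by convention (logged) rather than being skipped.
LLT-level scoring is available behind a flag; collision-group variants of
one PT therefore count as a single false positive.

## Synthetic data: what it emulates, and what it does not

The generator's defaults mirror the study conditions of the targeted
corpus: 1164 single-ingredient NDA labels, 31.5% with a Boxed Warning and
~99% with WP/AR sections, a 22-disorder-SOC terminology (~286 disorder
PTs at 13 PTs/SOC, plus the 5 excluded SOCs), and mean planted mention
counts increasing BW < WP < AR (2, 6, 12): severity decreases and
coverage increases across the three sections.  Every present section
plants `1 + Poisson(rate − 1)` distinct PTs, so each ADR section mentions
at least one ADR and per-drug recall under an x% reworded-mention rate
has expectation exactly 1 − x/100.  Mentions are verbatim LLT surface
forms (case-jittered) embedded in filler prose drawn from a fixed word
list disjoint, after normalization, from every dictionary token —
known-answer tests are therefore exact, and with failure modes off the
full pipeline scores recall = precision = 1.0 by construction, which the
tests verify by running it.

Limitations to keep in mind when interpreting green tests: filler prose
is not language; mentions are never negated, hedged or coordinated; the
synthetic PT universe is ~75× smaller than a real terminology (286 vs
~22,000 PTs), so whole-corpus PT coverage saturates (most PTs reach some
Boxed Warning at paper scale) and per-section coverage percentages run
far higher than in real corpora.  For that reason SOC enrichment from the
full-text corpus is uninformative at default scale, and enrichment
calibration uses a direct PT-level sampler instead (below).  Gold
annotations list *all* planted mentions, including reworded ones a
contiguous matcher cannot find — that is precisely how the evaluator's
false-negative behavior is exercised.

## Statistical calibration designs

Two experiments are sampled at the PT level (`sample_bw_universe`), which
carries exactly the sufficient statistics of the enrichment test, rather
than through text generation:

* **Null size.**  Fisher's exact test is conservative at small counts, so
  a null design with small SOCs cannot exhibit a ~5% flag rate.  The null
  design (22 SOCs × 120 PTs, BW inclusion probability 0.45, 500 corpora)
  was chosen by computing the test's exact unconditional size over a grid
  of designs and taking the one closest to nominal (achieved size 0.0485)
  before any test was run.
* **Planted-effect power.**  With the enrichment multiplier fixed at 5
  and a 286-PT universe, the base inclusion rate 0.18 (enriched SOC: 0.9)
  was chosen by an a-priori power calculation to give ≥99% detection
  probability at the 0.002 Bonferroni threshold.

The cluster-recovery experiment (`sample_block_matrix`) plants disjoint
per-block Boxed-Warning PT profiles (each drug drops one random PT so
profiles are not identical) and checks that the 2-cluster cut recovers
the planted partition exactly (adjusted Rand index 1.0).

## Numerical and design choices

* Degenerate Fisher tables (an empty row or column) return p = 1; SOCs
  with no PTs in the universe are reported with p = 1 and a warning
  rather than dropped.
* Reported "generator tolerance" for the 0.90 reworded-recall check is
  ±0.05, about 2.4 binomial standard deviations at the problem size used
  in the test (400 drugs, ~126 with Boxed Warnings).
* Acceptance-script problem sizes: the descriptive study runs at the full
  default scale (1164 labels); evaluation regimes run at 300–800 labels,
  enough for stable macro averages at desk runtime.
* Source material reports two slightly different PT counts for the BW and
  WP sections in different passages (460 vs 466, 2013 vs 2023); the
  package computes and emits a single number per section and takes no
  position on which printed figure is authoritative.
* When a normalized sequence maps to several LLTs, all are emitted; PT-
  level deduplication makes the choice harmless downstream, and it is the
  behavior that reproduces the documented collision false positives.
* Table cells and footnotes inside sections are indexed like any other
  text node (assumption; the alternative is not recoverable from the
  source material).
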