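# Methods

## Overview

`tisnet` treats a tissue interactome as the sub-network of a global,
context-free PPI network induced by expression-based node removal: an
interaction can only occur in a tissue if both partners are present
there. The package consists of (i) expressed-gene calling and
cross-platform combination, (ii) interactome filtering and structure
statistics, (iii) disease-gene median-contrast statistics with a
label-permutation test, and (iv) a synthetic-data generator that supplies
cohorts with the structure the analysis assumes.

## Expressed-gene calling

* Microarray intensities: expressed when the value is **strictly above**
  the threshold (default 100; relaxed variant 30). RNA-seq RPKM:
  expressed when the value is **at least** the threshold (default 1.0;
  relaxed 0.3). The asymmetry follows the conventional phrasings "above"
  versus "at least"; both thresholds and both comparison senses are
  configurable.
* Repeated (gene, sample) measurements: the highest value wins. For
  ordinal IHC data the rule is monotone, so a gene is expressed in a
  sample iff *any* antibody measurement qualifies.
* IHC rule: staining level ∈ {low, medium, high} AND (antibody
  reliability ∈ {medium, high} OR (reliability low/absent AND ≥ 1
  supportive AND 0 negative validity scores)). A *low* reliability score
  is treated as "not available" and falls through to the validity rule
  rather than blocking outright; the fall-through is logged per call.
  This is the more permissive of the two defensible readings; the strict
  alternative would only shrink the IHC expressome.
* Calls are made at the lowest sampling level and consolidated into the
  16 main tissues by a per-dataset subpart → tissue scheme; the combined
  expressome is the per-tissue union across datasets ("expressed in at
  least one dataset"). Subpart-level sets are retained because the
  interactome filter requires co-expression within one sample, not
  merely within one tissue.
* Gene identifiers are opaque strings; probe/protein-to-gene mapping is
  an upstream data operation, not part of the method.

## Interactome construction

* The global interactome is the union of per-source edge lists,
  canonically ordered and deduplicated. Self-loops are dropped at ingest
  (with a logged count): PPI degree counts *partners*, and a self-partner
  would distort hub calls.
* Tissue filter: an edge is kept iff some (dataset, subpart) mapped to
  the tissue contains both endpoints in its expressed set; edges
  recovered in different subparts of a tissue are united. The node set of
  a tissue interactome is the endpoints of its kept edges — expressed
  genes with no surviving interaction are reported in the expressome, not
  the interactome.
* Core = edge intersection of all tissue interactomes; edge breadth = the
  number of tissues containing the edge (0–16); TS-PPIs are edges of
  breadth ≤ `k_ts`, attributed to every tissue containing them.
  `k_ts` defaults to 3, mirroring the gene-level tissue-specific class
  (1–3 tissues); "almost exclusively" has no canonical numeric value, so
  the cutoff is exposed as a parameter.

## Network statistics

* Hubs: nodes with degree strictly above the smallest threshold that
  keeps the strictly-greater set within the top 5% — boundary ties are
  excluded together, so the hub fraction can never exceed the nominal
  one. The threshold is recomputed per interactome (and reported for the
  global interactome as well).
* Expression–degree correlation: Spearman over genes with RPKM > 0 and
  ≥ 1 PPI in the tissue; the binned variant sorts by (RPKM, gene id) —
  deterministic under ties — splits into 10 equal-count bins (remainder
  on the lowest bins), and correlates bin medians. p-values use the
  large-sample approximation, with exhaustive permutation enumeration
  below n = 10.

## Disease-gene statistics

* For each causal gene, metrics (RPKM, PPI degree, TS-PPI count) are
  compared between disease and non-disease tissues via strict median
  contrast V_d > V_nd, restricted to tissues expressing the gene; ties
  count as failure. A gene causal for several diseases enters once, with
  the union of its disease tissues (the per-disease view is retained for
  the disease-level summary). Tissue-specific disease genes are excluded
  from all tests because their non-disease tissue set is empty.
* Permutation test: each run redraws, independently per gene, a uniform
  x-subset of the gene's expressing tissues; p is the raw upper-tail
  fraction over 10,000 runs (the add-one Davison–Hinkley variant is
  available behind a flag because the raw estimator can return 0). Each
  gene draws from its own RNG substream keyed by a stable hash of the
  gene id, so results are independent of iteration order and of the
  presence of excluded genes.
* Exact mode enumerates each gene's C(m, x) selections and convolves the
  per-gene Bernoulli success probabilities into the exact Poisson-
  binomial null. The guard bounds the *total* number of enumerated
  selections (default 10⁶), which is the actual cost of the convolution
  approach; the product space is never materialised.
* Disease-level summary: a disease counts as "elevated"/"tsppi" if any of
  its causal genes carries the corresponding success flag; the
  aggregation rule is a package choice (the any-gene rule is the natural
  reading when most diseases have a single causal gene).
* Differential-expression calls are out of scope; an externally produced
  per-gene DE table can be merged into reports by the caller.

## Synthetic-data generator

The generator emulates what the analysis assumes about real data:

* **Breadth**: classes drawn from `breadth_mixture` (default 0.14 / 0.25
  / 0.61 for specific / intermediate / global). Within-class tissue-count
  distributions are peaked at the extremes (specific: 1 tissue with
  probability 0.65; global: 16 tissues with probability 0.85;
  intermediate uniform on 4–13). Real combined expressomes detect most
  ubiquitous genes in *every* tissue, and this concentration is what
  makes the core sub-network dominate each tissue interactome; a uniform
  within-class draw cannot reproduce that dominance (with only a third of
  global genes at full breadth, at most ~8% of a tissue's edges could be
  core edges).
* **Abundance**: log-normal with marginal log-sd 1.2 (arbitrary units).
  The median is class-dependent (specific 4, intermediate 8, global 16),
  reflecting housekeeping-gene dosage, and log-abundance is decomposed as
  gene-base + per-tissue deviation with a gene-level variance share of
  0.8, matching the strong cross-tissue coherence of real expression
  atlases (typical cross-tissue correlations 0.75–0.85). Both choices
  were fixed at design time from these qualitative considerations.
* **Panels**: RNA-seq value = abundance × log-normal noise (sd 0.15,
  coverage 0.98); microarray intensity = 100 × abundance × noise /
  detection-bias (bias 4, coverage 0.5, noise 0.3), so the microarray
  panel detects markedly fewer genes, as older platforms do; the IHC
  panel maps noisy abundance through its 25/50/75% quantiles to
  not-detected/low/medium/high and attaches sampled reliability
  (high 0.3 / medium 0.4 / low 0.15 / absent 0.15) and validity labels,
  exercising every branch of the IHC calling rule. A missing row is a
  below-detection readout; a configurable false-positive rate (default 0)
  adds spurious readouts. One sample per tissue per dataset, with the
  identity consolidation scheme.
* **Network**: growth model in which each arriving node attaches to
  existing nodes with probability ∝ abundance^coupling × (degree + 1).
  Abundance enters through two further mass-action channels, both off at
  coupling 0: arrival order is an abundance-weighted random permutation,
  and the per-node stub count scales as (abundance/median)^(coupling/2)
  (capped at 10× the base). Fixed per-node stub counts would couple only
  the hub tail to abundance and leave the bin-median degree flat.
* **Disease planting**: causal genes are drawn among genes expressed in
  ≥ 4 tissues and covered by the RNA-seq panel (the expression effect
  must have a value to scale); each disease gets one causal gene and 1–2
  uniformly drawn disease tissues. The uniform draw makes the planted
  labels exchangeable with the permutation null, so the no-effect mode is
  an exact null for the test. Planted TS-partners are existing
  single-tissue genes when available and freshly minted tissue-specific
  genes otherwise (written to the RNA-seq panel), keeping the planting
  guarantee unconditional.

What the generator does **not** emulate: probe-level microarray
structure, read-level RNA-seq, isoforms, antibody staining images,
cross-dataset batch effects (noise scales are free parameters, not
estimates of the real platforms), or literature-derived study bias in
which PPIs get assayed. Passing tests therefore validate the method's
statistical machinery and its qualitative structural claims, not any
quantitative property of the original external datasets.

## Problem sizes and numerical choices

* Default structural study: 2,000 genes, ~7,000 global PPIs, 16 tissues —
  a scale at which every structural signature (bi-modal breadth, dominant
  core, ≤ 5% hubs, binned correlation ≥ 0.9) is stable across seeds while
  a full run takes seconds.
* Permutation studies: 600-gene cohorts with 100 diseases; type-I
  calibration uses 200 null cohorts at 1,000 runs, effect recovery 50
  cohorts at 10,000 runs.
* Medians of even-length sets are midpoints; all ties break
  deterministically (stable sorts keyed by identifiers); every RNG is
  seeded from one master seed via named substreams, so identical
  configurations reproduce byte-identical outputs.
* Degenerate inputs: empty catalogs, empty expressomes, and empty graphs
  return empty results; an empty overlap set reports p = 1 with a
  warning; an empty hub threshold is null.

## Known limitations

* The pipeline recomputes rather than resumes: a rerun with the same
  configuration reproduces identical manifest digests, but partial
  results are not reused.
* The exact permutation mode is limited by the enumeration bound; very
  broad genes in large panels require the Monte-Carlo mode.
* The unbinned expression–degree correlations in the synthetic cohorts
  are stronger than those typically seen in real tissues, because the
  generator's only sources of degree variation are abundance and
  topology; the binned-median statistic, not the unbinned value, is the
  calibrated signature.
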