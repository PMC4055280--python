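# tisnet — tissue interactomes and the tissue specificity of hereditary diseases

Hereditary diseases are caused by germline aberrations carried by every
cell of the body, yet most of them damage only one or a few tissues —
even though their causal genes are usually expressed in many tissues.
`tisnet` implements a comparative tissue-interactome analysis of this
phenomenon for systems biologists: it builds per-tissue protein–protein
interaction (PPI) networks by expression-based node removal, characterises
their shared and tissue-specific structure, and tests whether causal
genes show elevated expression, higher PPI degree, and tissue-specific
interactions (TS-PPIs) preferentially in their disease tissues.

## Method

**Tissue expressomes.** Three expression platforms are integrated over 16
main human tissues: microarray intensities (gene expressed when intensity
> 100), RNA-seq (RPKM ≥ 1), and ordinal immunohistochemistry calls (level
low/medium/high, antibody reliability medium/high or, failing that, ≥ 1
supportive and 0 negative validity scores). Calls are made per tissue
subpart/sample, consolidated into main tissues, and combined across
datasets by union. Gene *breadth* (number of expressing tissues, 1–16)
classifies genes as tissue-specific (1–3), intermediate (4–13), or
globally expressed (14–16).

**Tissue interactomes.** The global interactome is the union of PPI
sources as an undirected simple graph. A tissue interactome keeps an edge
only if both partners are co-expressed in the same sample/subpart at the
lowest hierarchy level. The *core* sub-network is the edge intersection of
all 16 tissue interactomes; an edge present in at most `k_ts` tissues
(default 3) is a TS-PPI of each tissue containing it. Hubs are nodes whose
degree ranks in the top 5% of an interactome; per-tissue RPKM and PPI
degree are correlated (Spearman), unbinned and over 10 equal-count RPKM
bins.

**Disease-gene statistics.** For a causal gene with disease-tissue set of
size *x*, let V_d be the median of a metric (RPKM, degree, or TS-PPI
count) over its disease tissues and V_nd the median over its other
expressing tissues; V_d > V_nd (strict) is a success. Significance of the
total success count is a label permutation: each of 10,000 runs redraws,
independently per gene, a uniform *x*-subset of the gene's expressing
tissues and recounts successes,

    p = #{runs with null successes ≥ observed} / 10,000.

An exact mode enumerates each gene's selection space and convolves the
per-gene Bernoulli probabilities into the exact Poisson-binomial null.
Tissue-specific disease genes (empty non-disease set) are excluded.

Because the original external datasets are not redistributable at desk
scale, a first-class synthetic generator (`tisnet.synthetic`) produces
cohorts with the assumed structure — bi-modal breadth, three partially
overlapping platforms driven by a shared latent abundance, a scale-free
PPI network with abundance-coupled degree, and disease panels with
planted effects (plus a null mode) — so every claim the package makes is
testable end to end.

## Worked example

The numbered scripts under `analysis/` run the study on the default
synthetic cohort (2,000 genes, 100 diseases, planted 1.5× expression and
2 TS-PPIs per causal gene) and write tables under `results/`:

```bash
cd analysis
python 01_simulate.py --seed 1
python 02_build_interactomes.py --seed 1
python 03_network_statistics.py --seed 1
python 04_disease_statistics.py --seed 1
```

Script 02 prints the shared structure of the 16 tissue interactomes:

```
gene breadth: 60% global (14-16 tissues), 13% tissue-specific (1-3) -- bi-modal
global interactome: 7182 PPIs between 2000 proteins
core sub-network: 969 proteins, 3413 PPIs (>= 63% of every tissue interactome's edges)
```

— most genes are either globally expressed or tissue-specific, and a
common core dominates every tissue interactome. Script 03 reports the
expression–degree coupling (binned-median Spearman 0.98–0.99 across all
16 tissues) and ≤ 5% hubs per tissue. Script 04 runs the disease tests:

```
  rpkm: higher in disease tissues for 76/99 genes (permutation p = 0)
  degree: higher in disease tissues for 92/99 genes (permutation p = 0)
  tsppi_count: higher in disease tissues for 99/99 genes (permutation p = 0)
diseases with elevated expression and/or TS-PPIs in their disease tissues: 100%
```

— the planted elevation and planted TS-PPIs are recovered: far more than
the ~50% of genes expected under the null succeed, and the permutation
p-values are below 1/10,000 (reported as 0 by the raw-fraction
estimator). The same machinery is exposed as a CLI for file-based runs:
`tisnet simulate|build|stats|disease|run --config cfg.yaml --seed N --out DIR`.

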