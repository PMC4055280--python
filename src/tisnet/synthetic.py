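"""Synthetic tissue-expression, PPI, and disease-panel generator.

The generator emulates the statistical structure the downstream analysis
assumes, so that every stage is testable without external downloads:

* a bi-modal gene-breadth distribution over 16 tissues (most genes either
  tissue-specific or globally expressed);
* three partially overlapping expression datasets driven by a shared
  latent abundance -- a high-coverage RNA-seq-like panel (RPKM), a
  lower-coverage microarray-like panel (intensities), and an ordinal
  IHC-like panel with antibody reliability/validity labels;
* a scale-free PPI network whose degree is positively coupled to
  abundance (preferential attachment with abundance-weighted attachment);
* disease panels with planted elevated expression and planted
  tissue-specific edges in the disease tissues, plus a null mode.

Latent log-abundance is decomposed into a gene-level component and
independent per-tissue deviations (gene-level variance share
``cross_tissue_correlation``), giving the cross-tissue coherence real
expression atlases show; the abundance median rises with expression
breadth, reflecting housekeeping-gene dosage. Both features are what make
the synthetic tissue interactomes share a dominant core, as the real ones
do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError
from .expression import ExpressionPanel, IHC_COLUMNS, QUANT_COLUMNS

TISSUES_16 = (
    "adipose", "adrenal", "brain", "breast", "colon", "heart", "kidney",
    "liver", "lung", "lymph_node", "ovary", "prostate", "skeletal_muscle",
    "testis", "thyroid", "white_blood_cells",
)

DATASET_ORDER = ("microarray", "rnaseq", "ihc")

BREADTH_CLASSES = ("specific", "intermediate", "global")

#: tissue-count distributions within each breadth class. Peaked at the
#: extremes (1 and 16): ubiquitous genes are overwhelmingly detected in
#: every tissue, and tissue-specific genes mostly in exactly one.
CLASS_SIZE_PMF: dict[str, dict[int, float]] = {
    "specific": {1: 0.65, 2: 0.22, 3: 0.13},
    "intermediate": {k: 0.1 for k in range(4, 14)},
    "global": {14: 0.04, 15: 0.11, 16: 0.85},
}

#: abundance median (arbitrary units) per breadth class -- breadth-coupled
#: dosage: broadly expressed genes are on average more abundant.
CLASS_ABUNDANCE_MEDIAN = {"specific": 4.0, "intermediate": 8.0, "global": 16.0}

_IHC_RELIABILITY_P = {"high": 0.30, "medium": 0.40, "low": 0.15, "absent": 0.15}


@dataclass
class DatasetSpec:
    """Per-dataset generation knobs.

    coverage        fraction of genes the platform measures at all
    noise_scale     sd of the multiplicative log-normal measurement noise
    detection_bias  divides the measured signal (platforms with bias > 1
                    push more true values below the detection threshold)
    """

    coverage: float = 1.0
    noise_scale: float = 0.2
    detection_bias: float = 1.0


def default_dataset_specs() -> dict[str, DatasetSpec]:
    return {
        "microarray": DatasetSpec(coverage=0.50, noise_scale=0.30, detection_bias=4.0),
        "rnaseq": DatasetSpec(coverage=0.98, noise_scale=0.15, detection_bias=1.0),
        "ihc": DatasetSpec(coverage=0.60, noise_scale=0.40, detection_bias=1.0),
    }


@dataclass
class GeneratorConfig:
    n_genes: int = 2000
    tissue_names: Sequence[str] = TISSUES_16
    breadth_mixture: tuple[float, float, float] = (0.14, 0.25, 0.61)
    dataset_specs: dict[str, DatasetSpec] = field(default_factory=default_dataset_specs)
    degree_coupling: float = 1.0
    edges_per_node: int = 3
    n_diseases: int = 0
    expression_effect: float = 1.0
    n_planted_ts_edges: int = 0
    abundance_log_sd: float = 1.2
    class_abundance_median: Mapping[str, float] = field(
        default_factory=lambda: dict(CLASS_ABUNDANCE_MEDIAN)
    )
    cross_tissue_correlation: float = 0.8
    false_positive_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_genes < 0:
            problems.append("n_genes must be >= 0")
        if len(self.tissue_names) != len(set(self.tissue_names)):
            problems.append("tissue_names must be unique")
        if len(self.breadth_mixture) != 3:
            problems.append("breadth_mixture needs exactly 3 probabilities")
        elif abs(sum(self.breadth_mixture) - 1.0) > 1e-9:
            problems.append("breadth_mixture must sum to 1 (within 1e-9)")
        elif any(p < 0 for p in self.breadth_mixture):
            problems.append("breadth_mixture probabilities must be >= 0")
        for name, spec in self.dataset_specs.items():
            if not 0 <= spec.coverage <= 1:
                problems.append(f"dataset {name}: coverage must be in [0, 1]")
            if spec.noise_scale < 0:
                problems.append(f"dataset {name}: noise_scale must be >= 0")
            if spec.detection_bias <= 0:
                problems.append(f"dataset {name}: detection_bias must be > 0")
        if self.degree_coupling < 0:
            problems.append("degree_coupling must be >= 0")
        if self.edges_per_node < 1:
            problems.append("edges_per_node must be >= 1")
        if self.n_diseases < 0:
            problems.append("n_diseases must be >= 0")
        if self.expression_effect < 1:
            problems.append("expression_effect must be >= 1")
        if self.n_planted_ts_edges < 0:
            problems.append("n_planted_ts_edges must be >= 0")
        if not 0 <= self.cross_tissue_correlation <= 1:
            problems.append("cross_tissue_correlation must be in [0, 1]")
        if not 0 <= self.false_positive_rate <= 1:
            problems.append("false_positive_rate must be in [0, 1]")
        if problems:
            raise ConfigError("; ".join(problems))

    def _rng(self, *stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % 2**31, *stream])


@dataclass(frozen=True)
class Gene:
    gene_id: str
    breadth_class: str
    expressing_tissues: frozenset[str]
    latent_abundance: Mapping[str, float]  # defined exactly on expressing tissues

    @property
    def mean_abundance(self) -> float:
        return float(np.mean(list(self.latent_abundance.values())))


@dataclass(frozen=True)
class DiseaseAssignment:
    disease_id: str
    gene_id: str
    disease_tissues: tuple[str, ...]


@dataclass
class SyntheticDataset:
    config: GeneratorConfig
    catalog: list[Gene]
    panels: dict[str, ExpressionPanel]
    network: nx.Graph
    assignments: list[DiseaseAssignment]


# ---------------------------------------------------------------------------
# catalog


def generate_catalog(config: GeneratorConfig) -> list[Gene]:
    """Draw the gene catalog: breadth class, expressing tissues, abundance.

    Class membership follows ``breadth_mixture``; tissue-set sizes follow
    the per-class distributions in :data:`CLASS_SIZE_PMF`; the expressing
    tissues themselves are a uniform subset. Log-abundance is
    gene-base + tissue-deviation, normal with total sd ``abundance_log_sd``
    around the class-dependent log-median.
    """
    config.validate()
    if config.n_genes == 0:
        return []
    rng = config._rng(0)
    tissues = list(config.tissue_names)
    n_t = len(tissues)
    sd = config.abundance_log_sd
    rho = config.cross_tissue_correlation
    sd_gene = sd * math.sqrt(rho)
    sd_tissue = sd * math.sqrt(1 - rho)

    classes = rng.choice(len(BREADTH_CLASSES), size=config.n_genes, p=list(config.breadth_mixture))
    genes: list[Gene] = []
    for i in range(config.n_genes):
        cls = BREADTH_CLASSES[classes[i]]
        pmf = CLASS_SIZE_PMF[cls]
        sizes = sorted(pmf)
        size = int(rng.choice(sizes, p=[pmf[s] for s in sizes]))
        size = min(size, n_t)
        chosen = [tissues[j] for j in rng.choice(n_t, size=size, replace=False)]
        mu = math.log(config.class_abundance_median[cls])
        base = rng.normal(mu, sd_gene)
        dev = rng.normal(0.0, sd_tissue, size=size)
        abundance = {t: float(np.exp(base + d)) for t, d in zip(chosen, dev)}
        genes.append(Gene(f"G{i:05d}", cls, frozenset(chosen), abundance))
    return genes


# ---------------------------------------------------------------------------
# expression panels


def _quant_rows(gene: Gene, noise: np.ndarray, transform) -> list[tuple]:
    rows = []
    for (t, a), eps in zip(sorted(gene.latent_abundance.items()), noise):
        rows.append((gene.gene_id, t, t, transform(a * math.exp(eps))))
    return rows


def generate_expression_panels(
    catalog: Sequence[Gene], config: GeneratorConfig
) -> dict[str, ExpressionPanel]:
    """Generate the microarray-, RNA-seq-, and IHC-like panels.

    Values exist only for (covered gene, expressing tissue) pairs -- an
    absent row is a below-detection readout. One sample per tissue per
    dataset: the subpart column repeats the tissue name and the identity
    consolidation scheme applies. A configurable false-positive rate
    (default 0) adds spurious low-abundance readouts outside the
    expressing tissues.
    """
    config.validate()
    if not catalog:
        raise ValueError("catalog is empty")
    tissues = list(config.tissue_names)
    panels: dict[str, ExpressionPanel] = {}
    for k, dataset in enumerate(DATASET_ORDER):
        spec = config.dataset_specs[dataset]
        rng = config._rng(1, k)
        covered = rng.random(len(catalog)) < spec.coverage
        quant_rows: list[tuple] = []
        ihc_meas: list[tuple] = []  # gene, tissue, measured value
        for gi, gene in enumerate(catalog):
            if not covered[gi]:
                continue
            items = sorted(gene.latent_abundance.items())
            eps = rng.normal(0.0, spec.noise_scale, size=len(items))
            extra: list[tuple[str, float]] = []
            if config.false_positive_rate > 0:
                absent = [t for t in tissues if t not in gene.expressing_tissues]
                fp_mask = rng.random(len(absent)) < config.false_positive_rate
                fp_ab = np.exp(rng.normal(
                    math.log(config.class_abundance_median["specific"]),
                    config.abundance_log_sd, size=len(absent)))
                extra = [(t, float(a)) for t, a, m in zip(absent, fp_ab, fp_mask) if m]
            measured = [(t, a * math.exp(e)) for (t, a), e in zip(items, eps)] + extra
            if dataset == "rnaseq":
                quant_rows += [(gene.gene_id, t, t, float(v)) for t, v in measured]
            elif dataset == "microarray":
                quant_rows += [
                    (gene.gene_id, t, t, float(100.0 * v / spec.detection_bias))
                    for t, v in measured
                ]
            else:
                ihc_meas += [(gene.gene_id, t, float(v / spec.detection_bias)) for t, v in measured]

        if dataset in ("rnaseq", "microarray"):
            df = pd.DataFrame(quant_rows, columns=QUANT_COLUMNS)
            df = df.sort_values(["gene_id", "tissue"], kind="stable").reset_index(drop=True)
            panels[dataset] = ExpressionPanel(dataset, dataset, df)
        else:
            values = np.array([v for _, _, v in ihc_meas]) if ihc_meas else np.array([0.0])
            cuts = np.quantile(values, [0.25, 0.5, 0.75])
            rel_names = sorted(_IHC_RELIABILITY_P)
            rel_p = [_IHC_RELIABILITY_P[r] for r in rel_names]
            rows = []
            for gene_id, t, v in ihc_meas:
                level = _ihc_level(v, cuts)
                reliability = rel_names[int(rng.choice(len(rel_names), p=rel_p))]
                validity = _draw_validity(rng)
                rows.append((gene_id, t, t, level, reliability, validity))
            df = pd.DataFrame(rows, columns=IHC_COLUMNS)
            df = df.sort_values(["gene_id", "tissue"], kind="stable").reset_index(drop=True)
            panels[dataset] = ExpressionPanel(dataset, "ihc", df, meta={"cuts": list(map(float, cuts))})
    return panels


def _ihc_level(v: float, cuts: np.ndarray) -> str:
    if v < cuts[0]:
        return "not-detected"
    if v < cuts[1]:
        return "low"
    if v < cuts[2]:
        return "medium"
    return "high"


def _draw_validity(rng: np.random.Generator) -> tuple[str, ...]:
    n_sup = int(rng.binomial(2, 0.6))
    n_unc = int(rng.binomial(1, 0.3))
    n_neg = int(rng.binomial(1, 0.2))
    return ("supportive",) * n_sup + ("uncertain",) * n_unc + ("negative",) * n_neg


# ---------------------------------------------------------------------------
# PPI network


def generate_ppi_network(catalog: Sequence[Gene], config: GeneratorConfig) -> nx.Graph:
    """Preferential attachment with abundance-weighted attachment.

    Each arriving node attaches a number of edges to existing nodes drawn
    without replacement with probability proportional to
    ``mean_abundance**degree_coupling * (degree + 1)``. Abundance couples
    into the whole degree distribution, not just the hub tail, through two
    further mass-action channels (both inactive at ``degree_coupling = 0``,
    where the construction reduces to a standard scale-free growth model):
    arrival order is an abundance-weighted random permutation (an
    exponential race -- abundant proteins enter the interaction-rich part
    of the network early), and the per-node stub count scales as
    ``edges_per_node * (abundance / median)**(degree_coupling / 2)``
    (abundant proteins initiate more interactions), tempered by the square
    root and capped at ``10 * edges_per_node`` so the log-normal abundance
    tail cannot dominate the edge budget.
    """
    config.validate()
    if not catalog:
        raise ValueError("catalog is empty")
    rng = config._rng(2)
    n = len(catalog)
    ids = [g.gene_id for g in catalog]
    abundance = np.array([g.mean_abundance for g in catalog])
    wbase = abundance ** config.degree_coupling
    rel = abundance / np.median(abundance)
    stubs = np.clip(
        np.rint(config.edges_per_node * rel ** (config.degree_coupling / 2.0)),
        1, 10 * config.edges_per_node,
    ).astype(int)
    order = np.argsort(rng.exponential(1.0, size=n) / wbase)
    g = nx.Graph(scope="global")
    g.add_nodes_from(ids)
    deg = np.zeros(n)
    for step in range(1, n):
        i = order[step]
        prev = order[:step]
        w = wbase[prev] * (deg[prev] + 1.0)
        p = w / w.sum()
        m = min(int(stubs[i]), step)
        targets = rng.choice(step, size=m, replace=False, p=p)
        for t in targets:
            j = prev[t]
            g.add_edge(ids[i], ids[j], sources={"synthetic"})
            deg[i] += 1
            deg[j] += 1
    return g


# ---------------------------------------------------------------------------
# disease planting


def plant_disease_panel(
    catalog: Sequence[Gene],
    panels: Mapping[str, ExpressionPanel],
    network: nx.Graph | None,
    config: GeneratorConfig,
) -> SyntheticDataset:
    """Select causal genes, assign disease tissues, and plant effects.

    Causal genes are drawn among genes expressed in >= 4 tissues that the
    RNA-seq panel covers (so the expression effect has a value to scale);
    each disease gets one causal gene and 1-2 disease tissues drawn
    uniformly from the gene's expressing tissues. ``expression_effect``
    multiplies the gene's RNA-seq values in its disease tissues;
    ``n_planted_ts_edges`` edges per causal gene are added to partner genes
    expressed only in the (first) disease tissue, minting new
    tissue-specific genes when no unused eligible partner exists. With
    ``expression_effect == 1`` and ``n_planted_ts_edges == 0`` (null mode)
    the inputs are returned unmodified.
    """
    config.validate()
    catalog = list(catalog)
    rng = config._rng(3)
    assignments: list[DiseaseAssignment] = []
    if config.n_diseases > 0:
        rnaseq_genes = set(panels["rnaseq"].records["gene_id"])
        eligible = [
            g for g in catalog
            if len(g.expressing_tissues) >= 4 and g.gene_id in rnaseq_genes
        ]
        if len(eligible) < config.n_diseases:
            raise ConfigError(
                f"need {config.n_diseases} causal genes but only {len(eligible)} are "
                "eligible (expressed in >= 4 tissues and covered by the RNA-seq panel)"
            )
        chosen = rng.choice(len(eligible), size=config.n_diseases, replace=False)
        for d, gi in enumerate(chosen):
            gene = eligible[gi]
            x = int(rng.integers(1, 3))
            tset = sorted(gene.expressing_tissues)
            dts = tuple(sorted(tset[j] for j in rng.choice(len(tset), size=x, replace=False)))
            assignments.append(DiseaseAssignment(f"D{d:04d}", gene.gene_id, dts))

    null_mode = config.expression_effect == 1.0 and config.n_planted_ts_edges == 0
    if null_mode:
        return SyntheticDataset(config, catalog, dict(panels), network, assignments)

    panels = dict(panels)
    if config.expression_effect > 1.0:
        df = panels["rnaseq"].records.copy()
        for a in assignments:
            mask = (df["gene_id"] == a.gene_id) & df["tissue"].isin(a.disease_tissues)
            df.loc[mask, "value"] *= config.expression_effect
        panels["rnaseq"] = ExpressionPanel("rnaseq", "rnaseq", df, meta=dict(panels["rnaseq"].meta))

    if config.n_planted_ts_edges > 0:
        if network is None:
            raise ConfigError("n_planted_ts_edges > 0 requires a network")
        network = network.copy()
        by_single_tissue: dict[str, list[Gene]] = {}
        for g in catalog:
            if len(g.expressing_tissues) == 1:
                (t,) = g.expressing_tissues
                by_single_tissue.setdefault(t, []).append(g)
        minted = 0
        new_rows: list[tuple] = []
        sd_t = config.abundance_log_sd * math.sqrt(1 - config.cross_tissue_correlation)
        sd_g = config.abundance_log_sd * math.sqrt(config.cross_tissue_correlation)
        for a in assignments:
            dt = a.disease_tissues[0]
            pool = [
                g for g in by_single_tissue.get(dt, [])
                if g.gene_id != a.gene_id and not network.has_edge(a.gene_id, g.gene_id)
            ]
            idx = rng.permutation(len(pool))
            take = [pool[j] for j in idx[: config.n_planted_ts_edges]]
            while len(take) < config.n_planted_ts_edges:
                mu = math.log(config.class_abundance_median["specific"])
                ab = float(np.exp(rng.normal(mu, sd_g) + rng.normal(0.0, sd_t)))
                new = Gene(f"TS{minted:05d}", "specific", frozenset({dt}), {dt: ab})
                minted += 1
                catalog.append(new)
                by_single_tissue.setdefault(dt, []).append(new)
                # minted partners appear in the RNA-seq panel (an RNA-seq-
                # detected tissue-specific transcript)
                noise = math.exp(rng.normal(0.0, config.dataset_specs["rnaseq"].noise_scale))
                new_rows.append((new.gene_id, dt, dt, ab * noise))
                take.append(new)
            for partner in take:
                network.add_edge(a.gene_id, partner.gene_id, sources={"synthetic-planted"})
        if new_rows:
            df = panels["rnaseq"].records
            df = pd.concat([df, pd.DataFrame(new_rows, columns=QUANT_COLUMNS)], ignore_index=True)
            df = df.sort_values(["gene_id", "tissue"], kind="stable").reset_index(drop=True)
            panels["rnaseq"] = ExpressionPanel("rnaseq", "rnaseq", df, meta=dict(panels["rnaseq"].meta))

    return SyntheticDataset(config, catalog, panels, network, assignments)


# ---------------------------------------------------------------------------
# one-call front end


def simulate(config: GeneratorConfig) -> SyntheticDataset:
    """Catalog -> panels -> network -> disease planting, all from one seed."""
    catalog = generate_catalog(config)
    panels = generate_expression_panels(catalog, config)
    network = generate_ppi_network(catalog, config)
    return plant_disease_panel(catalog, panels, network, config)


def null_config(config: GeneratorConfig) -> GeneratorConfig:
    """The matched no-effect configuration (same seed and sizes)."""
    return replace(config, expression_effect=1.0, n_planted_ts_edges=0)
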