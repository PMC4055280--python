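"""Disease-gene statistics: median contrasts, permutation test, overlaps.

For each causal gene and each per-tissue metric (RPKM, PPI degree, TS-PPI
count) we compare the median over the gene's disease tissues (V_d) with
the median over its non-disease expressing tissues (V_nd); a strict
V_d > V_nd is a success. Significance of the total success count is
assessed by a label permutation: each run redraws, independently per gene,
a uniformly random x-subset of the gene's expressing tissues as its
"disease" tissues (x = the gene's true number of disease tissues) and
recounts successes; the p-value is the fraction of runs whose success
count is at least the observed one. Tissue-specific disease genes (no
non-disease expressing tissue) are excluded throughout. An exact mode
enumerates each gene's selection space and convolves the per-gene success
probabilities into the exact Poisson-binomial null.
"""

from __future__ import annotations

import csv
import hashlib
import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError, ExcludedGeneError
from .expression import Expressome, fisher_overlap_p
from .interactome import TSPPISet

logger = logging.getLogger(__name__)

METRICS = ("rpkm", "degree", "tsppi_count")


@dataclass(frozen=True)
class DiseaseEntry:
    disease_id: str
    tissues: frozenset[str]
    genes: tuple[str, ...]


@dataclass
class GeneRecord:
    """One analyzed causal gene.

    ``disease_tissues`` is the union over the gene's diseases of the
    disease tissues in which the gene is expressed (a gene causal for
    several diseases contributes once, with pooled tissues). ``excluded``
    flags tissue-specific disease genes, whose non-disease set is empty.
    """

    gene_id: str
    expressing: tuple[str, ...]  # sorted
    disease_tissues: frozenset[str]
    metrics: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.disease_tissues:
            raise ValueError(f"gene {self.gene_id}: empty disease-tissue set")
        if not self.disease_tissues <= set(self.expressing):
            raise ValueError(f"gene {self.gene_id}: disease tissues not all expressing")

    @property
    def excluded(self) -> bool:
        return len(set(self.expressing) - self.disease_tissues) == 0

    @property
    def x(self) -> int:
        return len(self.disease_tissues)

    def values(self, metric: str) -> np.ndarray:
        vals = self.metrics[metric]
        return np.array([vals.get(t, 0.0) for t in self.expressing], dtype=float)


@dataclass
class DiseasePanel:
    diseases: list[DiseaseEntry]
    genes: dict[str, GeneRecord]
    n_dropped_rows: int = 0
    n_dropped_associations: int = 0

    def included_genes(self) -> list[GeneRecord]:
        return [r for _, r in sorted(self.genes.items()) if not r.excluded]


@dataclass
class MedianContrast:
    gene_id: str
    metric: str
    v_d: float
    v_nd: float

    @property
    def success(self) -> bool:
        return self.v_d > self.v_nd


@dataclass
class PermutationResult:
    metric: str
    observed: int
    n_genes: int
    mode: str
    p_value: float
    seed: int | None = None
    n_runs: int | None = None
    null_counts: np.ndarray | None = None
    exact_null_pmf: np.ndarray | None = None
    add_one: bool = False


# ---------------------------------------------------------------------------
# panel loading


def read_associations(path) -> pd.DataFrame:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != ["disease_id", "gene_id", "tissue"]:
            raise ConfigError(f"bad associations header: {header!r}")
        rows = [r for r in reader if r and any(c.strip() for c in r)]
    return pd.DataFrame(rows, columns=["disease_id", "gene_id", "tissue"])


def load_disease_panel(
    associations: pd.DataFrame | str | Path,
    expressome: Expressome,
    rpkm: pd.DataFrame | None = None,
    tissue_graphs: Mapping[str, nx.Graph] | None = None,
    tsppis: TSPPISet | None = None,
    tissue_vocab: Iterable[str] | None = None,
) -> DiseasePanel:
    """Apply the expressed-in-disease-tissue filter and attach metrics.

    Rows naming an unknown tissue or a gene absent from the expression
    data are dropped with a warning; (disease, gene) associations whose
    gene is expressed in none of the disease tissues are dropped and
    counted. ``rpkm`` is a gene_id/tissue/value frame (RNA-seq panel,
    consolidated); degree and TS-PPI counts come from the tissue
    interactomes when provided.
    """
    if not isinstance(associations, pd.DataFrame):
        associations = read_associations(associations)
    vocab = set(tissue_vocab) if tissue_vocab is not None else set(expressome.tissues)
    expressed_in: dict[str, set[str]] = {}
    for t, genes in expressome.tissues.items():
        for g in genes:
            expressed_in.setdefault(g, set()).add(t)

    n_dropped_rows = 0
    clean = []
    for row in associations.itertuples(index=False):
        if row.tissue not in vocab:
            logger.warning("dropping row: unknown tissue %r", row.tissue)
            n_dropped_rows += 1
            continue
        if row.gene_id not in expressed_in:
            logger.warning("dropping row: gene %r absent from expression data", row.gene_id)
            n_dropped_rows += 1
            continue
        clean.append((row.disease_id, row.gene_id, row.tissue))

    # group rows into (disease, gene) associations with tissue sets
    assoc: dict[tuple[str, str], set[str]] = {}
    for did, gid, t in clean:
        assoc.setdefault((did, gid), set()).add(t)

    n_dropped_assoc = 0
    diseases: dict[str, dict] = {}
    per_gene_tissues: dict[str, set[str]] = {}
    for (did, gid), tset in sorted(assoc.items()):
        expressed_dts = tset & expressed_in[gid]
        if not expressed_dts:
            n_dropped_assoc += 1
            continue
        d = diseases.setdefault(did, {"tissues": set(), "genes": set()})
        d["tissues"] |= tset
        d["genes"].add(gid)
        per_gene_tissues.setdefault(gid, set()).update(expressed_dts)

    rpkm_lookup: dict[tuple[str, str], float] = {}
    if rpkm is not None:
        for row in rpkm.itertuples(index=False):
            rpkm_lookup[(row.gene_id, row.tissue)] = float(row.value)

    genes: dict[str, GeneRecord] = {}
    for gid, dts in sorted(per_gene_tissues.items()):
        expressing = tuple(sorted(expressed_in[gid]))
        metrics: dict[str, dict[str, float]] = {}
        if rpkm is not None:
            metrics["rpkm"] = {t: rpkm_lookup.get((gid, t), 0.0) for t in expressing}
        if tissue_graphs is not None:
            metrics["degree"] = {
                t: float(tissue_graphs[t].degree(gid)) if gid in tissue_graphs[t] else 0.0
                for t in expressing
            }
        if tsppis is not None:
            metrics["tsppi_count"] = {t: float(tsppis.count_for(gid, t)) for t in expressing}
        genes[gid] = GeneRecord(gid, expressing, frozenset(dts), metrics)

    entries = [
        DiseaseEntry(did, frozenset(d["tissues"]), tuple(sorted(d["genes"])))
        for did, d in sorted(diseases.items())
    ]
    return DiseasePanel(entries, genes, n_dropped_rows, n_dropped_assoc)


# ---------------------------------------------------------------------------
# median contrast


def median_contrast(record: GeneRecord, metric: str) -> MedianContrast:
    """V_d / V_nd medians over expressing tissues; strict success.

    Even-length medians are midpoints of the two central values.
    """
    if record.excluded:
        raise ExcludedGeneError(
            f"gene {record.gene_id} is tissue-specific for its diseases "
            "(no non-disease expressing tissue)"
        )
    vals = record.values(metric)
    mask = np.array([t in record.disease_tissues for t in record.expressing])
    v_d = float(np.median(vals[mask]))
    v_nd = float(np.median(vals[~mask]))
    return MedianContrast(record.gene_id, metric, v_d, v_nd)


def compute_contrasts(panel: DiseasePanel, metrics: Sequence[str]) -> dict[str, dict[str, MedianContrast]]:
    out: dict[str, dict[str, MedianContrast]] = {}
    for metric in metrics:
        out[metric] = {
            rec.gene_id: median_contrast(rec, metric) for rec in panel.included_genes()
        }
    return out


# ---------------------------------------------------------------------------
# permutation test


def _gene_stream(seed: int, gene_id: str) -> np.random.Generator:
    # keyed by a stable hash of the gene id so results are independent of
    # gene iteration order (and of genes that are skipped as excluded)
    h = int.from_bytes(hashlib.sha256(gene_id.encode()).digest()[:4], "big")
    return np.random.default_rng([int(seed) % 2**31, h])


def _exact_success_prob(values: np.ndarray, x: int) -> tuple[int, float]:
    """(number of selections, success probability) by exhaustive enumeration."""
    m = len(values)
    idx = range(m)
    n_success = 0
    total = 0
    for combo in itertools.combinations(idx, x):
        sel = np.array(combo)
        rest = np.setdiff1d(np.arange(m), sel)
        if np.median(values[sel]) > np.median(values[rest]):
            n_success += 1
        total += 1
    return total, n_success / total


def permutation_test(
    panel: DiseasePanel,
    metric: str,
    n_runs: int = 10_000,
    seed: int = 0,
    mode: str = "monte_carlo",
    add_one: bool = False,
    max_enumeration: int = 1_000_000,
) -> PermutationResult:
    """Label-permutation significance of the total success count.

    Monte-Carlo mode: each run redraws, independently per gene, a uniform
    x-subset of the gene's expressing tissues and recounts successes;
    p = (#runs with null >= observed) / n_runs (the raw fraction; the
    ``add_one`` Davison-Hinkley variant, (r+1)/(n+1), avoids p = 0).
    Exact mode: enumerates each gene's selection space and convolves the
    per-gene Bernoulli success probabilities into the exact null of the
    success-count sum, returning the exact upper-tail probability.
    """
    records = panel.included_genes()
    if not records:
        raise ConfigError("all disease genes are excluded (tissue-specific)")
    if mode not in ("monte_carlo", "exact"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "monte_carlo" and n_runs < 1:
        raise ConfigError("n_runs must be >= 1")

    observed = sum(median_contrast(r, metric).success for r in records)

    if mode == "exact":
        total_selections = sum(math.comb(len(r.expressing), r.x) for r in records)
        if total_selections > max_enumeration:
            raise ConfigError(
                f"exact mode would enumerate {total_selections} selections "
                f"(> {max_enumeration}); use monte_carlo"
            )
        pmf = np.array([1.0])
        for rec in records:
            _, p_g = _exact_success_prob(rec.values(metric), rec.x)
            pmf = np.convolve(pmf, [1.0 - p_g, p_g])
        p = float(pmf[observed:].sum())
        return PermutationResult(
            metric, observed, len(records), "exact", p, exact_null_pmf=pmf
        )

    null_counts = np.zeros(n_runs, dtype=np.int64)
    for rec in records:
        rng = _gene_stream(seed, rec.gene_id)
        v = rec.values(metric)
        m, x = len(v), rec.x
        r = rng.random((n_runs, m))
        part = np.argpartition(r, x - 1, axis=1)
        sel = v[part[:, :x]]
        rest = v[part[:, x:]]
        v_d = np.median(sel, axis=1)
        v_nd = np.median(rest, axis=1)
        null_counts += v_d > v_nd
    n_ge = int((null_counts >= observed).sum())
    p = (n_ge + 1) / (n_runs + 1) if add_one else n_ge / n_runs
    return PermutationResult(
        metric, observed, len(records), "monte_carlo", float(p),
        seed=seed, n_runs=n_runs, null_counts=null_counts, add_one=add_one,
    )


# ---------------------------------------------------------------------------
# factor overlaps


@dataclass
class OverlapReport:
    pairwise: pd.DataFrame
    tsppi_enrichment: dict | None = None


def factor_overlap_tests(
    panel: DiseasePanel,
    contrasts: Mapping[str, Mapping[str, MedianContrast]],
    interactome_genes: set[str] | None = None,
    genes_with_tsppi: set[str] | None = None,
) -> OverlapReport:
    """One-sided Fisher overlaps between the per-metric success gene sets.

    The universe is the set of analyzed (non-excluded) disease genes.
    Optionally also tests whether causal genes are enriched among
    interactome genes with at least one TS-PPI anywhere.
    """
    included = [r.gene_id for r in panel.included_genes()]
    if not included:
        raise ConfigError("empty universe: no included disease genes")
    universe = len(included)
    success_sets = {
        metric: {g for g, c in contrasts[metric].items() if c.success}
        for metric in sorted(contrasts)
    }
    rows = []
    names = sorted(success_sets)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            sa, sb = success_sets[a], success_sets[b]
            if not sa or not sb:
                warnings.warn(f"empty success set in overlap test ({a} vs {b}); p = 1")
                p = 1.0
            else:
                p = fisher_overlap_p(len(sa), len(sb), len(sa & sb), universe)
            rows.append((a, b, len(sa), len(sb), len(sa & sb), universe, p))
    pairwise = pd.DataFrame(
        rows, columns=["metric_a", "metric_b", "n_a", "n_b", "overlap", "universe", "fisher_p"]
    )

    enrichment = None
    if interactome_genes is not None and genes_with_tsppi is not None:
        causal = set(panel.genes) & interactome_genes
        with_ts = genes_with_tsppi & interactome_genes
        k = len(causal & with_ts)
        p = fisher_overlap_p(len(causal), len(with_ts), k, len(interactome_genes))
        enrichment = {
            "n_interactome": len(interactome_genes),
            "n_causal_in_interactome": len(causal),
            "n_with_tsppi": len(with_ts),
            "n_causal_with_tsppi": k,
            "fisher_p": p,
        }
    return OverlapReport(pairwise, enrichment)


# ---------------------------------------------------------------------------
# TS-PPI candidate report


def tsppi_candidate_report(
    panel: DiseasePanel,
    tsppis: TSPPISet,
    tissue_graphs: Mapping[str, nx.Graph],
) -> pd.DataFrame:
    """Per (disease, gene, disease tissue): the TS-PPI candidate filter.

    Reports the gene's total PPIs in the tissue, its TS-PPI partners
    there, and the reduction factor total/TS-PPI count (null when the gene
    has no TS-PPI in the tissue). Focusing follow-up on the TS-PPI
    partners shrinks the candidate interaction list by this factor.
    """
    rows = []
    for disease in panel.diseases:
        for gid in disease.genes:
            rec = panel.genes.get(gid)
            if rec is None:
                continue
            for tissue in sorted(disease.tissues & set(rec.expressing)):
                g = tissue_graphs.get(tissue)
                total = int(g.degree(gid)) if g is not None and gid in g else 0
                partners = tsppis.partners_of(gid, tissue)
                factor = (total / len(partners)) if partners else None
                rows.append((
                    disease.disease_id, gid, tissue, total, len(partners),
                    ";".join(partners), factor,
                ))
    return pd.DataFrame(rows, columns=[
        "disease_id", "gene_id", "tissue", "total_ppis", "n_tsppi",
        "tsppi_partners", "reduction_factor",
    ])


# ---------------------------------------------------------------------------
# disease-level factor summary


def disease_factor_summary(
    panel: DiseasePanel,
    contrasts: Mapping[str, Mapping[str, MedianContrast]],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Label each disease by its causal genes' success factors.

    A disease counts as "elevated" (resp. "tsppi") if ANY of its
    non-excluded causal genes has a success for the rpkm (resp.
    tsppi_count) metric; labels are both / elevated-only / tsppi-only /
    neither, and the headline fraction is elevated-and/or-tsppi.
    """
    rows = []
    for disease in panel.diseases:
        elevated = any(
            contrasts.get("rpkm", {}).get(g) is not None
            and contrasts["rpkm"][g].success
            for g in disease.genes
        )
        tsppi = any(
            contrasts.get("tsppi_count", {}).get(g) is not None
            and contrasts["tsppi_count"][g].success
            for g in disease.genes
        )
        if elevated and tsppi:
            label = "both"
        elif elevated:
            label = "elevated-only"
        elif tsppi:
            label = "tsppi-only"
        else:
            label = "neither"
        rows.append((disease.disease_id, elevated, tsppi, label))
    df = pd.DataFrame(rows, columns=["disease_id", "elevated", "tsppi", "label"])
    n = len(df)
    fractions = {
        label: (float((df["label"] == label).mean()) if n else float("nan"))
        for label in ("both", "elevated-only", "tsppi-only", "neither")
    }
    fractions["elevated_or_tsppi"] = (
        float(((df["elevated"]) | (df["tsppi"])).mean()) if n else float("nan")
    )
    return df, fractions
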