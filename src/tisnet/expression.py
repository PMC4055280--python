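"""Expression panels, expressed-gene calling, and tissue expressomes.

Three kinds of expression evidence are supported, mirroring the three
platforms commonly integrated for human tissue profiling:

* ``microarray`` -- quantitative intensities; a gene is expressed in a
  sample when its intensity is strictly above the threshold (default 100).
* ``rnaseq`` -- quantitative RPKM; expressed when the value is at least
  the threshold (default 1.0 RPKM).
* ``ihc`` -- ordinal immunohistochemistry calls (level, antibody
  reliability, antibody validity); expressed when the staining level is
  low/medium/high and the antibody passes the reliability-or-validity rule.

Per-dataset calls are made at the finest sampling level (tissue subpart or
sample), consolidated into 16 main tissues via a :class:`ConsolidationScheme`,
and combined across datasets by union ("expressed in at least one dataset").
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from scipy import stats

from .errors import ParseError, UnmappedSubpartError

logger = logging.getLogger(__name__)

QUANT_DIALECTS = ("microarray", "rnaseq")
DIALECTS = QUANT_DIALECTS + ("ihc",)

QUANT_COLUMNS = ["gene_id", "tissue", "subpart", "value"]
IHC_COLUMNS = ["gene_id", "tissue", "subpart", "level", "reliability", "validity"]

LEVELS = ("not-detected", "low", "medium", "high")
RELIABILITIES = ("high", "medium", "low", "absent")
VALIDITY_TOKENS = ("supportive", "uncertain", "negative")

#: default stringent thresholds; the relaxed variants are 30 / 0.3
DEFAULT_THRESHOLDS = {"microarray": 100.0, "rnaseq": 1.0}

BREADTH_SPECIFIC_MAX = 3
BREADTH_GLOBAL_MIN = 14
N_MAIN_TISSUES = 16


@dataclass
class ExpressionPanel:
    """One dataset's expression records.

    ``records`` is a DataFrame with columns :data:`QUANT_COLUMNS` for the
    quantitative dialects or :data:`IHC_COLUMNS` for the ordinal dialect
    (``validity`` holds a tuple of tokens). ``(gene, subpart)`` pairs may
    repeat: multiple measurements are resolved at call time.
    """

    dataset_id: str
    dialect: str
    records: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def is_quantitative(self) -> bool:
        return self.dialect in QUANT_DIALECTS


@dataclass
class ConsolidationScheme:
    """Maps each (dataset, subpart) to one of the 16 main tissues."""

    mapping: Mapping[tuple[str, str], str]

    def tissue_for(self, dataset_id: str, subpart: str) -> str:
        try:
            return self.mapping[(dataset_id, subpart)]
        except KeyError:
            raise UnmappedSubpartError(f"unmapped subpart: {subpart}") from None

    @classmethod
    def from_yaml(cls, path) -> "ConsolidationScheme":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        mapping = {}
        for dataset_id, submap in raw.items():
            for subpart, tissue in (submap or {}).items():
                mapping[(str(dataset_id), str(subpart))] = str(tissue)
        return cls(mapping)

    def to_yaml(self, path) -> None:
        out: dict[str, dict[str, str]] = {}
        for (ds, sp), tissue in sorted(self.mapping.items()):
            out.setdefault(ds, {})[sp] = tissue
        with open(path, "w") as fh:
            yaml.safe_dump(out, fh, sort_keys=True)

    @classmethod
    def identity(cls, dataset_ids: Iterable[str], tissues: Iterable[str]) -> "ConsolidationScheme":
        tissues = list(tissues)
        return cls({(ds, t): t for ds in dataset_ids for t in tissues})


@dataclass
class Expressome:
    """Sets of expressed genes per tissue, with the finest-level sets kept.

    ``subpart_sets`` retains the per-(dataset, subpart) expressed sets; the
    tissue interactome filter needs them because co-expression is required
    within a single subpart/sample, not merely within the tissue.
    """

    scope: str  # "dataset:<id>" or "combined"
    tissues: dict[str, set[str]]
    subpart_sets: dict[tuple[str, str], frozenset[str]]
    subpart_tissue: dict[tuple[str, str], str]

    def genes(self) -> set[str]:
        out: set[str] = set()
        for s in self.tissues.values():
            out |= s
        return out

    def subparts_of(self, tissue: str) -> list[tuple[str, str]]:
        return [k for k, t in self.subpart_tissue.items() if t == tissue]


# ---------------------------------------------------------------------------
# reading / writing


def read_expression_table(path, dialect: str, dataset_id: str | None = None) -> ExpressionPanel:
    """Parse a tab-delimited expression table; errors carry line numbers."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect: {dialect!r}")
    expected = QUANT_COLUMNS if dialect in QUANT_DIALECTS else IHC_COLUMNS
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty file, header missing", line=1) from None
        if header != expected:
            raise ParseError(
                f"bad header {header!r}, expected {expected!r}", line=1
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(expected):
                raise ParseError(
                    f"expected {len(expected)} columns, got {len(row)}", line=lineno
                )
            if dialect in QUANT_DIALECTS:
                gene, tissue, subpart, value = row
                try:
                    v = float(value)
                except ValueError:
                    raise ParseError(f"non-numeric value {value!r}", line=lineno) from None
                if v < 0:
                    raise ParseError(f"negative value {v}", line=lineno)
                rows.append((gene, tissue, subpart, v))
            else:
                gene, tissue, subpart, level, reliability, validity = row
                if level not in LEVELS:
                    raise ParseError(f"unknown level {level!r}", line=lineno)
                if reliability not in RELIABILITIES:
                    raise ParseError(f"unknown reliability {reliability!r}", line=lineno)
                tokens = tuple(t for t in validity.split(",") if t)
                for t in tokens:
                    if t not in VALIDITY_TOKENS:
                        raise ParseError(f"unknown validity token {t!r}", line=lineno)
                rows.append((gene, tissue, subpart, level, reliability, tokens))
    records = pd.DataFrame(rows, columns=expected)
    if records.empty:
        records = pd.DataFrame(columns=expected)
    return ExpressionPanel(dataset_id or dialect, dialect, records)


def write_expression_table(panel: ExpressionPanel, path) -> None:
    df = panel.records
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        if panel.is_quantitative:
            writer.writerow(QUANT_COLUMNS)
            for row in df.itertuples(index=False):
                writer.writerow([row.gene_id, row.tissue, row.subpart, repr(float(row.value))])
        else:
            writer.writerow(IHC_COLUMNS)
            for row in df.itertuples(index=False):
                writer.writerow(
                    [row.gene_id, row.tissue, row.subpart, row.level,
                     row.reliability, ",".join(row.validity)]
                )


# ---------------------------------------------------------------------------
# expressed-gene calling


def call_expressed_quantitative(
    panel: ExpressionPanel, threshold: float, strict: bool | None = None
) -> dict[str, set[str]]:
    """Per-subpart expressed gene sets for a quantitative panel.

    ``strict`` controls the comparison: strictly above for microarray
    intensities ("above 100"), at-least for RNA-seq RPKM ("at least 1").
    Repeated (gene, subpart) measurements use the highest value.
    """
    if not panel.is_quantitative:
        raise TypeError("ordinal (ihc) panel passed to call_expressed_quantitative")
    if strict is None:
        strict = panel.dialect == "microarray"
    df = panel.records
    out: dict[str, set[str]] = {sp: set() for sp in df["subpart"].unique()}
    if df.empty:
        return out
    best = df.groupby(["subpart", "gene_id"], sort=False)["value"].max()
    mask = best > threshold if strict else best >= threshold
    for (subpart, gene) in best.index[mask]:
        out[subpart].add(gene)
    return out


def _ihc_qualifies(level: str, reliability: str, validity: Sequence[str]) -> bool:
    if level not in ("low", "medium", "high"):
        return False
    if reliability in ("medium", "high"):
        return True
    # low or absent reliability falls through to the validity rule
    return "supportive" in validity and "negative" not in validity


def call_expressed_ihc(panel: ExpressionPanel) -> dict[str, set[str]]:
    """Per-subpart expressed sets under the antibody reliability/validity rule.

    A gene is expressed in a subpart iff at least one of its antibody
    measurements there has level low/medium/high AND either a medium/high
    reliability score or, failing that, >=1 supportive and 0 negative
    validity scores. With repeated measurements any qualifying antibody
    suffices (highest level wins; the rule is monotone in level).
    """
    if panel.is_quantitative:
        raise TypeError("quantitative panel passed to call_expressed_ihc")
    df = panel.records
    out: dict[str, set[str]] = {sp: set() for sp in df["subpart"].unique()}
    for row in df.itertuples(index=False):
        if row.gene_id in out[row.subpart]:
            continue
        if _ihc_qualifies(row.level, row.reliability, row.validity):
            out[row.subpart].add(row.gene_id)
        elif row.reliability in ("low", "absent") and row.level != "not-detected":
            logger.debug(
                "gene %s subpart %s: reliability %r fell through to validity rule and failed",
                row.gene_id, row.subpart, row.reliability,
            )
    return out


def call_expressed(panel: ExpressionPanel, thresholds: Mapping[str, float] | None = None) -> dict[str, set[str]]:
    """Dispatch on dialect with the default (or given) thresholds."""
    if panel.dialect == "ihc":
        return call_expressed_ihc(panel)
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    return call_expressed_quantitative(panel, thr[panel.dialect])


# ---------------------------------------------------------------------------
# consolidation and combination


def consolidate(
    expressed: Mapping[str, Iterable[str]],
    scheme: ConsolidationScheme,
    dataset_id: str,
) -> Expressome:
    """Union per-subpart sets into main-tissue sets, keeping the subpart sets."""
    tissues: dict[str, set[str]] = {}
    subpart_sets: dict[tuple[str, str], frozenset[str]] = {}
    subpart_tissue: dict[tuple[str, str], str] = {}
    for subpart, genes in expressed.items():
        tissue = scheme.tissue_for(dataset_id, subpart)
        genes = frozenset(genes)
        key = (dataset_id, subpart)
        subpart_sets[key] = genes
        subpart_tissue[key] = tissue
        tissues.setdefault(tissue, set()).update(genes)
    return Expressome(f"dataset:{dataset_id}", tissues, subpart_sets, subpart_tissue)


def combine_datasets(expressomes: Sequence[Expressome]) -> Expressome:
    """Per-tissue union across datasets; subpart-level sets are retained."""
    tissues: dict[str, set[str]] = {}
    subpart_sets: dict[tuple[str, str], frozenset[str]] = {}
    subpart_tissue: dict[tuple[str, str], str] = {}
    for ex in expressomes:
        for t, genes in ex.tissues.items():
            tissues.setdefault(t, set()).update(genes)
        subpart_sets.update(ex.subpart_sets)
        subpart_tissue.update(ex.subpart_tissue)
    return Expressome("combined", tissues, subpart_sets, subpart_tissue)


# ---------------------------------------------------------------------------
# breadth classification


def classify_breadth(n_tissues: int) -> str:
    if n_tissues <= BREADTH_SPECIFIC_MAX:
        return "specific"
    if n_tissues >= BREADTH_GLOBAL_MIN:
        return "global"
    return "intermediate"


def breadth_classify(expressome: Expressome) -> pd.DataFrame:
    """Per-gene expressing-tissue count and breadth class (combined scope).

    Genes expressed in 1-3 tissues are tissue-specific, 14-16 globally
    expressed, the remainder intermediate. Genes in zero tissues do not
    appear (there is nothing to count).
    """
    counts: dict[str, int] = {}
    for genes in expressome.tissues.values():
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    rows = [(g, n, classify_breadth(n)) for g, n in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["gene_id", "n_tissues", "breadth_class"])


def breadth_histogram(classified: pd.DataFrame, n_max: int = N_MAIN_TISSUES) -> pd.Series:
    """Histogram of gene counts over breadth 1..n_max."""
    counts = classified["n_tissues"].value_counts()
    return counts.reindex(range(1, n_max + 1), fill_value=0).sort_index()


# ---------------------------------------------------------------------------
# cross-dataset compatibility


def fisher_overlap_p(n_a: int, n_b: int, overlap: int, universe: int) -> float:
    """One-sided (upper tail) Fisher exact p for the overlap of two sets."""
    if overlap == 0 and (n_a == 0 or n_b == 0):
        warnings.warn("overlap test with an empty set; reporting p = 1")
        return 1.0
    return float(stats.hypergeom.sf(overlap - 1, universe, n_a, n_b))


_LEVEL_CODE = {lvl: i for i, lvl in enumerate(LEVELS)}


def tissue_values(panel: ExpressionPanel, scheme: ConsolidationScheme) -> pd.DataFrame:
    """Per-(gene, main tissue) expression value: max over subparts/replicates.

    Ordinal levels are coded 0..3 so that rank statistics apply uniformly.
    """
    df = panel.records
    if df.empty:
        return pd.DataFrame(columns=["gene_id", "tissue", "value"])
    if panel.is_quantitative:
        vals = df["value"]
    else:
        vals = df["level"].map(_LEVEL_CODE).astype(float)
    tmp = pd.DataFrame({
        "gene_id": df["gene_id"],
        "tissue": [scheme.tissue_for(panel.dataset_id, sp) for sp in df["subpart"]],
        "value": vals,
    })
    out = tmp.groupby(["gene_id", "tissue"], sort=True, as_index=False)["value"].max()
    return out


@dataclass
class CompatibilityReport:
    """Cross-dataset overlap and concordance of tissue expressomes."""

    pairs: pd.DataFrame       # dataset_a, tissue_a, dataset_b, tissue_b, overlap stats, tau
    match_ranks: pd.DataFrame  # dataset_a, dataset_b, tissue, rank of the matching tissue


def dataset_compatibility(
    expressomes: Sequence[Expressome],
    panels: Sequence[ExpressionPanel],
    scheme: ConsolidationScheme,
    universe_size: int,
) -> CompatibilityReport:
    """Fisher overlap + Kendall tau between every cross-dataset tissue pair.

    For each pair of datasets and each tissue pair, reports the one-sided
    Fisher exact p for the expressome overlap (hypergeometric upper tail on
    the stated protein universe) and Kendall's tau over the expression
    levels of commonly expressed genes; then, per tissue, the rank of the
    matching tissue among all cross-dataset correlations (1 = best).
    """
    by_id = {p.dataset_id: p for p in panels}
    ex_by_id = {}
    for ex in expressomes:
        if not ex.scope.startswith("dataset:"):
            raise ValueError("dataset_compatibility expects dataset-scoped expressomes")
        ex_by_id[ex.scope.split(":", 1)[1]] = ex
    values = {ds: tissue_values(by_id[ds], scheme) for ds in ex_by_id if ds in by_id}

    rows = []
    ids = sorted(ex_by_id)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            for ta, genes_a in sorted(ex_by_id[a].tissues.items()):
                for tb, genes_b in sorted(ex_by_id[b].tissues.items()):
                    ov = genes_a & genes_b
                    p = fisher_overlap_p(len(genes_a), len(genes_b), len(ov), universe_size)
                    tau = tau_p = float("nan")
                    if a in values and b in values:
                        va = values[a][values[a]["tissue"] == ta].set_index("gene_id")["value"]
                        vb = values[b][values[b]["tissue"] == tb].set_index("gene_id")["value"]
                        common = sorted(set(va.index) & set(vb.index) & ov)
                        if len(common) >= 2:
                            res = stats.kendalltau(va.loc[common], vb.loc[common])
                            tau, tau_p = float(res.statistic), float(res.pvalue)
                    rows.append((a, ta, b, tb, len(genes_a), len(genes_b), len(ov), p, tau, tau_p))
    pairs = pd.DataFrame(rows, columns=[
        "dataset_a", "tissue_a", "dataset_b", "tissue_b",
        "n_a", "n_b", "overlap", "fisher_p", "kendall_tau", "kendall_p",
    ])

    rank_rows = []
    for (a, b), grp in pairs.groupby(["dataset_a", "dataset_b"]):
        for tissue in sorted(set(grp["tissue_a"]) & set(grp["tissue_b"])):
            sub = grp[grp["tissue_a"] == tissue].dropna(subset=["kendall_tau"])
            if sub.empty:
                continue
            ranked = sub.sort_values("kendall_tau", ascending=False).reset_index()
            pos = ranked.index[ranked["tissue_b"] == tissue]
            if len(pos):
                rank_rows.append((a, b, tissue, int(pos[0]) + 1, len(ranked)))
    match_ranks = pd.DataFrame(
        rank_rows, columns=["dataset_a", "dataset_b", "tissue", "match_rank", "n_candidates"]
    )
    return CompatibilityReport(pairs, match_ranks)
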