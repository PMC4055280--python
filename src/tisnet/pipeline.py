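"""End-to-end orchestration: simulate -> build -> stats -> disease.

A :class:`RunConfig` (YAML-loadable) names either a synthetic-generator
configuration or real input files (expression TSVs + consolidation scheme
+ edge list + disease associations) plus the analysis thresholds. The
pipeline executes its stages in order, writes diff-able TSV/JSON artifacts
into the output directory, and finishes with a manifest listing every
output file with a content digest; a rerun with the same configuration and
seed reproduces identical digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import disease as dis
from . import expression as expr
from . import interactome as inter
from . import netstats
from . import synthetic as synth
from .errors import ConfigError, PipelineError

logger = logging.getLogger(__name__)

STAGES = ("input", "expression", "interactome", "network_stats", "disease")

THRESHOLD_DEFAULTS = {
    "intensity": 100.0,
    "rpkm": 1.0,
    "k_ts": 3,
    "hub_quantile": 0.95,
    "n_bins": 10,
    "n_runs": 10_000,
}


@dataclass
class InputPaths:
    expression: dict[str, str] = field(default_factory=dict)  # dataset_id -> path
    dialects: dict[str, str] = field(default_factory=dict)    # dataset_id -> dialect
    scheme: str | None = None
    edges: str | None = None
    associations: str | None = None


@dataclass
class Thresholds:
    intensity: float = 100.0
    rpkm: float = 1.0
    k_ts: int = 3
    hub_quantile: float = 0.95
    n_bins: int = 10
    n_runs: int = 10_000


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str | None = None
    universe_size: int = 21_450  # protein-coding universe for overlap tests
    generator: synth.GeneratorConfig | None = None
    inputs: InputPaths | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)

    def to_dict(self) -> dict:
        out = {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "universe_size": self.universe_size,
            "thresholds": dataclasses.asdict(self.thresholds),
        }
        if self.generator is not None:
            g = dataclasses.asdict(self.generator)
            g["tissue_names"] = list(g["tissue_names"])
            g["breadth_mixture"] = list(g["breadth_mixture"])
            out["generator"] = g
        if self.inputs is not None:
            out["inputs"] = dataclasses.asdict(self.inputs)
        return out


def _check_keys(section: str, given: dict, allowed: set[str], problems: list[str]) -> None:
    for key in given:
        if key not in allowed:
            problems.append(f"{section}: unknown key {key!r}")


def validate_config(source) -> RunConfig:
    """Parse + validate a config mapping or YAML path; list all violations.

    Missing thresholds take the stringent defaults (intensity 100, 1 RPKM,
    k_ts 3, hub quantile 0.95, 10 bins, 10,000 permutation runs). Unknown
    keys are rejected. An empty config is valid (all defaults, no input
    source -- running it then fails at the input stage).
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source or {})
    problems: list[str] = []
    _check_keys("config", raw, {"seed", "out_dir", "universe_size", "generator",
                                "inputs", "thresholds"}, problems)

    thr_raw = dict(raw.get("thresholds") or {})
    _check_keys("thresholds", thr_raw, set(THRESHOLD_DEFAULTS), problems)
    thr_vals = dict(THRESHOLD_DEFAULTS)
    thr_vals.update({k: v for k, v in thr_raw.items() if k in THRESHOLD_DEFAULTS})
    for key in ("intensity", "rpkm"):
        if not isinstance(thr_vals[key], (int, float)) or thr_vals[key] <= 0:
            problems.append(f"thresholds.{key} must be a positive number")
    if not isinstance(thr_vals["k_ts"], int) or thr_vals["k_ts"] < 1:
        problems.append("thresholds.k_ts must be a positive integer")
    if not 0 <= float(thr_vals["hub_quantile"]) <= 1:
        problems.append("thresholds.hub_quantile must be in [0, 1]")
    if not isinstance(thr_vals["n_bins"], int) or thr_vals["n_bins"] < 1:
        problems.append("thresholds.n_bins must be a positive integer")
    if not isinstance(thr_vals["n_runs"], int) or thr_vals["n_runs"] < 1:
        problems.append("thresholds.n_runs must be a positive integer")

    generator = None
    if raw.get("generator") is not None:
        graw = dict(raw["generator"])
        fields = {f.name for f in dataclasses.fields(synth.GeneratorConfig)}
        _check_keys("generator", graw, fields, problems)
        graw = {k: v for k, v in graw.items() if k in fields}
        if "dataset_specs" in graw and graw["dataset_specs"] is not None:
            graw["dataset_specs"] = {
                name: synth.DatasetSpec(**spec) if isinstance(spec, dict) else spec
                for name, spec in graw["dataset_specs"].items()
            }
        if "breadth_mixture" in graw:
            graw["breadth_mixture"] = tuple(graw["breadth_mixture"])
        try:
            generator = synth.GeneratorConfig(**graw)
            generator.validate()
        except (TypeError, ConfigError) as e:
            problems.append(f"generator: {e}")

    inputs = None
    if raw.get("inputs") is not None:
        iraw = dict(raw["inputs"])
        _check_keys("inputs", iraw,
                    {"expression", "dialects", "scheme", "edges", "associations"}, problems)
        inputs = InputPaths(
            expression=dict(iraw.get("expression") or {}),
            dialects=dict(iraw.get("dialects") or {}),
            scheme=iraw.get("scheme"),
            edges=iraw.get("edges"),
            associations=iraw.get("associations"),
        )
        for ds in inputs.expression:
            dialect = inputs.dialects.get(ds, ds)
            if dialect not in expr.DIALECTS:
                problems.append(f"inputs: dataset {ds!r} has unknown dialect {dialect!r}")

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        problems.append("seed must be an integer")
        seed = 0
    if problems:
        raise ConfigError("; ".join(problems))
    if generator is not None:
        generator = dataclasses.replace(generator, seed=seed)
    return RunConfig(
        seed=seed,
        out_dir=raw.get("out_dir"),
        universe_size=int(raw.get("universe_size", 21_450)),
        generator=generator,
        inputs=inputs,
        thresholds=Thresholds(**thr_vals),
    )


# ---------------------------------------------------------------------------
# dataset writing (synthetic -> the same TSV dialects the readers consume)


def write_dataset(ds: synth.SyntheticDataset, out_dir) -> InputPaths:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = InputPaths()
    for name, panel in sorted(ds.panels.items()):
        p = out / f"expression_{name}.tsv"
        expr.write_expression_table(panel, p)
        paths.expression[name] = str(p)
        paths.dialects[name] = panel.dialect
    scheme = expr.ConsolidationScheme.identity(ds.panels, ds.config.tissue_names)
    paths.scheme = str(out / "scheme.yaml")
    scheme.to_yaml(paths.scheme)
    paths.edges = str(out / "edges.tsv")
    inter.write_edge_list(ds.network, paths.edges, source_attr=True)
    paths.associations = str(out / "associations.tsv")
    with open(paths.associations, "w") as fh:
        fh.write("disease_id\tgene_id\ttissue\n")
        for a in ds.assignments:
            for t in a.disease_tissues:
                fh.write(f"{a.disease_id}\t{a.gene_id}\t{t}\n")
    return paths


# ---------------------------------------------------------------------------
# pipeline


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: RunConfig, out_dir=None, stages=STAGES) -> dict:
    """Execute the requested stages in order; return the manifest dict.

    Any stage error aborts with a :class:`PipelineError` naming the stage.
    """
    out = Path(out_dir or config.out_dir or ".")
    out.mkdir(parents=True, exist_ok=True)
    last = max(STAGES.index(s) for s in stages)
    wanted = STAGES[: last + 1]
    state: dict = {}
    for stage in wanted:
        t0 = time.monotonic()
        logger.info("stage %s: starting", stage)
        try:
            _STAGE_FUNCS[stage](config, out, state)
        except Exception as e:  # noqa: BLE001 - stage name + cause contract
            raise PipelineError(f"stage '{stage}' failed: {e}") from e
        logger.info("stage %s: done in %.2fs", stage, time.monotonic() - t0)

    files = {}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            files[str(p.relative_to(out))] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {"config": config.to_dict(), "stages": list(wanted), "files": files}
    _write_json(manifest, out / "manifest.json")
    return manifest


def _stage_input(config: RunConfig, out: Path, state: dict) -> None:
    if config.generator is not None:
        ds = synth.simulate(config.generator)
        state["inputs"] = write_dataset(ds, out / "data")
    elif config.inputs is not None and config.inputs.expression:
        state["inputs"] = config.inputs
    else:
        raise ConfigError("no input source: provide a generator or input files")


def _stage_expression(config: RunConfig, out: Path, state: dict) -> None:
    inputs: InputPaths = state["inputs"]
    scheme = expr.ConsolidationScheme.from_yaml(inputs.scheme)
    panels, expressomes = {}, []
    for ds_id in sorted(inputs.expression):
        dialect = inputs.dialects.get(ds_id, ds_id)
        panel = expr.read_expression_table(inputs.expression[ds_id], dialect, dataset_id=ds_id)
        thresholds = {"microarray": config.thresholds.intensity, "rnaseq": config.thresholds.rpkm}
        called = expr.call_expressed(panel, thresholds)
        expressomes.append(expr.consolidate(called, scheme, ds_id))
        panels[ds_id] = panel
    combined = expr.combine_datasets(expressomes)
    state.update(panels=panels, scheme=scheme, expressomes=expressomes, combined=combined)

    rows = [(t, g) for t in sorted(combined.tissues) for g in sorted(combined.tissues[t])]
    _write_tsv(pd.DataFrame(rows, columns=["tissue", "gene_id"]), out / "expressomes.tsv")
    classified = expr.breadth_classify(combined)
    _write_tsv(classified, out / "gene_breadth.tsv")
    hist = expr.breadth_histogram(classified)
    _write_tsv(
        pd.DataFrame({"n_tissues": hist.index, "n_genes": hist.values}),
        out / "gene_breadth_histogram.tsv",
    )
    state["classified"] = classified


def _stage_interactome(config: RunConfig, out: Path, state: dict) -> None:
    inputs: InputPaths = state["inputs"]
    rows = inter.read_edge_list(inputs.edges)
    by_source: dict[str, list[tuple[str, str]]] = {}
    for a, b, src in rows:
        by_source.setdefault(src, []).append((a, b))
    global_g = inter.build_global_interactome(by_source)
    combined = state["combined"]
    tissue_graphs = {
        t: inter.build_tissue_interactome(global_g, combined, t)
        for t in sorted(combined.tissues)
    }
    core = inter.compute_core(tissue_graphs)
    breadth = inter.edge_breadth(global_g, tissue_graphs)
    tsppis = inter.identify_ts_ppis(breadth, config.thresholds.k_ts)
    state.update(global_g=global_g, tissue_graphs=tissue_graphs, core=core,
                 breadth=breadth, tsppis=tsppis)

    inter.write_edge_list(core, out / "core_edges.tsv")
    rows = [(t, u, v) for t in sorted(tissue_graphs)
            for u, v in sorted(map(lambda e: inter.edge_key(*e), tissue_graphs[t].edges))]
    _write_tsv(pd.DataFrame(rows, columns=["tissue", "gene_a", "gene_b"]),
               out / "tissue_edges.tsv")
    hist = breadth.histogram()
    _write_tsv(pd.DataFrame({"n_tissues": hist.index, "n_edges": hist.values}),
               out / "edge_breadth_histogram.tsv")
    inter.write_tsppi_table(tsppis, breadth, out / "tsppi.tsv")


def _rpkm_by_tissue(state: dict) -> pd.DataFrame:
    panel = state["panels"].get("rnaseq")
    if panel is None:
        return pd.DataFrame(columns=["gene_id", "tissue", "value"])
    return expr.tissue_values(panel, state["scheme"])


def _stage_network_stats(config: RunConfig, out: Path, state: dict) -> None:
    tissue_graphs = state["tissue_graphs"]
    scopes = {"global": state["global_g"], "core": state["core"], **tissue_graphs}
    hub_rows, hist_rows = [], []
    for scope in sorted(scopes):
        g = scopes[scope]
        hubs, threshold = netstats.detect_hubs(g, config.thresholds.hub_quantile)
        for h in sorted(hubs):
            hub_rows.append((scope, h, g.degree(h), threshold))
        counts, frac = netstats.degree_histogram(g)
        for d, c in counts.items():
            hist_rows.append((scope, d, c, frac))
    _write_tsv(pd.DataFrame(hub_rows, columns=["scope", "gene_id", "degree", "threshold"]),
               out / "hubs.tsv")
    _write_tsv(pd.DataFrame(hist_rows, columns=["scope", "degree", "n_nodes", "frac_deg_le5"]),
               out / "degree_histogram.tsv")

    rpkm_df = _rpkm_by_tissue(state)
    state["rpkm_df"] = rpkm_df
    corr_rows = []
    for tissue in sorted(tissue_graphs):
        g = tissue_graphs[tissue]
        sub = rpkm_df[rpkm_df["tissue"] == tissue]
        rpkm = dict(zip(sub["gene_id"], sub["value"]))
        degree = dict(g.degree())
        rep = netstats.expression_degree_correlation(
            rpkm, degree, config.thresholds.n_bins, tissue=tissue)
        corr_rows.append((tissue, rep.n_eligible, rep.unbinned_rho, rep.unbinned_p,
                          rep.binned_rho, rep.binned_p))
    _write_tsv(pd.DataFrame(corr_rows, columns=[
        "tissue", "n_eligible", "unbinned_rho", "unbinned_p", "binned_rho", "binned_p"]),
        out / "correlation.tsv")


def _stage_disease(config: RunConfig, out: Path, state: dict) -> None:
    inputs: InputPaths = state["inputs"]
    if not inputs.associations:
        logger.info("no disease associations provided; skipping disease stage")
        return
    rpkm_df = state.get("rpkm_df")
    if rpkm_df is None:
        rpkm_df = _rpkm_by_tissue(state)
    panel = dis.load_disease_panel(
        inputs.associations, state["combined"], rpkm=rpkm_df,
        tissue_graphs=state["tissue_graphs"], tsppis=state["tsppis"],
    )
    metrics = [m for m in dis.METRICS]
    contrasts = dis.compute_contrasts(panel, metrics)
    rows = [
        (m, c.gene_id, c.v_d, c.v_nd, c.success)
        for m in metrics for c in sorted(contrasts[m].values(), key=lambda c: c.gene_id)
    ]
    _write_tsv(pd.DataFrame(rows, columns=["metric", "gene_id", "v_d", "v_nd", "success"]),
               out / "contrasts.tsv")

    perm_out = {}
    for i, metric in enumerate(metrics):
        res = dis.permutation_test(
            panel, metric, n_runs=config.thresholds.n_runs, seed=config.seed + i)
        perm_out[metric] = {
            "observed": res.observed, "n_genes": res.n_genes, "n_runs": res.n_runs,
            "p_value": res.p_value, "seed": res.seed, "mode": res.mode,
        }
    _write_json(perm_out, out / "permutation.json")

    overlap = dis.factor_overlap_tests(
        panel, contrasts,
        interactome_genes=set(state["global_g"].nodes),
        genes_with_tsppi=state["tsppis"].genes_with_tsppi(),
    )
    _write_tsv(overlap.pairwise, out / "factor_overlaps.tsv")

    candidates = dis.tsppi_candidate_report(panel, state["tsppis"], state["tissue_graphs"])
    _write_tsv(candidates, out / "candidates.tsv")

    per_disease, fractions = dis.disease_factor_summary(panel, contrasts)
    _write_tsv(per_disease, out / "disease_factors.tsv")
    summary = {
        "n_diseases": len(panel.diseases),
        "n_genes_analyzed": len(panel.included_genes()),
        "n_genes_excluded_tissue_specific": len(panel.genes) - len(panel.included_genes()),
        "n_dropped_rows": panel.n_dropped_rows,
        "n_dropped_associations": panel.n_dropped_associations,
        "disease_factor_fractions": fractions,
        "tsppi_enrichment": overlap.tsppi_enrichment,
        "permutation": perm_out,
    }
    _write_json(summary, out / "summary.json")


_STAGE_FUNCS = {
    "input": _stage_input,
    "expression": _stage_expression,
    "interactome": _stage_interactome,
    "network_stats": _stage_network_stats,
    "disease": _stage_disease,
}
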