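"""Convenience assembly of the synthetic study, shared by scripts and tests.

These helpers wire the generator output through the same calling,
consolidation, and filtering code paths the file-based pipeline uses, but
in memory: simulate -> expressomes -> tissue interactomes -> disease
panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from . import disease as dis
from . import expression as expr
from . import interactome as inter
from . import synthetic as synth


@dataclass
class Study:
    dataset: synth.SyntheticDataset
    scheme: expr.ConsolidationScheme
    expressomes: list[expr.Expressome]
    combined: expr.Expressome
    tissue_graphs: dict[str, nx.Graph] | None = None
    core: nx.Graph | None = None
    breadth: inter.EdgeBreadth | None = None
    tsppis: inter.TSPPISet | None = None
    rpkm: pd.DataFrame | None = None
    panel: dis.DiseasePanel | None = None


def build_expressomes(ds: synth.SyntheticDataset) -> Study:
    """Call expressed genes per dataset and combine into tissue expressomes."""
    scheme = expr.ConsolidationScheme.identity(ds.panels, ds.config.tissue_names)
    expressomes = [
        expr.consolidate(expr.call_expressed(panel), scheme, name)
        for name, panel in sorted(ds.panels.items())
    ]
    combined = expr.combine_datasets(expressomes)
    return Study(ds, scheme, expressomes, combined)


def build_networks(study: Study, k_ts: int = 3) -> Study:
    """Tissue interactomes, core, edge breadth, and TS-PPIs."""
    ds = study.dataset
    study.tissue_graphs = {
        t: inter.build_tissue_interactome(ds.network, study.combined, t)
        for t in ds.config.tissue_names
    }
    study.core = inter.compute_core(study.tissue_graphs)
    study.breadth = inter.edge_breadth(ds.network, study.tissue_graphs)
    study.tsppis = inter.identify_ts_ppis(study.breadth, k_ts)
    return study


def build_disease_panel(study: Study, with_network: bool = True) -> dis.DiseasePanel:
    """Load the planted disease associations against the detected data."""
    ds = study.dataset
    rows = [
        (a.disease_id, a.gene_id, t)
        for a in ds.assignments for t in a.disease_tissues
    ]
    assoc = pd.DataFrame(rows, columns=["disease_id", "gene_id", "tissue"])
    study.rpkm = expr.tissue_values(ds.panels["rnaseq"], study.scheme)
    study.panel = dis.load_disease_panel(
        assoc,
        study.combined,
        rpkm=study.rpkm,
        tissue_graphs=study.tissue_graphs if with_network else None,
        tsppis=study.tsppis if with_network else None,
    )
    return study.panel


def assemble(config: synth.GeneratorConfig, with_network: bool = True, k_ts: int = 3) -> Study:
    """simulate + expressomes (+ networks) + disease panel in one call."""
    study = build_expressomes(synth.simulate(config))
    if with_network:
        build_networks(study, k_ts)
    if study.dataset.assignments:
        build_disease_panel(study, with_network=with_network)
    return study
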