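"""Shared study configuration for the numbered analysis scripts.

One synthetic cohort drives all four scripts: 2,000 genes across the 16
main tissues, 100 hereditary diseases whose causal genes carry a planted
1.5x expression elevation and 2 planted tissue-specific PPIs in their
disease tissues. Scripts 02-04 re-derive the cheap upstream stages in
memory from the same seed rather than parsing script 01's files, so each
can be run on its own; determinism of the generator guarantees they all
see the same data.
"""

from pathlib import Path

from tisnet import synthetic

RESULTS = Path(__file__).resolve().parent.parent / "results"


def study_config(seed: int = 1) -> synthetic.GeneratorConfig:
    return synthetic.GeneratorConfig(
        n_genes=2000,
        n_diseases=100,
        expression_effect=1.5,
        n_planted_ts_edges=2,
        degree_coupling=1.0,
        seed=seed,
    )
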