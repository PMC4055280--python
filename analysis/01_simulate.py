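"""Generate the synthetic study cohort and write it to results/data/.

Produces the three expression panels (microarray intensities, RNA-seq
RPKM, ordinal IHC calls), the global PPI edge list, the disease-gene-
tissue associations, and the subpart consolidation scheme -- the same TSV
dialects the real-data readers consume.
"""

import argparse

from _config import RESULTS, study_config
from tisnet import pipeline, synthetic


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cfg = study_config(args.seed)
    ds = synthetic.simulate(cfg)
    out = RESULTS / "data"
    pipeline.write_dataset(ds, out)

    n_minted = sum(1 for g in ds.catalog if g.gene_id.startswith("TS"))
    print(f"wrote synthetic cohort to {out}")
    print(f"  genes: {len(ds.catalog)} ({n_minted} minted TS-partners)")
    print(f"  global PPIs: {ds.network.number_of_edges()}")
    print(f"  diseases: {len(ds.assignments)} "
          f"(1-2 disease tissues each, effect x{cfg.expression_effect}, "
          f"{cfg.n_planted_ts_edges} planted TS-PPIs per causal gene)")


if __name__ == "__main__":
    main()
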