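"""Disease-gene tissue specificity: median contrasts and permutation tests.

For each causal gene, compares the median RPKM, PPI degree, and TS-PPI
count between its disease tissues and its other expressing tissues
(strict V_d > V_nd = success), assesses the total success count with the
10,000-run label-permutation test, tests the pairwise overlap of the
success gene sets (Fisher exact), and writes the TS-PPI candidate filter
report and the disease-level factor summary.
"""

import argparse
import json

import pandas as pd

from _config import RESULTS, study_config
from tisnet import disease as dis
from tisnet import study


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-runs", type=int, default=10_000)
    args = ap.parse_args()
    out = RESULTS
    out.mkdir(parents=True, exist_ok=True)

    st = study.assemble(study_config(args.seed))
    panel = st.panel
    n_inc = len(panel.included_genes())
    print(f"disease panel: {len(panel.diseases)} diseases, {len(panel.genes)} "
          f"causal genes ({n_inc} analyzed, "
          f"{len(panel.genes) - n_inc} tissue-specific and excluded)")

    contrasts = dis.compute_contrasts(panel, dis.METRICS)
    rows, perm = [], {}
    for i, metric in enumerate(dis.METRICS):
        res = dis.permutation_test(panel, metric, n_runs=args.n_runs,
                                   seed=args.seed + i)
        perm[metric] = {"observed": res.observed, "n_genes": res.n_genes,
                        "n_runs": res.n_runs, "p_value": res.p_value}
        print(f"  {metric}: higher in disease tissues for {res.observed}/"
              f"{res.n_genes} genes (permutation p = {res.p_value:.4g})")
        rows += [(metric, c.gene_id, c.v_d, c.v_nd, c.success)
                 for c in sorted(contrasts[metric].values(), key=lambda c: c.gene_id)]
    pd.DataFrame(rows, columns=["metric", "gene_id", "v_d", "v_nd", "success"]).to_csv(
        out / "contrasts.tsv", sep="\t", index=False)

    overlap = dis.factor_overlap_tests(
        panel, contrasts,
        interactome_genes=set(st.dataset.network.nodes),
        genes_with_tsppi=st.tsppis.genes_with_tsppi())
    overlap.pairwise.to_csv(out / "factor_overlaps.tsv", sep="\t", index=False)
    enr = overlap.tsppi_enrichment
    print(f"causal genes with >= 1 TS-PPI anywhere: "
          f"{enr['n_causal_with_tsppi']}/{enr['n_causal_in_interactome']} "
          f"(enrichment Fisher p = {enr['fisher_p']:.2g})")

    candidates = dis.tsppi_candidate_report(panel, st.tsppis, st.tissue_graphs)
    candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
    with_ts = candidates[candidates["n_tsppi"] > 0]
    if len(with_ts):
        print(f"TS-PPI candidate filter: median {with_ts['reduction_factor'].median():.1f}"
              f"-fold reduction of candidate PPIs "
              f"({len(with_ts)}/{len(candidates)} associations with >= 1 TS-PPI)")

    per_disease, fractions = dis.disease_factor_summary(panel, contrasts)
    per_disease.to_csv(out / "disease_factors.tsv", sep="\t", index=False)
    with open(out / "disease_summary.json", "w") as fh:
        json.dump({"permutation": perm, "fractions": fractions,
                   "tsppi_enrichment": enr}, fh, indent=2)
        fh.write("\n")
    print(f"diseases with elevated expression and/or TS-PPIs in their disease "
          f"tissues: {fractions['elevated_or_tsppi']:.0%}")


if __name__ == "__main__":
    main()
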