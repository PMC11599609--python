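"""Covariation and cluster analysis of the normalized scute variables.

Filters unusable scutes, size-corrects by the fitted exponents,
log-transforms, standardizes, runs the PCA and Ward clustering at k = 5,
and compares the clusters with the generator's planted scute types.
Writes PC loadings/scores, assignments, cluster summaries, per-specimen
cluster frequencies and the linkage tree under results/clusters/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from boxtess.pipeline import analyze_batch, linkage_to_newick  # noqa: E402

BASE = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    records = pd.read_csv(BASE / "measured" / "scute_records.csv")
    summaries = pd.read_csv(BASE / "measured" / "specimen_summaries.csv")
    planted = pd.read_csv(BASE / "simulated" / "planted_types.csv")
    out = BASE / "clusters"
    out.mkdir(parents=True, exist_ok=True)

    result = analyze_batch(records, summaries)
    model = result["cluster_model"]
    matrix = result["matrix"]

    print(f"retained {len(matrix.data)} of {len(records)} scutes "
          f"({100 * len(matrix.data) / len(records):.0f}%); dropped: "
          f"{matrix.dropped.reason.value_counts().to_dict()}")
    var_exp = result["pca"]["variance_explained"]
    print(f"PC1+PC2 explain {var_exp[:2].sum():.1f}% of variance")

    assign = model.meta.copy()
    assign["cluster"] = model.assignment
    key = planted.set_index(["specimen", "scute_id"]).planted_type
    assign["planted_type"] = [key.loc[(s, i)] for s, i
                              in zip(assign.specimen, assign.scute_id)]
    ari = adjusted_rand_score(assign.planted_type, assign.cluster)
    print(f"adjusted Rand index vs planted types at k=5: {ari:.3f}")
    print(pd.crosstab(assign.planted_type, assign.cluster))

    assign.to_csv(out / "cluster_assignments.csv", index=False)
    result["pca"]["loadings"].reset_index(names="variable").to_csv(
        out / "pc_loadings.csv", index=False)
    pd.DataFrame(model.pc_scores[:, :4],
                 columns=["PC1", "PC2", "PC3", "PC4"]).to_csv(
        out / "pc_scores.csv", index=False)
    model.summaries.to_csv(out / "cluster_summaries.csv", index=False)
    model.frequencies.to_csv(out / "cluster_frequencies.csv", index=False)
    result["correlations"].reset_index(names="variable").to_csv(
        out / "correlations.csv", index=False)
    (out / "linkage_tree.nwk").write_text(linkage_to_newick(model.linkage))
    print(f"wrote cluster outputs to {out}")
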