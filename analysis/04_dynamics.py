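#!/usr/bin/env python
"""Temporal structure of the coding and noncoding transcriptomes.

Spearman-distance MDS per RNA class with the dimension-1-vs-time fit,
complete-linkage clustering of samples, nearest-neighbour orientation
correlations for lncRNAs, and the lncRNA x mRNA correlation matrix at
FDR < 0.01 with the |SC| >= 0.85 display threshold.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ncrna.dynamics import (
    corr_fdr_pairs,
    dendrogram_newick,
    dim1_time_fit,
    hcluster,
    mds_embed,
    neighbor_correlations,
    sample_distance_matrix,
)
from ncrna.io_formats import read_annotation, read_matrix, write_matrix

BASE = Path(__file__).resolve().parent.parent / "results"
DATA = BASE / "data"


def main() -> None:
    classified = pd.read_csv(BASE / "classification.tsv", sep="\t", index_col=0)
    matrix = read_matrix(BASE / "rpkm.tsv")
    meta = pd.read_csv(DATA / "samples.tsv", sep="\t", index_col=0)
    annotation = read_annotation(DATA / "reference.gff3")
    models = read_annotation(DATA / "models.gtf")

    # replicate-averaged time-point profiles
    groups = meta.loc[matrix.columns, "time_hr"]
    tp = matrix.T.groupby(groups).mean().T
    times = sorted(tp.columns)
    tp = tp[times]

    for klass in ("mRNA", "lncRNA"):
        ids = classified.index[classified["class"] == klass]
        D = sample_distance_matrix(np.log2(tp.loc[ids] + 0.01))
        coords, _ = mds_embed(D, order_hint=times)
        slope, intercept, r2 = dim1_time_fit(coords, times)
        pd.DataFrame(
            {"time_hr": times, "dim1": coords[:, 0],
             "dim2": coords[:, 1] if coords.shape[1] > 1 else np.nan}
        ).to_csv(BASE / f"mds_{klass}.tsv", sep="\t", index=False)
        Z, order = hcluster(D, labels=[str(t) for t in times])
        (BASE / f"dendrogram_{klass}.nwk").write_text(
            dendrogram_newick(Z, [str(t) for t in times])
        )
        adj = np.array([D.iloc[i, i + 1] for i in range(len(times) - 1)])
        leaps = (np.argsort(adj)[-2:] + 1).tolist()
        print(f"{klass}: dimension 1 vs time r^2 = {r2:.3f}; "
              f"largest adjacent leaps into time points {sorted(leaps)} "
              f"({[times[i] for i in sorted(leaps)]} hr)")

    # neighbour orientation analysis for surviving lncRNAs
    lnc_ids = classified.index[classified["class"] == "lncRNA"]
    lnc_models = [models.genes[i] for i in lnc_ids]
    gene_rows = tp.loc[[f"TM.{g}" for g in annotation.genes]].rename(
        index={f"TM.{g}": g for g in annotation.genes}
    )
    combined = pd.concat([tp.loc[lnc_ids], gene_rows])
    nbr = neighbor_correlations(lnc_models, annotation, combined, seed=1)
    nbr["pairs"].to_csv(BASE / "neighbor_correlations.tsv", sep="\t", index=False)
    print("neighbour categories:",
          json.dumps(nbr["summary"], default=float))
    print(f"random gene-pair median SC: {nbr['random_median_sc']:.3f}")

    # lncRNA x mRNA correlation matrix under FDR control
    mrna_ids = classified.index[classified["class"] == "mRNA"]
    dynamic = tp.loc[mrna_ids].std(axis=1).nlargest(100).index
    out = corr_fdr_pairs(tp.loc[lnc_ids], tp.loc[dynamic])
    rows = [
        {"lncrna": r.pair[0], "mrna": r.pair[1], "sc": r.sc,
         "p_adjusted": r.p_adjusted}
        for r in out["pairs"]
    ]
    pd.DataFrame(rows).to_csv(BASE / "correlated_pairs.tsv", sep="\t", index=False)
    write_matrix(out["z_lnc"], BASE / "zscores_lncrna.tsv")
    print(f"lncRNA-mRNA pairs at FDR<0.01 and |SC|>=0.85: {len(rows)} "
          f"of {len(lnc_ids) * len(dynamic)} tested")


if __name__ == "__main__":
    main()
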