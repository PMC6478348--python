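"""Cluster analysis of the miRNA-hosting exons (in-package fixture).

Reproduces the machine-learning characterization of the 23 printed
miRNA host exons: spatial randomness (Hopkins) of the real matrix
versus a matched uniform dataset, cluster-number selection on the
standardized 22-observation matrix (the dominant-abundance exon is
excluded from clustering), abundance-ordered k = 3 k-means, the fuzzy
c-means cross-check, the VAT ordering, and the SOM refusal on a
15 x 10 map.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from exonml import (
    fuzzy_cmeans,
    generate_random_matrix,
    hopkins,
    kmeans_multi,
    load_mirna_fixture,
    order_clusters_by_abundance,
    select_k,
    som_fit,
    vat,
)
from exonml.features import FeatureMatrix, scale_matrix
from exonml.som import InsufficientObservationsError


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()
    out = Path(args.out) / "mirna"
    out.mkdir(parents=True, exist_ok=True)

    fx = load_mirna_fixture()
    m23 = fx.matrix(drop_outlier=False)
    m22 = fx.matrix(drop_outlier=True)
    print(f"{fx.n_records} miRNA host exons ({fx.unique_mirnas} distinct miRNAs); "
          f"{len(m22)} observations after excluding the dominant-abundance exon")

    # cluster tendency: the real matrix vs a range-matched uniform one
    h_real = hopkins(m23, repeats=300, seed=args.seed)
    ranges = {c: (float(m22[c].min()), float(m22[c].max())) for c in m22.columns}
    lo = np.array([r[0] for r in ranges.values()])
    hi = np.array([r[1] for r in ranges.values()])
    h_unif = np.mean([
        hopkins(generate_random_matrix(len(m22), ranges, seed=args.seed + 1000 + i),
                repeats=20, seed=args.seed + i, ranges=(lo, hi)).H
        for i in range(50)
    ])
    print(f"Hopkins: miRNA matrix H = {h_real.H:.3f}; uniform reference H = {h_unif:.3f} "
          "(0.5 = spatially random; the miRNA exons are strongly clustered)")

    # cluster-number selection on the standardized matrix
    z22 = scale_matrix(FeatureMatrix(data=m22))
    sel = select_k(z22, kmax=10, n_starts=50, gap_B=100, seed=args.seed)
    print(f"optimal k: elbow {sel.elbow_k}, silhouette {sel.silhouette_k}, "
          f"gap {sel.gap_k} -> consensus {sel.consensus_k}")
    sel.table.to_csv(out / "k_selection.tsv", sep="\t")

    # k = 3 k-means on the raw variables: clusters are defined by
    # shared transcript abundance
    km = kmeans_multi(m22, 3, n_starts=50, seed=args.seed)
    abundance = m22[["alc1", "alc2", "cont1", "cont2"]].mean(axis=1)
    ordered = order_clusters_by_abundance(km, abundance)
    sizes = ordered.value_counts().sort_index()
    print("k-means (k=3) cluster sizes, least to most abundant: "
          + " / ".join(str(int(s)) for s in sizes))
    ordered.rename("cluster").to_csv(out / "kmeans_clusters.tsv", sep="\t")

    fc = fuzzy_cmeans(m22, 3, seed=args.seed)
    agree = (order_clusters_by_abundance(fc, abundance) == ordered).mean()
    print(f"fuzzy c-means hard labels agree with k-means on {agree:.0%} of exons")
    fc.membership.round(4).to_csv(out / "fuzzy_membership.tsv", sep="\t")

    v = vat(m22)
    pd.DataFrame(v.ordered_dissimilarity,
                 index=m22.index[v.ordering], columns=m22.index[v.ordering]
                 ).to_csv(out / "vat_matrix.tsv", sep="\t")

    try:
        som_fit(z22, grid=(15, 10), seed=args.seed)
        som_note = "unexpectedly accepted"
    except InsufficientObservationsError:
        som_note = ("refused: 22 observations cannot populate a 15x10 map "
                    "(the network cannot learn the dataset)")
    print(f"SOM on the miRNA matrix: {som_note}")

    summary = {
        "hopkins_mirna": round(h_real.H, 3),
        "hopkins_uniform": round(float(h_unif), 3),
        "elbow_k": sel.elbow_k,
        "silhouette_k": sel.silhouette_k,
        "gap_k": sel.gap_k,
        "consensus_k": sel.consensus_k,
        "kmeans_sizes_by_abundance": [int(s) for s in sizes],
        "som": som_note,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(f"reports in {out}")


if __name__ == "__main__":
    main()
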