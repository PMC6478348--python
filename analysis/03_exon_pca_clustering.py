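"""Unsupervised analysis of the significant exons.

Standardized PCA over normalized counts + usage coefficients, the
top-contributor ranking (the exons explaining the most component
variance), HCPC with Ward linkage and k-means consolidation,
cluster-number selection (elbow / silhouette / gap and their
consensus), fuzzy memberships, Hopkins and VAT, and — when the dataset
is large enough to populate a map — a SOM cross-check.
"""

import argparse
import json
from pathlib import Path

from exonml.pipeline import PipelineConfig, run_ml


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    cfg = PipelineConfig(output_dir=args.out, seed=args.seed, gap_B=50)
    out = run_ml(cfg)
    summary = json.loads((Path(out) / "ml_summary.json").read_text())
    print(f"Hopkins H = {summary['hopkins']:.3f} "
          f"(m = {summary['hopkins_m']}, {summary['hopkins_repeats']} repeats)")
    print(f"cluster number: elbow {summary['elbow_k']}, silhouette {summary['silhouette_k']}, "
          f"gap {summary['gap_k']} -> consensus {summary['consensus_k']}")
    print(f"HCPC cut at k = {summary['hcpc_k']}; "
          f"k-means total WSS {summary['kmeans_wss']:.1f}")
    print(f"reports in {out}")


if __name__ == "__main__":
    main()
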