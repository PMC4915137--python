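"""Ward clustering of signed max-Z encoding features, per area.

Uses the unit classification from analysis 03: three features per unit
(feedback, checkwork, cued side), zeros where not significant.  The tree is
cut at the largest dendrogram gap; cluster means identify the functional
classes, flagging any cluster jointly loaded on negative feedback and
Check.

Usage: python analysis/05_clustering.py [--out results]
"""

from __future__ import annotations

import argparse
from pathlib import Path

import pandas as pd

from checkdyn.clustering import characterize_clusters, feature_matrix, ward_cluster


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--cut", default="gap", help="'gap' or an integer k")
    args = ap.parse_args()
    table = pd.read_csv(args.out / "03_unit_classification.csv")
    cut = args.cut if args.cut == "gap" else int(args.cut)

    frames = []
    for area in ("MCC", "LPFC"):
        sub = table[table["area"] == area].reset_index(drop=True)
        feats = feature_matrix(sub)
        res = ward_cluster(feats, cut=cut)
        summary = characterize_clusters(res.labels, feats)
        summary["area"] = area
        frames.append(summary)
        labels = pd.DataFrame({"unit_id": sub["unit_id"], "cluster": res.labels, "area": area})
        labels.to_csv(args.out / f"05_cluster_labels_{area}.csv", index=False)
        print(f"{area}: {res.n_clusters} clusters (cut={cut})")
        print(summary.round(2).to_string(index=False))
    pd.concat(frames, ignore_index=True).to_csv(args.out / "05_cluster_summary.csv", index=False)


if __name__ == "__main__":
    main()
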