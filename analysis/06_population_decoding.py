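"""Population decoding: timecourses, cross-temporal matrices, area contrast,
and Lasso distance-to-check decoding with the contributing-neuron census.

Ridge readouts are trained per 200 ms bin on pseudotrial populations
(n=20 per condition, 60/40 split, 5-fold-CV regularization, repeated);
permutation nulls set the significance threshold.  Writes per-bin accuracy
tables, the cross-temporal matrix, and the distance-decoding summary.

Usage: python analysis/06_population_decoding.py [--seed 0] [--out results]
       [--nrep 50] [--nperm 100]
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from checkdyn.core import AlignmentSpec, read_session
from checkdyn.decoding import (
    compare_areas,
    decode_timecourse,
    lasso_distance_decoding,
    permutation_null,
)

FACTOR_ALIGN = {
    "feedback": AlignmentSpec("feedback_onset", -0.3, 1.2),
    "checkwork": AlignmentSpec("lever_touch", -1.0, 0.5),
    "cued": AlignmentSpec("cue_onset", -0.3, 1.2),
}


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--nrep", type=int, default=50)
    ap.add_argument("--nperm", type=int, default=100)
    args = ap.parse_args()
    d = args.out / "session"
    trials, units = read_session(d / "trials.csv", d / "spikes.csv")
    by_area = {a: [u for u in units if u.area == a] for a in ("MCC", "LPFC")}

    rows = []
    for factor, align in FACTOR_ALIGN.items():
        results = {}
        for area, area_units in by_area.items():
            res = decode_timecourse(
                area_units, trials, factor, align, n_rep=args.nrep, seed=args.seed
            )
            res = permutation_null(
                area_units, trials, factor, align, res,
                n_perm=args.nperm, n_rep=max(args.nrep // 10, 3), seed=args.seed + 1,
            )
            results[area] = res
            for j, c in enumerate(res.bin_centers_s):
                rows.append(
                    {
                        "factor": factor, "area": area, "bin_center_s": c,
                        "accuracy": res.mean_accuracy[j], "p": res.p_per_bin[j],
                    }
                )
            lat = res.first_significant_s
            print(f"{factor:<9s} {area:<4s} peak={res.mean_accuracy.max():.2f} "
                  f"first significant bin: {lat if lat is None else round(lat, 2)}")
        contrast = compare_areas(results["MCC"], results["LPFC"])
        contrast.to_csv(args.out / f"06_area_contrast_{factor}.csv", index=False)
    pd.DataFrame(rows).to_csv(args.out / "06_decoding_timecourses.csv", index=False)

    # cross-temporal matrix for the decision factor in MCC
    ct = decode_timecourse(
        by_area["MCC"], trials, "checkwork", FACTOR_ALIGN["checkwork"],
        n_rep=max(args.nrep // 2, 10), seed=args.seed + 2, cross_temporal=True,
    )
    np.savetxt(args.out / "06_crosstemporal_checkwork_MCC.csv", ct.mean_accuracy, delimiter=",")

    # distance-to-check decoding from inter-trial activity (MCC)
    lasso = lasso_distance_decoding(
        by_area["MCC"], trials, distances=(1, 2, 3), n_rep=max(args.nrep, 20),
        seed=args.seed + 3,
    )
    summary = {}
    for dist, res in lasso["by_distance"].items():
        if res is None:
            summary[f"n-{dist}"] = None
            continue
        census = res.nonzero_fraction
        summary[f"n-{dist}"] = {
            "accuracy": float(res.accuracy.mean()),
            "n_contributing": int(census["contributing"].sum()),
        }
    print("distance decoding:", json.dumps(summary, indent=2))
    (args.out / "06_distance_decoding.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
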