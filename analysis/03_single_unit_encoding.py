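"""Sliding-GLM encoding of every unit, area proportions and their contrasts.

Runs the feedback-period model (feedback valence, next Check/Work decision,
gauge) on the feedback and peri-decision alignments and the cued-decision
model (side, difficulty, gauge) on the cue alignment, applies the
four-consecutive-bin rule per factor, and compares the proportion of
encoding units between MCC and LPFC with uncorrected Pearson chi-square
tests.  Also reports the feedback/check max-|Z| correlation across units.

Usage: python analysis/03_single_unit_encoding.py [--out results]
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from checkdyn.core import AlignmentSpec, read_session
from checkdyn.encoding import (
    CUED_MODEL,
    FEEDBACK_MODEL,
    classify_units,
    encode_unit,
    feature_correlation,
)

ALIGNMENTS = [
    (FEEDBACK_MODEL, AlignmentSpec("feedback_onset", -0.5, 1.5)),
    (FEEDBACK_MODEL, AlignmentSpec("next_lever_touch", -1.2, 0.6)),
    (CUED_MODEL, AlignmentSpec("cue_onset", -0.3, 1.5)),
]
EPOCHS = {
    "FEEDBACK_MODEL:feedback_onset": (0.0, 1.5),
    "FEEDBACK_MODEL:next_lever_touch": (-1.0, 0.5),
    "CUED_MODEL:cue_onset": (0.0, 1.5),
}
USE_TERMS = {
    "FEEDBACK_MODEL:feedback_onset": ("feedback", "gauge"),
    "FEEDBACK_MODEL:next_lever_touch": ("checkwork",),
    "CUED_MODEL:cue_onset": ("space", "difficulty"),
}


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    d = args.out / "session"
    trials, units = read_session(d / "trials.csv", d / "spikes.csv")

    profiles = []
    for spec, align in ALIGNMENTS:
        for u in units:
            profiles.append(encode_unit(u, trials, spec, align))
    res = classify_units(profiles, EPOCHS, use_terms=USE_TERMS)

    print("encoding proportions per area:")
    print(res["proportions"].round(3).to_string(index=False))
    print("\narea chi2 contrasts (MCC vs LPFC):")
    for term, (chi2, p) in res["area_chi2"].items():
        print(f"  {term:<11s} chi2={chi2:6.2f}  p={p:.2g}")
    corr = feature_correlation(res["classification"], "feedback", "checkwork")
    print("\nfeedback x checkwork |Z| correlation:", {k: tuple(round(x, 3) for x in v) for k, v in corr.items()})

    res["classification"].to_csv(args.out / "03_unit_classification.csv", index=False)
    res["proportions"].to_csv(args.out / "03_area_proportions.csv", index=False)
    (args.out / "03_area_chi2.json").write_text(json.dumps(res["area_chi2"]))
    (args.out / "03_congruence.json").write_text(json.dumps(res["congruence"]))


if __name__ == "__main__":
    main()
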