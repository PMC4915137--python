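"""Oculomotor analyses: lever scanning, last-fixation latency, fixation counts.

Cleans the gaze trace per pre-decision period, detects lever fixations
(>=150 ms dwell inside 2.5x-lever windows), derives the three measures and
fits the binomial/Gaussian/Poisson GLMs on gauge, distance to check,
previous performance and the upcoming Check/Work choice.

Usage: python analysis/07_oculomotor.py [--out results]
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from checkdyn.core import read_gaze, read_session
from checkdyn.oculomotor import gaze_glms, session_gaze_measures


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    d = args.out / "session"
    trials, _ = read_session(d / "trials.csv", d / "spikes.csv")
    gaze = read_gaze(d / "gaze.csv")

    measures = session_gaze_measures(gaze, trials)
    print(f"{len(measures)} trials with usable gaze; scan rate "
          f"{measures['scan'].mean():.2f}")
    fits = gaze_glms(measures)
    report = {}
    for name in ("scan", "latency", "n_fixations"):
        fit = fits.get(name)
        if fit is None:
            report[name] = fits.get(f"{name}_flag", "not fit")
            continue
        report[name] = {
            "params": {k: round(float(v), 4) for k, v in fit.params.items()},
            "pvalues": {k: float(v) for k, v in fit.pvalues.items()},
        }
        print(f"\n{name} model estimates:")
        for k, v in fit.params.items():
            print(f"  {k:<16s} {v:+.3f}  (p={fit.pvalues[k]:.3g})")
    measures.to_csv(args.out / "07_gaze_measures.csv", index=False)
    (args.out / "07_gaze_glms.json").write_text(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
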