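"""Generate the canonical synthetic study session and write it to disk.

The session couples the default checking agent (≈12.5% checks, gauge-driven
policy, difficulty-graded accuracy) with 40 MCC + 40 LPFC units whose
tuning mixes emulate the area asymmetries the downstream stages look for.
Writes trials/spikes/gaze CSVs plus a behavioral summary.

Usage: python analysis/01_simulate_session.py [--seed 0] [--out results]
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np

from checkdyn.core import write_session
from checkdyn.study import build_study_session


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    sess = build_study_session(seed=args.seed)
    out = args.out / "session"
    out.mkdir(parents=True, exist_ok=True)
    write_session(sess.trials, sess.spikes, out / "trials.csv", out / "spikes.csv")
    sess.gaze.to_csv(out / "gaze.csv", index=False)

    n_check = sum(t.choice == "CHECK" for t in sess.trials)
    summary = {
        "seed": args.seed,
        "n_trials": len(sess.trials),
        "n_blocks": sess.trials[-1].block_index,
        "check_fraction": round(n_check / len(sess.trials), 4),
        "n_units": len(sess.spikes),
        "mean_rate_hz": round(
            float(
                np.mean(
                    [
                        len(u.spike_times_s)
                        / (sess.trials[-1].events["end_of_trial"] + 2.5)
                        for u in sess.spikes
                    ]
                )
            ),
            2,
        ),
    }
    (args.out / "01_session_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"wrote session to {out}")
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
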