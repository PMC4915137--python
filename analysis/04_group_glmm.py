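"""Group GLMM timecourse: population-level Check/Work, gauge and
previous-performance effects per area, with OLRE for overdispersion.

Counts are aligned on the lever touch (the decision); each bin is fit with
a Poisson mixed model (unit random intercept + observation-level random
effect) and the per-bin fixed-effect estimates are written out.  Positive
checkwork estimates mean a population bias toward Check.

Usage: python analysis/04_group_glmm.py [--area MCC] [--out results]
"""

from __future__ import annotations

import argparse
from pathlib import Path

from checkdyn.core import AlignmentSpec, read_session
from checkdyn.glmm import GroupModelSpec, glmm_timecourse, group_long_table


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--area", choices=["MCC", "LPFC"], default="MCC")
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    d = args.out / "session"
    trials, units = read_session(d / "trials.csv", d / "spikes.csv")
    units = [u for u in units if u.area == args.area]

    align = AlignmentSpec("lever_touch", -0.8, 0.6, bin_width_s=0.2, bin_step_s=0.2)
    long = group_long_table(units, trials, align, max_trials=250)
    tc = glmm_timecourse(long, GroupModelSpec())
    table = tc.table
    table.to_csv(args.out / f"04_glmm_timecourse_{args.area}.csv", index=False)
    cw = table[table["term"] == "checkwork"]
    print(f"{args.area}: checkwork estimates per bin (positive = bias toward Check)")
    print(cw[["bin_center_s", "beta", "se", "p", "significant"]].round(3).to_string(index=False))


if __name__ == "__main__":
    main()
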