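"""Behavioral analyses of the study session.

Fits the checking logistic model (gauge, previous performance, speed, block),
the log-RT model, the within-block reward-rate profile with its no-checking
counterfactual, and the re-check distance vs the gauge seen at the previous
check.  Writes the four result tables under results/.

Usage: python analysis/02_behavior.py [--seed 0] [--out results]
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

from checkdyn import behavior as bh
from checkdyn.core import read_session


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    session_dir = args.out / "session"
    trials, _ = read_session(session_dir / "trials.csv", session_dir / "spikes.csv")

    check_fit = bh.fit_check_model(trials)
    print("check model (logit scale):")
    print(check_fit.summary().tables[1])

    rt_fit, rt_anova = bh.fit_rt_model(trials)
    print("\nlog-RT model ANOVA:")
    print(rt_anova)

    profile = bh.reward_rate_profile(trials)
    mean_prof = profile[profile["block"] == -1]
    print("\nmean reward rate per decile (with vs without checking):")
    print(mean_prof[["decile", "rate_with_check", "rate_without_check"]].round(2).to_string(index=False))

    dist = bh.distance_vs_gauge(trials)
    print("\ndistance-to-next-check vs gauge: pearson r=%.3f (p=%.2g), spearman r=%.3f"
          % (dist["pearson"][0], dist["pearson"][1], dist["spearman"][0]))

    check_fit.params.rename("estimate").to_csv(args.out / "02_check_model.csv")
    rt_anova.to_csv(args.out / "02_rt_anova.csv")
    profile.to_csv(args.out / "02_reward_rate.csv", index=False)
    dist["pairs"].to_csv(args.out / "02_distance_pairs.csv", index=False)
    (args.out / "02_distance_corr.json").write_text(
        json.dumps({"pearson": dist["pearson"], "spearman": dist["spearman"]})
    )


if __name__ == "__main__":
    main()
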