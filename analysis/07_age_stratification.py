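#!/usr/bin/env python
"""Stratify subtype expressions by age brackets in both cohorts.

Computes mean +/- SD of each component's brain scores within the adult
(40-70 years) and child (100-140 months) brackets and reports whether
the age trend reverses between the cohorts, mode by mode.
"""

import numpy as np
import pandas as pd

from common import study_config
from chronomodes.pipeline import cmd_stratify


def trend(df: pd.DataFrame) -> float:
    mid = (df["bracket_low"] + df["bracket_high"]) / 2
    ok = df["n"] > 0
    return float(np.polyfit(mid[ok], df.loc[ok, "mean"], 1)[0])


def main() -> None:
    cfg = study_config()
    artifacts = cmd_stratify(cfg)
    summary = pd.read_csv(artifacts["age_summary"], sep="\t")
    print(summary.to_string(index=False))
    print("\nage-trend direction (bracket-mean slope sign):")
    reversals = 0
    for comp, group in summary.groupby("component"):
        s_src = trend(group[group["cohort"] == "source"])
        s_ext = trend(group[group["cohort"] == "external"])
        flip = "reversed" if np.sign(s_src) == -np.sign(s_ext) else "same"
        reversals += flip == "reversed"
        print(f"  mode {comp}: source {'+' if s_src > 0 else '-'}  "
              f"external {'+' if s_ext > 0 else '-'}  -> {flip}")
    print(f"\n{reversals} of {summary['component'].nunique()} modes show "
          "reversed age distributions between the cohorts")


if __name__ == "__main__":
    main()
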