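#!/usr/bin/env python
"""Phenome-wide association scans (PheWAS / DiaWAS / MedWAS).

Correlates every component's brain scores with each phenotype family
under per-family Bonferroni control and prints the top hit per family
and component.
"""

import pandas as pd

from common import study_config
from chronomodes.pipeline import cmd_phewas


def main() -> None:
    cfg = study_config()
    artifacts = cmd_phewas(cfg)
    hits = pd.read_csv(artifacts["assoc_hits"], sep="\t")
    if hits.empty:
        print("no family-wise significant associations")
        return
    top = (hits.sort_values("neglog10p", ascending=False)
               .groupby(["family", "component"]).head(1))
    cols = ["component", "family", "phenotype", "category", "r", "neglog10p"]
    print("top hit per family and component:")
    print(top[cols].to_string(index=False))
    print(f"\ntotal family-wise significant associations: {len(hits)}")


if __name__ == "__main__":
    main()
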