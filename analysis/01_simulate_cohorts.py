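#!/usr/bin/env python
"""Generate the source (adult) and external (child) synthetic cohorts.

Writes participants/brain/phenome TSVs plus the planted ground truth for
both cohorts under results/study/.
"""

from common import study_config
from chronomodes.pipeline import cmd_simulate


def main() -> None:
    cfg = study_config()
    artifacts = cmd_simulate(cfg)
    print(f"wrote {len(artifacts)} artifacts under {cfg.work_dir}")
    print("source cohort: participants.tsv + 397-feature brain.tsv "
          "+ 3 phenome families (977/1396/133 phenotypes)")
    print("external cohort: GMV-only features, ages 107-133 months, "
          "age-latent associations sign-reversed by construction")


if __name__ == "__main__":
    main()
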