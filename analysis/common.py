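"""Shared study configuration for the numbered analysis drivers.

All drivers operate on the same working directory (``results/study``) so
each stage picks up the artifacts of the previous one, exactly like the
staged CLI.  The cohort is the default synthetic design: n=2000 adults,
139 GMV + 48 FA + 210 FC features, five planted modes with latent-target
correlations 0.30...0.10, and a 977/1396/133-phenotype phenome.
"""

import logging

from chronomodes.pipeline import PipelineConfig

logging.basicConfig(level=logging.INFO, format="%(asctime)s | %(message)s")


def study_config() -> PipelineConfig:
    return PipelineConfig(
        work_dir="results/study",
        external_n=1500,
        k=5,
        B_perm=1000,
        B_boot=1000,
        alpha_perm=0.001,
        seed=2026,
    )
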