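"""Readers and writers binding the pipeline stages together.

Everything on disk is plain text: tab-separated tables with metadata
header lines (prefixed ``#``), JSON for models and the run manifest, and
a flat YAML file for configuration.  ``brain.tsv`` carries a
``#block`` annotation line tagging every feature column; the per-family
phenome tables carry ``#category`` and ``#type`` lines.  All writes are
atomic (temp file + rename) so a crashed stage never leaves a truncated
artifact behind.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import CohortBundle, GeneratorConfig, GroundTruth


def atomic_write_text(path: str | Path, text: str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return path


def write_tsv(df: pd.DataFrame, path: str | Path, *,
              meta_lines: dict[str, list[str]] | None = None,
              index: bool = False) -> Path:
    """TSV with optional ``#key<TAB>v1<TAB>v2...`` metadata header lines."""
    header = ""
    if meta_lines:
        for key, values in meta_lines.items():
            header += "#" + key + "\t" + "\t".join(map(str, values)) + "\n"
    body = df.to_csv(sep="\t", index=index, float_format="%.17g")
    return atomic_write_text(path, header + body)


def read_tsv(path: str | Path, *, index_col=None
             ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    path = Path(path)
    meta: dict[str, list[str]] = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, *values = line.rstrip("\n").split("\t")
            meta[key[1:]] = values
            skip += 1
    df = pd.read_csv(path, sep="\t", skiprows=skip, index_col=index_col)
    return df, meta


def write_cohort(bundle: CohortBundle, out_dir: str | Path) -> dict[str, Path]:
    """participants.tsv, brain.tsv (block-annotated), phenome_<family>.tsv."""
    out = Path(out_dir)
    paths = {
        "participants": write_tsv(bundle.participants, out / "participants.tsv"),
        "brain": write_tsv(
            bundle.brain.reset_index(), out / "brain.tsv",
            meta_lines={"block": ["participant_id"] + list(bundle.brain_blocks)}),
    }
    for family, table in bundle.phenome.items():
        meta = bundle.phenome_meta.get(family)
        meta_lines = None
        if meta is not None:
            meta_lines = {
                "category": ["participant_id"] + list(meta["category"]),
                "type": ["participant_id"] + list(meta["type"]),
            }
        paths[f"phenome_{family}"] = write_tsv(
            table.reset_index(), out / f"phenome_{family}.tsv",
            meta_lines=meta_lines)
    return paths


def read_cohort(in_dir: str | Path) -> CohortBundle:
    in_dir = Path(in_dir)
    participants, _ = read_tsv(in_dir / "participants.tsv")
    brain, brain_meta = read_tsv(in_dir / "brain.tsv", index_col="participant_id")
    if "block" not in brain_meta:
        raise ValueError(f"{in_dir / 'brain.tsv'} lacks the #block annotation line")
    blocks = pd.Series(brain_meta["block"][1:], index=brain.columns, name="block")
    phenome: dict[str, pd.DataFrame] = {}
    phenome_meta: dict[str, pd.DataFrame] = {}
    for path in sorted(in_dir.glob("phenome_*.tsv")):
        family = path.stem.removeprefix("phenome_")
        table, meta = read_tsv(path, index_col="participant_id")
        phenome[family] = table
        phenome_meta[family] = pd.DataFrame({
            "phenotype": table.columns,
            "category": meta.get("category", [""] * (len(table.columns) + 1))[1:],
            "type": meta.get("type", [""] * (len(table.columns) + 1))[1:],
            "family": family,
        })
    bundle = CohortBundle(participants, brain, blocks, phenome, phenome_meta)
    bundle.validate()
    return bundle


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    payload = {
        "latent_scores": truth.latent_scores.tolist(),
        "true_loadings": truth.true_loadings.tolist(),
        "feature_names": truth.feature_names,
        "true_target_correlations": truth.true_target_correlations.tolist(),
        "target": truth.target.tolist(),
        "age_effects": truth.age_effects.tolist(),
        "phenotype_effect_map": {k: [int(m), float(e)]
                                 for k, (m, e) in truth.phenotype_effect_map.items()},
    }
    return atomic_write_text(path, json.dumps(payload))


def read_ground_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        latent_scores=np.asarray(d["latent_scores"], dtype=float),
        true_loadings=np.asarray(d["true_loadings"], dtype=float),
        feature_names=list(d["feature_names"]),
        true_target_correlations=np.asarray(d["true_target_correlations"], dtype=float),
        target=np.asarray(d["target"], dtype=float),
        age_effects=np.asarray(d["age_effects"], dtype=float),
        phenotype_effect_map={k: (int(m), float(e))
                              for k, (m, e) in d["phenotype_effect_map"].items()},
    )


def write_config(config: GeneratorConfig, path: str | Path) -> Path:
    return atomic_write_text(path, yaml.safe_dump(config.to_dict(), sort_keys=True))


def read_config(path: str | Path) -> GeneratorConfig:
    return GeneratorConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
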