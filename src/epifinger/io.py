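"""Readers and writers for the pipeline's plain-text formats.

All matrices travel as TSV (first column = feature id, header = sample
ids), the probe manifest as an Illumina-style CSV, the fingerprint model as
a plain-text key-value document.  Output files carry ``#``-prefixed header
comments with the package version and a configuration hash so every
artifact is traceable to the run that made it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .selection import FingerprintModel

logger = logging.getLogger(__name__)


def config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _provenance_header(meta: dict | None) -> str:
    meta = dict(meta or {})
    meta.setdefault("package", f"epifinger {__version__}")
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def read_methylation_matrix(path: str | Path) -> pd.DataFrame:
    """Read a CpG x sample beta-value TSV.

    Blank and NA cells become missing; any non-missing value outside
    [0, 1] or non-numeric cell is rejected with its coordinates; duplicate
    probe or sample ids are rejected.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    if raw.index.duplicated().any():
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate probe ids: {dups}")
    if pd.Index(raw.columns).duplicated().any():
        dups = pd.Index(raw.columns)
        raise ValueError(
            f"duplicate sample ids: {dups[dups.duplicated()].tolist()}")

    values = raw.apply(pd.to_numeric, errors="coerce")
    # blank/NA cells are already NaN in raw; anything else that failed to
    # parse is genuinely non-numeric text
    bad = values.isna() & raw.notna()
    bad_cells = np.argwhere(bad.to_numpy())
    if len(bad_cells):
        r, c = bad_cells[0]
        raise ValueError(
            f"non-numeric cell at probe {raw.index[r]!r}, "
            f"sample {raw.columns[c]!r}: {raw.iat[r, c]!r}")
    out_of_range = (values < 0) | (values > 1)
    if out_of_range.to_numpy().any():
        r, c = np.argwhere(out_of_range.to_numpy())[0]
        raise ValueError(
            f"beta value out of [0, 1] at probe {values.index[r]!r}, "
            f"sample {values.columns[c]!r}: {values.iat[r, c]}")
    return values


def write_matrix(frame: pd.DataFrame, path: str | Path,
                 index_label: str = "CpG", meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(meta))
        frame.to_csv(fh, sep="\t", index_label=index_label)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_table(frame: pd.DataFrame, path: str | Path,
                meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(meta))
        frame.to_csv(fh, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path, comment="#")
    required = {"CpG", "CHR", "MAPINFO"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest lacks columns: {sorted(missing)}")
    return manifest


def write_fingerprint_model(model: FingerprintModel, path: str | Path,
                            meta: dict | None = None) -> None:
    """Serialize the fingerprint as a plain-text key-value document."""
    with open(path, "w") as fh:
        fh.write(_provenance_header(meta))
        fh.write(f"training_cohort\t{model.training_cohort}\n")
        fh.write(f"n\t{model.n}\n")
        fh.write(f"n_events\t{model.n_events}\n")
        fh.write(f"flag\t{model.flag}\n")
        fh.write(f"intercept\t{model.intercept!r}\n")
        for cpg in model.cpgs:
            fh.write(f"weight:{cpg}\t{model.weights[cpg]!r}\n")


def read_fingerprint_model(path: str | Path) -> FingerprintModel:
    fields: dict[str, str] = {}
    weights: dict[str, float] = {}
    cpgs: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            key, value = line.rstrip("\n").split("\t", 1)
            if key.startswith("weight:"):
                cpg = key.split(":", 1)[1]
                cpgs.append(cpg)
                weights[cpg] = float(value)
            else:
                fields[key] = value
    return FingerprintModel(
        cpgs=cpgs, intercept=float(fields["intercept"]), weights=weights,
        training_cohort=fields.get("training_cohort", ""),
        n=int(fields.get("n", 0)), n_events=int(fields.get("n_events", 0)),
        flag=fields.get("flag", ""))
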