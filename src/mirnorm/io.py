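"""File formats and configuration for the pipeline.

Canonical on-disk dialect is TSV (CSV accepted on read); every file written
here carries provenance comment lines beginning ``#`` (tool version, kind,
and any extra key=value pairs such as the seed or a config hash), which the
readers skip.  Matrices are genes/assays × samples with identifiers in the
first column; missing values round-trip as empty cells.
"""

from __future__ import annotations

import hashlib
import os
import tempfile
from dataclasses import dataclass, asdict, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_table",
    "write_table",
    "read_cq_dataset",
    "write_cq_dataset",
    "write_truth",
    "PipelineConfig",
    "load_config",
    "config_hash",
]


def _provenance_lines(kind: str, meta: dict | None) -> str:
    lines = [f"# mirnorm {__version__}", f"# kind={kind}"]
    for k, v in (meta or {}).items():
        lines.append(f"# {k}={v}")
    return "\n".join(lines) + "\n"


def _atomic_write(path: str | Path, text: str) -> None:
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


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return "\t" if "\t" in line else ","
    return "\t"


def write_matrix(
    df: pd.DataFrame, path: str | Path, kind: str = "matrix", meta: dict | None = None
) -> None:
    """Write a genes × samples matrix as TSV with a provenance header."""
    if df.index.has_duplicates:
        raise ValueError("duplicate row identifiers")
    if df.columns.has_duplicates:
        raise ValueError("duplicate column identifiers")
    body = df.to_csv(sep="\t", index_label="id", na_rep="")
    _atomic_write(path, _provenance_lines(kind, meta) + body)


def read_matrix(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a matrix written by :func:`write_matrix` (or any id-first TSV/CSV).

    Duplicate identifiers and non-numeric cells are rejected with the
    offending coordinates named.
    """
    path = Path(path)
    sep = sep or _sniff_sep(path)
    with open(path) as fh:  # pandas mangles duplicate headers; check raw line
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            header = line.rstrip("\n").split(sep)[1:]
            dups = sorted({h for h in header if header.count(h) > 1})
            if dups:
                raise ValueError(f"duplicate column identifiers: {dups}")
            break
    df = pd.read_csv(path, sep=sep, comment="#", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row identifiers: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate column identifiers: {dups}")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col].replace({"": None, "NA": None}), errors="coerce")
        bad = converted.isna() & df[col].notna() & ~df[col].isin(["", "NA"])
        if bad.any():
            row = bad.idxmax()
            raise ValueError(
                f"non-numeric cell at row {row!r}, column {col!r}: {df.loc[row, col]!r}"
            )
        out[col] = converted
    out.index.name = df.index.name
    return out


def write_table(
    df: pd.DataFrame, path: str | Path, kind: str = "table",
    meta: dict | None = None, index: bool = True,
) -> None:
    """Write an arbitrary tidy table as TSV with a provenance header."""
    body = df.to_csv(sep="\t", index=index, na_rep="NA")
    _atomic_write(path, _provenance_lines(kind, meta) + body)


def read_table(path: str | Path, sep: str | None = None, index_col=None) -> pd.DataFrame:
    """Read a tidy TSV/CSV table, skipping provenance comment lines."""
    path = Path(path)
    sep = sep or _sniff_sep(path)
    return pd.read_csv(path, sep=sep, comment="#", index_col=index_col,
                       na_values=["NA"], keep_default_na=True)


def write_cq_dataset(d, outdir: str | Path, meta: dict | None = None) -> None:
    """Write a CqDataset as tidy TSVs: wells, sample metadata and assays."""
    outdir = Path(outdir)
    write_table(d.wells, outdir / "cq_wells.tsv", kind="cq_wells", meta=meta, index=False)
    write_table(d.meta, outdir / "sample_meta.tsv", kind="sample_meta", meta=meta)
    write_table(
        d.efficiencies.rename("efficiency").to_frame(),
        outdir / "assays.tsv",
        kind="assays",
        meta=meta,
    )


def read_cq_dataset(indir: str | Path):
    """Read a CqDataset written by :func:`write_cq_dataset`."""
    from .quantify import CqDataset

    indir = Path(indir)
    wells = read_table(indir / "cq_wells.tsv")
    wells["is_irc"] = wells["is_irc"].astype(bool)
    meta = read_table(indir / "sample_meta.tsv", index_col=0)
    assays = read_table(indir / "assays.tsv", index_col=0)
    return CqDataset(wells=wells, efficiencies=assays["efficiency"], meta=meta)


def write_truth(truth, path: str | Path) -> None:
    """Serialize a PlantedTruth as structured YAML-ish text."""
    data = {
        "stable_assays": sorted(truth.stable_assays),
        "planted_log2fc": {f"{a}|{g}": float(v) for (a, g), v in truth.planted_log2fc.items()},
        "loading_effects": {k: float(v) for k, v in truth.loading_effects.items()},
        "true_efficiency": {k: float(v) for k, v in truth.true_efficiency.items()},
    }
    _atomic_write(path, yaml.safe_dump(data, sort_keys=True))


@dataclass
class PipelineConfig:
    """End-to-end pipeline thresholds and mode switches.

    Defaults are the study's operating points: fold-change threshold 1.2 and
    alpha 0.05 for candidate selection, pool Cq cutoff 35 for measurability,
    geNorm V cutoff 0.15, BestKeeper SD cutoff 1.0 cycles, co-expression
    threshold 0.60.
    """

    fc_threshold: float = 1.2
    alpha: float = 0.05
    cq_cutoff: float = 35.0
    v_cutoff: float = 0.15
    sd_cutoff: float = 1.0
    coexpression: float = 0.60
    calibration_mode: str = "mean_center"
    group_test: str = "kruskal_wallis"
    bestkeeper_compat: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.fc_threshold > 1:
            raise ValueError("fc_threshold must exceed 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.cq_cutoff < 45:
            raise ValueError("cq_cutoff must lie in (0, 45)")
        if not self.v_cutoff > 0:
            raise ValueError("v_cutoff must be positive")
        if not self.sd_cutoff > 0:
            raise ValueError("sd_cutoff must be positive")
        if not -1 <= self.coexpression <= 1:
            raise ValueError("coexpression threshold must lie in [-1, 1]")
        if self.calibration_mode not in ("mean_center", "calibrator"):
            raise ValueError(f"unknown calibration_mode {self.calibration_mode!r}")
        if self.group_test not in ("kruskal_wallis", "anova"):
            raise ValueError(f"unknown group_test {self.group_test!r}")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline configuration; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def config_hash(cfg: PipelineConfig) -> str:
    """Short stable hash of a configuration, for provenance headers."""
    blob = yaml.safe_dump(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
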