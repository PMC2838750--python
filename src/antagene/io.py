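"""Readers and writers for the pipeline's tab-separated formats.

One tabular dialect throughout: TSV, UTF-8, '.' decimal; gzip is handled
transparently by extension.  Formats: expression matrix (rows =
transcripts, columns = sample IDs), sample sheet (sample_id, sex, line,
batch, replicate), fitness assays (line, sex, replicate, value[, sired,
total]), tissue atlas (gene, tissue columns..., whole_fly), annotation
tables (gene, arm, band, subband) and (gene, term), truth labels as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import TruthLabels


class InputError(ValueError):
    """Malformed or inconsistent input file."""


def read_expression_matrix(path) -> pd.DataFrame:
    """Read a transcripts x samples log2 matrix.

    First column = transcript IDs (kept in order), header = sample IDs.
    Duplicate transcript IDs and non-numeric cells are rejected with
    coordinates.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise InputError(f"duplicate transcript IDs: {dup}")
    if df.shape[1] == 0:
        raise InputError("matrix has no sample columns (missing header?)")
    try:
        out = df.astype(float)
    except (TypeError, ValueError):
        for j, col in enumerate(df.columns):
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                i = int(np.argmax(bad.to_numpy()))
                raise InputError(
                    f"non-numeric cell at row {df.index[i]!r}, column {col!r}: "
                    f"{df[col].iloc[i]!r}"
                ) from None
        raise
    out.index.name = "transcript"
    return out


def write_expression_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "sex", "line", "batch", "replicate"}
    if not required.issubset(df.columns):
        raise InputError(f"sample sheet needs columns {sorted(required)}")
    if not df["sex"].isin(["M", "F"]).all():
        raise InputError("sex must be 'M' or 'F'")
    if df["sample_id"].duplicated().any():
        raise InputError("duplicate sample IDs in sample sheet")
    return df


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_fitness_assays(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"line", "sex", "replicate", "value"}
    if not required.issubset(df.columns):
        raise InputError(f"fitness table needs columns {sorted(required)}")
    return df


def write_fitness_assays(assays: pd.DataFrame, path) -> None:
    assays.to_csv(path, sep="\t", index=False)


def read_fitness_covariate(path) -> pd.DataFrame:
    """Long (line, sex, fitness) covariate table."""
    df = pd.read_csv(path, sep="\t")
    if not {"line", "sex", "fitness"}.issubset(df.columns):
        raise InputError("fitness covariate needs columns line, sex, fitness")
    return df


def read_atlas(path, wholefly_col: str = "whole_fly") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if wholefly_col not in df.columns:
        raise InputError(f"atlas lacks the {wholefly_col!r} column")
    return df.astype(float)


def write_atlas(atlas: pd.DataFrame, path) -> None:
    atlas.to_csv(path, sep="\t")


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns:
        raise InputError("annotation table needs a 'gene' column")
    return df


def write_annotations(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_truth(truth: TruthLabels, path) -> None:
    """Serialise planted truth to JSON (tables as records)."""
    obj = {}
    for f in dataclasses.fields(truth):
        v = getattr(truth, f.name)
        if v is None:
            continue
        if isinstance(v, pd.DataFrame):
            obj[f.name] = v.to_dict(orient="list")
        elif isinstance(v, dict):
            obj[f.name] = {
                k: sorted(x) if isinstance(x, (set, frozenset))
                else (x.tolist() if isinstance(x, np.ndarray) else x)
                for k, x in v.items()
            }
        elif isinstance(v, (set, frozenset)):
            obj[f.name] = sorted(v)
        else:
            obj[f.name] = v
    Path(path).write_text(json.dumps(obj, indent=1))


def read_truth(path) -> TruthLabels:
    obj = json.loads(Path(path).read_text())
    kw = {}
    for f in dataclasses.fields(TruthLabels):
        if f.name not in obj:
            continue
        v = obj[f.name]
        if f.name in ("line_effects", "transcripts"):
            kw[f.name] = pd.DataFrame(v)
        elif f.name == "tissue_specific":
            kw[f.name] = {k: set(x) for k, x in v.items()}
        elif f.name in ("unexpressed_genes", "enriched_terms", "interest_set"):
            kw[f.name] = set(v)
        else:
            kw[f.name] = v
    return TruthLabels(**kw)


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PipelineConfig:
    """Paths, thresholds and sampler settings for the end-to-end run."""

    assays: str | None = None
    matrix: str | None = None
    samples: str | None = None
    atlas: str | None = None
    chrom_annotations: str | None = None
    go_annotations: str | None = None
    out_dir: str = "antagene_out"
    alpha_anova: float = 0.001
    alpha_regression: float = 0.05
    fold: float = 2.0
    unexpressed: float = 3.4
    n_tissues: int = 17
    log2_threshold: float = 1.0
    n_iter: int = 20_000
    burn_in: int = 5_000
    thin: int = 10
    n_chains: int = 4
    seed: int = 0

    def validate(self, check_paths: bool = True) -> None:
        if not (0 < self.alpha_anova < 1 and 0 < self.alpha_regression < 1):
            raise InputError("alpha thresholds must lie in (0, 1)")
        if self.fold < 1 or self.unexpressed <= 0 or self.n_tissues < 1:
            raise InputError("fold >= 1, unexpressed > 0, n_tissues >= 1 required")
        if self.burn_in >= self.n_iter:
            raise InputError("burn_in must be smaller than n_iter")
        if check_paths:
            for name in ("assays", "matrix", "samples", "atlas",
                         "chrom_annotations", "go_annotations"):
                p = getattr(self, name)
                if p is not None and not Path(p).exists():
                    raise InputError(f"{name} file not found: {p}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)
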