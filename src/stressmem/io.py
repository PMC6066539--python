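"""Readers, writers and containers for the tabular artifacts.

Dialects: tab-separated for expression and annotation tables, comma-
separated for physiology; header row mandatory; UTF-8.  Readers validate
and fail with located errors rather than silently coercing.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import StageDesign

__all__ = [
    "ExpressionStudy",
    "PhysiologyTable",
    "AnnotationTable",
    "read_expression",
    "write_expression",
    "read_physiology",
    "write_physiology",
    "read_annotations",
    "write_annotations",
    "setup_logging",
]

log = logging.getLogger("stressmem")


def setup_logging(level: str = "INFO") -> None:
    """Timestamped, leveled logging to standard error."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    root = logging.getLogger("stressmem")
    root.handlers[:] = [handler]
    root.setLevel(level.upper())


@dataclass
class ExpressionStudy:
    """FPKM-normalised gene x sample matrix with its stage/replicate design.

    ``fpkm`` is indexed by gene id with one column per sample;
    ``samples`` is indexed by sample name with columns ``stage`` and
    ``replicate``.
    """

    fpkm: pd.DataFrame
    samples: pd.DataFrame
    design: StageDesign = field(default_factory=StageDesign)

    def __post_init__(self) -> None:
        if self.fpkm.index.duplicated().any():
            dups = self.fpkm.index[self.fpkm.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        vals = self.fpkm.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("expression matrix contains non-finite values")
        if (vals < 0).any():
            bad = self.fpkm.index[(vals < 0).any(axis=1)][0]
            raise ValueError(f"negative FPKM value at gene {bad!r}")
        missing = [s for s in self.samples.index if s not in self.fpkm.columns]
        if missing:
            raise ValueError(f"samples in sheet missing from matrix: {missing}")
        extra = [c for c in self.fpkm.columns if c not in self.samples.index]
        if extra:
            raise ValueError(f"matrix columns absent from sample sheet: {extra}")
        bad_stage = set(self.samples["stage"]) - set(self.design.transcriptome_stages)
        if bad_stage:
            raise ValueError(f"unknown stage labels: {sorted(bad_stage)}")
        # canonical column order: sheet order
        self.fpkm = self.fpkm.loc[:, list(self.samples.index)]

    @property
    def genes(self) -> pd.Index:
        return self.fpkm.index

    @property
    def n_samples(self) -> int:
        return self.fpkm.shape[1]

    def stage_samples(self, stage: str) -> list[str]:
        hits = list(self.samples.index[self.samples["stage"] == stage])
        if not hits:
            raise ValueError(f"no samples for stage {stage!r}")
        return hits

    def stage_means(self) -> pd.DataFrame:
        """Per-stage mean FPKM profile (replicates averaged), genes x stages."""
        cols = {}
        for stage in self.design.transcriptome_stages:
            if (self.samples["stage"] == stage).any():
                cols[stage] = self.fpkm[self.stage_samples(stage)].mean(axis=1)
        return pd.DataFrame(cols)

    def log2_matrix(self) -> pd.DataFrame:
        """log2(FPKM + 1), the variance-stabilised working scale."""
        return np.log2(self.fpkm + 1.0)

    def subset_genes(self, genes) -> "ExpressionStudy":
        return ExpressionStudy(self.fpkm.loc[genes].copy(), self.samples, self.design)


def read_expression(
    path: str | Path,
    sample_sheet: str | Path,
    design: StageDesign | None = None,
) -> ExpressionStudy:
    """Read an FPKM TSV (gene-id column + one column per sample) and its
    sample sheet (sample, stage, replicate)."""
    design = design or StageDesign()
    mat = pd.read_csv(path, sep="\t", index_col=0)
    try:
        mat = mat.astype(float)
    except ValueError as e:
        raise ValueError(f"non-numeric expression value in {path}: {e}") from None
    sheet = pd.read_csv(sample_sheet, sep="\t")
    required = {"sample", "stage", "replicate"}
    if not required.issubset(sheet.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    if sheet["sample"].duplicated().any():
        raise ValueError("duplicate sample names in sample sheet")
    sheet = sheet.set_index("sample")
    study = ExpressionStudy(mat, sheet, design)
    log.info("read expression: %d genes x %d samples", *study.fpkm.shape)
    return study


def write_expression(study: ExpressionStudy, path: str | Path, sample_sheet: str | Path) -> None:
    study.fpkm.to_csv(path, sep="\t", index_label="gene")
    study.samples.to_csv(sample_sheet, sep="\t", index_label="sample")


@dataclass
class PhysiologyTable:
    """Long-format physiology records: one value per plant x stage x parameter."""

    data: pd.DataFrame  # columns: plant_id, stage, parameter, value
    design: StageDesign = field(default_factory=StageDesign)

    def __post_init__(self) -> None:
        required = {"plant_id", "stage", "parameter", "value"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"physiology table needs columns {sorted(required)}")
        bad = set(self.data["stage"]) - set(self.design.physiology_stages)
        if bad:
            raise ValueError(f"unknown physiology stage labels: {sorted(bad)}")
        vals = pd.to_numeric(self.data["value"], errors="coerce")
        if vals.isna().any():
            idx = int(np.flatnonzero(vals.isna())[0])
            raise ValueError(f"non-numeric physiology value at row {idx}")
        self.data = self.data.assign(value=vals.astype(float)).reset_index(drop=True)

    @property
    def parameters(self) -> list[str]:
        return sorted(self.data["parameter"].unique())

    def values_for(self, parameter: str, stage: str) -> np.ndarray:
        sel = (self.data["parameter"] == parameter) & (self.data["stage"] == stage)
        return self.data.loc[sel, "value"].to_numpy()

    def stage_means(self, parameter: str) -> pd.Series:
        sub = self.data[self.data["parameter"] == parameter]
        means = sub.groupby("stage")["value"].mean()
        order = [s for s in self.design.physiology_stages if s in means.index]
        return means.loc[order]


def read_physiology(path: str | Path, design: StageDesign | None = None) -> PhysiologyTable:
    """Read long-format physiology CSV (plant_id, stage, parameter, value)."""
    design = design or StageDesign()
    df = pd.read_csv(path, sep=",")
    table = PhysiologyTable(df, design)
    log.info(
        "read physiology: %d plants, %d parameters",
        table.data["plant_id"].nunique(),
        len(table.parameters),
    )
    return table


def write_physiology(table: PhysiologyTable, path: str | Path) -> None:
    table.data.to_csv(path, sep=",", index=False)


@dataclass
class AnnotationTable:
    """Gene -> GO term assignments (one row per pair)."""

    data: pd.DataFrame  # columns: gene, term

    def __post_init__(self) -> None:
        if not {"gene", "term"}.issubset(self.data.columns):
            raise ValueError("annotation table needs columns ['gene', 'term']")
        self.data = self.data.drop_duplicates().reset_index(drop=True)

    @property
    def terms(self) -> list[str]:
        return sorted(self.data["term"].unique())

    def genes_for(self, term: str) -> set[str]:
        return set(self.data.loc[self.data["term"] == term, "gene"])

    def term_sets(self) -> dict[str, set[str]]:
        return {t: set(g["gene"]) for t, g in self.data.groupby("term")}


def read_annotations(path: str | Path) -> AnnotationTable:
    return AnnotationTable(pd.read_csv(path, sep="\t"))


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)
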