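"""File formats and validated pipeline configuration.

CSV dialect throughout: UTF-8, comma separator, ``.`` decimal, header row
required.  Judgment matrices are square CSVs with the item labels as both
header row and first column.  The YAML pipeline configuration is validated
against a strict schema (unknown keys rejected) before any computation.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .ahp import JudgmentMatrix
from .rsm import FactorMapping
from .screen import CriterionSpec

__all__ = [
    "read_judgment_matrix",
    "write_judgment_matrix",
    "read_ccd_runs",
    "write_ccd_runs",
    "CriterionConfig",
    "FactorConfig",
    "PipelineConfig",
    "load_config",
]


def read_judgment_matrix(path) -> JudgmentMatrix:
    df = pd.read_csv(path, index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError(
            f"{path}: row labels {list(df.index)} != column labels "
            f"{list(df.columns)}")
    return JudgmentMatrix(df.to_numpy(float), list(df.columns.astype(str)))


def write_judgment_matrix(matrix: JudgmentMatrix, path) -> None:
    pd.DataFrame(matrix.entries, index=matrix.labels,
                 columns=matrix.labels).to_csv(path)


def read_ccd_runs(path, response_col: str = "response"):
    """Read a coded CCD run table ``run,x1,...,xk,response``.

    Returns ``(X, y)`` with X the (runs x k) coded matrix; ``y`` is None
    when the response column is absent.
    """
    df = pd.read_csv(path)
    xcols = sorted(
        (c for c in df.columns if c.startswith("x") and c[1:].isdigit()),
        key=lambda c: int(c[1:]))
    if not xcols:
        raise ValueError(f"{path}: no coded factor columns x1..xk found")
    X = df[xcols].to_numpy(float)
    y = df[response_col].to_numpy(float) if response_col in df.columns else None
    return X, y


def write_ccd_runs(X, y=None, path=None, response_col: str = "response"):
    X = np.asarray(X, float)
    df = pd.DataFrame(X, columns=[f"x{i+1}" for i in range(X.shape[1])])
    df.insert(0, "run", np.arange(1, len(df) + 1))
    if y is not None:
        df[response_col] = np.asarray(y, float)
    if path is not None:
        df.to_csv(path, index=False)
    return df


class CriterionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    column: Optional[str] = None
    direction: Literal[-1, 1] = 1
    rank: int = Field(ge=1)

    def to_spec(self) -> CriterionSpec:
        return CriterionSpec(self.name, self.column or self.name,
                             self.direction, self.rank)


class FactorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    center: float
    step: float = Field(gt=0)

    def to_mapping(self) -> FactorMapping:
        return FactorMapping(self.name, self.center, self.step)


class PipelineConfig(BaseModel):
    """Strict schema for the analysis configuration file."""

    model_config = ConfigDict(extra="forbid")

    criteria: Optional[list[CriterionConfig]] = None
    quantizer: Literal["ceil", "nearest", "log"] = "ceil"
    lambda_method: Literal["row_ratio", "eigen"] = "row_ratio"
    cr_threshold: float = Field(default=0.1, gt=0)
    ri_table: Optional[dict[int, float]] = None
    normalization: Literal["sum", "max", "minmax"] = "sum"
    factors: Optional[list[FactorConfig]] = None
    bounds: Optional[list[tuple[float, float]]] = None
    seed: int = 0
    out_dir: Optional[str] = None

    def criterion_specs(self):
        if self.criteria is None:
            return None
        return tuple(c.to_spec() for c in self.criteria)

    def factor_mappings(self):
        if self.factors is None:
            return None
        return tuple(f.to_mapping() for f in self.factors)


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return PipelineConfig.model_validate(data)
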