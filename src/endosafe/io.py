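"""Readers, writers and validation for the matrix and metadata formats used
throughout the pipeline.

Matrices are tab-separated, features in rows and samples in columns, with the
first header field literally ``feature_id``.  Sample sheets are
comma-separated.  Gene sets use the standard GMT layout (set name,
description, then tab-separated member genes).
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("endosafe")

REQUIRED_SHEET_COLUMNS = ("sample_id", "subject_id", "group", "timepoint", "age")

#: fraction of missing values above which a CpG is dropped at load
MISSING_DROP_FRACTION = 0.2


class MatrixParseError(ValueError):
    """Raised when a matrix file violates the format contract."""


class SampleSheetError(ValueError):
    """Raised when a sample sheet violates its contract."""


def _check_unique(ids, what: str) -> None:
    dup = pd.Index(ids)[pd.Index(ids).duplicated()]
    if len(dup):
        raise MatrixParseError(f"duplicate {what}: {sorted(set(dup))[:5]}")


@dataclass
class BetaMatrix:
    """CpG x sample matrix of methylation fractions (beta values) in [0, 1]."""

    values: pd.DataFrame  # float, index = CpG ids, columns = sample ids

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "feature ids")
        _check_unique(self.values.columns, "sample ids")
        v = self.values.to_numpy(dtype=float)
        finite = v[np.isfinite(v)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise MatrixParseError(
                "beta values outside [0, 1]: "
                f"min={finite.min():.6g}, max={finite.max():.6g}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class CountMatrix:
    """Gene/transcript x sample matrix of non-negative integer read counts."""

    values: pd.DataFrame  # int64, index = feature ids, columns = sample ids

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "feature ids")
        _check_unique(self.values.columns, "sample ids")
        v = self.values.to_numpy()
        if not np.issubdtype(v.dtype, np.integer):
            vf = v.astype(float)
            if not np.all(vf == np.round(vf)):
                bad = np.argwhere(vf != np.round(vf))[0]
                raise MatrixParseError(
                    f"non-integer count at feature "
                    f"{self.values.index[bad[0]]!r}, sample "
                    f"{self.values.columns[bad[1]]!r}"
                )
            self.values = self.values.astype(np.int64)
            v = self.values.to_numpy()
        if v.size and v.min() < 0:
            bad = np.argwhere(v < 0)[0]
            raise MatrixParseError(
                f"negative count at feature {self.values.index[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class SampleSheet:
    """Per-sample metadata: identity, arm, timepoint and covariates.

    ``data`` keeps one row per sample; any column beyond the required five is
    carried along as an extra covariate.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in REQUIRED_SHEET_COLUMNS:
            if col not in self.data.columns:
                raise SampleSheetError(f"missing required column {col!r}")
        if self.data["sample_id"].duplicated().any():
            dup = self.data.loc[self.data["sample_id"].duplicated(), "sample_id"]
            raise SampleSheetError(f"duplicate sample_id: {sorted(set(dup))}")
        st = self.data[["subject_id", "timepoint"]].astype(str)
        if st.duplicated().any():
            raise SampleSheetError("duplicate (subject_id, timepoint) pair")
        age = pd.to_numeric(self.data["age"], errors="coerce")
        if (age.dropna() <= 0).any():
            raise SampleSheetError("age must be > 0 where present")
        self.data = self.data.copy()
        self.data["age"] = age

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in REQUIRED_SHEET_COLUMNS]

    def indexed(self) -> pd.DataFrame:
        return self.data.set_index("sample_id")

    def aligned_to(self, sample_ids) -> pd.DataFrame:
        """Rows reindexed to ``sample_ids``; raises if any sample is absent."""
        idx = self.indexed()
        missing = [s for s in sample_ids if s not in idx.index]
        if missing:
            raise SampleSheetError(f"samples absent from sheet: {missing[:5]}")
        return idx.loc[list(sample_ids)]


@dataclass
class ReferenceProfiles:
    """Marker-CpG x cell-type matrix of expected beta fractions.

    Level 1 covers the major endometrial compartments (epithelial,
    fibroblast, immune); level 2 resolves immune subtypes.
    """

    level: Literal[1, 2]
    values: pd.DataFrame  # marker CpG ids x cell-type names

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "marker ids")
        if self.values.shape[1] < 2:
            raise MatrixParseError("reference needs at least 2 cell types")
        v = self.values.to_numpy(dtype=float)
        if v.min() < -1e-9 or v.max() > 1 + 1e-9:
            raise MatrixParseError("reference betas outside [0, 1]")

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class PipelineConfig:
    """Run configuration mirroring the YAML config file."""

    betas: str | None = None
    counts: str | None = None
    sheet: str | None = None
    ref_l1: str | None = None
    ref_l2: str | None = None
    gene_sets: str | None = None
    out_dir: str = "results"
    train_fraction: float = 0.7
    alphas: tuple[float, ...] = (0.0, 0.5, 1.0)
    feature_counts: tuple[int, ...] = (100, 500, 1000, 2000, 3000, 4000, 5000)
    min_count: int = 10
    min_fraction: float = 0.8
    strict_count_filter: bool = True
    fdr_threshold: float = 0.05
    de_p_threshold: float = 0.01
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")
        if self.min_count < 0 or self.fdr_threshold < 0 or self.de_p_threshold < 0:
            raise ValueError("thresholds must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extras"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        for key in ("alphas", "feature_counts"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        extras = {k: v for k, v in raw.items() if k not in known}
        return cls(**kwargs, extras=extras)


def read_matrix(path: str | Path, kind: Literal["beta", "count"]):
    """Parse a TSV matrix into a :class:`BetaMatrix` or :class:`CountMatrix`.

    Beta matrices may contain ``NA`` entries: CpGs missing in more than 20% of
    samples are dropped (logged), the remainder mean-imputed per CpG so index
    scoring always sees complete vectors.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if not header or header[0] != "feature_id":
        raise MatrixParseError(
            f"{path}: first header field must be 'feature_id', got {header[:1]}"
        )
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                     keep_default_na=False, float_precision="round_trip")
    df.index.name = None
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    if kind == "beta":
        df = df.apply(pd.to_numeric, errors="raise")
        arr = df.to_numpy(dtype=float)
        bad = np.argwhere((arr < -1e-9) | (arr > 1 + 1e-9))
        if len(bad):
            r, c = bad[0]
            raise MatrixParseError(
                f"{path}: beta value {arr[r, c]} outside [0,1] at row "
                f"{df.index[r]!r}, column {df.columns[c]!r}"
            )
        miss_frac = df.isna().mean(axis=1)
        drop = miss_frac > MISSING_DROP_FRACTION
        if drop.any():
            logger.info("dropping %d CpGs with >%.0f%% missing values",
                        int(drop.sum()), 100 * MISSING_DROP_FRACTION)
            df = df.loc[~drop]
        if df.isna().to_numpy().any():
            row_means = df.mean(axis=1)
            df = df.T.fillna(row_means).T
        return BetaMatrix(df)

    if kind == "count":
        if df.isna().to_numpy().any():
            r, c = np.argwhere(df.isna().to_numpy())[0]
            raise MatrixParseError(
                f"{path}: missing count at row {df.index[r]!r}, "
                f"column {df.columns[c]!r}"
            )
        arr = df.to_numpy(dtype=float)
        bad = np.argwhere(arr != np.round(arr))
        if len(bad):
            r, c = bad[0]
            raise MatrixParseError(
                f"{path}: non-integer count {arr[r, c]} at row "
                f"{df.index[r]!r}, column {df.columns[c]!r}"
            )
        return CountMatrix(df.astype(np.int64))

    raise ValueError(f"unknown matrix kind {kind!r}")


def write_matrix(matrix: BetaMatrix | CountMatrix, path: str | Path) -> None:
    """Write a matrix in the TSV dialect of :func:`read_matrix`.

    Floats are printed with :func:`repr` semantics (shortest round-tripping
    decimal), so ``read_matrix(write_matrix(m)) == m`` bit-exactly.
    """
    path = Path(path)
    df = matrix.values
    with open(path, "w") as fh:
        fh.write("feature_id\t" + "\t".join(map(str, df.columns)) + "\n")
        if isinstance(matrix, CountMatrix):
            for fid, row in zip(df.index, df.to_numpy()):
                fh.write(str(fid) + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
        else:
            for fid, row in zip(df.index, df.to_numpy(dtype=float)):
                fh.write(str(fid) + "\t"
                         + "\t".join("NA" if np.isnan(v) else repr(float(v))
                                     for v in row) + "\n")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a CSV sample sheet; 'NA' ages become missing, not errors."""
    df = pd.read_csv(path, dtype=str, na_values=["NA"], keep_default_na=False)
    missing = [c for c in REQUIRED_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise SampleSheetError(f"{path}: missing required columns {missing}")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.data.to_csv(path, index=False, na_rep="NA")


def validate_dataset(matrix, sheet: SampleSheet) -> dict:
    """Report sample ids present in exactly one of matrix / sheet.

    Report-only: pipeline stages that need alignment require both mismatch
    lists to be empty.  Order-insensitive.
    """
    m = set(matrix.sample_ids)
    s = set(sheet.sample_ids)
    return {
        "matrix_only": sorted(m - s),
        "sheet_only": sorted(s - m),
        "shared": sorted(m & s),
        "ok": m == s,
    }


def read_reference_profiles(path: str | Path, level: int) -> ReferenceProfiles:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ReferenceProfiles(level=level, values=df)


def write_reference_profiles(profiles: ReferenceProfiles, path: str | Path) -> None:
    out = profiles.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file: name, description, members."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise MatrixParseError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, _desc, *members = fields
            sets[name] = [m for m in members if m]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, ""] + list(members)) + "\n")


def configure_logging(verbose: bool = False) -> None:
    """Send all pipeline logging to stderr; results never go there."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.WARNING)
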