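"""Input tables, validation, run configuration, and the analysis-organized output tree.

The pipeline consumes two tables: an expression/abundance matrix (variables in
rows, samples in columns, first column variable IDs, header sample IDs) and a
per-sample metadata table with at least a sample-ID column and a group column.
Survival analysis additionally expects the columns ``age``, ``outcome.time``
and ``outcome`` (event indicator, 0 = censored, 1 = event).
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

DATATYPES = ("array", "seq", "ms", "other")

#: Missing-value tokens accepted in input matrices (covers R and Python exports).
MISSING_TOKENS = ("", "NA", "NaN", "nan")

#: Metadata column names auto-detected as the survival triplet.
SURVIVAL_COLS = ("age", "outcome.time", "outcome")


class ValidationError(ValueError):
    """Raised when an input table violates the pipeline's contracts."""


@dataclass
class ExpressionMatrix:
    """A variables x samples value grid with IDs and a data-type tag.

    ``values`` is a float array; missing entries are NaN (allowed only before
    imputation). For ``datatype == "seq"`` all non-missing values must be
    non-negative integers (raw counts) prior to normalization.
    """

    variable_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    datatype: str = "other"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.datatype not in DATATYPES:
            raise ValidationError(
                f"datatype must be one of {DATATYPES}, got {self.datatype!r}"
            )
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        if self.values.shape != (len(self.variable_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value grid {self.values.shape} does not match "
                f"{len(self.variable_ids)} variables x {len(self.sample_ids)} samples"
            )
        for name, ids in (("variable", self.variable_ids), ("sample", self.sample_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise ValidationError(f"duplicate {name} IDs: {sorted(dupes)}")
        if self.datatype == "seq":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (np.any(finite < 0) or np.any(finite != np.round(finite))):
                bad = np.argwhere(
                    np.isfinite(self.values)
                    & ((self.values < 0) | (self.values != np.round(self.values)))
                )[0]
                raise ValidationError(
                    "seq data must be non-negative integer counts; offending cell at "
                    f"variable {self.variable_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
                )

    @property
    def n_variables(self) -> int:
        return len(self.variable_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def copy_with(self, values: np.ndarray, datatype: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.variable_ids),
            list(self.sample_ids),
            np.array(values, dtype=float),
            datatype or self.datatype,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.variable_ids, columns=self.sample_ids)

    def subset_variables(self, keep: Iterable[str]) -> "ExpressionMatrix":
        keep = list(keep)
        idx = {v: i for i, v in enumerate(self.variable_ids)}
        rows = [idx[v] for v in keep]
        return ExpressionMatrix(keep, list(self.sample_ids), self.values[rows], self.datatype)


@dataclass
class SampleMetadata:
    """Per-sample group/batch/covariate table, optionally with survival columns.

    ``table`` is indexed by sample ID. The survival triplet (``age``,
    ``outcome.time``, ``outcome``) must be all present or all absent.
    """

    table: pd.DataFrame
    group_col: str
    batch_col: str | None = None
    covariate_cols: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.group_col not in self.table.columns:
            raise ValidationError(f"group column {self.group_col!r} not in metadata")
        if self.batch_col is not None and self.batch_col not in self.table.columns:
            raise ValidationError(f"batch column {self.batch_col!r} not in metadata")
        dupes = _duplicates(self.table.index)
        if dupes:
            raise ValidationError(f"duplicate sample IDs: {sorted(dupes)}")
        present = [c for c in SURVIVAL_COLS if c in self.table.columns]
        if present and len(present) != len(SURVIVAL_COLS):
            missing = sorted(set(SURVIVAL_COLS) - set(present))
            raise ValidationError(
                f"survival columns must be all present or all absent; missing {missing}"
            )
        if self.has_survival:
            outcome = self.table["outcome"].to_numpy()
            bad = set(np.unique(outcome[np.isfinite(outcome.astype(float))])) - {0.0, 1.0}
            if bad:
                raise ValidationError(
                    f"outcome (event indicator) must be 0 or 1; found {sorted(bad)}"
                )
            times = self.table["outcome.time"].astype(float)
            if (times <= 0).any():
                raise ValidationError("outcome.time must be positive follow-up times")
            if (self.table["age"].astype(float) < 0).any():
                raise ValidationError("age must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def groups(self) -> pd.Series:
        return self.table[self.group_col].astype(str)

    @property
    def has_survival(self) -> bool:
        return all(c in self.table.columns for c in SURVIVAL_COLS)

    def check_against(self, matrix: ExpressionMatrix) -> None:
        meta_ids, mat_ids = set(self.sample_ids), set(matrix.sample_ids)
        if meta_ids != mat_ids:
            diff = sorted(meta_ids.symmetric_difference(mat_ids))
            raise ValidationError(
                f"sample IDs differ between metadata and matrix; symmetric difference: {diff}"
            )

    def aligned_to(self, sample_ids: list[str]) -> "SampleMetadata":
        return SampleMetadata(
            self.table.loc[sample_ids].copy(), self.group_col, self.batch_col,
            list(self.covariate_cols),
        )


@dataclass
class RunConfig:
    """Pipeline run options; defaults mirror the published tool's behaviour."""

    datatype: str = "other"
    group_col: str = "group"
    batch_col: str | None = None
    covariate_cols: list[str] = field(default_factory=list)
    fdr: float = 0.05
    logfc: float = 1.0
    alpha: float = 0.5
    runs: int = 10
    kmeans: bool = False
    wgcna: str = "none"  # none | de | all
    survival: bool = False
    ppi_path: str | None = None
    mirna_path: str | None = None
    outdir: str = "markerpipe_out"
    seed: int = 1234
    overwrite: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.fdr < 1:
            raise ValidationError("fdr threshold must be in (0, 1)")
        if not 0 <= self.alpha <= 1:
            raise ValidationError("elastic-net alpha must be in [0, 1]")
        if self.runs < 1:
            raise ValidationError("repeat count must be >= 1")
        if self.wgcna not in ("none", "de", "all"):
            raise ValidationError("wgcna must be one of none|de|all")
        if self.datatype not in DATATYPES:
            raise ValidationError(f"datatype must be one of {DATATYPES}")


def _duplicates(ids: Iterable) -> set:
    seen, dup = set(), set()
    for i in ids:
        if i in seen:
            dup.add(i)
        seen.add(i)
    return dup


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_matrix(
    path: str | Path, datatype: str, transpose: bool = False
) -> ExpressionMatrix:
    """Read a variables x samples matrix from TSV/CSV.

    Delimiter is chosen by extension (``.csv`` comma, otherwise tab). Empty
    cells and the tokens NA/NaN/nan parse as missing. ``transpose`` accepts a
    samples x variables file instead.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str,
                      keep_default_na=False)
    if transpose:
        raw = raw.T
    var_ids = [str(v) for v in raw.index]
    sample_ids = [str(s) for s in raw.columns]
    values = np.empty(raw.shape, dtype=float)
    cells = raw.to_numpy()
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            tok = cells[i, j].strip() if isinstance(cells[i, j], str) else cells[i, j]
            if tok in MISSING_TOKENS:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(tok)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"non-numeric cell {tok!r} at variable {var_ids[i]!r}, "
                    f"sample {sample_ids[j]!r}"
                ) from None
    if datatype == "seq":
        bad = np.argwhere(np.isfinite(values) & ((values < 0) | (values != np.round(values))))
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"seq datatype requires non-negative integer counts; cell "
                f"{values[i, j]!r} at variable {var_ids[i]!r}, sample {sample_ids[j]!r}"
            )
    return ExpressionMatrix(var_ids, sample_ids, values, datatype)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    matrix.to_frame().to_csv(path, sep=_sep_for(path), index_label="id")


def read_metadata(
    path: str | Path,
    id_col: str,
    group_col: str,
    batch_col: str | None = None,
    covariate_cols: list[str] | None = None,
    matrix: ExpressionMatrix | None = None,
) -> SampleMetadata:
    """Read the per-sample metadata table and validate it against the matrix.

    Survival columns are auto-detected by the exact names ``age``,
    ``outcome.time``, ``outcome``; alternate names must be renamed upstream
    (CLI flags map them).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, sep=_sep_for(path))
    for col in [id_col, group_col] + ([batch_col] if batch_col else []) + (covariate_cols or []):
        if col not in table.columns:
            raise ValidationError(f"column {col!r} missing from metadata header "
                                  f"{list(table.columns)}")
    table = table.set_index(id_col)
    table.index = table.index.astype(str)
    meta = SampleMetadata(table, group_col, batch_col, covariate_cols or [])
    if matrix is not None:
        meta.check_against(matrix)
    return meta


def write_output_tree(
    results: Mapping[str, Mapping[str, pd.DataFrame | str]],
    outdir: str | Path,
    overwrite: bool = False,
) -> list[str]:
    """Write per-analysis result bundles into one subfolder per analysis.

    ``results`` maps analysis name (e.g. ``"dea"``) to a mapping of file name
    to DataFrame (written as TSV) or string (written verbatim). Returns the
    manifest: every path written, relative to ``outdir``. The manifest itself
    is stored as ``manifest.tsv``.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(
            f"output directory {outdir} is not empty; pass overwrite=True to replace it"
        )
    if outdir.exists() and overwrite:
        shutil.rmtree(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: list[str] = []
    for analysis, files in results.items():
        sub = outdir / analysis
        sub.mkdir(exist_ok=True)
        for fname, content in files.items():
            dest = sub / fname
            if isinstance(content, pd.DataFrame):
                content.to_csv(dest, sep="\t", index=False, lineterminator="\n")
            else:
                dest.write_text(str(content))
            manifest.append(f"{analysis}/{fname}")
    manifest.append("manifest.tsv")
    manifest = sorted(manifest)
    pd.DataFrame({"file": manifest}).to_csv(
        outdir / "manifest.tsv", sep="\t", index=False, lineterminator="\n"
    )
    return manifest
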