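"""Delimited-text readers and writers.

Beta matrices travel as CSV/TSV with CpG ids in the first column and sample
ids in the header; annotations as two-column (sample_id, cell_type) tables;
proportions as sample_id plus one column per cell type; libraries as one
CpG id per line. Writers prepend '#' metadata comment lines (tool version,
seed, timestamp) which readers skip; the timestamp can be suppressed for
byte-identical reruns.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import CellTypeAnnotation, MethylationMatrix, MixtureProportions
from .exceptions import ValidationError

__all__ = [
    "read_beta_matrix",
    "write_beta_matrix",
    "read_annotation",
    "write_annotation",
    "read_proportions",
    "write_proportions",
    "read_library",
    "write_library",
]

_FLOAT_FMT = "%.10g"


def _header(seed=None, no_timestamp: bool = False) -> str:
    parts = [f"# resetlib v{__version__}"]
    if seed is not None:
        parts.append(f"# seed: {seed}")
    if not no_timestamp:
        parts.append(f"# written: {datetime.datetime.now().isoformat(timespec='seconds')}")
    return "\n".join(parts) + "\n"


def _read_table(path, delimiter: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=delimiter, comment="#", index_col=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, OSError) as e:
        raise ValidationError(f"cannot parse {path}: {e}") from e
    return df


def read_beta_matrix(path, delimiter: str = ",", allow_any_real: bool = False) -> MethylationMatrix:
    """Read a CpG x sample matrix; values must be finite and, unless
    ``allow_any_real``, within [0, 1]."""
    df = _read_table(path, delimiter)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"{path}: duplicate CpG ids {dup}")
    if df.columns.has_duplicates:
        raise ValidationError(f"{path}: duplicate sample ids")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as e:
        bad = df.map(lambda x: not isinstance(x, (int, float, np.number)))
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at CpG {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        ) from e
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise ValidationError(
            f"{path}: missing value at CpG {df.index[r]!r}, sample {df.columns[c]!r} "
            "(no imputation is performed)"
        )
    if not allow_any_real:
        out = (values < 0) | (values > 1)
        if out.any():
            r, c = np.argwhere(out)[0]
            raise ValidationError(
                f"{path}: beta value {values[r, c]} outside [0, 1] at CpG "
                f"{df.index[r]!r}, sample {df.columns[c]!r}; pass allow_any_real "
                "to accept arbitrary reals"
            )
    return MethylationMatrix(df.index.to_numpy(object), df.columns.to_numpy(object), values)


def write_beta_matrix(
    m: MethylationMatrix, path, delimiter: str = ",", seed=None, no_timestamp: bool = False
) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed, no_timestamp))
        m.to_frame().to_csv(fh, sep=delimiter, float_format=_FLOAT_FMT, index_label="cpg_id")


def read_annotation(path, delimiter: str = ",") -> CellTypeAnnotation:
    """Read a two-column (sample_id, cell_type) table."""
    df = _read_table(path, delimiter)
    if df.shape[1] != 1:
        raise ValidationError(f"{path}: annotation must have exactly two columns (sample_id, cell_type)")
    labels = df.iloc[:, 0]
    if labels.isna().any():
        missing = df.index[labels.isna()].tolist()[:5]
        raise ValidationError(f"{path}: samples without a cell-type label: {missing}")
    return CellTypeAnnotation(df.index.to_numpy(object), labels.to_numpy(object))


def write_annotation(ann: CellTypeAnnotation, path, delimiter: str = ",", no_timestamp: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_header(no_timestamp=no_timestamp))
        pd.DataFrame({"cell_type": ann.labels}, index=pd.Index(ann.sample_ids, name="sample_id")).to_csv(
            fh, sep=delimiter
        )


def read_proportions(path, delimiter: str = ",") -> MixtureProportions:
    """Read a sample x cell-type fraction table and enforce the simplex-with-slack invariants."""
    df = _read_table(path, delimiter)
    try:
        w = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as e:
        raise ValidationError(f"{path}: non-numeric cell proportion") from e
    if np.isnan(w).any():
        raise ValidationError(f"{path}: missing cell proportion")
    if np.any(w < -1e-6) or np.any(w > 1 + 1e-6):
        raise ValidationError(f"{path}: cell proportions outside [0, 1]")
    sums = w.sum(axis=1)
    if np.any(sums > 1 + 1e-6):
        bad = df.index[sums > 1 + 1e-6].tolist()[:5]
        raise ValidationError(f"{path}: proportions sum to more than 1 for samples {bad}")
    return MixtureProportions(df.index.to_numpy(object), list(df.columns), np.clip(w, 0.0, 1.0))


def write_proportions(
    w: MixtureProportions, path, delimiter: str = ",", seed=None, no_timestamp: bool = False
) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed, no_timestamp))
        w.to_frame().to_csv(fh, sep=delimiter, float_format=_FLOAT_FMT, index_label="sample_id")


def read_library(path) -> list:
    """Read one CpG id per line; blank lines and '#' comments are ignored."""
    ids = []
    seen = set()
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line in seen:
            raise ValidationError(f"{path}: duplicate CpG id {line!r}")
        seen.add(line)
        ids.append(line)
    if not ids:
        raise ValidationError(f"{path}: empty library file")
    return ids


def write_library(cpg_ids, path, seed=None, no_timestamp: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed, no_timestamp))
        for c in cpg_ids:
            fh.write(f"{c}\n")
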