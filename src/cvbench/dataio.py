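"""Reading, writing, and merging of tabular sample-by-feature datasets.

Supported dialects: tab-separated (``.tsv``), comma-separated (``.csv``),
their transposed variants (``.ttsv``/``.tcsv``, features as rows), and the
attribute-relation file format (``.arff``).  Any of these may carry an
additional ``.gz`` suffix, in which case the file is gzip-compressed.

Delimited files must have a header row and a row-name column.  The class
column is located by name (``Class``, case-insensitive, by default); in ARFF
files the attribute named ``class`` — or, failing that, the last attribute —
carries the labels, following the format's convention.

Missing values: the tokens ``?``, ``NA``, and the empty string all map to a
single internal missing marker (``NaN``) on read.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "MISSING",
    "MISSING_TOKENS",
    "read_dataset",
    "write_dataset",
    "merge_datasets",
    "FormatError",
    "IntegrityError",
    "SchemaError",
    "ParseError",
    "MergeError",
]

#: Canonical internal missing marker.  Stored as NaN so that numeric columns
#: stay float-typed and ``pandas.isna`` identifies missing cells uniformly.
MISSING = float("nan")

#: Input tokens that map to :data:`MISSING` on read.
MISSING_TOKENS = frozenset({"?", "NA", ""})

NUMERIC = "numeric"
CATEGORICAL = "categorical"

_DELIMITED_EXTENSIONS = {".tsv": "\t", ".csv": ",", ".ttsv": "\t", ".tcsv": ","}
_SUPPORTED_EXTENSIONS = set(_DELIMITED_EXTENSIONS) | {".arff"}


class FormatError(ValueError):
    """Unrecognized file extension or malformed dialect."""


class IntegrityError(ValueError):
    """Duplicate identifiers, colliding features, or conflicting labels."""


class SchemaError(ValueError):
    """No identifiable class column."""


class ParseError(ValueError):
    """Structurally broken file content (e.g. ragged rows)."""


class MergeError(ValueError):
    """No overlapping sample identifiers between input files."""


def is_missing(value) -> bool:
    """True if *value* is the internal missing marker."""
    return pd.isna(value)


@dataclass
class Dataset:
    """A samples x features table with one categorical class label per sample.

    Attributes
    ----------
    X : pandas.DataFrame
        Feature values indexed by sample identifier.  Numeric feature columns
        hold floats, categorical columns hold strings; missing cells are NaN
        in either case.
    feature_kinds : dict[str, str]
        Maps each feature name to ``"numeric"`` or ``"categorical"``.
    y : pandas.Series
        Class label per sample, aligned with ``X.index``.  Never missing.
    """

    X: pd.DataFrame
    feature_kinds: dict[str, str]
    y: pd.Series
    name: str = field(default="dataset")

    def __post_init__(self) -> None:
        if self.X.index.has_duplicates:
            dupes = self.X.index[self.X.index.duplicated()].unique().tolist()
            raise IntegrityError(f"duplicate sample identifiers: {dupes}")
        if self.X.columns.has_duplicates:
            dupes = self.X.columns[self.X.columns.duplicated()].unique().tolist()
            raise IntegrityError(f"duplicate feature names: {dupes}")
        if set(self.feature_kinds) != set(self.X.columns):
            raise IntegrityError("feature_kinds do not match feature names")
        bad = set(self.feature_kinds.values()) - {NUMERIC, CATEGORICAL}
        if bad:
            raise IntegrityError(f"unknown feature kinds: {bad}")
        if not self.X.index.equals(self.y.index):
            raise IntegrityError("class labels are not aligned with samples")
        if self.y.isna().any():
            raise IntegrityError("class labels must never be missing")
        # note: a full dataset must carry >= 2 class levels (checked at the
        # read/generate boundary), but a cross-validation partition may
        # legitimately degenerate to one level and still be a Dataset.

    @property
    def sample_ids(self) -> list[str]:
        return list(self.X.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    @property
    def n_samples(self) -> int:
        return len(self.X)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def class_levels(self) -> list[str]:
        return sorted(self.y.unique())

    def subset(self, sample_ids: Sequence[str], features: Sequence[str] | None = None) -> "Dataset":
        """Row (and optionally column) subset preserving the given order."""
        features = list(features) if features is not None else self.feature_names
        return Dataset(
            X=self.X.loc[list(sample_ids), features],
            feature_kinds={f: self.feature_kinds[f] for f in features},
            y=self.y.loc[list(sample_ids)],
            name=self.name,
        )

    def equals(self, other: "Dataset") -> bool:
        """Field-by-field equality (numeric cells compared with NaN == NaN)."""
        if self.feature_kinds != other.feature_kinds:
            return False
        if self.sample_ids != other.sample_ids or self.feature_names != other.feature_names:
            return False
        if not self.y.astype(str).equals(other.y.astype(str)):
            return False
        for col in self.X.columns:
            a, b = self.X[col], other.X[col]
            if self.feature_kinds[col] == NUMERIC:
                if not np.allclose(
                    a.astype(float), b.astype(float), rtol=1e-12, atol=0, equal_nan=True
                ):
                    return False
            else:
                if not (a.isna() == b.isna()).all():
                    return False
                mask = ~a.isna()
                if not (a[mask].astype(str) == b[mask].astype(str)).all():
                    return False
        return True


def _split_extension(path: Path) -> tuple[str, bool]:
    """Return (dialect extension, gzipped?) after stripping an optional .gz."""
    name = path.name.lower()
    gz = name.endswith(".gz")
    if gz:
        name = name[: -len(".gz")]
    for ext in _SUPPORTED_EXTENSIONS:
        if name.endswith(ext):
            return ext, gz
    raise FormatError(
        f"unsupported file extension on {path.name!r}; expected one of "
        f"{sorted(e.lstrip('.') for e in _SUPPORTED_EXTENSIONS)} (optionally .gz)"
    )


def _open_text(path: Path, gz: bool, mode: str = "rt") -> io.TextIOBase:
    if gz:
        return gzip.open(path, mode, encoding="utf-8")
    return open(path, mode, encoding="utf-8")


def _mask_missing(frame: pd.DataFrame) -> pd.DataFrame:
    return frame.map(lambda v: MISSING if (pd.isna(v) or v in MISSING_TOKENS) else v)


def _infer_kind(column: pd.Series) -> str:
    """Numeric iff every non-missing cell parses as a number."""
    values = column.dropna()
    if values.empty:
        return NUMERIC
    try:
        values.astype(float)
        return NUMERIC
    except (TypeError, ValueError):
        return CATEGORICAL


def _find_class_column(columns: Iterable[str], class_column: str | None) -> str:
    if class_column is not None:
        for col in columns:
            if col == class_column:
                return col
        raise SchemaError(f"class column {class_column!r} not found")
    matches = [c for c in columns if c.lower() == "class"]
    if not matches:
        raise SchemaError(
            "no class column found: expected a column named 'Class' "
            "(case-insensitive) or an explicit class_column argument"
        )
    return matches[0]


def _frame_to_dataset(
    frame: pd.DataFrame,
    class_column: str | None,
    name: str,
    kinds: dict[str, str] | None = None,
) -> Dataset:
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if frame.index.has_duplicates:
        raise IntegrityError("duplicate sample identifiers in file")
    if frame.columns.has_duplicates:
        raise IntegrityError("duplicate feature names in file")
    label_col = _find_class_column(frame.columns, class_column)
    y = frame[label_col]
    if y.isna().any():
        raise IntegrityError("missing class labels")
    y = y.astype(str)
    if y.nunique() < 2:
        raise IntegrityError(f"need at least 2 class levels, found {y.nunique()}")
    X = frame.drop(columns=[label_col])
    if kinds is None:
        kinds = {col: _infer_kind(X[col]) for col in X.columns}
    else:
        kinds = {c: kinds[c] for c in X.columns}
    for col, kind in kinds.items():
        if kind == NUMERIC:
            try:
                X[col] = X[col].astype(float)
            except (TypeError, ValueError) as exc:
                raise ParseError(f"non-numeric value in numeric column {col!r}: {exc}")
        else:
            X[col] = X[col].map(lambda v: v if pd.isna(v) else str(v))
    return Dataset(X=X, feature_kinds=kinds, y=y, name=name)


def _read_delimited(path: Path, ext: str, gz: bool, class_column: str | None) -> Dataset:
    sep = _DELIMITED_EXTENSIONS[ext]
    with _open_text(path, gz) as handle:
        frame = pd.read_csv(
            handle, sep=sep, index_col=0, dtype=str, keep_default_na=False
        )
    # keep_default_na=False means no token parses to NaN, so any NaN present
    # can only come from pandas padding short rows -> structurally ragged.
    if frame.isna().any().any():
        raise ParseError(f"ragged rows in {path.name}")
    if ext in (".ttsv", ".tcsv"):
        frame = frame.transpose()
    frame = _mask_missing(frame)
    return _frame_to_dataset(frame, class_column, name=path.name)


# --- ARFF ------------------------------------------------------------------
# Minimal attribute-relation format support: numeric/real/integer and
# nominal {a,b,c} attribute types, quoted tokens, '?' missing, '%' comments.
# A string attribute named 'id' carries sample identifiers when present.

_ARFF_ATTR_RE = re.compile(r"@attribute\s+(?P<name>'[^']*'|\"[^\"]*\"|\S+)\s+(?P<type>.+)", re.I)


def _unquote(token: str) -> str:
    token = token.strip()
    if len(token) >= 2 and token[0] == token[-1] and token[0] in "'\"":
        return token[1:-1]
    return token


def _split_arff_row(line: str) -> list[str]:
    tokens, current, quote = [], [], None
    for ch in line:
        if quote:
            if ch == quote:
                quote = None
            else:
                current.append(ch)
        elif ch in "'\"":
            quote = ch
        elif ch == ",":
            tokens.append("".join(current).strip())
            current = []
        else:
            current.append(ch)
    tokens.append("".join(current).strip())
    return tokens


def _read_arff(path: Path, gz: bool, class_column: str | None) -> Dataset:
    attrs: list[tuple[str, str, list[str] | None]] = []  # (name, kind, levels)
    rows: list[list[str]] = []
    in_data = False
    with _open_text(path, gz) as handle:
        for raw in handle:
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            low = line.lower()
            if in_data:
                values = _split_arff_row(line)
                if len(values) != len(attrs):
                    raise ParseError(
                        f"ragged @data row in {path.name}: expected "
                        f"{len(attrs)} values, got {len(values)}"
                    )
                rows.append(values)
            elif low.startswith("@relation"):
                continue
            elif low.startswith("@attribute"):
                match = _ARFF_ATTR_RE.match(line)
                if not match:
                    raise ParseError(f"malformed @attribute line: {line!r}")
                attr_name = _unquote(match.group("name"))
                type_spec = match.group("type").strip()
                if type_spec.startswith("{"):
                    levels = [_unquote(t) for t in _split_arff_row(type_spec.strip("{} "))]
                    attrs.append((attr_name, CATEGORICAL, levels))
                elif type_spec.lower() in ("numeric", "real", "integer"):
                    attrs.append((attr_name, NUMERIC, None))
                elif type_spec.lower() == "string":
                    attrs.append((attr_name, "string", None))
                else:
                    raise FormatError(f"unsupported attribute type {type_spec!r}")
            elif low.startswith("@data"):
                in_data = True
            else:
                raise ParseError(f"unrecognized ARFF header line: {line!r}")
    if not in_data:
        raise ParseError(f"no @data section in {path.name}")
    names = [a[0] for a in attrs]
    frame = pd.DataFrame(rows, columns=names, dtype=object)
    frame = _mask_missing(frame)

    id_attrs = [a for a in attrs if a[1] == "string" and a[0].lower() == "id"]
    if id_attrs:
        index = frame[id_attrs[0][0]].astype(str)
        frame = frame.drop(columns=[id_attrs[0][0]])
        frame.index = index
    else:
        frame.index = pd.Index([f"sample_{i + 1}" for i in range(len(frame))])
    kinds = {a[0]: a[1] for a in attrs if a[1] != "string"}

    if class_column is None:
        nominal = [a[0] for a in attrs if a[1] == CATEGORICAL]
        named = [c for c in kinds if c.lower() == "class"]
        if named:
            class_column = named[0]
        elif nominal:
            class_column = [a[0] for a in attrs if a[1] != "string"][-1]
        else:
            raise SchemaError("no class attribute identifiable in ARFF file")
    kinds.pop(class_column, None)
    return _frame_to_dataset(frame, class_column, name=path.name, kinds=kinds)


def read_dataset(path: str | Path, class_column: str | None = None) -> Dataset:
    """Read one file in any supported dialect into a :class:`Dataset`.

    Parameters
    ----------
    path : str or Path
        File ending in ``.tsv``, ``.csv``, ``.ttsv``, ``.tcsv``, or ``.arff``,
        optionally followed by ``.gz``.
    class_column : str, optional
        Name of the column/attribute holding class labels.  Defaults to a
        column named ``Class`` (case-insensitive); ARFF files fall back to
        their last attribute.
    """
    path = Path(path)
    ext, gz = _split_extension(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if ext == ".arff":
        return _read_arff(path, gz, class_column)
    return _read_delimited(path, ext, gz, class_column)


def _format_cell(value, kind: str, missing_token: str) -> str:
    if pd.isna(value):
        return missing_token
    if kind == NUMERIC:
        as_float = float(value)
        if as_float == int(as_float) and abs(as_float) < 1e15:
            return str(int(as_float))
        return repr(as_float)
    return str(value)


def _needs_quote(token: str) -> bool:
    return any(c in token for c in ", '\"{}%") or token == ""


def _arff_quote(token: str) -> str:
    return f"'{token}'" if _needs_quote(token) else token


def _write_arff(d: Dataset, path: Path, gz: bool, class_column: str) -> None:
    lines = [f"@relation {_arff_quote(d.name or 'dataset')}", "", "@attribute id string"]
    for feat in d.feature_names:
        if d.feature_kinds[feat] == NUMERIC:
            lines.append(f"@attribute {_arff_quote(feat)} numeric")
        else:
            levels = sorted({str(v) for v in d.X[feat].dropna().unique()})
            spec = ",".join(_arff_quote(l) for l in levels)
            lines.append(f"@attribute {_arff_quote(feat)} {{{spec}}}")
    class_levels = ",".join(_arff_quote(l) for l in d.class_levels)
    lines.append(f"@attribute {_arff_quote(class_column)} {{{class_levels}}}")
    lines.append("")
    lines.append("@data")
    for sid in d.sample_ids:
        cells = [_arff_quote(str(sid))]
        for feat in d.feature_names:
            cells.append(
                _arff_quote(_format_cell(d.X.at[sid, feat], d.feature_kinds[feat], "?"))
            )
        cells.append(_arff_quote(str(d.y.at[sid])))
        lines.append(",".join(cells))
    with _open_text(path, gz, "wt") as handle:
        handle.write("\n".join(lines) + "\n")


def write_dataset(d: Dataset, path: str | Path, class_column: str = "Class") -> None:
    """Write *d* to *path* in the dialect implied by the file extension.

    Round-trip guarantee: ``read_dataset`` on the written file reproduces the
    dataset field-by-field, up to numeric-text formatting (and, for delimited
    dialects, up to re-inference of feature kinds from cell contents).
    """
    path = Path(path)
    ext, gz = _split_extension(path)
    if ext == ".arff":
        _write_arff(d, path, gz, class_column)
        return
    sep = _DELIMITED_EXTENSIONS[ext]
    table = pd.DataFrame(index=d.X.index)
    for feat in d.feature_names:
        kind = d.feature_kinds[feat]
        table[feat] = d.X[feat].map(lambda v, k=kind: _format_cell(v, k, "NA"))
    table[class_column] = d.y.astype(str)
    if ext in (".ttsv", ".tcsv"):
        table = table.transpose()
    table.index.name = "id"
    with _open_text(path, gz, "wt") as handle:
        table.to_csv(handle, sep=sep, lineterminator="\n")


def merge_datasets(parts: Sequence[Dataset]) -> Dataset:
    """Merge datasets on their overlapping sample identifiers.

    Sample order follows the first part; features are concatenated in part
    order and must be disjoint across parts.  Labels must agree wherever two
    parts both carry them for a shared sample.
    """
    if not parts:
        raise MergeError("need at least one dataset to merge")
    if len(parts) == 1:
        return parts[0]
    shared = [s for s in parts[0].sample_ids if all(s in set(p.sample_ids) for p in parts[1:])]
    if not shared:
        raise MergeError("no sample identifiers shared by all input files")
    seen: set[str] = set()
    for part in parts:
        collision = seen & set(part.feature_names)
        if collision:
            raise IntegrityError(f"feature names collide across files: {sorted(collision)}")
        seen |= set(part.feature_names)
    reference = parts[0].y.loc[shared].astype(str)
    for part in parts[1:]:
        other = part.y.loc[shared].astype(str)
        disagree = reference[reference != other]
        if len(disagree):
            raise IntegrityError(
                f"class labels disagree for shared samples: {list(disagree.index[:5])}"
            )
    X = pd.concat([p.X.loc[shared] for p in parts], axis=1)
    kinds: dict[str, str] = {}
    for part in parts:
        kinds.update(part.feature_kinds)
    return Dataset(X=X, feature_kinds=kinds, y=reference, name=parts[0].name)
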