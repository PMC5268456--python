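"""Plain-text I/O for expression matrices, sample metadata, gene tables,
GMT gene sets, and two-column mapping/score/phenotype tables.

All files are TSV with ``.`` as the decimal separator and no thousands
separators; identifiers are compared case-sensitively (gene symbol case
carries species information, e.g. rat ``Psma4`` vs human ``PSMA4``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "GeneTable",
    "GeneSet",
    "GeneSetCollection",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_gene_table",
    "write_gene_table",
    "read_gene_sets",
    "write_gene_sets",
    "read_two_column_table",
    "write_two_column_table",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _first_duplicate(values: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for v in values:
        if v in seen:
            return v
        seen.add(v)
    return None


class ExpressionMatrix:
    """A gene-by-sample matrix of non-negative, finite expression values
    (FPKM-like units).

    Rows are addressed by unique gene (or transcript) identifiers, columns
    by unique sample identifiers; construction validates all invariants.
    """

    def __init__(self, data: pd.DataFrame):
        index = pd.Index([str(g) for g in data.index], name="gene_id")
        columns = pd.Index([str(s) for s in data.columns])
        dup = _first_duplicate(index)
        if dup is not None:
            raise FormatError(f"duplicate gene identifier: {dup!r}")
        dup = _first_duplicate(columns)
        if dup is not None:
            raise FormatError(f"duplicate sample identifier: {dup!r}")
        values = np.asarray(data.to_numpy(), dtype=float)
        if values.ndim != 2:
            raise FormatError("expression data must be two-dimensional")
        bad = ~np.isfinite(values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"non-finite value at gene {index[i]!r}, sample {columns[j]!r}"
            )
        neg = values < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise FormatError(
                f"negative value {values[i, j]} at gene {index[i]!r}, "
                f"sample {columns[j]!r}"
            )
        self._data = pd.DataFrame(values, index=index, columns=columns)

    # -- accessors ---------------------------------------------------------

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def gene_ids(self) -> list[str]:
        return list(self._data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._data.columns)

    @property
    def values(self) -> np.ndarray:
        return self._data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self._data.shape[0]

    @property
    def n_samples(self) -> int:
        return self._data.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    def row(self, gene_id: str) -> np.ndarray:
        return self._data.loc[gene_id].to_numpy()

    def select_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        """Row subset, in the order given."""
        return ExpressionMatrix(self._data.loc[list(gene_ids)])

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        """Same labels, new values (shape must match)."""
        if values.shape != self._data.shape:
            raise ValueError("replacement values have wrong shape")
        return ExpressionMatrix(
            pd.DataFrame(values, index=self._data.index, columns=self._data.columns)
        )

    def relabel_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        new = self._data.copy()
        new.index = pd.Index([str(g) for g in gene_ids], name="gene_id")
        return ExpressionMatrix(new)

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self._data.equals(other._data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples)"


@dataclass(frozen=True)
class GeneTable:
    """Transcript-to-gene annotation; an empty-string gene_id encodes a
    transcript with no gene annotation (no Entrez ID)."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "mapping", dict(self.mapping))

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.mapping

    def gene_id(self, transcript_id: str) -> str:
        try:
            return self.mapping[transcript_id]
        except KeyError:
            raise KeyError(f"transcript {transcript_id!r} not in gene table") from None

    def is_annotated(self, transcript_id: str) -> bool:
        return self.gene_id(transcript_id) != ""

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"gene set {self.name!r} is empty")
        dup = _first_duplicate(self.members)
        if dup is not None:
            raise FormatError(f"gene set {self.name!r} repeats member {dup!r}")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    """Named gene sets (as read from a GMT file)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self.sets:
            raise FormatError(f"duplicate gene set name: {gene_set.name!r}")
        self.sets[gene_set.name] = gene_set

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    @property
    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# expression matrix


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes-x-samples TSV (first column gene IDs, header row sample
    IDs) into an :class:`ExpressionMatrix`.

    Duplicate identifiers and negative or non-numeric cells are hard errors
    that name the offending identifier or coordinate.
    """
    # pandas de-duplicates repeated header names on read; check the raw header
    with open(path, "r", encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
    dup = _first_duplicate(header[1:])
    if dup is not None:
        raise FormatError(f"{path}: duplicate sample identifier: {dup!r}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    dup = _first_duplicate(raw.index)
    if dup is not None:
        raise FormatError(f"{path}: duplicate gene identifier: {dup!r}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {raw.iat[i, j]!r} at gene "
            f"{raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    try:
        return ExpressionMatrix(numeric)
    except FormatError as err:
        raise FormatError(f"{path}: {err}") from None


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# sample metadata

_METADATA_COLUMNS = ("sample_id", "organ", "age", "sex", "replicate")


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample design sheet (sample_id, organ, age, sex, replicate).

    ``sample_id`` must be unique and the (organ, age, sex, replicate)
    combination must be jointly unique.
    """
    meta = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata column(s): {missing}")
    meta = meta[list(_METADATA_COLUMNS)]
    meta["replicate"] = pd.to_numeric(meta["replicate"], errors="raise").astype(int)
    if (meta["replicate"] <= 0).any():
        raise FormatError(f"{path}: replicate numbers must be positive")
    dup = _first_duplicate(meta["sample_id"])
    if dup is not None:
        raise FormatError(f"{path}: duplicate sample_id: {dup!r}")
    design = list(zip(meta["organ"], meta["age"], meta["sex"], meta["replicate"]))
    if len(set(design)) != len(design):
        raise FormatError(f"{path}: (organ, age, sex, replicate) not jointly unique")
    return meta


def write_sample_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta[list(_METADATA_COLUMNS)].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene annotation table


def read_gene_table(path: str | Path) -> GeneTable:
    """Read a transcript_id / gene_id TSV; empty gene_id means unannotated."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("transcript_id", "gene_id"):
        if col not in table.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    dup = _first_duplicate(table["transcript_id"])
    if dup is not None:
        raise FormatError(f"{path}: duplicate transcript_id: {dup!r}")
    return GeneTable(dict(zip(table["transcript_id"], table["gene_id"])))


def write_gene_table(genes: GeneTable, path: str | Path) -> None:
    pd.DataFrame(
        {"transcript_id": list(genes.mapping), "gene_id": list(genes.mapping.values())}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name TAB description TAB member TAB member ...).

    Duplicate members within a line are collapsed with a warning; a line
    with fewer than three fields is a hard error naming the line number.
    """
    collection = GeneSetCollection()
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected name, description and at "
                    f"least one member, got {len(fields)} field(s)"
                )
            name, description = fields[0], fields[1]
            members: list[str] = []
            seen: set[str] = set()
            for member in fields[2:]:
                if not member:
                    continue
                if member in seen:
                    warnings.warn(
                        f"{path}: line {lineno}: set {name!r} lists member "
                        f"{member!r} more than once; collapsed",
                        stacklevel=2,
                    )
                    continue
                seen.add(member)
                members.append(member)
            if not members:
                raise FormatError(f"{path}: line {lineno}: set {name!r} has no members")
            collection.add(GeneSet(name, description, tuple(members)))
    return collection


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for gene_set in collection:
            handle.write(
                "\t".join((gene_set.name, gene_set.description, *gene_set.members))
                + "\n"
            )


# ---------------------------------------------------------------------------
# two-column tables (homolog maps, lethality flags, scalar gene scores)

_BOOLEAN_TOKENS = {
    "true": True, "false": False,
    "1": True, "0": False,
    "yes": True, "no": False,
}


def _parse_value(token: str, value_kind: str, where: str):
    if value_kind == "identifier":
        return token
    if value_kind == "numeric":
        try:
            value = float(token)
        except ValueError:
            raise FormatError(f"{where}: cannot parse {token!r} as numeric") from None
        if not math.isfinite(value):
            raise FormatError(f"{where}: non-finite numeric value {token!r}")
        return value
    if value_kind == "boolean":
        try:
            return _BOOLEAN_TOKENS[token.strip().lower()]
        except KeyError:
            raise FormatError(f"{where}: cannot parse {token!r} as boolean") from None
    raise ValueError(f"unknown value_kind {value_kind!r}")


def read_two_column_table(
    path: str | Path, value_kind: str = "identifier", header: bool = True
) -> dict:
    """Read a key/value TSV into a dict.

    ``value_kind`` is one of ``identifier``, ``numeric`` or ``boolean``.
    Exact duplicate (key, value) rows are collapsed; a key that reappears
    with a different value is a hard error naming the line.
    """
    result: dict = {}
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(fields)}"
                )
            key = fields[0]
            value = _parse_value(fields[1], value_kind, f"{path}: line {lineno}")
            if key in result and result[key] != value:
                raise FormatError(
                    f"{path}: line {lineno}: key {key!r} repeated with "
                    f"conflicting values ({result[key]!r} vs {value!r})"
                )
            result[key] = value
    return result


def write_two_column_table(
    table: Mapping, path: str | Path, columns: tuple[str, str] = ("key", "value")
) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join(columns) + "\n")
        for key, value in table.items():
            if isinstance(value, bool):
                value = "true" if value else "false"
            handle.write(f"{key}\t{value}\n")
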