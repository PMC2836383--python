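"""Readers and writers for the tab-separated formats used across the pipeline.

Supported dialects
------------------
* expression matrices: plain TSV (header row of sample ids, one row per gene)
  and GCT v1.2 (two header lines plus a ``Description`` column);
* gene-set collections: GMT, one set per line
  (``name <TAB> description <TAB> gene1 <TAB> gene2 ...``);
* binary class labels: CLS (``N 2 1`` / ``# nameA nameB`` / token row) or a
  two-column TSV of ``sample_id <TAB> label``;
* generic result tables: TSV with a header row, floats at >= 6 significant
  digits.

Parsers reject malformed input with :class:`FormatError`; they never repair
it silently.  Expression values are taken as-is — the pipeline assumes a
processed (log-scale, normalised) matrix and performs no background
correction or re-normalisation.  Empty expression cells become NaN and are
treated downstream as "not measured".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ExpressionDataset",
    "Pathway",
    "PathwayCollection",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_cls",
    "write_cls",
    "read_labels_tsv",
    "write_table",
    "read_table",
    "collapse_duplicate_genes",
]


class FormatError(ValueError):
    """Malformed input file (wrong shape, duplicate ids, bad tokens...)."""


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionDataset:
    """A genes x samples expression matrix with optional binary class labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.  NaN
        entries mean "not measured" for that gene in that sample.
    labels
        Optional mapping ``sample_id -> class label``.  Scoring operations
        require exactly two distinct labels covering every sample.
    """

    values: pd.DataFrame
    labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate gene id: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        if self.labels is not None:
            missing = [s for s in cols if s not in self.labels]
            if missing:
                raise FormatError(f"samples without a class label: {missing}")
            self.labels = {s: self.labels[s] for s in cols}

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def classes(self) -> tuple[str, str]:
        """The two class labels, in first-appearance order over samples.

        Raises
        ------
        FormatError
            if labels are absent or the number of distinct labels is not 2.
        """
        if self.labels is None:
            raise FormatError("dataset has no class labels")
        seen: list[str] = []
        for s in self.sample_ids:
            lab = self.labels[s]
            if lab not in seen:
                seen.append(lab)
        if len(seen) != 2:
            raise FormatError(
                f"scoring requires exactly 2 classes, found {len(seen)}: {seen}"
            )
        return seen[0], seen[1]

    def with_labels(self, labels: Mapping[str, str]) -> "ExpressionDataset":
        return ExpressionDataset(self.values, dict(labels))


@dataclass(frozen=True)
class Pathway:
    name: str
    description: str
    genes: frozenset[str]


@dataclass
class PathwayCollection:
    """An ordered collection of named gene sets (GMT content)."""

    entries: list[Pathway] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.entries:
            if p.name in seen:
                raise FormatError(f"duplicate pathway name: {p.name!r}")
            if not p.genes:
                raise FormatError(f"pathway {p.name!r} has an empty gene set")
            seen.add(p.name)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, name: str) -> Pathway:
        for p in self.entries:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.entries]

    def subset(self, names: Sequence[str]) -> "PathwayCollection":
        known = set(self.names)
        unknown = [n for n in names if n not in known]
        if unknown:
            raise KeyError(f"unknown pathway name(s): {unknown}")
        wanted = set(names)
        return PathwayCollection([p for p in self.entries if p.name in wanted])


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


def _parse_float(token: str, path: Path, lineno: int) -> float:
    token = token.strip()
    if token == "" or token.upper() in {"NA", "NAN", "NULL"}:
        return math.nan
    try:
        return float(token)
    except ValueError:
        raise FormatError(
            f"{path}:{lineno}: cannot parse expression value {token!r}"
        ) from None


def read_expression(
    path: str | Path, dialect: Literal["tsv", "gct"] = "tsv"
) -> ExpressionDataset:
    """Read a genes x samples expression matrix (no labels attached).

    ``tsv``: first line is the sample-id header (an optional leading cell for
    the gene-id column is tolerated), then one row per gene.
    ``gct``: GCT v1.2 — ``#1.2`` line, a ``<n_genes> <n_samples>`` line, a
    header with ``Name``/``Description`` columns, then data rows whose second
    column (Description) is discarded.  Declared dimensions are enforced.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if dialect == "gct":
        if len(lines) < 3:
            raise FormatError(f"{path}: truncated GCT file")
        if not lines[0].startswith("#1."):
            raise FormatError(f"{path}:1: missing GCT version line '#1.2'")
        dims = lines[1].split()
        if len(dims) < 2:
            raise FormatError(f"{path}:2: expected '<n_genes> <n_samples>'")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        header = lines[2].split("\t")
        sample_ids = header[2:]
        if len(sample_ids) != n_samples:
            raise FormatError(
                f"{path}:3: header has {len(sample_ids)} samples, "
                f"line 2 declares {n_samples}"
            )
        data_lines = [ln for ln in lines[3:] if ln.strip() != ""]
        if len(data_lines) != n_genes:
            raise FormatError(
                f"{path}: {len(data_lines)} data rows but line 2 declares {n_genes}"
            )
        first_data = 4
        value_offset = 2
    else:
        if not lines:
            raise FormatError(f"{path}: empty file")
        header = lines[0].split("\t")
        # leading cell may label the gene-id column; detect by row width below
        data_lines = [ln for ln in lines[1:] if ln.strip() != ""]
        if not data_lines:
            raise FormatError(f"{path}: no data rows")
        width = len(data_lines[0].split("\t"))
        if width == len(header) + 1:
            sample_ids = header
        elif width == len(header):
            sample_ids = header[1:]
        else:
            raise FormatError(
                f"{path}:2: row has {width} fields, header has {len(header)}"
            )
        first_data = 2
        value_offset = 1

    gene_ids: list[str] = []
    rows: list[list[float]] = []
    expected = value_offset + len(sample_ids)
    for i, ln in enumerate(data_lines):
        lineno = first_data + i
        fields = ln.split("\t")
        if len(fields) != expected:
            raise FormatError(
                f"{path}:{lineno}: ragged row ({len(fields)} fields, "
                f"expected {expected})"
            )
        gene_ids.append(fields[0])
        rows.append([_parse_float(t, path, lineno) for t in fields[value_offset:]])

    values = pd.DataFrame(
        np.asarray(rows, dtype=float), index=gene_ids, columns=sample_ids
    )
    return ExpressionDataset(values)


def write_expression(
    dataset: ExpressionDataset,
    path: str | Path,
    dialect: Literal["tsv", "gct"] = "tsv",
) -> None:
    """Write an expression matrix; NaN cells are emitted as empty fields."""
    path = Path(path)
    df = dataset.values

    def fmt(x: float) -> str:
        return "" if math.isnan(x) else format(x, ".12g")

    with path.open("w") as fh:
        if dialect == "gct":
            fh.write("#1.2\n")
            fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
            fh.write("Name\tDescription\t" + "\t".join(df.columns) + "\n")
            for gene, row in zip(df.index, df.to_numpy()):
                fh.write(gene + "\tna\t" + "\t".join(fmt(x) for x in row) + "\n")
        else:
            fh.write("gene_id\t" + "\t".join(df.columns) + "\n")
            for gene, row in zip(df.index, df.to_numpy()):
                fh.write(gene + "\t" + "\t".join(fmt(x) for x in row) + "\n")


def collapse_duplicate_genes(
    dataset: ExpressionDataset,
    how: Literal["mean", "max"] = "mean",
    uppercase: bool = True,
) -> ExpressionDataset:
    """Collapse expression rows that map to the same gene symbol.

    Platforms often carry several probes per gene; gene-set files use one
    symbol per gene.  Rows are grouped by (optionally upper-cased) gene id
    and collapsed by ``mean`` (default) or ``max``, ignoring NaN.  Row order
    follows the first occurrence of each symbol.
    """
    df = dataset.values
    keys = [g.upper() for g in df.index] if uppercase else list(df.index)
    order: list[str] = []
    seen: set[str] = set()
    for k in keys:
        if k not in seen:
            seen.add(k)
            order.append(k)
    grouped = df.groupby(pd.Index(keys, name=df.index.name), sort=False)
    agg = grouped.mean() if how == "mean" else grouped.max()
    agg = agg.loc[order]
    return ExpressionDataset(agg, dict(dataset.labels) if dataset.labels else None)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> PathwayCollection:
    """Parse a GMT gene-set file, preserving file order.

    Genes are de-duplicated within each set; blank trailing fields are
    ignored.  Lines with fewer than three tab-separated fields and duplicate
    set names are hard errors.
    """
    path = Path(path)
    entries: list[Pathway] = []
    names: set[str] = set()
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        if ln.strip() == "":
            continue
        fields = ln.split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT line needs name, description and >=1 gene "
                f"(got {len(fields)} fields)"
            )
        name, description = fields[0], fields[1]
        if name in names:
            raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        genes = []
        seen_g: set[str] = set()
        for g in fields[2:]:
            g = g.strip()
            if g and g not in seen_g:
                seen_g.add(g)
                genes.append(g)
        if not genes:
            raise FormatError(f"{path}:{lineno}: set {name!r} has no genes")
        names.add(name)
        entries.append(Pathway(name, description, frozenset(genes)))
    if not entries:
        raise FormatError(f"{path}: no gene sets found")
    return PathwayCollection(entries)


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for p in collection:
            fh.write(p.name + "\t" + p.description + "\t")
            fh.write("\t".join(sorted(p.genes)) + "\n")


# ---------------------------------------------------------------------------
# class labels (CLS / TSV)
# ---------------------------------------------------------------------------


def read_cls(path: str | Path) -> list[str]:
    """Parse a binary CLS class file into a positional list of label names.

    Line 1: ``N n_classes 1``; line 2: ``# nameA nameB``; line 3: N
    space-separated tokens, either the label names themselves or 0/1 indices
    into the line-2 name order.  Exactly two classes are required.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip() != ""]
    if len(lines) < 3:
        raise FormatError(f"{path}: CLS file needs 3 non-empty lines")
    head = lines[0].split()
    if len(head) < 2:
        raise FormatError(f"{path}:1: expected 'N n_classes 1'")
    n, n_classes = int(head[0]), int(head[1])
    if n_classes != 2:
        raise FormatError(
            f"{path}:1: binary labels required, file declares {n_classes} classes"
        )
    name_line = lines[1].split()
    if not name_line or name_line[0] != "#":
        raise FormatError(f"{path}:2: expected '# nameA nameB'")
    class_names = name_line[1:]
    if len(class_names) != 2:
        raise FormatError(
            f"{path}:2: expected 2 class names, got {len(class_names)}"
        )
    tokens = lines[2].split()
    if len(tokens) != n:
        raise FormatError(
            f"{path}:3: {len(tokens)} class tokens, line 1 declares {n}"
        )
    distinct = sorted(set(tokens))
    if len(distinct) > 2:
        raise FormatError(f"{path}:3: more than 2 distinct class tokens: {distinct}")
    if set(distinct) <= {"0", "1"}:
        return [class_names[int(t)] for t in tokens]
    unknown = [t for t in distinct if t not in class_names]
    if unknown:
        raise FormatError(
            f"{path}:3: tokens {unknown} are neither 0/1 nor declared class names"
        )
    return list(tokens)


def write_cls(labels: Sequence[str], path: str | Path) -> None:
    order: list[str] = []
    for lab in labels:
        if lab not in order:
            order.append(lab)
    if len(order) != 2:
        raise FormatError(f"CLS output requires exactly 2 classes, got {order}")
    with Path(path).open("w") as fh:
        fh.write(f"{len(labels)} 2 1\n")
        fh.write("# " + " ".join(order) + "\n")
        fh.write(" ".join(str(order.index(lab)) for lab in labels) + "\n")


def read_labels_tsv(path: str | Path) -> dict[str, str]:
    """Read a two-column ``sample_id <TAB> label`` file (no header)."""
    path = Path(path)
    labels: dict[str, str] = {}
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        if ln.strip() == "":
            continue
        fields = ln.split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
        sid, lab = fields[0].strip(), fields[1].strip()
        if sid in labels:
            raise FormatError(f"{path}:{lineno}: duplicate sample id {sid!r}")
        labels[sid] = lab
    if not labels:
        raise FormatError(f"{path}: no labels found")
    return labels


# ---------------------------------------------------------------------------
# generic result tables
# ---------------------------------------------------------------------------


def write_table(rows: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    """Write a result table as TSV: header row, floats at 12 significant
    digits (round-trip safe to 1e-9 for values up to ~1e3), row order
    preserved.  Empty tables are an error."""
    if rows.shape[0] == 0 or rows.shape[1] == 0:
        raise FormatError("refusing to write an empty table")
    rows.to_csv(
        Path(path),
        sep="\t",
        float_format="%.12g",
        index=index_label is not None,
        index_label=index_label,
    )


def read_table(path: str | Path, index_col: int | None = None) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t", index_col=index_col)
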