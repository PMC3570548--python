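"""Readers/writers for the text formats the pipeline touches.

Expression matrices travel as tab-separated tables (row identifiers in the
first column, sample identifiers in the header).  Gene-signature collections
use the GMT format, classifier feature tables the Weka ARFF format, and gene
identifiers are harmonised against a two-column alias->approved symbol table
(an HGNC-style download; the snapshot to use is the caller's choice).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CLASS_NAMES = ("ABC", "GCB", "Type-III")


class Level(str, Enum):
    """Whether matrix rows are array probes or collapsed gene symbols."""

    PROBE = "probe"
    GENE = "gene"


@dataclass
class ExpressionMatrix:
    """Expression values (probes or genes x samples) with identity metadata.

    ``values`` is a DataFrame indexed by row identifier with one column per
    sample, in arbitrary non-negative intensity units (typically log2 scale).
    """

    values: pd.DataFrame
    level: Level = Level.GENE
    platform_name: str = ""

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.level == Level.GENE and self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids in GENE-level matrix: {dups}")

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.level, self.platform_name)


@dataclass
class GeneSignature:
    """A named gene set from a signature collection (one GMT line)."""

    name: str
    source: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has no genes")


@dataclass
class SurvivalRecord:
    """Right-censored overall-survival observation for one sample."""

    sample_id: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"negative survival time for {self.sample_id}")
        if self.event not in (0, 1):
            raise ValueError(f"event flag must be 0/1, got {self.event!r}")


_NUMBER_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def parse_expression_table(
    path: str | Path | io.StringIO,
    orientation: str = "samples-in-columns",
    level: Level = Level.GENE,
    platform_name: str = "",
) -> ExpressionMatrix:
    """Parse a tab-separated expression table.

    The first column holds row identifiers and the header row sample
    identifiers; ``orientation="samples-in-rows"`` accepts the transposed
    layout.  Cells must be plain or scientific-notation decimals; anything
    else (including ``NA``) is rejected with the offending row/column named.
    """
    if orientation not in ("samples-in-columns", "samples-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    text = path.getvalue() if isinstance(path, io.StringIO) else Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty expression table")
    header = lines[0].split("\t")
    col_ids = header[1:]
    if not col_ids:
        raise ValueError("expression table has no data columns")
    n_cols = len(col_ids)
    row_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != n_cols + 1:
            raise ValueError(
                f"ragged row at line {lineno}: expected {n_cols + 1} fields, got {len(fields)}"
            )
        rid = fields[0]
        vals = []
        for cid, cell in zip(col_ids, fields[1:]):
            if not _NUMBER_RE.match(cell.strip()):
                raise ValueError(
                    f"non-numeric cell {cell!r} at row {rid!r}, column {cid!r}"
                )
            vals.append(float(cell))
        row_ids.append(rid)
        rows.append(vals)
    if not rows:
        raise ValueError("expression table has a header but no data rows")
    df = pd.DataFrame(np.asarray(rows, dtype=float), index=row_ids, columns=col_ids)
    if orientation == "samples-in-rows":
        df = df.T
    return ExpressionMatrix(df, level=level, platform_name=platform_name)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="ID")


def parse_gmt(path: str | Path | io.StringIO) -> list[GeneSignature]:
    """Parse a GMT v2 signature collection: name TAB source TAB gene TAB ...

    Duplicate genes within a line are collapsed; a line with fewer than three
    fields is an error reported with its line number.
    """
    text = path.getvalue() if isinstance(path, io.StringIO) else Path(path).read_text()
    sigs: list[GeneSignature] = []
    for lineno, ln in enumerate(text.splitlines(), start=1):
        if not ln.strip():
            continue
        fields = ln.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {lineno} has {len(fields)} fields; need >=3")
        name, source = fields[0], fields[1]
        genes = frozenset(g for g in fields[2:] if g)
        sigs.append(GeneSignature(name=name, source=source, genes=genes))
    return sigs


def write_gmt(signatures: Iterable[GeneSignature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, sig.source, *sorted(sig.genes)]) + "\n")


def read_symbol_table(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column TSV (alias TAB approved-symbol) into alias -> set."""
    table: dict[str, set[str]] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        fields = ln.split("\t")
        if len(fields) != 2:
            raise ValueError(f"symbol table line needs 2 fields: {ln!r}")
        alias, approved = fields
        if not approved:
            raise ValueError(f"empty approved symbol for alias {alias!r}")
        table.setdefault(alias, set()).add(approved)
    return table


def reannotate_symbols(
    ids: Sequence[str], symbol_table: Mapping[str, set[str]]
) -> dict[str, str]:
    """Map identifiers to approved symbols where the mapping is unambiguous.

    An identifier is replaced only when its alias maps to exactly one approved
    symbol; otherwise (no entry, or several candidate symbols) the original is
    kept verbatim.  Composite identifiers containing ``#`` (e.g. "ISY1#RAB43")
    are treated as atomic and never remapped.
    """
    if len(ids) == 0:
        raise ValueError("no identifiers to re-annotate")
    mapping: dict[str, str] = {}
    for gid in ids:
        if "#" in gid:
            mapping[gid] = gid
            continue
        targets = symbol_table.get(gid, set())
        mapping[gid] = next(iter(targets)) if len(targets) == 1 else gid
    return mapping


# --- ARFF ------------------------------------------------------------------

def _quote_arff(name: str) -> str:
    if re.search(r"[\s,'\"%{}]", name):
        return "'" + name.replace("\\", "\\\\").replace("'", "\\'") + "'"
    return name


def _unquote_arff(token: str) -> str:
    token = token.strip()
    if len(token) >= 2 and token[0] == token[-1] and token[0] in "'\"":
        return token[1:-1].replace("\\'", "'").replace("\\\\", "\\")
    return token


def write_arff(
    matrix: ExpressionMatrix,
    labels: Mapping[str, str] | None,
    relation_name: str,
    path: str | Path,
) -> None:
    """Write samples as ARFF rows: one numeric attribute per gene plus a
    nominal class attribute over {ABC, GCB, Type-III}.  Samples without a
    label get the ARFF missing marker '?'.
    """
    labels = labels or {}
    for sid, lab in labels.items():
        if lab not in CLASS_NAMES:
            raise ValueError(f"unknown class label {lab!r} for sample {sid!r}")
    with open(path, "w") as fh:
        fh.write(f"@relation {_quote_arff(relation_name)}\n\n")
        for gene in matrix.row_ids:
            fh.write(f"@attribute {_quote_arff(gene)} numeric\n")
        fh.write(f"@attribute class {{{','.join(CLASS_NAMES)}}}\n\n@data\n")
        for sid in matrix.sample_ids:
            vals = matrix.values[sid].to_numpy()
            cls = labels.get(sid, "?")
            fh.write(",".join(f"{v:.10g}" for v in vals) + f",{cls}\n")


def read_arff(path: str | Path) -> tuple[pd.DataFrame, list[str | None]]:
    """Round-trip reader for ARFF files produced by :func:`write_arff`.

    Returns (samples x genes feature frame, per-sample label list with None
    for missing).  Sample identifiers are not part of ARFF; rows are numbered.
    """
    attrs: list[str] = []
    data_rows: list[list[float]] = []
    row_labels: list[str | None] = []
    in_data = False
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("%"):
            continue
        low = ln.lower()
        if low.startswith("@attribute"):
            rest = ln[len("@attribute"):].strip()
            if rest.startswith(("'", '"')):
                quote = rest[0]
                end = rest.index(quote, 1)
                while end > 0 and rest[end - 1] == "\\":
                    end = rest.index(quote, end + 1)
                name = _unquote_arff(rest[: end + 1])
            else:
                name = rest.split()[0]
            attrs.append(name)
        elif low.startswith("@data"):
            in_data = True
        elif in_data:
            fields = ln.split(",")
            *vals, cls = fields
            data_rows.append([float(v) for v in vals])
            row_labels.append(None if cls.strip() == "?" else cls.strip())
    genes = attrs[:-1]  # last attribute is the class
    df = pd.DataFrame(np.asarray(data_rows, dtype=float), columns=genes)
    return df, row_labels


def read_survival_table(path: str | Path) -> list[SurvivalRecord]:
    """Read a TSV of (sample_id, time, event) with a header row."""
    records = []
    lines = Path(path).read_text().splitlines()
    for ln in lines[1:]:
        if not ln.strip():
            continue
        sid, time, event = ln.split("\t")
        records.append(SurvivalRecord(sid, float(time), int(event)))
    return records


def write_survival_table(records: Iterable[SurvivalRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\ttime\tevent\n")
        for r in records:
            fh.write(f"{r.sample_id}\t{r.time:.10g}\t{r.event}\n")
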