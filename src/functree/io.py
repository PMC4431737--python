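"""Parsing and writing of the package's delimited text formats.

Formats handled here:

* node-value association list — TSV with columns
  ``node_id  value  [color]  [opacity]``, one function per line;
* gene list — one gene id per line;
* gene -> KO mapping — ``gene<TAB>ko`` pairs;
* abundance / gene-count profiles — delimited matrix with sample (or
  organism) rows and KO columns;
* result tables — TSV with columns
  ``function_id  name  layer  value  p_raw  p_corrected  coverage``.

Lines starting with '#' and blank lines are ignored everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Iterable, Mapping

import pandas as pd

from .errors import ParseError

RESULT_COLUMNS = ("function_id", "name", "layer", "value",
                  "p_raw", "p_corrected", "coverage")


@dataclass(frozen=True)
class NodeValueRecord:
    """One (function id, value) association, with optional styling."""

    node_id: str
    value: float
    color: str | None = None
    opacity: float | None = None


@dataclass(frozen=True)
class GeneList:
    """A query gene set within a genome-wide universe.

    gene_to_ko maps gene id -> set of KO ids; genes without an entry (or
    with an empty set) are simply unannotated and never associate with any
    function.
    """

    genes: frozenset[str]
    organism_universe: frozenset[str]
    gene_to_ko: Mapping[str, frozenset[str]]

    def validate(self) -> None:
        if not self.genes:
            raise ParseError("empty gene list")
        missing = self.genes - self.organism_universe
        if missing:
            raise ParseError("gene ids absent from the organism universe: %s"
                             % ", ".join(sorted(missing)))


def _lines(stream: IO[str] | str):
    text = stream if isinstance(stream, str) else stream.read()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        yield lineno, line


def parse_node_values(stream: IO[str] | str,
                      delimiter: str = "\t") -> list[NodeValueRecord]:
    """Parse a node-value association list.

    Duplicate node ids are an error (an ambiguous mapping), as are
    non-finite values, out-of-range opacities and extra columns.
    """
    records: list[NodeValueRecord] = []
    seen: dict[str, int] = {}
    for lineno, line in _lines(stream):
        fields = [f.strip() for f in line.split(delimiter)]
        if len(fields) < 2:
            raise ParseError("line %d: expected at least `node_id%svalue`"
                             % (lineno, "<TAB>" if delimiter == "\t" else delimiter))
        if len(fields) > 4:
            raise ParseError("line %d: at most 4 columns allowed "
                             "(node_id, value, color, opacity)" % lineno)
        node_id = fields[0]
        if not node_id:
            raise ParseError("line %d: empty node id" % lineno)
        if node_id in seen:
            raise ParseError("line %d: duplicate node id %r (first at line %d)"
                             % (lineno, node_id, seen[node_id]))
        seen[node_id] = lineno
        try:
            value = float(fields[1])
        except ValueError:
            raise ParseError("line %d: non-numeric value %r" % (lineno, fields[1])) from None
        if not math.isfinite(value):
            raise ParseError("line %d: value must be finite, got %r" % (lineno, fields[1]))
        color = fields[2] if len(fields) > 2 and fields[2] else None
        opacity = None
        if len(fields) > 3 and fields[3]:
            try:
                opacity = float(fields[3])
            except ValueError:
                raise ParseError("line %d: non-numeric opacity %r"
                                 % (lineno, fields[3])) from None
            if not 0.0 <= opacity <= 1.0:
                raise ParseError("line %d: opacity %g outside [0, 1]" % (lineno, opacity))
        records.append(NodeValueRecord(node_id, value, color, opacity))
    return records


def write_node_values(records: Iterable[NodeValueRecord],
                      delimiter: str = "\t") -> str:
    out = []
    for r in records:
        fields = [r.node_id, repr(r.value)]
        if r.color is not None or r.opacity is not None:
            fields.append(r.color or "")
        if r.opacity is not None:
            fields.append(repr(r.opacity))
        out.append(delimiter.join(fields))
    return "\n".join(out) + ("\n" if out else "")


def parse_gene_list(stream: IO[str] | str) -> frozenset[str]:
    """One gene id per line; whitespace trimmed, duplicates collapsed."""
    return frozenset(line for _, line in _lines(stream))


def parse_gene_to_ko(stream: IO[str] | str) -> dict[str, frozenset[str]]:
    """Parse `gene<TAB>ko` pairs into gene -> set-of-KOs."""
    out: dict[str, set[str]] = {}
    for lineno, line in _lines(stream):
        fields = line.split("\t")
        if len(fields) != 2 or not all(fields):
            raise ParseError("line %d: expected `gene<TAB>ko`" % lineno)
        out.setdefault(fields[0], set()).add(fields[1])
    return {g: frozenset(ks) for g, ks in out.items()}


def read_profiles(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a samples-by-KO (or organisms-by-KO) matrix with a header row."""
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0, comment="#")
    except Exception as exc:
        raise ParseError("could not read profile matrix %s: %s" % (path, exc)) from exc
    if df.empty:
        raise ParseError("profile matrix %s has no data rows" % path)
    if not all(df.dtypes.apply(lambda t: t.kind in "fiu")):
        raise ParseError("profile matrix %s contains non-numeric columns" % path)
    return df


def write_profiles(df: pd.DataFrame, path, delimiter: str = "\t") -> None:
    df.to_csv(path, sep=delimiter, index_label="sample")


def write_table(results, sort_by: str = "value", descending: bool = True,
                delimiter: str = "\t") -> str:
    """Render enrichment/aggregation results as a delimited table.

    Stable sort by ``sort_by`` with ties broken by function id ascending, so
    output is byte-deterministic.
    """
    if sort_by not in RESULT_COLUMNS:
        raise ParseError("unknown sort key %r (expected one of %s)"
                         % (sort_by, ", ".join(RESULT_COLUMNS)))
    rows = []
    for r in results:
        rows.append({
            "function_id": r.function_id,
            "name": getattr(r, "name", r.function_id),
            "layer": r.layer,
            "value": r.val,
            "p_raw": r.p_raw,
            "p_corrected": r.p_corrected,
            "coverage": r.cov,
        })
    rows.sort(key=lambda row: row["function_id"])
    if sort_by != "function_id":
        rows.sort(key=lambda row: row[sort_by], reverse=descending)
    lines = [delimiter.join(RESULT_COLUMNS)]
    for row in rows:
        lines.append(delimiter.join(
            repr(row[c]) if isinstance(row[c], float) else str(row[c])
            for c in RESULT_COLUMNS))
    return "\n".join(lines) + "\n"
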