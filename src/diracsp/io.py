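"""Round-trip-safe file I/O: edge lists and node/edge signal tables.

Formats (all plain text):

* edge list — two integer columns ``source,target``, comma or tab
  separated, ``#`` comments and an optional header allowed;
* signal CSV — columns ``kind,id,value`` with ``kind`` in {node, edge},
  ``id`` a node label or an ``r-s`` edge key (either orientation; a
  reversed key flips the sign of the stored value), ``value`` a float.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np

from .complexes import OrientedComplex, build_complex
from .spinor import TopologicalSpinor

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_signal",
    "write_signal",
]

logger = logging.getLogger(__name__)


def _detect_delimiter(line: str) -> str:
    return "\t" if ("\t" in line and "," not in line) else ","


def _is_int(token: str) -> bool:
    try:
        int(token)
        return True
    except ValueError:
        return False


def read_edge_list(path) -> OrientedComplex:
    """Read a two-column integer edge list into a canonical complex.

    The separator (comma/tab) is auto-detected; ``#`` comment lines and a
    non-numeric header row are skipped.  Malformed rows, self-loops and
    duplicate undirected edges raise errors naming the offending line.
    """
    path = Path(path)
    edges: list[tuple[int, int]] = []
    seen: dict[frozenset, int] = {}
    with path.open() as fh:
        delim = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if delim is None:
                delim = _detect_delimiter(line)
            parts = [p.strip() for p in line.split(delim)]
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            if not (_is_int(parts[0]) and _is_int(parts[1])):
                if not edges and lineno <= 2:
                    continue  # header row
                raise ValueError(f"{path}:{lineno}: non-integer node ids {line!r}")
            r, s = int(parts[0]), int(parts[1])
            if r == s:
                raise ValueError(f"{path}:{lineno}: self-loop on node {r}")
            key = frozenset((r, s))
            if key in seen:
                raise ValueError(
                    f"{path}:{lineno}: duplicate undirected edge ({r},{s}) "
                    f"(first seen on line {seen[key]})"
                )
            seen[key] = lineno
            edges.append((r, s))
    if not edges:
        raise ValueError(f"{path}: no edges found")
    return build_complex(edges)


def write_edge_list(c: OrientedComplex, path, delimiter: str = ",") -> None:
    """Write the stored (oriented) edge list with a ``source,target`` header."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["source", "target"])
        for r, s in c.edges:
            w.writerow([r, s])


def read_signal(path, c: OrientedComplex) -> TopologicalSpinor:
    """Read a ``kind,id,value`` CSV into a spinor on complex ``c``.

    Simplices absent from the file default to 0 (the count is logged).  Edge
    keys are matched irrespective of orientation; a key opposing the stored
    orientation sign-flips the value.  Unknown or duplicate ids raise.
    """
    path = Path(path)
    values = np.zeros(c.n_simplices)
    filled: set[tuple[str, int]] = set()
    with path.open() as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].strip().startswith("#"):
                continue
            kind = row[0].strip().lower()
            if kind == "kind":
                continue  # header
            if kind not in ("node", "edge"):
                raise ValueError(f"{path}:{lineno}: unknown kind {row[0]!r}")
            if len(row) < 3:
                raise ValueError(f"{path}:{lineno}: expected kind,id,value")
            ident, value = row[1].strip(), float(row[2])
            if kind == "node":
                if not _is_int(ident):
                    raise ValueError(f"{path}:{lineno}: bad node id {ident!r}")
                label = int(ident)
                if label not in c.node_index:
                    raise ValueError(f"{path}:{lineno}: unknown node {label}")
                pos = c.node_index[label]
                if ("node", pos) in filled:
                    raise ValueError(f"{path}:{lineno}: duplicate node id {label}")
                filled.add(("node", pos))
                values[pos] = value
            else:
                parts = ident.split("-")
                if len(parts) != 2 or not all(map(_is_int, parts)):
                    raise ValueError(f"{path}:{lineno}: bad edge key {ident!r}")
                r, s = int(parts[0]), int(parts[1])
                try:
                    j = c.edge_key((r, s))
                except KeyError:
                    raise ValueError(f"{path}:{lineno}: unknown edge {ident!r}") from None
                if ("edge", j) in filled:
                    raise ValueError(f"{path}:{lineno}: duplicate edge key {ident!r}")
                filled.add(("edge", j))
                values[c.n_nodes + j] = c.edge_sign((r, s)) * value
    missing = c.n_simplices - len(filled)
    if missing:
        logger.info("%s: %d simplices not referenced, defaulted to 0", path, missing)
    return TopologicalSpinor(values, c)


def write_signal(psi: TopologicalSpinor, path) -> None:
    """Write a spinor as a ``kind,id,value`` CSV (canonical edge keys)."""
    c = psi.complex
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["kind", "id", "value"])
        for label, v in zip(c.node_ids, psi.chi):
            w.writerow(["node", label, repr(float(v))])
        for (r, s), v in zip(c.edges, psi.phi):
            w.writerow(["edge", f"{r}-{s}", repr(float(v))])
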