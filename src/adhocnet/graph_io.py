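"""Read/write interaction networks and annotation tables.

Interaction networks are simple undirected graphs: self-loops are dropped,
duplicate rows (in either orientation) are collapsed, and node identifiers
are case-sensitive opaque strings -- no ID mapping or aliasing is
attempted, so reconciling e.g. DIP vs SGD identifiers is the caller's job.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

logger = logging.getLogger(__name__)

LETHALITY_STATUSES = frozenset({"lethal", "viable", "unknown"})
ANNOTATION_CATEGORIES = frozenset(
    {"molecular_function", "biological_process", "cellular_component", "lethality"}
)

#: cluster_id used for inter-module (interspersed) nodes in cluster TSVs
INTER_MODULE_ID = "INTER_MODULE"


class ParseError(ValueError):
    """Malformed input row; message names the offending line number."""


@dataclass
class AnnotationTable:
    """Protein -> term-set mapping (GO use) or protein -> lethality status.

    Proteins absent from the table are treated as unannotated (GO) or
    ``unknown`` (lethality).
    """

    category: str
    terms: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in ANNOTATION_CATEGORIES:
            raise ValueError(
                f"category must be one of {sorted(ANNOTATION_CATEGORIES)}, "
                f"got {self.category!r}"
            )
        if self.category == "lethality":
            for protein, statuses in self.terms.items():
                bad = statuses - LETHALITY_STATUSES
                if bad:
                    raise ValueError(
                        f"invalid lethality status {sorted(bad)} for {protein!r}"
                    )

    @property
    def is_lethality(self) -> bool:
        return self.category == "lethality"

    def terms_for(self, protein: str) -> set[str]:
        return self.terms.get(protein, set())

    def status(self, protein: str) -> str:
        """Lethality status; proteins not listed are ``unknown``."""
        if not self.is_lethality:
            raise ValueError("status() is only defined for lethality tables")
        statuses = self.terms.get(protein)
        return next(iter(statuses)) if statuses else "unknown"

    def annotated_proteins(self) -> set[str]:
        return {p for p, t in self.terms.items() if t}


def _iter_rows(path: str | Path):
    with open(path, newline="") as handle:
        for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].lstrip().startswith("#"):
                continue
            yield lineno, [f.strip() for f in row]


def read_edge_list(
    path: str | Path,
    dialect: str = "tsv",
    node_list: str | Path | None = None,
) -> nx.Graph:
    """Read a network from a 2-column TSV edge list or a SIF file.

    SIF rows ``A <relation> B [C ...]`` expand to pairwise edges from A;
    the relation string is ignored.  Self-loops are dropped and duplicate
    edges collapsed (counts logged).  ``node_list`` optionally names a file
    of one identifier per line declaring nodes (e.g. degree-0 proteins an
    edge list cannot express).
    """
    if dialect not in ("tsv", "sif"):
        raise ValueError(f"dialect must be 'tsv' or 'sif', got {dialect!r}")
    graph = nx.Graph()
    self_loops = duplicates = 0
    for lineno, row in _iter_rows(path):
        if dialect == "tsv":
            if len(row) < 2 or not row[0] or not row[1]:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns, "
                    f"got {len(row)}"
                )
            pairs = [(row[0], row[1])]
        else:  # sif
            if len(row) == 1 and " " in row[0]:
                row = row[0].split()
            if len(row) == 1:
                graph.add_node(row[0])
                continue
            if len(row) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: SIF row needs source, relation and "
                    f"at least one target"
                )
            src, _relation, *targets = row
            pairs = [(src, t) for t in targets if t]
        for a, b in pairs:
            if a == b:
                self_loops += 1
                continue
            if graph.has_edge(a, b):
                duplicates += 1
                continue
            graph.add_edge(a, b)
    if node_list is not None:
        for _lineno, row in _iter_rows(node_list):
            graph.add_node(row[0])
    if self_loops or duplicates:
        logger.info(
            "read_edge_list(%s): dropped %d self-loop row(s), %d duplicate row(s)",
            path, self_loops, duplicates,
        )
    return graph


def read_annotations(path: str | Path, category: str) -> AnnotationTable:
    """Read a 2-column protein<TAB>term (or protein<TAB>status) TSV.

    Repeated rows per protein accumulate terms.  In lethality mode any
    status outside {lethal, viable, unknown} is a parse error.
    """
    if category not in ANNOTATION_CATEGORIES:
        raise ValueError(
            f"category must be one of {sorted(ANNOTATION_CATEGORIES)}, got {category!r}"
        )
    terms: dict[str, set[str]] = {}
    for lineno, row in _iter_rows(path):
        if len(row) < 2 or not row[0] or not row[1]:
            raise ParseError(
                f"{path}: line {lineno}: expected 2 tab-separated columns"
            )
        protein, term = row[0], row[1]
        if category == "lethality":
            if term not in LETHALITY_STATUSES:
                raise ParseError(
                    f"{path}: line {lineno}: unknown lethality status {term!r} "
                    f"(expected one of {sorted(LETHALITY_STATUSES)})"
                )
            terms[protein] = {term}
        else:
            terms.setdefault(protein, set()).add(term)
    return AnnotationTable(category=category, terms=terms)


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """Write a graph as a sorted 2-column TSV edge list."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            writer.writerow([a, b])


def write_clusters(result, path: str | Path) -> None:
    """Write a ClusteringResult as TSV (k, cluster_id, protein, node_class).

    Inter-module nodes get ``cluster_id = INTER_MODULE``; a node belonging
    to m clusters appears on m rows.
    """
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["k", "cluster_id", "protein", "node_class"])
        for cluster in result.clusters:
            for protein in sorted(cluster.members):
                writer.writerow(
                    [result.k, cluster.id, protein, result.classes[protein].name]
                )
        for protein in sorted(result.inter_module):
            writer.writerow(
                [result.k, INTER_MODULE_ID, protein, result.classes[protein].name]
            )


def read_clusters(path: str | Path):
    """Round-trip reader for :func:`write_clusters` output.

    Returns ``(k, memberships, inter_module)`` where *memberships* maps
    cluster_id -> member set.
    """
    memberships: dict[str, set[str]] = {}
    inter_module: set[str] = set()
    k = None
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if header is not None and header[:4] != ["k", "cluster_id", "protein", "node_class"]:
            raise ParseError(f"{path}: unexpected header {header!r}")
        for row in reader:
            if not row:
                continue
            k = float(row[0])
            if row[1] == INTER_MODULE_ID:
                inter_module.add(row[2])
            else:
                memberships.setdefault(row[1], set()).add(row[2])
    return k, memberships, inter_module
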