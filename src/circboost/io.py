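"""File formats, domain containers, and validation.

All tabular formats are UTF-8 TSV. Matrices carry a header row and an
identifier first column; annotation maps and association/ontology edge
lists are two-column TSVs. Sequences are FASTA. Entity identifiers are
always indexed in lexicographic order, fixed at load time, and every
downstream module inherits that order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("circboost")

_SEQ_ALPHABET = set("ACGTN")

__all__ = [
    "AssociationMatrix",
    "SimilarityMatrix",
    "ExpressionMatrix",
    "OntologyDAG",
    "read_associations",
    "read_fasta",
    "read_similarity_matrix",
    "read_expression_matrix",
    "read_annotations",
    "read_ontology",
    "read_id_mapping",
    "write_matrix",
    "write_associations",
    "write_annotations",
    "write_fasta",
    "write_ontology",
    "write_json",
    "read_json",
    "configure_logging",
]


def configure_logging(verbose: bool = False) -> None:
    """Route package logs to stderr; DEBUG level when *verbose*."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class AssociationMatrix:
    """Binary circRNA x disease association matrix A."""

    circ_ids: list[str]
    disease_ids: list[str]
    values: np.ndarray  # shape (|C|, |D|), dtype float64, entries in {0, 1}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.circ_ids), len(self.disease_ids)):
            raise ValueError("association matrix shape does not match identifier lists")
        if len(set(self.circ_ids)) != len(self.circ_ids):
            raise ValueError("duplicate circRNA identifiers")
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise ValueError("duplicate disease identifiers")
        uniq = np.unique(self.values)
        if not np.all(np.isin(uniq, (0.0, 1.0))):
            raise ValueError("association matrix entries must be 0 or 1")

    @property
    def n_pairs(self) -> int:
        return int(self.values.sum())

    def pairs(self) -> list[tuple[str, str]]:
        return [
            (self.circ_ids[i], self.disease_ids[j])
            for i, j in zip(*np.nonzero(self.values))
        ]


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix in [0, 1] with unit diagonal."""

    ids: list[str]
    values: np.ndarray

    SYM_TOL = 1e-9

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"similarity matrix must be square over {n} ids, got {self.values.shape}"
            )
        if len(set(self.ids)) != n:
            raise ValueError("duplicate identifiers in similarity matrix")

    def validate(self) -> "SimilarityMatrix":
        v = self.values
        if not np.allclose(v, v.T, atol=self.SYM_TOL):
            raise ValueError("similarity matrix is not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=self.SYM_TOL):
            raise ValueError("similarity matrix diagonal is not 1")
        off = v[~np.eye(len(self.ids), dtype=bool)]
        if off.size and (off.min() < -self.SYM_TOL or off.max() > 1 + self.SYM_TOL):
            raise ValueError("similarity entries outside [0, 1]")
        return self

    def subset(self, ids: list[str]) -> "SimilarityMatrix":
        pos = {x: k for k, x in enumerate(self.ids)}
        missing = [x for x in ids if x not in pos]
        if missing:
            raise KeyError(f"ids missing from similarity matrix: {missing[:5]}")
        idx = np.array([pos[x] for x in ids])
        return SimilarityMatrix(list(ids), self.values[np.ix_(idx, idx)])


@dataclass
class ExpressionMatrix:
    """Expression levels of circRNAs across measurement sites (RPM-like)."""

    circ_ids: list[str]
    site_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.circ_ids), len(self.site_labels)):
            raise ValueError("expression matrix shape mismatch")
        if len(self.site_labels) < 2:
            raise ValueError("expression matrix needs at least 2 sites")


@dataclass
class OntologyDAG:
    """Directed acyclic ontology: edges point child -> parent (is_a)."""

    terms: set[str]
    edges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for child, parent in self.edges:
            if child not in self.terms or parent not in self.terms:
                raise ValueError(f"edge endpoint not in term set: ({child}, {parent})")
        g = self.graph()
        if self.terms:
            try:
                cycle = nx.find_cycle(g)
            except nx.NetworkXNoCycle:
                cycle = None
            if cycle:
                raise ValueError(f"ontology contains a cycle: {cycle}")
            if not self.roots():
                raise ValueError("ontology has no root term")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(self.edges)
        return g

    def roots(self) -> list[str]:
        have_parent = {c for c, _ in self.edges}
        return sorted(self.terms - have_parent)

    def parents(self, term: str) -> list[str]:
        return sorted(p for c, p in self.edges if c == term)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_pair_lines(path: str | Path) -> list[tuple[str, str]]:
    """Two-column TSV -> list of (a, b); tolerates one optional header line."""
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not any(line.strip() for line in lines):
        raise ValueError(f"{path}: empty file")
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
            raise ValueError(f"{path}: malformed line {lineno}: {line!r}")
        pairs.append((fields[0].strip(), fields[1].strip()))
    return pairs


_HEADER_TOKENS = {
    "circrna", "circ", "circ_id", "circrna_id", "disease", "disease_id",
    "entity", "entity_id", "term", "term_id", "gene", "gene_id",
    "child", "parent", "source", "target", "id", "from", "to",
}


def _strip_header(pairs: list[tuple[str, str]]) -> list[tuple[str, str]]:
    if pairs and all(f.lower() in _HEADER_TOKENS for f in pairs[0]):
        return pairs[1:]
    return pairs


def read_associations(path: str | Path) -> AssociationMatrix:
    """Load a circRNA-disease association edge list into a binary matrix.

    Duplicated pairs collapse to a single 1. Entities are indexed in
    lexicographic order. An edge list mentions only entities with at least
    one association, so every row and column of the result is non-empty.
    """
    pairs = _strip_header(_read_pair_lines(path))
    if not pairs:
        raise ValueError(f"{path}: no association pairs found")
    uniq = sorted(set(pairs))
    circ_ids = sorted({c for c, _ in uniq})
    disease_ids = sorted({d for _, d in uniq})
    ci = {c: k for k, c in enumerate(circ_ids)}
    di = {d: k for k, d in enumerate(disease_ids)}
    values = np.zeros((len(circ_ids), len(disease_ids)))
    for c, d in uniq:
        values[ci[c], di[d]] = 1.0
    n_dup = len(pairs) - len(uniq)
    if n_dup:
        logger.warning("%s: collapsed %d duplicate association pair(s)", path, n_dup)
    return AssociationMatrix(circ_ids, disease_ids, values)


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {id: sequence}; uppercased, U mapped to T, ACGTN enforced."""
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper().replace("U", "T")
        bad = set(seq) - _SEQ_ALPHABET
        if bad:
            raise ValueError(
                f"{path}: sequence {record.id!r} has invalid characters {sorted(bad)}"
            )
        if not seq:
            raise ValueError(f"{path}: sequence {record.id!r} is empty")
        if record.id in seqs:
            raise ValueError(f"{path}: duplicate sequence id {record.id!r}")
        seqs[record.id] = seq
    if not seqs:
        raise ValueError(f"{path}: no FASTA records")
    return dict(sorted(seqs.items()))


def _read_matrix_frame(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: matrix contains missing values")
    return df


def read_similarity_matrix(path: str | Path) -> SimilarityMatrix:
    df = _read_matrix_frame(path)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: expected a square similarity matrix, got {df.shape}")
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: similarity matrix row/column identifiers differ")
    order = sorted(df.index)
    df = df.loc[order, order]
    return SimilarityMatrix([str(i) for i in order], df.to_numpy(dtype=float))


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    dropped = df.index[df.isna().any(axis=1)]
    if len(dropped):
        logger.warning(
            "%s: dropped %d circRNA row(s) with missing sites", path, len(dropped)
        )
        df = df.dropna(axis=0)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expression matrix needs >= 2 sites")
    df = df.sort_index()
    return ExpressionMatrix(
        [str(i) for i in df.index], [str(c) for c in df.columns],
        df.to_numpy(dtype=float),
    )


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (entity, term/gene) -> {entity: set of terms}."""
    pairs = _strip_header(_read_pair_lines(path))
    annot: dict[str, set[str]] = {}
    for entity, term in pairs:
        annot.setdefault(entity, set()).add(term)
    return dict(sorted(annot.items()))


def read_ontology(path: str | Path) -> OntologyDAG:
    """Ontology from a child->parent edge TSV, or OBO (id / is_a only)."""
    path = Path(path)
    if path.suffix.lower() == ".obo":
        import obonet

        graph = obonet.read_obo(str(path))
        terms = set(graph.nodes)
        # obonet edges run child -> parent for is_a
        edges = sorted(
            (c, p) for c, p, key in graph.edges(keys=True) if key == "is_a"
        )
        return OntologyDAG(terms, edges)
    pairs = _strip_header(_read_pair_lines(path))
    terms = {t for pair in pairs for t in pair}
    return OntologyDAG(terms, sorted(set(pairs)))


def read_id_mapping(path: str | Path) -> dict[str, str]:
    """Optional two-column old-id -> new-id mapping TSV."""
    pairs = _strip_header(_read_pair_lines(path))
    mapping = dict(pairs)
    if len(mapping) != len(pairs):
        raise ValueError(f"{path}: duplicate source ids in mapping")
    return mapping


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_matrix(
    obj: SimilarityMatrix | ExpressionMatrix | AssociationMatrix, path: str | Path
) -> None:
    if isinstance(obj, SimilarityMatrix):
        df = pd.DataFrame(obj.values, index=obj.ids, columns=obj.ids)
    elif isinstance(obj, ExpressionMatrix):
        df = pd.DataFrame(obj.values, index=obj.circ_ids, columns=obj.site_labels)
    else:
        df = pd.DataFrame(obj.values, index=obj.circ_ids, columns=obj.disease_ids)
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_associations(assoc: AssociationMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("circrna_id\tdisease_id\n")
        for c, d in assoc.pairs():
            fh.write(f"{c}\t{d}\n")


def write_annotations(annot: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("entity_id\tterm_id\n")
        for entity in sorted(annot):
            for term in sorted(annot[entity]):
                fh.write(f"{entity}\t{term}\n")


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            s = seqs[name]
            for k in range(0, len(s), 70):
                fh.write(s[k : k + 70] + "\n")


def write_ontology(dag: OntologyDAG, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("child\tparent\n")
        for child, parent in sorted(dag.edges):
            fh.write(f"{child}\t{parent}\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
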