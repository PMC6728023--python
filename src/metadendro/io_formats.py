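"""Readers and writers for every external representation the toolkit touches.

Formats: FASTA (sequences, header dialect ``>organism|marker|copy``), Newick
(dendrograms), tab-separated edge lists (metabolic networks), tab-separated
labeled distance matrices, plain-text ensemble files (one organism set per
line), and a flat YAML run configuration.  All text is UTF-8; ``#`` starts a
comment line in tabular formats.

The marker id of a sequence is either ``RIBO`` (the 16S-like universal
marker) or an Enzyme Commission-style tag ``EC:a.b.c.d`` identifying the
enzyme family the sequence belongs to.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from .dendro import Dendrogram, DendroNode, DistanceMatrix, SYMMETRY_TOL
from .netdist import MetabolicNetwork

__all__ = [
    "Alphabet",
    "SequenceRecord",
    "EnsembleSpec",
    "Dataset",
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_network_tsv",
    "write_network_tsv",
    "read_newick",
    "write_newick",
    "newick_string",
    "read_ensemble_file",
    "write_ensemble_file",
    "read_distance_tsv",
    "write_distance_tsv",
]

log = logging.getLogger(__name__)

NUCLEOTIDE_CHARS = set("ACGTU")
# 20 standard amino acids plus the NCBI ambiguity codes scored by BLOSUM/PAM
AMINO_CHARS = set("ACDEFGHIKLMNPQRSTVWY") | set("BZX*")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


class Alphabet(enum.Enum):
    NUCLEOTIDE = "nucleotide"
    AMINO_ACID = "amino_acid"

    @property
    def chars(self) -> set[str]:
        return NUCLEOTIDE_CHARS if self is Alphabet.NUCLEOTIDE else AMINO_CHARS


RIBO_MARKER = "RIBO"
_EC_RE = re.compile(r"^EC:\d+\.\d+\.\d+\.\d+$")


@dataclass(frozen=True)
class SequenceRecord:
    """One sequence of one organism, the unit of pairwise alignment."""

    organism_id: str
    marker_id: str
    residues: str
    copy_index: int = 1
    alphabet: Alphabet = Alphabet.NUCLEOTIDE

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(
                f"empty sequence for {self.organism_id}|{self.marker_id}|{self.copy_index}"
            )
        bad = set(self.residues) - self.alphabet.chars
        if bad:
            raise ValueError(
                f"characters {sorted(bad)} not in {self.alphabet.value} alphabet "
                f"({self.organism_id}|{self.marker_id})"
            )
        if self.copy_index < 1:
            raise ValueError("copy_index must be >= 1")

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.organism_id, self.marker_id, self.copy_index)


@dataclass
class EnsembleSpec:
    """Ordered list of organism sets, one evaluation run per set."""

    sets: list[list[str]]

    def __post_init__(self) -> None:
        for k, s in enumerate(self.sets):
            if len(set(s)) != len(s):
                raise ParseError(f"duplicate organism id in set {k + 1}")
            if len(s) < 3:
                raise ParseError(f"set {k + 1} has fewer than 3 organisms")


@dataclass
class Dataset:
    """In-memory bundle of sequences and networks for a set of organisms."""

    sequences: dict[tuple[str, str], list[SequenceRecord]] = field(default_factory=dict)
    networks: dict[str, MetabolicNetwork] = field(default_factory=dict)

    def add_record(self, rec: SequenceRecord) -> None:
        bucket = self.sequences.setdefault((rec.organism_id, rec.marker_id), [])
        if any(r.copy_index == rec.copy_index for r in bucket):
            raise ParseError(
                f"duplicate record {rec.organism_id}|{rec.marker_id}|{rec.copy_index}"
            )
        bucket.append(rec)

    def add_network(self, net: MetabolicNetwork) -> None:
        self.networks[net.organism_id] = net

    def organisms(self) -> list[str]:
        orgs = {org for org, _ in self.sequences} | set(self.networks)
        return sorted(orgs)

    def markers_of(self, organism_id: str) -> set[str]:
        return {m for (org, m) in self.sequences if org == organism_id}

    def get_seqs(self, organism_id: str, marker_id: str) -> list[SequenceRecord]:
        return sorted(
            self.sequences.get((organism_id, marker_id), []),
            key=lambda r: r.copy_index,
        )

    @classmethod
    def from_dir(cls, path: str | Path) -> "Dataset":
        """Load the on-disk layout: ``sequences.fasta`` + ``networks/<org>.tsv``."""
        path = Path(path)
        ds = cls()
        fasta = path / "sequences.fasta"
        if fasta.exists():
            for rec in read_fasta(fasta):
                ds.add_record(rec)
        netdir = path / "networks"
        if netdir.is_dir():
            for f in sorted(netdir.glob("*.tsv")):
                ds.add_network(read_network_tsv(f, organism_id=f.stem))
        return ds


# ---------------------------------------------------------------------------
# FASTA


def _infer_alphabet(residues: str) -> Alphabet:
    if set(residues) <= NUCLEOTIDE_CHARS:
        return Alphabet.NUCLEOTIDE
    return Alphabet.AMINO_ACID


def read_fasta(path: str | Path, alphabet: Alphabet | None = None) -> list[SequenceRecord]:
    """Parse a FASTA file with ``>organism|marker|copy`` headers.

    The copy field is optional (default 1).  The alphabet is inferred per
    record (ACGTU-only means nucleotide) unless forced by ``alphabet``.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[tuple[str, str, int]] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        parts = entry.id.split("|")
        if len(parts) not in (2, 3) or not all(parts[:2]):
            raise ParseError(
                f"{path}: malformed header {entry.id!r}; expected 'organism|marker|copy'"
            )
        organism, marker = parts[0], parts[1]
        if marker != RIBO_MARKER and not _EC_RE.match(marker):
            raise ParseError(f"{path}: marker {marker!r} is neither RIBO nor EC:a.b.c.d")
        try:
            copy = int(parts[2]) if len(parts) == 3 else 1
        except ValueError as exc:
            raise ParseError(f"{path}: non-integer copy index in {entry.id!r}") from exc
        residues = str(entry.seq).upper()
        if not residues:
            raise ParseError(f"{path}: empty sequence for record {entry.id!r}")
        if "-" in residues:
            raise ParseError(f"{path}: gap characters in input record {entry.id!r}")
        alph = alphabet or _infer_alphabet(residues)
        rec = SequenceRecord(
            organism_id=organism,
            marker_id=marker,
            copy_index=copy,
            residues=residues,
            alphabet=alph,
        )
        if rec.key in seen:
            raise ParseError(f"{path}: duplicate record {'|'.join(map(str, rec.key))}")
        seen.add(rec.key)
        records.append(rec)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    entries = [
        SeqRecord(
            Seq(r.residues),
            id=f"{r.organism_id}|{r.marker_id}|{r.copy_index}",
            description="",
        )
        for r in records
    ]
    SeqIO.write(entries, str(path), "fasta")


# ---------------------------------------------------------------------------
# Network edge lists


def read_network_tsv(path: str | Path, organism_id: str | None = None) -> MetabolicNetwork:
    """Parse a two-column metabolite edge list into an undirected simple graph.

    Duplicate lines and (u,v)/(v,u) repeats collapse to a single edge;
    self-loops are dropped with a warning; ``NODE\\t<id>`` lines declare
    isolated metabolites.
    """
    path = Path(path)
    org = organism_id or path.stem
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 tab-separated fields")
            u, v = fields
            if u == "NODE":
                nodes.add(v)
                continue
            if u == v:
                log.warning("%s:%d: self-loop on %r dropped", path, lineno, u)
                nodes.add(u)
                continue
            nodes.update((u, v))
            edges.add((u, v) if u <= v else (v, u))
    if not nodes:
        raise ParseError(f"{path}: network file declares no metabolites")
    return MetabolicNetwork(organism_id=org, nodes=nodes, edges=edges)


def write_network_tsv(net: MetabolicNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# metabolic network of {net.organism_id}\n")
        covered: set[str] = set()
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{v}\n")
            covered.update((u, v))
        for node in sorted(net.nodes - covered):
            fh.write(f"NODE\t{node}\n")


# ---------------------------------------------------------------------------
# Newick


def newick_string(d: Dendrogram) -> str:
    """Serialize a dendrogram with branch lengths = height differences."""

    def fmt(node: DendroNode, parent_height: float) -> str:
        bl = parent_height - node.height
        if node.is_leaf:
            return f"{node.label}:{bl:.10g}"
        inner = ",".join(fmt(c, node.height) for c in node.children)
        return f"({inner}):{bl:.10g}"

    root = d.root
    inner = ",".join(fmt(c, root.height) for c in root.children)
    return f"({inner});"


def write_newick(d: Dendrogram, path: str | Path) -> None:
    Path(path).write_text(newick_string(d) + "\n", encoding="utf-8")


def _from_dendropy(node: "dendropy.Node") -> tuple[DendroNode, float]:
    """Convert a dendropy node; returns (node, max distance to a leaf below)."""
    if node.is_leaf():
        return DendroNode(height=0.0, label=node.taxon.label), 0.0
    children = []
    depth = 0.0
    for ch in node.child_nodes():
        sub, subdepth = _from_dendropy(ch)
        bl = ch.edge.length if ch.edge.length is not None else 0.0
        children.append(sub)
        depth = max(depth, subdepth + bl)
    return DendroNode(height=depth, label=None, children=children), depth


def read_newick(path: str | Path) -> Dendrogram:
    """Parse Newick into a dendrogram.

    Node heights are reconstructed as the maximum branch-length distance to a
    descendant leaf; for the ultrametric trees this toolkit writes, this
    inverts :func:`write_newick` exactly.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:
        raise ParseError(f"{path}: invalid Newick: {exc}") from exc
    root, _ = _from_dendropy(tree.seed_node)
    d = Dendrogram(root=root)
    d.validate()
    return d


# ---------------------------------------------------------------------------
# Ensemble files


def read_ensemble_file(path: str | Path) -> EnsembleSpec:
    """One organism set per non-comment line, whitespace-separated codes."""
    path = Path(path)
    sets: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            codes = line.split()
            if len(set(codes)) != len(codes):
                raise ParseError(f"{path}:{lineno}: duplicate organism code in set")
            sets.append(codes)
    if not sets:
        log.warning("%s: empty ensemble file", path)
        return EnsembleSpec(sets=[])
    return EnsembleSpec(sets=sets)


def write_ensemble_file(spec: EnsembleSpec, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in spec.sets:
            fh.write(" ".join(s) + "\n")


# ---------------------------------------------------------------------------
# Distance matrices


def write_distance_tsv(D: DistanceMatrix, path: str | Path) -> None:
    """Write the full symmetric matrix with header row and column."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t" + "\t".join(D.labels) + "\n")
        for i, lab in enumerate(D.labels):
            row = "\t".join(f"{D.values[i, j]:.12g}" for j in range(D.n))
            fh.write(f"{lab}\t{row}\n")


def read_distance_tsv(path: str | Path) -> DistanceMatrix:
    """Read a labeled square matrix, verifying symmetry and zero diagonal."""
    path = Path(path)
    lines = [
        ln for ln in path.read_text(encoding="utf-8").splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise ParseError(f"{path}: empty distance matrix file")
    header = lines[0].split("\t")
    labels = header[1:] if header[0] == "" else header
    n = len(labels)
    if len(lines) != n + 1:
        raise ParseError(f"{path}: expected {n} data rows, found {len(lines) - 1}")
    vals = np.zeros((n, n))
    for i, ln in enumerate(lines[1:]):
        fields = ln.split("\t")
        if len(fields) != n + 1:
            raise ParseError(f"{path}: row {i + 1} has {len(fields) - 1} values, expected {n}")
        if fields[0] != labels[i]:
            raise ParseError(
                f"{path}: row label {fields[0]!r} does not match column label {labels[i]!r}"
            )
        try:
            vals[i] = [float(x) for x in fields[1:]]
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric entry in row {i + 1}") from exc
    if np.any(vals < 0):
        raise ParseError(f"{path}: negative distance entries")
    if np.max(np.abs(vals - vals.T)) > SYMMETRY_TOL:
        raise ParseError(f"{path}: matrix asymmetric beyond {SYMMETRY_TOL}")
    if np.any(np.abs(np.diag(vals)) > 0):
        raise ParseError(f"{path}: non-zero diagonal")
    return DistanceMatrix(labels=labels, values=vals)
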