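"""Domain types and file I/O for the drug-disease heterogeneous network.

The network couples two node families -- drugs and diseases -- through four
similarity views and one binary association matrix:

* ``C`` chemical view: Tanimoto similarity of drug substructure fingerprints,
* ``T`` therapeutic view: averaged local-alignment similarity of the protein
  targets of each drug pair,
* ``M`` semantic view: shared-ancestry similarity of disease terms in a
  rooted ontology DAG,
* ``A`` target view: Jaccard similarity of disease target-gene sets.

All matrices carry explicit, ordered identifier vectors; joins between
matrices are by token, never by position.  Files are UTF-8 TSV with a header
row; matrix files carry identifiers in the first row and column.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import (
    AcyclicityError,
    DimensionError,
    DuplicateKeyError,
    FormatError,
    ResolutionError,
)

VIEWS_DRUG = ("C", "T")
VIEWS_DISEASE = ("M", "A")
VIEWS = VIEWS_DRUG + VIEWS_DISEASE

#: views whose measure is reflexive, so a unit diagonal is enforced.  The
#: therapeutic view excludes self-pairs of identical targets, so its
#: diagonal is left as computed.
_UNIT_DIAGONAL_VIEWS = frozenset({"C", "M", "A"})


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class DrugRecord:
    """One drug: identifier, substructure fingerprint, known target ids."""

    drug_id: str
    fingerprint: np.ndarray  # uint8 0/1 vector, fixed length per registry
    target_ids: frozenset[str] = frozenset()

    def __post_init__(self):
        fp = np.asarray(self.fingerprint, dtype=np.uint8)
        if fp.ndim != 1:
            raise FormatError(f"fingerprint of {self.drug_id!r} must be 1-D")
        if not np.isin(fp, (0, 1)).all():
            raise FormatError(f"fingerprint of {self.drug_id!r} must be 0/1")
        self.fingerprint = fp
        self.target_ids = frozenset(self.target_ids)


@dataclass
class DiseaseRecord:
    """One disease: identifier, its ontology term, known target ids."""

    disease_id: str
    dag_node: str
    target_ids: frozenset[str] = frozenset()

    def __post_init__(self):
        self.target_ids = frozenset(self.target_ids)


class DiseaseDAG:
    """Rooted directed acyclic graph of ontology terms.

    Edges point parent -> child.  The ancestor closure ``N(s)`` of a term
    contains the term itself plus every ancestor reachable against edge
    direction.
    """

    def __init__(self, edges: Iterable[tuple[str, str]], nodes: Iterable[str] = ()):
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        if g.number_of_nodes() == 0:
            raise FormatError("DAG has no nodes")
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise AcyclicityError(f"ontology edges contain a cycle: {cycle}")
        self._g = g
        self.roots = tuple(sorted(n for n in g.nodes if g.in_degree(n) == 0))

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self._g.nodes)

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(self._g.edges)

    def __contains__(self, term: str) -> bool:
        return term in self._g

    def children(self, term: str) -> tuple[str, ...]:
        return tuple(self._g.successors(term))

    def parents(self, term: str) -> tuple[str, ...]:
        return tuple(self._g.predecessors(term))

    def closure(self, term: str) -> frozenset[str]:
        """Ancestor closure ``N(term)``: the term plus all its ancestors."""
        if term not in self._g:
            raise ResolutionError("ontology term", [term])
        return frozenset(nx.ancestors(self._g, term)) | {term}


@dataclass
class SimilarityMatrix:
    """Square symmetric [0, 1] similarity matrix over one node family."""

    view: str
    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.ids = tuple(self.ids)
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise DimensionError(
                f"similarity payload {v.shape} does not match {n} ids"
            )
        if self.view not in VIEWS:
            raise FormatError(f"unknown view tag {self.view!r}")
        if len(set(self.ids)) != n:
            raise DuplicateKeyError("duplicate ids in similarity matrix")
        if n and not np.allclose(v, v.T, atol=1e-9, rtol=0.0):
            raise FormatError(f"view {self.view}: matrix is not symmetric")
        if n and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
            raise FormatError(
                f"view {self.view}: entries outside [0, 1] "
                f"(min {v.min():.3g}, max {v.max():.3g})"
            )
        if n and self.view in _UNIT_DIAGONAL_VIEWS:
            if not np.allclose(np.diag(v), 1.0, atol=1e-9):
                raise FormatError(f"view {self.view}: diagonal must be 1")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class AssociationMatrix:
    """Binary drug x disease association labels with aligned id axes."""

    drug_ids: tuple[str, ...]
    disease_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.drug_ids = tuple(self.drug_ids)
        self.disease_ids = tuple(self.disease_ids)
        v = np.asarray(self.values)
        if v.shape != (len(self.drug_ids), len(self.disease_ids)):
            raise DimensionError(
                f"association payload {v.shape} does not match id axes "
                f"({len(self.drug_ids)} x {len(self.disease_ids)})"
            )
        if v.size and not np.isin(v, (0, 1)).all():
            raise FormatError("association entries must be 0/1")
        self.values = v.astype(np.int8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class HeterogeneousNetwork:
    """The four similarity views plus the association labels, id-aligned."""

    G_C: SimilarityMatrix
    G_T: SimilarityMatrix
    G_M: SimilarityMatrix
    G_A: SimilarityMatrix
    assoc: AssociationMatrix

    def __post_init__(self):
        if self.G_C.view != "C" or self.G_T.view != "T":
            raise FormatError("drug views must be tagged C and T")
        if self.G_M.view != "M" or self.G_A.view != "A":
            raise FormatError("disease views must be tagged M and A")
        if not (self.G_C.ids == self.G_T.ids == self.assoc.drug_ids):
            raise FormatError("drug id order differs across matrices")
        if not (self.G_M.ids == self.G_A.ids == self.assoc.disease_ids):
            raise FormatError("disease id order differs across matrices")

    @property
    def drug_ids(self) -> tuple[str, ...]:
        return self.assoc.drug_ids

    @property
    def disease_ids(self) -> tuple[str, ...]:
        return self.assoc.disease_ids

    def drug_view(self, tag: str) -> SimilarityMatrix:
        return {"C": self.G_C, "T": self.G_T}[tag]

    def disease_view(self, tag: str) -> SimilarityMatrix:
        return {"M": self.G_M, "A": self.G_A}[tag]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_tsv(path) -> tuple[list[str], list[list[str]]]:
    with open(path, encoding="utf-8", newline="") as fh:
        rows = [row for row in csv.reader(fh, delimiter="\t") if row]
    if not rows:
        raise FormatError(f"{path}: empty file (header row required)")
    return rows[0], rows[1:]


def read_fingerprints(path, backend=None) -> dict[str, DrugRecord]:
    """Read a drug fingerprint table into an ordered registry.

    Expected columns: ``drug_id`` plus either ``fingerprint`` (a 0/1
    string of uniform length) or ``smiles``.  SMILES rows require a
    fingerprinting ``backend`` callable (``smiles -> 0/1 array``); the
    bundled :func:`maccs_backend` uses RDKit when available.
    """
    header, rows = _read_tsv(path)
    cols = {name: i for i, name in enumerate(header)}
    if "drug_id" not in cols:
        raise FormatError(f"{path}: missing 'drug_id' column")
    if "fingerprint" not in cols and "smiles" not in cols:
        raise FormatError(f"{path}: need a 'fingerprint' or 'smiles' column")

    registry: dict[str, DrugRecord] = {}
    fp_len = None
    for row in rows:
        drug_id = row[cols["drug_id"]]
        if drug_id in registry:
            raise DuplicateKeyError(f"{path}: duplicate drug id {drug_id!r}")
        if "fingerprint" in cols and row[cols["fingerprint"]]:
            bits = row[cols["fingerprint"]]
            if set(bits) - {"0", "1"}:
                raise FormatError(f"{path}: non-binary fingerprint for {drug_id!r}")
            fp = np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0")
        else:
            if backend is None:
                raise FormatError(
                    f"{path}: row {drug_id!r} provides SMILES only and no "
                    "fingerprinting backend was supplied"
                )
            fp = np.asarray(backend(row[cols["smiles"]]), dtype=np.uint8)
        if fp_len is None:
            fp_len = fp.size
        elif fp.size != fp_len:
            raise FormatError(
                f"{path}: fingerprint of {drug_id!r} has length {fp.size}, "
                f"expected {fp_len}"
            )
        registry[drug_id] = DrugRecord(drug_id, fp)
    return registry


def maccs_backend(smiles: str) -> np.ndarray:
    """SMILES -> MACCS key bit vector via RDKit (optional dependency)."""
    from rdkit import Chem
    from rdkit.Chem import MACCSkeys

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FormatError(f"unparseable SMILES: {smiles!r}")
    return np.asarray(MACCSkeys.GenMACCSKeys(mol), dtype=np.uint8)


def read_dag(path, extra_nodes: Iterable[str] = ()) -> DiseaseDAG:
    """Read a parent-child edge TSV (columns ``parent``, ``child``).

    Rows with an empty ``child`` cell declare isolated terms; additional
    isolated terms may be passed via ``extra_nodes``.
    """
    header, rows = _read_tsv(path)
    if len(header) < 2 or header[0] != "parent" or header[1] != "child":
        raise FormatError(f"{path}: expected header 'parent\\tchild'")
    edges, nodes = [], list(extra_nodes)
    for row in rows:
        parent = row[0]
        child = row[1] if len(row) > 1 else ""
        if child:
            edges.append((parent, child))
        else:
            nodes.append(parent)
    return DiseaseDAG(edges, nodes)


def read_diseases(path, dag: DiseaseDAG) -> dict[str, DiseaseRecord]:
    """Read a disease table (columns ``disease_id``, ``dag_node``).

    Records whose term is absent from ``dag`` are rejected outright:
    dropping them silently would shrink the disease family.
    """
    header, rows = _read_tsv(path)
    cols = {name: i for i, name in enumerate(header)}
    for need in ("disease_id", "dag_node"):
        if need not in cols:
            raise FormatError(f"{path}: missing '{need}' column")
    registry: dict[str, DiseaseRecord] = {}
    missing = []
    for row in rows:
        disease_id, term = row[cols["disease_id"]], row[cols["dag_node"]]
        if disease_id in registry:
            raise DuplicateKeyError(f"{path}: duplicate disease id {disease_id!r}")
        if term not in dag:
            missing.append(term)
            continue
        registry[disease_id] = DiseaseRecord(disease_id, term)
    if missing:
        raise ResolutionError("ontology term", missing)
    return registry


def read_target_map(path, id_column: str) -> dict[str, frozenset[str]]:
    """Read an entity -> target mapping TSV (columns ``<id_column>``, ``target_id``)."""
    header, rows = _read_tsv(path)
    cols = {name: i for i, name in enumerate(header)}
    for need in (id_column, "target_id"):
        if need not in cols:
            raise FormatError(f"{path}: missing '{need}' column")
    out: dict[str, set[str]] = {}
    for row in rows:
        out.setdefault(row[cols[id_column]], set()).add(row[cols["target_id"]])
    return {k: frozenset(v) for k, v in out.items()}


def attach_targets(registry: Mapping, target_map: Mapping[str, frozenset[str]]):
    """Return a copy of a drug/disease registry with target sets attached."""
    out = {}
    for key, rec in registry.items():
        targets = frozenset(target_map.get(key, frozenset()))
        if isinstance(rec, DrugRecord):
            out[key] = DrugRecord(rec.drug_id, rec.fingerprint, targets)
        else:
            out[key] = DiseaseRecord(rec.disease_id, rec.dag_node, targets)
    return out


def read_associations(
    path, drug_ids: Sequence[str], disease_ids: Sequence[str]
) -> AssociationMatrix:
    """Read known association pairs (columns ``drug_id``, ``disease_id``).

    Repeated pairs collapse to a single 1; ids must resolve against the
    supplied registries.
    """
    header, rows = _read_tsv(path)
    cols = {name: i for i, name in enumerate(header)}
    for need in ("drug_id", "disease_id"):
        if need not in cols:
            raise FormatError(f"{path}: missing '{need}' column")
    gi = {d: i for i, d in enumerate(drug_ids)}
    si = {s: i for i, s in enumerate(disease_ids)}
    values = np.zeros((len(drug_ids), len(disease_ids)), dtype=np.int8)
    bad = [
        row[cols["drug_id"]]
        for row in rows
        if row[cols["drug_id"]] not in gi
    ] + [
        row[cols["disease_id"]]
        for row in rows
        if row[cols["disease_id"]] not in si
    ]
    if bad:
        raise ResolutionError("drug/disease", bad)
    for row in rows:
        values[gi[row[cols["drug_id"]]], si[row[cols["disease_id"]]]] = 1
    return AssociationMatrix(tuple(drug_ids), tuple(disease_ids), values)


# ---------------------------------------------------------------------------
# matrix round-trip
# ---------------------------------------------------------------------------

_SIM_TAG = "similarity"
_ASSOC_TAG = "association"


def write_matrix(matrix: SimilarityMatrix | AssociationMatrix, path) -> None:
    """Write a matrix as TSV: tag cell + column ids, then row id + values."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        if isinstance(matrix, SimilarityMatrix):
            w.writerow([f"{_SIM_TAG}:{matrix.view}", *matrix.ids])
            for rid, row in zip(matrix.ids, matrix.values):
                w.writerow([rid, *(repr(float(x)) for x in row)])
        else:
            w.writerow([_ASSOC_TAG, *matrix.disease_ids])
            for rid, row in zip(matrix.drug_ids, matrix.values):
                w.writerow([rid, *(str(int(x)) for x in row)])


def read_matrix(path) -> SimilarityMatrix | AssociationMatrix:
    """Inverse of :func:`write_matrix`; validates all type invariants."""
    header, rows = _read_tsv(path)
    tag, col_ids = header[0], tuple(header[1:])
    row_ids = tuple(r[0] for r in rows)
    try:
        values = np.array([[float(x) for x in r[1:]] for r in rows])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric matrix entry ({exc})") from exc
    if values.size and values.shape[1] != len(col_ids):
        raise FormatError(f"{path}: ragged matrix rows")
    if tag.startswith(f"{_SIM_TAG}:"):
        view = tag.split(":", 1)[1]
        if row_ids != col_ids:
            raise FormatError(f"{path}: similarity matrix must be square over one id set")
        return SimilarityMatrix(view, row_ids, values)
    if tag == _ASSOC_TAG:
        return AssociationMatrix(row_ids, col_ids, values)
    raise FormatError(f"{path}: unknown matrix tag {tag!r}")


def read_fasta(path) -> dict[str, str]:
    """Read target protein sequences keyed by record id."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=k, description="") for k, s in sequences.items()]
    seqio_write(records, str(path), "fasta")
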