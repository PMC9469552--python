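"""Synthetic heterogeneous-network fixtures with planted cluster structure.

The generator emulates all five raw inputs so the full pipeline can be
exercised offline:

* drugs fall into clusters sharing a prototype fingerprint (perturbed by a
  bit-flip rate) and a pool of protein targets,
* diseases in the matching cluster attach to nearby branches of a rooted
  ontology DAG and draw overlapping target sets,
* target protein sequences are random peptides, mutated within a cluster so
  local-alignment similarity is higher inside clusters than between them,
* associations are planted cluster-diagonally (drug cluster i <-> disease
  cluster i) and a noise rate flips individual cells.

Because every similarity view then carries signal about the planted
association blocks, guilt-by-association methods should recover held-out
links -- that is what the end-to-end benchmark measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .hetnet import (
    AssociationMatrix,
    DiseaseDAG,
    DiseaseRecord,
    DrugRecord,
    attach_targets,
    read_associations,
    read_dag,
    read_diseases,
    read_fasta,
    read_fingerprints,
    read_target_map,
    write_fasta,
)

_AMINO = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic network.

    Defaults give a 100-drug x 60-disease network with 5 planted clusters,
    MACCS-length fingerprints with a 5% within-cluster bit-flip rate, a
    depth-3 ontology, 30 targets of length 80 with 10% within-cluster
    mutations, and cluster-diagonal associations with 5% label noise.
    """

    n_drugs: int = 100
    n_diseases: int = 60
    n_targets: int = 30
    n_clusters: int = 5
    fingerprint_len: int = 166
    flip_rate: float = 0.05
    dag_depth: int = 3
    dag_branching: int = 2
    rank: int | None = None  # planted cluster pairings; default n_clusters
    noise_rate: float = 0.05
    seq_len: int = 80
    mutation_rate: float = 0.10
    targets_per_drug: int = 3
    targets_per_disease: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters > min(self.n_drugs, self.n_diseases):
            raise ConfigError("n_clusters must be <= min(n_drugs, n_diseases)")
        if not 0 <= self.noise_rate < 0.5:
            raise ConfigError("noise rate must be in [0, 0.5)")
        if not 0 <= self.flip_rate <= 1:
            raise ConfigError("flip rate must be in [0, 1]")
        if self.rank is not None and not 1 <= self.rank <= self.n_clusters:
            raise ConfigError("rank must be in [1, n_clusters]")
        if self.n_targets < self.n_clusters:
            raise ConfigError("need at least one target per cluster")


@dataclass
class SyntheticBundle:
    """Everything :func:`generate` plants, including the hidden labels."""

    drugs: dict[str, DrugRecord]
    diseases: dict[str, DiseaseRecord]
    dag: DiseaseDAG
    target_sequences: dict[str, str]
    assoc: AssociationMatrix
    drug_clusters: np.ndarray
    disease_clusters: np.ndarray
    clean_assoc: AssociationMatrix = None  # pre-noise planted labels


def _cluster_assignment(n: int, k: int) -> np.ndarray:
    # contiguous, near-equal blocks: drug/disease i belongs to cluster i*k//n
    return (np.arange(n) * k) // n


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = _AMINO[rng.integers(len(_AMINO))]
    return "".join(chars)


def generate(spec: SyntheticSpec) -> SyntheticBundle:
    """Draw one bundle; byte-identical for identical specs."""
    rng = np.random.default_rng(spec.seed)
    k = spec.n_clusters
    drug_clusters = _cluster_assignment(spec.n_drugs, k)
    disease_clusters = _cluster_assignment(spec.n_diseases, k)

    # --- targets: per-cluster prototype peptides with point mutations -----
    target_cluster = _cluster_assignment(spec.n_targets, k)
    prototypes_seq = [
        "".join(_AMINO[i] for i in rng.integers(len(_AMINO), size=spec.seq_len))
        for _ in range(k)
    ]
    target_ids = [f"t{i:03d}" for i in range(spec.n_targets)]
    target_sequences = {
        tid: _mutate(prototypes_seq[target_cluster[i]], spec.mutation_rate, rng)
        for i, tid in enumerate(target_ids)
    }
    cluster_targets = [
        [target_ids[i] for i in range(spec.n_targets) if target_cluster[i] == c]
        for c in range(k)
    ]

    # --- drugs: prototype fingerprints + cluster target subsets -----------
    prototypes_fp = rng.integers(0, 2, size=(k, spec.fingerprint_len), dtype=np.uint8)
    drugs: dict[str, DrugRecord] = {}
    for i in range(spec.n_drugs):
        c = drug_clusters[i]
        flips = rng.random(spec.fingerprint_len) < spec.flip_rate
        fp = np.where(flips, 1 - prototypes_fp[c], prototypes_fp[c]).astype(np.uint8)
        pool = cluster_targets[c]
        n_pick = min(spec.targets_per_drug, len(pool))
        picked = rng.choice(len(pool), size=n_pick, replace=False)
        drugs[f"d{i:03d}"] = DrugRecord(
            f"d{i:03d}", fp, frozenset(pool[j] for j in picked)
        )

    # --- ontology DAG: one branch per cluster under a shared root ---------
    edges: list[tuple[str, str]] = []
    leaf_pool: list[list[str]] = []
    for c in range(k):
        branch = f"B{c}"
        edges.append(("ROOT", branch))
        level = [branch]
        for depth in range(1, spec.dag_depth + 1):
            nxt = []
            for node in level:
                for b in range(spec.dag_branching):
                    child = f"{node}.{depth}{b}"
                    edges.append((node, child))
                    nxt.append(child)
            level = nxt
        leaf_pool.append(level)

    diseases: dict[str, DiseaseRecord] = {}
    disease_terms: list[tuple[str, str]] = []
    for j in range(spec.n_diseases):
        c = disease_clusters[j]
        parent = leaf_pool[c][rng.integers(len(leaf_pool[c]))]
        term = f"D{j:03d}"
        edges.append((parent, term))
        pool = cluster_targets[c]
        n_pick = min(spec.targets_per_disease, len(pool))
        picked = rng.choice(len(pool), size=n_pick, replace=False)
        diseases[f"s{j:03d}"] = DiseaseRecord(
            f"s{j:03d}", term, frozenset(pool[i] for i in picked)
        )
        disease_terms.append((term, parent))
    dag = DiseaseDAG(edges)

    # --- associations: cluster-diagonal blocks + cell-flip noise ----------
    rank = spec.rank if spec.rank is not None else k
    clean = np.zeros((spec.n_drugs, spec.n_diseases), dtype=np.int8)
    for c in range(rank):
        clean[np.ix_(drug_clusters == c, disease_clusters == c)] = 1
    noise = rng.random(clean.shape) < spec.noise_rate
    noisy = np.where(noise, 1 - clean, clean).astype(np.int8)

    drug_ids = tuple(drugs)
    disease_ids = tuple(diseases)
    return SyntheticBundle(
        drugs=drugs,
        diseases=diseases,
        dag=dag,
        target_sequences=target_sequences,
        assoc=AssociationMatrix(drug_ids, disease_ids, noisy),
        drug_clusters=drug_clusters,
        disease_clusters=disease_clusters,
        clean_assoc=AssociationMatrix(drug_ids, disease_ids, clean),
    )


# ---------------------------------------------------------------------------
# fixture files
# ---------------------------------------------------------------------------


def write_fixture(bundle: SyntheticBundle, directory) -> dict[str, Path]:
    """Write the bundle in the standard file dialects; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        name: directory / fname
        for name, fname in [
            ("fingerprints", "fingerprints.tsv"),
            ("dag", "dag.tsv"),
            ("diseases", "diseases.tsv"),
            ("drug_targets", "drug_targets.tsv"),
            ("disease_targets", "disease_targets.tsv"),
            ("targets", "targets.fasta"),
            ("associations", "associations.tsv"),
        ]
    }
    with open(paths["fingerprints"], "w", encoding="utf-8") as fh:
        fh.write("drug_id\tfingerprint\n")
        for rec in bundle.drugs.values():
            fh.write(f"{rec.drug_id}\t{''.join(map(str, rec.fingerprint))}\n")
    with open(paths["dag"], "w", encoding="utf-8") as fh:
        fh.write("parent\tchild\n")
        for parent, child in bundle.dag.edges:
            fh.write(f"{parent}\t{child}\n")
    with open(paths["diseases"], "w", encoding="utf-8") as fh:
        fh.write("disease_id\tdag_node\n")
        for rec in bundle.diseases.values():
            fh.write(f"{rec.disease_id}\t{rec.dag_node}\n")
    for name, registry, col in (
        ("drug_targets", bundle.drugs, "drug_id"),
        ("disease_targets", bundle.diseases, "disease_id"),
    ):
        with open(paths[name], "w", encoding="utf-8") as fh:
            fh.write(f"{col}\ttarget_id\n")
            for key, rec in registry.items():
                for tid in sorted(rec.target_ids):
                    fh.write(f"{key}\t{tid}\n")
    write_fasta(bundle.target_sequences, paths["targets"])
    with open(paths["associations"], "w", encoding="utf-8") as fh:
        fh.write("drug_id\tdisease_id\n")
        rows, cols = np.nonzero(bundle.assoc.values)
        for i, j in zip(rows, cols):
            fh.write(f"{bundle.assoc.drug_ids[i]}\t{bundle.assoc.disease_ids[j]}\n")
    return paths


def load_fixture(directory) -> SyntheticBundle:
    """Re-load fixture files written by :func:`write_fixture`.

    Cluster labels and the pre-noise matrix are not stored in the standard
    dialects, so the returned bundle carries ``None`` for them.
    """
    directory = Path(directory)
    drugs = read_fingerprints(directory / "fingerprints.tsv")
    dag = read_dag(directory / "dag.tsv")
    diseases = read_diseases(directory / "diseases.tsv", dag)
    drugs = attach_targets(drugs, read_target_map(directory / "drug_targets.tsv", "drug_id"))
    diseases = attach_targets(
        diseases, read_target_map(directory / "disease_targets.tsv", "disease_id")
    )
    assoc = read_associations(
        directory / "associations.tsv", tuple(drugs), tuple(diseases)
    )
    return SyntheticBundle(
        drugs=drugs,
        diseases=diseases,
        dag=dag,
        target_sequences=read_fasta(directory / "targets.fasta"),
        assoc=assoc,
        drug_clusters=None,
        disease_clusters=None,
        clean_assoc=None,
    )
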