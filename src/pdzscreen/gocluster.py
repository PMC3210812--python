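"""Clustering proteins by Gene Ontology annotation similarity.

The similarity between two proteins within one GO aspect (BP, MF or CC)
is the simUI graph measure: the size of the intersection of their induced
annotation sets (direct terms plus all is_a/part_of ancestors up to the
aspect root) divided by the size of the union.  Similarities are turned
into dissimilarities (1 - sim), clustered with Partitioning Around
Medoids (deterministic BUILD + SWAP), the number of clusters k selected
by the average silhouette width, and the result exported as a thresholded
protein network (edges with dissimilarity strictly above 0.4 for BP/MF or
0.3 for CC are removed, matching the study's visualisation rule).
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import obonet
import pandas as pd

from .errors import (FormatError, IntegrityError, ProcessingError, UsageError,
                     ValidationError)

logger = logging.getLogger(__name__)

ASPECTS = ("BP", "MF", "CC")
_NAMESPACE_TO_ASPECT = {"biological_process": "BP", "molecular_function": "MF",
                        "cellular_component": "CC"}
_GAF_ASPECT = {"P": "BP", "F": "MF", "C": "CC"}

#: Default dissimilarity thresholds for network export, per aspect.
EDGE_THRESHOLDS = {"BP": 0.4, "MF": 0.4, "CC": 0.3}

DEFAULT_RELATIONS = ("is_a", "part_of")


# ---------------------------------------------------------------------------
# ontology and annotations
# ---------------------------------------------------------------------------

class GoDag:
    """An acyclic GO term graph with per-namespace roots.

    Wraps the networkx MultiDiGraph produced by obonet (edges point
    child -> parent, keyed by relation type).
    """

    def __init__(self, graph: nx.MultiDiGraph):
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise IntegrityError(f"ontology contains a cycle through {cycle[0][0]}")
        self.graph = graph
        self.namespace: dict[str, str] = {
            t: data.get("namespace", "") for t, data in graph.nodes(data=True)
        }
        self.roots: dict[str, str] = {}
        for term in graph.nodes:
            if graph.out_degree(term) == 0:
                aspect = _NAMESPACE_TO_ASPECT.get(self.namespace[term])
                if aspect:
                    if aspect in self.roots:
                        raise IntegrityError(
                            f"multiple roots in aspect {aspect}: "
                            f"{self.roots[aspect]} and {term}"
                        )
                    self.roots[aspect] = term

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def aspect_of(self, term: str) -> str | None:
        return _NAMESPACE_TO_ASPECT.get(self.namespace.get(term, ""))

    def ancestors(self, term: str,
                  relations: Sequence[str] = DEFAULT_RELATIONS) -> set[str]:
        """All terms reachable from ``term`` along the given relations."""
        seen: set[str] = set()
        stack = [term]
        rel = set(relations)
        while stack:
            cur = stack.pop()
            for _child, parent, key in self.graph.out_edges(cur, keys=True):
                if key in rel and parent not in seen:
                    seen.add(parent)
                    stack.append(parent)
        return seen


def parse_obo(source: str | Path | io.TextIOBase) -> GoDag:
    """Parse an OBO 1.2 ontology; obsolete terms are skipped."""
    if isinstance(source, io.TextIOBase):
        text = source.read()
    else:
        text = Path(source).read_text()
    n_obsolete = text.count("is_obsolete: true")
    if n_obsolete:
        logger.warning("skipping %d obsolete term(s)", n_obsolete)
    graph = obonet.read_obo(io.StringIO(text), ignore_obsolete=True)
    return GoDag(graph)


@dataclass
class AnnotationSet:
    """Direct term annotations per protein, split by GO aspect."""

    direct: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    def add(self, protein_id: str, aspect: str, term: str) -> None:
        self.direct.setdefault(aspect, {}).setdefault(protein_id, set()).add(term)

    def terms(self, protein_id: str, aspect: str) -> set[str]:
        return self.direct.get(aspect, {}).get(protein_id, set())

    def proteins(self, aspect: str) -> list[str]:
        return sorted(self.direct.get(aspect, {}))


def read_gaf(source: str | Path | io.TextIOBase, dag: GoDag) -> AnnotationSet:
    """Read GAF 2.x annotations against a loaded ontology.

    NOT-qualified rows are dropped; annotations to terms absent from the
    ontology are dropped with a warning; malformed rows are skipped with
    their line numbers logged, but more than 10% malformed rows is a
    format error.
    """
    if isinstance(source, io.TextIOBase):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()
    ann = AnnotationSet()
    n_data = n_bad = 0
    bad_lines: list[int] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("!"):
            continue
        n_data += 1
        cols = line.split("\t")
        if len(cols) < 15:
            n_bad += 1
            bad_lines.append(lineno)
            continue
        qualifier, go_id, aspect_letter = cols[3], cols[4], cols[8]
        protein_id = cols[1]
        if "NOT" in qualifier.split("|"):
            continue
        aspect = _GAF_ASPECT.get(aspect_letter)
        if aspect is None or not protein_id or not go_id:
            n_bad += 1
            bad_lines.append(lineno)
            continue
        if go_id not in dag:
            logger.warning("line %d: unknown term %s dropped", lineno, go_id)
            continue
        ann.add(protein_id, aspect, go_id)
    if bad_lines:
        logger.warning("skipped %d malformed GAF row(s) at lines %s",
                       n_bad, bad_lines[:20])
    if n_data and n_bad / n_data > 0.10:
        raise FormatError(
            f"{n_bad}/{n_data} GAF rows malformed (> 10%); refusing to continue"
        )
    return ann


# ---------------------------------------------------------------------------
# simUI
# ---------------------------------------------------------------------------

def induced_terms(protein_id: str, aspect: str, dag: GoDag,
                  annotations: AnnotationSet,
                  relations: Sequence[str] = DEFAULT_RELATIONS) -> set[str]:
    """The protein's direct annotations plus all their ancestors."""
    direct = annotations.terms(protein_id, aspect)
    if not direct:
        raise ValidationError(f"{protein_id}: no {aspect} annotation")
    induced = set(direct)
    for term in direct:
        induced |= dag.ancestors(term, relations)
    return induced


def simui_similarity(protein_a: str, protein_b: str, aspect: str, dag: GoDag,
                     annotations: AnnotationSet,
                     relations: Sequence[str] = DEFAULT_RELATIONS) -> float:
    """simUI: |induced_a n induced_b| / |induced_a u induced_b|."""
    a = induced_terms(protein_a, aspect, dag, annotations, relations)
    b = induced_terms(protein_b, aspect, dag, annotations, relations)
    return len(a & b) / len(a | b)


@dataclass
class DissimilarityMatrix:
    """Symmetric, zero-diagonal d = 1 - simUI matrix over an ID order."""

    ids: list[str]
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def dissimilarity_matrix(proteins: Sequence[str], aspect: str, dag: GoDag,
                         annotations: AnnotationSet,
                         relations: Sequence[str] = DEFAULT_RELATIONS,
                         ) -> DissimilarityMatrix:
    """Pairwise 1 - simUI over the annotated subset of ``proteins``.

    Proteins lacking any annotation in the aspect are excluded (logged);
    fewer than three annotated proteins is a processing error.
    """
    annotated, skipped = [], []
    for p in proteins:
        (annotated if annotations.terms(p, aspect) else skipped).append(p)
    if skipped:
        logger.info("excluded %d unannotated protein(s) in %s: %s",
                    len(skipped), aspect, skipped[:10])
    if len(annotated) < 3:
        raise ProcessingError(
            f"need >= 3 annotated proteins in {aspect}, got {len(annotated)}"
        )
    induced = {p: induced_terms(p, aspect, dag, annotations, relations)
               for p in annotated}
    n = len(annotated)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        a, b = induced[annotated[i]], induced[annotated[j]]
        sim = len(a & b) / len(a | b)
        d[i, j] = d[j, i] = 1.0 - sim
    return DissimilarityMatrix(ids=list(annotated), values=d)


# ---------------------------------------------------------------------------
# PAM and silhouette
# ---------------------------------------------------------------------------

@dataclass
class ClusterSolution:
    k: int
    medoids: list[str]
    assignment: dict[str, int]
    cost: float
    avg_silhouette: float

    def labels(self, ids: Sequence[str]) -> np.ndarray:
        return np.array([self.assignment[i] for i in ids])


def _assign(d: np.ndarray, medoid_idx: Sequence[int]) -> np.ndarray:
    # nearest medoid; ties resolve to the lowest cluster index via argmin
    return np.argmin(d[:, list(medoid_idx)], axis=1)


def _cost(d: np.ndarray, medoid_idx: Sequence[int]) -> float:
    return float(d[:, list(medoid_idx)].min(axis=1).sum())


def pam(matrix: DissimilarityMatrix, k: int, seed: int | None = None,
        ) -> ClusterSolution:
    """Partitioning Around Medoids on a precomputed dissimilarity matrix.

    BUILD greedily adds the medoid that most reduces total cost (first
    medoid: the point minimising total dissimilarity); SWAP repeatedly
    applies the single medoid/non-medoid exchange with the largest strict
    cost decrease until none exists.  Fully deterministic: all ties break
    to the lowest point index; ``seed`` is accepted for interface
    compatibility but unused.
    """
    d = matrix.values
    n = len(matrix)
    if not 1 <= k <= n:
        raise UsageError(f"k must satisfy 1 <= k <= {n}, got {k}")

    # BUILD
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        nearest = d[:, medoids].min(axis=1)
        best_gain, best_cand = -math.inf, None
        for cand in range(n):
            if cand in medoids:
                continue
            gain = float(np.maximum(nearest - d[:, cand], 0.0).sum())
            if gain > best_gain + 1e-12:
                best_gain, best_cand = gain, cand
        medoids.append(best_cand)

    # SWAP (steepest descent)
    current = _cost(d, medoids)
    while True:
        best_delta, best_swap = -1e-12, None
        medoid_set = set(medoids)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoid_set:
                    continue
                trial = medoids[:mi] + [h] + medoids[mi + 1:]
                delta = current - _cost(d, trial)
                if delta > best_delta + 1e-12:
                    best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        mi, h = best_swap
        medoids[mi] = h
        current = _cost(d, medoids)

    medoids = sorted(medoids)
    labels = _assign(d, medoids)
    # medoids always belong to their own cluster
    for ci, m in enumerate(medoids):
        labels[m] = ci
    assignment = {matrix.ids[i]: int(labels[i]) for i in range(n)}
    sil = float(np.mean(silhouette_widths(d, labels))) if k > 1 else 0.0
    return ClusterSolution(k=k, medoids=[matrix.ids[m] for m in medoids],
                           assignment=assignment, cost=_cost(d, medoids),
                           avg_silhouette=sil)


def silhouette_widths(d: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-point silhouette s = (b - a) / max(a, b) on a dissimilarity
    matrix; members of singleton clusters get s = 0."""
    labels = np.asarray(labels)
    n = len(labels)
    clusters = np.unique(labels)
    s = np.zeros(n)
    if clusters.size == 1:
        return s
    for i in range(n):
        own = labels[i]
        own_mask = labels == own
        if own_mask.sum() == 1:
            s[i] = 0.0
            continue
        a = d[i, own_mask].sum() / (own_mask.sum() - 1)
        b = min(d[i, labels == c].mean() for c in clusters if c != own)
        s[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return s


def select_k(matrix: DissimilarityMatrix, k_min: int = 2,
             k_max: int | None = None,
             ) -> tuple[int, ClusterSolution, dict[int, float]]:
    """Choose k by maximising the average silhouette width over PAM runs.

    Default search range 2 .. min(15, n-1); ties go to the smaller k.
    """
    n = len(matrix)
    if k_max is None:
        k_max = min(15, n - 1)
    if not 2 <= k_min <= k_max <= n - 1:
        raise UsageError(f"invalid k range [{k_min}, {k_max}] for n={n}")
    profile: dict[int, float] = {}
    solutions: dict[int, ClusterSolution] = {}
    for k in range(k_min, k_max + 1):
        sol = pam(matrix, k)
        solutions[k] = sol
        profile[k] = sol.avg_silhouette
    best_k = max(profile, key=lambda k: (profile[k], -k))
    return best_k, solutions[best_k], profile


# ---------------------------------------------------------------------------
# network export and labelling
# ---------------------------------------------------------------------------

def cluster_network(matrix: DissimilarityMatrix, solution: ClusterSolution,
                    aspect: str, edge_threshold: float | None = None,
                    ) -> nx.Graph:
    """Build the thresholded similarity network for visualisation.

    Edges whose dissimilarity is strictly above the threshold (0.4 for
    BP/MF, 0.3 for CC by default) are removed; retained edges carry the
    dissimilarity as weight and a display width inversely related to it
    (d near 0 -> thick edge).  Every node carries its cluster index and a
    medoid flag; the node set is unaffected by the threshold.
    """
    if aspect not in ASPECTS:
        raise UsageError(f"unknown aspect {aspect!r}; expected one of {ASPECTS}")
    if edge_threshold is None:
        edge_threshold = EDGE_THRESHOLDS[aspect]
    g = nx.Graph(aspect=aspect, edge_threshold=float(edge_threshold))
    medoids = set(solution.medoids)
    for pid in matrix.ids:
        ci = solution.assignment[pid]
        g.add_node(pid, cluster=int(ci), is_medoid=bool(pid in medoids),
                   color=f"c{ci}", label=pid,
                   size=2.0 if pid in medoids else 1.0)
    n = len(matrix)
    for i, j in combinations(range(n), 2):
        d = float(matrix.values[i, j])
        if d > edge_threshold:
            continue
        width = 1.0 + 4.0 * (1.0 - d / edge_threshold) if edge_threshold > 0 else 1.0
        g.add_edge(matrix.ids[i], matrix.ids[j], dissimilarity=d, width=width)
    return g


def write_network(graph: nx.Graph, outdir: str | Path, stem: str = "network",
                  ) -> tuple[Path, Path]:
    """Write the network as GraphML and SIF (plus a SIF edge-attribute file)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    graphml = outdir / f"{stem}.graphml"
    sif = outdir / f"{stem}.sif"
    nx.write_graphml(graph, graphml)
    with open(sif, "w") as fh:
        isolated = set(graph.nodes)
        for a, b in graph.edges:
            fh.write(f"{a}\tsim\t{b}\n")
            isolated.discard(a)
            isolated.discard(b)
        for node in sorted(isolated):
            fh.write(f"{node}\n")
    return graphml, sif


def term_information_content(terms: Iterable[str], aspect: str, dag: GoDag,
                             annotations: AnnotationSet,
                             proteins: Sequence[str]) -> dict[str, float]:
    """IC(term) = -log(fraction of the clustered proteins whose induced
    set contains the term)."""
    induced = {p: induced_terms(p, aspect, dag, annotations) for p in proteins}
    n = len(proteins)
    ic = {}
    for term in terms:
        freq = sum(term in ind for ind in induced.values()) / n
        ic[term] = -math.log(freq) if freq > 0 else math.inf
    return ic


def label_cluster(solution: ClusterSolution, cluster_index: int, dag: GoDag,
                  annotations: AnnotationSet, aspect: str,
                  proteins: Sequence[str] | None = None,
                  overrides: Mapping[int, str] | None = None) -> str:
    """Label a cluster by its medoid's most informative direct term.

    The automated label is the medoid's direct annotation with the highest
    information content among the clustered proteins (the aspect root has
    IC 0 and is never chosen over a more specific term); ties break on the
    term identifier.  ``overrides`` supplies curated labels per cluster.
    """
    if overrides and cluster_index in overrides:
        return overrides[cluster_index]
    members = [p for p, c in solution.assignment.items() if c == cluster_index]
    if not members:
        raise UsageError(f"cluster {cluster_index} is empty")
    medoid = solution.medoids[cluster_index]
    direct = annotations.terms(medoid, aspect)
    if not direct:
        raise ValidationError(f"medoid {medoid}: no {aspect} annotation")
    universe = list(proteins) if proteins is not None else sorted(solution.assignment)
    ic = term_information_content(direct, aspect, dag, annotations, universe)
    best = max(sorted(direct), key=lambda t: ic[t])
    return dag.name(best)
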