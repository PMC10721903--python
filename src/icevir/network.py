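"""Gene-sharing network construction and taxa demarcation.

Protein clusters (PCs) come from MCL on the all-vs-all protein similarity
graph (E-value <= 1e-5, bitscore >= 50). Genome pairs are scored by the
hypergeometric tail probability of their shared-PC count; MCL on pairs
scoring >= 1 yields viral clusters (VCs, >= 2 members). Intergenomic
similarity supports ICTV-style species/genus demarcation by
single-linkage clustering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import hypergeom

from .core_io import AlignmentHit


@dataclass
class MclParams:
    inflation: float = 2.0
    expansion: int = 2
    pruning: float = 1e-5
    max_iterations: int = 100
    tolerance: float = 1e-8

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")


@dataclass
class ProteinCluster:
    pc_id: str
    proteins: frozenset
    genomes: frozenset = frozenset()


@dataclass
class GenomePairScore:
    genome_a: str
    genome_b: str
    shared_pcs: int
    pvalue: float
    score: float


@dataclass
class ViralCluster:
    vc_id: str
    members: frozenset

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a VC requires >= 2 members")


def filter_protein_edges(hits: Iterable[AlignmentHit],
                         max_evalue: float = 1e-5,
                         min_bitscore: float = 50.0) -> nx.Graph:
    """Build the weighted protein graph from all-vs-all hits.

    Keeps hits with ``evalue <= max_evalue`` and ``bitscore >=
    min_bitscore``; self-hits are dropped and reciprocal hits merged
    keeping the maximum bitscore as the edge weight.
    """
    g = nx.Graph()
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        if h.evalue > max_evalue or h.bitscore < min_bitscore:
            continue
        w = h.bitscore
        if g.has_edge(h.query_id, h.subject_id):
            if w > g[h.query_id][h.subject_id]["weight"]:
                g[h.query_id][h.subject_id]["weight"] = w
        else:
            g.add_edge(h.query_id, h.subject_id, weight=w)
    return g


def mcl(graph: nx.Graph, params: MclParams = MclParams()) -> list[frozenset]:
    """Markov clustering on an undirected weighted graph.

    Self-loops of weight 1 are added, columns are normalized, and the
    expansion (matrix power) / inflation (entrywise power + renormalize)
    loop runs with pruning of entries below ``params.pruning`` until the
    matrix change falls below ``params.tolerance`` or the iteration limit
    is hit (in which case a warning flag is attached to the clustering).
    Clusters are the connected components of the limit matrix's nonzero
    pattern, so every node lands in exactly one cluster.
    """
    nodes = sorted(graph.nodes())
    if not nodes:
        return []
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    rows, cols, vals = [], [], []
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w < 0:
            raise ValueError("MCL requires non-negative edge weights")
        rows += [idx[u], idx[v]]
        cols += [idx[v], idx[u]]
        vals += [w, w]
    # self-loops at each node's max incident weight keep heavy edges from
    # oscillating the flow into per-node attractors
    loop = {i: 1.0 for i in range(n)}
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        loop[idx[u]] = max(loop[idx[u]], w)
        loop[idx[v]] = max(loop[idx[v]], w)
    for i in range(n):
        rows.append(i)
        cols.append(i)
        vals.append(loop[i])
    m = sparse.csc_matrix((vals, (rows, cols)), shape=(n, n))
    m = _normalize_columns(m)

    converged = False
    for _ in range(params.max_iterations):
        prev = m.copy()
        m = m ** params.expansion
        m = m.power(params.inflation)
        m.data[m.data < params.pruning] = 0.0
        m.eliminate_zeros()
        m = _normalize_columns(m)
        diff = abs(m - prev)
        if diff.nnz == 0 or diff.max() < params.tolerance:
            converged = True
            break

    clusters = _read_clusters(m, nodes)
    if not converged:
        import logging
        logging.getLogger("icevir").warning(
            "MCL did not converge in %d iterations", params.max_iterations)
    return clusters


def _normalize_columns(m: sparse.csc_matrix) -> sparse.csc_matrix:
    sums = np.asarray(m.sum(axis=0)).ravel()
    sums[sums == 0] = 1.0
    d = sparse.diags(1.0 / sums)
    return (m @ d).tocsc()


def _read_clusters(m: sparse.csc_matrix, nodes: Sequence) -> list[frozenset]:
    sym = m + m.T
    n_comp, labels = connected_components(sym, directed=False)
    out: dict[int, set] = {}
    for node, lab in zip(nodes, labels):
        out.setdefault(lab, set()).add(node)
    return sorted((frozenset(s) for s in out.values()), key=lambda c: sorted(c)[0])


def protein_clusters(graph: nx.Graph,
                     all_proteins: Iterable[str],
                     protein_genome: Mapping[str, str],
                     params: MclParams = MclParams()) -> list[ProteinCluster]:
    """MCL protein clusters; proteins absent from the graph become singleton PCs."""
    clusters = mcl(graph, params)
    clustered = set().union(*clusters) if clusters else set()
    for p in sorted(all_proteins):
        if p not in clustered:
            clusters.append(frozenset([p]))
    clusters.sort(key=lambda c: sorted(c)[0])
    out = []
    for i, members in enumerate(clusters):
        genomes = frozenset(protein_genome[p] for p in members if p in protein_genome)
        out.append(ProteinCluster(f"PC_{i:05d}", members, genomes))
    return out


def hypergeometric_similarity(pcs_a: int, pcs_b: int, shared: int,
                              universe: int, n_pairs: int) -> GenomePairScore:
    """Score a genome pair by shared-PC enrichment.

    ``pvalue = P[X >= shared]`` for ``X ~ Hypergeometric(universe, pcs_a,
    pcs_b)`` and ``score = -log10(pvalue * n_pairs)`` (a Bonferroni-style
    scaling over all genome pairs). The score may be negative.
    """
    if universe <= 0:
        raise ValueError("PC universe must be > 0")
    if not shared <= min(pcs_a, pcs_b) <= universe:
        raise ValueError("require shared <= min(pcs_a, pcs_b) <= universe")
    logp = hypergeom.logsf(shared - 1, universe, pcs_a, pcs_b)
    pvalue = float(np.exp(logp))
    score = float(-(logp / math.log(10) + math.log10(n_pairs)))
    return GenomePairScore("", "", shared, pvalue, score)


def genome_pair_scores(pcs: Sequence[ProteinCluster],
                       genomes: Sequence[str]) -> list[GenomePairScore]:
    """Hypergeometric scores for every genome pair sharing >= 1 PC.

    The PC universe is the number of distinct PCs across all genomes in
    the run; n_pairs is C(#genomes, 2).
    """
    profile: dict[str, set] = {g: set() for g in genomes}
    for pc in pcs:
        for g in pc.genomes:
            if g in profile:
                profile[g].add(pc.pc_id)
    universe = len({pc for s in profile.values() for pc in s})
    n_pairs = max(len(genomes) * (len(genomes) - 1) // 2, 1)
    out = []
    for a, b in combinations(sorted(genomes), 2):
        shared = len(profile[a] & profile[b])
        if shared < 1:
            continue
        s = hypergeometric_similarity(len(profile[a]), len(profile[b]),
                                      shared, universe, n_pairs)
        s.genome_a, s.genome_b = a, b
        out.append(s)
    return out


def build_vcs(scores: Iterable[GenomePairScore],
              genomes: Sequence[str],
              score_threshold: float = 1.0,
              params: MclParams = MclParams()) -> tuple[list[ViralCluster], list[str]]:
    """Viral clusters from pair scores: edge filter, MCL, size >= 2 rule.

    Returns (vcs, singletons); genomes in no VC — including edge-less
    ones — are singletons/outliers.
    """
    g = nx.Graph()
    g.add_nodes_from(genomes)
    for s in scores:
        if s.score >= score_threshold:
            g.add_edge(s.genome_a, s.genome_b, weight=s.score)
    clusters = mcl(g, params)
    vcs = [ViralCluster(f"VC_{i:04d}", c)
           for i, c in enumerate(c for c in clusters if len(c) >= 2)]
    in_vc = set().union(*(vc.members for vc in vcs)) if vcs else set()
    singletons = sorted(set(genomes) - in_vc)
    return vcs, singletons


def singleton_fraction(vcs: Sequence[ViralCluster], genomes: Sequence[str]) -> float:
    """Fraction of genomes not belonging to any VC."""
    if not genomes:
        raise ValueError("no genomes supplied")
    in_vc = set().union(*(vc.members for vc in vcs)) if vcs else set()
    return sum(1 for g in genomes if g not in in_vc) / len(genomes)


def jaccard_vc(pcs_a: Iterable[str], pcs_b: Iterable[str]) -> float:
    """Jaccard similarity of two VCs' PC sets."""
    a, b = set(pcs_a), set(pcs_b)
    if not a and not b:
        raise ValueError("both PC sets empty")
    return len(a & b) / len(a | b)


def _merge_weighted_intervals(intervals: list[tuple[int, int, float]]) -> float:
    """Sum of interval lengths weighted by identity after removing overlaps.

    Intervals are (start, end, identity_fraction), 1-based inclusive on
    one genome. Higher-identity intervals take precedence inside overlaps.
    """
    covered: list[tuple[int, int]] = []  # disjoint, sorted
    total = 0.0
    for start, end, ident in sorted(intervals, key=lambda t: (-t[2], t[0])):
        segments = [(start, end)]
        for cs, ce in covered:
            nxt = []
            for s, e in segments:
                if e < cs or s > ce:
                    nxt.append((s, e))
                    continue
                if s < cs:
                    nxt.append((s, cs - 1))
                if e > ce:
                    nxt.append((ce + 1, e))
            segments = nxt
            if not segments:
                break
        for s, e in segments:
            total += (e - s + 1) * ident
            covered.append((s, e))
        covered.sort()
    return total


def intergenomic_similarity(hits: Iterable[AlignmentHit],
                            len_a: int, len_b: int,
                            genome_a: Optional[str] = None) -> float:
    """VIRIDIC-style percent similarity between two genomes.

    ``100 * (sum of non-overlapping aligned bases, weighted by fraction
    identity) / mean(len_a, len_b)``; overlapping intervals on the query
    genome are merged before summation. No hits -> 0.
    """
    intervals = []
    for h in hits:
        if genome_a is not None and h.query_id != genome_a:
            continue
        intervals.append((h.q_start, h.q_end, h.pct_identity / 100.0))
    if not intervals:
        return 0.0
    weighted = _merge_weighted_intervals(intervals)
    return min(100.0 * weighted / ((len_a + len_b) / 2.0), 100.0)


def demarcate_taxa(similarity: pd.DataFrame,
                   species_cutoff: float = 95.0,
                   genus_cutoff: float = 70.0) -> tuple[dict, dict]:
    """Single-linkage species and genus clusterings from a similarity matrix.

    Returns (species_of, genus_of) mapping genome id -> cluster label.
    Species clusters always nest within genus clusters because the edge
    set at the higher cutoff is a subset of the lower one.
    """
    mat = similarity.to_numpy(dtype=float)
    if list(similarity.index) != list(similarity.columns):
        raise ValueError("similarity matrix index and columns differ")
    if not np.allclose(mat, mat.T, atol=1e-9):
        raise ValueError("similarity matrix must be symmetric")
    ids = list(similarity.index)

    def cluster(cutoff: float, prefix: str) -> dict:
        g = nx.Graph()
        g.add_nodes_from(ids)
        n = len(ids)
        for i in range(n):
            for j in range(i + 1, n):
                if mat[i, j] >= cutoff:
                    g.add_edge(ids[i], ids[j])
        comps = sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
        return {m: f"{prefix}_{k:04d}" for k, c in enumerate(comps) for m in c}

    return cluster(species_cutoff, "species"), cluster(genus_cutoff, "genus")


def write_vcs(vcs: Sequence[ViralCluster], singletons: Sequence[str], outdir) -> None:
    from pathlib import Path
    outdir = Path(outdir)
    rows = [{"vc_id": vc.vc_id, "genome_id": g}
            for vc in vcs for g in sorted(vc.members)]
    pd.DataFrame(rows, columns=["vc_id", "genome_id"]).to_csv(
        outdir / "vcs.tsv", sep="\t", index=False)
    (outdir / "singletons.txt").write_text("".join(f"{s}\n" for s in singletons))
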