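"""Orthologous-group construction and representative (OGR) selection.

Proteins from multiple species are compared all-vs-all with seeded local
alignment; the resulting similarity graph is partitioned by Markov
clustering (expansion + inflation to a fixed point).  One representative
protein per group — the OGR — is then chosen as the member concentrating
the most distinct associated contigs, with protein length and gene id as
tie-breaks.  Groups with no contig association at all are flagged
representative-less and excluded from downstream read binning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from . import _align
from .io_formats import SequenceRecord

logger = logging.getLogger("polygenespace")


@dataclass
class OrthoGroup:
    group_id: str
    members: list[tuple[str, str]]  # (species, gene_id)
    representative: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("OrthoGroup must have at least one member")
        if self.representative is not None and self.representative not in {
            g for _, g in self.members
        }:
            raise ValueError("representative must be a member of the group")


def all_vs_all_protein_similarity(
    proteins: Mapping[str, SequenceRecord] | Sequence[SequenceRecord],
    *,
    score_cutoff: float = 0.3,
    seed_k: int = 4,
    min_seeds: int = 2,
) -> nx.Graph:
    """Build the weighted protein similarity graph.

    Edge weight is the local alignment score normalized by the self-score
    of the shorter sequence, kept when >= ``score_cutoff``.  Pairs without
    ``min_seeds`` shared ``seed_k``-mers are never aligned (seed
    prefilter), which empirically excludes unrelated random proteins.
    """
    if not isinstance(proteins, Mapping):
        proteins = {p.id: p for p in proteins}
    if len(proteins) < 2:
        raise ValueError("need at least two proteins")
    seqs = {pid: rec.seq for pid, rec in proteins.items()}
    index = _align.PeptideIndex(seqs, k=seed_k)
    self_scores = {pid: _align.self_score(s) for pid, s in seqs.items()}
    graph = nx.Graph()
    graph.add_nodes_from(seqs)
    ids = sorted(seqs)
    for qid in ids:
        for sid in index.candidates(seqs[qid], min_seeds=min_seeds):
            if sid <= qid:
                continue
            hit = _align.align_protein_local(seqs[qid], seqs[sid])
            if hit is None:
                continue
            shorter = min(self_scores[qid], self_scores[sid])
            if shorter <= 0:
                continue
            weight = hit.score / shorter
            if weight >= score_cutoff:
                prev = graph.get_edge_data(qid, sid)
                if prev is None or weight > prev["weight"]:
                    graph.add_edge(qid, sid, weight=weight)
    return graph


def markov_cluster(
    graph: nx.Graph,
    inflation: float = 1.5,
    max_iter: int = 100,
    eps: float = 1e-6,
    species_of: Optional[Mapping[str, str]] = None,
) -> list[OrthoGroup]:
    """Markov clustering of the similarity graph.

    Alternates expansion (matrix squaring) and inflation (element-wise
    power with column renormalization) until the flow matrix is stable;
    attractor rows then define the clusters.  Every node lands in exactly
    one cluster (partition).  Non-convergence within ``max_iter`` returns
    the current hard clustering with a warning.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    nodes = sorted(graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        M[idx[a], idx[b]] = data.get("weight", 1.0)
        M[idx[b], idx[a]] = data.get("weight", 1.0)
    np.fill_diagonal(M, np.maximum(M.max(axis=0), 1e-12))  # self-loops stabilize
    M /= M.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        prev = M
        M = M @ M
        M = np.power(M, inflation)
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M /= colsum
        M[M < 1e-12] = 0.0
        M /= M.sum(axis=0, keepdims=True)
        if np.abs(M - prev).max() < eps:
            converged = True
            break
    if not converged:
        warnings.warn("Markov clustering did not converge; returning current clustering")
    # attractors: rows with nonzero mass; cluster = nodes that flow into them
    clusters: list[set[int]] = []
    assigned = {}
    for i in range(n):
        if M[i].max() <= 0:
            continue
        members = set(np.nonzero(M[i] > 1e-9)[0].tolist())
        if not members:
            continue
        merged = False
        for c in clusters:
            if c & members:
                c |= members
                merged = True
                break
        if merged:
            # transitive merge pass
            changed = True
            while changed:
                changed = False
                for a in range(len(clusters)):
                    for b in range(a + 1, len(clusters)):
                        if clusters[a] & clusters[b]:
                            clusters[a] |= clusters[b]
                            del clusters[b]
                            changed = True
                            break
                    if changed:
                        break
        else:
            clusters.append(members)
    covered = set().union(*clusters) if clusters else set()
    for i in range(n):
        if i not in covered:
            clusters.append({i})
    # deterministic: assign each node to exactly one cluster (first containing it)
    seen: set[int] = set()
    groups = []
    clusters.sort(key=lambda c: min(c))
    for gi, c in enumerate(clusters):
        member_ids = sorted(nodes[i] for i in c - seen)
        seen |= c
        if not member_ids:
            continue
        members = [
            ((species_of or {}).get(g, ""), g) for g in member_ids
        ]
        groups.append(OrthoGroup(group_id=f"OG{gi:05d}", members=members))
    return groups


def select_ogr(
    groups: Sequence[OrthoGroup],
    contig_associations: Mapping[str, set[str]],
    protein_lengths: Mapping[str, int],
) -> tuple[list[OrthoGroup], list[OrthoGroup]]:
    """Pick each group's representative gene model.

    The representative is the member with the most distinct associated
    contigs; ties fall to the longest protein, then to the
    lexicographically smallest gene id.  Groups whose members have zero
    contig associations are returned separately (excluded from binning).
    """
    with_rep: list[OrthoGroup] = []
    excluded: list[OrthoGroup] = []
    for g in groups:
        best = None
        best_key = None
        for _, gid in g.members:
            n_contigs = len(contig_associations.get(gid, set()))
            key = (n_contigs, protein_lengths.get(gid, 0), _NegStr(gid))
            if best_key is None or key > best_key:
                best, best_key = gid, key
        if best_key is not None and best_key[0] == 0:
            excluded.append(OrthoGroup(g.group_id, list(g.members), None))
        else:
            with_rep.append(OrthoGroup(g.group_id, list(g.members), best))
    return with_rep, excluded


class _NegStr(str):
    """String whose ordering is reversed, so max() prefers the smaller id."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)
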