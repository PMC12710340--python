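"""Sequence similarity networks over excised RRE domains.

Pairwise scores come from Needleman-Wunsch global alignment (BLOSUM62,
gap open 10 / extend 0.5). Networks connect sequences whose pairwise
significance score clears a user-set threshold; representative-node
(RepNode) collapsing merges near-identical sequences before analysis,
mirroring standard SSN practice. The default edge metric is an explicit
Karlin-Altschul-style -log10(expectation) proxy computed from the raw
alignment score and the two sequence lengths; it is documented as an
approximation of SSN-service alignment scores, monotone in the same
direction, not numerically equivalent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx

# Gapped Karlin-Altschul parameters for BLOSUM62 (standard table values)
KA_LAMBDA = 0.267
KA_K = 0.041


@dataclass
class AlignmentResult:
    score: float
    identity: float      # % identical over aligned columns
    similarity: float    # % positive-scoring over aligned columns
    aligned_length: int  # columns excluding terminal overhangs, incl. internal gaps

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= self.similarity + 1e-9 <= 100.0 + 1e-9):
            raise ValueError("need 0 <= identity <= similarity <= 100")


_ALIGNER = None


def _aligner():
    global _ALIGNER
    if _ALIGNER is None:
        from Bio import Align
        from Bio.Align import substitution_matrices

        matrix = substitution_matrices.load("BLOSUM62")
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = matrix
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -0.5
        _ALIGNER = aligner
    return _ALIGNER


def _pair_score(a: str, b: str) -> float:
    matrix = _aligner().substitution_matrix
    if a not in matrix.alphabet or b not in matrix.alphabet:
        return 0.0
    return float(matrix[a, b])


def global_align(a: str, b: str) -> AlignmentResult:
    """Optimal global alignment of two amino-acid sequences.

    Identity and similarity are percentages over the aligned region
    (terminal overhangs trimmed, internal gaps counted as columns);
    similarity counts columns whose substitution score is positive.
    Non-standard letters (X etc.) are tolerated and score 0.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aln = _aligner().align(a.upper(), b.upper())[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    # trim terminal overhangs (leading/trailing columns with a gap)
    start = 0
    end = len(row_a)
    while start < end and (row_a[start] == "-" or row_b[start] == "-"):
        start += 1
    while end > start and (row_a[end - 1] == "-" or row_b[end - 1] == "-"):
        end -= 1
    identical = positive = 0
    ncols = end - start
    for x, y in zip(row_a[start:end], row_b[start:end]):
        if x == "-" or y == "-":
            continue
        if x == y:
            identical += 1
            positive += 1
        elif _pair_score(x, y) > 0:
            positive += 1
    if ncols == 0:  # pathological: alignment is all overhang
        return AlignmentResult(float(aln.score), 0.0, 0.0, 0)
    return AlignmentResult(score=float(aln.score),
                           identity=100.0 * identical / ncols,
                           similarity=100.0 * positive / ncols,
                           aligned_length=ncols)


def neg_log10_expect(raw_score: float, len_a: int, len_b: int) -> float:
    """-log10 of a Karlin-Altschul expectation proxy, E = K*m*n*exp(-lambda*S).

    Larger is more significant; grows linearly with the raw score and
    shrinks with log(sequence lengths).
    """
    ln_e = math.log(KA_K) + math.log(len_a) + math.log(len_b) - KA_LAMBDA * raw_score
    return -ln_e / math.log(10.0)


@dataclass
class RepNodeClustering:
    identity_threshold: float
    clusters: dict[str, list[str]] = field(default_factory=dict)  # rep -> members (incl. rep)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def representative_of(self, seq_id: str) -> str:
        for rep, members in self.clusters.items():
            if seq_id in members:
                return rep
        raise KeyError(seq_id)


def repnode_collapse(seqs: dict[str, str], identity_threshold: float) -> RepNodeClustering:
    """Greedy length-sorted centroid clustering (CD-HIT-style RepNodes).

    Sequences are visited in descending length (ties by id); each joins the
    first-founded representative whose global-alignment identity is at
    least the threshold, otherwise founds a new cluster.
    """
    if not seqs:
        raise ValueError("no sequences")
    order = sorted(seqs, key=lambda k: (-len(seqs[k]), k))
    reps: list[str] = []
    clusters: dict[str, list[str]] = {}
    for sid in order:
        home = None
        for rep in reps:
            if seqs[rep] == seqs[sid] or \
               global_align(seqs[rep], seqs[sid]).identity >= identity_threshold:
                home = rep
                break
        if home is None:
            reps.append(sid)
            clusters[sid] = [sid]
        else:
            clusters[home].append(sid)
    return RepNodeClustering(identity_threshold=identity_threshold, clusters=clusters)


def build_network(seqs: dict[str, str], threshold: float,
                  edge_metric: str = "neg_log10_evalue_proxy",
                  metadata: Optional[dict[str, dict]] = None) -> nx.Graph:
    """All-vs-all similarity network; an edge is kept iff its score clears
    the threshold. Node attributes carry sequence length plus any supplied
    metadata; graph attributes record the metric and threshold."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    if edge_metric not in ("neg_log10_evalue_proxy", "bitscore"):
        raise ValueError(f"unknown edge metric {edge_metric!r}")
    g = nx.Graph(edge_metric=edge_metric, threshold=threshold)
    metadata = metadata or {}
    for sid, seq in seqs.items():
        g.add_node(sid, length=len(seq), **metadata.get(sid, {}))
    ids = sorted(seqs)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            res = global_align(seqs[a], seqs[b])
            if edge_metric == "bitscore":
                score = res.score
            else:
                score = neg_log10_expect(res.score, len(seqs[a]), len(seqs[b]))
            if score >= threshold:
                g.add_edge(a, b, score=score, identity=res.identity,
                           similarity=res.similarity)
    return g


def extract_groups(net: nx.Graph, min_size: int = 10) -> list[list[str]]:
    """Connected components with at least ``min_size`` nodes, largest first
    (ties by lexicographically smallest member id); members sorted."""
    groups = [sorted(c) for c in nx.connected_components(net) if len(c) >= min_size]
    groups.sort(key=lambda g: (-len(g), g[0]))
    return groups


# ---------------------------------------------------------------------------
# I/O

def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in seqs.items():
            fh.write(f">{sid}\n{seq}\n")


def write_edge_list(net: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tscore\n")
        for a, b, data in sorted(net.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['score']:.4f}\n")


def write_graphml(net: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(net, str(path))


def write_cluster_tsv(clustering: RepNodeClustering, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# identity_threshold={clustering.identity_threshold}\n")
        fh.write("representative\tmember\n")
        for rep in sorted(clustering.clusters):
            for member in clustering.clusters[rep]:
                fh.write(f"{rep}\t{member}\n")
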