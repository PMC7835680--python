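"""Tandem-repeat detection and consensus-monomer reconstruction.

Reads drawn from a satellite array tile a circular sequence — the
monomer — so the k-mer de Bruijn graph of such a cluster is dominated
by a single heavy cycle whose length is the monomer length. The
monomer consensus is recovered by a greedy heaviest-edge walk from the
heaviest k-mer; the walk's closed cycle is reported as the consensus
when it carries enough of the graph's weight.

Monomers are circular, so a consensus is identified by its canonical
rotation: the lexicographically smallest string over all rotations of
both strands. Perfect multimers are reduced to their primitive root.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import ReadSet, revcomp


@dataclass
class KmerGraph:
    """Weighted de Bruijn graph, canonicalized over strands.

    ``counts`` maps each canonical k-mer (min of the k-mer and its
    reverse complement) to its occurrence count across the reads;
    nodes are the implicit (k-1)-mers.
    """

    k: int
    counts: dict[str, int]
    max_read_length: int

    @property
    def n_edges(self) -> int:
        return len(self.counts)

    @property
    def total_weight(self) -> int:
        return sum(self.counts.values())

    def weight(self, kmer: str) -> int:
        return self.counts.get(min(kmer, revcomp(kmer)), 0)


@dataclass
class TandemConsensus:
    """A reconstructed tandem-repeat monomer."""

    cluster_id: int | str
    monomer: str  # canonical rotation
    monomer_length: int
    confidence: float
    abundance_pct: float = 0.0
    low_confidence: bool = False

    def __post_init__(self):
        if self.monomer_length < 10:
            raise ValueError("monomer must be >= 10 bp")


def build_kmer_graph(reads: ReadSet | list[str], k: int = 21) -> KmerGraph:
    """Count canonical k-mers of a cluster's reads."""
    seqs = [r.seq for r in reads] if isinstance(reads, ReadSet) else list(reads)
    if not seqs:
        return KmerGraph(k=k, counts={}, max_read_length=0)
    if k >= min(len(s) for s in seqs):
        raise ValueError(f"k={k} must be smaller than the shortest read")
    counts: dict[str, int] = {}
    for seq in seqs:
        for i in range(len(seq) - k + 1):
            km = seq[i:i + k]
            if "N" in km:
                continue
            canon = min(km, revcomp(km))
            counts[canon] = counts.get(canon, 0) + 1
    return KmerGraph(k=k, counts=counts, max_read_length=max(len(s) for s in seqs))


def primitive_root(seq: str) -> str:
    """Smallest repeating unit of a (linear view of a) circular word."""
    m = len(seq)
    for p in range(1, m // 2 + 1):
        if m % p == 0 and seq == seq[:p] * (m // p):
            return seq[:p]
    return seq


def canonical_rotation(seq: str) -> str:
    """Lexicographically smallest rotation over both strands."""
    best = None
    for s in (seq, revcomp(seq)):
        for i in range(len(s)):
            rot = s[i:] + s[:i]
            if best is None or rot < best:
                best = rot
    return best if best is not None else seq


def detect_monomer_cycle(
    graph: KmerGraph,
    cluster_id: int | str = 0,
    min_confidence: float = 0.45,
    min_cycle_length: int = 10,
    min_count: int = 2,
    solid_fraction: float = 0.2,
) -> TandemConsensus | None:
    """Greedy heaviest-cycle extraction from the k-mer graph.

    Starting at the heaviest k-mer, the walk repeatedly follows the
    heaviest outgoing k-mer until it closes a cycle; the monomer is
    the cycle sequence reduced to its primitive root and canonical
    rotation. Confidence is the cycle's share of the graph weight.

    Both the walk and the weight total use only "solid" k-mers: count
    at least ``min_count`` and at least ``solid_fraction`` of the
    heaviest k-mer's count. The heaviest k-mer is effectively always
    true consensus sequence, while any individual sequencing-error
    k-mer recurs at a small multiple of the per-base error rate of
    it, so this coverage-adaptive floor strips the error cloud
    without a fixed depth assumption. Returns ``None`` when no cycle
    reaches ``min_confidence`` and ``min_cycle_length``.

    Monomers longer than twice the read length cannot be spanned by
    individual reads; such calls are flagged ``low_confidence``.
    """
    if graph.counts:
        floor = max(min_count, math.ceil(solid_fraction * max(graph.counts.values())))
    else:
        floor = min_count
    solid = {km: c for km, c in graph.counts.items() if c >= floor}
    if not solid:
        return None
    total = sum(solid.values())

    def w(kmer: str) -> int:
        return solid.get(min(kmer, revcomp(kmer)), 0)

    start = min(solid, key=lambda km: (-solid[km], km))
    path: list[str] = [start]
    index: dict[str, int] = {start: 0}
    cycle: list[str] | None = None
    limit = 2 * len(solid) + 1
    for _ in range(limit):
        cur = path[-1]
        suffix = cur[1:]
        best_next, best_w = None, 0
        for b in "ACGT":
            cand = suffix + b
            cw = w(cand)
            if cw > best_w or (cw == best_w and cw > 0 and (best_next is None or cand < best_next)):
                best_next, best_w = cand, cw
        if best_next is None:
            break  # dead end: no tandem cycle
        j = index.get(best_next)
        if j is not None:
            cycle = path[j:]
            break
        rc_next = revcomp(best_next)
        j = index.get(rc_next)
        if j is not None:
            # closed onto the reverse strand of the walked path; the
            # traversed stretch still defines the repeat cycle
            cycle = path[j:]
            break
        index[best_next] = len(path)
        path.append(best_next)
    if cycle is None or len(cycle) < min_cycle_length:
        return None
    cyc_weight = sum(w(km) for km in cycle)
    confidence = cyc_weight / total if total else 0.0
    if confidence < min_confidence:
        return None
    monomer = "".join(km[0] for km in cycle)
    monomer = canonical_rotation(primitive_root(monomer))
    if len(monomer) < min_cycle_length:
        return None
    return TandemConsensus(
        cluster_id=cluster_id,
        monomer=monomer,
        monomer_length=len(monomer),
        confidence=confidence,
        low_confidence=len(monomer) > 2 * graph.max_read_length,
    )


def periodicity_check(sequence: str, min_lag: int = 10,
                      refine_tolerance: float = 0.05) -> tuple[int, float]:
    """Autocorrelation periodicity estimate of a (consensus) sequence.

    For each lag in ``min_lag .. len/2`` the score is the fraction of
    positions matching their lag-shifted copy; the best-scoring lag is
    then reduced to its smallest divisor scoring within
    ``refine_tolerance`` of it, so multiples of a short period report
    the period itself. Returns ``(period, score)``.
    """
    import numpy as np

    seq = sequence.upper()
    n = len(seq)
    if n < 20:
        raise ValueError("sequence shorter than 20 bp")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)

    def score(lag: int) -> float:
        return float(np.count_nonzero(arr[:-lag] == arr[lag:]) / (n - lag))

    best_lag, best_score = min_lag, -1.0
    for lag in range(min_lag, n // 2 + 1):
        s = score(lag)
        if s > best_score:
            best_lag, best_score = lag, s
    for d in range(2, best_lag):
        if best_lag % d == 0 and score(d) >= best_score - refine_tolerance:
            return d, score(d)
    return best_lag, best_score


def call_tandem_clusters(
    clusters, reads_by_id: dict[str, str], k: int = 21,
    min_confidence: float = 0.45,
) -> dict[int, TandemConsensus]:
    """Run monomer detection on every cluster; map cluster_id -> call."""
    calls: dict[int, TandemConsensus] = {}
    for c in clusters:
        seqs = [reads_by_id[rid] for rid in c.read_ids]
        g = build_kmer_graph(seqs, k=k)
        cons = detect_monomer_cycle(g, cluster_id=c.cluster_id,
                                    min_confidence=min_confidence)
        if cons is not None:
            cons.abundance_pct = c.genome_proportion
            calls[c.cluster_id] = cons
    return calls
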