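"""Read-similarity graph construction and repeat clustering.

Repeat families in unassembled skimming reads reveal themselves as
dense communities in the all-vs-all read-similarity graph: two reads
are connected when their best local alignment reaches 90% identity
over at least 55% of the read length (both strands considered). The
graph is clustered into repeat families; each cluster's share of the
analyzed reads estimates that family's genome proportion, and in the
multi-species comparative mode the per-cluster species composition and
inter-species edge counts feed the repeat-based phylogeny.

Candidate read pairs are pre-screened by shared canonical k-mers
(k = 17) before alignment; any pair sharing an exact stretch of at
least ``ceil(theta_cov * L)`` bases shares far more k-mers than the
screening minimum, so no qualifying pair is lost.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import readprep
from ._align import local_identity, local_score
from .core import ReadSet, revcomp

THETA_ID = 0.90
THETA_COV = 0.55

LINEAGE_VOCAB = frozenset(
    [f"Ty3/gypsy: {x}" for x in ("Athila", "CRM", "Tekay", "Galadriel", "Reina", "Ogre/Tat")]
    + [f"Ty1/copia: {x}" for x in ("Ale", "Bianca", "Angela", "Ivana", "TAR", "Tork", "SIRE")]
    + [f"DNA: {x}" for x in ("Harbinger", "Helitron", "CACTA", "Mariner", "Mutator", "hAT")]
    + ["LINE", "SINE", "rDNA", "tandem", "unclassified"]
)


@dataclass
class SimilarityGraph:
    """Read-overlap graph: nodes are read ids, edges carry identity/overlap."""

    graph: nx.Graph
    read_length: int

    @property
    def n_reads(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class RepeatCluster:
    """One repeat family: a community of similar reads."""

    cluster_id: int
    read_ids: list[str]
    species_counts: dict[str, int]
    n_edges: int
    inter_species_edges: dict[tuple[str, str], int]
    genome_proportion: float = 0.0
    annotate: bool = False
    annotation: str = "unclassified"

    @property
    def size(self) -> int:
        return len(self.read_ids)


def _canonical_kmer_positions(seq: str, k: int) -> set[str]:
    rc = revcomp(seq)
    n = len(seq)
    return {
        min(seq[i:i + k], rc[n - k - i:n - i])
        for i in range(n - k + 1)
    }


def _kmer_position_map(seq: str, k: int) -> dict[str, tuple[int, int]]:
    """canonical k-mer -> (position, strand) of its first occurrence.

    strand is +1 when the forward k-mer at that position equals the
    canonical form, else -1.
    """
    rc = revcomp(seq)
    n = len(seq)
    out: dict[str, tuple[int, int]] = {}
    for i in range(n - k + 1):
        fwd = seq[i:i + k]
        rev = rc[n - k - i:n - i]
        if fwd <= rev:
            out.setdefault(fwd, (i, 1))
        else:
            out.setdefault(rev, (i, -1))
    return out


def _ungapped_best(
    a_arr: np.ndarray, b_arr: np.ndarray, b_rc_arr: np.ndarray,
    offsets: set[tuple[int, int]], min_cols: int,
) -> tuple[float, int]:
    """Best ungapped identity over candidate (offset, orientation) pairs.

    ``offsets`` holds ``(offset, orientation)`` with orientation +1
    for a-vs-b and -1 for a-vs-revcomp(b); offset is the position of
    b's start relative to a's. Returns (identity, columns) of the
    best candidate with at least ``min_cols`` overlap columns.
    """
    L = len(a_arr)
    best_id, best_cols = 0.0, 0
    for off, orient in offsets:
        cols = L - abs(off)
        if cols < min_cols:
            continue
        bb = b_arr if orient == 1 else b_rc_arr
        if off >= 0:
            x, y = a_arr[off:], bb[:cols]
        else:
            x, y = a_arr[:cols], bb[-off:]
        ident = np.count_nonzero(x == y) / cols
        if ident > best_id or (ident == best_id and cols > best_cols):
            best_id, best_cols = float(ident), cols
    return best_id, best_cols


def find_overlaps(
    reads: ReadSet,
    theta_id: float = THETA_ID,
    theta_cov: float = THETA_COV,
    k: int = 17,
    min_shared_kmers: int = 3,
    dp_margin: float = 0.04,
) -> SimilarityGraph:
    """All-vs-all read comparison under the similarity thresholds.

    An edge connects two reads when a local alignment (+1 match, -1
    mismatch, -2 gap; both strands) reaches ``identity = matches /
    aligned_columns >= theta_id`` over ``aligned_columns >= theta_cov
    * L`` (both inclusive).

    Pairs are screened in three stages. (1) Shared canonical k-mers
    nominate candidate pairs; a pair sharing an exact stretch of
    ``ceil(theta_cov * L)`` bases shares far more k-mers than the
    ``min_shared_kmers`` minimum, so no qualifying pair is lost.
    (2) The offsets implied by shared k-mers are tested ungapped: a
    candidate already meeting both thresholds without gaps is an edge,
    and one falling more than ``dp_margin`` below the identity
    threshold at its best offset cannot be rescued by gapped alignment
    and is dropped. (3) Only the inconclusive band goes to the dynamic
    programming kernel, whose best-scoring alignment then decides.
    """
    L = reads.uniform_length() if len(reads) else 0
    g = nx.Graph()
    for r in reads:
        g.add_node(r.id, species=r.species)
    if len(reads) < 2:
        return SimilarityGraph(graph=g, read_length=L)
    if k >= L:
        raise ValueError(f"prescreen k={k} must be < read length {L}")

    n = len(reads)
    kmaps = [_kmer_position_map(r.seq, k) for r in reads]
    arrs = [np.frombuffer(r.seq.encode(), dtype=np.uint8) for r in reads]
    rc_arrs = [np.frombuffer(revcomp(r.seq).encode(), dtype=np.uint8) for r in reads]

    postings: dict[str, list[int]] = defaultdict(list)
    for i, kmap in enumerate(kmaps):
        for km in kmap:
            postings[km].append(i)
    chunks = []
    for plist in postings.values():
        if len(plist) < 2:
            continue
        arr = np.asarray(plist, dtype=np.int64)
        ii, jj = np.triu_indices(len(arr), k=1)
        chunks.append(arr[ii] * n + arr[jj])
    if not chunks:
        return SimilarityGraph(graph=g, read_length=L)
    codes, counts = np.unique(np.concatenate(chunks), return_counts=True)
    codes = codes[counts >= min_shared_kmers]

    min_cols = int(np.ceil(theta_cov * L))
    # any qualifying alignment has score >= (3*theta_id - 2) * min_cols
    score_gate = (3 * theta_id - 2) * min_cols if theta_id > 2 / 3 else -np.inf

    for code in codes:
        a, b = int(code) // n, int(code) % n
        ka, kb = kmaps[a], kmaps[b]
        small, big = (ka, kb) if len(ka) <= len(kb) else (kb, ka)
        offsets: set[tuple[int, int]] = set()
        for km, (pos_s, strand_s) in small.items():
            hit = big.get(km)
            if hit is None:
                continue
            pos_b, strand_b = hit
            pa, sa = (pos_s, strand_s) if small is ka else (pos_b, strand_b)
            pb, sb = (pos_b, strand_b) if small is ka else (pos_s, strand_s)
            if sa == sb:
                offsets.add((pa - pb, 1))
            else:
                offsets.add((pa - (L - k - pb), -1))
        ident, cols = _ungapped_best(arrs[a], arrs[b], rc_arrs[b], offsets, min_cols)
        if ident >= theta_id and cols >= min_cols:
            g.add_edge(reads[a].id, reads[b].id,
                       identity=float(ident), overlap=cols / L)
            continue
        if ident < theta_id - dp_margin:
            continue
        ra, rb = reads[a], reads[b]
        seq_b_rc = revcomp(rb.seq)
        s_f = local_score(ra.seq, rb.seq)
        s_r = local_score(ra.seq, seq_b_rc)
        if max(s_f, s_r) < score_gate:
            continue
        ident, cols = local_identity(ra.seq, rb.seq if s_f >= s_r else seq_b_rc)
        if cols >= min_cols and ident >= theta_id:
            g.add_edge(ra.id, rb.id, identity=float(ident), overlap=cols / L)
    return SimilarityGraph(graph=g, read_length=L)


def genome_proportion(cluster_size: int, total_reads: int,
                      annotate_threshold: float = 0.01) -> tuple[float, bool]:
    """Cluster genome proportion (percent) and the detailed-annotation flag.

    Only clusters *strictly above* the threshold (default 0.01% of
    analyzed reads) are flagged for detailed annotation.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    p = 100.0 * cluster_size / total_reads
    return p, p > annotate_threshold


def cluster_graph(
    sim: SimilarityGraph,
    total_reads: int | None = None,
    refine_below_density: float = 0.01,
    min_split_size: int = 8,
) -> tuple[list[RepeatCluster], list[str]]:
    """Cluster the similarity graph into repeat families.

    Clusters are connected components; extremely sparse components
    (edge density below ``refine_below_density``) are additionally
    split by greedy modularity community detection when that yields a
    better-than-trivial partition. The default threshold is
    deliberately conservative: reads tiling a long element form a
    low-density chain of positional overlaps that is one real family,
    so refinement only fires on components far sparser than that. Clusters are numbered by read count (1 =
    largest; ties broken by smallest read id) and singleton reads are
    pooled separately as unclustered.
    """
    g = sim.graph
    total = total_reads if total_reads is not None else g.number_of_nodes()
    groups: list[list[str]] = []
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        n = len(comp)
        if n >= min_split_size:
            sub = g.subgraph(comp)
            m = sub.number_of_edges()
            density = 2 * m / (n * (n - 1))
            if density < refine_below_density:
                comms = nx.community.greedy_modularity_communities(sub)
                if len(comms) > 1 and nx.community.modularity(sub, comms) > 0.3:
                    groups.extend(sorted(c) for c in comms)
                    continue
        groups.append(comp)
    clusters: list[RepeatCluster] = []
    unclustered: list[str] = []
    for members in groups:
        if len(members) == 1:
            unclustered.extend(members)
            continue
        clusters.append(members)  # type: ignore[arg-type]
    clusters_sorted = sorted(clusters, key=lambda ms: (-len(ms), min(ms)))
    out: list[RepeatCluster] = []
    for idx, members in enumerate(clusters_sorted, start=1):
        sub = g.subgraph(members)
        sp_counts: Counter = Counter(g.nodes[n]["species"] for n in members)
        o_ij: Counter = Counter()
        for u, v in sub.edges():
            su, sv = g.nodes[u]["species"], g.nodes[v]["species"]
            if su != sv:
                o_ij[tuple(sorted((su, sv)))] += 1
        p, flag = genome_proportion(len(members), total)
        out.append(RepeatCluster(
            cluster_id=idx,
            read_ids=list(members),
            species_counts=dict(sp_counts),
            n_edges=sub.number_of_edges(),
            inter_species_edges=dict(o_ij),
            genome_proportion=p,
            annotate=flag,
        ))
    return out, sorted(unclustered)


def annotate_cluster(
    cluster: RepeatCluster,
    reads_by_id: dict[str, str],
    reference_library: list[tuple[str, str, str]],
    theta_id: float = THETA_ID,
    min_hit_columns: int = 50,
    min_hit_read_fraction: float = 0.20,
    k: int = 13,
) -> str:
    """Assign a repeat-lineage label to a cluster.

    ``reference_library`` holds ``(ref_id, lineage, sequence)`` with
    lineage labels from the controlled vocabulary. Each cluster read is
    scored against candidate references (shared-k-mer prescreen, then
    the local alignment kernel); a read hits a reference when identity
    >= ``theta_id`` over >= ``min_hit_columns`` columns. The cluster
    label is the majority lineage among hitting reads, or
    "unclassified" when fewer than 20% of reads hit anything.
    """
    if not reference_library:
        raise ValueError("reference library is empty")
    for ref_id, lineage, _ in reference_library:
        if lineage not in LINEAGE_VOCAB:
            raise ValueError(f"reference {ref_id}: unknown lineage label {lineage!r}")
    ref_kmers: list[set[str]] = []
    for _, _, seq in reference_library:
        ref_kmers.append(_canonical_kmer_positions(seq, k))
    votes: Counter = Counter()
    n_hit = 0
    for rid in cluster.read_ids:
        seq = reads_by_id[rid]
        read_kmers = _canonical_kmer_positions(seq, k)
        best_lineage, best_ident = None, 0.0
        for (ref_id, lineage, ref_seq), rk in zip(reference_library, ref_kmers):
            if not (read_kmers & rk):
                continue
            s_f = local_score(ref_seq, seq)
            s_r = local_score(ref_seq, revcomp(seq))
            target = seq if s_f >= s_r else revcomp(seq)
            ident, cols = local_identity(ref_seq, target)
            if cols >= min_hit_columns and ident >= theta_id and ident > best_ident:
                best_lineage, best_ident = lineage, ident
        if best_lineage is not None:
            n_hit += 1
            votes[best_lineage] += 1
    if n_hit < min_hit_read_fraction * max(len(cluster.read_ids), 1) or not votes:
        return "unclassified"
    # majority vote, ties broken alphabetically for determinism
    top = max(votes.items(), key=lambda kv: (kv[1], kv[0]))
    return top[0]


@dataclass
class ComparativeResult:
    """Output of the multi-species comparative clustering."""

    clusters: list[RepeatCluster]
    unclustered: list[str]
    abundance: pd.DataFrame  # clusters x species, percent of species reads
    sampled_counts: dict[str, int]
    total_reads: int
    graph: SimilarityGraph = field(repr=False, default=None)
    pooled: ReadSet = field(repr=False, default=None)


def comparative_cluster(
    readsets: dict[str, ReadSet],
    genome_sizes_mb: dict[str, float],
    cfg: readprep.PrepConfig | None = None,
    theta_id: float = THETA_ID,
    theta_cov: float = THETA_COV,
) -> ComparativeResult:
    """Pooled clustering of coverage-normalized reads from >= 2 species.

    Each species' (already trimmed) reads are subsampled to the
    configured coverage, tagged with their species, pooled, and
    clustered. The returned abundance matrix gives each cluster's read
    share per species in percent of that species' sampled reads.
    """
    cfg = cfg or readprep.PrepConfig()
    if len(readsets) < 2:
        raise ValueError("comparative mode needs >= 2 species")
    if len(set(readsets)) != len(readsets):
        raise ValueError("duplicate species ids")
    from .core import Read

    pooled: list[Read] = []
    sampled_counts: dict[str, int] = {}
    for sid in sorted(readsets):
        rs = readsets[sid]
        sub = readprep.subsample_coverage(rs, genome_sizes_mb[sid], cfg)
        sampled_counts[sid] = len(sub)
        for r in sub:
            rid = r.id if r.id.startswith(sid) else f"{sid}:{r.id}"
            pooled.append(Read(id=rid, seq=r.seq, qual=r.qual, species=sid, family=r.family))
    pool = ReadSet(reads=pooled)
    sim = find_overlaps(pool, theta_id=theta_id, theta_cov=theta_cov)
    clusters, unclustered = cluster_graph(sim, total_reads=len(pool))
    species = sorted(readsets)
    rows = []
    for c in clusters:
        rows.append({
            "cluster_id": c.cluster_id,
            **{
                sid: 100.0 * c.species_counts.get(sid, 0) / sampled_counts[sid]
                for sid in species
            },
        })
    abundance = pd.DataFrame(rows).set_index("cluster_id") if rows else pd.DataFrame(columns=species)
    return ComparativeResult(
        clusters=clusters, unclustered=unclustered, abundance=abundance,
        sampled_counts=sampled_counts, total_reads=len(pool), graph=sim,
        pooled=pool,
    )


def clusters_table(clusters: list[RepeatCluster]) -> pd.DataFrame:
    """Summary TSV-ready table of clusters."""
    rows = []
    for c in clusters:
        row = {
            "cluster_id": c.cluster_id,
            "size": c.size,
            "n_edges": c.n_edges,
            "genome_proportion_pct": c.genome_proportion,
            "annotate": c.annotate,
            "annotation": c.annotation,
        }
        for sid, n in sorted(c.species_counts.items()):
            row[f"n_{sid}"] = n
        rows.append(row)
    return pd.DataFrame(rows)
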