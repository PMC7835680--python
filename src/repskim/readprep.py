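"""Read preprocessing: quality filtering, fixed-length trimming,
organelle-read removal, and coverage-normalized subsampling.

The preprocessing contract for repeatome skimming: reads are kept only
if at least 90% of their bases reach Q20, trimmed to a fixed 140 bp
(5'-anchored), purged of chloroplast/mitochondrial reads, and finally
subsampled so that each species contributes the same genome coverage
(default 0.1x) to the comparative clustering — without this
normalization, differences in sequencing depth masquerade as
differences in repeat abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Read, ReadSet, revcomp


@dataclass
class PrepConfig:
    quality_cutoff: int = 20          # phred Q
    min_good_fraction: float = 0.90   # fraction of bases >= Q required
    target_length: int = 140          # bp kept from the 5' end
    organelle_k: int = 31             # k-mer size for the organelle index
    organelle_min_hit_fraction: float = 0.5
    target_coverage: float = 0.1      # x, for comparative subsampling
    fasta_input: bool = False         # skip the quality filter (no quals)
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.min_good_fraction <= 1:
            raise ValueError("min_good_fraction must be in (0, 1]")
        if self.target_length <= 0:
            raise ValueError("target_length must be positive")
        if self.target_coverage <= 0:
            raise ValueError("target_coverage must be positive")


@dataclass
class PrepLog:
    """Per-stage read counts, for the processing log TSV."""

    counts: list[tuple[str, int, int]] = field(default_factory=list)

    def record(self, stage: str, n_in: int, n_out: int) -> None:
        self.counts.append((stage, n_in, n_out))


def quality_trim(reads: ReadSet, cfg: PrepConfig | None = None,
                 log: PrepLog | None = None) -> ReadSet:
    """Quality-filter and trim reads to a fixed length.

    A read survives iff at least ``min_good_fraction`` of its bases are
    >= ``quality_cutoff`` and it is at least ``target_length`` long;
    survivors keep their 5'-most ``target_length`` bases. FASTA input
    (no qualities) skips the quality test but not the length test.
    """
    cfg = cfg or PrepConfig()
    L = cfg.target_length
    out = []
    for r in reads:
        if len(r.seq) < L:
            continue
        if r.qual is None:
            if not cfg.fasta_input:
                raise ValueError(f"read {r.id} has no qualities; set fasta_input=True")
        else:
            good = np.count_nonzero(r.qual >= cfg.quality_cutoff)
            if good < cfg.min_good_fraction * len(r.qual):
                continue
        out.append(Read(id=r.id, seq=r.seq[:L],
                        qual=None if r.qual is None else r.qual[:L],
                        species=r.species, family=r.family))
    if log is not None:
        log.record("quality_trim", len(reads), len(out))
    return ReadSet(reads=out, species=reads.species)


def _canonical_kmers(seq: str, k: int) -> set[str]:
    rc = revcomp(seq)
    n = len(seq)
    out = set()
    for i in range(n - k + 1):
        fwd = seq[i:i + k]
        rev = rc[n - k - i:n - i]
        out.add(fwd if fwd <= rev else rev)
    return out


def build_organelle_index(references: list[str], k: int = 31) -> set[str]:
    """Canonical k-mer set of the organelle reference sequences."""
    idx: set[str] = set()
    for ref in references:
        idx |= _canonical_kmers(ref.upper(), k)
    return idx


def filter_organelle(reads: ReadSet, organelle_refs: list[str],
                     cfg: PrepConfig | None = None,
                     log: PrepLog | None = None) -> ReadSet:
    """Remove reads matching the organelle k-mer index.

    A read is dropped iff at least ``organelle_min_hit_fraction`` of
    its canonical k-mers occur in the index built from the chloroplast
    and mitochondrial references (both strands, via canonicalization).
    """
    cfg = cfg or PrepConfig()
    if not organelle_refs:
        raise ValueError("organelle reference list is empty")
    k = cfg.organelle_k
    if reads.reads and k > min(len(r.seq) for r in reads):
        raise ValueError(f"k={k} exceeds shortest read")
    idx = build_organelle_index(organelle_refs, k)
    out = []
    for r in reads:
        kmers = _canonical_kmers(r.seq, k)
        hits = sum(1 for km in kmers if km in idx)
        if kmers and hits / len(kmers) >= cfg.organelle_min_hit_fraction:
            continue
        out.append(r)
    if log is not None:
        log.record("filter_organelle", len(reads), len(out))
    return ReadSet(reads=out, species=reads.species)


def subsample_coverage(reads: ReadSet, genome_size_mb: float,
                       cfg: PrepConfig | None = None,
                       log: PrepLog | None = None) -> ReadSet:
    """Subsample reads to a target genome coverage.

    Draws ``round(c * G / L)`` reads uniformly without replacement
    (fixed seed); if fewer are available, returns all of them. Coverage
    arithmetic counts single reads, matching read-count x length /
    genome-size accounting.
    """
    cfg = cfg or PrepConfig()
    if genome_size_mb <= 0:
        raise ValueError("genome size must be positive")
    n_target = int(round(cfg.target_coverage * genome_size_mb * 1e6 / cfg.target_length))
    if n_target >= len(reads):
        out = list(reads.reads)
    else:
        rng = np.random.default_rng(cfg.seed)
        keep = np.sort(rng.choice(len(reads), size=n_target, replace=False))
        out = [reads[int(i)] for i in keep]
    if log is not None:
        log.record("subsample_coverage", len(reads), len(out))
    return ReadSet(reads=out, species=reads.species)


def preprocess(reads: ReadSet, genome_size_mb: float,
               organelle_refs: list[str] | None = None,
               cfg: PrepConfig | None = None) -> tuple[ReadSet, PrepLog]:
    """Full preprocessing chain: trim -> organelle filter -> subsample."""
    cfg = cfg or PrepConfig()
    log = PrepLog()
    rs = quality_trim(reads, cfg, log)
    if organelle_refs:
        rs = filter_organelle(rs, organelle_refs, cfg, log)
    rs = subsample_coverage(rs, genome_size_mb, cfg, log)
    return rs, log
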