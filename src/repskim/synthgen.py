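"""Synthetic multi-species repeatome generator.

Generates what a low-coverage genome-skimming experiment would see for
a small clade of plant species: a known species tree with clades, a
library of repeat families (dispersed transposable-element families
and tandem-repeat/satellite families) with a known sharing structure
along that tree, per-species genomes carrying those families at
requested genome fractions, and short error-bearing reads — plus
machine-readable truth tables so every downstream stage of the
pipeline can be scored against ground truth.

Evolution of repeat consensus sequences is substitution-only
(Jukes–Cantor kernel per tree edge), tandem arrays are emitted as
single contiguous head-to-tail blocks, and background sequence is
i.i.d. over {A,C,G,T}. These simplifications keep identity and
alignment expectations closed-form; see the package methods note for
what they do and do not emulate.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from skbio import TreeNode

from .core import Read, ReadSet, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE2IDX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE2IDX[_b] = _i


# ---------------------------------------------------------------------------
# specs


@dataclass
class SpeciesSpec:
    """One simulated species.

    ``repeat_fractions`` maps family_id -> fraction of the genome that
    family should occupy in this species; the remainder (1 - sum) is
    low-copy background.
    """

    species_id: str
    clade_id: str
    genome_size_mb: float
    repeat_fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not (0 < len(self.species_id) <= 6 and self.species_id.isalnum()):
            raise ValueError(f"species_id {self.species_id!r} must be 1-6 alphanumeric chars")
        if self.genome_size_mb <= 0:
            raise ValueError("genome size must be positive")
        if any(f < 0 for f in self.repeat_fractions.values()):
            raise ValueError("repeat fractions must be non-negative")
        if sum(self.repeat_fractions.values()) > 1:
            raise ValueError("repeat fractions sum to more than 1")


@dataclass
class RepeatFamilySpec:
    """One repeat family and where on the tree it occurs.

    ``divergence`` is the expected substitutions/site the family
    accumulates along *each* branch of the species tree, so two sister
    species carrying it are separated by twice that.
    """

    family_id: str
    kind: str  # "TE" or "tandem"
    length: int  # monomer length (tandem) or element length (TE)
    sharing: frozenset
    divergence: float = 0.0
    rate: float | None = None  # subs/site per unit branch length (overrides divergence)
    lineage: str = ""  # annotation label for TE families, e.g. "Ty3/gypsy: Athila"

    def __post_init__(self):
        if self.kind not in ("TE", "tandem"):
            raise ValueError(f"kind must be TE or tandem, got {self.kind!r}")
        if self.kind == "tandem" and self.length < 10:
            raise ValueError("tandem monomer length must be >= 10 bp")
        if not 0 <= self.divergence < 0.75:
            raise ValueError("divergence must be in [0, 0.75)")
        if self.rate is not None and self.rate < 0:
            raise ValueError("rate must be non-negative")
        self.sharing = frozenset(self.sharing)
        if not self.sharing:
            raise ValueError("sharing set must be non-empty")


# ---------------------------------------------------------------------------
# species tree


def make_species_tree(
    n_species: int,
    clade_sizes: list[int],
    depth: float = 0.1,
    seed: int = 0,
    species_ids: list[str] | None = None,
    clade_ids: list[str] | None = None,
    within_band: tuple[float, float] = (0.08, 0.30),
    clade_band: tuple[float, float] = (0.70, 1.0),
) -> TreeNode:
    """Random rooted, ultrametric binary species tree with monophyletic
    clades.

    Species of each clade are joined first (random pairwise joins at
    increasing node heights within the shallow 8-30% band of the tree
    depth), and the clade roots are then joined in the deep 70-100%
    band, so every clade is monophyletic and within-clade divergences
    are clearly smaller than cross-clade ones — the pattern an
    infrageneric radiation leaves. ``depth`` is the root-to-tip path
    length in expected substitutions/site; all branch lengths are
    positive.
    """
    if sum(clade_sizes) != n_species:
        raise ValueError(f"clade sizes {clade_sizes} do not sum to {n_species}")
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if any(c < 1 for c in clade_sizes):
        raise ValueError("clade sizes must be positive")
    rng = np.random.default_rng(seed)
    if clade_ids is None:
        clade_ids = [chr(ord("A") + i) for i in range(len(clade_sizes))]
    if species_ids is None:
        species_ids = [f"SP{i + 1:02d}" for i in range(n_species)]
    if len(set(species_ids)) != n_species:
        raise ValueError("species ids must be unique")

    def _join_all(nodes: list[TreeNode], heights: list[float],
                  join_heights: np.ndarray) -> tuple[TreeNode, float]:
        nodes, heights = list(nodes), list(heights)
        for h in join_heights:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            b, hb = nodes.pop(j), heights.pop(j)
            a, ha = nodes.pop(i), heights.pop(i)
            a.length = float(h - ha)
            b.length = float(h - hb)
            nodes.append(TreeNode(children=[a, b]))
            heights.append(float(h))
        return nodes[0], heights[0]

    idx = 0
    clade_roots: list[TreeNode] = []
    clade_heights: list[float] = []
    for cid, size in zip(clade_ids, clade_sizes):
        tips = []
        for _ in range(size):
            t = TreeNode(name=species_ids[idx])
            t.clade_id = cid
            tips.append(t)
            idx += 1
        if size > 1:
            hs = np.sort(rng.uniform(within_band[0] * depth, within_band[1] * depth,
                                     size=size - 1))
            croot, ch = _join_all(tips, [0.0] * size, hs)
        else:
            croot, ch = tips[0], 0.0
        clade_roots.append(croot)
        clade_heights.append(ch)
    if len(clade_roots) > 1:
        hs = np.sort(rng.uniform(clade_band[0] * depth, clade_band[1] * depth,
                                 size=len(clade_roots) - 1))
        tree, _ = _join_all(clade_roots, clade_heights, hs)
    else:
        tree = clade_roots[0]
    tree.length = None
    return tree


def clade_map(tree: TreeNode) -> dict[str, str]:
    """species_id -> clade_id for a tree built by make_species_tree."""
    return {t.name: getattr(t, "clade_id", "") for t in tree.tips()}


# ---------------------------------------------------------------------------
# sequence evolution


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _jc_mutate(seq: str, d: float, rng: np.random.Generator) -> str:
    """Apply one Jukes-Cantor edge of expected ``d`` subs/site.

    Per site the probability of ending in a different base is
    ``3/4 (1 - exp(-4d/3))``, uniform over the three alternatives;
    this kernel composes exactly along a path of edges.
    """
    if d == 0:
        return seq
    arr = _BASE2IDX[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.int64)
    p_change = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
    hit = rng.random(len(arr)) < p_change
    shift = rng.integers(1, 4, size=int(hit.sum()))
    arr[hit] = (arr[hit] + shift) % 4
    return _BASES[arr].tobytes().decode()


@dataclass
class RepeatLibrary:
    """Evolved per-species consensus sequences for every family."""

    root_consensus: dict[str, str]
    species_consensus: dict[str, dict[str, str]]  # family -> species -> seq
    specs: dict[str, RepeatFamilySpec]

    def families_of(self, species_id: str) -> list[str]:
        return [f for f, per_sp in self.species_consensus.items() if species_id in per_sp]


def evolve_repeat_library(
    tree: TreeNode, specs: list[RepeatFamilySpec], seed: int = 0
) -> RepeatLibrary:
    """Evolve each family's consensus down the species tree.

    The root consensus is i.i.d. random; along every tree edge the
    family accumulates expected substitutions/site (JC kernel) equal
    to ``spec.rate * edge_length`` when a rate is set, otherwise the
    flat per-branch ``spec.divergence``. Either way expected pairwise
    identity between carriers decays with tree distance.
    """
    leaves = {t.name for t in tree.tips()}
    rng = np.random.default_rng(seed)
    root_consensus: dict[str, str] = {}
    species_consensus: dict[str, dict[str, str]] = {}
    for spec in sorted(specs, key=lambda s: s.family_id):
        unknown = spec.sharing - leaves
        if unknown:
            raise ValueError(f"family {spec.family_id} shared with unknown species {sorted(unknown)}")
        root = _random_seq(rng, spec.length)
        root_consensus[spec.family_id] = root
        per_species: dict[str, str] = {}

        def _walk(node: TreeNode, seq: str) -> None:
            if node.is_tip():
                if node.name in spec.sharing:
                    per_species[node.name] = seq
                return
            for child in node.children:
                d = (spec.rate * float(child.length or 0.0)
                     if spec.rate is not None else spec.divergence)
                _walk(child, _jc_mutate(seq, d, rng))

        _walk(tree, root)
        species_consensus[spec.family_id] = per_species
    return RepeatLibrary(root_consensus, species_consensus, {s.family_id: s for s in specs})


# ---------------------------------------------------------------------------
# genome assembly


@dataclass
class SyntheticGenome:
    """One species' simulated genome plus its truth annotation."""

    species_id: str
    sequence: str
    intervals: list[tuple[int, int, str]]  # (start, end, family_id), sorted, disjoint
    realized_fractions: dict[str, float]
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)


def build_genome(
    spec: SpeciesSpec, library: RepeatLibrary, seed: int = 0
) -> SyntheticGenome:
    """Assemble a genome from repeat blocks and random background.

    Tandem families become one contiguous head-to-tail array each
    (copy number = requested fraction x genome / monomer length,
    dropped with a warning if < 2); TE families become dispersed
    copies. Blocks are placed in random order separated by random-size
    background chunks, so realized fractions match requests to within
    one monomer/element.
    """
    rng = np.random.default_rng(seed)
    G = int(round(spec.genome_size_mb * 1e6))
    blocks: list[tuple[str, str]] = []  # (family_id, sequence)
    warnings: list[str] = []
    for fam_id in sorted(spec.repeat_fractions):
        frac = spec.repeat_fractions[fam_id]
        if frac == 0:
            continue
        fspec = library.specs.get(fam_id)
        if fspec is None:
            raise ValueError(f"unknown family {fam_id}")
        consensus = library.species_consensus[fam_id].get(spec.species_id)
        if consensus is None:
            raise ValueError(
                f"family {fam_id} is not carried by species {spec.species_id}"
            )
        n_copies = int(round(frac * G / fspec.length))
        if fspec.kind == "tandem":
            if n_copies < 2:
                warnings.append(
                    f"{fam_id}: fraction {frac} too small for >=2 tandem copies; dropped"
                )
                continue
            blocks.append((fam_id, consensus * n_copies))
        else:
            if n_copies < 1:
                warnings.append(f"{fam_id}: fraction {frac} too small for one element; dropped")
                continue
            for _ in range(n_copies):
                blocks.append((fam_id, consensus))
    repeat_len = sum(len(b) for _, b in blocks)
    if repeat_len > G:
        raise ValueError(f"repeat blocks ({repeat_len} bp) exceed genome size ({G} bp)")
    bg_len = G - repeat_len
    order = rng.permutation(len(blocks))
    # split background into len(blocks)+1 chunks at random cut points
    cuts = np.sort(rng.integers(0, bg_len + 1, size=len(blocks))) if blocks else np.array([], dtype=int)
    chunk_sizes = np.diff(np.concatenate(([0], cuts, [bg_len])))
    parts: list[str] = []
    intervals: list[tuple[int, int, str]] = []
    pos = 0
    for i, bi in enumerate(order):
        chunk = _random_seq(rng, int(chunk_sizes[i]))
        parts.append(chunk)
        pos += len(chunk)
        fam_id, block = blocks[bi]
        parts.append(block)
        intervals.append((pos, pos + len(block), fam_id))
        pos += len(block)
    parts.append(_random_seq(rng, int(chunk_sizes[-1]) if blocks else bg_len))
    sequence = "".join(parts)
    realized: dict[str, float] = {}
    for start, end, fam in intervals:
        realized[fam] = realized.get(fam, 0.0) + (end - start) / G
    return SyntheticGenome(spec.species_id, sequence, intervals, realized, warnings)


# ---------------------------------------------------------------------------
# read simulation


def simulate_reads(
    genome: SyntheticGenome,
    read_length: int = 151,
    coverage: float = 0.2,
    error_rate: float = 0.001,
    seed: int = 0,
) -> ReadSet:
    """Uniform single-position reads with i.i.d. substitution errors.

    The number of reads is ``round(coverage * G / read_length)``;
    start positions and strands are uniform. Qualities are constant at
    the phred score implied by ``error_rate``. Mates are emulated as
    independent reads with alternating ``/1``/``/2`` suffixes. Each
    read is assigned to the truth family owning the majority of its
    bases (or background).
    """
    G = len(genome.sequence)
    if read_length > G:
        raise ValueError("read length exceeds genome length")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    n_reads = int(round(coverage * G / read_length))
    if n_reads < 1:
        raise ValueError("coverage yields zero reads")
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, G - read_length + 1, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)
    q = 40 if error_rate <= 0 else min(40, int(round(-10 * math.log10(error_rate))))
    qual = np.full(read_length, q, dtype=np.int16)

    ivs = genome.intervals
    iv_starts = np.array([s for s, _, _ in ivs], dtype=int)
    iv_ends = np.array([e for _, e, _ in ivs], dtype=int)

    def _truth_family(s: int) -> str:
        e = s + read_length
        lo = int(np.searchsorted(iv_ends, s, side="right"))
        hi = int(np.searchsorted(iv_starts, e, side="left"))
        best_fam, best_ov = "", 0
        for k in range(lo, hi):
            ov = min(e, int(iv_ends[k])) - max(s, int(iv_starts[k]))
            if ov > best_ov:
                best_ov, best_fam = ov, ivs[k][2]
        return best_fam if best_ov * 2 >= read_length else ""

    reads = []
    for i in range(n_reads):
        s = int(starts[i])
        seq = genome.sequence[s:s + read_length]
        if strands[i]:
            seq = revcomp(seq)
        if error_rate > 0:
            n_err = rng.binomial(read_length, error_rate)
            if n_err:
                pos = rng.choice(read_length, size=n_err, replace=False)
                arr = _BASE2IDX[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.int64)
                arr[pos] = (arr[pos] + rng.integers(1, 4, size=n_err)) % 4
                seq = _BASES[arr].tobytes().decode()
        mate = 1 if i % 2 == 0 else 2
        reads.append(
            Read(
                id=f"{genome.species_id}_{i:07d}/{mate}",
                seq=seq,
                qual=qual.copy(),
                species=genome.species_id,
                family=_truth_family(s),
            )
        )
    return ReadSet(reads=reads, species=genome.species_id)


# ---------------------------------------------------------------------------
# Ks simulation (four-fold degenerate codon pairs)

# codon prefixes whose third position is four-fold degenerate and whose
# first two positions have no synonymous single-nucleotide neighbors
_FOURFOLD_PREFIXES = ["GG", "GC", "GT", "CC", "AC", "TC"]


def simulate_fourfold_cds_pairs(
    n_pairs: int, n_codons: int, ks_values, seed: int = 0
) -> list[tuple[str, str, str]]:
    """Codon-aligned CDS pairs with known synonymous divergence.

    Codons are drawn from four-fold-degenerate families only, so every
    codon carries exactly one synonymous site at its third position and
    that site evolves as a clean four-state JC process: the JC-corrected
    Ks estimator is unbiased for the requested divergence. ``ks_values``
    is one expected Ks per pair (scalar broadcastable).
    """
    rng = np.random.default_rng(seed)
    ks_values = np.broadcast_to(np.asarray(ks_values, dtype=float), (n_pairs,))
    pairs = []
    for i in range(n_pairs):
        prefixes = rng.choice(len(_FOURFOLD_PREFIXES), size=n_codons)
        thirds = rng.integers(0, 4, size=n_codons)
        cds1 = "".join(
            _FOURFOLD_PREFIXES[p] + "ACGT"[t] for p, t in zip(prefixes, thirds)
        )
        third_seq = _BASES[thirds].tobytes().decode()
        third_mut = _jc_mutate(third_seq, float(ks_values[i]), rng)
        cds2 = "".join(
            _FOURFOLD_PREFIXES[p] + b for p, b in zip(prefixes, third_mut)
        )
        pairs.append((f"pair{i:05d}", cds1, cds2))
    return pairs


# ---------------------------------------------------------------------------
# scenarios


@dataclass
class Scenario:
    """A full simulation design: tree, families, species, read model."""

    species: list[SpeciesSpec]
    families: list[RepeatFamilySpec]
    clade_sizes: list[int]
    tree_depth: float = 0.1
    tree_within_band: tuple[float, float] = (0.08, 0.30)
    tree_clade_band: tuple[float, float] = (0.70, 1.0)
    read_length: int = 151
    coverage: float = 0.2
    error_rate: float = 0.001
    organelle_fraction: float = 0.0
    organelle_length: int = 20000
    seed: int = 0


@dataclass
class ScenarioResult:
    """Everything a downstream test needs: data plus ground truth."""

    tree: TreeNode
    library: RepeatLibrary
    genomes: dict[str, SyntheticGenome]
    readsets: dict[str, ReadSet]
    clades: dict[str, str]
    organelle: str | None = None


def run_scenario(sc: Scenario) -> ScenarioResult:
    """Simulate a scenario end to end (tree -> library -> genomes -> reads)."""
    ids = [s.species_id for s in sc.species]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate species ids")
    clade_ids = sorted({s.clade_id for s in sc.species})
    # order species by clade so the tree's monophyletic groups line up
    by_clade = {c: [s.species_id for s in sc.species if s.clade_id == c] for c in clade_ids}
    ordered = [sid for c in clade_ids for sid in by_clade[c]]
    sizes = [len(by_clade[c]) for c in clade_ids]
    if sizes != list(sc.clade_sizes):
        raise ValueError(f"clade sizes {sizes} do not match declared {sc.clade_sizes}")
    tree = make_species_tree(
        len(ordered), sizes, depth=sc.tree_depth, seed=sc.seed,
        species_ids=ordered, clade_ids=clade_ids,
        within_band=sc.tree_within_band, clade_band=sc.tree_clade_band,
    )
    library = evolve_repeat_library(tree, sc.families, seed=sc.seed + 1)
    rng = np.random.default_rng(sc.seed + 2)
    organelle = _random_seq(rng, sc.organelle_length) if sc.organelle_fraction > 0 else None
    genomes, readsets = {}, {}
    for k, spec in enumerate(sc.species):
        g = build_genome(spec, library, seed=sc.seed + 10 + k)
        genomes[spec.species_id] = g
        rs = simulate_reads(
            g, read_length=sc.read_length, coverage=sc.coverage,
            error_rate=sc.error_rate, seed=sc.seed + 100 + k,
        )
        if organelle is not None:
            rs = _spike_organelle(rs, organelle, sc.organelle_fraction,
                                  sc.read_length, sc.error_rate,
                                  np.random.default_rng(sc.seed + 200 + k))
        readsets[spec.species_id] = rs
    return ScenarioResult(tree=tree, library=library, genomes=genomes,
                          readsets=readsets, clades=clade_map(tree),
                          organelle=organelle)


def _spike_organelle(rs: ReadSet, organelle: str, fraction: float,
                     read_length: int, error_rate: float,
                     rng: np.random.Generator) -> ReadSet:
    """Append organelle-derived reads (a fixed fraction of the total)."""
    n = int(round(len(rs) * fraction))
    q = 40 if error_rate <= 0 else min(40, int(round(-10 * math.log10(error_rate))))
    qual = np.full(read_length, q, dtype=np.int16)
    reads = list(rs.reads)
    for i in range(n):
        s = int(rng.integers(0, len(organelle) - read_length + 1))
        seq = organelle[s:s + read_length]
        if rng.integers(0, 2):
            seq = revcomp(seq)
        reads.append(Read(id=f"{rs.species}_org{i:06d}/1", seq=seq, qual=qual.copy(),
                          species=rs.species, family="organelle"))
    return ReadSet(reads=reads, species=rs.species)


def four_clade_scenario(
    seed: int = 0,
    genome_mb: float = 1.0,
    clade_sizes: tuple[int, ...] = (6, 2, 6, 1),
    coverage: float = 0.15,
    read_length: int = 151,
    error_rate: float = 0.001,
    organelle_fraction: float = 0.02,
) -> Scenario:
    """The default four-clade study design at desk scale.

    Fifteen species in clades of 6/2/6/1 carrying: six TE families
    shared by all species, evolving clock-like along the ultrametric
    tree at a rate placing cross-clade read pairs near the 90% edge
    threshold while within-clade pairs pass comfortably — the
    similarity-edge density gradient that carries the phylogenetic
    signal; three tandem families per multi-species clade shared by
    the whole clade; one species-specific tandem per species; and one
    cross-clade "relic" tandem. Per-species repeat content lands near
    30% of the genome, tandem monomers are dominated by 170-190 bp,
    and reads are 151 bp at modest coverage with a simple error model
    — mirroring the conditions of published skimming studies of small
    plant genomes while staying small enough to run on a desktop.
    """
    clade_ids = [chr(ord("A") + i) for i in range(len(clade_sizes))]
    n = sum(clade_sizes)
    ids = [f"SP{i + 1:02d}" for i in range(n)]
    clade_of = {}
    k = 0
    for cid, size in zip(clade_ids, clade_sizes):
        for _ in range(size):
            clade_of[ids[k]] = cid
            k += 1
    all_sp = frozenset(ids)
    te_lineages = [
        "Ty3/gypsy: Athila", "Ty3/gypsy: CRM", "Ty3/gypsy: Tekay",
        "Ty1/copia: Bianca", "DNA: CACTA",
    ]
    # at tree depth 0.1, cross-clade distances are ~0.18-0.2 subs/site;
    # a TE clock rate of 0.58 puts cross-clade copy identity near the
    # 90% edge threshold (sparse but nonzero edge density) while
    # within-clade identity stays around 97-99% (near-complete edge
    # density) — the contrast that carries the phylogenetic signal
    families = [
        RepeatFamilySpec(
            family_id=f"TE{i + 1}", kind="TE", length=1200, sharing=all_sp,
            rate=0.58, lineage=lin,
        )
        for i, lin in enumerate(te_lineages)
    ]
    monomers = [171, 180, 184]
    for cid, size in zip(clade_ids, clade_sizes):
        if size < 2:
            continue
        members = frozenset(s for s in ids if clade_of[s] == cid)
        for j, m in enumerate(monomers):
            families.append(RepeatFamilySpec(
                family_id=f"SAT{cid}{j + 1}", kind="tandem", length=m,
                sharing=members, rate=0.4,
            ))
    for sid in ids:
        families.append(RepeatFamilySpec(
            family_id=f"SAT{sid}", kind="tandem", length=177,
            sharing=frozenset([sid]), divergence=0.0,
        ))
    # one relic repeat shared across two clades (B and D), as seen for
    # old satellites that survive cladogenesis
    relic_members = frozenset(s for s in ids if clade_of[s] in ("B", "D"))
    if len(relic_members) >= 2:
        families.append(RepeatFamilySpec(
            family_id="SATrelic", kind="tandem", length=158,
            sharing=relic_members, rate=0.4,
        ))
    rng = np.random.default_rng(seed)
    species = []
    for sid in ids:
        fr: dict[str, float] = {}
        for i in range(len(te_lineages)):
            fr[f"TE{i + 1}"] = float(rng.uniform(0.055, 0.068))
        cid = clade_of[sid]
        if sum(1 for s in ids if clade_of[s] == cid) >= 2:
            for j in range(len(monomers)):
                fr[f"SAT{cid}{j + 1}"] = float(rng.uniform(0.016, 0.024))
        fr[f"SAT{sid}"] = float(rng.uniform(0.02, 0.028))
        if sid in relic_members:
            fr["SATrelic"] = float(rng.uniform(0.016, 0.024))
        species.append(SpeciesSpec(
            species_id=sid, clade_id=cid, genome_size_mb=genome_mb,
            repeat_fractions=fr,
        ))
    return Scenario(
        species=species, families=families, clade_sizes=list(clade_sizes),
        tree_depth=0.1, tree_within_band=(0.03, 0.10),
        tree_clade_band=(0.90, 1.0),
        read_length=read_length, coverage=coverage,
        error_rate=error_rate, organelle_fraction=organelle_fraction,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# scenario file IO


def load_scenario(path: str | Path) -> Scenario:
    """Load a YAML scenario file (see ``scenario_to_dict`` for layout)."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return scenario_from_dict(d)


def scenario_from_dict(d: dict) -> Scenario:
    species = [
        SpeciesSpec(
            species_id=s["species_id"], clade_id=s["clade_id"],
            genome_size_mb=float(s["genome_size_mb"]),
            repeat_fractions={k: float(v) for k, v in s.get("repeat_fractions", {}).items()},
        )
        for s in d["species"]
    ]
    families = [
        RepeatFamilySpec(
            family_id=f["family_id"], kind=f["kind"], length=int(f["length"]),
            sharing=frozenset(f["sharing"]), divergence=float(f.get("divergence", 0.0)),
            lineage=f.get("lineage", ""),
        )
        for f in d["families"]
    ]
    return Scenario(
        species=species, families=families,
        clade_sizes=[int(c) for c in d["clade_sizes"]],
        tree_depth=float(d.get("tree_depth", 0.1)),
        read_length=int(d.get("read_length", 151)),
        coverage=float(d.get("coverage", 0.2)),
        error_rate=float(d.get("error_rate", 0.001)),
        organelle_fraction=float(d.get("organelle_fraction", 0.0)),
        organelle_length=int(d.get("organelle_length", 20000)),
        seed=int(d.get("seed", 0)),
    )


def scenario_to_dict(sc: Scenario) -> dict:
    return {
        "species": [
            {
                "species_id": s.species_id, "clade_id": s.clade_id,
                "genome_size_mb": s.genome_size_mb,
                "repeat_fractions": dict(s.repeat_fractions),
            }
            for s in sc.species
        ],
        "families": [
            {
                "family_id": f.family_id, "kind": f.kind, "length": f.length,
                "sharing": sorted(f.sharing), "divergence": f.divergence,
                "lineage": f.lineage,
            }
            for f in sc.families
        ],
        "clade_sizes": list(sc.clade_sizes),
        "tree_depth": sc.tree_depth,
        "read_length": sc.read_length,
        "coverage": sc.coverage,
        "error_rate": sc.error_rate,
        "organelle_fraction": sc.organelle_fraction,
        "organelle_length": sc.organelle_length,
        "seed": sc.seed,
    }


def write_outputs(result: ScenarioResult, outdir: str | Path) -> None:
    """Write FASTQ, genome FASTA, truth TSVs, and the tree as Newick."""
    from .core import write_fasta, write_fastq

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    result.tree.write(buf)
    (outdir / "species_tree.nwk").write_text(buf.getvalue())
    with open(outdir / "clades.tsv", "w") as fh:
        fh.write("species_id\tclade_id\n")
        for sid, cid in sorted(result.clades.items()):
            fh.write(f"{sid}\t{cid}\n")
    with open(outdir / "truth_fractions.tsv", "w") as fh:
        fh.write("species_id\tfamily_id\trealized_fraction\n")
        for sid in sorted(result.genomes):
            for fam, frac in sorted(result.genomes[sid].realized_fractions.items()):
                fh.write(f"{sid}\t{fam}\t{frac:.6f}\n")
    for sid in sorted(result.readsets):
        write_fastq(result.readsets[sid], outdir / f"{sid}.fastq")
        write_fasta([(sid, result.genomes[sid].sequence)], outdir / f"{sid}_genome.fasta")
    consensus_records = []
    for fam in sorted(result.library.species_consensus):
        for sid, seq in sorted(result.library.species_consensus[fam].items()):
            consensus_records.append((f"{fam}|{sid}", seq))
    write_fasta(consensus_records, outdir / "family_consensus.fasta")
    if result.organelle is not None:
        write_fasta([("organelle_decoy", result.organelle)], outdir / "organelle.fasta")
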