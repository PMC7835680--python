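"""End-to-end analysis orchestration.

Chains the individual stages into the full comparative repeatome
analysis: preprocessing per species, pooled comparative clustering,
repeat-similarity consensus phylogeny, abundance dendrogram,
per-species tandem-monomer calling, and cross-species shared-repeat
classification. Used both as the library's high-level entry point and
by the synthetic end-to-end validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from skbio import TreeNode

from . import graphclust, readprep, repeatphylo, sharedrep, tandemcall
from .core import ReadSet
from .synthgen import Scenario, ScenarioResult, run_scenario


@dataclass
class AnalysisResult:
    """Everything the comparative pipeline produces."""

    comparative: graphclust.ComparativeResult
    consensus: TreeNode | None
    dendrogram: TreeNode
    nj_trees: list[TreeNode]
    used_cluster_ids: list[int]
    tandem_records: list[sharedrep.MonomerRecord]
    shared_families: list[sharedrep.SharedRepeatFamily]
    sharing_summary: dict
    per_species_clusters: dict[str, list] = field(repr=False, default_factory=dict)


def preprocess_all(
    readsets: dict[str, ReadSet],
    organelle_refs: list[str] | None = None,
    cfg: readprep.PrepConfig | None = None,
) -> dict[str, ReadSet]:
    """Quality-trim (and organelle-filter) every species' reads."""
    cfg = cfg or readprep.PrepConfig()
    out = {}
    for sid in sorted(readsets):
        rs = readprep.quality_trim(readsets[sid], cfg)
        if organelle_refs:
            rs = readprep.filter_organelle(rs, organelle_refs, cfg)
        out[sid] = rs
    return out


def species_tandem_monomers(
    readsets: dict[str, ReadSet],
    genome_sizes_mb: dict[str, float],
    cfg: readprep.PrepConfig | None = None,
    min_cluster_size: int = 5,
) -> tuple[list[sharedrep.MonomerRecord], dict[str, list]]:
    """Per-species clustering and tandem-monomer calling.

    Each species is clustered on its own (at the configured sampling
    coverage) and every sufficiently large cluster is screened for a
    tandem monomer; confident calls become per-species monomer
    records, the counting unit of the sharing analysis.
    """
    cfg = cfg or readprep.PrepConfig()
    records: list[sharedrep.MonomerRecord] = []
    per_species: dict[str, list] = {}
    for sid in sorted(readsets):
        rs = readprep.subsample_coverage(readsets[sid], genome_sizes_mb[sid], cfg)
        sim = graphclust.find_overlaps(rs)
        clusters, _ = graphclust.cluster_graph(sim, total_reads=len(rs))
        per_species[sid] = clusters
        reads_by_id = {r.id: r.seq for r in rs}
        calls = tandemcall.call_tandem_clusters(
            [c for c in clusters if c.size >= min_cluster_size], reads_by_id
        )
        for cid, cons in sorted(calls.items()):
            records.append(sharedrep.MonomerRecord(
                species_id=sid, consensus_id=f"CL{cid}", monomer=cons.monomer,
            ))
    return records, per_species


def analyze(
    readsets: dict[str, ReadSet],
    genome_sizes_mb: dict[str, float],
    clades: dict[str, str],
    organelle_refs: list[str] | None = None,
    cfg: readprep.PrepConfig | None = None,
    max_clusters: int = 100,
) -> AnalysisResult:
    """Run the full comparative analysis on preprocessed-or-raw reads."""
    cfg = cfg or readprep.PrepConfig()
    prepped = preprocess_all(readsets, organelle_refs, cfg)
    comp = graphclust.comparative_cluster(prepped, genome_sizes_mb, cfg)
    trees, used = repeatphylo.repeat_similarity_trees(comp, max_clusters=max_clusters)
    consensus = repeatphylo.consensus_tree(trees) if trees else None
    proportions = {c.cluster_id: c.genome_proportion for c in comp.clusters}
    dendro = repeatphylo.abundance_dendrogram(comp.abundance, proportions=proportions)
    records, per_species = species_tandem_monomers(prepped, genome_sizes_mb, cfg)
    if records:
        families = sharedrep.find_shared_families(records)
        summary = sharedrep.classify_sharing(families, clades)
    else:
        families, summary = [], {"counts": {}, "percent": {}, "total": 0}
    return AnalysisResult(
        comparative=comp, consensus=consensus, dendrogram=dendro,
        nj_trees=trees, used_cluster_ids=used, tandem_records=records,
        shared_families=families, sharing_summary=summary,
        per_species_clusters=per_species,
    )


def analyze_scenario(sc: Scenario, cfg: readprep.PrepConfig | None = None
                     ) -> tuple[AnalysisResult, ScenarioResult]:
    """Simulate a scenario and run the full analysis on it."""
    truth = run_scenario(sc)
    genome_sizes = {s.species_id: s.genome_size_mb for s in sc.species}
    organelle = [truth.organelle] if truth.organelle else None
    res = analyze(truth.readsets, genome_sizes, truth.clades,
                  organelle_refs=organelle, cfg=cfg)
    return res, truth


def contains_clade(tree: TreeNode, members: set[str]) -> bool:
    """Whether the tree has a split separating ``members`` from the rest."""
    taxa = {t.name for t in tree.tips()}
    members = set(members)
    if not 2 <= len(members) <= len(taxa) - 2:
        return True  # trivial splits are present in every tree
    ref = min(taxa)
    side = frozenset(members) if ref not in members else frozenset(taxa - members)
    return side in repeatphylo.tree_splits(tree)


def clade_recovery(tree: TreeNode, clades: dict[str, str]) -> float:
    """Fraction of the (nontrivial) true clades present in the tree."""
    groups: dict[str, set[str]] = {}
    for sid, cid in clades.items():
        groups.setdefault(cid, set()).add(sid)
    testable = [g for g in groups.values() if 2 <= len(g) <= len(clades) - 2]
    if not testable:
        return 1.0
    return sum(contains_clade(tree, g) for g in testable) / len(testable)
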