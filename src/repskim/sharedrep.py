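"""Cross-species comparison and classification of tandem repeats.

Consensus monomers from different species are compared with a
rotation- and strand-aware global alignment (monomers are circular, so
linear alignment would penalize an arbitrary phase offset), grouped
into homologous families by single-linkage over an identity threshold,
and each family is classified by where its members sit on the species
tree: species-specific, shared within one clade, or shared across
clades. The class tallies count per-species repeat records, not
families, matching how shared-repeat inventories are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._align import global_identity
from .core import revcomp
from .repstats import proportion_percent


@dataclass
class MonomerRecord:
    """One species' consensus monomer (the counting unit for sharing)."""

    species_id: str
    consensus_id: str
    monomer: str


@dataclass
class SharedRepeatFamily:
    family_id: int
    members: list[MonomerRecord]
    classification: str = ""  # species_specific | within_clade | cross_clade
    pairwise_identity: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def species(self) -> set[str]:
        return {m.species_id for m in self.members}


def circular_align(monomer_a: str, monomer_b: str) -> tuple[float, int, str]:
    """Best global identity over all rotations and strands.

    The shorter monomer is rotated; for every rotation of it and of
    its reverse complement the two sequences are globally aligned
    (+1/-1/-2, end gaps penalized) and identity = matches / alignment
    columns. Returns ``(identity_percent, best_rotation, strand)``
    with strand "+" or "-". Symmetric in its arguments.
    """
    a, b = monomer_a.upper(), monomer_b.upper()
    if len(a) < 10 or len(b) < 10:
        raise ValueError("monomers must be >= 10 bp")
    # rotate the shorter sequence; identity is symmetric because the
    # rotation orbit of (a, b) equals that of (b, a) up to phase
    if len(b) > len(a):
        a, b = b, a
    best = (-1.0, 0, "+")
    for strand, seq in (("+", b), ("-", revcomp(b))):
        for rot in range(len(seq)):
            rotated = seq[rot:] + seq[:rot]
            ident, _ = global_identity(a, rotated)
            if ident > best[0]:
                best = (ident, rot, strand)
    return 100.0 * best[0], best[1], best[2]


def _doubled_kmers(seq: str, k: int) -> set[str]:
    """Canonical k-mers of the doubled sequence (rotation-invariant)."""
    dd = seq + seq[:k - 1]
    rc = revcomp(dd)
    n = len(dd)
    return {min(dd[i:i + k], rc[n - k - i:n - i]) for i in range(len(seq))}


def find_shared_families(
    consensuses: list[MonomerRecord],
    min_identity: float = 80.0,
    max_length_ratio: float = 2.0,
    prescreen_k: int = 13,
) -> list[SharedRepeatFamily]:
    """Group homologous monomers across species by single linkage.

    Two monomers are linked when their circular identity is at least
    ``min_identity`` percent and their lengths are within
    ``max_length_ratio``-fold; families are the connected components
    of that graph. A shared-k-mer prescreen on doubled sequences skips
    hopeless pairs before the rotation scan. Family numbering is by
    size (largest first), ties by smallest member id, so output is
    invariant to input order.
    """
    if not consensuses:
        raise ValueError("no consensus monomers given")
    recs = sorted(consensuses, key=lambda m: (m.species_id, m.consensus_id))
    keys = [f"{m.species_id}|{m.consensus_id}" for m in recs]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (species, consensus) records")
    g = nx.Graph()
    g.add_nodes_from(range(len(recs)))
    kmers = []
    for m in recs:
        k = min(prescreen_k, len(m.monomer))
        kmers.append(_doubled_kmers(m.monomer, k))
    ident_cache: dict[tuple[int, int], float] = {}
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            la, lb = len(recs[i].monomer), len(recs[j].monomer)
            if max(la, lb) > max_length_ratio * min(la, lb):
                continue
            if not (kmers[i] & kmers[j]):
                continue
            ident, _, _ = circular_align(recs[i].monomer, recs[j].monomer)
            if ident >= min_identity:
                g.add_edge(i, j)
                ident_cache[(i, j)] = ident
    comps = sorted(
        (sorted(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), keys[c[0]]),
    )
    families = []
    for fid, comp in enumerate(comps, start=1):
        members = [recs[i] for i in comp]
        names = [keys[i] for i in comp]
        mat = pd.DataFrame(np.full((len(comp), len(comp)), np.nan),
                           index=names, columns=names)
        for ai, i in enumerate(comp):
            mat.iloc[ai, ai] = 100.0
            for aj, j in enumerate(comp):
                if j <= i:
                    continue
                ident = ident_cache.get((i, j))
                if ident is None:
                    ident, _, _ = circular_align(recs[i].monomer, recs[j].monomer)
                mat.iloc[ai, aj] = mat.iloc[aj, ai] = ident
        families.append(SharedRepeatFamily(family_id=fid, members=members,
                                           pairwise_identity=mat))
    return families


def classify_sharing(
    families: list[SharedRepeatFamily], clade_map: dict[str, str]
) -> dict:
    """Classify families and tally repeats per sharing class.

    A family is species-specific when all members come from one
    species, within-clade when members span several species of one
    clade, and cross-clade otherwise. Counts are per-species repeat
    records; percentages are rounded half-up to one decimal.
    """
    counts = {"species_specific": 0, "within_clade": 0, "cross_clade": 0}
    for fam in families:
        missing = fam.species - set(clade_map)
        if missing:
            raise ValueError(f"species missing from clade map: {sorted(missing)}")
        if len(fam.species) == 1:
            cls = "species_specific"
        elif len({clade_map[s] for s in fam.species}) == 1:
            cls = "within_clade"
        else:
            cls = "cross_clade"
        fam.classification = cls
        counts[cls] += len(fam.members)
    total = sum(counts.values())
    pct = {
        k: (proportion_percent(v, total, 1) if total else 0.0)
        for k, v in counts.items()
    }
    return {"counts": counts, "percent": pct, "total": total}


def presence_absence_matrix(
    families: list[SharedRepeatFamily], species_order: list[str] | None = None
) -> pd.DataFrame:
    """Family x species 0/1 matrix (number of member records per species)."""
    species = species_order or sorted({m.species_id for f in families for m in f.members})
    rows = []
    for f in families:
        row = {s: 0 for s in species}
        for m in f.members:
            row[m.species_id] += 1
        rows.append({"family_id": f.family_id, **row})
    return pd.DataFrame(rows).set_index("family_id")
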