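"""Synonymous-distance (Ks) estimation, peak detection, and WGD dating.

Paralog pairs retained after a whole-genome duplication (WGD) all
diverged at roughly the same time, so the within-genome distribution of
Ks — synonymous substitutions per synonymous site — shows a peak at the
Ks corresponding to that event. Dividing peak Ks by twice the
per-lineage synonymous substitution rate converts it to an age in
years.

Counting follows Nei & Gojobori (1986): per-codon synonymous and
nonsynonymous site fractions are obtained by enumerating the nine
single-nucleotide neighbors of each codon under the standard genetic
code (mutations creating stop codons are excluded from denominators),
and codons differing at several positions are resolved by averaging
over all minimal mutational pathways that avoid stop codons. The
proportion of synonymous differences is corrected for multiple hits
with the Jukes–Cantor formula.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import log

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

BASES = "TCAG"

# Standard genetic code, codons in TCAG order.
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
GENETIC_CODE = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(BASES)
    for j, b in enumerate(BASES)
    for k, c in enumerate(BASES)
}
STOP_CODONS = {c for c, aa in GENETIC_CODE.items() if aa == "*"}


def _codon_site_counts(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site fractions of one codon.

    Each of the three positions contributes ``f/3`` synonymous sites
    where ``f`` is the fraction of its single-nucleotide changes that
    are synonymous; changes to stop codons are dropped from the
    denominator. Total sites per codon is 3 minus the stop-neighbor
    deficit, following the NG86 convention.
    """
    aa = GENETIC_CODE[codon]
    syn = 0.0
    total = 0.0
    for pos in range(3):
        n_syn = 0
        n_valid = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if mut in STOP_CODONS:
                continue
            n_valid += 1
            if GENETIC_CODE[mut] == aa:
                n_syn += 1
        if n_valid:
            syn += n_syn / n_valid
            total += 1.0
    return syn, total - syn


_SITE_TABLE = {
    c: _codon_site_counts(c) for c in GENETIC_CODE if c not in STOP_CODONS
}


def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous differences between two codons.

    Averages over all orderings of the differing positions whose
    intermediate codons are not stops; if every pathway passes through
    a stop, falls back to averaging over all pathways (degenerate but
    never reached for biologically sensible input).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:  # all pathways blocked by stops: count them anyway
        for order in itertools.permutations(diff_pos):
            cur = c1
            sd = nd = 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((sd, nd))
    sds, nds = zip(*paths)
    return float(np.mean(sds)), float(np.mean(nds))


@dataclass
class PairCounts:
    """NG86 site and difference counts for one aligned coding pair."""

    S: float
    N: float
    Sd: float
    Nd: float

    @property
    def ps(self) -> float:
        return self.Sd / self.S if self.S > 0 else float("nan")


def _validate_cds(seq: str, name: str) -> None:
    if len(seq) % 3:
        raise ValueError(f"{name}: length {len(seq)} not divisible by 3")
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        if "-" in codon:
            continue
        if codon in STOP_CODONS and i < len(seq) - 3:
            raise ValueError(f"{name}: internal stop codon {codon} at {i}")


def count_sites_and_diffs(seq1: str, seq2: str) -> PairCounts:
    """NG86 synonymous/nonsynonymous sites and differences.

    Sequences must be codon-aligned (equal length, multiple of 3); gap
    codons (any codon containing ``-``) are skipped. Site counts are
    averaged over the two sequences.
    """
    seq1, seq2 = seq1.upper(), seq2.upper()
    if len(seq1) != len(seq2):
        raise ValueError("aligned sequences differ in length")
    _validate_cds(seq1, "seq1")
    _validate_cds(seq2, "seq2")
    S1 = N1 = S2 = N2 = Sd = Nd = 0.0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i:i + 3], seq2[i:i + 3]
        if "-" in c1 or "-" in c2 or "N" in c1 or "N" in c2:
            continue
        # terminal stops are legal input but uncounted
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            continue
        s1, n1 = _SITE_TABLE[c1]
        s2, n2 = _SITE_TABLE[c2]
        S1 += s1
        N1 += n1
        S2 += s2
        N2 += n2
        sd, nd = _pathway_diffs(c1, c2)
        Sd += sd
        Nd += nd
    return PairCounts(S=(S1 + S2) / 2, N=(N1 + N2) / 2, Sd=Sd, Nd=Nd)


SATURATION_PS = 0.75


def ks_value(counts: PairCounts) -> tuple[float, bool]:
    """Jukes–Cantor-corrected Ks from NG86 counts.

    Returns ``(ks, saturated)``; ``ks`` is ``nan`` when the proportion
    of synonymous differences reaches the JC domain boundary (ps ≥
    0.75) or no synonymous sites exist.
    """
    if counts.S <= 0:
        return float("nan"), True
    ps = counts.ps
    if ps >= SATURATION_PS:
        return float("nan"), True
    return -0.75 * log(1.0 - 4.0 * ps / 3.0), False


@dataclass
class KsPeak:
    location: float
    height: float


@dataclass
class KsDistribution:
    """Ks values for a set of gene pairs plus detected density peaks."""

    values: np.ndarray
    peaks: list[KsPeak] = field(default_factory=list)
    low_n: bool = False


def detect_peaks(
    ks_values,
    bandwidth: float | str | None = None,
    ks_range: tuple[float, float] = (0.0, 2.0),
    min_prominence_frac: float = 0.10,
    grid: int = 512,
) -> KsDistribution:
    """Find peaks of the Ks density on ``ks_range``.

    A Gaussian kernel density is evaluated on a regular grid and local
    maxima with prominence at least ``min_prominence_frac`` of the
    maximum density are reported, sorted by height (highest first).
    ``bandwidth`` is passed to ``scipy.stats.gaussian_kde`` (Scott's
    rule by default). Saturated/undefined values (NaN) are dropped;
    with fewer than 50 usable values peaks are still reported but the
    distribution is flagged ``low_n``.
    """
    vals = np.asarray(ks_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    vals = vals[(vals >= ks_range[0]) & (vals <= ks_range[1])]
    low_n = len(vals) < 50
    if len(vals) == 0:
        return KsDistribution(values=vals, peaks=[], low_n=True)
    if np.ptp(vals) == 0:  # degenerate: all values identical
        return KsDistribution(
            values=vals, peaks=[KsPeak(float(vals[0]), float("inf"))], low_n=low_n
        )
    kde = gaussian_kde(vals, bw_method=bandwidth)
    xs = np.linspace(ks_range[0], ks_range[1], grid)
    dens = kde(xs)
    idx, _ = find_peaks(dens, prominence=min_prominence_frac * dens.max())
    peaks = [KsPeak(float(xs[i]), float(dens[i])) for i in idx]
    # an interior maximum at the grid edge (truncated distributions) counts too
    if dens.argmax() == 0 and 0 not in idx:
        peaks.append(KsPeak(float(xs[0]), float(dens[0])))
    peaks.sort(key=lambda p: -p.height)
    return KsDistribution(values=vals, peaks=peaks, low_n=low_n)


def date_from_ks(ks: float, mu: float) -> float:
    """Divergence time in years from a Ks value.

    ``T = Ks / (2 mu)``: the synonymous distance between two diverging
    lineages accumulates at twice the per-lineage rate ``mu``
    (substitutions per synonymous site per year).
    """
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    if mu <= 0:
        raise ValueError("substitution rate must be positive")
    return ks / (2.0 * mu)


def ks_table(pairs: list[tuple[str, str, str]]) -> "pandas.DataFrame":
    """Per-pair NG86/Ks table from ``(pair_id, cds1, cds2)`` triples."""
    import pandas as pd

    rows = []
    for pid, s1, s2 in pairs:
        c = count_sites_and_diffs(s1, s2)
        ks, sat = ks_value(c)
        rows.append({
            "pair_id": pid, "S": c.S, "N": c.N, "Sd": c.Sd, "Nd": c.Nd,
            "ps": c.ps, "Ks": ks, "saturated": sat,
        })
    return pd.DataFrame(rows)
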