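"""Summary accounting utilities for repeatome composition tables.

Small deterministic helpers that back the published-style tables:
repeat-category totals and their low/single-copy complement, rounded
percentage reporting, the parsimony-informative fraction of an
alignment, and the repeat-content vs genome-size regression.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy import stats


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero, as printed tables do."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def total_and_complement(categories) -> tuple[float, float]:
    """Total repeat percent and its low/single-copy complement.

    ``categories`` is a mapping or iterable of per-category genome
    percents. Total is their sum rounded to 2 decimals; complement is
    ``100 - total`` so the two always add to exactly 100.
    """
    vals = list(categories.values()) if hasattr(categories, "values") else list(categories)
    if any(v < 0 for v in vals):
        raise ValueError("category percents must be non-negative")
    total = round_half_up(float(sum(vals)), 2)
    if total > 100:
        raise ValueError(f"category percents sum to {total} > 100")
    return total, round_half_up(100.0 - total, 2)


def proportion_percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """``100 * numerator / denominator`` rounded half-up."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be within [0, denominator]")
    return round_half_up(100.0 * numerator / denominator, decimals)


_IGNORED_STATES = set("-.NRYSWKMBDHVX?")


def parsimony_informative_fraction(sequences) -> tuple[int, int, float]:
    """Count parsimony-informative columns of an alignment.

    ``sequences`` is a list of equal-length strings (≥ 4 of them). A
    column is parsimony-informative iff at least two distinct residues
    each occur in at least two sequences; gaps and ambiguity codes are
    not counted as states. Returns ``(n_sites, n_informative,
    percent)`` with percent rounded to 1 decimal.
    """
    seqs = [s.upper() for s in sequences]
    if len(seqs) < 4:
        raise ValueError("need at least 4 sequences")
    lens = {len(s) for s in seqs}
    if len(lens) != 1:
        raise ValueError("sequences must be aligned to equal length")
    n_sites = lens.pop()
    n_inf = 0
    for col in zip(*seqs):
        counts: dict[str, int] = {}
        for c in col:
            if c in _IGNORED_STATES:
                continue
            counts[c] = counts.get(c, 0) + 1
        if sum(1 for v in counts.values() if v >= 2) >= 2:
            n_inf += 1
    return n_sites, n_inf, proportion_percent(n_inf, n_sites, 1)


def regress_vs_genome_size(genome_sizes_mb, abundances) -> dict:
    """OLS of repeat abundance on genome size.

    Returns slope, intercept, ``r2`` (squared Pearson correlation) and
    the two-sided p-value of the slope t-test. Abundance may be in Mb
    or percent; the regression does not care, only the caller's
    interpretation does.
    """
    x = np.asarray(genome_sizes_mb, dtype=float)
    y = np.asarray(abundances, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("genome sizes have zero variance")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue ** 2),
        "p": float(res.pvalue),
    }
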