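"""Shared local/global alignment kernel.

One scoring scheme (+1 match, -1 mismatch, -2 gap) is used everywhere
a read or monomer is compared, so identity thresholds mean the same
thing in read clustering, cluster annotation, and monomer comparison.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align

from .core import revcomp

MATCH = 1
MISMATCH = -1
GAP = -2


@lru_cache(maxsize=None)
def _aligner(mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner(
        mode=mode,
        match_score=MATCH,
        mismatch_score=MISMATCH,
        open_gap_score=GAP,
        extend_gap_score=GAP,
    )
    # global mode penalizes end gaps with the same open/extend scores by
    # default, which is what a circular-rotation comparison needs
    return al


def local_score(a: str, b: str) -> float:
    return _aligner("local").score(a, b)


def local_identity(a: str, b: str) -> tuple[float, int]:
    """Identity and column count of the best (max-score) local alignment.

    Identity counts matches over all alignment columns including
    internal gap columns. Returns ``(0.0, 0)`` when no positive-score
    alignment exists.
    """
    al = _aligner("local")
    try:
        aln = al.align(a, b)[0]
    except IndexError:
        return 0.0, 0
    if aln.length == 0:
        return 0.0, 0
    c = aln.counts()
    return c.identities / aln.length, aln.length


def best_local_identity_bothstrands(a: str, b: str) -> tuple[float, int]:
    """Best local alignment of ``a`` vs ``b`` or its reverse complement.

    Orientation is chosen by alignment score (forward wins ties), then
    identity/columns are measured on that orientation's best alignment.
    """
    b_rc = revcomp(b)
    s_f = local_score(a, b)
    s_r = local_score(a, b_rc)
    return local_identity(a, b if s_f >= s_r else b_rc)


def max_local_score_bothstrands(a: str, b: str) -> float:
    return max(local_score(a, b), local_score(a, revcomp(b)))


def global_identity(a: str, b: str) -> tuple[float, int]:
    """Identity of the best global alignment (end gaps penalized)."""
    al = _aligner("global")
    aln = al.align(a, b)[0]
    c = aln.counts()
    return c.identities / aln.length, aln.length
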