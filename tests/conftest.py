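"""Shared fixtures and test helpers."""

from __future__ import annotations

import numpy as np
import pytest

from repskim.core import Read, ReadSet


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def mutate(seq: str, n_subs: int, rng) -> str:
    """Apply exactly ``n_subs`` substitutions at distinct positions."""
    pos = rng.choice(len(seq), size=n_subs, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = "ACGT"[("ACGT".index(out[p]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def reads_from(seqs, species: str = "SP", q: int = 30, prefix: str = "r") -> ReadSet:
    """Wrap raw strings as a ReadSet with constant qualities."""
    return ReadSet(
        reads=[
            Read(id=f"{species}_{prefix}{i:05d}", seq=s,
                 qual=np.full(len(s), q, dtype=np.int16), species=species)
            for i, s in enumerate(seqs)
        ],
        species=species,
    )


def tile_reads(template: str, read_length: int, n_reads: int, rng,
               error_rate: float = 0.0, both_strands: bool = True) -> list[str]:
    """Uniformly sampled reads from a template sequence."""
    from repskim.core import revcomp

    out = []
    for _ in range(n_reads):
        s = int(rng.integers(0, len(template) - read_length + 1))
        seq = template[s:s + read_length]
        if error_rate > 0:
            k = rng.binomial(read_length, error_rate)
            if k:
                seq = mutate(seq, k, rng)
        if both_strands and rng.integers(0, 2):
            seq = revcomp(seq)
        out.append(seq)
    return out
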