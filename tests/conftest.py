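"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest

from culturegap.io_formats import SequenceRecord

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def mutate(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    """Exactly n_subs substitutions at distinct positions."""
    pos = rng.choice(len(seq), size=n_subs, replace=False)
    chars = list(seq)
    for p in pos:
        chars[p] = BASES[(BASES.index(chars[p]) + int(rng.integers(1, 4))) % 4]
    return "".join(chars)


def records(seqs, dataset_id="ds"):
    return [
        SequenceRecord(id=f"{dataset_id}_{i:03d}", dataset_id=dataset_id,
                       residues=s)
        for i, s in enumerate(seqs)
    ]


def random_newick(rng: np.random.Generator, n_tips: int,
                  min_len: float = 0.05, max_len: float = 1.0) -> str:
    """Random binary tree with uniform branch lengths, as a newick string."""
    assert n_tips >= 2
    labels = [f"t{i:03d}" for i in range(n_tips)]
    rng.shuffle(labels)

    def build(tips: list[str]) -> str:
        if len(tips) == 1:
            return f"{tips[0]}:{rng.uniform(min_len, max_len):.6f}"
        k = int(rng.integers(1, len(tips)))
        blen = rng.uniform(min_len, max_len)
        return f"({build(tips[:k])},{build(tips[k:])}):{blen:.6f}"

    k = int(rng.integers(1, n_tips))
    return f"({build(labels[:k])},{build(labels[k:])});"


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
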