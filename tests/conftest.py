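import re

import numpy as np
import pytest

from eetscan.seqio import ProteinRecord

AMINO = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_protein(rng, length, alphabet=AMINO, pid="p"):
    return ProteinRecord(pid, "".join(alphabet[i] for i in
                                      rng.integers(0, len(alphabet), length)))


def brute_force_motif_count(seq: str, min_x: int = 2, max_x: int = 4) -> int:
    """Independent oracle: enumerate every C-x(2,4)-C-H occurrence and take
    the maximum number of mutually non-overlapping intervals by exact
    dynamic programming over intervals sorted by end position."""
    intervals = []
    for m in re.finditer("C", seq):
        i = m.start()
        for nx in range(min_x, max_x + 1):
            j = i + 1 + nx
            if j + 1 < len(seq) and seq[j] == "C" and seq[j + 1] == "H":
                intervals.append((i, j + 1))
    intervals.sort(key=lambda t: t[1])
    best_at = []  # best count using intervals[0..k] (by end)
    for k, (s, e) in enumerate(intervals):
        take = 1
        for prev in range(k - 1, -1, -1):
            if intervals[prev][1] < s:
                take = 1 + best_at[prev]
                break
        skip = best_at[k - 1] if k else 0
        best_at.append(max(take, skip))
    return best_at[-1] if best_at else 0


def exhaustive_motif_count(seq: str) -> int:
    """Subset-enumeration oracle for tiny instances."""
    from itertools import combinations

    intervals = []
    for m in re.finditer("C", seq):
        i = m.start()
        for nx in range(2, 5):
            j = i + 1 + nx
            if j + 1 < len(seq) and seq[j] == "C" and seq[j + 1] == "H":
                intervals.append((i, j + 1))
    best = 0
    for r in range(len(intervals), 0, -1):
        for combo in combinations(intervals, r):
            ok = all(a[1] < b[0] for a, b in zip(combo, combo[1:]))
            if ok:
                return r
    return best
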