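"""Independent brute-force oracles used to validate the implementation.

These deliberately share no code with the package: naive enumeration of
recognition sites, a from-scratch UPGMA over frozensets, and direct
Pearson arithmetic.
"""

import itertools

import numpy as np

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def brute_terminal_fragment(amplicon: str, recognition: str, cut_offset: int,
                            reverse: bool):
    """Enumerate every occurrence; the labeled fragment ends at the cut
    inside the first occurrence on the labeled strand."""
    seq = revcomp(amplicon) if reverse else amplicon
    occurrences = [
        i for i in range(len(seq) - len(recognition) + 1)
        if seq[i : i + len(recognition)] == recognition
    ]
    if not occurrences:
        return None
    return min(occurrences) + cut_offset


def brute_primer_positions(seq: str, primer: str, max_mm: int):
    """All start positions where the primer matches with <= max_mm
    mismatches (exact bases only; oracle inputs are concrete ACGT)."""
    hits = []
    for i in range(len(seq) - len(primer) + 1):
        mm = sum(1 for a, b in zip(seq[i : i + len(primer)], primer) if a != b)
        if mm <= max_mm:
            hits.append(i)
    return hits


def brute_upgma_cophenetic(d: np.ndarray) -> np.ndarray:
    """Cophenetic matrix of UPGMA clustering, computed from scratch:
    clusters as frozensets, inter-cluster distance = unweighted mean of
    the original pairwise distances."""
    n = d.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    coph = np.zeros((n, n))

    def dist(a, b):
        return np.mean([d[i, j] for i in a for j in b])

    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            v = dist(a, b)
            if best is None or v < best[0]:
                best = (v, a, b)
        v, a, b = best
        for i in a:
            for j in b:
                coph[i, j] = coph[j, i] = v
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(a | b)
    return coph


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    return float((x * y).sum() / np.sqrt((x * x).sum() * (y * y).sum()))
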