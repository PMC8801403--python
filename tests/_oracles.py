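"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from first principles (naive scans,
quadratic DP, grid search) and shares no code with the package internals.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e18


@njit(cache=True)
def _gotoh(t_codes, q_codes, match, mismatch, gap_open, gap_extend):
    n, m = len(t_codes), len(q_codes)
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in query (consumes target)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in target (consumes query)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Iy[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if t_codes[i - 1] == q_codes[j - 1] else mismatch
            best_prev = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            M[i, j] = best_prev + s
            Ix[i, j] = max(M[i - 1, j] + gap_open, Ix[i - 1, j] + gap_extend,
                           Iy[i - 1, j] + gap_open)
            Iy[i, j] = max(M[i, j - 1] + gap_open, Iy[i, j - 1] + gap_extend,
                           Ix[i, j - 1] + gap_open)
    return max(M[n, m], Ix[n, m], Iy[n, m])


def global_affine_score(target: str, query: str, match=2.0, mismatch=-3.0,
                        gap_open=-5.0, gap_extend=-2.0) -> float:
    """Textbook Gotoh global alignment score.

    Gap convention: the first base of a gap scores ``gap_open``, each
    further base ``gap_extend``; end gaps are penalized.
    """
    enc = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
    t = np.array([enc[c] for c in target], dtype=np.int8)
    q = np.array([enc[c] for c in query], dtype=np.int8)
    return float(_gotoh(t, q, match, mismatch, gap_open, gap_extend))


def brute_force_guides(locus, intron_index, policy):
    """Every 20-mer + NGG site (either strand) cutting in the safe intron core,
    found by checking each offset independently of the package scanner."""
    from geis.design import reverse_complement

    seq = locus.sequence
    intron = locus.introns[intron_index]
    lo = intron.start + policy.donor_window_nt
    hi = intron.end - policy.acceptor_window_nt
    hits = set()
    for i in range(len(seq) - 22):
        site = seq[i : i + 23]
        if "N" in site:
            continue
        if site[21:23] == "GG":
            cut = i + 17
            if lo < cut < hi:
                hits.add((site[:20], site[20:], "+", cut))
        rc = reverse_complement(site)
        if rc[21:23] == "GG":
            cut = i + 6
            if lo < cut < hi:
                hits.add((rc[:20], rc[20:], "-", cut))
    return hits


def naive_motif_scan(seq: str, motifs) -> list[tuple[str, int]]:
    hits = []
    for i in range(len(seq)):
        for motif in motifs:
            if seq[i : i + len(motif)] == motif:
                hits.append((motif, i))
    return sorted(hits, key=lambda h: (h[1], h[0]))


def grid_search_geometric_mle(a, b, grid_step=1e-4):
    """Interval-censored geometric MLE by exhaustive grid search over p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    grid = np.arange(grid_step, 1.0, grid_step)
    ll = np.full(grid.size, -np.inf)
    for k, p in enumerate(grid):
        term = p ** a - p ** b  # p**inf == 0
        if np.all(term > 0):
            ll[k] = np.sum(np.log(term))
    return float(grid[np.argmax(ll)]), float(ll.max())


def overlap_length(a0, a1, b0, b1):
    """Brute-force interval overlap by integer enumeration (small intervals)."""
    return len(set(range(a0, a1)) & set(range(b0, b1)))
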