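"""Independent oracles used by the test suite.

Everything here is deliberately naive (pure-Python dynamic programming,
exhaustive enumeration, grid search) and shares no code with the package's
production paths.
"""

from __future__ import annotations

import itertools
import math
import random


def naive_max_matches(a: str, b: str) -> int:
    """Classic O(nm) table for the maximum number of identical aligned
    residues (gaps and mismatches unpenalized, end gaps free)."""
    m, n = len(a), len(b)
    dp = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        row = dp[i]
        prev = dp[i - 1]
        ai = a[i - 1]
        for j in range(1, n + 1):
            best = prev[j - 1] + 1 if ai == b[j - 1] else 0
            if prev[j] > best:
                best = prev[j]
            if row[j - 1] > best:
                best = row[j - 1]
            row[j] = best
    return dp[m][n]


def naive_identity(a: str, b: str) -> float:
    return 100.0 * naive_max_matches(a, b) / min(len(a), len(b))


def sw_oracle_score(q, s, score_fn, gap_open: int, gap_extend: int) -> int:
    """Pure-Python affine-gap local alignment score (Gotoh), no banding.

    ``score_fn(qa, sa)`` returns the substitution score. First gap residue
    costs gap_open + gap_extend.
    """
    m, n = len(q), len(s)
    NEG = -(10**9)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend, F[i - 1][j] - gap_extend)
            H[i][j] = max(
                0,
                H[i - 1][j - 1] + score_fn(q[i - 1], s[j - 1]),
                E[i][j],
                F[i][j],
            )
            if H[i][j] > best:
                best = H[i][j]
    return best


# hand-copied standard genetic code for translation cross-checks
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def brute_force_best_hits(rows, max_evalue, min_identity, min_aln_len):
    """Exhaustive per-query scan: filter then collect all minimum-E rows.

    ``rows`` are (query, subject, identity, alnlen, evalue) tuples; returns
    {query: set of subjects of the tied best hits}.
    """
    by_query = {}
    for row in rows:
        by_query.setdefault(row[0], []).append(row)
    out = {}
    for query, group in by_query.items():
        passing = [
            r for r in group
            if r[4] <= max_evalue and r[2] >= min_identity and r[3] >= min_aln_len
        ]
        if not passing:
            continue
        best_e = min(r[4] for r in passing)
        out[query] = {r[1] for r in passing if r[4] == best_e}
    return out


def grid_search_simplex(matrix, sample, step: float = 0.01):
    """Best residual over the abundance simplex on a coarse grid (<= 3 cols)."""
    n_genera = matrix.shape[1]
    assert n_genera <= 3
    steps = int(round(1.0 / step))
    best = (math.inf, None)
    for combo in itertools.product(range(steps + 1), repeat=n_genera - 1):
        if sum(combo) > steps:
            continue
        x = [c * step for c in combo]
        x.append(1.0 - sum(x))
        resid = 0.0
        for i in range(matrix.shape[0]):
            pred = sum(matrix[i, j] * x[j] for j in range(n_genera))
            resid += (pred - sample[i]) ** 2
        resid = math.sqrt(resid)
        if resid < best[0]:
            best = (resid, x)
    return best


def random_protein(rng: random.Random, length: int, alphabet: str = "ACDEFGHIKLMNPQRSTVWY") -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))
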