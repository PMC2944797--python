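"""Affine-gap local alignment kernels.

Smith-Waterman with affine gap penalties (a gap of length k costs
open + k * extend), JIT-compiled with numba. Nucleotide scoring is
match +1 / mismatch -1 with gap open 2 / extend 1; protein scoring is
BLOSUM62 with gap open 11 / extend 1. Identity is defined as
matches / alignment columns x 100 throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

# Karlin-Altschul-style parameters for e-values. These are the standard
# ungapped +1/-1 nucleotide values and gapped BLOSUM62 values; they set
# the *scale* of significance for the synthetic databases searched here,
# not a bit-for-bit reproduction of any published search tool.
NT_LAMBDA, NT_K = 1.28, 0.46
AA_LAMBDA, AA_K = 0.267, 0.041

NT_MATCH, NT_MISMATCH = 1, -1
NT_GAP_OPEN, NT_GAP_EXTEND = 2, 1
AA_GAP_OPEN, AA_GAP_EXTEND = 11, 1


def _build_nt_matrix() -> np.ndarray:
    m = np.full((128, 128), NT_MISMATCH, dtype=np.int32)
    for c in "ACGT":
        m[ord(c), ord(c)] = NT_MATCH
    # N never rewards a match
    for c in "ACGTN":
        m[ord("N"), ord(c)] = NT_MISMATCH
        m[ord(c), ord("N")] = NT_MISMATCH
    return m


def _build_aa_matrix() -> np.ndarray:
    blosum = substitution_matrices.load("BLOSUM62")
    m = np.full((128, 128), -4, dtype=np.int32)
    for a in blosum.alphabet:
        for b in blosum.alphabet:
            m[ord(a), ord(b)] = int(blosum[a, b])
    return m


NT_MATRIX = _build_nt_matrix()
AA_MATRIX = _build_aa_matrix()


def encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).astype(np.int32)


@njit(cache=True)
def _sw_fill(q, t, sub, gap_open, gap_extend):  # pragma: no cover - jitted
    n, m = len(q), len(t)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), -10**8, dtype=np.int32)
    F = np.full((n + 1, m + 1), -10**8, dtype=np.int32)
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 stop, 1 diag, 2 E(left), 3 F(up)
    eptr = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1 opened, 0 extended
    fptr = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            e_open = H[i, j - 1] - gap_open - gap_extend
            e_ext = E[i, j - 1] - gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                eptr[i, j] = 1
            else:
                E[i, j] = e_ext
            f_open = H[i - 1, j] - gap_open - gap_extend
            f_ext = F[i - 1, j] - gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                fptr[i, j] = 1
            else:
                F[i, j] = f_ext
            diag = H[i - 1, j - 1] + sub[qi, t[j - 1]]
            h = 0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptr[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return H, ptr, eptr, fptr, best, bi, bj


@njit(cache=True)
def _sw_score_only(q, t, sub, gap_open, gap_extend):  # pragma: no cover - jitted
    n, m = len(q), len(t)
    Hp = np.zeros(m + 1, dtype=np.int32)  # holds previous row until overwritten
    Fp = np.full(m + 1, -10**8, dtype=np.int32)
    best = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        h_diag = 0  # H[i-1, j-1]
        e = -10**8  # E[i, 0]
        for j in range(1, m + 1):
            # Hp[j-1] is already H[i, j-1]; Hp[j] is still H[i-1, j]
            e = max(Hp[j - 1] - gap_open - gap_extend, e - gap_extend)
            Fp[j] = max(Hp[j] - gap_open - gap_extend, Fp[j] - gap_extend)
            h = h_diag + sub[qi, t[j - 1]]
            if e > h:
                h = e
            if Fp[j] > h:
                h = Fp[j]
            if h < 0:
                h = 0
            h_diag = Hp[j]
            Hp[j] = h
            if h > best:
                best = h
    return best


@dataclass
class Alignment:
    """A traced local alignment (coordinates 0-based half-open)."""

    score: int
    matches: int
    mismatches: int
    gap_opens: int
    gap_columns: int
    length: int  # alignment columns
    qstart: int
    qend: int
    tstart: int
    tend: int

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.length


def smith_waterman(query: str, target: str, alphabet: str = "nucleotide") -> Alignment | None:
    """Full local alignment with traceback; None when best score is 0."""
    if alphabet == "nucleotide":
        sub, go, ge = NT_MATRIX, NT_GAP_OPEN, NT_GAP_EXTEND
    else:
        sub, go, ge = AA_MATRIX, AA_GAP_OPEN, AA_GAP_EXTEND
    q, t = encode(query), encode(target)
    if len(q) == 0 or len(t) == 0:
        return None
    H, ptr, eptr, fptr, best, bi, bj = _sw_fill(q, t, sub, go, ge)
    if best <= 0:
        return None
    matches = mismatches = gap_opens = gap_cols = length = 0
    i, j = bi, bj
    state = 0  # 0 = in H, 2 = in E, 3 = in F
    while i > 0 and j > 0:
        if state == 0:
            p = ptr[i, j]
            if p == 0:
                break
            if p == 1:
                length += 1
                if q[i - 1] == t[j - 1]:
                    matches += 1
                else:
                    mismatches += 1
                i -= 1
                j -= 1
            else:
                state = p
        elif state == 2:  # gap in query, consumes target
            length += 1
            gap_cols += 1
            opened = eptr[i, j]
            j -= 1
            if opened:
                gap_opens += 1
                state = 0
        else:  # state == 3, gap in target, consumes query
            length += 1
            gap_cols += 1
            opened = fptr[i, j]
            i -= 1
            if opened:
                gap_opens += 1
                state = 0
    return Alignment(
        score=int(best), matches=matches, mismatches=mismatches,
        gap_opens=gap_opens, gap_columns=gap_cols, length=length,
        qstart=i, qend=bi, tstart=j, tend=bj,
    )


def local_score(query: str, target: str, alphabet: str = "nucleotide") -> int:
    """Best local alignment score only (linear memory)."""
    if alphabet == "nucleotide":
        sub, go, ge = NT_MATRIX, NT_GAP_OPEN, NT_GAP_EXTEND
    else:
        sub, go, ge = AA_MATRIX, AA_GAP_OPEN, AA_GAP_EXTEND
    q, t = encode(query), encode(target)
    if len(q) == 0 or len(t) == 0:
        return 0
    return int(_sw_score_only(q, t, sub, go, ge))


def evalue(score: int, query_len: int, db_len: int, alphabet: str = "nucleotide") -> tuple[float, float]:
    """(e-value, bit score) from a raw score for the database actually searched."""
    lam, k = (NT_LAMBDA, NT_K) if alphabet == "nucleotide" else (AA_LAMBDA, AA_K)
    bits = (lam * score - math.log(k)) / math.log(2.0)
    e = query_len * db_len * math.pow(2.0, -bits)
    return e, bits
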