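"""Vectorized 2-bit k-mer encoding shared by the aligner and the QV module.

K-mers up to k=31 are packed into int64 codes (2 bits per base). Canonical
form is the lexicographic minimum of a k-mer and its reverse complement, so
read strand never matters. Windows containing N are flagged invalid.
"""

from __future__ import annotations

import numpy as np

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _BASE_CODE[ord(b)] = i


def encode_kmers(seq: str, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-position canonical k-mer codes for one sequence.

    Returns ``(codes, fwd_is_canonical, valid)``, each of length
    ``len(seq) - k + 1`` (empty arrays when the sequence is shorter than k).
    ``valid`` is False wherever the window contains a non-ACGT base.
    """
    n = len(seq)
    m = n - k + 1
    if m <= 0:
        z = np.zeros(0, dtype=np.int64)
        return z, np.zeros(0, dtype=bool), np.zeros(0, dtype=bool)
    vals = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    invalid = vals > 3
    vals64 = (vals & 3).astype(np.int64)
    fwd = np.zeros(m, dtype=np.int64)
    rev = np.zeros(m, dtype=np.int64)
    for j in range(k):
        fwd = (fwd << 2) | vals64[j : j + m]
        rev = (rev << 2) | (3 - vals64[k - 1 - j : k - 1 - j + m])
    fwd_canon = fwd <= rev
    codes = np.where(fwd_canon, fwd, rev)
    # window validity: no invalid base in [i, i+k)
    bad = np.concatenate(([0], np.cumsum(invalid, dtype=np.int64)))
    valid = (bad[k:] - bad[:-k]) == 0
    return codes, fwd_canon, valid


class CodeIndex:
    """Code-sorted view of a genome's k-mer multiset, built with one sort.

    ``select(lo, hi)`` returns the (still code-sorted) codes and positions of
    k-mers whose genome-wide multiplicity lies in [lo, hi]; multi-copy codes
    repeat once per occurrence.
    """

    def __init__(self, codes: np.ndarray, valid: np.ndarray):
        pos = np.flatnonzero(valid)
        c = codes[pos]
        order = np.argsort(c, kind="stable")
        self.codes = c[order]
        self.pos = pos[order]
        boundary = np.concatenate(([True], self.codes[1:] != self.codes[:-1]))
        run_ids = np.cumsum(boundary) - 1
        counts = np.bincount(run_ids) if len(run_ids) else np.zeros(0, np.int64)
        self.multiplicity = counts[run_ids] if len(run_ids) else run_ids

    def select(self, lo: int, hi: int) -> tuple[np.ndarray, np.ndarray]:
        keep = (self.multiplicity >= lo) & (self.multiplicity <= hi)
        return self.codes[keep], self.pos[keep]


def unique_code_positions(
    codes: np.ndarray,
    valid: np.ndarray,
    min_count: int = 1,
    max_count: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Positions of k-mers whose genome-wide multiplicity is in range."""
    return CodeIndex(codes, valid).select(min_count, max_count)


def match_sorted(
    a_codes: np.ndarray, b_codes: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Indices into two code-sorted arrays where values match.

    ``b_codes`` must be unique; ``a_codes`` may repeat. Returns
    (a_indices, b_indices) with one row per matching element of ``a_codes``.
    """
    idx = np.searchsorted(b_codes, a_codes)
    idx[idx == len(b_codes)] = max(len(b_codes) - 1, 0)
    hit = len(b_codes) > 0
    sel = (b_codes[idx] == a_codes) if hit else np.zeros(len(a_codes), bool)
    return np.flatnonzero(sel), idx[sel]
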