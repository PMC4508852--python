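"""Dynamic-programming alignment kernels shared across the package.

Two primitives live here:

* a global (Needleman-Wunsch) aligner with unit scores (match +1, mismatch 0,
  linear gap -1) used for the CD-HIT-style identity computation and for
  center-star MSA construction, and
* a local (Smith-Waterman) aligner with affine gaps over a precomputed
  column-pair score matrix, used for profile-profile comparison.

Both are numba-jitted when numba is importable; a pure-Python fallback with
identical semantics is kept so the package degrades gracefully.

The global DP maximises the pair (score, #identities) lexicographically, so
the number of identical aligned positions is well defined even when several
alignments share the optimal score.  Traceback priority is diagonal > up >
left, making alignments fully deterministic.
"""

from __future__ import annotations

import numpy as np

GAP = -1  # linear gap score for the unit-score global aligner

# traceback codes
_DIAG, _UP, _LEFT = 0, 1, 2


def _nw_kernel_py(a, b, ptr):
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1), dtype=np.int64)
    match = np.zeros((n + 1, m + 1), dtype=np.int64)
    for i in range(1, n + 1):
        score[i, 0] = i * GAP
        ptr[i, 0] = _UP
    for j in range(1, m + 1):
        score[0, j] = j * GAP
        ptr[0, j] = _LEFT
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            eq = 1 if ai == b[j - 1] else 0
            sd = score[i - 1, j - 1] + eq
            md = match[i - 1, j - 1] + eq
            su = score[i - 1, j] + GAP
            mu = match[i - 1, j]
            sl = score[i, j - 1] + GAP
            ml = match[i, j - 1]
            # lexicographic max over (score, matches), priority diag > up > left
            bs, bm, bp = sd, md, _DIAG
            if su > bs or (su == bs and mu > bm):
                bs, bm, bp = su, mu, _UP
            if sl > bs or (sl == bs and ml > bm):
                bs, bm, bp = sl, ml, _LEFT
            score[i, j] = bs
            match[i, j] = bm
            ptr[i, j] = bp
    return score[n, m], match[n, m]


def _sw_kernel_py(sigma, gap_open, gap_ext):
    n, m = sigma.shape
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), -np.inf)
    F = np.full((n + 1, m + 1), -np.inf)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_ext)
            F[i, j] = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_ext)
            h = H[i - 1, j - 1] + sigma[i - 1, j - 1]
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0.0:
                h = 0.0
            H[i, j] = h
            if h > best:
                best = h
    return best


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _nw_kernel = njit(cache=False)(_nw_kernel_py)
    _sw_kernel = njit(cache=False)(_sw_kernel_py)
except Exception:  # pragma: no cover
    _nw_kernel = _nw_kernel_py
    _sw_kernel = _sw_kernel_py


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("latin-1"), dtype=np.uint8).astype(np.int64)


def global_align_stats(a: str, b: str) -> tuple[int, int]:
    """Optimal global score and the max #identities among co-optimal alignments."""
    ptr = np.zeros((len(a) + 1, len(b) + 1), dtype=np.int8)
    s, m = _nw_kernel(_encode(a), _encode(b), ptr)
    return int(s), int(m)


def global_align(a: str, b: str) -> tuple[str, str, int, int]:
    """Global alignment of two sequences.

    Returns the two gapped rows plus (score, identities).  Deterministic:
    co-optimal cells are resolved diagonal > up > left.
    """
    ptr = np.zeros((len(a) + 1, len(b) + 1), dtype=np.int8)
    s, m = _nw_kernel(_encode(a), _encode(b), ptr)
    i, j = len(a), len(b)
    ra, rb = [], []
    while i > 0 or j > 0:
        p = ptr[i, j]
        if i > 0 and j > 0 and p == _DIAG:
            ra.append(a[i - 1])
            rb.append(b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and (p == _UP or j == 0):
            ra.append(a[i - 1])
            rb.append("-")
            i -= 1
        else:
            ra.append("-")
            rb.append(b[j - 1])
            j -= 1
    return "".join(reversed(ra)), "".join(reversed(rb)), int(s), int(m)


def local_profile_score(sigma: np.ndarray, gap_open: float = 2.5,
                        gap_extend: float = 0.5) -> float:
    """Best Smith-Waterman score over a column-pair score matrix.

    A gap of length k costs ``gap_open + (k - 1) * gap_extend`` bits.
    The score is clamped at >= 0 (empty local alignment).
    """
    if sigma.size == 0:
        return 0.0
    return float(_sw_kernel(np.ascontiguousarray(sigma, dtype=np.float64),
                            float(gap_open), float(gap_extend)))
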