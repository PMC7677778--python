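"""Exact dynamic-programming alignment kernels.

Row-vectorised numpy implementations of local (Smith-Waterman) and
semi-global alignment with linear gap costs.  These are exact full-matrix
algorithms, used for overlap scoring in the assembler and as the oracle the
seeded mapper is checked against; they are meant for desk-scale instances
(a few kb), not genome-scale mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from hetcorr.simulate import seq_to_codes

# op codes: '=' match, 'X' substitution, 'I' insertion in query
# (consumes query only), 'D' deletion from query (consumes target only)
Ops = list[tuple[str, int]]


def _compress(ops: list[str]) -> Ops:
    out: Ops = []
    for op in ops:
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + 1)
        else:
            out.append((op, 1))
    return out


@dataclass
class LocalAlignment:
    score: float
    query_span: tuple[int, int]  # half-open on sequence a
    target_span: tuple[int, int]  # half-open on sequence b
    ops: Ops

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return sum(n for _, n in self.ops)


def _dp_matrix(a_codes, b_codes, match, mismatch, gap):
    """Full local-alignment DP matrix H[(len(a)+1) x (len(b)+1)]."""
    n, m = a_codes.size, b_codes.size
    H = np.zeros((n + 1, m + 1), dtype=np.float64)
    jgap = np.arange(m + 1) * gap
    for i in range(1, n + 1):
        s = np.where(b_codes == a_codes[i - 1], match, mismatch)
        cand = np.maximum(H[i - 1, :-1] + s, H[i - 1, 1:] + gap)
        cand = np.maximum(cand, 0.0)
        # resolve within-row (horizontal) gaps with a prefix-max scan:
        # H[i,j] = max(cand[j], H[i,j-1] + gap)
        t = np.empty(m + 1)
        t[0] = -jgap[0]
        t[1:] = cand - jgap[1:]
        np.maximum.accumulate(t, out=t)
        row = t + jgap
        row[0] = 0.0
        H[i] = np.maximum(row, 0.0)
    return H


def _traceback(H, a_codes, b_codes, i, j, match, mismatch, gap):
    ops: list[str] = []
    while i > 0 or j > 0:
        h = H[i, j]
        if h == 0:
            break
        if i > 0 and j > 0:
            s = match if a_codes[i - 1] == b_codes[j - 1] else mismatch
            if h == H[i - 1, j - 1] + s:
                ops.append("=" if s == match else "X")
                i -= 1
                j -= 1
                continue
        if i > 0 and h == H[i - 1, j] + gap:
            ops.append("I")
            i -= 1
            continue
        if j > 0 and h == H[i, j - 1] + gap:
            ops.append("D")
            j -= 1
            continue
        break
    ops.reverse()
    return i, j, _compress(ops)


def smith_waterman(
    a: str, b: str, match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0
) -> LocalAlignment:
    """Exact local alignment of ``a`` vs ``b`` (full-matrix Smith-Waterman)."""
    a_codes, b_codes = seq_to_codes(a), seq_to_codes(b)
    H = _dp_matrix(a_codes, b_codes, match, mismatch, gap)
    i, j = np.unravel_index(int(np.argmax(H)), H.shape)
    score = float(H[i, j])
    if score <= 0:
        return LocalAlignment(0.0, (0, 0), (0, 0), [])
    i0, j0, ops = _traceback(H, a_codes, b_codes, int(i), int(j), match, mismatch, gap)
    return LocalAlignment(score, (i0, int(i)), (j0, int(j)), ops)


def semiglobal(
    a: str, b: str, match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0
) -> LocalAlignment:
    """Glocal alignment: all of query ``a`` against a substring of target ``b``.

    Gaps before/after the query's footprint on the target are free; the
    query itself is aligned end to end.  Used as the exhaustive mapping
    oracle.
    """
    a_codes, b_codes = seq_to_codes(a), seq_to_codes(b)
    n, m = a_codes.size, b_codes.size
    # H[i, j]: best score aligning a[:i] ending exactly at target position j,
    # with free leading target gap (H[0, :] = 0).
    H = np.zeros((n + 1, m + 1), dtype=np.float64)
    H[:, 0] = np.arange(n + 1) * gap
    jgap = np.arange(m + 1) * gap
    for i in range(1, n + 1):
        s = np.where(b_codes == a_codes[i - 1], match, mismatch)
        cand = np.maximum(H[i - 1, :-1] + s, H[i - 1, 1:] + gap)
        t = np.empty(m + 1)
        t[0] = H[i, 0] - jgap[0]
        t[1:] = cand - jgap[1:]
        np.maximum.accumulate(t, out=t)
        row = t + jgap
        row[0] = H[i, 0]
        H[i] = row
    j_end = int(np.argmax(H[n]))
    score = float(H[n, j_end])
    # traceback from (n, j_end) until i == 0
    i, j = n, j_end
    ops: list[str] = []
    while i > 0:
        h = H[i, j]
        if j > 0:
            s = match if a_codes[i - 1] == b_codes[j - 1] else mismatch
            if h == H[i - 1, j - 1] + s:
                ops.append("=" if s == match else "X")
                i -= 1
                j -= 1
                continue
            if h == H[i, j - 1] + gap:
                ops.append("D")
                j -= 1
                continue
        if h == H[i - 1, j] + gap:
            ops.append("I")
            i -= 1
            continue
        raise AssertionError("traceback failed")  # pragma: no cover
    ops.reverse()
    return LocalAlignment(score, (0, n), (j, j_end), _compress(ops))
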