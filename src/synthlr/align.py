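"""Affine-gap alignment engines.

Two modes share one banded dynamic-programming core:

* ``local`` — Smith–Waterman local alignment (EMBOSS-water-like scoring),
  used for dual-parent mixture classification;
* ``overlap`` — global alignment with free end gaps on both sequences,
  used to align synthetic reads to their known truth fragments; unaligned
  query ends are reported as clipping.

A gap of length g scores ``gap_open + g * gap_extend`` (both negative).
The band is centred on a diagonal estimated from shared k-mers; with no band
the DP is exact. Scores are float32; all score parameters used here are
exactly representable, so value-based traceback is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io import reverse_complement

NEG = np.float32(-1e30)
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


def _codes(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(slots=True)
class AlignmentStats:
    """Counts over the aligned columns of one pairwise alignment."""

    score: float = 0.0
    matches: int = 0
    mismatches: int = 0
    insertions: int = 0  # query bases aligned to a gap
    deletions: int = 0  # target bases aligned to a gap
    clip_left: int = 0
    clip_right: int = 0
    query_start: int = 0
    query_end: int = 0
    target_start: int = 0
    target_end: int = 0
    strand: str = "+"
    # 0-based query positions of aligned columns and mismatch flags
    query_positions: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    mismatch_flags: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    insertion_positions: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    deletion_positions: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))

    @property
    def aligned_length(self) -> int:
        return self.matches + self.mismatches + self.insertions + self.deletions

    @property
    def identity(self) -> float:
        cols = self.aligned_length
        return self.matches / cols if cols else 0.0

    @property
    def mismatch_rate(self) -> float:
        cols = self.matches + self.mismatches
        return self.mismatches / cols if cols else 0.0


def seed_diagonal(query: str, target: str, k: int = 31) -> Optional[int]:
    """Modal (target - query) offset of shared k-mers, or None if none shared."""
    if len(query) < k or len(target) < k:
        return None
    index: dict[str, list[int]] = {}
    for j in range(len(target) - k + 1):
        index.setdefault(target[j : j + k], []).append(j)
    votes: dict[int, int] = {}
    for i in range(len(query) - k + 1):
        for j in index.get(query[i : i + k], ()):
            d = j - i
            votes[d] = votes.get(d, 0) + 1
    if not votes:
        return None
    return max(sorted(votes), key=lambda d: votes[d])


def shared_kmer_count(query: str, target: str, k: int = 21) -> int:
    tset = {target[j : j + k] for j in range(len(target) - k + 1)}
    return sum(1 for i in range(len(query) - k + 1) if query[i : i + k] in tset)


def _affine_dp(
    query: str,
    target: str,
    match: float,
    mismatch: float,
    gap_open: float,
    gap_extend: float,
    mode: str,
    diagonal: Optional[int] = None,
    bandwidth: Optional[int] = None,
) -> AlignmentStats:
    assert mode in ("local", "overlap")
    n, m = len(query), len(target)
    if n == 0 or m == 0:
        raise ValueError("empty sequence in alignment")
    q = _codes(query)
    t = _codes(target)
    if bandwidth is None or diagonal is None:
        d0, w = 0, n + m  # full DP
    else:
        d0, w = diagonal, max(1, bandwidth)
    lo = np.empty(n + 1, dtype=np.int64)
    hi = np.empty(n + 1, dtype=np.int64)
    lo[0] = max(0, d0 - w)
    hi[0] = min(m, d0 + w)
    for i in range(1, n + 1):
        lo[i] = min(max(1, i + d0 - w), m)
        hi[i] = min(m, i + d0 + w)
    W = int((hi - lo).max()) + 1
    H = np.full((n + 1, W), NEG, dtype=np.float32)
    E = np.full((n + 1, W), NEG, dtype=np.float32)
    F = np.full((n + 1, W), NEG, dtype=np.float32)
    H[0, : hi[0] - lo[0] + 1] = 0.0
    go = np.float32(gap_open)
    ge = np.float32(gap_extend)
    ma = np.float32(match)
    mi = np.float32(mismatch)

    def prev_slice(row: np.ndarray, i: int, j_from: int, j_to: int) -> np.ndarray:
        """row values at columns [j_from, j_to] of DP row i, NEG outside band."""
        out = np.full(j_to - j_from + 1, NEG, dtype=np.float32)
        a = max(j_from, lo[i])
        b = min(j_to, hi[i])
        if a <= b:
            out[a - j_from : b - j_from + 1] = row[a - lo[i] : b - lo[i] + 1]
        return out

    best_val, best_i, best_j = NEG, 0, 0
    for i in range(1, n + 1):
        jl, jr = int(lo[i]), int(hi[i])
        if jl > jr:
            continue
        width = jr - jl + 1
        sub = np.where(t[jl - 1 : jr] == q[i - 1], ma, mi)
        if q[i - 1] == 4:
            sub[:] = mi
        h_diag = prev_slice(H[i - 1], i - 1, jl - 1, jr - 1)
        h_vert = prev_slice(H[i - 1], i - 1, jl, jr)
        f_vert = prev_slice(F[i - 1], i - 1, jl, jr)
        if jl == 1:
            h_diag[0] = 0.0  # column 0: free query prefix (overlap) / fresh start (local)
        Frow = np.maximum(f_vert + ge, h_vert + go + ge)
        G = np.maximum(h_diag + sub, Frow)
        if mode == "local":
            G = np.maximum(G, np.float32(0.0))
        # E via prefix max: E[j] = max_{k<j} G[k] + go + (j-k)*ge
        idx = np.arange(width, dtype=np.float32)
        run = np.maximum.accumulate(G - ge * idx)
        Erow = np.full(width, NEG, dtype=np.float32)
        if width > 1:
            Erow[1:] = run[:-1] + go + ge * idx[1:]
        Hrow = np.maximum(G, Erow)
        H[i, :width] = Hrow
        E[i, :width] = Erow
        F[i, :width] = Frow
        if mode == "local":
            j_best = int(np.argmax(Hrow))
            if Hrow[j_best] > best_val:
                best_val, best_i, best_j = Hrow[j_best], i, jl + j_best
        else:
            if jr == m and Hrow[width - 1] > best_val:
                best_val, best_i, best_j = Hrow[width - 1], i, m
    if mode == "overlap":
        jl, jr = int(lo[n]), int(hi[n])
        row = H[n, : jr - jl + 1]
        j_best = int(np.argmax(row))
        if row[j_best] >= best_val:
            best_val, best_i, best_j = row[j_best], n, jl + j_best
    if best_val <= 0 and mode == "local":
        return AlignmentStats(score=0.0)

    stats = _traceback(
        q, t, H, E, F, lo, hi, int(best_i), int(best_j), mode, ma, mi, go, ge
    )
    stats.score = float(best_val)
    if mode == "overlap":
        stats.clip_left = stats.query_start
        stats.clip_right = n - stats.query_end
    return stats


def _get(mat: np.ndarray, lo: np.ndarray, hi: np.ndarray, i: int, j: int) -> np.float32:
    if i < 0 or j < lo[i] or j > hi[i]:
        return NEG
    return mat[i, j - lo[i]]


def _traceback(q, t, H, E, F, lo, hi, i, j, mode, ma, mi, go, ge) -> AlignmentStats:
    stats = AlignmentStats()
    stats.query_end, stats.target_end = i, j
    qpos: list[int] = []
    mmflag: list[bool] = []
    ins_pos: list[int] = []
    del_pos: list[int] = []
    state = "H"

    def hget(i: int, j: int) -> np.float32:
        if i == 0 or j == 0:
            return np.float32(0.0)  # free prefixes in both modes
        return _get(H, lo, hi, i, j)

    def gval(i: int, j: int) -> np.float32:
        """max over non-E predecessors of cell (i, j)."""
        s = ma if (q[i - 1] == t[j - 1] and q[i - 1] != 4) else mi
        v = max(hget(i - 1, j - 1) + s, _get(F, lo, hi, i, j))
        if mode == "local":
            v = max(v, np.float32(0.0))
        return v

    while True:
        if i == 0 or j == 0:
            break
        if state == "H":
            v = _get(H, lo, hi, i, j)
            if mode == "local" and v <= 0:
                break
            e = _get(E, lo, hi, i, j)
            state = "E" if v == e else "G"
            continue
        if state == "G":
            v = gval(i, j)
            if mode == "local" and v == 0:
                break
            f = _get(F, lo, hi, i, j)
            if v == f:
                state = "F"
                continue
            # diagonal step
            is_mm = not (q[i - 1] == t[j - 1] and q[i - 1] != 4)
            qpos.append(i - 1)
            mmflag.append(is_mm)
            if is_mm:
                stats.mismatches += 1
            else:
                stats.matches += 1
            i -= 1
            j -= 1
            state = "H"
            continue
        if state == "E":
            # consume target base j against a gap
            del_pos.append(i)
            stats.deletions += 1
            e_here = _get(E, lo, hi, i, j)
            e_prev = _get(E, lo, hi, i, j - 1)
            j -= 1
            if e_here == e_prev + ge:
                continue
            state = "G"
            continue
        if state == "F":
            ins_pos.append(i - 1)
            stats.insertions += 1
            f_here = _get(F, lo, hi, i, j)
            f_prev = _get(F, lo, hi, i - 1, j)
            i -= 1
            if f_here == f_prev + ge:
                continue
            state = "H"
            continue
    stats.query_start, stats.target_start = i, j
    stats.query_positions = np.array(qpos[::-1], dtype=np.int64)
    stats.mismatch_flags = np.array(mmflag[::-1], dtype=bool)
    stats.insertion_positions = np.array(ins_pos[::-1], dtype=np.int64)
    stats.deletion_positions = np.array(del_pos[::-1], dtype=np.int64)
    return stats


def local_align(
    query: str,
    target: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
    band: Optional[int] = None,
    max_full_len: int = 800,
) -> AlignmentStats:
    """Optimal (or banded) Smith–Waterman local alignment with affine gaps.

    Exact full DP is used when either sequence is short or no band is
    requested; for two long sequences a band around the shared-k-mer diagonal
    is used (exact whenever the optimal path stays inside the band, which
    holds for the near-collinear comparisons this toolkit makes).
    """
    if not query or not target:
        raise ValueError("local_align requires non-empty sequences")
    if band is None and min(len(query), len(target)) > max_full_len:
        band = max(64, int(0.05 * max(len(query), len(target))))
    diagonal = None
    if band is not None:
        diagonal = seed_diagonal(query, target, k=21)
        if diagonal is None:
            diagonal = seed_diagonal(query, target, k=11)
        if diagonal is None:
            band = None  # no seed: fall back to full DP
    return _affine_dp(
        query, target, match, mismatch, gap_open, gap_extend, "local", diagonal, band
    )


def align_ends_free(
    query: str,
    target: str,
    match: float = 1.0,
    mismatch: float = -4.0,
    gap_open: float = -6.0,
    gap_extend: float = -1.0,
    band: float = 0.05,
    seed_k: int = 31,
) -> Optional[AlignmentStats]:
    """Banded global alignment with free end gaps, seeded by shared k-mers.

    The query is aligned against the target and its reverse complement; the
    better-scoring strand is kept. Returns None when no ``seed_k``-mer is
    shared on either strand (unalignable).
    """
    best: Optional[AlignmentStats] = None
    for strand, qseq in (("+", query), ("-", reverse_complement(query))):
        d0 = seed_diagonal(qseq, target, k=seed_k)
        if d0 is None:
            continue
        w = max(16, int(band * max(len(qseq), len(target))))
        stats = _affine_dp(
            qseq, target, match, mismatch, gap_open, gap_extend, "overlap", d0, w
        )
        stats.strand = strand
        if strand == "-":
            # report positions/clips in original query coordinates
            n = len(query)
            stats.query_positions = (n - 1 - stats.query_positions)[::-1].copy()
            stats.mismatch_flags = stats.mismatch_flags[::-1].copy()
            stats.insertion_positions = (n - 1 - stats.insertion_positions)[::-1].copy()
            stats.clip_left, stats.clip_right = stats.clip_right, stats.clip_left
            stats.query_start, stats.query_end = n - stats.query_end, n - stats.query_start
        if best is None or stats.score > best.score:
            best = stats
    return best
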