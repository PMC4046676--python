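"""Anchor-vs-supporting-read overlap detection.

Supporting reads (SRs) are indexed once per pass with a blocked spaced seed
(contiguous care-blocks separated by a don't-care gap). Each anchor read (AR)
is then scanned base by base; a shared seed key makes an (AR, SR, diagonal)
candidate, which is verified by gapless extension across the full implied
overlap and, when the extension fails on excessive mismatches, by a local
Smith-Waterman alignment. Only forward overlaps (same-strand matches against
the anchor's raw reads) admit an SR pair into the anchor's local cluster: a
forward overlap implies the SR's partner points into the anchor's unsequenced
gap, whereas a reverse overlap implies it points away.

Anchors attracting far more verified hits than the coverage expectation
E = D*(2*(L-O)+1)/L are flagged repetitive and skipped.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np

try:
    import numba as _numba
except ImportError:  # pragma: no cover - numba is a standard dependency
    _numba = None

from .seqs import kmer_codes, revcomp

logger = logging.getLogger("pseudosanger")

#: two 9-base care blocks separated by a 4-base don't-care gap (span 22,
#: weight 18) — short enough to catch minimum-length (30 bp) overlaps on
#: error-carrying reads, heavy enough that random key collisions are
#: negligible at typical depths
DEFAULT_SEED_PATTERN = "1" * 9 + "0" * 4 + "1" * 9


@dataclasses.dataclass(frozen=True)
class OverlapParams:
    """Tunable thresholds of the overlap stage (all exposed on the CLI)."""

    seed_pattern: str = DEFAULT_SEED_PATTERN
    sr_stride: int = 2
    min_overlap: int = 30
    max_mismatch_rate: float = 0.08
    sw_match: int = 1
    sw_mismatch: int = -2
    sw_gap_open: int = -3
    sw_gap_extend: int = -1
    sw_min_identity: float = 0.92
    repeat_factor: float = 1.5
    insert_sd_multiple: float = 3.0

    @property
    def sw_scoring(self) -> tuple[int, int, int, int]:
        return (self.sw_match, self.sw_mismatch,
                self.sw_gap_open, self.sw_gap_extend)


# ---------------------------------------------------------------------------
# spaced-seed index
# ---------------------------------------------------------------------------

class SpacedSeedIndex:
    """Blocked-spaced-seed index over a matrix of equal-length reads.

    Keys are packed 2-bit codes of the care positions; windows containing an N
    are never indexed. Lookup is binary search over the sorted unique keys.
    """

    def __init__(self, reads: np.ndarray, pattern: str = DEFAULT_SEED_PATTERN,
                 step: int = 1):
        if not pattern or pattern[0] != "1" or pattern[-1] != "1" or \
                set(pattern) - {"0", "1"}:
            raise ValueError("pattern must be a 0/1 mask starting/ending in 1")
        if step < 1:
            raise ValueError("step must be >= 1")
        self.pattern = pattern
        self.step = step
        self.care = np.flatnonzero(np.frombuffer(pattern.encode(), np.uint8)
                                   == ord("1"))
        self.span = len(pattern)
        self.weight = len(self.care)
        if 2 * self.weight > 62:
            raise ValueError("seed weight too large to pack into int64")
        reads = np.atleast_2d(np.asarray(reads, dtype=np.uint8))
        self.n_reads, self.read_len = reads.shape
        self.n_skipped_short = 0
        if self.read_len < self.span:
            self.n_skipped_short = self.n_reads
            logger.debug("all %d reads shorter than seed span", self.n_reads)
            self._empty()
            return
        positions = np.arange(0, self.read_len - self.span + 1, step)
        keys = extract_keys(reads, positions, self.care)  # (n, P)
        offs = np.broadcast_to(positions, keys.shape)
        rows = np.broadcast_to(np.arange(self.n_reads)[:, None], keys.shape)
        valid = keys >= 0
        keys, offs, rows = keys[valid], offs[valid], rows[valid]
        order = np.argsort(keys, kind="stable")
        keys = keys[order]
        self.entry_read = rows[order].astype(np.int32)
        self.entry_off = offs[order].astype(np.int32)
        self.unique_keys, starts = np.unique(keys, return_index=True)
        self.bucket_starts = np.append(starts, keys.size).astype(np.int64)

    def _empty(self):
        self.unique_keys = np.empty(0, dtype=np.int64)
        self.bucket_starts = np.zeros(1, dtype=np.int64)
        self.entry_read = np.empty(0, dtype=np.int32)
        self.entry_off = np.empty(0, dtype=np.int32)

    def __len__(self) -> int:
        return self.entry_read.size

    def lookup(self, key: int) -> tuple[np.ndarray, np.ndarray]:
        """(read ids, read offsets) holding this exact key."""
        i = np.searchsorted(self.unique_keys, key)
        if i == self.unique_keys.size or self.unique_keys[i] != key:
            return (np.empty(0, dtype=np.int32),) * 2
        s, e = self.bucket_starts[i], self.bucket_starts[i + 1]
        return self.entry_read[s:e], self.entry_off[s:e]

    def lookup_many(self, keys: np.ndarray):
        """Batch lookup: (query index, read id, read offset) triples."""
        keys = np.asarray(keys, dtype=np.int64)
        pos = np.searchsorted(self.unique_keys, keys)
        pos_c = np.minimum(pos, max(self.unique_keys.size - 1, 0))
        found = (keys >= 0) & (self.unique_keys.size > 0)
        found &= self.unique_keys[pos_c] == keys
        qi = np.flatnonzero(found)
        starts = self.bucket_starts[pos[qi]]
        counts = self.bucket_starts[pos[qi] + 1] - starts
        total = int(counts.sum())
        if total == 0:
            return (np.empty(0, np.int64), np.empty(0, np.int32),
                    np.empty(0, np.int32))
        rep_q = np.repeat(qi, counts)
        base = np.repeat(starts, counts)
        within = np.arange(total) - np.repeat(np.cumsum(counts) - counts,
                                              counts)
        ei = base + within
        return rep_q, self.entry_read[ei], self.entry_off[ei]


def extract_keys(reads: np.ndarray, positions: np.ndarray,
                 care: np.ndarray) -> np.ndarray:
    """Packed seed keys at each start position of each read; -1 where any
    care position holds an N."""
    reads = np.atleast_2d(reads)
    cols = positions[:, None] + care[None, :]
    sub = reads[:, cols].astype(np.int64)  # (n, P, W)
    weights = (np.int64(1) << (2 * np.arange(care.size, dtype=np.int64)))
    keys = (sub * weights).sum(axis=2)
    keys[(sub == 4).any(axis=2)] = -1
    return keys


def build_spaced_index(sr_reads, pattern: str = DEFAULT_SEED_PATTERN,
                       step: int = 1) -> SpacedSeedIndex:
    """Index a read set (matrix of codes or list of strings)."""
    if not isinstance(sr_reads, np.ndarray):
        from .seqs import encode
        if len(sr_reads) == 0:
            sr_reads = np.empty((0, 0), dtype=np.uint8)
        else:
            sr_reads = np.vstack([encode(s) for s in sr_reads])
    return SpacedSeedIndex(sr_reads, pattern, step)


# ---------------------------------------------------------------------------
# candidate scan and gapless verification
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class OverlapHit:
    """A verified pairwise placement of a read against a target sequence.

    ``offset`` is the read's start in target coordinates (may be negative);
    ``strand`` is the read's orientation relative to the target.
    """

    read_id: int
    strand: str  # '+' or '-'
    offset: int
    overlap_len: int
    mismatches: int
    gapped: bool = False
    score: int = 0


def scan_anchor(ar_read: np.ndarray, index: SpacedSeedIndex):
    """All (read id, strand, diagonal) seed candidates along an anchor read.

    The anchor is scanned base by base on both orientations; duplicates are
    collapsed per (read, strand, diagonal). Returns (rows, strands, diags)
    arrays with strands as '+'/'-' characters.
    """
    out_rows, out_strands, out_diags = [], [], []
    for strand, codes in (("+", ar_read), ("-", revcomp(ar_read))):
        rows, diags = _scan_one_strand(codes, index)
        out_rows.append(rows)
        out_diags.append(diags)
        out_strands.append(np.full(rows.size, strand))
    return (np.concatenate(out_rows), np.concatenate(out_strands),
            np.concatenate(out_diags))


def _scan_one_strand(target: np.ndarray, index: SpacedSeedIndex):
    """Dedup'd (read row, diagonal) seed candidates, target scanned as-is.

    diagonal = read start position in target coordinates.
    """
    T = target.size
    if T < index.span or len(index) == 0:
        return np.empty(0, np.int32), np.empty(0, np.int64)
    positions = np.arange(0, T - index.span + 1)
    keys = extract_keys(target, positions, index.care)[0]
    qi, rows, offs = index.lookup_many(keys)
    if qi.size == 0:
        return np.empty(0, np.int32), np.empty(0, np.int64)
    diags = positions[qi] - offs
    packed = rows.astype(np.int64) * (2 * (T + index.read_len) + 1) + \
        (diags + index.read_len)
    _, first = np.unique(packed, return_index=True)
    return rows[first], diags[first]


def batch_gapless(target: np.ndarray, reads: np.ndarray, rows: np.ndarray,
                  diags: np.ndarray):
    """Gapless extension over the full implied overlap for many candidates.

    Returns (overlap_len, mismatches) arrays; N counts as a mismatch. One
    vectorized comparison against a padded sliding-window view of the target
    covers every candidate regardless of diagonal; padding positions always
    mismatch and are subtracted out.
    """
    T = target.size
    reads = np.atleast_2d(reads)
    L = reads.shape[1]
    ov = np.zeros(rows.size, dtype=np.int64)
    mism = np.zeros(rows.size, dtype=np.int64)
    if rows.size == 0:
        return ov, mism
    padded = np.full(T + 2 * L, 5, dtype=np.uint8)  # 5: matches nothing
    padded[L:L + T] = target
    win = np.lib.stride_tricks.sliding_window_view(padded, L)
    d = np.clip(diags, -L, T)
    sub = win[d + L]
    rd = reads[rows]
    tot = ((sub != rd) | (sub == 4) | (rd == 4)).sum(axis=1)
    ov = np.maximum(np.minimum(T, d + L) - np.maximum(0, d), 0)
    mism = np.where(ov > 0, tot - (L - ov), 0)
    return ov.astype(np.int64), mism.astype(np.int64)


def gapless_extend(ar_read: np.ndarray, sr_read: np.ndarray, diagonal: int,
                   min_overlap: int = 30,
                   max_mismatch_rate: float = 0.08) -> OverlapHit | None:
    """Extend a single candidate without gaps across the implied overlap.

    Returns a hit when the overlap is long enough and the mismatch fraction
    is within threshold, else None (caller falls back to :func:`sw_align`).
    """
    sr_read = np.asarray(sr_read, dtype=np.uint8)
    ov, mism = batch_gapless(ar_read, sr_read[None, :],
                             np.zeros(1, np.int64),
                             np.asarray([diagonal], np.int64))
    o, m = int(ov[0]), int(mism[0])
    if o < min_overlap or m > max_mismatch_rate * o:
        return None
    return OverlapHit(read_id=0, strand="+", offset=int(diagonal),
                      overlap_len=o, mismatches=m, score=o - 2 * m)


# ---------------------------------------------------------------------------
# Smith-Waterman (affine gaps, Gotoh)
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SWAlignment:
    """Optimal local alignment with affine gap costs.

    Intervals are 0-based half-open; cigar is a list of (op, length) with ops
    'M' (match/mismatch column), 'I' (base in a only), 'D' (base in b only).
    """

    score: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    cigar: list[tuple[str, int]]
    matches: int
    columns: int

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


def _sw_fill_numpy(a, b, match, mismatch, gap_open, gap_ext):
    n, m = a.size, b.size
    NEG = -(10**9)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in b (vertical)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in a (horizontal)
    jj = np.arange(1, m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        sub = np.where((b == a[i - 1]) & (a[i - 1] != 4) & (b != 4),
                       match, mismatch)
        F[i, 1:] = np.maximum(F[i - 1, 1:] + gap_ext, H[i - 1, 1:] + gap_open)
        G = np.maximum.reduce([np.zeros(m, dtype=np.int64),
                               H[i - 1, :-1] + sub, F[i, 1:]])
        # E exactly via prefix max: re-opening from an E-derived H cell is
        # never better than extending, because gap_open <= gap_ext.
        T = np.full(m + 1, NEG, dtype=np.int64)
        T[0] = H[i, 0]  # j=0 column of H is 0
        T[1:] = G - gap_ext * jj
        runmax = np.maximum.accumulate(T[:-1])
        E[i, 1:] = runmax + gap_ext * (jj - 1) + gap_open
        H[i, 1:] = np.maximum(G, E[i, 1:])
    return H, E, F


def _sw_fill_plain(a, b, match, mismatch, gap_open, gap_ext):  # noqa: C901
    n, m = a.size, b.size
    NEG = -(10**9)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            bj = b[j - 1]
            s = match if (ai == bj and ai != 4 and bj != 4) else mismatch
            e = max(H[i, j - 1] + gap_open, E[i, j - 1] + gap_ext)
            f = max(H[i - 1, j] + gap_open, F[i - 1, j] + gap_ext)
            h = max(0, H[i - 1, j - 1] + s, e, f)
            E[i, j] = e
            F[i, j] = f
            H[i, j] = h
    return H, E, F


if _numba is not None:
    _sw_fill = _numba.njit(cache=False)(_sw_fill_plain)
else:  # pragma: no cover
    _sw_fill = _sw_fill_numpy


def sw_align(seq_a: np.ndarray, seq_b: np.ndarray,
             scoring: tuple[int, int, int, int] = (1, -2, -3, -1),
             ) -> SWAlignment | None:
    """Smith-Waterman local alignment of two code arrays (Gotoh affine).

    Ties are broken toward the smaller end coordinate in a, then in b, and a
    deterministic diagonal > deletion > insertion preference in the traceback.
    Returns None when no cell scores positive.
    """
    a = np.asarray(seq_a, dtype=np.uint8)
    b = np.asarray(seq_b, dtype=np.uint8)
    if a.size == 0 or b.size == 0:
        raise ValueError("sequences must be non-empty")
    match, mismatch, gap_open, gap_ext = scoring
    if gap_open > gap_ext:
        raise ValueError("gap_open must be <= gap_extend (both negative)")
    n, m = a.size, b.size
    H, E, F = _sw_fill(a, b, match, mismatch, gap_open, gap_ext)
    best = int(H.max())
    if best <= 0:
        return None
    flat = np.flatnonzero(H.ravel() == best)[0]
    i, j = divmod(int(flat), m + 1)
    a_end, b_end = i, j
    # traceback
    cigar_rev: list[str] = []
    matches = 0
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0:
                break
            sub = match if (a[i - 1] == b[j - 1] and a[i - 1] != 4) \
                else mismatch
            if H[i, j] == H[i - 1, j - 1] + sub:
                cigar_rev.append("M")
                matches += a[i - 1] == b[j - 1] and a[i - 1] != 4
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            cigar_rev.append("I")
            if F[i, j] != F[i - 1, j] + gap_ext:
                state = "H"
            i -= 1
        else:  # E
            cigar_rev.append("D")
            if E[i, j] != E[i, j - 1] + gap_ext:
                state = "H"
            j -= 1
    cigar: list[tuple[str, int]] = []
    for op in reversed(cigar_rev):
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    return SWAlignment(score=best, a_start=i, a_end=a_end, b_start=j,
                       b_end=b_end, cigar=cigar, matches=int(matches),
                       columns=len(cigar_rev))


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ClusterMember:
    """One admitted SR pair, orientation-normalized to fragment-forward.

    ``aligned_fwd`` overlapped an anchor read directly; its offset is relative
    to that anchor read's start (left anchor = fragment coordinate 0; right
    anchor offsets become fragment coordinates only once the layout fixes the
    span). ``partner_fwd`` fills the gap and is placed by the overlap graph.
    """

    pair_row: int
    side: str  # 'L' (overlaps left anchor) or 'R'
    aligned_read_row: int
    aligned_fwd: np.ndarray
    anchor_offset: int
    partner_read_row: int
    partner_fwd: np.ndarray
    overlap_len: int
    mismatches: int


@dataclasses.dataclass
class LocalCluster:
    """Everything local assembly needs for one anchor pair."""

    ar_id: str
    left_anchor_seq: np.ndarray   # AR read1, fragment-forward
    right_anchor_seq: np.ndarray  # revcomp(AR read2), fragment-forward
    insert_range: tuple[int, int]
    members: list[ClusterMember]
    n_anchor_hits: int = 0
    repetitive: bool = False


def cluster_for_anchor(ar_read1: np.ndarray, ar_read2: np.ndarray,
                       pool, index: SpacedSeedIndex,
                       params: OverlapParams,
                       insert_range: tuple[int, int],
                       ar_id: str = "AR") -> LocalCluster:
    """Collect the forward-overlapping SR pairs of one anchor pair.

    Each anchor read is scanned on its own strand only: a same-strand
    (forward) overlap implies the SR partner points into the anchor gap, so
    the pair is admitted with both reads re-expressed fragment-forward;
    reverse-strand overlaps are discarded. Partners are admitted untested and
    vetted later by the overlap graph. ``pool`` is an :class:`SRPool`.
    """
    members: list[ClusterMember] = []
    n_hits = 0
    for side, anchor in (("L", ar_read1), ("R", ar_read2)):
        rows, diags = _scan_one_strand(anchor, index)
        if rows.size == 0:
            continue
        ov, mism = batch_gapless(anchor, pool.reads, rows, diags)
        ok = (ov >= params.min_overlap) & \
             (mism <= params.max_mismatch_rate * ov)
        n_hits += int(ok.sum())
        for r, d, o, mm in zip(rows[ok], diags[ok], ov[ok], mism[ok]):
            r = int(r)
            partner = pool.partner_row(r)
            if side == "L":
                aligned_fwd = pool.reads[r]
                partner_fwd = revcomp(pool.reads[partner])
                offset = int(d)
            else:
                # X matched AR read2 raw; fragment-forward X = revcomp(X) at
                # offset -d relative to the right anchor's start.
                aligned_fwd = revcomp(pool.reads[r])
                partner_fwd = pool.reads[partner]
                offset = -int(d)
            members.append(ClusterMember(
                pair_row=r >> 1, side=side, aligned_read_row=r,
                aligned_fwd=aligned_fwd, anchor_offset=offset,
                partner_read_row=partner, partner_fwd=partner_fwd,
                overlap_len=int(o), mismatches=int(mm),
            ))
    return LocalCluster(ar_id=ar_id, left_anchor_seq=ar_read1,
                        right_anchor_seq=revcomp(ar_read2),
                        insert_range=insert_range, members=members,
                        n_anchor_hits=n_hits)


# ---------------------------------------------------------------------------
# repeat gate
# ---------------------------------------------------------------------------

def expected_sr_count(L: int, O: int, D: float) -> float:
    """Expected number of SR reads forward-overlapping an anchor pair.

    Under uniform coverage, read starts landing within +-(L-O) of an anchor
    read's start occur at rate D/L per position, giving D*(2*(L-O)+1)/L per
    strand-compatible anchor read; summed over the two anchor reads and
    halved for strand this equals the same expression with the full depth D.
    """
    if not (0 < O <= L):
        raise ValueError("require 0 < O <= L")
    if D <= 0:
        raise ValueError("depth must be positive")
    return D * (2 * (L - O) + 1) / L


def is_repetitive(cluster: "LocalCluster | int", E: float,
                  factor: float = 1.5) -> bool:
    """True iff verified anchor hits strictly exceed factor * E."""
    if E <= 0:
        raise ValueError("E must be positive")
    count = cluster if isinstance(cluster, (int, np.integer)) \
        else cluster.n_anchor_hits
    return count > factor * E


# ---------------------------------------------------------------------------
# SR pool
# ---------------------------------------------------------------------------

class SRPool:
    """All supporting reads of one pass, stacked for vectorized access.

    Row 2*i is pair i's read1 and row 2*i+1 its read2; ``partner_row`` flips
    the last bit. Pairs keep their (library index, within-library index)
    provenance for bookkeeping.
    """

    def __init__(self, libraries: Sequence, lib_indices: Sequence[int]):
        mats, self.pair_lib, self.pair_within = [], [], []
        for li, lib in zip(lib_indices, libraries):
            inter = np.empty((2 * lib.n_pairs, lib.read_length),
                             dtype=np.uint8)
            inter[0::2] = lib.reads1
            inter[1::2] = lib.reads2
            mats.append(inter)
            self.pair_lib.append(np.full(lib.n_pairs, li, dtype=np.int32))
            self.pair_within.append(np.arange(lib.n_pairs, dtype=np.int32))
        if mats:
            self.reads = np.vstack(mats)
            self.pair_lib = np.concatenate(self.pair_lib)
            self.pair_within = np.concatenate(self.pair_within)
        else:
            self.reads = np.empty((0, 0), dtype=np.uint8)
            self.pair_lib = np.empty(0, dtype=np.int32)
            self.pair_within = np.empty(0, dtype=np.int32)
        self.libraries = list(libraries)
        self.lib_indices = list(lib_indices)

    @property
    def n_pairs(self) -> int:
        return self.pair_lib.size

    @property
    def read_length(self) -> int:
        return self.reads.shape[1]

    @staticmethod
    def partner_row(row: int) -> int:
        return row ^ 1

    def pair_of(self, row: int) -> int:
        return row >> 1

    def insert_spec(self, pair_index: int):
        """LibrarySpec of the library this pair came from."""
        li = int(self.pair_lib[pair_index])
        return self.libraries[self.lib_indices.index(li)].spec
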