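"""Inner-SR recruitment and final consensus of a pseudo-Sanger read.

The primitive consensus is built from only the handful of reads on the layout
path; its quality is then raised by recruiting every SR pair located inside
the primitive's span and re-voting all columns. Recruitment follows a cheap
first pass (spaced-seed match plus gapless verification, no gap alignment);
for pairs with exactly one placed end the partner is sought inside the window
implied by its library's insert range — first by a gapless scan over every
offset in the window, then, if that fails, by Smith-Waterman. Pairs whose
partner cannot be placed on the primitive are dropped entirely, so only
both-ends-inside pairs vote. Placements may overhang the primitive ends; the
overlapping part (>= min_overlap) is verified and clipped, which keeps the
terminal columns as deep as the interior.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .assembly import OverlapGraph, PrimitivePS, placement_rank, vote_columns
from .overlap import (OverlapParams, SpacedSeedIndex, SRPool, batch_gapless,
                      _scan_one_strand, sw_align)
from .seqs import decode, kmer_codes, revcomp

_PRESCREEN_K = 12


@dataclasses.dataclass(frozen=True)
class InnerPlacement:
    """A recruited SR read placed on the primitive PS sequence."""

    pair_row: int
    read_row: int
    orient: str            # '+' raw read matches the primitive forward
    offset: int            # read start in primitive coordinates (may be < 0)
    overlap_len: int
    mismatches: int
    gapped: bool = False
    # read-local half-open interval whose alignment was verified; only these
    # bases may vote in the final consensus (None = whole read)
    vote_interval: tuple[int, int] | None = None


@dataclasses.dataclass
class PSRead:
    """Final pseudo-Sanger read with per-column depth and derived quality."""

    id: str
    sequence: np.ndarray          # uint8 codes
    depth: np.ndarray
    quality: np.ndarray           # per-column Phred score (int)
    anchor_library: str
    flags: frozenset[str]         # {'refined'} or {'primitive_only'}
    source_pair_id: str = ""

    def __len__(self) -> int:
        return self.sequence.size

    @property
    def seq_str(self) -> str:
        return decode(self.sequence)

    @property
    def quality_str(self) -> str:
        return "".join(chr(33 + q) for q in self.quality)


# ---------------------------------------------------------------------------
# recruitment
# ---------------------------------------------------------------------------

def recruit_inner_srs(primitive: PrimitivePS, pool: SRPool,
                      sr_index: SpacedSeedIndex,
                      params: OverlapParams | None = None,
                      ) -> list[InnerPlacement]:
    """Place every SR pair whose two reads both land on the primitive.

    First pass: seed candidates on both orientations of the primitive,
    verified by gapless extension only. Pairs with one placed end get a
    partner rescue inside the insert-range window (gapless offset scan, then
    Smith-Waterman); pairs whose partner window falls off the primitive, or
    whose partner cannot be verified, are discarded entirely.
    """
    params = params or OverlapParams()
    prim = primitive.sequence
    span = primitive.span
    L = pool.read_length
    if pool.n_pairs == 0 or span < params.min_overlap:
        return []
    placed: dict[int, InnerPlacement] = {}  # read_row -> best placement
    for orient, target in (("+", prim), ("-", revcomp(prim))):
        rows, diags = _scan_one_strand(target, sr_index)
        if rows.size == 0:
            continue
        ov, mism = batch_gapless(target, pool.reads, rows, diags)
        ok = (ov >= params.min_overlap) & \
             (mism <= params.max_mismatch_rate * ov)
        for r, d, o, mm in zip(rows[ok], diags[ok], ov[ok], mism[ok]):
            off = int(d) if orient == "+" else span - int(d) - L
            cand = InnerPlacement(pair_row=int(r) >> 1, read_row=int(r),
                                  orient=orient, offset=off,
                                  overlap_len=int(o), mismatches=int(mm))
            prev = placed.get(int(r))
            if prev is None or _better(cand, prev):
                placed[int(r)] = cand
    # pair rule: both reads inside, or partner rescued, else dropped
    by_pair: dict[int, list[InnerPlacement]] = {}
    for pl in placed.values():
        by_pair.setdefault(pl.pair_row, []).append(pl)
    ctx = _ScanContext(prim, L)
    out: list[InnerPlacement] = []
    for pair_row, pls in sorted(by_pair.items()):
        if len(pls) == 2:
            out.extend(sorted(pls, key=lambda p: p.read_row))
            continue
        pl = pls[0]
        rescue = _rescue_partner(pl, prim, pool, params, ctx)
        if rescue is not None:
            out.extend(sorted([pl, rescue], key=lambda p: p.read_row))
    return out


class _ScanContext:
    """Precomputed sliding windows and 12-mers of one primitive sequence,
    plus the Smith-Waterman rescue budget for this recruitment round.

    The budget bounds worst-case work in repeat-dense spans, where hundreds
    of half-placed foreign pairs can pass the k-mer prescreen; pairs are
    processed in deterministic (sorted) order, so results are reproducible.
    """

    SW_BUDGET = 12

    def __init__(self, prim: np.ndarray, L: int):
        padded = np.full(prim.size + 2 * L, 4, dtype=np.uint8)
        padded[L:L + prim.size] = prim
        self.win = np.lib.stride_tricks.sliding_window_view(padded, L)
        self.prim_k = kmer_codes(prim, _PRESCREEN_K).ravel() \
            if prim.size >= _PRESCREEN_K else np.empty(0, np.int64)
        self.sw_budget = self.SW_BUDGET


def _better(a: InnerPlacement, b: InnerPlacement) -> bool:
    ka = (a.mismatches / max(a.overlap_len, 1), -a.overlap_len, a.offset)
    kb = (b.mismatches / max(b.overlap_len, 1), -b.overlap_len, b.offset)
    return ka < kb


def _rescue_partner(pl: InnerPlacement, prim: np.ndarray, pool: SRPool,
                    params: OverlapParams,
                    ctx: "_ScanContext | None" = None
                    ) -> InnerPlacement | None:
    """Place the unplaced mate of a half-placed pair, or None to drop it.

    Within a proper pair the '+'-oriented read is the fragment's left end and
    the '-'-oriented read its right end, separated by the library insert.
    """
    span = prim.size
    L = pool.read_length
    partner_row = pool.partner_row(pl.read_row)
    spec = pool.insert_spec(pl.pair_row)
    imin, imax = spec.insert_range(params.insert_sd_multiple)
    if pl.orient == "+":
        orient = "-"
        lo, hi = pl.offset + imin - L, pl.offset + imax - L
    else:
        orient = "+"
        lo, hi = pl.offset + L - imax, pl.offset + L - imin
    O = params.min_overlap
    lo = max(lo, -(L - O))
    hi = min(hi, span - O)
    if hi < lo:
        return None  # implied window beyond the primitive
    raw = pool.reads[partner_row]
    read = raw if orient == "+" else revcomp(raw)
    ctx = ctx or _ScanContext(prim, L)
    best = _gapless_window_scan(prim, read, lo, hi, params, ctx)
    if best is None and ctx.sw_budget > 0 and \
            _shares_kmer(prim, read, lo, hi, L, params.min_overlap, ctx=ctx):
        ctx.sw_budget -= 1
        best = _sw_window(prim, read, lo, hi, params)
    if best is None:
        return None
    off, o, mm, gapped, vote_iv = best
    return InnerPlacement(pair_row=pl.pair_row, read_row=partner_row,
                          orient=orient, offset=off, overlap_len=o,
                          mismatches=mm, gapped=gapped,
                          vote_interval=vote_iv)


def _gapless_window_scan(prim: np.ndarray, read: np.ndarray, lo: int,
                         hi: int, params: OverlapParams,
                         ctx: "_ScanContext | None" = None):
    """Try every offset in [lo, hi]; return the best passing placement."""
    span, L = prim.size, read.size
    ctx = ctx or _ScanContext(prim, L)
    offs = np.arange(lo, hi + 1)
    sub = ctx.win[offs + L]
    tot = ((sub != read) | (sub == 4) | (read == 4)).sum(axis=1)
    ov = np.minimum(span, offs + L) - np.maximum(0, offs)
    mism = tot - (L - ov)
    ok = (ov >= params.min_overlap) & (mism <= params.max_mismatch_rate * ov)
    if not ok.any():
        return None
    rate = np.where(ok, mism / np.maximum(ov, 1), np.inf)
    key = rate - ov * 1e-9  # prefer low rate, then long overlap
    i = int(np.argmin(key))
    return int(offs[i]), int(ov[i]), int(mism[i]), False, None


def _shares_kmer(prim: np.ndarray, read: np.ndarray, lo: int, hi: int,
                 L: int, min_overlap: int = 30, slack: int = 5,
                 ctx: "_ScanContext | None" = None) -> bool:
    """Prescreen before Smith-Waterman: a shared 12-mer whose implied offset
    both lies (within indel slack) inside the window and permits at least the
    minimum overlap. The gapless scan already covered every exact offset, so
    Smith-Waterman can only help when an indel shifts the diagonal."""
    a = max(0, lo)
    b = min(prim.size, hi + L)
    if b - a < _PRESCREEN_K:
        return False
    ctx = ctx or _ScanContext(prim, L)
    kw = ctx.prim_k[a:max(a, b - _PRESCREEN_K + 1)]
    kr = kmer_codes(read, _PRESCREEN_K).ravel()
    common, iw, ir = np.intersect1d(kw, kr, return_indices=True)
    keep = common >= 0
    if not keep.any():
        return False
    offs = a + iw[keep] - ir[keep]
    span = prim.size
    ov = np.minimum(span, offs + L) - np.maximum(0, offs)
    ok = (offs >= lo - slack) & (offs <= hi + slack) & (ov >= min_overlap)
    return bool(ok.any())


def _sw_window(prim: np.ndarray, read: np.ndarray, lo: int, hi: int,
               params: OverlapParams, end_slack: int = 4):
    """Smith-Waterman placement of a partner inside its insert window.

    The local alignment must cover (within a small slack) the read's whole
    extent inside the primitive's span: a partial high-identity alignment —
    e.g. the repeat-matching half of a read that truly belongs elsewhere —
    is rejected, and only the aligned read interval is allowed to vote.
    """
    span, L = prim.size, read.size
    a = max(0, lo)
    b = min(span, hi + L)
    if b <= a:
        return None
    aln = sw_align(read, prim[a:b], params.sw_scoring)
    if aln is None or aln.columns < params.min_overlap or \
            aln.identity < params.sw_min_identity:
        return None
    off = a + aln.b_start - aln.a_start
    ext_lo = max(0, -off)                 # read-local in-span extent
    ext_hi = min(L, span - off)
    if aln.a_start > ext_lo + end_slack or aln.a_end < ext_hi - end_slack:
        return None
    return (int(off), int(aln.columns), int(aln.columns - aln.matches), True,
            (int(aln.a_start), int(aln.a_end)))


# ---------------------------------------------------------------------------
# final consensus
# ---------------------------------------------------------------------------

def final_consensus(primitive: PrimitivePS,
                    placements: list[InnerPlacement],
                    graph: OverlapGraph, pool: SRPool,
                    ps_id: str = "PS", anchor_library: str = "",
                    source_pair_id: str = "") -> PSRead:
    """Re-vote every column over layout reads plus recruited inner SRs.

    Same tie rules as the layout consensus (plurality; tie toward the
    smaller-offset read; anchor reads outrank SRs). Per-column quality is the
    Phred-scaled confidence of the winning base, capped at Q40.
    """
    span = primitive.span
    votes = [
        (graph.node_codes[node], off,
         placement_rank(off, graph.nodes[node].kind.startswith("anchor"), i))
        for i, (node, off) in enumerate(primitive.placements)
    ]
    base_i = len(votes)
    for i, pl in enumerate(placements):
        raw = pool.reads[pl.read_row]
        codes = raw if pl.orient == "+" else revcomp(raw)
        off = pl.offset
        if pl.vote_interval is not None:
            lo_v, hi_v = pl.vote_interval
            codes = codes[lo_v:hi_v]
            off = off + lo_v
        votes.append((codes, off,
                      placement_rank(off, False, base_i + i)))
    seq, depth, counts = vote_columns(span, votes)
    winner = counts[np.arange(span), np.minimum(seq, 3)]
    with np.errstate(divide="ignore", invalid="ignore"):
        f_major = np.where(depth > 0, winner / np.maximum(depth, 1), 0.0)
    err = np.maximum(1.0 - f_major, 1e-4)
    qual = np.minimum(40, np.rint(-10 * np.log10(err)).astype(int))
    qual[depth == 0] = 0
    flags = frozenset({"refined"} if placements else {"primitive_only"})
    return PSRead(id=ps_id, sequence=seq, depth=depth, quality=qual,
                  anchor_library=anchor_library, flags=flags,
                  source_pair_id=source_pair_id)
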