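"""Constrained local overlap-layout-consensus assembly of one cluster.

An overlap graph is built over the cluster's fragment-forward reads (anchors,
anchor-overlapping SRs and their partners): nodes are reads, directed edges
are suffix-prefix overlaps of at least the minimum overlap passing the
identity threshold. The layout search is constrained to start at the left
anchor read and end at the right anchor read, maximizes the total number of
overlapped bases, and only accepts layouts whose span falls inside the anchor
library's insert range. The consensus over the layout's reads is the
primitive pseudo-Sanger sequence.

Because every edge carries a strictly positive start offset, path span grows
monotonically along any walk; the layout optimum is found exactly by dynamic
programming over (node, span-offset) states — for uniform read length L the
total overlapped bases of a path equal n_edges*L - span_offset, so maximizing
edge count per offset and then scanning feasible spans maximizes overlap.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np

from .overlap import LocalCluster, OverlapParams, sw_align
from .seqs import decode

_GRAPH_K = 16          # exact k-mer used for in-cluster candidate discovery
_MAX_RUN = 64          # cap on k-mer bucket size (repeat guard)
_SW_BUDGET = 200       # max Smith-Waterman fallbacks per cluster
_RANK_CAP = (1 << 31) - 1


@dataclasses.dataclass
class GraphNode:
    """One fragment-forward read in the overlap graph."""

    read_row: int          # row in the SR pool; -1 for anchors
    orient: str            # '+' raw, '-' reverse-complemented
    kind: str              # 'anchor_L', 'anchor_R', 'member', 'partner'
    pair_row: int = -1


@dataclasses.dataclass
class OverlapGraph:
    """Reads as nodes, verified suffix-prefix overlaps as directed edges."""

    node_codes: np.ndarray          # (n, L) uint8
    nodes: list[GraphNode]
    edge_u: np.ndarray
    edge_v: np.ndarray
    edge_d: np.ndarray              # start offset of v relative to u (> 0)
    edge_ov: np.ndarray
    edge_mism: np.ndarray
    containments: list[tuple[int, int]]     # duplicate/contained node pairs
    sw_cigars: dict[tuple[int, int], list]  # gapped edges (rare)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return self.edge_u.size

    @property
    def read_length(self) -> int:
        return self.node_codes.shape[1]


@dataclasses.dataclass
class Layout:
    """Ordered read placements from the left anchor to the right anchor."""

    placements: list[tuple[int, int]]   # (node id, offset from left anchor)
    total_span: int
    total_overlap: int


@dataclasses.dataclass
class PrimitivePS:
    """First-pass consensus over the layout reads."""

    sequence: np.ndarray          # uint8 codes, length == span
    depth: np.ndarray             # per-column vote count
    placements: list[tuple[int, int]]
    span: int


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def build_overlap_graph(cluster: LocalCluster,
                        params: OverlapParams | None = None) -> OverlapGraph:
    """Assemble the overlap graph of a (non-repetitive) cluster.

    Candidate shifts between cluster reads are discovered via shared exact
    16-mers, verified by gapless comparison over the implied overlap, with a
    Smith-Waterman fallback for candidates that fail on mismatches. Zero-shift
    duplicates are recorded as containments, never as path edges.
    """
    params = params or OverlapParams()
    codes_list = [cluster.left_anchor_seq, cluster.right_anchor_seq]
    nodes = [GraphNode(-1, "+", "anchor_L"), GraphNode(-1, "+", "anchor_R")]
    seen: dict[tuple[int, str], int] = {}
    for m in cluster.members:
        a_or = "+" if m.side == "L" else "-"
        p_or = "-" if m.side == "L" else "+"
        for row, orient, codes, kind in (
            (m.aligned_read_row, a_or, m.aligned_fwd, "member"),
            (m.partner_read_row, p_or, m.partner_fwd, "partner"),
        ):
            if (row, orient) not in seen:
                seen[(row, orient)] = len(nodes)
                nodes.append(GraphNode(row, orient, kind, m.pair_row))
                codes_list.append(codes)
    node_codes = np.vstack(codes_list) if codes_list else \
        np.empty((0, 0), dtype=np.uint8)
    n = len(nodes)
    L = node_codes.shape[1]

    cand = _kmer_candidates(node_codes)
    eu, ev, ed, eo, em = [], [], [], [], []
    containments: list[tuple[int, int]] = []
    sw_cigars: dict[tuple[int, int], list] = {}
    sw_left = _SW_BUDGET
    if cand.size:
        i, j, t = cand[:, 0], cand[:, 1], cand[:, 2]
        # normalize direction: edge runs from the left-starting read
        u = np.where(t >= 0, i, j)
        v = np.where(t >= 0, j, i)
        d = np.abs(t)
        packed = np.sort((u * n + v) * (2 * L + 1) + d)
        uniq = packed[np.concatenate(([True], np.diff(packed) != 0))] \
            if packed.size else packed
        d = (uniq % (2 * L + 1)).astype(np.int64)
        uv = uniq // (2 * L + 1)
        u, v = uv // n, uv % n
        ov = L - d
        keep = (d == 0) | (ov >= params.min_overlap)
        u, v, d, ov = u[keep], v[keep], d[keep], ov[keep]
        mism = _pairwise_mismatches(node_codes, u, v, d)
        dup = (d == 0) & (mism <= params.max_mismatch_rate * L)
        containments = [(int(a), int(b)) for a, b in zip(u[dup], v[dup])]
        good = (d > 0) & (mism <= params.max_mismatch_rate * ov)
        eu, ev, ed = list(u[good]), list(v[good]), list(d[good])
        eo, em = list(ov[good]), list(mism[good])
        retry = (d > 0) & ~good & (mism <= 0.2 * ov)
        for ui, vi in zip(u[retry], v[retry]):
            if sw_left <= 0:
                break
            sw_left -= 1
            aln = sw_align(node_codes[ui], node_codes[vi], params.sw_scoring)
            if aln is None or aln.columns < params.min_overlap or \
                    aln.identity < params.sw_min_identity:
                continue
            if aln.a_end != L or aln.b_start != 0 or aln.a_start == 0:
                continue  # not a proper suffix-prefix dovetail
            eu.append(ui); ev.append(vi); ed.append(aln.a_start)
            eo.append(aln.columns)
            em.append(aln.columns - aln.matches)
            sw_cigars[(int(ui), int(vi))] = aln.cigar
    return OverlapGraph(
        node_codes=node_codes, nodes=nodes,
        edge_u=np.asarray(eu, dtype=np.int32),
        edge_v=np.asarray(ev, dtype=np.int32),
        edge_d=np.asarray(ed, dtype=np.int32),
        edge_ov=np.asarray(eo, dtype=np.int32),
        edge_mism=np.asarray(em, dtype=np.int32),
        containments=containments, sw_cigars=sw_cigars,
    )


def _kmer_candidates(node_codes: np.ndarray) -> np.ndarray:
    """(i, j, t) triples with i < j sharing a k-mer; t = start of j in i's
    coordinates. Not deduplicated."""
    from .seqs import kmer_codes
    n, L = node_codes.shape
    if n < 2 or L < _GRAPH_K:
        return np.empty((0, 3), dtype=np.int64)
    km = kmer_codes(node_codes, _GRAPH_K)          # (n, P)
    P = km.shape[1]
    flat = km.ravel()
    node_of = np.repeat(np.arange(n, dtype=np.int64), P)
    pos_of = np.tile(np.arange(P, dtype=np.int64), n)
    valid = flat >= 0
    flat, node_of, pos_of = flat[valid], node_of[valid], pos_of[valid]
    order = np.argsort(flat, kind="stable")
    flat, node_of, pos_of = flat[order], node_of[order], pos_of[order]
    bounds = np.flatnonzero(np.diff(flat)) + 1
    starts = np.concatenate(([0], bounds))
    ends = np.concatenate((bounds, [flat.size]))
    sizes = ends - starts
    run_id = np.repeat(np.arange(sizes.size), sizes)
    keep_entry = sizes[run_id] <= _MAX_RUN
    idx = np.flatnonzero(keep_entry)
    if idx.size == 0:
        return np.empty((0, 3), dtype=np.int64)
    run_end = ends[run_id[idx]]
    reps = run_end - idx - 1
    first = np.repeat(idx, reps)
    tot = int(reps.sum())
    if tot == 0:
        return np.empty((0, 3), dtype=np.int64)
    second = first + 1 + (np.arange(tot) -
                          np.repeat(np.cumsum(reps) - reps, reps))
    a, b = node_of[first], node_of[second]
    pa, pb = pos_of[first], pos_of[second]
    keep = a != b
    a, b, pa, pb = a[keep], b[keep], pa[keep], pb[keep]
    swap = a > b
    a2 = np.where(swap, b, a)
    b2 = np.where(swap, a, b)
    pa2 = np.where(swap, pb, pa)
    pb2 = np.where(swap, pa, pb)
    return np.stack([a2, b2, pa2 - pb2], axis=1)


def _pairwise_mismatches(node_codes: np.ndarray, u, v, d) -> np.ndarray:
    """Mismatch counts of suffix(u)-prefix(v) overlaps, grouped by shift."""
    L = node_codes.shape[1]
    out = np.zeros(u.size, dtype=np.int64)
    order = np.argsort(d, kind="stable")
    ds = d[order]
    bounds = np.flatnonzero(np.diff(ds)) + 1
    for s, e in zip(np.concatenate(([0], bounds)),
                    np.concatenate((bounds, [ds.size]))):
        di = int(ds[s])
        idx = order[s:e]
        su = node_codes[u[idx], di:]
        sv = node_codes[v[idx], :L - di]
        out[idx] = ((su != sv) | (su == 4) | (sv == 4)).sum(axis=1)
    return out


# ---------------------------------------------------------------------------
# layout search
# ---------------------------------------------------------------------------

def traverse(graph: OverlapGraph, left_anchor: int = 0, right_anchor: int = 1,
             insert_range: tuple[int, int] = (0, 10**6)) -> Layout | None:
    """Best layout from the left anchor to the right anchor, or None.

    Maximizes total overlapped bases subject to the layout span lying inside
    ``insert_range``; ties prefer the smaller span, then the path backtracked
    through the smallest node ids. On acyclic graphs — the only kind true
    suffix-prefix overlaps of positioned reads can produce — this is exact
    (matches exhaustive enumeration of simple paths). Cycles, which require
    spurious repeat-induced overlaps, are broken deterministically by
    dropping DFS back edges first.
    """
    L = graph.read_length
    lo, hi = insert_range
    max_start = hi - L
    if max_start < 0 or graph.n_edges == 0:
        return None
    keep = _on_path_nodes(graph, left_anchor, right_anchor)
    if keep is None:
        return None
    emask = keep[graph.edge_u] & keep[graph.edge_v]
    steps = np.full((graph.n_nodes, max_start + 1), -1, dtype=np.int16)
    steps[left_anchor, 0] = 0
    eu = graph.edge_u[emask]
    ev = graph.edge_v[emask]
    ed = graph.edge_d[emask]
    order = _topo_order_sub(graph.n_nodes, eu, ev)
    if order is None:
        # repeat-induced cycles (possible only through spurious overlaps):
        # drop back edges found by a deterministic DFS, then proceed acyclic
        eu, ev, ed = _break_cycles(graph.n_nodes, eu, ev, ed, left_anchor)
        order = _topo_order_sub(graph.n_nodes, eu, ev)
    if order is not None:
        W = max_start + 1
        eorder = np.argsort(ev, kind="stable")
        ev_s = ev[eorder]
        eu_s = eu[eorder]
        ed_s = ed[eorder]
        estart = np.searchsorted(ev_s, np.arange(graph.n_nodes))
        eend = np.searchsorted(ev_s, np.arange(graph.n_nodes) + 1)
        buf = np.full((max(int((eend - estart).max(initial=0)), 1), W), -1,
                      dtype=np.int16)
        for node in order:
            s0, s1 = int(estart[node]), int(eend[node])
            if s1 == s0:
                continue
            k = s1 - s0
            buf[:k] = -1
            for i in range(k):
                d = int(ed_s[s0 + i])
                if d < W:
                    buf[i, d:] = steps[eu_s[s0 + i], :W - d]
            m = buf[:k].max(axis=0)
            np.maximum(steps[node],
                       np.where(m >= 0, m + 1, -1).astype(np.int16),
                       out=steps[node])
    row = steps[right_anchor]
    feas = np.flatnonzero(row >= 1)
    feas = feas[(feas + L >= lo) & (feas + L <= hi)]
    if feas.size == 0:
        return None
    overlap = row[feas].astype(np.int64) * L - feas
    best = int(np.argmax(overlap))  # argmax takes the first (smallest span)
    s_star = int(feas[best])
    total_overlap = int(overlap[best])
    placements = _backtrack(eu, ev, ed, steps, left_anchor, right_anchor,
                            s_star)
    return Layout(placements=placements, total_span=s_star + L,
                  total_overlap=total_overlap)


def _on_path_nodes(graph: OverlapGraph, left: int, right: int):
    """Boolean mask of nodes reachable from the left anchor AND reaching the
    right anchor; None when the anchors are not connected."""
    n = graph.n_nodes
    fwd = _reach(n, graph.edge_u, graph.edge_v, left)
    if not fwd[right]:
        return None
    back = _reach(n, graph.edge_v, graph.edge_u, right)
    return fwd & back


def _reach(n: int, src: np.ndarray, dst: np.ndarray, start: int) -> np.ndarray:
    seen = np.zeros(n, dtype=bool)
    seen[start] = True
    frontier = seen
    while True:
        hit = seen[src]
        new = np.zeros(n, dtype=bool)
        new[dst[hit]] = True
        new &= ~seen
        if not new.any():
            return seen
        seen = seen | new


def _topo_order_sub(n: int, eu: np.ndarray, ev: np.ndarray):
    """Kahn topological order, or None if cyclic."""
    indeg = np.zeros(n, dtype=np.int64)
    np.add.at(indeg, ev, 1)
    out_edges: dict[int, list[int]] = {}
    for k in range(eu.size):
        out_edges.setdefault(int(eu[k]), []).append(int(ev[k]))
    stack = [i for i in range(n) if indeg[i] == 0]
    order = []
    while stack:
        u = stack.pop()
        order.append(u)
        for v in out_edges.get(u, ()):
            indeg[v] -= 1
            if indeg[v] == 0:
                stack.append(v)
    return order if len(order) == n else None


def _break_cycles(n: int, eu: np.ndarray, ev: np.ndarray, ed: np.ndarray,
                  start: int):
    """Remove back edges found by an iterative DFS (deterministic order)."""
    out_edges: dict[int, list[int]] = {}
    for k in np.argsort(eu * (n + 1) + ev, kind="stable"):
        out_edges.setdefault(int(eu[k]), []).append(int(k))
    color = np.zeros(n, dtype=np.int8)  # 0 white, 1 on stack, 2 done
    drop = np.zeros(eu.size, dtype=bool)
    for root in [start] + list(range(n)):
        if color[root]:
            continue
        stack = [(root, iter(out_edges.get(root, ())))]
        color[root] = 1
        while stack:
            node, it = stack[-1]
            advanced = False
            for k in it:
                v = int(ev[k])
                if color[v] == 1:
                    drop[k] = True
                elif color[v] == 0:
                    color[v] = 1
                    stack.append((v, iter(out_edges.get(v, ()))))
                    advanced = True
                    break
            if not advanced:
                color[node] = 2
                stack.pop()
    keep = ~drop
    return eu[keep], ev[keep], ed[keep]


def _backtrack(edge_u, edge_v, edge_d, steps: np.ndarray, left: int,
               right: int, s_star: int) -> list[tuple[int, int]]:
    in_edges: dict[int, list[tuple[int, int]]] = {}
    for k in range(edge_u.size):
        in_edges.setdefault(int(edge_v[k]), []).append(
            (int(edge_u[k]), int(edge_d[k])))
    placements = [(right, s_star)]
    node, s = right, s_star
    e = int(steps[right, s_star])
    while node != left or s != 0:
        cands = [
            (u, d) for u, d in in_edges.get(node, ())
            if d <= s and steps[u, s - d] == e - 1
        ]
        u, d = min(cands)  # deterministic: smallest node id, then offset
        node, s, e = u, s - d, e - 1
        placements.append((node, s))
    placements.reverse()
    return placements


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def vote_columns(span: int,
                 placements: Iterable[tuple[np.ndarray, int, int]]):
    """Column-wise plurality vote.

    ``placements`` yields (codes, offset, rank); codes are clipped to
    [0, span), N bases cast no vote, and column ties resolve toward the base
    carried by the lowest-rank placement. Returns (sequence codes, depth,
    counts) where uncovered columns decode to N.
    """
    counts = np.zeros((span, 4), dtype=np.int64)
    minrank = np.full((span, 4), _RANK_CAP, dtype=np.int64)
    placements = list(placements)
    if placements:
        lengths = {p[0].size for p in placements}
        if len(lengths) == 1:
            codes_mat = np.stack([p[0] for p in placements])
            offs = np.asarray([p[1] for p in placements], dtype=np.int64)
            ranks = np.minimum(
                np.asarray([p[2] for p in placements], dtype=np.int64),
                _RANK_CAP)
            L = codes_mat.shape[1]
            cols = offs[:, None] + np.arange(L)
            valid = (cols >= 0) & (cols < span) & (codes_mat < 4)
            cols_f = cols[valid]
            base = codes_mat[valid].astype(np.int64)
            rank_f = np.broadcast_to(ranks[:, None], cols.shape)[valid]
        else:  # ragged placements (anchors of unequal read length etc.)
            cols_l, base_l, rank_l = [], [], []
            for codes, off, rank in placements:
                s, e = max(0, off), min(span, off + codes.size)
                if e <= s:
                    continue
                seg = codes[s - off:e - off]
                valid = seg < 4
                cols_l.append(np.arange(s, e)[valid])
                base_l.append(seg[valid].astype(np.int64))
                rank_l.append(np.full(int(valid.sum()),
                                      min(rank, _RANK_CAP), dtype=np.int64))
            cols_f = np.concatenate(cols_l) if cols_l else np.empty(0, int)
            base = np.concatenate(base_l) if base_l else np.empty(0, int)
            rank_f = np.concatenate(rank_l) if rank_l else np.empty(0, int)
        if cols_f.size:
            np.add.at(counts, (cols_f, base), 1)
            np.minimum.at(minrank, (cols_f, base), rank_f)
    score = counts * (_RANK_CAP + 2) + (_RANK_CAP - minrank)
    seq = np.argmax(score, axis=1).astype(np.uint8)
    depth = counts.sum(axis=1)
    seq[depth == 0] = 4
    return seq, depth, counts


def placement_rank(offset: int, is_anchor: bool, index: int) -> int:
    """Tie-break rank: smaller offset wins, anchors outrank SRs, then input
    order. Lower is stronger."""
    off = max(0, offset + 1024)
    return ((off * 2 + (0 if is_anchor else 1)) * 1024 + min(index, 1023))


def layout_consensus(layout: Layout, graph: OverlapGraph) -> PrimitivePS:
    """Majority-vote consensus over the layout's reads (the primitive PS)."""
    span = layout.total_span
    placements = [
        (graph.node_codes[node], off,
         placement_rank(off, graph.nodes[node].kind.startswith("anchor"), i))
        for i, (node, off) in enumerate(layout.placements)
    ]
    seq, depth, _ = vote_columns(span, placements)
    return PrimitivePS(sequence=seq, depth=depth,
                       placements=list(layout.placements), span=span)


# ---------------------------------------------------------------------------
# debug dumps
# ---------------------------------------------------------------------------

def graph_to_dot(graph: OverlapGraph) -> str:
    """GraphViz DOT rendering for inspection."""
    lines = ["digraph overlap {"]
    for i, nd in enumerate(graph.nodes):
        lines.append(f'  n{i} [label="{i}:{nd.kind}"];')
    for k in range(graph.n_edges):
        lines.append(
            f"  n{graph.edge_u[k]} -> n{graph.edge_v[k]} "
            f'[label="d={graph.edge_d[k]},ov={graph.edge_ov[k]}"];'
        )
    lines.append("}")
    return "\n".join(lines)


def layout_to_tsv(layout: Layout, graph: OverlapGraph) -> str:
    """Documented TSV: node_id, kind, offset, sequence."""
    rows = ["node_id\tkind\toffset\tsequence"]
    for node, off in layout.placements:
        rows.append(f"{node}\t{graph.nodes[node].kind}\t{off}\t"
                    f"{decode(graph.node_codes[node])}")
    return "\n".join(rows)
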