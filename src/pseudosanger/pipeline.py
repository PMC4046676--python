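"""End-to-end pseudo-Sanger construction and evaluation.

The driver takes nested paired-end libraries sorted by decreasing insert
size. Pass 1 uses the largest library's pairs as anchor reads (ARs) against
all smaller libraries' supporting reads (SRs): each anchor is scanned against
the SR seed index, gated on the repeat-coverage expectation, locally
assembled, and refined into a pseudo-Sanger (PS) read. Later passes promote
the next-largest library's pairs to ARs — excluding pairs already consumed as
both-ends-inside contributors to an emitted PS read — over the libraries
below them, recovering regions lost to repeat gating or assembly failure.

When simulator truth is available, every PS read is globally aligned to its
source anchor's true fragment and residual errors are counted per column;
a PS base matching the other haplotype's allele at a known heterozygous site
is tolerated (the consensus keeps the majority allele by design).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import multiprocessing as mp
from typing import Sequence

import edlib
import numpy as np

from .assembly import build_overlap_graph, layout_consensus, traverse
from .overlap import (OverlapParams, SpacedSeedIndex, SRPool,
                      cluster_for_anchor, expected_sr_count, is_repetitive)
from .refine import PSRead, final_consensus, recruit_inner_srs
from .simulate import (DiploidReference, PairedLibrary, TruthRecord, decode,
                       revcomp)

logger = logging.getLogger("pseudosanger")


# ---------------------------------------------------------------------------
# configuration and report
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """Validated pipeline inputs.

    ``libraries`` must hold at least two libraries with strictly decreasing
    insert means and one common read length.
    """

    libraries: list[PairedLibrary]
    params: OverlapParams = dataclasses.field(default_factory=OverlapParams)
    seed: int = 0
    workers: int = 1

    def __post_init__(self):
        if len(self.libraries) < 2:
            raise ValueError(
                "at least two libraries must be provided: the largest-insert "
                "library supplies anchors and the rest supply supporting "
                "reads")
        means = [lib.spec.insert_mean for lib in self.libraries]
        if sorted(means, reverse=True) != means or len(set(means)) != len(means):
            raise ValueError("libraries must be sorted by strictly "
                             "decreasing insert mean")
        lengths = {lib.read_length for lib in self.libraries if lib.n_pairs}
        if len(lengths) > 1:
            raise ValueError(f"inconsistent read lengths across libraries: "
                             f"{sorted(lengths)}")


@dataclasses.dataclass
class PassCounters:
    library: str
    attempted: int = 0
    gated_repetitive: int = 0
    assembled: int = 0
    failed: int = 0
    used_in_layout: int = 0
    recruited_inner: int = 0
    unused: int = 0


@dataclasses.dataclass
class RunReport:
    per_library_pairs: dict[str, int]
    passes: list[PassCounters]
    ps_count: int = 0
    total_bases: int = 0
    mean_length: float = 0.0
    n50: int = 0
    n90: int = 0
    params: dict = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


@dataclasses.dataclass
class PipelineResult:
    ps_reads: list[PSRead]
    report: RunReport
    unused_pairs: list[tuple[str, str]]   # (library name, pair id)
    consumed: list[np.ndarray]            # per-library consumed masks


# ---------------------------------------------------------------------------
# per-anchor work unit
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class _AnchorOutcome:
    ar_index: int
    status: str                           # 'gated' | 'failed' | 'assembled'
    ps: PSRead | None = None
    layout_pairs: tuple[int, ...] = ()    # pool pair rows on the layout path
    recruited_pairs: tuple[int, ...] = ()


def _assemble_anchor(ar_index: int, read1, read2, ar_id: str,
                     pool: SRPool, index: SpacedSeedIndex,
                     params: OverlapParams, insert_range, E: float,
                     lib_name: str) -> _AnchorOutcome:
    cluster = cluster_for_anchor(read1, read2, pool, index, params,
                                 insert_range, ar_id)
    if is_repetitive(cluster, E, params.repeat_factor):
        return _AnchorOutcome(ar_index, "gated")
    graph = build_overlap_graph(cluster, params)
    layout = traverse(graph, 0, 1, insert_range)
    if layout is None:
        return _AnchorOutcome(ar_index, "failed")
    primitive = layout_consensus(layout, graph)
    placements = recruit_inner_srs(primitive, pool, index, params)
    ps = final_consensus(primitive, placements, graph, pool,
                         ps_id=f"PS:{ar_id}", anchor_library=lib_name,
                         source_pair_id=ar_id)
    layout_nodes = [graph.nodes[nd] for nd, _ in layout.placements]
    layout_rows = {n.read_row for n in layout_nodes if n.read_row >= 0}
    layout_pairs = tuple(sorted(
        {r >> 1 for r in layout_rows
         if (r ^ 1) in layout_rows}))  # both reads on the path
    recruited_pairs = tuple(sorted({pl.pair_row for pl in placements}))
    return _AnchorOutcome(ar_index, "assembled", ps=ps,
                          layout_pairs=layout_pairs,
                          recruited_pairs=recruited_pairs)


_WORKER_STATE: dict = {}


def _worker_init(state):
    _WORKER_STATE.update(state)


def _worker_task(ar_index: int) -> _AnchorOutcome:
    s = _WORKER_STATE
    lib = s["ar_lib"]
    return _assemble_anchor(
        ar_index, lib.reads1[ar_index], lib.reads2[ar_index],
        lib.pair_ids[ar_index], s["pool"], s["index"], s["params"],
        s["insert_range"], s["E"], lib.spec.name)


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def demote_anchors(consumed: np.ndarray, library: PairedLibrary) -> np.ndarray:
    """Anchor candidates for a later pass: indices of pairs not yet consumed
    as both-ends-inside contributors to an emitted PS read."""
    if consumed.size != library.n_pairs:
        raise ValueError("consumed mask does not match library size")
    return np.flatnonzero(~consumed)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every pass, emit PS reads, and account for every SR pair."""
    libs = config.libraries
    params = config.params
    consumed = [np.zeros(lib.n_pairs, dtype=bool) for lib in libs]
    layout_used = [np.zeros(lib.n_pairs, dtype=bool) for lib in libs]
    recruited_used = [np.zeros(lib.n_pairs, dtype=bool) for lib in libs]
    ps_reads: list[PSRead] = []
    passes: list[PassCounters] = []
    for k in range(len(libs) - 1):
        ar_lib = libs[k]
        sr_libs = libs[k + 1:]
        pool = SRPool(sr_libs, list(range(k + 1, len(libs))))
        index = SpacedSeedIndex(pool.reads, params.seed_pattern,
                                params.sr_stride)
        L = pool.read_length
        D = sum(lib.spec.depth for lib in sr_libs)
        E = expected_sr_count(L, params.min_overlap, D)
        insert_range = ar_lib.spec.insert_range(params.insert_sd_multiple)
        counters = PassCounters(library=ar_lib.spec.name)
        candidates = np.arange(ar_lib.n_pairs) if k == 0 else \
            demote_anchors(consumed[k], ar_lib)
        counters.attempted = candidates.size
        logger.info("pass %d: %d ARs from %s against %d SR pairs (E=%.2f)",
                    k + 1, candidates.size, ar_lib.spec.name, pool.n_pairs, E)
        outcomes = _map_anchors(candidates, ar_lib, pool, index, params,
                                insert_range, E, config.workers)
        pass_layout = np.zeros(pool.n_pairs, dtype=bool)
        pass_recruited = np.zeros(pool.n_pairs, dtype=bool)
        for oc in outcomes:
            if oc.status == "gated":
                counters.gated_repetitive += 1
            elif oc.status == "failed":
                counters.failed += 1
            else:
                counters.assembled += 1
                ps_reads.append(oc.ps)
                pass_layout[list(oc.layout_pairs)] = True
                pass_recruited[list(oc.recruited_pairs)] = True
                consumed[k][oc.ar_index] = True
        # fold pool-level usage back into per-library masks
        for lib_i, within, was_layout, was_recr in zip(
                pool.pair_lib, pool.pair_within, pass_layout, pass_recruited):
            if was_layout:
                layout_used[lib_i][within] = True
                consumed[lib_i][within] = True
            if was_recr:
                recruited_used[lib_i][within] = True
                consumed[lib_i][within] = True
        counters.used_in_layout = int(pass_layout.sum())
        counters.recruited_inner = int((pass_recruited & ~pass_layout).sum())
        counters.unused = pool.n_pairs - int(
            (pass_layout | pass_recruited).sum())
        passes.append(counters)
    unused_pairs = [
        (lib.spec.name, lib.pair_ids[i])
        for j, lib in enumerate(libs)
        for i in np.flatnonzero(~(layout_used[j] | recruited_used[j]
                                  | consumed[j]))
    ]
    lengths = [len(ps) for ps in ps_reads]
    total, mean, n50, n90 = compute_length_stats(lengths) if lengths else \
        (0, 0.0, 0, 0)
    report = RunReport(
        per_library_pairs={lib.spec.name: lib.n_pairs for lib in libs},
        passes=passes, ps_count=len(ps_reads), total_bases=total,
        mean_length=mean, n50=n50, n90=n90,
        params=dataclasses.asdict(params),
    )
    return PipelineResult(ps_reads=ps_reads, report=report,
                          unused_pairs=unused_pairs, consumed=consumed)


def _map_anchors(candidates, ar_lib, pool, index, params, insert_range, E,
                 workers: int) -> list[_AnchorOutcome]:
    if workers <= 1:
        return [
            _assemble_anchor(int(i), ar_lib.reads1[i], ar_lib.reads2[i],
                             ar_lib.pair_ids[i], pool, index, params,
                             insert_range, E, ar_lib.spec.name)
            for i in candidates
        ]
    state = dict(ar_lib=ar_lib, pool=pool, index=index, params=params,
                 insert_range=insert_range, E=E)
    ctx = mp.get_context("fork")
    with ctx.Pool(workers, initializer=_worker_init,
                  initargs=(state,)) as pool_exec:
        # chunked, order-preserving: results merged in input order
        return pool_exec.map(_worker_task, [int(i) for i in candidates],
                             chunksize=64)


# ---------------------------------------------------------------------------
# statistics and evaluation
# ---------------------------------------------------------------------------

def compute_length_stats(lengths: Sequence[int]):
    """(total, mean, N50, N90): Nxx is the length of the smallest element in
    the minimal descending-sorted prefix reaching xx% of the total."""
    if len(lengths) == 0:
        raise ValueError("empty length list")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    if (arr <= 0).any():
        raise ValueError("lengths must be positive")
    total = int(arr.sum())
    csum = np.cumsum(arr)
    n50 = int(arr[np.searchsorted(csum, 0.5 * total)])
    n90 = int(arr[np.searchsorted(csum, 0.9 * total)])
    return total, float(arr.mean()), n50, n90


@dataclasses.dataclass
class EvalResult:
    total_ps_bases: int
    total_errors: int
    error_rate_pct: float
    bin_errors: np.ndarray       # 20 relative-position bins
    bin_bases: np.ndarray
    n_reads: int
    excused_het_sites: int

    @property
    def bin_rates(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.bin_bases > 0,
                            self.bin_errors / np.maximum(self.bin_bases, 1),
                            0.0)


def evaluate_against_truth(ps_reads: Sequence[PSRead],
                           truth: Sequence[TruthRecord],
                           reference: DiploidReference,
                           n_bins: int = 20) -> EvalResult:
    """Residual error of PS reads against their anchors' true fragments.

    Each PS read is globally aligned (edlib NW) to the true fragment of its
    source anchor pair, oriented to the anchor's read1 strand. Mismatches and
    indels are counted over the alignment; a mismatch whose PS base equals
    the OTHER haplotype's allele at that position is a tolerated heterozygous
    site, not an error. The per-position profile bins errors by relative PS
    position.
    """
    by_id = {t.pair_id: t for t in truth}
    haps = {"a": reference.hap_a, "b": reference.hap_b}
    other = {"a": reference.hap_b, "b": reference.hap_a}
    bin_errors = np.zeros(n_bins, dtype=np.int64)
    bin_bases = np.zeros(n_bins, dtype=np.int64)
    total_bases = 0
    total_errors = 0
    excused = 0
    for ps in ps_reads:
        t = by_id.get(ps.source_pair_id)
        if t is None:
            raise KeyError(f"no truth record for PS source "
                           f"{ps.source_pair_id!r}")
        frag = haps[t.haplotype][t.fragment_start:t.fragment_end]
        frag_o = other[t.haplotype][t.fragment_start:t.fragment_end]
        if t.strand == "-":
            frag, frag_o = revcomp(frag), revcomp(frag_o)
        n = len(ps)
        total_bases += n
        q = np.floor(np.arange(n) * n_bins / n).astype(int)
        np.add.at(bin_bases, q, 1)
        errs = _alignment_errors(ps.sequence, frag, frag_o)
        for qpos, is_het in errs:
            if is_het:
                excused += 1
                continue
            total_errors += 1
            bin_errors[min(n_bins - 1, qpos * n_bins // n)] += 1
    rate = 100.0 * total_errors / total_bases if total_bases else 0.0
    return EvalResult(total_ps_bases=total_bases, total_errors=total_errors,
                      error_rate_pct=rate, bin_errors=bin_errors,
                      bin_bases=bin_bases, n_reads=len(ps_reads),
                      excused_het_sites=excused)


def _alignment_errors(ps_codes: np.ndarray, frag: np.ndarray,
                      frag_other: np.ndarray):
    """(ps position, is_tolerated_het) for every non-identity column of the
    global alignment of the PS read to the true fragment."""
    q = decode(ps_codes)
    tseq = decode(frag)
    res = edlib.align(q, tseq, mode="NW", task="path")
    out = []
    qi = ti = 0
    for length, op in _parse_cigar(res["cigar"]):
        if op == "=":
            qi += length
            ti += length
        elif op == "X":
            for _ in range(length):
                is_het = (frag[ti] != frag_other[ti] and
                          ps_codes[qi] == frag_other[ti])
                out.append((qi, bool(is_het)))
                qi += 1
                ti += 1
        elif op == "I":        # bases in PS only
            for _ in range(length):
                out.append((qi, False))
                qi += 1
        elif op == "D":        # bases in fragment only
            for _ in range(length):
                out.append((min(qi, len(q) - 1), False))
                ti += 1
        else:  # pragma: no cover - edlib emits only =, X, I, D
            raise ValueError(f"unexpected cigar op {op!r}")
    return out


def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""
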