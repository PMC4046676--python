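"""Diploid paired-end read simulator for nested insert-size libraries.

A wgsim-style generator: it draws a random diploid reference (two haplotypes
separated by independent single-base substitutions at a given heterozygosity),
then samples paired-end fragments per library with normally distributed insert
lengths and injects uniform substitution sequencing errors. No coverage bias,
no chimeric fragments, no indel errors — reads are exact (reverse-complemented)
substrings of a haplotype apart from the injected substitutions, and every
pair's provenance is emitted as a truth record so downstream consensus quality
can be measured without mapping.

Orientation convention (FR): read1 is the 5' end of the fragment on the
sampled strand; read2 is the reverse complement of the fragment's 3' end.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqs import BASES, decode, encode, revcomp

#: constant per-base quality written to FASTQ (Q30); the method never uses it
QUAL_CHAR = "?"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DiploidReference:
    """Two equal-length haplotypes plus the exact list of differing sites.

    ``repeats`` records intervals written by :func:`seed_repeats` (half-open,
    identical on both haplotypes); empty for plain random references.
    """

    hap_a: np.ndarray  # uint8 codes
    hap_b: np.ndarray
    variants: list[tuple[int, str, str]]
    repeats: list[tuple[int, int]] = dataclasses.field(default_factory=list)

    def __post_init__(self):
        if len(self.hap_a) != len(self.hap_b):
            raise ValueError("haplotypes must have equal length")

    def __len__(self) -> int:
        return len(self.hap_a)

    @property
    def haplotype_a(self) -> str:
        return decode(self.hap_a)

    @property
    def haplotype_b(self) -> str:
        return decode(self.hap_b)

    def variant_map(self) -> dict[int, tuple[str, str]]:
        """position -> (allele_a, allele_b)."""
        return {p: (a, b) for p, a, b in self.variants}


@dataclasses.dataclass(frozen=True)
class LibrarySpec:
    """Parameters of one paired-end library.

    insert_mean/insert_sd in bp, depth in fold coverage, error_rate as a
    per-base substitution probability. insert_sd defaults to 10% of the mean.
    """

    insert_mean: float
    depth: float
    read_length: int = 100
    error_rate: float = 0.005
    insert_sd: float | None = None
    name: str = ""

    def __post_init__(self):
        if self.insert_mean <= self.read_length:
            raise ValueError("insert_mean must exceed read_length")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be in [0, 1)")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.insert_sd is None:
            object.__setattr__(self, "insert_sd", 0.1 * self.insert_mean)
        if not self.name:
            object.__setattr__(self, "name", f"lib{int(self.insert_mean)}")

    def insert_range(self, n_sd: float = 3.0) -> tuple[int, int]:
        """(min, max) fragment length accepted for layouts of this library."""
        lo = int(round(self.insert_mean - n_sd * self.insert_sd))
        hi = int(round(self.insert_mean + n_sd * self.insert_sd))
        return max(self.read_length + 1, lo), hi


@dataclasses.dataclass(frozen=True)
class TruthRecord:
    """Provenance of one simulated pair (0-based, half-open fragment)."""

    pair_id: str
    haplotype: str  # 'a' or 'b'
    fragment_start: int
    fragment_end: int
    strand: str  # strand of read1: '+' or '-'
    error_positions_r1: tuple[int, ...]
    error_positions_r2: tuple[int, ...]


@dataclasses.dataclass
class PairedLibrary:
    """A set of read pairs sharing an insert-size distribution.

    reads1/reads2 are (n, L) uint8 code matrices; truth arrays are parallel to
    the rows and present only for simulated libraries.
    """

    spec: LibrarySpec
    reads1: np.ndarray
    reads2: np.ndarray
    pair_ids: list[str]
    truth: list[TruthRecord] | None = None

    @property
    def n_pairs(self) -> int:
        return self.reads1.shape[0]

    @property
    def read_length(self) -> int:
        return self.reads1.shape[1]


# ---------------------------------------------------------------------------
# reference construction
# ---------------------------------------------------------------------------

def make_diploid_reference(
    length: int,
    het_rate: float,
    seed: int,
    base_composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> DiploidReference:
    """Draw a random diploid reference.

    Haplotype A is i.i.d. over ACGT at ``base_composition``; haplotype B copies
    it with each site independently substituted to a different base with
    probability ``het_rate``.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if not (0 <= het_rate < 1):
        raise ValueError("het_rate must be in [0, 1)")
    comp = np.asarray(base_composition, dtype=float)
    if comp.shape != (4,) or comp.min() < 0 or not np.isclose(comp.sum(), 1.0):
        raise ValueError("base_composition must be a 4-vector summing to 1")
    rng = np.random.default_rng(seed)
    hap_a = rng.choice(4, size=length, p=comp).astype(np.uint8)
    hap_b = hap_a.copy()
    sites = np.flatnonzero(rng.random(length) < het_rate)
    if sites.size:
        shift = rng.integers(1, 4, size=sites.size).astype(np.uint8)
        hap_b[sites] = (hap_a[sites] + shift) % 4
    variants = [(int(p), BASES[hap_a[p]], BASES[hap_b[p]]) for p in sites]
    return DiploidReference(hap_a, hap_b, variants)


def seed_repeats(
    reference: DiploidReference,
    unit_length: int,
    copies: int,
    seed: int,
    max_tries: int = 1000,
) -> DiploidReference:
    """Plant ``copies`` identical copies of one random subsequence.

    A haplotype-A subsequence of ``unit_length`` is pasted at ``copies``
    random, mutually non-overlapping positions (also avoiding the source) on
    both haplotypes, making the repeat homozygous and its copies 100%
    identical. The variant list is recomputed after pasting.
    """
    glen = len(reference)
    if unit_length <= 0 or copies < 0:
        raise ValueError("unit_length must be positive and copies >= 0")
    if unit_length > glen or unit_length * (copies + 1) > glen:
        raise ValueError("repeat copies do not fit in the reference")
    if copies == 0:
        return dataclasses.replace(
            reference,
            hap_a=reference.hap_a.copy(),
            hap_b=reference.hap_b.copy(),
            variants=list(reference.variants),
            repeats=list(reference.repeats),
        )
    rng = np.random.default_rng(seed)
    src = int(rng.integers(0, glen - unit_length + 1))
    unit = reference.hap_a[src:src + unit_length].copy()
    taken = [(src, src + unit_length)]
    placed: list[tuple[int, int]] = []
    tries = 0
    while len(placed) < copies:
        tries += 1
        if tries > max_tries * copies:
            raise RuntimeError("could not place repeat copies without overlap")
        p = int(rng.integers(0, glen - unit_length + 1))
        iv = (p, p + unit_length)
        if any(iv[0] < e and s < iv[1] for s, e in taken):
            continue
        taken.append(iv)
        placed.append(iv)
    hap_a = reference.hap_a.copy()
    hap_b = reference.hap_b.copy()
    for s, e in placed:
        hap_a[s:e] = unit
        hap_b[s:e] = unit
    diff = np.flatnonzero(hap_a != hap_b)
    variants = [(int(p), BASES[hap_a[p]], BASES[hap_b[p]]) for p in diff]
    return DiploidReference(hap_a, hap_b, variants, repeats=sorted(placed))


# ---------------------------------------------------------------------------
# read generation
# ---------------------------------------------------------------------------

def n_pairs_for(length: int, spec: LibrarySpec) -> int:
    """Pair count giving ``spec.depth`` fold coverage of ``length`` bases."""
    return int(round(length * spec.depth / (2 * spec.read_length)))


def generate_library(
    reference: DiploidReference,
    spec: LibrarySpec,
    seed: int,
) -> PairedLibrary:
    """Simulate one paired-end library with truth records.

    Fragment starts are uniform, the haplotype and the strand of read1 are
    uniform, insert lengths are Normal(insert_mean, insert_sd) rounded and
    truncated to [read_length+1, genome length]. Each base is substituted
    (never to itself) with probability ``spec.error_rate``.
    """
    glen = len(reference)
    L = spec.read_length
    if glen <= spec.insert_mean + 3 * spec.insert_sd:
        raise ValueError("reference shorter than the maximum insert")
    n = n_pairs_for(glen, spec)
    rng = np.random.default_rng(seed)

    hap = rng.integers(0, 2, size=n)
    insert = np.rint(rng.normal(spec.insert_mean, spec.insert_sd, size=n))
    insert = np.clip(insert, L + 1, glen).astype(np.int64)
    start = (rng.random(n) * (glen - insert + 1)).astype(np.int64)
    strand = rng.integers(0, 2, size=n)  # 0 = '+', 1 = '-'

    haps = np.stack([reference.hap_a, reference.hap_b])
    pos = np.arange(L)
    left = haps[hap[:, None], start[:, None] + pos]
    right = haps[hap[:, None], (start + insert - L)[:, None] + pos]
    rc_right = revcomp(right)
    minus = strand == 1
    reads1 = np.where(minus[:, None], rc_right, left)
    reads2 = np.where(minus[:, None], left, rc_right)
    # '-' strand: read1 = revcomp(3' end of forward) = 5' end on the reverse
    # strand; read2 = the fragment's left end read forward (revcomp twice).

    err1 = _inject_errors(reads1, spec.error_rate, rng)
    err2 = _inject_errors(reads2, spec.error_rate, rng)

    pair_ids = [f"{spec.name}:{i}" for i in range(n)]
    truth = [
        TruthRecord(
            pair_id=pair_ids[i],
            haplotype="ab"[hap[i]],
            fragment_start=int(start[i]),
            fragment_end=int(start[i] + insert[i]),
            strand="+-"[strand[i]],
            error_positions_r1=err1[i],
            error_positions_r2=err2[i],
        )
        for i in range(n)
    ]
    return PairedLibrary(spec, reads1, reads2, pair_ids, truth)


def _inject_errors(reads: np.ndarray, rate: float, rng) -> list[tuple[int, ...]]:
    """Substitute bases in place; returns per-read error offsets."""
    n, L = reads.shape
    if rate <= 0:
        return [()] * n
    mask = rng.random((n, L)) < rate
    ri, ci = np.nonzero(mask)
    shift = rng.integers(1, 4, size=ri.size).astype(np.uint8)
    reads[ri, ci] = (reads[ri, ci] + shift) % 4
    out: list[tuple[int, ...]] = [()] * n
    if ri.size:
        order = np.lexsort((ci, ri))
        ri, ci = ri[order], ci[order]
        bounds = np.searchsorted(ri, np.arange(n + 1))
        out = [tuple(int(c) for c in ci[bounds[i]:bounds[i + 1]]) for i in range(n)]
    return out


def derive_seed(master_seed: int, index: int) -> int:
    """Deterministic per-library stream below 2**31."""
    return (master_seed * 1_000_003 + 7919 * (index + 1)) % (2**31 - 1)


# ---------------------------------------------------------------------------
# file IO
# ---------------------------------------------------------------------------

def write_fastq_pair(library: PairedLibrary, path_r1, path_r2) -> None:
    """Write a library as two Sanger-FASTQ files (/1 and /2 id suffixes)."""
    for reads, path, suffix in (
        (library.reads1, path_r1, "/1"),
        (library.reads2, path_r2, "/2"),
    ):
        with open(path, "w") as fh:
            SeqIO.write(
                (
                    _fastq_record(library.pair_ids[i] + suffix, reads[i])
                    for i in range(library.n_pairs)
                ),
                fh,
                "fastq",
            )


def _fastq_record(rid: str, codes: np.ndarray) -> SeqRecord:
    rec = SeqRecord(Seq(decode(codes)), id=rid, description="")
    rec.letter_annotations["phred_quality"] = \
        [ord(QUAL_CHAR) - 33] * len(codes)
    return rec


def read_fastq_pair(path_r1, path_r2, spec: LibrarySpec | None = None) -> PairedLibrary:
    """Load a pair of FASTQ files back into a :class:`PairedLibrary`.

    Raises ValueError on malformed records (Biopython enforces the 4-line
    structure and quality/sequence length agreement) or mismatched pairing.
    """
    ids1, mat1 = _read_fastq(path_r1, "/1")
    ids2, mat2 = _read_fastq(path_r2, "/2")
    if ids1 != ids2:
        raise ValueError("read1/read2 files disagree on pair ids")
    if spec is None:
        L = mat1.shape[1] if mat1.size else 0
        spec = LibrarySpec(insert_mean=max(2 * L, 1) + 1, depth=1.0,
                           read_length=max(L, 1), error_rate=0.0)
    return PairedLibrary(spec, mat1, mat2, ids1)


def _read_fastq(path, suffix: str) -> tuple[list[str], np.ndarray]:
    ids: list[str] = []
    rows: list[np.ndarray] = []
    for rec in SeqIO.parse(str(path), "fastq"):
        rid = rec.id
        if rid.endswith(("/1", "/2")):
            rid = rid[:-2]
        ids.append(rid)
        rows.append(encode(str(rec.seq)))
    if not rows:
        return ids, np.empty((0, 0), dtype=np.uint8)
    lengths = {r.size for r in rows}
    if len(lengths) > 1:
        raise ValueError(f"inconsistent read lengths in {path}: {sorted(lengths)}")
    return ids, np.vstack(rows)


def write_reference_fasta(reference: DiploidReference, path) -> None:
    recs = [
        SeqRecord(Seq(reference.haplotype_a), id="hap_a", description=""),
        SeqRecord(Seq(reference.haplotype_b), id="hap_b", description=""),
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_reference_fasta(path) -> DiploidReference:
    recs = {r.id: encode(str(r.seq)) for r in SeqIO.parse(str(path), "fasta")}
    if set(recs) != {"hap_a", "hap_b"}:
        raise ValueError("expected records 'hap_a' and 'hap_b'")
    hap_a, hap_b = recs["hap_a"], recs["hap_b"]
    diff = np.flatnonzero(hap_a != hap_b)
    variants = [(int(p), BASES[hap_a[p]], BASES[hap_b[p]]) for p in diff]
    return DiploidReference(hap_a, hap_b, variants)


TRUTH_COLUMNS = [
    "pair_id", "haplotype", "start", "end", "strand", "err_r1", "err_r2",
]


def write_truth_tsv(truth: Iterable[TruthRecord], path) -> None:
    df = pd.DataFrame(
        [
            (
                t.pair_id, t.haplotype, t.fragment_start, t.fragment_end,
                t.strand,
                ",".join(map(str, t.error_positions_r1)),
                ",".join(map(str, t.error_positions_r2)),
            )
            for t in truth
        ],
        columns=TRUTH_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"err_r1": str, "err_r2": str},
                     keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            TruthRecord(
                pair_id=str(row.pair_id),
                haplotype=str(row.haplotype),
                fragment_start=int(row.start),
                fragment_end=int(row.end),
                strand=str(row.strand),
                error_positions_r1=_parse_offsets(row.err_r1),
                error_positions_r2=_parse_offsets(row.err_r2),
            )
        )
    return out


def _parse_offsets(field: str) -> tuple[int, ...]:
    field = str(field).strip()
    if not field or field == "nan":
        return ()
    return tuple(int(x) for x in field.split(","))
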