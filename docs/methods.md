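# Methods

## Model and procedure

`pseudosanger` reconstructs the unsequenced interior of paired-end
fragments. The input is a nested set of paired-end libraries with strictly
decreasing insert means; reads are assumed uniform in length within a run
(the pipeline validates this). Read pairs are FR-oriented: read1 is the 5'
end of the fragment on its sampled strand, read2 the reverse complement of
the 3' end. Each pair of the largest-insert library in turn serves as an
anchor; the two anchor reads become the fixed endpoints of a local
assembly over supporting reads from all smaller libraries, and the
consensus across the resulting layout — re-voted after recruiting every
supporting pair that lies wholly inside it — is emitted as one
pseudo-Sanger (PS) read.

Only *forward* overlaps (same-strand matches against the anchor's raw
reads) admit a supporting pair into an anchor's cluster. This is a
geometric fact, not a heuristic: because any supporting insert is shorter
than the anchor insert, a same-strand overlap implies the partner read
falls inside the anchor's gap, while a reverse-strand overlap implies it
points away. Partners are admitted unverified and vetted by the overlap
graph.

## Stages and the parameters that matter

**Seed index.** Supporting reads are indexed with a blocked spaced seed —
two 9-base care blocks separated by a 4-base don't-care gap (span 22,
weight 18) — at stride 2; anchors are scanned base by base on both
orientations. The pattern is a sensitivity/cost trade-off: the span must
fit comfortably inside the minimum overlap (30 bp) so that short overlaps
on error-carrying reads retain several seed positions (measured admission
of truly-overlapping pairs is ≥ 99%), while weight 18 keeps random key
collisions negligible (4⁻¹⁸ per comparison). N bases are never indexed and
always count as mismatches.

**Overlap verification.** A shared seed key implies a diagonal; the
overlap is verified gaplessly across its full extent and accepted when the
mismatch fraction is ≤ `max_mismatch_rate` (default 8%). Failures fall
back to a Smith–Waterman alignment (Gotoh affine; match +1, mismatch −2,
gap open −3, gap extend −1; accepted at identity ≥ 92% over ≥ 30 columns).
Both thresholds are flags; the defaults accommodate two error-carrying
reads (~1% pairwise mismatch) plus heterozygous sites with wide margin.

**Repeat gate.** The expected number of verified forward-overlap hits per
anchor pair under uniform coverage is `E = D·(2(L−O)+1)/L`, with `D` the
summed depth of the current pass's supporting libraries (all SRs are
clustered together), `L` the read length and `O` the minimum overlap: read
starts within ±(L−O) of an anchor-read start occur at rate `D/L` per
position, and the strand restriction (half the reads) cancels against
there being two anchor reads. Anchors with strictly more than
`repeat_factor × E` hits (default factor 1.5) are gated; the strict
inequality means an exactly-expected count passes. A Monte-Carlo check of
the formula agrees within 1%.

**Layout search.** The overlap graph carries directed suffix–prefix edges
with strictly positive start offsets; zero-offset duplicates are recorded
as containments, never as path edges. The layout from left anchor to right
anchor maximizes total overlapped bases subject to the span lying in the
anchor library's insert range (mean ± 3 sd — the simulator's truncation
bound, so true inserts are feasible by construction). Because total
overlap equals `n_edges·L − span` for uniform read length, the search is
solved exactly by dynamic programming over (node, span-offset) states in
topological order: for every feasible span offset, maximize the edge
count, then scan feasible spans for the overlap optimum. Ties prefer the
smaller span, then a backtrack through the smallest node ids — fully
deterministic. On acyclic graphs (the only kind true overlaps of
positioned reads can produce) this equals exhaustive simple-path
enumeration; cycles, which require spurious repeat-induced overlaps, are
first broken by dropping DFS back edges in deterministic order. In-cluster
edge candidates are discovered by shared exact 16-mers (sort-and-scan,
bucket size capped at 64 as a repeat guard); within an already-localized
cluster this is a sensitivity superset of the spaced seed.

**Consensus.** Columns are decided by plurality over all placed reads;
ties resolve toward the base carried by the smallest-offset read, with
anchor reads outranking supporting reads at equal offset, then input
order — a total, deterministic order. At a heterozygous site the
higher-frequency allele therefore wins. Consensus columns are ungapped;
the rare indel-bearing (Smith–Waterman) overlap contributes votes at its
net-offset projection rather than via per-column gap symbols — with a
substitution-only error model such edges essentially never appear on
layouts, and the deep re-vote dominates the outcome.

**Recruitment and final consensus.** The primitive consensus is queried
against the seed index on both orientations; placements are verified
gaplessly only (no gap alignment in the first pass). Placements may
overhang the primitive's ends: the overlapping part (≥ 30 bp) is verified
and clipped. This matters for error correction at the PS termini — were
only fully-contained reads allowed to vote, the first and last few columns
would be covered almost solely by the anchor read and would retain its
~0.5% error concentrated at the ends; clipped overhangs give the termini
the same ~30–45× vote depth as the interior, which is what makes the
residual error profile flat. A pair votes only if both of its reads place
("both ends inside"): for half-placed pairs the partner is sought inside
the window implied by its library's insert range (mean ± 3 sd), first by
an exhaustive gapless offset scan, then — if a shared 12-mer at a
window-consistent diagonal suggests an indel-shifted match — by
Smith–Waterman. A Smith–Waterman rescue must cover the read's whole
in-span extent (4 bp slack) and only its aligned interval may vote;
without this rule, a read whose repeat-matching half aligns but whose
other half belongs elsewhere would systematically vote foreign sequence.
Smith–Waterman rescues are capped at 12 per anchor (pairs are processed in
sorted order, so the cap is deterministic); in repeat-dense spans hundreds
of foreign half-placed pairs can reach the prescreen, and the cap bounds
that work at no cost to substitution-only data, where the exhaustive
gapless scan already finds every true placement. Per-column quality is
`Q = min(40, round(−10·log₁₀(max(1−f, 10⁻⁴))))` with `f` the winning
base's vote fraction — a derived confidence, not a calibrated error
probability.

**Multi-pass driver.** Pass k uses library k's pairs as anchors against
all smaller libraries. A pair is excluded from later anchor candidacy iff
it was a both-ends-inside contributor to an emitted PS read (layout member
or recruited); everything else — including pairs whose anchors were
repeat-gated — remains eligible, which is how regions skipped in pass 1
are recovered with smaller inserts. Work units are per-anchor and
independent; the optional fork-based parallel path merges results in input
order, so any worker count reproduces the serial output byte for byte.

## Simulator

The generator emulates whole-genome shotgun paired-end sequencing of a
diploid individual: haplotype A is i.i.d. uniform over ACGT; haplotype B
substitutes each site independently with probability `het_rate` (default
0.001); fragments start uniformly, choose a haplotype and strand
uniformly, and draw insert lengths from Normal(mean, sd) rounded and
truncated to [read length + 1, genome length], with sd defaulting to 10%
of the mean; sequencing errors are independent per-base substitutions
(never to the same base) at `error_rate` (default 0.005). Qualities are a
constant Q30 symbol — the method never consumes them. `seed_repeats`
pastes one haplotype-A subsequence at non-overlapping positions on both
haplotypes, so repeat copies are identical and homozygous — the hardest
case for placement (no diagnostic differences between copies) and the
cleanest for measuring mis-placement, since any cross-copy vote is still
the true base and residual errors must come from placement mistakes at
copy boundaries.

Deliberately not modeled: GC/coverage bias, chimeric fragments, indel
sequencing errors, quality-score structure, PCR duplicates. Passing tests
therefore demonstrate the algorithm's behavior under its stated error
model, not robustness to platform-specific artifacts; on real data the
Smith–Waterman fallbacks and the mismatch thresholds do the work that the
simulator never exercises.

## Evaluation

Each PS read is globally aligned (edlib, NW mode) to the true fragment of
its source anchor, oriented to the anchor's read1 strand; mismatches and
indel columns are counted over the alignment. A mismatch whose PS base
equals the *other* haplotype's allele at a known variant site is a
tolerated heterozygous site, not an error — the consensus keeps the
majority allele by design, which mismatches the source haplotype at about
half of all heterozygous sites, so counting those as errors would impose a
floor of roughly `het_rate/2` (0.05% at the default heterozygosity)
unrelated to sequencing-error correction. The per-position profile bins
errors into 20 relative-position bins per read.

## Problem sizes used in the checks

The end-to-end checks run the standard conditions — four libraries
(200/300/400/600 bp inserts) at 15× each, 100 bp reads, error 0.005,
heterozygosity 0.001 — on a 100 kb repeat-free genome and on a 200 kb
genome carrying 50 copies of one 400 bp repeat unit (shorter than the
anchor insert, hence resolvable). These sizes give ~7,500 and ~15,000
anchors respectively, enough for stable rate estimates at desk scale.
Unit tests use 10–15 kb genomes under the same conditions.

## Known limitations

- Uniform read length per run is required by the vectorized core.
- The layout consensus is ungapped; genuinely indel-rich data would need
  per-column gap voting in `layout_consensus`.
- Repeat units longer than the anchor insert are not resolvable by
  construction; their anchors are gated and those regions are left to
  whatever downstream assembly consumes the PS reads.
- The recruitment Smith–Waterman budget (12 per anchor) bounds worst-case
  repeat work; data with dense true indels would want it raised.
- PS qualities are vote fractions, not calibrated probabilities.
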