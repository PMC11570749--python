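# Methods

## Channel model and rule scoring

The DNA storage channel is modelled as a set of hard sequence
constraints plus an erasure mechanism.  A stored sequence must satisfy:

* **Homopolymer limit** `H(s) ≤ h_max`, where `H(s)` is the longest run
  of one base.  Default `h_max = 3`, the common in-vitro synthesis limit
  (typical practice ranges 2–5).
* **GC content** `gc_min ≤ GC(s) ≤ gc_max` globally (default 0.40–0.60;
  some pipelines accept 0.30–0.70) and optionally per sliding window of
  `gc_window` nt, stride 1.  The windowed default is 50 nt, matching the
  windows used when screening oligos for PCR stability.
* **Forbidden motifs**: no member of the configured set `K` (closed under
  reverse complement when `include_revcomp` is set) may occur as a
  substring.  Typical entries are primer sites, Lox sites, and
  sequencing adapters.

Scores are floating point rather than boolean so that near-misses remain
comparable.  The shape is: each *hard* rule class (homopolymer, global
GC, motif presence) contributes exactly 1.0 when violated; each
out-of-band GC window contributes its distance outside the band divided
by the band width, with the windowed class capped at 1.0.  A packet with
`total ≥ 1.0` is treated as unusable.  The exact per-rule penalty values
used by earlier rule engines in this area are not published; this graded
scheme reproduces the binary usable/unusable split while keeping the
"mean error of clean packets" metric informative.  Secondary-structure
(minimum-free-energy) scoring is deliberately out of scope; the rule set
is extensible if a thermodynamics backend is wanted.

Empty sequences are a scoring error, not a pass.

## Byte ↔ DNA mapping

Fixed bijection, two bits per base, MSB first: `00→A, 01→C, 10→G,
11→T`.  Any fixed bijection works; this one is documented so that wire
formats are stable across versions.

## Packet construction

A file is split into `n` equal chunks (`chunk_size` bytes, last chunk
zero-padded).  When the header chunk is enabled it occupies index 0 and
stores the file length (8 bytes big-endian) and CRC-32 (4 bytes); the
remaining `chunk_size − 12` bytes are free and available for metadata
codeword embedding.  An alternative layout where `chunk_size` counts the
whole packet (seed and checksum included) is available via configuration;
the two layouts differ only in arithmetic.

Per packet, keyed by an integer seed of `l` bytes (default 2):

1. The seed seeds an MT19937 stream.  The degree is drawn first by
   inverse CDF over the 40-entry degree distribution (capped at `n`),
   then `degree` distinct chunk indices are drawn uniformly without
   replacement from the same stream.  The draw order is part of the wire
   contract: published implementations do not print their exact stream
   layout, so pool compositions are comparable only qualitatively across
   toolkits.
2. The payload is the XOR (GF(2)) of the selected chunks.
3. Optional payload masking XORs the payload with an MT19937 byte stream
   keyed by `(seed, salt)`; the salt constant separates this stream's
   domain from the recipe stream, which would otherwise correlate the
   mask with the chunk selection.
4. The wire form is `seed ∥ payload ∥ CRC-32` (checksum optional),
   translated to DNA.  A per-packet CRC-32 acts as the erasure detector:
   corrupted reads are dropped rather than corrected, simulating the
   erasure channel fountain codes expect.  (A Reed-Solomon inner code
   would additionally correct; detection is sufficient for the decoder
   model used here.)
5. Seed spacing interleaves the seed bases into the payload: after each
   seed base, `spacing` payload bases are emitted, with the payload
   remainder appended (the placement when the payload is not a multiple
   of `spacing·|seed|` follows this append rule; it is one of several
   consistent choices and is fixed by the wire contract).  Spacing is
   rejected when `spacing·|seed_nt| > |payload_nt|`, the point beyond
   which seed bases would pile up unspaced at the tail.
6. Seed masking XORs the *iteration counter* with a static mask (default
   `0xAC34` repeated to the seed width) to form the effective seed that
   is stored and keys the PRNG.  The decoder therefore needs no mask
   knowledge.  Over a full seed range masking only permutes the pool; its
   value is for iterative encoding from counter 0, where it prevents
   bursts of leading-zero (all-A) seeds.

All transforms are involutions or exactly invertible merges, so the
decoder recovers the pre-transform packet bit-exactly.

## Decoding

Packets form a GF(2) linear system (rows = packets over `n` chunk
columns, right-hand side = payloads).  Rows are Python integer bitmasks;
insertion reduces incrementally against current pivots, so the
draw-until-success estimator costs one reduction per drawn packet.
Decoding succeeds iff rank = `n`; otherwise the system is brought to
reduced row-echelon form and every column resolvable as a unit vector is
reported (partial recovery).  The result depends only on the packet
*set* — order independence is tested.  An inconsistent system (a zero
row with non-zero payload) raises an integrity error, which can only
arise from corruption that slipped past the CRC.

Sampling estimators (all deterministic per RNG seed):

* *overhead* — mean packets drawn uniformly **without replacement**
  until success, minus `n`.  Without replacement matches the store-once
  medium: a stored pool cannot repeat a sequence as a new packet.
* *zero-overhead success rate* — fraction of repetitions where exactly
  `n` packets decode.
* *unrecovered chunks* — mean `n −` solved chunks at exactly `n` packets.

## Degree distributions

`raptor_rfc5053()` is the standard Raptor table (mass at degrees 1, 2,
3, 4, 10, 11, 40; degree-2 mass 481,341/1,048,576).  `robust_soliton(n,
c, δ)` is the classical LT baseline, folded to the 40-degree support and
renormalized.  A valid distribution satisfies: entries in `[0, 1)`, sum
1 (±1e−9), `deg[1] > 0`, and ≥ 2 active degrees.  `enforce_constraints`
projects arbitrary vectors onto this set by clipping, a `1e−6` floor on
degree 1, random activation of a second degree when needed, and
normalization.

## Fitness and optimization

Candidate distributions are evaluated by generating the full packet pool
over the configured seed range for every (file, chunk size) experiment:
per-degree mean error (averaged unweighted across occupied degrees, so
degrees are comparable within a distribution), the same restricted to
clean packets, duplicate payloads counted by canonical chunk-set key,
and the decode metrics above.  The fitness is the weighted sum with
default impact factors 0.4 (overhead), 0.3 (duplicates), 0.1
(unrecovered); the two error factors default to 0.1 each and are
config-exposed.  Counts enter raw (unnormalized), so fitness values are
comparable only between runs with identical parameters — a deliberate
property, since normalization constants would themselves depend on the
experiment set.

Two optimizers are implemented from scratch (off-the-shelf optimizers do
not maintain the distribution constraints):

* **Evolutionary** (default): elitist — the incumbent best survives
  verbatim, making the best-fitness trace monotone non-increasing —
  with tournament selection (size 3), arithmetic crossover (rate 0.7),
  Gaussian mutation (σ = 0.02), and constraint repair after every
  variation.
* **Differential evolution**: rand/1/bin with F = 0.5, CR = 0.9
  (standard settings; no values are published for this problem), greedy
  replacement, constraint repair on each trial vector.

The initial population is the Raptor table plus Gaussian perturbations
(σ = 0.05), with the unperturbed table included so improvement is always
measured against the standard baseline.

Problem sizes for the in-repo optimization runs are scaled to desk
scale: population 20, 30 generations, a 512-byte constant (zero-entropy)
file at chunk size 40, and a 4,096-seed range.  These sizes preserve the
qualitative behaviour being tested — duplicate pressure from low-degree
saturation and error pressure from low-entropy payloads — at a few
minutes of CPU.  Production-scale runs (population 100, hundreds of
generations, 2^16 seeds, multiple chunk sizes) use the same code paths
via the CLI.

## Analytics

* Run counting: the number of quaternary strings of length `m` with all
  runs shorter than `r` follows `f(m) = 3·Σ_{j=1..r−1} f(m−j)` with
  `f(m) = 4^m` for `m < r`; violating counts are `4^m − f(m)`.  All
  arithmetic is arbitrary-precision — the 16-nt counts have 10 digits
  and must match exactly.
* Coupon collector: expected draws to collect all `n` payloads is
  `n·H_n` exactly, approximated by `n·(ln n + 0.57721)`; expected
  distinct payloads after `N` draws is `n·(1 − (1 − 1/n)^N)`.
* Capacity: `⌊2^seed_bits · chunk_bytes · valid_fraction⌋`, computed
  with exact rationals because binary floats round printed fractions
  like `1 − 0.532` a hair below `0.468`, which would floor off one byte.
  Reported "GB" means GiB (2^30).

## Synthetic inputs

`generate_file` draws bases from the one-spike family `(a, (1−a)/3,
(1−a)/3, (1−a)/3)`; its entropy decreases monotonically from 2 (at
`a = 1/4`) to 0 (at `a = 1`), so any target in `[0, 2]` is solved by
bisection, then bases are packed two bits each.  This reproduces the
*entropy* of real inputs, not their structure: real bitmaps have runs
and spatial correlation, text has motif statistics, archives have
format headers.  Tests passing on these fixtures therefore validate the
entropy-dependence of rule violations and all coding-path logic, but
say nothing about content-specific effects such as burstiness of
violations within a structured file.  The default entropy ladder
(0.52611, 1.45598, 1.77103, 1.91665, 1.96631, 1.99996 bits/base) spans
the bitmap→text→JPEG→archive range of realistic inputs; the standard
text stand-in is 6,641 bytes at 1.941 bits/base, the size and entropy
regime of a short public-domain novel.

## Metadata codewords

Each metadata ID maps to a short DNA codeword (default 8 nt: expected
accidental occurrence ≈ `L/4^8` per sequence, and still easy to embed).
Encoding forbids every codeword except the target's across the whole
pool and searches random assignments of the header chunk's free bytes
until a rule-abiding packet contains the target codeword; fallback order
is header free bytes → last-chunk padding → an extra chunk (barred from
degree-1 emission, since a degree-1 packet of a synthetic chunk would
decode as file content).  Detection reports the unique codeword present,
or *undecided* when zero or several are found — never a wrong ID.  The
decoder can also trial-decode against all builtin distributions using
the header CRC as arbiter (`decode --try-all-dists`).

## Numerical and degenerate-input choices

* Degree is capped at `n` after sampling (truncation, no renormalization)
  so small files remain encodable under any distribution.
* `n = 1` degenerates to degree 1, chunk `{0}` for every seed.
* Scoring an empty sequence, chunking an empty file, and entropy of an
  empty input are errors, not passes.
* Ties in the GF(2) solver are broken by pivoting on the highest set
  bit; the solved-chunk count is pivot-order independent.
* Seeds wider than 32 bits key MT19937 via little-endian 32-bit words.

## Known limitations

* Published pool compositions (valid-packet percentages of specific
  encoders) depend on their exact PRNG stream layout and unpublished
  penalty tables; this package matches those numbers qualitatively, not
  bit-exactly.
* Under the binary hard-rule scoring used here, seed spacing's net gain
  concentrates where the seed region is genuinely violation-prone
  (sequential counter ranges, long seeds); over a full uniform 2-byte
  seed space, junction effects cancel most of the benefit.
* No belief-propagation or inactivation decoding; Gaussian elimination
  is cubic in the worst case but fast at oligo-scale `n` with bitmask
  rows.
* No Raptor pre-code: with a Gaussian-elimination decoder the LT
  construction over the Raptor degree table already achieves near-zero
  overhead, and a systematic pre-code would complicate the uniqueness
  accounting (linear-combination packets inflate duplicate counts).
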