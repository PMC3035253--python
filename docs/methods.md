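# Methods

## Model

`ggdist` treats a genome pair (x, y) as two *directed* sets of local
matches: the set found querying x against y and the set querying y against
x. Each match carries forward-strand, 0-based half-open intervals on one
query replicon and one subject replicon, an orientation flag, an alignment
length in columns, an identity count, a score, and (for HSPs) an e-value.
Exact matches (MUMs, or output of the built-in matcher) have
`identities = length = score` and no e-value; the match length stands in
for the missing aligner score.

Per direction, the reduced match set is summed into `H` (total match
length) and `I` (total identical base pairs), and the ten distance
functions are evaluated as described in the README: three similarity
families — `(H_xy+H_yx)/λ`, `(I_xy+I_yx)/(H_xy+H_yx)`, `(I_xy+I_yx)/λ` —
crossed with λ = sum of lengths or twice the minimum length (families 1 and
3 only) and an optional `−ln(1−d)` transform, indexed 0–9 in the
conventional GBDP order. Positions of matches in the genome play no role
beyond overlap bookkeeping, which is why incorrectly ordered draft contigs
do not perturb the distances.

Degenerate cases are defined, not special-cased downstream: with no match
in either direction every family returns the maximal distance 1 (family
2's 0/0 included); similarity ratios above 1 (possible only in raw-sum
coverage mode with repeats) clamp to distance 0; before a log transform, d
is capped at 1 − 1e-12 so the transform stays finite.

On exact-match input, `I = H` makes family 2 identically 0 and families 1
and 3 coincide; requesting family 2 on such input emits an
`IdentityOnlyWarning`. This degeneracy is inherent to identity-only
matches, not an implementation artifact.

## Greedy-with-trimming

Matches are processed in descending score order (ties: longer first, then
lexicographic coordinates — the tie-break is a determinism choice, since
the algorithm's usual description fixes only the score order). Each
candidate is clipped against the union of already-accepted intervals on the
query side and on the subject side, per replicon, never across replicons.
Clipping removes the overlapping prefix/suffix; when an accepted interval
splits a candidate internally, the single longest fragment is kept
(leftmost on ties) rather than emitting several fragments — this keeps
provenance one-to-one at the cost of occasionally discarding a short
second fragment. The opposite side's interval is shifted proportionally to
the positional cut, mirrored for reverse-orientation matches; alignment
length scales with the retained fraction and identities scale and round
*down* (the conservative direction — the discarded columns' identity
status is unknown). Query is clipped first, then subject, then both are
re-checked; because every clip yields a sub-interval on both sides the
procedure reaches a fixed point in at most two passes, and a final
disjointness guard drops any candidate that could not be made
overlap-free. The output therefore has zero pairwise overlap on both
genome sides, is idempotent under re-trimming, and never exceeds the input
total length.

## Coverage (no-trimming) variant

The exact H/I bookkeeping of the historical coverage distance is not
pinned down, so two modes exist. The default (`mode="union"`) scales the
raw H and I sums by the ratio of footprint-union lengths (query side plus
subject side) to raw span sums: each genomic position counts once per
side, the identity fraction I/H is preserved, a single match passes
through unchanged, and overlap-free input gives exactly the greedy totals.
`mode="raw"` keeps plain sums, in which repeats are multi-counted and
similarities can exceed 1 (then clamped).

## Threshold optimisation

The error ratio of a threshold T is
`(#{d ≤ T, DDH < cutoff} + #{d > T, DDH ≥ cutoff}) / N` with the boundary
inclusive on the same-species side and cutoff defaulting to 70%. T is
scanned on an inclusive 1001-point grid from the minimum to the maximum
observed distance (step = range/1000); among ties the smallest T wins,
which is conservative toward calling different species. The error ratio is
piecewise constant with breakpoints at observed distances, so the grid is
exact whenever all gaps between adjacent observed values exceed the step.
One consequence of anchoring the grid at the observed minimum: the
"everything is a different species" classifier (T below all observed
values) is not on the grid, so the optimum is bounded by the
all-same-species error `1 − prevalence` but not necessarily by
`prevalence` itself. The cutoff is a parameter because some genera accept
species boundaries at other DDH levels.

## Internal exact matcher

`find_exact_matches` enumerates all maximal exact matches of length ≥ k on
both strands via k-mer anchoring (k = the minimum length, so every
qualifying run contains a seed) and bidirectional extension, with a
per-diagonal high-water mark for deduplication. `N` never matches
anything, including `N`. No uniqueness filtering is applied (the
`-maxmatch` convention): trimming downstream is the mechanism that handles
repeats. Minimum lengths below 8 are rejected as unreliable seeding.
Output order is fully deterministic (query interval, subject interval,
strand). Reverse-strand hits are found against the reverse-complemented
subject and reflected to forward-strand coordinates at once, so no
downstream code sees reverse coordinates.

## Parsers

BLAST tabular (12-column outfmt 6/7): 1-based inclusive coordinates become
0-based half-open; `sstart > send` marks a minus-strand HSP stored on the
forward strand; identities are reconstructed as `round(pident·length/100)`
because the format carries a percentage, not a count (error < 1 bp per
HSP). Classic `mummer` lists: first numeric column is the reference
(subject) position, second the query position; `> id Reverse` headers
switch to reversed-query coordinates, which are reflected to forward
intervals at parse time. Internal matches serialise to a documented TSV
(0-based half-open, explicit strand, empty e-value field for exact
matches) that round-trips exactly.

## Incomplete-sequencing simulation

Per replicon of true length G, the read count N solves the Lander-Waterman
expected-coverage relation `1 − e^(−NL/G) = p` for the target retained
proportion p at fixed read length L (default 700 bp, a realistic single
read). N read starts are drawn uniformly with replacement; a position
array marks everything within L downstream of a start as sequenced; reads
truncate at the replicon end (linear molecules — wrapping is not modelled,
which slightly depresses terminal coverage, negligible for G ≫ L).
Unsequenced positions are removed and the surviving runs become contigs
`<replicon>_ctg<k>`. Reads are error-free by construction; no assembly or
quality model is attempted. Replicate r of a run derives its seed as
`base_seed + r` so each replicate is individually reproducible.

## Synthetic genome pairs

The pair generator emulates two closely related strains: genome A is iid
uniform over {A,C,G,T}; genome B applies iid substitutions at the
configured per-site rate (to a uniformly chosen different base), optional
extra copies of a repeat segment lifted from A, then disjoint fixed-length
segment deletions. The realised substitution count, deleted bp and repeat
placements are reported alongside the sequences. What this emulates well:
divergence-dependent exact-match length distributions, genome-length
asymmetry, repeats, and missing segments. What it does not emulate: indel
micro-heterogeneity, compositional bias (GC skew, codon structure),
horizontal transfer, and real rearrangement structure — so passing tests
demonstrate the *mechanics* of the distance functions (length
independence, repeat insensitivity, deletion robustness), not wet-lab
concordance, which inherently requires empirical genome pairs with
laboratory DDH values.

## Default parameters

| parameter | default | why |
|---|---|---|
| e-value filter threshold | 1e-2 | the conventional HSP-significance cutoff for this framework |
| distance function | index 6 (family 3, λ = sum, no log) | best HSP-based performer for DDH mimicry; family 2 (index 4) is the recommendation for draft genomes |
| reduction | trim | required for repeat-containing genomes with HSP input; coverage is the cheap alternative for MUM-like input, which is inherently repeat-filtered |
| DDH cutoff | 70% | the conventional species boundary; adjustable per taxon |
| reporting threshold without calibration | 0.044 | the published error-ratio-optimal distance threshold for unfiltered HSP input |
| read length | 700 bp | realistic single-read length for the simulation |
| internal matcher min_length | 20 | long enough that two unrelated 10-100 kb genomes share no match by chance (expected spurious count ≪ 1), short enough to sample 1-3% divergent pairs densely |

## Robustness analysis choices

The incompleteness contrast compares family 2 against the sum-of-lengths,
non-log representatives of families 1 and 3 (indices 0 and 6). The
2·min(λ) variants are deliberately excluded from the contrast: under
symmetric deletion both H and λ = 2·min shrink together, making those
variants partially robust for a different reason than family 2's
length-freedom. With exact-match input family 2 sits at distance 0
throughout (the I = H degeneracy), so the synthetic contrast shows the
λ-dependence mechanism in its sharpest form; the unit tests additionally
exercise family 2 non-degenerately through gapped HSP-style match sets
parsed from BLAST tabular text.

## Problem sizes

The test suite and the acceptance script run on desk-scale synthetic data
chosen to make every property measurable with comfortable statistical
margins: genomes of 2–40 kb for matcher and distance properties, a 0.5–1 Mb
replicon with 50–100 replicates for the Lander-Waterman calibration
(±0.01 tolerance on the mean retained fraction), 12–20 pairs for the
robustness contrasts, 100–200 random instances for the trimming, threshold
and statistics oracles. Empirical headline numbers from laboratory DDH
panels (correlations near −0.76, error ratios near 0.04) are not
reproducible from synthetic data by construction and are not asserted
anywhere; the package instead verifies every mechanical property those
numbers rest on.

## Known limitations

- Family 2 is uninformative (identically 0) for exact-match input; use
  HSP input when the identity fraction matters.
- The coverage variant's union bookkeeping is one defensible reading of
  the under-specified original; the raw-sum reading is available behind a
  flag.
- The internal matcher is a desk-scale tool (tens of kb per genome in
  seconds); for real genomes use an external aligner and the parsers.
- Internal splits during trimming keep only the longest fragment; a
  variant emitting all fragments would retain slightly more signal.
- The Euclidean distance between distance vectors is unnormalised; for a
  fixed number of pairs the two conventions are monotone in each other.
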