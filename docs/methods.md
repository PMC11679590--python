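# Methods

## The assay model

The package models a size-multiplexed, species-diagnostic PCR on the COI
DNA barcode (the ~657-bp Folmer region used throughout animal barcoding).
A panel of `k` target species shares one reverse primer bound in a window
conserved across every species; each species gets a forward primer whose 3′
end covers at least one *diagnostic site* for that species. Product length
for species `s` is

```
size(s) = reverse.end − forward(s).start + 1
```

i.e. both primer footprints are included. All coordinates in the package
are 1-based inclusive alignment columns; BED-style 0-based half-open
coordinates are available in exports behind an explicit flag. With the
looper panel's placements (forwards at 181–207 and 81–102, reverse at
357–379) the formula gives 199 and 299 nt, the two bands a gel reader
distinguishes at a glance.

A *diagnostic site* for species `s` is an alignment column where every row
of `s` carries one base that differs from the base of every row of every
other species. Comparison is strict: degenerate IUPAC codes whose base sets
overlap are treated as non-diagnostic, and columns containing gaps are never
diagnostic. This is deliberately conservative — a primer 3′ terminus is only
trusted to discriminate when the alignment guarantees a mismatch against
every off-target.

## Binding model (in-silico PCR)

Annealing stringency is abstracted to two parameters:

- `max_mismatches` (default 2): total mismatch budget over the primer;
- `three_prime_exact` (default 5 nt): a 3′-terminal window that must match
  with zero mismatches, reflecting the polymerase's intolerance of 3′
  mismatches — the mechanism that makes a single diagnostic SNP under the 3′
  end abolish off-target amplification.

Degenerate codes match wherever their base sets intersect; gaps are not
allowed in binding; templates are linear (barcodes are PCR fragments, not
circular mtDNA). A primer binds the plus strand directly or via its reverse
complement (reported as a − strand site whose 3′ end is its *left* edge in
plus-strand coordinates). Every forward-(+)/reverse-(−) site pair with
`forward.end < reverse.start` and product length inside the model's bounds
is reported — extra site pairs surface as the extra bands a real gel would
show. The defaults make a single 3′-terminal mismatch abolish amplification
while tolerating two internal mismatches, which reproduces the assay's
discrimination logic; the true mismatch tolerance of any particular wet
protocol is outside what this package can know, and the two knobs are
exposed on the CLI (`--max-mismatch`, `--three-prime-exact`).

The scanner encodes bases as 4-bit sets and evaluates all offsets with a
vectorised sliding window; the test suite pins it against a naive
per-offset, per-character oracle on random templates up to 2 kb.

## Pairwise alignment

`global_align_pair` is a Needleman–Wunsch implementation with linear gap
cost, defaults match = +1, mismatch = −1, gap = −2 (gap-averse, consistent
with substitution-only barcode divergence). Traceback tie-breaks are fixed:
diagonal, then up (gap in the second sequence), then left — so outputs are
deterministic. The score is checked against Biopython's `PairwiseAligner`
on random string pairs.

One caveat documented here because it is easy to over-claim: "substitution-
only pairs align gap-free whenever gaps cost more than mismatches" is not a
theorem at these scores. A one-column shift of a near-periodic string can
convert two or more mismatches into matches at the price of a single gap
pair (score +2k − 3 for k conversions), so e.g. `ACACAC` vs `CACACA`
optimally aligns *with* gaps. For barcode-like inputs — scattered
substitutions on a random background — the gapless alignment is optimal, and
that is the regime the property tests assert (including the 657-column,
56-substitution focal pair).

Percent identity is computed over columns where neither row is gapped and
left unrounded; presentation rounds to two decimals (601/657 → 91.48).

## Panel design

`DesignConstraints` defaults: primer length 18–28 nt, GC 30–60 %, Wallace
Tm 50–75 °C (2 °C per A/T + 4 °C per G/C), homopolymer runs ≤ 4, diagnostic
site required within the 3′-terminal k = 5 nt of a forward, product length
80–1000 nt, minimum pairwise product separation Δ = 50 nt. The published
assay is feasible under these defaults (its primers have Wallace Tm
60–74 °C and GC 36–44 %); Δ = 50 is half the looper assay's realised 100-nt
separation and is comfortably above gel resolution at these sizes. These
bounds are this package's own QC envelope — a screening default, not a
thermodynamic model.

Candidate enumeration is exhaustive and ordered (by start, then length):
reverse candidates from every all-species conserved window, forward
candidates from every placement of every allowed length whose 3′-terminal
k columns cover a diagnostic site of the target species, all filtered by
the QC bounds, with candidates read off the target species' rows and
required to be unanimous across them (which also makes the search invariant
to row order).

The assembly objective is lexicographic: maximise the minimum pairwise
product-size separation (must reach Δ), then the worst per-primer QC margin
(smallest slack to any GC/Tm bound); ties fall to smaller coordinates, then
shorter primers. Because product sizes depend only on the forward *start*
for a fixed reverse, the search reduces, per reverse placement, to picking
one start per species. That selection is solved exactly rather than by
enumerating the Cartesian product (which is exponential in `k` and already
intractable at five species): feasibility of "one start per species with
pairwise gaps ≥ d" is a subset-DP over species (any valid pick sorts into an
increasing sequence with consecutive gaps ≥ d), and both objective
thresholds are monotone, so each is a binary search over feasibility checks,
followed by a greedy lexicographically-smallest start assignment. The DP is
verified against exhaustive enumeration on small random instances in the
test suite. Ranked alternatives are the best panel of each runner-up
reverse placement. The subset DP caps the panel at 12 species — far beyond
any size-resolvable gel multiplex.

The 3′ cross-dimer check scores the longest perfect antiparallel
complementary run anchored at either primer's 3′ terminus (degenerate
positions pair when their sets can pair) and fails above a threshold
(default 4). It is a screening heuristic, not a thermodynamic ΔG model —
nearest-neighbour duplex energetics are out of scope.

## Classification

A lane is a list of observed band sizes. A band matches a species when it
lies within the tolerance (default ±10 nt absolute, a typical 2 % agarose
read-off error at these sizes; a percent mode is available) of that
species' expected size. Lanes whose bands match exactly one species are
called; no matching band → `no_call`; bands compatible with ≥ 2 species →
`ambiguous` (a size list carries no intensity information, so no
"strongest band wins"). Loading a panel whose expected sizes are separated
by ≤ 2× tolerance is a configuration error — calls would overlap.

Displayed percentages are integer-rounded half-away-from-zero from exact
fractions kept alongside (3/19 → 15.79 → 16, 16/19 → 84.21 → 84); the
rounding rule is an inference from those printed pairs, since ties at
exactly .5 never arise at n = 19.

## Synthetic data

`make_paper_panel` emulates the published five-species barcode alignment
without shipping or downloading any real sequence. Construction: a random
A/T-rich 657-nt background (typical insect mtDNA composition; the motifs,
not the background, carry all tested behaviour) with

- the *C. includens* forward motif embedded verbatim at columns 181–207,
  the *R. nu* forward at 81–102, and the reverse complement of the common
  reverse in **all** rows at 357–379;
- one diagnostic-breaking column inside each forward's 3′-terminal 5
  columns: the target keeps the primer base, the four other species share a
  different base (this is what makes each forward species-specific under
  the default binding model);
- exactly 56 substitution columns between the two focal rows — the count
  implied by 657 columns at 91.48 % identity — and ~55 private
  substitutions for each outgroup-like row, all drawn from columns outside
  the three motif regions and pairwise disjoint across species, so the
  generator can ledger every species' diagnostic columns exactly;
- divergent bases forced at the columns flanking 357–379 so the conserved
  window is delimited, and optional identical within-species replicates
  (with optional seeded private SNPs when within-species variation is
  wanted).

Everything is bit-reproducible per seed, and the seeded bookkeeping
(diagnostic columns, focal difference columns, batch composition) serves as
an independent oracle in the tests. What the generator does **not**
emulate: indel evolution, sequencing/chromatogram error, heteroplasmy,
within-species polymorphism beyond the seeded SNPs, and real phylogenetic
correlation structure between the outgroup rows. Passing tests therefore
demonstrate the machinery's correctness on substitution-only, motif-true
panels — they do not certify primer performance on real populations, where
unsampled haplotype variation under a primer's 3′ end remains the main
failure mode.

`make_random_panel` generates substitution-only panels from a random
ancestor with disjoint per-species mutated columns and returns the exact
diagnostic-column ledger (for two-species panels every differing column is
diagnostic for both sides, and the ledger says so). `make_field_batch`
turns a composition into one single-band lane per individual with optional
uniform size jitter, truth labels returned separately.

## Problem sizes in the checked examples

The test suite and acceptance script run on the scales the method actually
targets: 657-column alignments for the barcode panel, templates up to 2 kb
for the binding-scan/oracle equivalence, a 20-species × 1-kb panel for the
diagnostic-site oracle, and 19–50-lane batches for classification. The
whole suite completes in a few seconds.

## Known limitations

- No thermodynamic annealing model (Tm is Wallace-rule only; no
  nearest-neighbour ΔG, hairpins, or salt correction).
- Multiple alignment of divergent taxa is out of scope: panels are ingested
  pre-aligned or generated gap-free; only pairwise alignment is built in.
- Amplicon prediction is presence/absence with exact sizes — no yield,
  kinetics or competition between products.
- The classifier consumes size lists, not gel images.
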