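# Methods

## Candidate search

A candidate off-target site is any 20-nt genomic window, on either
strand, whose Hamming distance to the guide's protospacer is within the
mode's budget and whose 3'-adjacent trinucleotide belongs to an admitted
PAM class. The budgets encode the empirical tolerance asymmetry of the
system: dCas9 binding is detectable at loci with up to ~9–10 mismatches,
whereas cleavage requires closer matches, so binding mode searches to 9
mismatches and cleavage mode to 6. The scan is substitution-only by
construction — bulge/indel alignments are out of scope — and is
implemented as a vectorized per-offset byte comparison; its semantics are
pinned by a test-suite oracle that slides a window over every position of
both strands and counts mismatches character by character.

PAM classes follow the observed preference hierarchy GGG > NGG > NNG.
NGG (which subsumes GGG) is always searched; NNG is an explicit opt-in,
reflecting that NGG is the canonical *S. pyogenes* motif and NNG evidence
is weaker. The class enters the final ranking only as a tie-break.

Conventions and degenerate inputs:

- Coordinates are 0-based half-open (BED) and cover the protospacer only;
  the PAM occupies `[end, end+3)` on `+` and `[start-3, start)` on `-`.
- Non-ACGT genome bases (assembly gaps, IUPAC codes) count as mismatches
  at protospacer positions and never satisfy a required PAM guanine; an N
  at a PAM wildcard position is tolerated. This makes the treatment of
  gapped assemblies conservative and deterministic.
- Windows whose PAM would run off the chromosome end, and chromosomes
  shorter than 23 nt, contribute nothing. Overlapping windows are all
  reported independently.
- Output order is fixed: (chrom, start, strand).

## Base score

The protospacer is partitioned into three segments, by default 5 + 5 + 10
with segment 1 PAM-distal. Per segment *i*, a match earns +sᵢ, an
isolated mismatch −sᵢ/2, and every position inside a maximal run of ≥ 2
consecutive mismatches the full −sᵢ; a run that crosses segment
boundaries is charged, at each of its positions, the arithmetic mean of
the sᵢ of all segments it spans. Consecutive mismatches are counted as
positions, not runs, and runs longer than two take the full penalty at
every member position — the run-of-two description generalizes directly.
Scores are plain floats with no rounding until output (two decimals in
the TSV) and may go negative; no floor is applied.

The segment orientation is genuinely ambiguous in the source experiments
(the training description lists 5, 5, 10 in 5'→3' order, while the
results discussion speaks of a PAM-distal 10-bp block). We adopt the
5'→3' reading — s₁ covers the five PAM-distal positions, s₃ the ten
PAM-proximal ones — and expose `SegmentScheme(orientation=
"pam_proximal_first")` to flip it; with the shipped weight sets the
default puts the heavy penalties (70/50 and 60/50) on the PAM side, where
mismatch intolerance is strongest.

Trained weights, used as defaults:

| mode     | s₁ | s₂ | s₃ | d  | budget |
|----------|----|----|----|----|--------|
| binding  | 5  | 70 | 50 | 20 | 9      |
| cleavage | 20 | 60 | 50 | 10 | 6      |

## Chromatin accessibility

Per-cell-type open-chromatin peak sets are collapsed onto fixed-width
genomic bins; a bin's X is the number of cell types with ≥ 1 bp of peak
overlap (each cell type counts at most once per bin). A site takes the
maximum X over the bins it overlaps (a mean reduction is available) and
receives S_d = c·X·d with c = 0.0113 by default. The coefficient is the
slope of an empirical trend between cell-type-shared accessibility and
observed Cas9 binding; it is consumed as configuration, not re-derived
here. Bin width defaults to 200 bp — typical accessibility-peak
resolution; the X semantics, not the width, carry the method — and is
configurable. Final ranking is by S_f = S + S_d descending with a
deterministic tie-break (PAM class, chromosome, start, strand). Without a
track (non-human genomes, or no data) S_f = S and the ordering is
unchanged, which the tests assert as the all-zero-track identity.

## Weight training

The objective for a weight set is the number of the top-N (default 1000)
ranked predictions fully contained in a validated interval; the counting
unit is the prediction, so two predictions inside one gold interval count
twice. Candidates are enumerated once (enumeration is weight-independent)
and rescored per grid point. The grid over (s₁, s₂, s₃) is evaluated
exhaustively — deterministic total enumeration rather than random
starts, for reproducibility — and whenever the optimum lies on an axis's
upper boundary that axis is extended with uniform spacing until the best
objective on the extension frontier has dropped by ≥ `stop_drop`
(default 10) from the best seen. Single-value axes are treated as pinned
parameters and never extended. Ties resolve to the lexicographically
smallest weight triple; an all-zero objective surface is reported with a
warning flag. The chromatin weight d is trained afterwards by the same
objective over a 1-D grid with the segment weights frozen.

## Evaluation

`top_n_overlap` applies full-containment semantics: a prediction counts
only if 100% of its interval lies inside some gold interval (the
`bedtools intersect -f 1` convention with the fraction on the
prediction); a prediction inside several overlapping gold intervals
counts once. `overlap_curve` tabulates this over a range of N and is
non-decreasing by construction.

`random_region_enrichment` asks whether a site set preferentially falls
in bins open across many cell types. Each simulation places
length-matched regions uniformly at random, chromosome chosen
proportional to length. The global statistic is the mean per-site X; the
one-sided empirical p-value uses the add-one correction
p = (1 + #{sim ≥ obs}) / (n_sim + 1), so the smallest attainable p at
n simulations is 1/(n+1). Per-frequency-stratum overlap fractions with
simulated mean ± sd are reported alongside. The exact test behind the
original headline p-value is unspecified upstream, so agreement with any
parametrically derived value is not claimed.

## Synthetic data

The fixture generator emulates the study conditions: a (default 41% GC)
random genome hosting engineered sites at chosen mismatch configurations
and PAMs on either strand, accessibility tracks in which validated sites
sit in bins shared by most cell types while background peaks are
scattered at random, and gold intervals padded by 10 bp so a contained
20-bp prediction passes full containment. Generation is a pure function
of (spec, seed); if the random background corrupts a planted site the
genome is redrawn from a derived seed. Each fixture ships a manifest with
the ground truth and the expected candidate set computed by the naive
scanner, so search and scoring can be verified without re-deriving truth.

Two purpose-built constructions back the harder checks. The
weight-recovery fixture exploits the linearity of S in (s₁, s₂, s₃): it
consists of top-N gold candidates plus exactly one decoy whose
coefficient vector scores below every gold mask at the target weights but
above at least one gold mask at every other grid point, making the
objective uniquely maximal at the target — a property verified
exhaustively at build time, not assumed. The enrichment fixture builds a
125-cell-type track with a few bins shared by ≥ 100 cell types over a
low-X background.

What the synthetic data do not capture: real mismatch-identity effects
(rG:dT wobble vs rC:dC), sequence-composition biases around true Cas9
sites, bulges, peak-width and signal-strength heterogeneity of real
accessibility data, and the scale of a mammalian genome. Passing tests
therefore demonstrate algorithmic correctness and calibration of the
machinery, not predictive accuracy on biological data.

## Problem sizes and numerical choices

The test suite and acceptance script run on deliberately small inputs —
genomes of 1–10 kb, 20-genome oracle sweeps over budgets 0–12, 10⁵-mask
scoring cross-checks, 200-simulation enrichment runs repeated 20 times —
chosen as the smallest sizes at which each property is meaningfully
exercised. The two independent score evaluators are compared at 10⁻⁹
absolute tolerance (they may differ by float summation order); S_d uses
the same multiplication order everywhere so linearity checks are exact.
Ranking ties are broken deterministically at every stage, and all
randomness flows from explicit seeds kept below 2³¹.

## Known limitations

- Substitution-only alignment; DNA/RNA bulges are invisible.
- No on-target efficiency model; guide ranking is off-target burden only
  (sum of off-target S_f; count- and max-based alternatives are exposed
  as options in the report object).
- The 0.0113 coefficient and the trained weights are taken as given; on
  new gold-standard data they should be retrained via the optimizer.
- Whole-mammalian-genome throughput is out of scope; the scan is linear
  per chromosome and adequate to tens of megabases.
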