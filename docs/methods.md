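# Methods

## Data model

Input is one multiple sequence alignment per locus (FASTA, already
aligned — alignment itself is out of scope) plus a metadata table mapping
each accession to a species, an outermost-to-innermost clade path, an
optional region tag, and a representative flag. Residues are uppercased
on read; `?` and `N` are normalised to a single missing symbol. The
alphabet distinguishes four bases, the gap `-`, missing data, and IUPAC
ambiguity codes; the three non-base classes behave differently in
different computations (below), which is why they are kept apart
internally.

Datasets are assembled by concatenating loci in a stated order using
**complete cases only**: an accession enters a multi-locus dataset only if
it carries every component locus. This is the behaviour implied whenever
a combined dataset has fewer species than its components; the alternative
(padding absent loci with missing data) would silently turn concatenation
into a union and distort per-pair overlaps.

Interspecific comparisons use one **representative accession** per
species. When the metadata flags one, it is used; otherwise the accession
with the fewest gap/missing/ambiguous characters is chosen, ties broken
lexicographically by accession id — deterministic and data-quality
driven. Clade membership is carried in the metadata (optionally derivable
from a Newick tree with labelled internal nodes); the pipeline never
infers trees. Regions are flat tags, not coordinates.

## Distances

Pairwise distances follow the Kimura 2-parameter model,

d = −½ · ln[(1 − 2P − Q) · √(1 − 2Q)],

with P and Q the transition (A↔G, C↔T) and transversion proportions among
the pair's mutually resolved sites (**pairwise deletion**: a column is
dropped for a pair when either member is gap, missing, or ambiguous;
ambiguity codes are treated as missing, never partially matched). The
formula is undefined at saturation (1 − 2P − Q ≤ 0 or 1 − 2Q ≤ 0) and
when no sites overlap; such pairs carry an explicit undefined flag and
are excluded from every downstream summary, with the exclusion count
logged. Pairs with fewer than `min_overlap` resolved sites (default 100,
configurable) are likewise flagged: with fragmentary herbarium-style
sequences a distance estimated from a handful of sites is noise. No
gamma rate correction is applied — plain K2P only.

## Haplotypes

Two sequences share a haplotype when they show zero point-mutation
mismatches at positions where both are resolved. Under *gap-as-missing*,
gap, missing and ambiguity are all wildcards; under *gap-as-5th-state*
the gap becomes an ordinary symbol that mismatches both bases and
missing data (an absent stretch cannot equal an unread one) while
ambiguity codes stay fully wild. Only `-` changes status between modes.

Wildcard identity is not transitive (`AC?T` matches both `ACGT` and
`ACAT`, which differ), so "unique sequences" needs a tie-break rule.
Haplotypes are defined as **connected components** of the zero-mismatch
link relation: order-independent, idempotent, and the unique maximal
merge — the same collapse a statistical-parsimony tool performs at zero
differences. The fifth-state mode can only add mismatches, so its unique
count is never below the missing-mode count; both are reported, the
fifth-state count parenthesised when it differs.

The **Max ID rate** is 100 · (unique haplotypes) / (species); by default
it is computed on the representatives-only dataset so the denominator is
a species count and the statistic reads as "fraction of species that
could possibly be told apart". Values above 100% are possible (and
flagged) only when multiple accessions per species are included.
Variable characters are counted as alignment columns with at least two
distinct unambiguous bases, on the same representatives-only dataset.

## Discrimination summaries

Distances are partitioned into interspecific comparisons (representative
accessions, one per species) and intraspecific comparisons (all
within-species pairs of every species with ≥ 2 accessions). Because
species are unevenly sampled, intraspecific summaries average **within
species first**: each species contributes its mean once, and the reported
mean/SD are over those per-species means; the maximum stays the global
maximum over all intraspecific pairs, since it answers a different
question (how large can conspecific divergence get). Interspecific
mean/SD/max are plain summaries over representative pairs — with one
accession per species there is nothing to reweight. An alternative
reading, in which interspecific summaries are also recomputed after
per-species averaging, is deliberately not implemented: with
representatives the two readings coincide, and the package exposes the
raw partition for anyone wanting a different weighting.

Threshold fractions use strict inequality (comparisons *exceeding* 1%
and 2%), reported to two decimals; undefined distances are excluded from
numerator and denominator. The barcoding-gap diagnostic reports
min(interspecific) − max(intraspecific): a gap exists only for a strictly
positive margin (a shared zero is overlap, not separation). Histograms
use shared bins from 0 at width 0.005 substitutions/site by default; the
width is a display choice, configurable, with no effect on any statistic.

## Synthetic data generator

The generator emulates a densely sampled barcoding study of one plant
clade; it is the package's test bed and defines what the tests do and do
not show.

**Tree.** One pure-birth (Yule) subtree per named clade, grafted onto a
pure-birth backbone; total height 1, ultrametric. The off-the-shelf
birth–death simulator stops at the n-th birth, leaving a zero-length
cherry, so all tip branches are extended by the waiting time to the next
birth (Exp(n) at birth rate 1) — the exact continuation of the process —
before rescaling. Default clade crown depth is 0.35 of tree height; a
clade can override it (`crown_height`) to model a recent radiation.

**Sequences.** Root sequence uniform over {A,C,G,T}; sites evolve
independently along branches under the two-parameter (K80) process with
transition/transversion rate ratio κ (default 3, a typical plastid
value; 2 for the nuclear locus). Branch transition matrices are the
exact matrix exponential of the normalised rate matrix, so the expected
divergence between two species at a locus is exactly
(locus rate) × (path length) — the ground truth the recovery tests score
against.

**Defaults as study design.** 100 species in five clades (11, 28, 12,
21, 28), two of them region-tagged; the 'Mexico+Central America' clade
is a recent radiation (crown 0.12) while 'Japan' spans two distantly
related clades — the contrast that drives opposite regional outcomes.
Locus panel: rbcL 491 sites (rate 0.004), matK 725 (0.006), trnK 1068
(0.0075), rpl32-trnL 942 (0.0105), trnH-psbA 491 (0.013), nrITS 628
(0.037). The lengths are typical aligned lengths for these markers and
the rates are set so that, at the tree's mean path length (≈1.45),
simulated mean interspecific distances fall in the empirically observed
range and keep the markers' observed rank order; ranks, not values, are
what the tests assert, since one tree realisation shares its deep
branches across all pairs and dataset-level means fluctuate accordingly.

**Accessions and noise.** A species receives extra accessions with
probability 40/112 (uniform 2–6 of them, else 1), mirroring the sampling
depth of the emulated design. Extra accessions evolve a further
`intraspecific_depth` (default 0.05 tree units, i.e. well below typical
species splits) from the species sequence; the representative is the
accession left untouched by this intraspecific evolution. Alignment
artifacts — indel runs (geometric length, mean 3 sites, expected 1% of
sites) and terminal missing stretches (expected 2% of sites, one end) —
are injected into *all* accessions, representatives included: they model
sequencing/alignment quality, not biological divergence, and
representative datasets must contain gaps for the two gap conventions to
be distinguishable at all.

**What the simulator does not model:** coalescent within-species
genealogies, recombination, heterotachy or rate variation across sites,
indel-aware alignment (gaps overwrite columns rather than shifting
them), ambiguity codes, and base-composition bias. Passing tests
therefore demonstrate correctness of the statistics under the K80
generating process and robustness to patchy data — not robustness to
model misspecification in real alignments.

## Numerical and design choices

- Distances are `float64` throughout; undefined is NaN plus an explicit
  boolean mask (never silently dropped), and `-0.0` at zero divergence
  is normalised to `0.0`.
- Sample SD (ddof = 1) everywhere; a single value has SD 0 by
  convention.
- Haplotype components via a sparse graph; cluster order follows first
  appearance in the dataset so output is deterministic.
- Table serialisation: distances to 4 decimals, percentages to 2.
- All stochastic components derive from one integer seed; per-locus
  streams are salted with a CRC of the locus name so adding a locus does
  not perturb the others.
- The orchestration layer always computes both gap conventions (they
  share all the heavy work); empty subsets are skipped and logged rather
  than aborting a run.
- Problem sizes in the shipped analyses (100 species, ~214 accessions,
  six loci; 200 × 10,000-site replicates for estimator recovery) were
  chosen so the full analysis re-runs in well under a minute on one core
  while keeping Monte-Carlo error small relative to the effects measured.

## Known limitations

- The identity-based collapse implements only zero-difference
  dereplication; statistical-parsimony networks, connection limits and
  genealogies are out of scope.
- Only K2P is offered; for strongly saturated or composition-biased data
  a different model (and software) is appropriate.
- Tree-based discrimination tests (species monophyly, best-close-match)
  are not implemented; the distance matrix writers (PHYLIP, long TSV)
  exist partly so external tools can take over from there.
- The barcoding-gap margin compares distribution extremes and is
  sensitive to single outlier pairs; the histograms are provided so the
  full distributions can be judged alongside the flag.
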