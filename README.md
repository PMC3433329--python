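# barcodegap

Haplotype- and distance-based evaluation of multi-locus DNA barcodes —
globally, within nested phylogenetic subclades, and within geographic
regions.

## The problem

Short standardized loci (for plants: the chloroplast core barcode
*rbcL* + *matK*, with *trnH-psbA* or nrITS as supplementary markers) are
used to identify species from sequence alone. Reported success rates are
often inflated because the species compared are distant relatives. In
slowly evolving groups — long-lived woody plants in particular — the real
test is whether a barcode can separate *close* relatives, which requires
evaluating discrimination as a function of phylogenetic relatedness:
across a whole clade, then again restricted to its subclades, then again
within regional floras.

`barcodegap` implements that protocol for aligned multi-locus data, and
ships a clade-structured sequence simulator so the whole pipeline is
testable (and its estimators checkable against known truth) without any
sequence download.

## What it computes

For each dataset (a locus or concatenation, restricted to accessions
carrying every component locus):

- **Unique haplotypes.** Sequences are collapsed when they show zero
  point-mutation mismatches where both are resolved; missing data and
  IUPAC ambiguities are wildcards, and the alignment gap `-` is either a
  wildcard (*gap as missing*) or an ordinary fifth symbol (*gap as 5th
  state*). Because wildcard identity is not transitive, clusters are
  connected components of the zero-mismatch relation.
- **Max ID rate** = 100 · (unique haplotypes) / (species sampled): the
  ceiling on character-based discrimination, crediting even single-base
  differences.
- **Kimura 2-parameter distances** with pairwise deletion:
  *d* = −½ ln[(1 − 2*P* − *Q*)·√(1 − 2*Q*)], with *P*, *Q* the transition
  and transversion proportions over the pair's mutually resolved sites.
  Interspecific comparisons are one-to-one between representative
  accessions; intraspecific comparisons pool all within-species pairs and
  are averaged per species before summarising.
- **Threshold fractions** (% of interspecific comparisons strictly
  exceeding 1% and 2%) and the **barcoding gap** diagnostic
  (min interspecific − max intraspecific distance, plus histograms).

All of it can be re-run per subclade (matched anywhere on a clade path)
or per region tag.

## Worked example

```python
from barcodegap import CladeConfig, LocusConfig, SimulationConfig, build_dataset
from barcodegap.synthetic_data import simulate_bundle
from barcodegap.pipeline import evaluate_dataset

cfg = SimulationConfig(
    clades=(CladeConfig("North", 8, region="north"), CladeConfig("South", 8)),
    loci=(LocusConfig("rbcL", 500, 0.005), LocusConfig("nrITS", 600, 0.035)),
    seed=42,
)
aln, truth = simulate_bundle(cfg)
for loci in (["rbcL"], ["nrITS"], ["rbcL", "nrITS"]):
    ds = build_dataset(aln, loci)
    r = evaluate_dataset(ds, aln.metadata).report
    print(f"{r.dataset_name:11s} maxID {r.max_id_rate_pct:6.2f}%  "
          f"mean d {r.inter_mean:.4f}  >1% {r.pct_gt_1:5.2f}  gap={r.gap_exists}")
```

prints

```
rbcL        maxID  50.00%  mean d 0.0057  >1% 10.83  gap=False
nrITS       maxID  93.75%  mean d 0.0390  >1% 85.00  gap=False
rbcL+nrITS  maxID  93.75%  mean d 0.0234  >1% 74.17  gap=False
```

The slow locus alone resolves half of the 16 species at best; the fast
nuclear locus resolves nearly all of them; concatenating both keeps the
character-level resolution but *dilutes* the mean genetic distance, so
fewer comparisons clear a 1% cutoff than with the fast locus alone — the
characteristic trade-off of mixing slow and fast markers. No dataset
shows a barcoding gap (the intra- and interspecific distance
distributions overlap), which is why fixed 1%/2% cutoffs are needed at
all.

## Command line

```
barcodegap simulate --seed 1 --out sim/
barcodegap evaluate \
  --fasta rbcL=sim/rbcL.fasta --fasta matK=sim/matK.fasta \
  --fasta nrITS=sim/nrITS.fasta \
  --metadata sim/metadata.tsv \
  --combine rbcL+matK --combine rbcL+matK+nrITS \
  --subset clade:Solenotinus --subset region:Japan \
  --out eval/
```

`evaluate` accepts any aligned per-locus FASTA plus a metadata TSV
(columns `accession`, `species`, `clade_path` — `;`-delimited, outermost
first — `region`, `representative`), so real alignments drop in exactly
like simulated ones.

## The analysis

The `analysis/` scripts run the full study on simulated data, writing
tables under `results/`:

1. `01_simulate.py` — generate the default design: 100 species in five
   nested clades, six loci (rbcL slowest → nrITS fastest), 1–6
   accessions per species, gaps and missing data.
2. `02_global_discrimination.py` — the nine standard datasets evaluated
   across all species.
3. `03_subclade_analysis.py` — the same protocol inside four named
   subclades; quantifies the collapse of interspecific divergence among
   close relatives.
4. `04_regional_analysis.py` — evaluation within two regional samples
   with contrasting clade composition.
5. `05_barcoding_gap.py` — intra/inter distance histograms and gap
   margins per dataset.

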