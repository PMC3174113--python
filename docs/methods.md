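# Methods

## Peak detection model

A tiling-array experiment is modelled as, per chromosome, an ordered vector
of probe start coordinates (0-based) and one log2 IP:input ratio per probe.
The detector is deliberately simple and fully specified:

- **Cutoff.** At stringency *P* ∈ (0, 100] the threshold is
  `(P/100) · (mean + 6·SD)` over all the chromosome's probe ratios. SD is
  the *sample* standard deviation (n − 1 denominator); a single-probe track
  has no defined SD and is rejected. The base value is recomputed per
  chromosome and per replicate, so chromosome-to-chromosome scale
  differences do not leak across.
- **Window rule.** A probe seeds a detection when at least `min_probes`
  (default 4) probes — the probe itself included — whose *start* coordinates
  fall in the closed window `[start − flank, start + flank]` (flank 250 bp)
  have ratio strictly above the threshold. Counting by probe start with a
  closed window is a convention choice; the boundary behaviour is pinned by
  tests. At 100-bp spacing the window holds at most 5–6 probes, so the rule
  demands near-contiguous enrichment.
- **Merging.** Overlapping or adjacent seed windows merge; the peak spans
  the above-threshold probes inside the merged window (end = last probe
  start + probe length) and its height is their maximum ratio.

### Permutation null and FPR

The null model scrambles the ratio values among the chromosome's probes,
preserving the ratio multiset and the probe geometry while destroying
spatial clustering. Twenty scrambled tracks per chromosome (configurable)
are drawn once from a seeded generator and reused across the whole cutoff
sweep. At each cutoff,

    FPR = (mean peak count over scrambled tracks) / (observed peak count).

Zero observed peaks yields an undefined sentinel (NaN), never an error.
The FPR is a count ratio, not a probability: values above 1 are reported
as computed (on pure-noise tracks the estimator centres on 1 by
exchangeability, which the tests check). Each peak is assigned the FPR of
the *most stringent* cutoff at which it is first detected; since lowering
the cutoff only adds and widens peaks (a monotonicity the tests assert),
peak identity across the sweep is tracked by genomic overlap with the
final, least-stringent peak set.

### Replicate consensus

High-confidence sites require peaks from all replicates (default 3) that
mutually overlap by ≥ 1 bp, every contributor with FPR strictly below 0.05.
Mutual overlap of 1-D intervals is equivalent to a non-empty common
intersection, so the filter is implemented as a distinct-replicate coverage
sweep; the consensus interval is the contributors' intersection, its height
their mean, its FPR the worst contributor's. No reciprocal-overlap fraction
is required. The FPR filter is applied per replicate peak, not re-estimated
on the consensus set.

## Colocalization and genomic context

Two marks' peak sets are paired per chromosome by midpoint distance,
strictly below 500 bp, using greedy nearest-first one-to-one matching
(prevents one peak from counting in several loci; an edge-to-edge distance
mode is available). Context classification takes precedence promoter >
intragenic > intergenic: the promoter window spans 2,000 bp upstream to
500 bp downstream of a gene's 5' end, strand-appropriately — a common
convention, configurable because no single definition is canonical.
Intergenic loci further than 10 kb from the nearest 5' end are flagged
distal. An empty annotation classifies everything intergenic at infinite
distance. Overlap with an external gene list counts loci whose midpoint
falls within a window of a listed gene's span; names are resolved against
the annotation and unresolvable names are skipped with a warning.

## Motif-read clusters

Reads chain into clusters on ≥ 1 bp overlap (half-open intervals: abutting
reads do not chain). Cluster depth is the **maximum simultaneous
coverage** within the cluster, computed by an event sweep — not the read
count — so depth is invariant to cluster width. The depth histogram is fit
over depths 1..10 (nonzero counts only) by unweighted least squares on
log10–log10 axes; the exponent is the negative slope, with a NaN sentinel
when fewer than two depths are available. Depth strictly above 10 marks
high confidence: the deep-cluster excess sits above the threshold, so depth
exactly 10 is low-confidence. MLE fitting of the exponent would be more
efficient statistically but the histogram fit is the transparent default
for a visually evident power law.

## Allele-specific analytics

- **Bisulfite scoring** consumes a pre-extracted read × CpG call matrix
  (M/U/NA). Reads whose non-CpG cytosine conversion rate is below 0.9 are
  discarded as incompletely converted; per-site methylation is M/(M+U)
  over retained reads, NaN at zero coverage. This is a simplified analogue
  of interactive bisulfite-QC software, reduced to the scored quantity the
  downstream claims use.
- **Calibration** fits one OLS line per fluorescence channel against known
  mixture fractions (≥ 3 distinct fractions required); a constant signal
  gets slope 0 and R² = 0 by convention. Fraction estimation inverts each
  usable channel (|slope| above 1e-9) and averages — no combination rule
  is canonical, and the mean is transparent and exactly invertible in the
  noiseless case (a tested round-trip identity).
- **Genotype classification** is nearest-centroid against control
  centroids (homozygous AA/BB, heterozygous AB, no-template control), with
  points whose second-nearest centroid is within a 1.2× distance ratio of
  the nearest labelled undetermined.
- **Mono/biallelic calls**: homozygous gDNA is uninformative by
  definition; heterozygous samples are monoallelic when the cDNA
  minor-allele fraction is strictly below 1/6. The cut operationalizes the
  assay's demonstrated 1:5 discrimination range; it is a documented default,
  not a universal constant.

## Synthetic data: what it emulates, and what it does not

The generators produce every input the pipeline consumes with recorded
ground truth, all draws flowing from one seeded numpy generator per call
(equal seeds ⇒ bit-identical outputs, a tested invariant).

- **Tiling experiment**: per-chromosome probe grids (spacing 100 bp,
  50-mers; probe count = ⌊length/spacing⌋), i.i.d. Gaussian background
  log2 ratios (mean 0, SD 0.5 by default) and spiked sites that add a
  constant effect (default +3.0, i.e. six background SDs, over five
  probes) at identical positions in all replicates — biological replicates
  share biology, not noise. The i.i.d. Gaussian background is the simplest
  model under which the mean + 6·SD cutoff behaves predictably; real
  arrays show probe-sequence effects, spatial autocorrelation and dye
  bias that this deliberately omits, so passing tests certify algorithmic
  correctness and calibration under the stated noise model, not
  performance on any particular array platform.
- **Dual-mark experiment**: each mark-A site independently receives a
  mark-B partner with the stated probability (pair counts are binomial),
  jittered by a zero-mean Gaussian of configurable SD.
- **Gene annotation**: uniform random stranded gene bodies (2–20 kb);
  overlaps allowed, as in real annotations.
- **Motif clusters**: depths sampled by inverse CDF from a discrete power
  law on support 1..10, plus an excess component uniform over a high depth
  range (default 15–40), reproducing the bimodal depth spectrum without
  asserting an unstated generative law above the threshold.
- **Bisulfite reads**: Bernoulli calls at stated per-CpG probabilities;
  non-CpG conversion failures injected at a stated rate into dedicated
  columns, optional NA dropouts.
- **Allelic mixtures**: channel signals linear in the allele-A fraction
  plus Gaussian noise (default SD 0.02, the dilution series' ~2% error
  scale). Default lines are the published dilution-series calibration
  rescaled from the percent axis to fraction units (slope 1.02 /
  intercept 0.0415 for channel A; −0.85 / 0.9796 for channel B). The seven
  default fractions follow the published mixture labels taken literally,
  including the irregular 40:20 mixture (fraction 1/3).

## Numerical choices and degenerate inputs

- Threshold comparisons are strict (`ratio > cutoff`); pairing distance and
  the minor-allele cut are strict (`< 500 bp`, `< 1/6`); depth 10 at
  threshold 10 is low-confidence. All boundaries are pinned by tests.
- FPR sentinel: NaN for zero observed peaks; consensus excludes NaN-FPR
  contributors. Exponent sentinel: NaN for < 2 fit points.
- Sub-seeds for replicate × chromosome permutation plans are derived
  arithmetically from one master seed in the CLI and acceptance script,
  keeping runs reproducible end to end.

## Problem sizes

The test suite runs the consensus pipeline on 300–500 kb chromosomes
(3,000–5,000 probes) and the acceptance script on two 1-Mb chromosomes
(20,000 probes, 3 replicates, 17 cutoff levels × 20 permutations); the
vectorized detector makes both run in seconds. Oracle-equivalence checks
use exhaustive brute-force enumerations on tracks of up to 500 probes,
peak sets of 60 per mark, and 150–200 reads.

## Known limitations

- No probe-level normalization, dye-bias or GC correction: input tracks
  are assumed already ratio-normalized.
- The null scrambles ratios i.i.d., so probe-autocorrelated noise would
  make the FPR anti-conservative; with ~100-bp spacing and 300–600 bp
  chromatin fragments neighbouring probes are not fully independent on
  real arrays.
- The colocalizer's greedy matching is order-independent but not globally
  optimal (it is, however, the standard nearest-first heuristic and is
  oracle-tested for the one-to-one property).
- Genotype classification assumes control centroids are representative;
  no per-cluster covariance is modelled.
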