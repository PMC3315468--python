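# Methods

## The model

`azanome` implements the analytic chain that links passive, replication-driven
DNA demethylation to nucleosome remodeling and gene reactivation, at two
scales: single molecules (amplicon bisulfite clones) and arrays
(promoter beta values, expression matrices).

### Semiconservative demethylation

A cytidine-analog DNMT inhibitor is incorporated into replicating DNA and
traps the maintenance methyltransferase, so methylation is lost passively
through division.  The simulator represents each DNA duplex by per-CpG
boolean methylation flags on the top and bottom strands.  A division
replaces a duplex by two daughters, each keeping one parental strand; the
newly synthesised strand is

* unmethylated at every CpG with probability `incorporation_prob` while the
  drug is present (a division at time ≤ `washout_day`), and otherwise
* a maintenance copy of the parental strand, optionally with per-site
  de novo remethylation at `remethylation_prob` (post-washout only).

The population is held at `n_molecules` by uniform subsampling after each
division (a well-mixed population with no cell-cycle structure; divisions
occur at times `i / divisions_per_day`).  Two consequences anchor the tests:
starting fully methylated (F), one inhibited division makes every duplex
hemimethylated (H), and after `k` fully inhibited divisions the expected
class fractions are `H = 2^(1-k)`, `F = 0`, `U = 1 − 2^(1-k)` — verified
against an exact enumeration oracle.  Because daughters are deterministic
under full inhibition, the only stochasticity is the subsampling bottleneck,
whose variance is below the plain binomial bound used in the tests.

De novo remethylation applies to newly synthesised strands only; retained
unmethylated parental strands persist, so certain remethylation converts the
hemi fraction back to F at rate one-half per division rather than instantly.
This is the standard maintenance-at-the-fork picture; the simulator does not
model fork-independent remethylation.  Published kinetics for post-washout
remethylation are qualitative, so the default (`remethylation_prob = 0`,
consistent with methylation levels staying flat after the initial drop) is
illustrative, not fitted.

### Remodeling conditional on symmetric demethylation

Nucleosome depletion is modeled as an all-or-none promoter event that can
only happen on duplexes unmethylated on **both** strands at every CpG inside
the promoter window: such a duplex acquires an occupancy gap covering the
window with probability `p_ndr`, multiplied by `srcap_kd_factor` when the
remodeler-knockdown flag is set (H2A.Z deposition by the SRCAP complex is
represented only by this attenuation factor).  All other molecules are tiled
with 147-bp nucleosome cores separated by a `linker_bp` (default 50 bp)
linker at a uniformly random phase — occupancy, not phasing, is the modeled
quantity, so the phase is a nuisance variable.  Cores overlapping the gap
are dropped whole, keeping every core either full-width or truncated only at
a region edge.

### The NOMe readout

The GpC methyltransferase (M.CviPI) marks accessible DNA: each GCH site not
covered by a nucleosome core is methylated independently per strand with
probability `mcvipi_efficiency`; covered sites are never marked.  Bisulfite
conversion then turns unmethylated cytosines into thymines with probability
`conversion_rate` and (erroneously) methylated ones with probability
`inappropriate_conversion`.  Bottom strands are emitted as their PCR
top-strand image (conversion appears as G→A in reference coordinates), which
is how amplicon bisulfite alignments are normally inspected.

Site annotation partitions every CpG/GpC cytosine on the top strand into
HCG (endogenous methylation readout), GCH (accessibility readout) and
excluded GCG contexts, where the two signals cannot be distinguished.  Sites
whose flanking context is truncated by the region edge are also excluded.
The same annotation serves both strands: for a CpG at top position `p` the
bottom-strand readout base is `p+1`; for a GpC cytosine at `p` it is `p-1`.
Strand-specific H-contexts differ in principle between strands; using the
top-strand classification for both is a deliberate simplification, applied
consistently by the generator and the caller, so round-trips are exact.

Conversion QC uses strand cytosines outside all three contexts (the
synthetic amplicon carries one such cytosine per strand per 10-bp tile);
clones below `qc_min_conversion` (default 0.95) are excluded from all
statistics and counted in logs.

### Footprints and NDR calls

A clone's GCH calls collapse into maximal runs of same-state sites; missing
calls neither break runs nor contribute sites.  Segments are half-open bp
intervals: the outermost informative sites bound the span (no extrapolation
past them, with a +2 bp allowance covering the final GpC dinucleotide), and
interior boundaries between opposite-state neighbours sit at their midpoint
— the published diagrams draw continuous blocks without stating a rule, and
the midpoint is the symmetric choice.  Segment width is the segment's span;
for a terminal run this equals `last − first + 2`.  A clone carries an NDR
when an accessible segment spans **more than 146 bp** (strictly, one
nucleosome core; exposed as `min_span_bp`) and overlaps the promoter window
(default `[tss−100, tss+100)`; the 250-bp −1-nucleosome window is supplied
per region).  Population fractions come with exact Clopper–Pearson 95%
intervals.

`window_depletion_fraction` asks a stricter question — is the whole window
nucleosome-free? — requiring every informative in-window GCH call accessible
and no long protected run (site extent) intruding into the window.  With
incomplete enzyme efficiency the naive estimate is biased downward by
roughly `efficiency^m` for `m` in-window sites on a strand; the defaults
(efficiency 0.99, conversion 0.995) keep this bias small but nonzero, and it
is visible in the synthetic recovery tests.

### Hpa II hemimethylation deconvolution

Hpa II cuts CCGG only when the internal CpG is unmethylated on both strands.
With `m0` the methylated-strand fraction at that CpG before digestion and
`m1` after, and PCR reading both strands of surviving duplexes:

    m0 = F + H/2
    m1 = (F + H/2) / (F + H)

giving the closed-form inversion `H = 2·m0·(1/m1 − 1)`, `F = m0·(2 − 1/m1)`,
`U = 1 − H − F`.  The cited original equations are not printed in the
source literature, so the model is re-derived here from the digestion
chemistry; the forward model is shipped so the inversion can be verified
(it is the exact identity on the U/H/F simplex whenever `H + F > 0`, and
`m1 ≥ 1/2` holds automatically because every survivor carries at least one
methylated strand).  Feasibility checks reject `m1 < 1/2` or `m0 > m1`
beyond a 1e-6 tolerance; sub-tolerance violations are clamped and the
residual reported.  Digestion is modeled as complete ("excess" enzyme); a
`digestion_efficiency < 1` escape parameter exists for sensitivity analysis.
With several CCGG sites, destruction requires at least one fully
unmethylated site; deconvolution itself applies to a single designated site.

Combining digestion with demethylation-selective PCR (primers over CpGs that
must read unmethylated) isolates demethylated strands from hemimethylated
duplexes: symmetrically demethylated duplexes are destroyed, and fully
methylated survivors fail the primer filter.  On the default configuration
these selected strands show essentially zero window depletion — they were
generated occupied — reproducing the core single-molecule claim that only
symmetric demethylation licenses nucleosome loss.

### Array-scale statistics

Promoter methylation is a per-probe beta value in [0, 1].  Control samples
draw from a bimodal mixture (Beta(2, 20) / Beta(20, 2), equal weights)
concentrated below 0.2 and above 0.8; planted demethylated genes have all
their probes start above 0.8 and drop by 0.30–0.70 under treatment in both
siRNA conditions (knockdown barely affects methylation).  A probe is called
demethylated when its control beta exceeds 0.8 **and** the control-minus-
treated difference is at least 0.25 (`≥`, configurable — the published
threshold does not state strictness); genes collapse by "any probe
selected".

Differential expression uses the SAM two-class statistic
`d = (mean₂ − mean₁) / (s + s0)`, with `s` the pooled standard error and the
exchangeability offset `s0` chosen among the 0–100% quantiles (step 5%) of
`s` to minimise the coefficient of variation of the windowed MAD of `d`
across ~100 `s`-quantile windows.  The null comes from label permutations —
all distinct assignments when `C(n, n1) ≤ n_perm` (70 for a 4-vs-4 design),
otherwise `n_perm` seeded random draws.  FDR at the symmetric cut
`|d| ≥ t` is `pi0 · median_perms(#{|d*| ≥ t}) / #{|d| ≥ t}`, with `pi0`
estimated from the fraction of observed scores inside the permuted-score
interquartile range; q-values take the minimum FDR over all cuts containing
the transcript and are therefore monotone in `|d|`.  On pure-null matrices
the procedure is conservative (mean significant counts far below
`q · m`), and 4-SD planted effects are recovered essentially without
contamination.

The knockdown comparison takes the genes both demethylated and
significantly upregulated, computes per-gene log2 fold changes
(treated minus control means, transcripts averaged within genes) in each
siRNA condition, and applies a paired two-sided Wilcoxon signed-rank test to
the NC-minus-KD differences (the published analysis does not name its test;
the signed-rank test is the robust default, and a paired t-test on the same
table is trivial to run from the emitted per-gene output).  Box-plot
quartiles for both vectors and the per-gene table are emitted.
One-dimensional hierarchical clustering of the demethylated probes uses
Euclidean distance with average linkage (unspecified in the source figure;
both configurable), row-mean imputation for missing values in the distance
computation only, and deterministic leaf order.

Gene-set overlap between conditions is reported with an explicit
denominator convention; the default denominator is the control-siRNA
significant set, flagged as configurable because the published "81% overlap"
does not state its convention (nor whether it counts genes or transcripts).

## Default parameters

| parameter | default | meaning |
| --- | --- | --- |
| `n_molecules` | 500 | population size held by subsampling |
| `days` | 0, 1, 2, 3, 5 | sampling days |
| `divisions_per_day` | 1.0 | doubling rate of the line |
| `incorporation_prob` | 0.9 | P(inhibited synthesis) per strand, drug era |
| `washout_day` | 2 | last drug-affected day |
| `remethylation_prob` | 0.0 | post-washout de novo rate per site |
| `p_ndr` | 0.4 | P(NDR) for symmetrically demethylated promoters |
| `srcap_kd_factor` | 0.5 | multiplies `p_ndr` under knockdown |
| `conversion_rate` | 0.995 | bisulfite conversion of unmethylated C |
| `inappropriate_conversion` | 0.002 | conversion of methylated C |
| `mcvipi_efficiency` | 0.99 | GpC methylation of accessible sites |
| `linker_bp` | 50 | inter-nucleosome linker in tiling |

`p_ndr` and `srcap_kd_factor` are population effect sizes chosen to mirror
the observed depletion fractions (tens of percent, roughly halved under
knockdown); the time-course parameters sketch a 24-h pulse in a line
doubling daily.  None are fitted: the generator defines study conditions for
testing the analysis chain, not a calibrated kinetic model.

Array defaults: 5,000 probes over 2,500 genes (two probes per gene,
mirroring the ~1.9 probes/gene density of the 27k promoter platform),
250 planted demethylated genes of which 44 are also reactivated with a
+2.0 log2 effect, expression noise SD 0.5, beta noise SD 0.01, four
replicates per condition.  These sizes keep the full chain under a few
seconds while leaving every statistic well-powered.

## What the generator does not emulate

Real data complications deliberately out of scope: sequence-dependent
nucleosome positioning and partial/fuzzy occupancy; cell-cycle structure,
drug cytotoxicity and DNMT isoform differences; PCR and cloning bias among
molecules; Sanger base-calling errors and indels; array normalisation
artefacts, probe cross-hybridisation and batch effects; transcript-level
expression heterogeneity beyond a planted 1–2 transcripts per gene.  Passing
tests therefore certify the correctness of the analysis chain under the
stated model, not robustness to these real-data effects.

## Numerical and design choices

* Coordinates are 0-based, half-open, on the reference top strand
  throughout; a site's position is its cytosine's top-strand index.
* Strand inference compares mismatch counts under both conversion images,
  breaks ties toward "top" with a warning, and rejects reads over 10%
  mismatch under both models (a random sequence sits near 75%).
* Duplicate clones (identical call strings) are retained — amplicon cloning
  legitimately resamples molecules; deduplication would bias fractions.
* `FractionStat` intervals are exact (Clopper–Pearson) rather than normal
  approximations: clone counts are small (k = 1 of 25 is a real case).
* Simulation RNG streams are derived from `(seed, stage-salt)` seed
  sequences so stages are independently reproducible; every output file
  records the seed in its header.
* Degenerate inputs: empty CpG lists, windows outside the region, all-
  missing clones, empty denominators and all-zero paired differences are
  rejected or flagged rather than silently handled.

## Problem sizes

Default test and acceptance runs use 500–10,000 molecules, up to 600 clones
per pool, 2,000–5,000 probes/transcripts, 70 distinct permutations for the
4-vs-4 design, and 20 repeated seeds for null calibration — sizes chosen so
every statistic is comfortably powered while the complete suite runs in
seconds.
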