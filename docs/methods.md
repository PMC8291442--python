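# Methods

## Data model and conventions

All coordinates are 0-based half-open internally; the cytosine-report
dialect (1-based on disk) is converted at the I/O boundary and restored
exactly on write. The per-site methylation level is ML = n_meth/n_total.
Symmetric CpG dyads (+ strand at p, − strand at p+1) are pooled by
default before analysis — this is common practice and roughly doubles
effective coverage — and can be disabled; pooling conserves read counts
exactly. The default coverage filter for per-site statistics is
n_total ≥ 5, configurable everywhere it applies. Promoters default to
[TSS−1000, TSS+500) on the + strand and the numerically mirrored window
on the − strand, clipped at zero; both span parameters are configuration
values, since no single promoter definition is canonical.

## Global statistics

Global ML defaults to the unweighted mean of per-site MLs over retained
sites (the *site mean*); the pooled count-weighted ratio is always
reported alongside, and the two coincide exactly under uniform coverage.
The bisulfite conversion rate is estimated from a designated
truly-unmethylated control (a spike-in-like contig in the simulations)
as pooled unconverted reads over total reads; its complement, the
non-conversion rate, is subtracted from the raw mean CHG/CHH level to
give the corrected non-CpG ML, floored at zero (the correction is
monotone in the conversion rate and can never go negative). Bimodality
is summarized as the fraction of sites with ML ≤ 0.2 plus the fraction
with ML ≥ 0.8, over a histogram with 0.1-wide bins — conventional
cutoffs matching the all-or-nothing character of animal CpG methylation.
Density–methylation and replicate correlations use Pearson's r (the
field's usual choice for these comparisons) over non-overlapping
windows/bins; degenerate (constant) inputs return NaN with a warning
rather than an error.

## TSS metaprofiles

Profiles average over (gene, site) pairs rather than per-gene-then-bin:
with sparse mosaic methylomes many genes contribute a handful of CpGs,
and gene-first averaging would give those few sites outsized weight. The
strand-oriented offset of a site at p from a TSS at t is p − t (+ strand)
or t − p (− strand); bin k covers [−flank + k·bin, −flank + (k+1)·bin),
with flank 6000 bp and bin 100 bp by default (120 bins). A consequence
used as a test invariant: flipping every gene's strand while keeping the
TSS fixed mirrors the profile bin-for-bin, except for sites falling
exactly on bin boundaries.

## Domain segmentation

Mosaic methylomes are segmented by smoothed thresholding rather than an
HMM or change-point model: per-site MLs are smoothed with a centered
running mean over 5 CpGs (windows truncate at chromosome ends), sites
are called methylated at smoothed ML ≥ 0.5, maximal constant-state runs
become domains, and runs shorter than 5 CpGs are merged into the longer
flanking run (ties to the preceding run). The method is deterministic,
has three interpretable parameters, and is adequate because the data are
strongly bimodal; it is not a general segmentation method for
intermediate methylation. Each domain's final state is re-derived from
its mean raw ML, so the state label always agrees with the reported
mean, and the CpG-weighted mean of domain MLs reproduces the global
site-mean exactly. Chromosomes with fewer covered CpGs than the
smoothing window are emitted as a single domain with a warning.

## DMP calling and dynamics classification

Differential promoter methylation between two samples (typically sperm
vs oocyte) pools methylated/unmethylated read counts across each
promoter's covered CpGs (≥ 3 covered CpGs required in both samples) into
one 2×2 table, tested with a two-sided Fisher exact test and
Benjamini–Hochberg adjusted across tested promoters; calls additionally
require a pooled-level difference |Δ| ≥ 0.2. This deterministic
no-replicate design matches the two-condition WGBS setting; a per-CpG
test with aggregation was deliberately not used because the promoter is
the analysis unit here. The caller is symmetric: swapping samples
negates Δ and swaps hyper/hypo with identical p-values.

Stage dynamics are classified from the maximum pairwise difference D of
per-stage global MLs: none (D < 0.02), minor (< 0.05), moderate
(< 0.15), else dramatic. These thresholds operationalize qualitative
labels and are configuration values; the tests require only that the
calibrated preset trajectories map onto the expected labels. The
genome-wide demethylation flag fires when any non-gamete stage falls
below 0.5× the sperm/oocyte mean. Gametes are recognized by stage name
("sperm"/"oocyte", case-insensitive).

## Gene-set analysis

Gene-set methylation reports per-gene promoter ML and genic ML, the
latter over the gene span *excluding* the promoter window so promoter
hypomethylation cannot dilute gene-body contrasts. The paired promoter
test is a two-sided Wilcoxon signed-rank with zero differences dropped
(the classic convention — visible with small gene sets, hence explicit):
the null distribution is exact (subset-sum over all 2^n sign
assignments, average ranks doubled to integers under ties) for n ≤ 25
and a normal approximation with continuity and tie correction above.
Methylation–expression association uses Spearman's rho between promoter
ML and log2(FPKM+1), with a 2×2 contingency summary at FPKM ≥ 1
("expressed") and ML ≥ 0.5 ("methylated"); both cutoffs configurable.

## Synthetic methylome generator

The generator is first-class, tested code: it defines the study
conditions under which every recovery claim is checked.

**Landscape.** CpG positions get geometric inter-CpG spacing; CpG-island
(CGI) clusters are dense runs (10 bp spacing, ~50 CpGs per island)
covering a preset fraction of CpGs. Contiguous "units" — geometric runs
with mean 10 CpGs for background, one unit per island — are the atoms of
truth assignment. Real inter-domain length distributions are unknown;
the geometric choice is a modeling convenience that yields mosaic tracks
at small scale, flagged as such.

**Truth.** Mosaic presets methylate a random set of units accumulated
until the methylated-CpG fraction reaches p_dom (a quota construction:
p_dom is *defined* as the fraction of CpGs inside methylated domains, so
the realized fraction matches to within one run, and the closed-form
expectation p_dom·domain_ml + (1−p_dom)·background_ml holds tightly per
seed). Global presets methylate everything at domain_ml except islands
at cgi_ml. The oocyte truth switches the state of units covering the
gamete-asymmetry fraction of CpGs, split between hypo- and
hyper-methylating switches. Embryo stages follow the preset trajectory:
stable inheritance of the paternal pattern; maternal remodeling to the
paternal pattern by the MBT-like stage; or demethylation of the first
post-gamete stage to 0.3× the per-site gamete mean with later stages
restored to the gamete mean.

**Designed annotation.** Each dataset carries genes laid out in slots
across the genome (half on each strand), with a HOX-like cluster
(single 12-gene cluster for invertebrate presets; four clusters of
11/10/9/9 genes for vertebrate presets), 20 non-HOX homeobox genes
(levels drawn from {0.01·.., 0.5, 0.9} with weights 0.7/0.15/0.15,
static across stages), 20 signaling genes (unmethylated, static), and
regular genes. HOX truth per preset: invertebrates 0.01 at all stages;
fish-style sperm 0.03 / oocyte 0.85 / post-MBT 0.03; mammal-style
gametes per-gene uniform on (0.2, 0.8), ICM/embryo 0.03, placenta
per-gene uniform on (0.15, 0.7), with homeobox promoters at 0.45 in
placenta. Promoters of non-designed genes have the oocyte truth copied
from sperm so the only sperm–oocyte promoter differences are the
designed DMPs (0.90 vs 0.05, alternating direction). In vertebrate-style
presets 70% of regular-gene TSSs (and all HOX TSSs) sit on islands,
reproducing CGI-promoter hypomethylation and the high-density promoter
class.

**Counts.** Coverage is negative-binomial (mean 30, dispersion 5);
the observed per-read methylation probability is m(1−g) + (1−m)f with
non-conversion f (default 0.0074, matching a 99.26% conversion rate;
zero for the bee- and chicken-style presets, which are calibrated
without it) and over-conversion g (default 0.001). An unmethylated
control contig (m = 0 everywhere, default 10,000 sites) supports
conversion-rate estimation. All randomness derives from the spec seed
via named substreams; counts for replicate r of a stage come from a
per-(stage, replicate) stream over the shared truth, so replicates
differ only by sampling noise — which is what makes the
replicate-correlation bound (r ≥ 0.95 at 1 kb bins) a pure
sampling-noise statement.

**Preset calibration** (all overridable): anemone-style p_dom 0.115,
domain 0.92, background 0.005 (→ ≈0.11); bee-style 0.008/0.85/0.003
(→ ≈0.01); deuterostome-style 0.29/0.92/0.005 (→ ≈0.27); chicken-style
0.45/0.92/0.01 (→ ≈0.42); fish/mammal-style 90% of CpGs at 0.88 and 10%
CGI CpGs at 0.03 (→ ≈0.795). Gamete asymmetry 0 / 0 / 0.08 / 0.05 /
0.15 / 0.20 with hypo fractions chosen so the deuterostome gamete gap is
~0.03, the fish-style gap ~0.06 and the mammal-style gap ~0.10, giving a
strictly increasing divergence series and the expected dynamics labels.

**What the generator does not emulate.** No read-level simulation or
sequence composition beyond CpG spacing; no partially methylated
intermediate states outside the designed levels; no copy-number or
mappability artifacts; unit-level (not bp-level) domain boundaries.
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated statistical model, not robustness to every
artifact of real WGBS libraries.

## Problem sizes and determinism

Default simulations use 50,000 CpG dyads over a 5 Mb two-chromosome
genome — small enough for the full test suite to run in well under a
minute of compute per scenario while keeping standard errors on global
ML below ~0.002. The DMP-recovery scenario uses 1,000 regular genes with
200 designed DMPs. Fixed seeds make every generated table
bit-reproducible; the pipeline writes byte-identical summaries on
re-run with the same config.

## Known limitations

The Fisher+BH+Δ DMP definition is a documented stand-in for whatever a
particular study used; it is exposed as configuration. Dynamics-class
thresholds are an operationalization of qualitative labels. The
conversion-rate estimator assumes the control is truly unmethylated; if
only CHH sites are available, using them requires an explicit
assumed-unmethylated decision by the caller. GFF3 reading considers
`gene` features only.
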