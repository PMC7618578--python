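# Methods

`mccu` implements the computational side of base-pair-resolution MNase-based
chromosome conformation capture (Micro Capture-C ultra, MCCu): calling
ligation junctions at single-base precision from chimeric sonicated reads,
building contact matrices down to 1-bp pixels, reconstructing the
protein-protected sequences behind junction signal, and testing contact
matrices for differences between conditions. Because real libraries are
large and deposited externally, the package ships a ground-truthed simulator
that reproduces the physical structure of such libraries at desk scale;
every downstream component is validated against the simulator's exact truth
records.

All coordinates are 0-based, half-open (BED convention). A *cut* at
position c separates bases c−1 and c; a junction is recorded as the two
cut-adjacent bases — the last base of the upstream fragment and the first
base of the downstream fragment.

## The synthetic library generator

The generator mimics the steps of an MNase-3C protocol:

1. **Chromatin template.** A random-sequence reference is tiled with
   nucleosomes at a fixed repeat length (NRL, default 190 bp; 147-bp cores)
   over all sequence outside user-specified nucleosome-depleted regions
   (NDRs). Transcription-factor footprints and CTCF sites are annotated
   intervals. With `phase_mode="random"`, one global phase offset is
   redrawn per molecule (discretised to 32 offsets per repeat): individual
   nucleosome positions vary while spacing stays fixed, the configuration
   that produces ladder-like inter-junction periodicity at inactive loci.
2. **MNase digestion.** Per-bp cut weight is 0 inside nucleosome cores and
   TF footprints, 1 in linkers and NDR interiors, and 4 in the 5 bp
   flanking each footprint edge (nuclease attack is concentrated at
   protein-boundary DNA). Flank width and weight are module constants.
3. **Proximity ligation.** Junction cut pairs (a, b) are drawn with
   probability ∝ w(a)·w(b)·F(a,b)·(1+|a−b|)^(−γ). The enrichment F
   multiplies: a within-domain factor (domains bounded by NDR centres,
   default 3 — nanoscale-domain self-association), an NDR×NDR factor
   (default 10 — punctate contacts between depleted regions), a CTCF×CTCF
   factor (default 10), a TF-flank×TF-flank factor (default 1; raise it to
   simulate footprint-mediated motif contacts), and a linker×linker factor
   (default 1). γ defaults to 1.0, the canonical contact-frequency decay.
   Defaults are round magnitudes chosen to make the qualitative structures
   (domains, punctate NDR contacts, CTCF loops) clearly visible at
   10³–10⁴ events on a 10-kb fixture; they are not fitted to data.
4. **Fragment geometry.** Each ligated fragment runs from its junction cut
   to a second cut site snapped to the nearest candidate position around a
   Normal(250, 80) bp target (bounded [80, 500], ≥40 bp from the
   junction). A cut in a footprint flank extends *across* the footprint
   (the protein-bound, protected fragment) with probability 0.9 — this is
   what concentrates junction quartets at the corners around a
   protein-mediated contact. With probability 0.1 a third fragment is
   ligated at the second fragment's far cut (3-way products).
5. **Sonication and sequencing.** Molecules are broken at uniform positions
   into fragments with lengths Normal(200, 40) truncated to [100, 320] bp
   and sequenced as 150-bp read pairs (R2 reverse-complemented), with
   optional uniform substitution errors (≤10%) and optional PCR
   re-emission. A truth table links every read pair to the exact junction
   coordinates it carries; a junction left with fewer than 20 bp on either
   side of a sonication break is flagged *destroyed* (unrecoverable by
   sub-read mapping) and excluded from recall denominators.

**Canonical junction coordinates.** On random sequence, ~25% of junctions
have micro-homology: the downstream fragment begins with bases identical to
the upstream fragment's genomic continuation, so the breakpoint is only
defined up to that homology. Both the truth records and the sub-read
splitter resolve the ambiguity the same way — ambiguous bases belong to the
upstream fragment (the junction is shifted maximally rightward in read
orientation). Without a shared canonical form, base-exact agreement between
caller and truth would be capped near 75% for reasons unrelated to the
caller.

What the generator does **not** emulate: realistic base composition or
mappability structure (the reference is i.i.d. random, so 20-mers are
unique), trans contacts, chimeric PCR artifacts, ligation biases beyond the
pair-factor model, and biological replicate-to-replicate variability in
contact structure. Passing tests therefore demonstrate the correctness of
the *computation* under the stated generative model, not performance on
real libraries, where mappability and overdispersion will reduce precision
and power.

## Read reconstruction and sub-read splitting

Pairs are merged FLASH-style: best suffix(R1)/prefix(revcomp R2) overlap
with ≥10 bp and ≤25% mismatches, disagreements resolved to the
higher-quality base. With 200±40 bp fragments and 150-bp reads, ~99% of
pairs merge (pairs from fragments >290 bp cannot).

A capture pre-filter retains any read sharing an exact 20-mer (either
strand) with the capture region ±800 bp — a superset of truly overlapping
reads on error-free data.

Sub-read splitting uses a seeded exact-match mapper over the single-contig
reference (20-mer hash index over both strands): greedy left-to-right
chaining of maximal extensions, allowing ≤2 substitutions each followed by
≥4 matching bases (extensions always end on a match, so junction
breakpoints are never absorbed by the mismatch budget). Segments shorter
than 20 bp are discarded. Externally aligned sub-reads can be ingested from
SAM instead. Indel-containing alignments are out of scope.

## Junction calling

Each adjacent sub-read pair of a read yields one junction (3-way products
give two junctions; non-adjacent pairs are not emitted). The direction flag
of each end records which side of the cut the sequenced fragment — and the
protein footprint protecting it — lies on: `U` (toward upstream/lower
coordinates) or `D`. Junctions are canonically sorted (pos_a ≤ pos_b, flags
swapped together). PCR deduplication collapses on (positions, directions,
sonication fragment ends): two molecules ligated in opposite orientation at
the same coordinates, or fragments differing by a single sonication base,
remain distinct events. The short/long-range split defaults to 1 kb.

On error-free 10,000-molecule libraries the pipeline recovers ≥96% of
recoverable truth junctions with ≥98% base-exact precision.

## Contact matrices and normalization

Square matrices at pixel size p count junction (a, b) at pixel
(⌊(a−start)/p⌋, ⌊(b−start)/p⌋) and its transpose (diagonal counted once),
so the upper-triangle-plus-diagonal sum equals the number of in-region
junctions. A 5-kb region at 1-bp pixels is 5,000 single-bp viewpoint
profiles. Extended maps bin the partner end into coarse genome-wide columns
(default 500 bp) — a hybrid between a viewpoint profile and an all-vs-all
map. Aggregating a fine matrix into k×k blocks reproduces the coarse build
exactly (diagonal blocks are corrected for the mirrored off-diagonal pairs
they absorb).

*ICE balancing*: iterative row-sum correction to tolerance 1e-5 (max 200
sweeps), masking rows below the 0.02 coverage quantile; the returned bias
vector satisfies raw = bᵢbⱼ·balanced. *Cis normalization* scales each
viewpoint row to counts per 1e5 cis-unique junctions of that viewpoint
(capture-efficiency correction); *tiled* mode then symmetrizes by averaging
with the transpose. Rows with zero cis total are masked, never divided.

*Periodicity*: the inter-junction distance histogram (1-bp bins over
50–1000 bp) is smoothed with an 11-bp centered moving average — wide enough
to suppress single-base cut-bias spikes, symmetric so the maximum is not
shifted — and the dominant period is the largest local maximum beyond
100 bp. Regularly spaced chromatin with NRL 185 yields a dominant period in
the 180–190 bp band.

## Contact sequence reconstruction

A protein-mediated contact produces elevated junction counts at the four
corners around the contact point, because MNase cannot cut under the bound
proteins. Junctions are first binned into four directional channels indexed
by (dir_a, dir_b). Each channel is then smeared along each axis over a
window of `footprint` pixels (default 20, a typical TF footprint) extending
from the cut toward the protected side — `U` leftward, `D` rightward — and
the four channels are summed. A uniform window is the default; a triangular
kernel (weight decreasing from the cut) is available, since the true
intra-footprint contact geometry is unknown. Total signal is conserved
except at region edges. Corner quartets collapse onto the footprint pair;
with uninformative (random) direction flags the operation degrades
gracefully to a symmetric blur of the raw matrix.

## Differential testing of base-pair matrices

Per-pixel counts at 1-bp resolution are tiny and dominated by MNase
cut-site bias, so inference is performed on segmented blocks:

1. **Preprocessing.** Pixels whose maximum over all replicates is below 2
   are masked; values above the 0.999 quantile of pooled nonzero counts are
   winsorized; each replicate is scaled to the median replicate total; each
   pixel (i, j) is divided by cᵢ·cⱼ where c is the MNase cut propensity
   (supplied as a profile, or estimated from the pooled matrix margins,
   floored at 0.05 after mean-normalization); the grand total is restored.
2. **Segmentation.** Crossed 1D changepoint detection on the row- and
   column-margin profiles of the condition-difference grid: binary
   segmentation with squared-error cost and penalty 2σ̂²·log n per split
   (σ̂ from the MAD of first differences, which is robust to the
   piecewise-constant signal itself), minimum segment 10 pixels, at most 50
   changepoints per axis. Blocks are the cross product and tile the matrix.
3. **Refinement.** Block means are soft-thresholded against
   `lasso_penalty` × the median between-replicate standard error; blocks
   shrunk to zero are dropped as low-count. Inside high-count blocks (top
   decile of totals) a tensor-product cubic B-spline surface (default 6
   basis functions per axis) is fitted to the 98th-percentile-winsorized
   log1p pooled counts; replicate pixel values are capped at 3× the smooth
   before testing, damping isolated spikes.
4. **Testing.** Per retained block, replicate count sums are modelled as
   zero-inflated negative binomial with identity-link mean
   μ = β₀ + β₁·condition, NB2 dispersion α, and a condition-independent
   structural-zero probability π (a single π keeps the model identifiable
   at ~6 replicates). The likelihood clamps μ at 1e-8 and flags boundary
   fits. π estimates at the 1e-4 boundary trigger a plain-NB refit.
   Because per-block estimation of (α, π) from ~12 observations makes Wald
   standard errors unstable, the nuisance parameters are *moderated*: after
   a per-block full ML pass, the across-block medians of log α and logit π
   are held fixed in a second-pass two-parameter fit, and the Wald statistic
   for β₁ uses a t reference with n−2 degrees of freedom (with fewer than 8
   blocks the per-block full fit is used with df = n − n_params). This is
   the same information-sharing rationale as dispersion moderation in
   standard RNA-seq count models. Benjamini–Hochberg q-values are computed
   across retained, converged blocks; non-converged fits are flagged and
   excluded from the FDR denominator.

Under a null simulation (both conditions ZINB with μ=20, size=5, π=0.2, 6+6
replicates, 200 blocks) the empirical type-I error at p<0.05 is ≈0.03. The
effect estimate recovers an injected 2-fold difference with bias well below
10%. Power at a 2-fold shift from μ=50 under that same dispersion is
~0.5–0.6 per block: the Fisher information of 6+6 ZINB observations bounds
the standard error of β̂₁ near 23 even with known nuisance parameters, so no
composite test does materially better at these simulation settings; more
replicates or milder dispersion are needed for high per-block power.

## Viewpoint peak comparison

Peaks come from a deterministic local-enrichment caller (contiguous runs
above a rolling-median × enrichment-factor threshold; default factor 3,
window 2001 bp) or from an external BED; both pass the same width
[min, max] and minimum-distance-from-viewpoint filters, which are required
parameters. Per replicate, peak junction counts are scaled to per-1e5
cis-unique junctions of the viewpoint; conditions are compared by Welch's
t-test (the unequal-variance form of the t-test, chosen because replicate
variances are not known to be equal) with BH correction. A peak is
*significantly skewed* when q < 0.05 and |log₂ fold change| > 1.5. Skew is
log₂((mean_treated + 0.5)/(mean_control + 0.5)) in normalized units; the
0.5 pseudocount bounds the statistic for empty peaks. Annotation
enrichment is log₂ of the ratio of intersection fractions (≥1 bp overlap)
between significant and non-significant peaks, with a Haldane (+0.5)
correction when a fraction is 0 or 1.

The power property in the test suite (4-fold drop in 20 of 200 peaks,
3+3 replicates) simulates Poisson counting noise only; with biological
overdispersion above ~10% CV a 3-replicate t-test cannot reach the BH
threshold, so real-data power is expectedly lower.

## Capture design

Targets are tiled with 120-bp oligos at 50% overlap (step = round(length ×
(1 − overlap))); a final right-anchored oligo is added when the regular
tiling leaves more than half a step uncovered at the region end.

## Problem sizes and determinism

The bundled validation workloads use fixtures of 3–20 kb, libraries of
10⁴ molecules (junction fidelity), 5×10⁴ ligation events (periodicity and
NDR-enrichment properties), 20 random geometries (reconstruction
localization), and 100–500 simulated blocks (calibration, power, bias) —
sizes at which every property is measurable with comfortable statistical
margins on a single CPU. All randomness flows through seeded
`numpy.random.Generator` instances; rendering uses a separate error-stream
generator so fragmentation is invariant to the error rate, and the full
pipeline is byte-reproducible for a fixed seed.

## Known limitations

Single-contig references only (the seeded mapper and matrix builders assume
one chromosome; multi-contig support requires only index bookkeeping).
No gapped (indel) alignment inside sub-reads. Trans junctions are labelled
but otherwise passed through. The tiled-cis symmetrization and the
directional-window reconstruction are documented interpretations of
procedures whose exact published form is not fully specified; both are
parameterized so alternative conventions can be swapped in.
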