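# Methods

This note documents the models, conventions and numerical choices behind
`epicpipe`, and what the synthetic-data tests do and do not establish about
real array data.

## Coordinates and overlap semantics

All internal coordinates are 0-based, half-open; each reader converts at
the boundary (Illumina MAPINFO and GFF/GTF are 1-based inclusive, BED is
0-based half-open). A probe's target cytosine is modelled as a 1-bp point;
every overlap in the package is a point-in-interval test, so two intervals
that merely touch (`end == start`) never overlap. Chromosome names are
normalized to the `chr`-prefixed dialect. Sex chromosomes are `{chrX, chrY}`.

## Super-regions and the five-category annotation

chromHMM states 1–3 map to Promoter, 4–7 to Enhancer; the remaining eight
states are ignored. Within one cell line, consecutive same-kind segments
with zero gap are fused into maximal super-regions. An intervening ignored
state occupies coordinates and therefore breaks fusion — "consecutive"
means contiguous in the genome, the conservative reading. Region ids are
deterministic (`cellline:kind:chrom:start`).

A probe inside ≥ 1 Promoter super-region and no Enhancer super-region
(across all cell lines) is `Promoter`; the symmetric case is `Enhancer`;
both kinds somewhere means `Dual`; otherwise a probe inside any transcript
span `[min(TSS,TTS), max(TSS,TTS)]` is `GeneBody` (the full span is used
regardless of the probe's orientation relative to the transcript), and the
remainder is `Intergenic`. The Promoter/NonPromoter collapse groups
`{Promoter, Dual}` vs `{Enhancer, GeneBody, Intergenic}`.

Transcript association: every transcript whose TSS lies in a Promoter
super-region is attached to that region, and every probe in the region
inherits the transcript (the per-probe list is the deduplicated union over
cell lines). A *lncRNA* TSS inside an Enhancer super-region defines an
eRNA; coding or other-noncoding TSSs in enhancers yield no association.
EnhancerAtlas rows attach target transcripts to Enhancer super-regions by
positive interval overlap in the same cell line; enhancer probes whose
regions have no atlas overlap carry the explicit `unknown` target marker.
Enhancer-target inheritance applies to Enhancer super-regions only (not to
the promoter side of Dual loci), since targets are a property of the
enhancer call.

CGI context: islands are merged first; `Island` takes precedence, then
`Shore` (± 2 kb flanks, clipped at position 0), then `OpenSea`. An empty
island set degrades gracefully to `OpenSea` everywhere.

The Illumina-default collapse maps gene-group terms
{TSS1500, TSS200, 1stExon, 5'UTR} → Promoter and {Body, 3'UTR} → GeneBody;
any non-empty FANTOM4/FANTOM5/450k enhancer column marks the probe
Enhancer, upgraded to Dual when it is also Promoter; unrecognized terms are
warned about and ignored. The promoter-discrepancy profile restricts to
Illumina-Promoter probes, computes the signed strand-aware distance to the
nearest associated TSS (negative = upstream in transcript orientation),
bins by 200 bp (`floor(d / 200) · 200`), and reports per bin the percentage
of probes whose chromatin-state category is neither Promoter nor Dual
(Dual regions contain promoters in some cell lines, so counting them
discordant would overstate the disagreement).

## Filtering

Array probes are removed, in a fixed order recorded by the funnel report,
by: detection p ≥ 0.05 in *any* sample (the boundary is inclusive; removal
is probe-wide because downstream analyses are whole-matrix), sex
chromosome, cross-reactive list, SNP list, and finally incomplete
observation within a replicate group. Cross-reactive/SNP lists are plain
text inputs (one probe id per line), keeping the package download-free.

RRBS sites are removed below 10 reads (kept at exactly 10) or on sex
chromosomes. Opposite-strand calls of one CpG (minus strand at plus
position + 1) are averaged — coverage summed, position reported on the
plus strand, strand `.` — when |Δ fraction| < 0.10, and both discarded
otherwise. The 10% tolerance is interpreted as an absolute difference of
methylation fractions (percentage points), the natural reading for values
on a 0–1 scale; the comparison uses a 1e-9 float-safety margin so a delta
of exactly 0.10 is discarded. Pairs in which one strand has zero coverage
(undefined fraction) are discarded as incomparable. Every filter is
idempotent and every stage satisfies input = removed + surviving.

## Beta/M conversion and PBC

`M = log2(β/(1−β))` with β clamped to `[ε, 1−ε]`, ε = 1e-6 — large enough
to keep M finite, small enough to leave any realistic beta untouched. The
inverse is exact away from the clamps (round-trip error < 1e-9).

PBC operates per sample, independently of all other samples (it is a
within-array method). Peaks are located by Gaussian KDE with Silverman's
bandwidth on a 512-point grid, separately for `{M < 0}` and `{M > 0}`; a
side with fewer than two distinct values degenerates to that value, and an
empty side yields a missing peak. Type II values are rescaled side-wise on
the M scale, `M' = M · peakI/peakII` for the matching sign; `M = 0` is a
measure-zero tie-break left unchanged; type I values and the missingness
pattern are untouched. If a needed peak is missing the affected side
passes through with a warning. The side-wise linear rescale on M, the
bandwidth rule and the grid size are fixed here as the package's
definition of PBC; they are exposed only through this documented behaviour.

## The h statistic

Given a replicate group: M values per probe; per-probe SD `s` (ddof = 1)
and mean `m`; a loess smooth of `s` on `m` evaluated at every `mₚ` gives
`s*ₚ`; `s₀ = mean(s)`; `hₚ = |s*ₚ − s₀|`; `h = mean(hₚ)`. The local
regression is degree-2 with tricube weights over the `ceil(span·n)`
nearest neighbours, span 0.75 by default (exposed as a parameter); windows
with zero spread or a singular design fall back to the weighted mean. A
matrix with constant `s` gives `s* ≡ s₀` and `h = 0` exactly. The test
suite carries a second, independently written implementation of these
steps (naive O(n²) nearest-neighbour selection, `np.polyfit`) and requires
agreement to 1e-6.

Pairwise reproducibility distributions are computed on the beta scale
(the scale on which array results are reported); within-matrix mode counts
each unordered replicate pair once, between-matrix mode counts all cross
pairs, and only shared probes are compared. The summary statistic of
record is the median, with quartiles for boxplot parity. Cross-technology
comparisons use the partner technology's raw measurements.

## Differential methylation

Welch's t-test on M values is the default — 850k data show variance
heterogeneity, and Welch does not assume equal variances — with Student's
available for comparison. BH adjustment runs across all tested probes (the
test family is everything that survived filtering). Δβ is computed from
group medians on the beta scale of the analysed (normalized) matrix. A
probe with zero variance in both groups gets p = 1 and a flag rather than
an error. Calls require adjusted p < 0.05 and Δβ > 0.2 (both strict).

## The synthetic-data generator

`epicpipe.synth` emulates the pipeline's real inputs at toy scale with
full determinism (same seed + config → byte-identical files; all
randomness flows through `numpy.random.default_rng([seed, stream])`).

Chromatin tracks tile each chromosome with exponentially sized segments
(mean 800 bp, ≥ 100 bp) drawn from a configurable 15-state frequency
vector (~9% promoter, ~16% enhancer states by default). Transcripts (40%
LNCipedia lncRNAs, 60% Ensembl with a 70/20/10 coding/lncRNA/other split)
place half their TSSs inside regulatory regions so promoter/eRNA
associations are exercised; the enhancer atlas samples ~30% of enhancer
super-regions with ±100 bp jitter. Manifests are written in the Illumina
dialect (header block, `[Assay]`, `[Controls]`), with default-annotation
columns (RefGene groups, FANTOM5 flags) derived from the same toy genome,
and the 450k manifest a ~55% subset of the 850k one. A ground-truth table
records, for every probe, the category obtained by an intentionally naive
per-base scan of the raw tracks — the independent oracle for the
annotation tests.

Beta matrices: true per-probe M values come from a two-peak mixture at
M = ±4.5 (β ≈ 0.044/0.956) with SD 0.5. The type I peak position reflects
where real Infinium type I beta densities mode (near 0.03/0.97); it also
matters structurally: with peaks much closer to 0, the side-wise M rescale
of PBC would locally *expand* the beta axis around compressed type II
peaks and could not reduce replicate scatter, contradicting the observed
behaviour of PBC on real arrays that the generator is meant to emulate.
The type I/II bias is planted on the M scale, matching how it is
diagnosed: type II observed M = c·(true M) + noise with compression
c = 0.6 by default, type I observed M = true M + noise. Noise SDs
(type I 0.585, type II 0.52 M-units) were calibrated once so that the
median per-probe replicate beta-scale SD at n = 3 replicates is ≈ 0.013
for type I and ≈ 0.034 for type II probes — the reproducibility gap
observed on real 850k replicates. (On the M scale the two are similar;
the beta-scale gap arises from the slope of β(M) at the compressed vs
uncompressed peaks, and after PBC the type II M-scale noise 0.52/0.6 ≈ 0.87
remains above type I, so corrected type II probes stay the noisier class.)
An optional coefficient `b` inflates noise SD by `(1 + b·|true M|)` to
plant linear variance heterogeneity; the default is b = 0 (homoscedastic
on M), since no magnitude is established for real data.

Two-group designs plant differentially methylated cytosines in a
configurable fraction of probes (default 5%) by shifting the group-B beta
by Δβ = 0.3. DMC probes draw their baseline beta uniformly from
[0.1, 0.6]: a 0.3 beta shift is only a meaningful differential-methylation
scenario away from the saturated extremes of the logit scale, where
beta-scale noise maps to enormous M-scale variance. For DM benchmarking
the generator's beta-noise mode adds N(0, 0.03) directly on the beta scale
(clipped to [0, 1]). Detection-p failures are planted independently per
cell (default rate 0.001, echoing how rarely array probes fail in
triplicate).

RRBS: per-site coverage is negative-binomial (mean 30, dispersion 3),
methylated counts binomial around the true fraction, both strands emitted
independently; 10% of site/sample pairs are dropped (coverage
inconsistency between experiments) and 5% of sites get a minus-strand
fraction displaced by 0.3 to exercise the strand-merge discard path.

## What the synthetic tests show — and what they do not

Passing tests establish that the implementation is internally correct:
annotation agrees with a brute-force per-base oracle on hundreds of random
toy genomes, h agrees with an independent implementation to 1e-6 and is
near zero under a homoscedastic null, PBC recovers planted peak
compressions c ∈ {0.4, 0.6, 0.8} to within 0.15 M-units and improves both
within-replicate and cross-technology agreement, and DM calling achieves
≥ 0.9 sensitivity at ≤ 0.1 FDR under the planted-signal conditions. They
do not establish performance on real arrays: the generator has no
background fluorescence, dye or batch effects, no probe-sequence-dependent
bias, no U-shaped beta-scale noise profile, no correlated neighbouring
CpGs, and its chromatin tracks are memoryless rather than biologically
organized. Quantities that depend on those features (e.g., how much PBC
reduces h on real data, absolute annotation category counts) must be read
from real datasets, not from these fixtures.

## Problem sizes used by the checks

The bundled checks run at desk scale on one CPU: 200 toy genomes of 10 kb
for the annotation oracle; n = 5,000 probes for the homoscedastic-null h;
n = 20,000 probes × 3 replicates per compression level for PBC recovery;
20 × (2,000 probes, 4 vs 4) simulations for DM recovery plus 20 null
simulations; 3,000–5,400 RRBS sites for the funnel. These sizes give
stable medians and rates while keeping the whole suite around a minute.

## Known limitations

- IDAT decoding, detection-p computation and the nine external
  normalization methods are out of scope by design; normalized matrices
  enter as tagged TSVs.
- The loess evaluation is exact at every probe (no interpolation grid), so
  `variance_heterogeneity` is O(n²·span) — fine up to a few tens of
  thousands of probes, slow beyond.
- genome-build liftOver is not provided; all inputs must share one build.
- `rrbs_merge_strands` assumes the CpG +1 pairing convention of bisulphite
  calls; other dialects must be converted upstream.
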