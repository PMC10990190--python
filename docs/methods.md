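# Methods

`feralgen` implements the statistical machinery needed to characterise
*Saccharomyces cerevisiae* isolates from spontaneous (uninoculated) grape
ferments: where each piece of a mosaic genome came from, whether any of it
arrived by introgression from an unsampled divergent donor, how unstable the
genome is at the chromosome level, and which *sensu stricto* species a read
set belongs to. This note records the models, the parameters that matter,
the numerical choices, and what the synthetic-data tests do and do not
demonstrate.

## Genotype representation and quality control

Diploid genotypes are stored as a dense dosage matrix (samples × biallelic
SNVs; 0/1/2 alternate-allele copies, −1 missing) with optional per-genotype
GQ and DP. Three filters, applied in order:

1. **Genotype level** — a call with `GQ <= gq_min` (default 20) or
   `DP <= dp_min` (default 6) is set to missing. Both comparisons are
   inclusive: a genotype at exactly GQ 20 or DP 6 is discarded.
2. **Site level** — a site is removed when *strictly more than*
   `max_missing` (default 0.8) of sample genotypes are missing; a site at
   exactly 80% missing survives.
3. **Sample level** — a sample is kept when mean DP ≥ 6 and its genotyped
   fraction is *strictly above* 0.8.

The boundary semantics are deliberate and tested; they are documented only
here and in the function docstrings to keep one source of truth.
Multiallelic records are dropped (logged), not decomposed: every downstream
statistic is defined on biallelic frequencies. Coordinates are 0-based
half-open internally and converted at the VCF boundary.

Windows are tiled (`step == size`) or sliding intervals per contig; start
positions are every `step` up to `contig_length − size` (a final short
window at the contig end is kept and flagged `partial` so callers can drop
it). Sites inside repeat-mask intervals never enter a window's site list.
Supported painting window sizes are 10/15/20/25 kb with 25 kb the default;
the fd scan defaults to 10 kb. Per-isolate heterozygosity is the fraction
of non-missing genotypes that are heterozygous; the screens used to select
near-homozygous isolates for painting (0.5% or 0.05%, depending on how
strict a clonality requirement is wanted) are caller-side thresholds, not
baked in.

## Windowed population statistics

With within-population alternate-allele frequency `p` estimated from the
non-missing genotypes at a site and `n` the non-missing haplotype count:

* **π** (nucleotide diversity) — mean over sites of `2p(1−p)·n/(n−1)`.
* **d_XY** — mean over sites of `pA(1−pB) + pB(1−pA)`.
* **d_a** — `d_XY − (π_A + π_B)/2`, reported as-is (it may be negative;
  with identical populations it equals `−mean(2p(1−p))/(n−1)`, an O(1/n)
  residual of the unbiased-π/plug-in-d_XY combination rather than exactly
  zero).

Both π and d_XY are per-site averages. When only variant sites are
available the window average is over variant sites and the result carries
`mode="variant_sites"`; passing `n_accessible` divides by the accessible
site count instead. Exhaustive haplotype-pair enumeration on small complete
windows reproduces both to 1e-12 (tests).

**Identity by state** between two diploids is `1 − |g_A − g_B|/2` averaged
over co-genotyped sites; the missing fraction is reported alongside so
callers can discard windows with too little overlap. **Coancestry** is a
method-of-moments estimator on the allele-sharing scale: the observed mean
sharing is standardized against its closed-form expectation for two
independent Hardy–Weinberg draws from the panel-wide frequencies, so
duplicate samples score ~1 and panel-average pairs ~0.

**fd** estimates the fraction of a window affected by introgression from a
donor (P3) into a recipient (P2) relative to its sister (P1), polarized by
an outgroup (O). Sites are polarized so the outgroup *major* allele is
ancestral; outgroup frequency ties (0.5) are uninformative and skipped.
The numerator sums `(1−p1)p2p3(1−pO) − p1(1−p2)p3(1−pO)` over sites; the
denominator substitutes `pD = max(p2, p3)` for both p2 and p3, emulating
complete introgression. Windows with a non-positive numerator return 0
under the default `negative="clamp"` (fd is only interpretable as an
introgressed fraction when shared derived alleles are in excess);
`"undefined"` and `"keep"` are available. Null calibration uses `"keep"`:
clamping censors the negative tail, so the clamped null mean is strictly
positive (~0.03–0.04 in our simulations) while the signed windowed values
are symmetric about zero. The null test mirrors the control-test geometry —
sister P1/P2 (drift F = 0.05) with divergent P3/O (F = 0.5) — where the
signed mean stays within ±0.01 at 500 windows × 200 sites.

## Lineage collapsing and chromosome painting

Commercial starter products are near-clonal, so the reference panel is
collapsed into lineages before painting. Average-linkage hierarchical
clustering runs on `1 − IBS`; the dendrogram is cut top-down. A node is
retained as one lineage only when

* the minimum within-node pairwise IBS is ≥ `ibs_cutoff` (default 0.99), and
* the merge's permutation Z-score is `< z_cutoff` (default 3): the observed
  mean between-subcluster dissimilarity is compared against a null built by
  re-partitioning the merged members into random groups of the same sizes
  (`n_perm` draws, default 1000, seeded).

Otherwise the two subclusters are examined recursively; singletons become
unique-isolate lineages. The original procedure inspected the dendrogram
manually with the same two thresholds; making the rule algorithmic means
lineage counts on real data may differ slightly from a manual cut. A
lineage's category (starter / non-starter / mixed) is inherited from its
members' metadata.

**IBS painting** assigns each window of a query isolate to the lineage with
the best-matching member: the lineage score is the *maximum* member IBS
(lineages are near-clonal; the max is robust to one divergent member), the
assignment is the argmax lineage when its score reaches `min_ibs` (default
0.98), otherwise the window is UNASSIGNED. Windows where the query itself
is missing at more than `max_missing` (default 0.2) of sites are
TOO_MISSING. Ties break lexicographically on lineage id and are flagged.
IBS uses co-genotyped sites only, with the missing fraction reported — an
assumption, since an all-sites denominator would penalise missingness
instead of flagging it. Windows copied from a donor absent from the panel
fail the 0.98 cutoff and stay UNASSIGNED, which is exactly how admixture
loci announce themselves in this framework.

**d_a painting** assigns each window to the clade minimizing d_a between
the query (as a singleton population) and the clade, with the same
tie-break rule; per-clade genome proportions are computed over assignable
windows.

## Introgression scanning

Because the true donor population is unsampled, local trees are tested for
*subtree incongruence* rather than direct donor membership. For each window
tree and each focal haplotype, the tree is rooted on a designated outgroup
(if unrooted; absent outgroup leaves make the window UNRESOLVED), pruned to
the focal haplotype, the closest sampled relative of the putative source
(`source`), the Mediterranean-oak-like anchor clade (`mo`) and the wine
reference panel (`wrp`), and classified:

* **INCONGRUENT** — the clade spanned by {focal} ∪ source excludes every
  mo/wrp leaf *and* {focal} ∪ mo ∪ wrp is not a clade;
* **CONGRUENT** — {focal} ∪ mo ∪ wrp is a clade excluding the source;
* **UNRESOLVED** — anything else.

Zero-length or weakly supported internal branches are not collapsed
(collapse is available as an option, default off). Calls are invariant to
leaf order and to the presence of unrelated leaves (pruned away).

Per window, the admixture **allele frequency** is incongruent / resolved
calls; haplotypes missing from a window's tree are excluded from the
denominator; all-UNRESOLVED windows carry an undefined AF. **Fixed blocks**
are maximal runs of AF = 1 windows of length ≥ `min_run` (default 3) with
`trim` (default 1) breakpoint windows removed from each end, since terminal
windows may contain recombinant genotypes of both ancestries; runs never
span a chromosome boundary. fd and topology evidence combine by union; the
fd threshold for the union defaults to the 99th percentile of a control
(non-admixed) fd distribution supplied by the caller, since no fixed cut is
canonical.

## Read-depth aneuploidy and genome instability

Sequencing reads sample positions approximately independently, so a
chromosome present in k copies shifts its entire per-site depth
distribution by a factor k/2. Per chromosome:

* **Test** — two-sided Mann–Whitney of the chromosome's per-site depths
  against the pooled depths of all other chromosomes; effect size is the
  signed rank-biserial `r = 2U/(n₁n₂) − 1` (positive = deeper than
  background). A chromosome is aneuploid when `|r| ≥ 0.5` (a "large"
  effect), GAIN/LOSS by sign.
* **Copy number proxy** — the Hodges–Lehmann location shift (median of all
  pairwise chromosome-minus-background differences), divided by the median
  depth of chromosomes called euploid (genome-wide median as a flagged
  fallback when everything is called). A clean single duplication (3N)
  sits at +0.5 normalized shift; each further copy adds 0.5. Exact
  integer copy numbers are deliberately not called.
* **Instability** — per isolate with ≥ 2 polysomes, each polysome's
  normalized shift is regressed (OLS, i.e. Gaussian identity-link GLM) on
  the mean shift of its *other* polysomes, per chromosome stratum and
  pooled; strata with < 3 points are skipped. Admixed vs non-admixed
  isolates are compared by a one-sided Mann–Whitney on per-isolate mean
  polysome shifts (exact for combined n ≤ 50, otherwise normal
  approximation with continuity correction; the method used is reported).

Isolates below 20× mean depth are excluded (inclusive at 20.0).

**Numerics.** The exact Hodges–Lehmann estimator over full genome site
counts would need ~10¹³ pairwise differences; instead the k-th order
statistic of the pairwise-difference multiset is found by counting
bisection over integer difference values (depths are integers), averaging
the two middle order statistics for even pair counts. This is exact and
O((n₁+n₂)·log range); the dense-matrix path remains for small non-integer
inputs, and tests pin both to the exhaustive oracle at 1e-9. Optional
seeded site subsampling (`max_sites_per_group`) bounds cost further;
subsampling to 10⁴ sites per group moves the rank-biserial by < 0.02 on
Normal(30,10) profiles.

**Simulation designs.** Per-site depth is drawn from Normal(mean = 30,
σ = 10), scaled per event (`depth × (1 + shift)`), rounded, floored at 0.
Per-chromosome site counts default to proportions of the 16 S288C
chromosome lengths over 16,000 total sites — small enough for desk-scale
grids, large enough that a 3N chromosome is detected in ≥ 99% of runs.
Three designs are implemented:

1. **Whole-chromosome grid** — focal scaling −1..1 by 0.1 (0N–4N) against
   0–5 background chromosomes at 3N; records rank-biserial per replicate.
   At scale −1 the focal chromosome is all zeros; complete separation is
   approached but not exact, because flooring leaves ~0.1% zero-depth
   background sites that tie (observed r ≤ −0.996).
2. **Segmental grid** — a fraction −0.5..0.5 of the focal chromosome
   scaled to 1N (negative) or 3N (positive). Segmental events rarely reach
   the 0.5 call threshold (the design's point: segmental hemizygosity does
   not masquerade as whole-chromosome aneuploidy). Gain and loss are *not*
   symmetric in |r|: a 1N segment (N(15, 5)) separates from the 2N
   background more sharply in rank terms than a 3N segment (N(45, 15)),
   because depth variance scales with copy number.
3. **Co-occurrence grid** — 1–5 background polysomes at true normalized
   shifts 0–3 (2N–8N) alongside one foreground chromosome at true shift
   0–5 (up to a 10N gain); the foreground shift is re-estimated through the
   full calling pipeline. With no co-occurring polysomes the estimate is
   unbiased (< 3% relative error); the bias grows monotonically with both
   the number and copy number of co-occurring polysomes, reaching ~12%
   underestimation in the most extreme cell (5 polysomes at 8N,
   foreground 10N).

Aneuploid chromosomes in all three designs are selected with probability
proportional to 1/length by default (`background_weights="inverse_length"`);
observed aneuploidy frequency in yeast falls with chromosome length, and
uniform selection (available via `background_weights=None`) materially
overweights large-chromosome polysomes, inflating the co-occurrence bias to
~17%. The foreground chromosome is selected uniformly.

Sliding normalized-depth tracks (median depth in 10 kb windows stepped by
2 kb, divided by the euploid median) visualise within-chromosome structure;
site positions are taken as evenly spaced when explicit positions are
unavailable.

## k-mer species assignment

Each reference genome contributes its set of canonical 31-mers (canonical =
lexicographic minimum of a k-mer and its reverse complement, A<C<G<T; runs
of non-ACGT bases break windows). K-mers present in more than one species'
reference are removed, leaving pairwise-disjoint unique-marker sets. A read
set is reduced to canonical k-mers observed more than 4 times (≥ 5; the
count threshold suppresses sequencing-error k-mers), matched exactly, and
per-species proportions computed over *distinct* matched k-mers by default
(a count-weighted mode exists; with even coverage both agree closely).
Unmatched k-mers are excluded from the denominator and reported. Samples
with no matches are UNCLASSIFIED. Everything runs in memory; this is an
exact unique-marker classifier, not an LCA taxonomy tool.

## Synthetic data

The generators produce every input the pipeline consumes, with truth
tables, and are deterministic given their seed.

* **Panel** — ancestral frequencies ~ Uniform(0.05, 0.95); clade
  frequencies follow the Balding–Nichols Beta(p(1−F)/F, (1−p)(1−F)/F)
  drift model (default 3 clades, F = 0.2 — enough drift that clades are
  well separated without fixation); each lineage is founded by one
  haplotype drawn from its clade frequencies, members are *homozygous*
  founder clones with per-site flip rate 1e-3 (matching the near-homozygous
  isolates painting is designed for; within-lineage IBS ≈ 0.998).
* **Mosaics** — per window, the donor lineage follows a Markov chain with
  switch probability 0.3 (window-level truth is what painting consumes, so
  a window-level donor process, not a crossover-count model, is the right
  granularity); introgressed blocks overwrite consecutive windows with a
  haplotype from a heavily drifted unsampled donor; a heterozygosity target
  pairs two independent mosaic haplotypes.
* **Local trees** — newick per window: congruent windows nest every focal
  haplotype inside the wrp clade; introgressed windows place focal
  haplotypes inside the source clade; with probability `noise` a haplotype
  attaches above the source/(mo,wrp) split — a placement that is provably
  neither congruent nor incongruent, giving controlled UNRESOLVED calls
  without random-topology false positives.
* **Depth** — as in the simulation designs above.

What the generators do *not* emulate: linkage disequilibrium within
windows, sequencing error in genotypes, mapping bias, GC-coverage waves,
within-chromosome depth autocorrelation, or coalescent variance in tree
shapes. Passing tests therefore demonstrate that the statistics recover
the truth under their own modelling assumptions — clean frequency drift,
exchangeable depth noise, clonal lineage structure — not that they are
robust to every artefact of real short-read data. Real-data quantities
(aneuploid-isolate percentages, gain/loss asymmetries, real fd intervals
and regression slopes) require the original sequencing data and are out of
scope for the synthetic suite.

## Known limitations

* Painting is hard-cutoff argmax, not probabilistic (no Li–Stephens HMM);
  windows containing a recombination breakpoint get a single donor label.
* The lineage Z-score permutes at the matrix level (re-partitioning
  members), not at the site level, since the clustering operation receives
  only the IBS matrix.
* The AF denominator excludes haplotypes whose window trees failed; with
  many failures an AF of 1.0 can rest on few calls.
* `fd` windows with a tiny denominator are numerically fragile; rely on
  the reported per-window informative-site count when filtering.
* The co-occurrence bias figure depends on how aneuploid chromosomes are
  selected (inverse-length vs uniform changes it from ~12% to ~17%); the
  weighting is exposed precisely because real selection rates are an
  empirical quantity.
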