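# Methods

This note documents the statistical models implemented in `popgenscan`, the
conventions chosen where the field offers more than one, and what the
synthetic-data tests do and do not establish about real data.

## Input model and site masks

The unit of analysis is a `CodingAlignment`: n ≥ 2 aligned ingroup
haplotypes, one outgroup sequence of the same length, and sorted,
non-overlapping exon intervals whose concatenation is divisible by 3.
Heterozygote phasing, realignment and orientation are upstream concerns:
sequences are consumed as given, forward strand only.

Missing data follow **complete deletion**: a column with a gap or `N` in
any ingroup sequence is excluded from every statistic; a gap/`N` in the
outgroup additionally excludes the column from polarized (outgroup-
dependent) analyses only. This makes all per-site denominators shared
across statistics, at the cost of discarding columns pairwise deletion
would keep. Codons containing any masked column are excluded whole, so the
reading frame stays exact. A haplotype carrying an internal stop codon is
dropped with a warning naming it (it almost always indicates a frame or
annotation error); the terminal stop of a complete CDS is tolerated and
that codon is excluded from codon-level statistics.

## Diversity and divergence

* π is the mean over all C(n,2) ingroup pairs of per-site differences.
  Within-species π is **uncorrected** for multiple hits; between-species
  divergence is **Jukes–Cantor corrected**, K = −(3/4)·ln(1 − 4p/3),
  with a hard error for p ≥ 0.75. This asymmetry is the conventional
  behavior of the summary-statistics software this package is
  interoperable with.
* Synonymous/replacement partitioning is **Nei–Gojobori (1986)**:
  fractional site counts per codon (the fraction of the three possible
  changes at each position that are synonymous, changes to stops counting
  as replacement), and pathway-averaged difference counts between codons
  (all orderings of the differing positions, stop-free pathways only;
  if every pathway crosses a stop, all pathways are used with stop steps
  counted as replacement, and a warning is emitted). Site counts are
  averaged over all ingroup sequences — and over the outgroup too for
  divergence denominators — so no haplotype is privileged.
* Codon sites with more than two ingroup variants are decomposed as a star
  from the most frequent codon (ties broken alphabetically) and flagged.

## Neutrality tests

Tajima's D uses the 1989 constants (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂) and
is undefined for S = 0 or n < 4 (windows emit nulls there). The identity
D ≡ 0 when the count-form π equals S/a₁ is exact and is tested.

The unfolded SFS uses only biallelic ingroup columns where the outgroup
carries one of the two alleles; columns with a third-state outgroup or more
than two ingroup states are excluded from the SFS — but still count toward
S and D, which need no polarization. Fay & Wu's H is the **normalized**
version of Zeng, Fu, Shi & Wu (2006): H = (θ̂_π − θ̂_L)/√Var with
θ̂_L = Σ i·ξ_i/(n−1) and the published variance in terms of θ̂_W and
θ̂² = S(S−1)/(a₁² + a₂).

A deliberate property of these normalized statistics, verified against
independent msprime genealogies and tskit's own implementation: their
neutral **means are not exactly zero** (≈ −0.10 for D and ≈ +0.08 for H at
n = 24), although their scale is stabilized to ≈ 1. Calibration tests
therefore assert distribution-level agreement with the independent oracle
and analytic expectations of the genealogy process, not a zero mean.

## McDonald–Kreitman test

Counting rules, per codon fully usable including the outgroup: a column
with ≥ 2 ingroup states is polymorphic even when it also differs from the
outgroup (polymorphism takes precedence); a column monomorphic in the
ingroup and different from the outgroup is a fixed difference. Changes are
classified in codon context with pathway averaging; fractional counts are
kept exact internally and rounded only for table-style display.

Three test statistics are always computed: NI = (P_n/P_s)/(D_n/D_s) and
−log₁₀ NI (undefined with any zero cell; no continuity correction);
the likelihood-ratio G = 2·Σ O·ln(O/E) without Williams or Yates
correction, with its χ²₁ tail probability; and two-tailed Fisher's exact p
(sum of hypergeometric probabilities ≤ that of the observed table, counts
rounded to integers for the exact test). G and Fisher generally agree in
ordering but not in value for small tables; both are reported so either
convention can be compared against.

## Sliding windows

Windows run over alignment coordinates of the full sequenced region
(introns included); class-specific statistics are restricted to coding
columns inside each window. Geometry: starts at 0, step, 2·step, …, only
full-width windows (count = ⌊(L−width)/step⌋ + 1); an alignment shorter
than one window is an error. Defaults are 75/8 for π_syn and 250/25 for D,
H and K_A/K_S. Windows with S = 0 or no class sites emit nulls; window
K_A/K_S with zero synonymous divergence emits null rather than infinity.
K_A/K_S outliers are flagged above the 95th percentile (linear
interpolation) of a per-locus reference panel, defaulting to 1.14 when no
panel is supplied. No multiple-testing correction is applied across
windows; the scans are exploratory and the metadata says so.

## Coalescent null distributions

Time is in units of 4N₀ generations (ms convention): with k lineages in an
epoch of relative size λ, the coalescence waiting time is exponential with
rate k(k−1)/λ, and mutations fall at rate θ per unit branch length
(θ = 4N₀μ per locus). Under this convention E[T_MRCA] = 0.5 for n = 2,
E[T_total] = a_n, and E[S] = θ·a_n, all asserted within 3 Monte-Carlo SE.

Two mutation modes: `theta` (Poisson) and `fixed_S`, which places exactly S
mutations multinomially in proportion to realized branch lengths (Hudson's
`-s` semantics). Fixed-S is *not* identical to rejection-sampling the θ
model conditional on S; it is the standard conditioning for window-wise
bands and is also used for the gene-level nulls (θ mode is available for
sensitivity checks). Recombination is ignored everywhere — conservative
for identifying D/H outliers over short gene segments.

Empirical p-values are (1 + #{at least as extreme})/(R + 1) over defined
replicates; replicates with S = 0 in θ mode are excluded and their count
reported. One-tailed p (in the direction of the observed deviation from
the simulated median) and two-tailed p (double the smaller tail, capped at
1) are both reported, since published tail conventions vary. Per-window
95% bands condition on each window's observed S with the gene's n; windows
sharing S share one simulated null, so equal-S windows get identical bands
by construction. Band widths of the normalized statistics are roughly
constant in S — what low-S windows lose is resolution (few attainable
statistic values), not nominal band width.

Demography is piecewise-constant. A posterior over bottleneck parameters
can be supplied as a TSV of epoch draws (`start_1, size_1, …`, present-day
epoch implicit at size 1); one row is resampled per replicate. A toy
three-epoch bottleneck posterior generator ships for testing and is
labeled synthetic/non-biological.

## Synthetic data generator

The generator emulates the study design this package targets: 11–54
haplotypes, 1–4 exons over 1–3.5 kb, an outgroup at ~4–8% synonymous
divergence, and codon structure that exercises the syn/rep machinery end
to end. Defaults: θ = 0.012 per site (a typical genome-wide synonymous
diversity for an outcrossing tree), outgroup branch 4.0 × 4N₀ generations
(giving K_syn ≈ 0.05), ω = 0.25 (moderate purifying selection; replacement
mutations are accepted with probability ω, stop-creating mutations never).
Mutations are infinite-sites on real sequence: each accepted mutation is a
new column, so no column carries both an ingroup and an outgroup change
and polarization is exact by construction.

Scenarios are genealogy-shaping approximations, not forward simulations:
a sweep forces a star coalescence of a configurable fraction of the sample
(default 0.85) at a recent time (default 0.05), whose long subtending
branch accumulates high-frequency derived variants (negative H, and — for
a complete recent sweep — an excess of rare variants, negative D); a
balanced history forbids two clades (default split 50/50) from coalescing
before an old split depth (default 3.0), loading intermediate frequencies
(positive D). The generator does **not** emulate recombination, gene
conversion, population structure, sequencing error or alignment gaps in
coding regions; passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness of inference
on real resequencing data.

Classification of each generated mutation uses the ancestral codon context;
for codons hit more than once the post-hoc pathway classification can
differ, which is why truth-vs-recomputed class checks restrict to
single-hit codons (multi-hit codons are rare at the default θ).

## Pipeline conventions

Every gene derives its RNG stream from SHA-256 of (master seed, gene id)
reduced below 2³¹, so per-gene results are invariant to cohort composition
and run order. Outputs are TSV (1-based inclusive coordinates) plus a
full-precision JSON sidecar and a manifest of resolved parameters; reruns
with the same seed are byte-identical. A failure in one gene is recorded
in the manifest and does not stop the others. Cohort averages are reported
both unweighted and site-weighted, labeled as such, because averaging
conventions for per-gene summary tables vary between studies.

## Problem sizes used in the test suite

Simulation-based tests run at sizes chosen to give tight Monte-Carlo
error while keeping the default suite quick: 10⁴–10⁵ replicates for
analytic expectations, 4000 per configuration for the msprime
distributional cross-check (n ∈ {10, 24, 54}, S ∈ {12, 45, 87}), 500
trials × 999 replicates for p-value uniformity, and 100 replicate genes
per scenario for the sweep/balancing signature separation.

## Known limitations

* No recombination in the null model (conservative for outlier detection,
  but real windows are correlated along the gene).
* Jukes–Cantor is the only multiple-hit correction; no codon-model dN/dS.
* MK tables count each derived state at multi-allelic sites as one
  polymorphism (flagged); published tables may have pooled differently.
* The α (proportion of adaptive substitutions) family of MK extensions is
  out of scope.
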