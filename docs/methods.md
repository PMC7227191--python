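# Methods

This note documents the statistical models implemented in `mitopop`, the
conventions and numerical choices behind them, and what the synthetic-data
generator does and does not emulate.

## Data model and site filtering

All statistics operate on a rectangular alignment of same-locus,
equal-length nucleotide sequences (mtDNA amplicons are the intended input;
the package assumes an effectively haploid, non-recombining, maternally
inherited locus). Unequal-length input is rejected rather than aligned:
multiple sequence alignment is out of scope and must happen upstream.

Before analysis the **complete-deletion** filter removes every column that
contains a gap (`-`), `N`, or any IUPAC ambiguity code in *any* sequence.
Ambiguity codes are treated as missing data, not as partial information,
because downstream statistics need an unambiguous {A,C,G,T} state per cell.
The filter is idempotent, preserves row order, and reports retained column
indices. Internally coordinates are 0-based half-open; all reported
positions (segregating sites, network edge annotations) are 1-based.

## Diversity indices

For n sequences over L post-filter sites, with d_ij the Hamming difference
count of sequences i and j and p_i the relative frequency of haplotype i:

* K = (2 / n(n−1)) Σ_{i<j} d_ij — mean pairwise differences;
* π = K / L — nucleotide diversity per site. No multiple-hit correction is
  applied by default (the conventional presentation for closely related
  intraspecific haplotypes); a Jukes–Cantor transform is available behind
  `jukes_cantor=True`;
* Hd = n (1 − Σ p_i²) / (n − 1) — unbiased haplotype diversity;
* S — number of polymorphic columns.

Reports round to 4 decimals; machine-precision values are written to a
parallel `full_precision/` tree.

## Neutrality tests

**Tajima's D** contrasts K with S/a₁ using the standard normalising
constants a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂ (all closed-form in n; n ≥ 4
required). S = 0 yields an NaN sentinel, not an exception: a monomorphic
unit has no defined D.

**Fu's Fs** uses the Ewens sampling formula. With θ estimated by K (the
pairwise estimator, the convention that matches published mitochondrial
survey tables), the tail probability is

S′ = Σ_{k ≥ k_obs} |S1(n,k)| θ^k / (θ(θ+1)⋯(θ+n−1)),

where |S1(n,k)| are unsigned Stirling numbers of the first kind and k_obs
the observed haplotype count, and Fs = ln(S′/(1−S′)). The tail direction is
"at least k_obs alleles": haplotype-rich samples give small S′ and negative
Fs, the expansion signature. Stirling rows are computed once per n as exact
Python integers via the two-term recurrence and cached; numerator and
denominator are combined in log space, and Fs is formed as
logsumexp(upper tail) − logsumexp(lower tail), so both tails retain full
relative precision for any n of practical size (no arbitrary-precision
float library is needed). k_obs = 1 gives S′ = 1 and an +inf sentinel.

**Significance** comes from a fixed-S coalescent null: constant-size
Kingman genealogies with exactly S mutations dropped on branches with
probability proportional to branch length. Within each replicate K (for D)
and the haplotype partition plus K (for Fs) are recomputed. Defaults:
10,000 replicates, seeded.

P-value conventions differ between the common analysis packages. The
default here is the lower-tail proportion Pr(D_sim ≤ D_obs), which is the
convention that reproduces the published significance levels this package's
desk-scale checks target; `alternative="upper"`/`"two-sided"` and Tajima's
beta-distribution approximation (`method="beta"`) are selectable. For Fs
the p-value is Pr(Fs_sim ≤ Fs_obs); a monomorphic null draw contributes a
+inf Fs (maximally conservative). Note Fu's test is intentionally
conservative at nominal levels — the observed rejection rate at p < 0.05
under the null is well below 5%.

## AMOVA and fixation indices

Distance-based AMOVA treats the raw pairwise difference counts d_ij as
squared Euclidean distances. Sums of squares are computed from within-unit
pair sums (SS_unit = Σ_{i<j∈unit} d_ij / n_unit); variance components use
the unequal-sample-size coefficients (n′, n″, n‴ in the three-level design,
n₀ in the two-level design) from the mean-square expectations. Indices:
F_CT = Va/V, F_SC = Vb/(Vb+Vc), F_ST = (Va+Vb)/V (three-level) and
Φ_ST = Va/(Va+Vb) (two-level).

Negative variance components are *retained* in the components and percent
columns (they are legitimate estimates near zero differentiation); a
`percent_floored` column additionally clips at 0 for display conventions
that print no negatives. Percent variation always sums to 100 on the raw
components.

Permutation schemes, one per index: whole subpopulations permuted across
groups (F_CT); individuals permuted across subpopulations within their
group (F_SC); individuals permuted freely (F_ST / pairwise Φ_ST). P-values
are the plain proportion of permuted statistics ≥ observed (tie tolerance
1e-12); no +1/(B+1) correction is applied by default, so p = 0.000 can be
printed — matching the proportion-estimator convention of the standard
AMOVA software. Default 10,000 permutations, seeded.

Pairwise "F_ST" between two populations is the two-level Φ_ST on the
pair's individuals. A haplotype-frequency-only variant (identity distance
0/1) is available via `statistic="haplotype"` for comparison with purely
frequency-based fixation indices.

**Gene flow**: for a haploid maternal marker under the island model,
Nm = (1 − F_ST)/(2 F_ST). F_ST ≤ 0 maps to an +inf sentinel (reported
not-applicable: unbounded gene flow), F_ST > 1 is invalid.

Degenerate designs (a stratum with fewer than 2 units, or no residual
degrees of freedom, e.g. every individual its own population) raise a
"degenerate design" error rather than returning undefined components.

## Mismatch-distribution demography

The mismatch spectrum x_j is the relative frequency of sequence pairs at
Hamming distance j. Its mean equals K exactly. At demographic equilibrium
the expectation is geometric, F̂_j(θ) = θ^j/(θ+1)^{j+1}. Under a sudden
(stepwise) expansion from θ₀ to θ₁ at τ mutational time units ago, the
pairwise coalescence-time density is piecewise exponential and the
expected spectrum has the closed form

F_j(τ,θ₀,θ₁) = F̂_j(θ₁) · P(j+1, τ(1+1/θ₁))
             + e^{−τ(1+1/θ₁)} Σ_{i≤j} τ^{j−i}/(j−i)! · F̂_i(θ₀),

with P the regularised lower incomplete gamma function (this is the
Poisson(τ) convolution of the ancestral equilibrium plus the
post-expansion equilibrium weighted by the coalescence probability before
τ). The τ→0 and τ→∞ limits recover the θ₀ and θ₁ equilibria, which is
regression-tested.

**Fitting** minimises SSD = Σ_j (x_j − F_j)² over (τ, θ₀, θ₁) with
0 ≤ θ₀ ≤ θ₁ ≤ 10·d_max (the cap avoids the ridge toward θ₁ → ∞ and is
recorded in the output). The comparison support is
max(observed d_max, model 0.999 quantile), with the observed spectrum
zero-padded and the model renormalised over that support. A coarse grid
(τ resolved finely near the spectrum mean) is refined by Nelder–Mead from
the three best grid points; if refinement goes uphill the best grid point
is kept and the fit flagged unconverged. On spectra generated exactly from
the model, τ is recovered essentially exactly; the acceptance band used in
tests is ±0.5. A monomorphic (single-class) spectrum short-circuits to the
zero-diversity fit with SSD = 0.

**Harpending's raggedness** r = Σ_{i=1}^{d+1} (x_i − x_{i−1})², with
x_{d+1} ≡ 0; it depends only on relative frequencies.

**Bootstrap p-values**: `reps` coalescent samples of size n are simulated
under the fitted (τ, θ₀, θ₁) — directly in mutational units, pair
coalescence rate 1/θ(t) — each is refitted with the same grid/optimiser
settings, and p = Pr(simulated statistic ≥ observed) separately for SSD
and r. Default 1,000 replicates, seeded.

## Median-joining networks

Construction: (1) build the ε-relaxed minimum spanning network (MSN) over
the current sequence set — an edge of weight w enters iff its endpoints are
not connected using edges of weight < w − ε, all ties at a weight level
evaluated against the same connectivity state, so ε = 0 yields the union
of all minimum spanning trees; (2) for every connected triplet (a node and
two of its MSN neighbours) compute the site-wise majority consensus; ties
(three distinct states) resolve to the hub sequence's state, so no fourth
allele is ever created; (3) add all novel consensus vectors whose
connection cost is within ε of the minimum; (4) repeat until stable;
(5) prune latent (median) nodes of degree < 3 — they cannot be Steiner
points — rebuilding the MSN until none remain.

ε defaults to 0, all sites weighted equally. Median labels mv1, mv2, … are
creation-ordered and non-semantic; topology (graph isomorphism on small
cases) is the tested property. The network always spans the observed
haplotypes at minimum-spanning-tree cost or better (median vectors can
only shorten the spanning subgraph); when no medians are added the network
contains every MST exactly. Exports: GraphML (node frequency, per-
population composition, is_median; edge steps and differing positions),
flat node/edge TSVs, and DOT. Node layout/rendering is out of scope.

## Coalescent simulator

Scales: time is in per-deme coalescent units — a within-deme pair coalesces
at rate 1; θ is the scaled per-locus mutation rate on that scale (mutations
at rate θ/2 per lineage, so a single constant deme gives E[K] = θ and
E[S] = θ·a₁(n)); the island-model migration parameter M has each lineage
migrating at rate M/2 with a uniformly chosen destination, so Nm = M/2 and
the pairwise differentiation expectation for d demes is
Φ ≈ (d−1)/(Md+d−1). Expansion times are accepted in mutational units (the
scale of the mismatch τ) and converted internally (t_coal = τ/θ).

Mutations are dropped on branches Poisson(θ·L_total/2) and each is
assigned a distinct uniformly chosen site, redrawing collisions. This
finite-sites/at-most-one-mutation-per-site scheme keeps pairwise sequence
differences equal to mutation-path counts — the infinite-sites behaviour
the neutrality statistics assume — while emitting valid fixed-length
nucleotide FASTA (570 bp by default, the amplicon length of the motivating
survey design). Sequences descend from an all-A ancestor with a random
alternative base per mutation.

With migration = 0 and several demes the structured coalescent cannot
complete; once every deme reaches its local MRCA the remaining lineages
are merged into a single ancestral deme and coalesce panmictically from
that time backwards. This models demes that split from a common ancestral
population at the depth where within-deme coalescence finishes; it makes
the isolation limit well-defined (pairwise Φ_ST → 1 as θ grows) without a
user-supplied split time.

`simulate_fixed_s` provides the neutrality-test null generator: a
constant-size genealogy with exactly S mutations placed proportionally to
branch length, returning the implied distance matrix, haplotype count and
K. The fixed-S conditioning induces the known small negative bias in the
mean of D at small S (about −0.07 at n = 88, S = 9), which is part of the
null being matched, not an artefact.

`make_study_fixture` emulates the motivating three-population field
design: demes of 88/88/87 samples over 570 bp, each deme split into three
arbitrary subpopulations (the within-population layer carries no simulated
structure, so subpopulation-level differentiation is null), θ = 5 and
M = 6 chosen so the expected pairwise Φ_ST ≈ (d−1)/(Md+d−1) = 0.10, inside
the 0.05–0.15 band of the real survey, and a recent 10× expansion
(τ = 1 mutational unit) in the first deme. With migration this strong the
expansion signature is visible as the lowest *mean* Tajima's D across
replicate seeds, not as a deterministic signal in one draw.

What the generator does **not** emulate: recombination, selection,
sequencing/PCR error, base-composition bias, rate heterogeneity across
sites, unequal deme sizes, and geographic (stepping-stone) structure.
Passing tests on synthetic data therefore validate the estimators under
the neutral island-model assumptions those estimators themselves make —
they do not certify behaviour under selection, contamination, or
alignment error in real data.

## Test problem sizes

Calibration checks use sizes chosen to keep Monte-Carlo error a small
fraction of the tested tolerance: 2,000 replicates for the Watterson/
pairwise-θ expectations (n = 20, θ = 5; tolerances 3%/5% are ≈3 standard
errors), 4,000 null draws against 500 test datasets for the uniformity of
fixed-S p-values (KS at α = 0.01), 20 seeds for mean-D rank comparisons,
and 10,000 permutations where an exhaustive reference value exists (the
four-sequence two-population toy, where the exact permutation p is 1/3).

## Known limitations

* P-value conventions for Tajima's D differ across the standard packages
  (lower-tail simulation, two-sided beta approximation); the default here
  is the lower-tail simulation convention, and cross-package comparisons
  of p (not of D itself) should expect roughly a factor-of-two ambiguity.
* The sudden-expansion SSD surface is ridged in (τ, θ₀) and flat in θ₁ for
  spectra near equilibrium; fits flagged `converged=False` or hitting the
  θ₁ cap should be read as boundary estimates.
* Median-joining networks are reconstructions, not inferred genealogies;
  with high homoplasy (not generated under the finite-sites scheme used
  here, but present in real data) alternative equally parsimonious
  networks exist.
* AMOVA significance relies on exchangeability of individuals under the
  null; strong within-unit family structure would invalidate the
  permutation schemes.
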