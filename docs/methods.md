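# Methods

`barcodepop` analyses aligned mitochondrial barcode alignments (COI-type
fragments, hundreds of sites, maternally inherited, non-recombining) for
species delimitation by distance and for the demographic history of
populations within species. This note records the models implemented, the
defaults and why they were chosen, and what the synthetic data generator
does and does not emulate.

## Sequence handling

Sequences are strings over `{A,C,G,T,N,-}`; `N` and `-` are treated as
missing throughout. Haplotype collapsing uses strict string identity by
default: two sequences differing only at an `N` position remain distinct
haplotypes, matching the behaviour of the common FASTA-collapsing tools. An
`merge_ambiguous` switch merges sequences that agree at every mutually
informative site (transitive closure; the member with the fewest missing
sites represents the group). Trimming drops records whose informative span
(first to last non-missing site) is shorter than `min_keep` and cuts the
survivors to the intersection of their spans, so the output length is the
minimal retained informative length; the operation is idempotent.

## Distances and the barcoding gap

The p-distance is the proportion of differing nucleotides among sites
comparable in both sequences (pairwise deletion). Pairwise deletion is the
default because public barcode records have heterogeneous coverage; complete
deletion (drop any column with missing data first) is available as a switch,
and both modes are exposed because published summary figures rarely state
which was used. Between-group divergences are means over all between-group
pairs; their standard errors come from resampling alignment columns with
replacement (1000 replicates by default — the site bootstrap used by the
standard distance software, not a bootstrap over individuals). The
barcoding-gap analysis partitions all pairwise distances by the species
labels; a gap exists when the smallest interspecific distance exceeds the
largest intraspecific one, and the reported threshold is the midpoint of the
empty interval. The shared histogram uses 0.5% bins by default (published
gap histograms rarely state their bin width).

## Diversity and neutrality tests

For a sample of n sequences: haplotype diversity h = n/(n−1)·(1 − Σ p_i²)
over haplotype frequencies; nucleotide diversity π is the mean pairwise
p-distance per site; S counts polymorphic columns; k̄ is the mean absolute
pairwise difference. The Grant–Bowen four-quadrant reading of (h, π) uses
thresholds h = 0.5 and π = 0.5%, with boundary values assigned to the
"small" side; large-h/small-π is the founder-bottleneck-then-growth
signature.

Tajima's D uses the standard constants a1…e2 computed from n. Fu's Fs is
ln(S′/(1−S′)) with S′ = P(K ≥ k_obs) under the Ewens sampling distribution
at θ̂ = k̄, computed from exact integer Stirling numbers of the first kind
in log space (stable to n well beyond barcode sample sizes). P-values for
both tests come from neutral constant-size coalescent simulation (1000
replicates by default, seeded) conditioned on n, with θ̂ = S/a1 for D and
θ̂ = k̄ for Fs; P is the fraction of simulated statistics ≤ the observed
one, the convention of the standard population-genetics packages. Fs is
conventionally judged significant at α = 0.02; the package reports raw
P-values and leaves thresholds to the caller. Undefined statistics (S = 0,
or θ̂ = 0) are reported as NaN, never as 0.

## Mismatch distributions and expansion models

The observed mismatch distribution counts sequence pairs by absolute
nucleotide difference (pairwise deletion). Two expected forms are fitted,
both parameterised in mutational time τ = 2ut (u = per-sequence
per-generation mutation rate):

* **Sudden expansion.** The post-expansion population is treated as
  effectively infinite, so a pair carries Poisson(τ) recent differences on
  top of an equilibrium Geometric(θ) ancestral difference:
  F_j = Σ_k Pois(k; τ)·θ^{j−k}/(1+θ)^{j−k+1}. At τ = 0 this reduces to the
  equilibrium geometric F_j = θ^j/(θ+1)^{j+1}.
* **Spatial expansion.** An infinite-island form: the two lineages of a
  within-deme pair coalesce locally at rate 1/θ or separate by migration
  (pair rate 2M/θ, M = scaled migrant number Nm) during the τ recent time
  units; separated or surviving pairs coalesce in a panmictic ancestral deme
  of the same θ. This mixing density integrates in closed form to
  F_j = A_j + w·F_j^sudden(τ, θ), where A_j is an incomplete-gamma term for
  recent within-deme coalescence and w the probability of reaching the
  ancestral phase. The closed form is verified against numerical quadrature
  of the mixing density in the test suite; its limits (τ→0 or M→0 give the
  equilibrium geometric, M→∞ the sudden model) are exercised there too.

Fitting minimises the sum of squared deviations (SSD) between observed
relative frequencies and the expectation, with expected mass beyond the last
observed class lumped into that class. The optimiser is multi-start
Nelder–Mead on log-parameters (starts bracket the observed mean difference;
SSD tolerance 1e−8; the search box spans τ, θ ∈ [1e−4, 1e3], M ∈ [1e−4,
1e4], far beyond any biologically sensible estimate — boundary estimates of
θ → 0 are meaningful and indicate a purely star-like spectrum).

P-values for SSD and Harpending's raggedness r = Σ(x_{i+1} − x_i)² come from
a parametric bootstrap: coalescent samples are simulated under the fitted
model in mutational time (star phase for the sudden model; an explicit
infinite-island structured coalescent for the spatial model), each replicate
is refitted, and the P-value is the fraction of replicates with statistic ≥
observed. The spatial bootstrap exploits that migrants always land in empty
demes, so lineages alone in a deme are inert until the expansion time; this
bounds each replicate at O(n) events regardless of θ. Simulated spectra are
capped at twice the observed class range before refitting so that boundary
fits cannot blow up the refit cost.

The expansion age is t = τ/(2u) generations with u = μ_site/year · L /
(generations/year), reported in both generations and years. L and
generations-per-year are explicit parameters (defaults: the alignment length
and 1 generation/year) because only this combination resolves the mixed
per-site/per-year rate conventions in the source literature; the package
default clock is the COI rate 1.77×10⁻⁸ substitutions/site/year.

## Median-joining networks

Haplotype networks follow the median-joining construction: (i) the minimum
spanning network (all edges (u,v) with d(u,v) ≤ c(u,v) + ε, where c is the
single-linkage connection level) over the current node set; (ii) quasi-median
candidates from connected triplets (a centre linked to two neighbours);
per-site majority consensus, with three-way-disagreeing sites branching into
all three states (capped at 27 candidate sequences per triplet); (iii) the
candidate whose addition most reduces the total Steiner cost — measured as
the minimum-spanning-tree weight over the node set — is added, and the loop
repeats until no candidate reduces the cost; (iv) median vectors whose
removal leaves the cost unchanged are pruned. Adding one best candidate per
round (ties broken lexicographically on sequence) rather than all minimal
candidates makes the output deterministic under a fixed input; the classic
desktop implementation is input-order-dependent. The cost is a strictly
decreasing non-negative integer, so termination is guaranteed. ε defaults to
0 and character weights are uniform. For conflict-free (additive) data the
result is the minimum spanning tree with no median vectors; on small inputs
the node set is checked against an exhaustive quasi-median/Steiner search in
the tests. Group separation is the minimum Dijkstra path weight between
sampled nodes of different groups.

## Demographic scenarios and sequence simulation

The scenario object is a three-population colonization history: a source
population (Pop1, size N1) from which Pop2 (N2) and Pop3 (N3) were founded
at times t1 > t2 generations ago, each passing through a founder bottleneck
(N2b ≤ N2, N3b ≤ N3) lasting t_db < min(t1, t2) generations immediately
after colonization — backward in time the daughter size applies on
[0, t_split − t_db), the founder size on [t_split − t_db, t_split), and the
lineages then merge into Pop1. There is no migration after the splits. All
sizes are haploid effective numbers (mtDNA); all times are generations, with
year conversion only at reporting boundaries. Genealogies are simulated with
msprime (ploidy 1; colonizations expressed as backward lineage movements so
the source deme remains sampleable at the present).

Sequences evolve down the genealogy under HKY with optional discrete-gamma
rate heterogeneity (per-site rates drawn from Gamma(shape, mean 1)). The
CTMC is sampled exactly by uniformization: with Q normalised to one expected
substitution per unit time and λ = max_i(−q_ii), each site receives
Poisson(b·μ·r_i·λ) candidate events on a branch of b generations, resolved
through I + Q/λ (self-transitions allowed). A user-supplied root sequence
can be fixed — this is what lets the study-like generator place several
species at controlled divergences; otherwise the root is drawn from the
equilibrium base frequencies. The engine is validated against the HKY
matrix exponential on long branches, against msprime's own HKY mutation
model (after converting between event-rate and substitution-rate
conventions), and against Watterson's E[S] = a1·θ.

## ABC scenario choice

The reference table draws a scenario (equal prior), a parameter vector from
per-parameter uniform/log-uniform priors (draws violating scenario geometry
are rejected and redrawn, with a counter), simulates a dataset, and stores a
30-component DIYABC-style summary vector: per population the haplotype
count, S, mean and variance of pairwise differences, Tajima's D (imputed 0
with an NA indicator column when undefined) and private segregating sites;
per population pair the mean between-population difference, a Hudson-style
Fst = 1 − H_w/H_b, and the shared-haplotype count. Statistics are
normalised by their median absolute deviation over the table (robust to the
heavy tails of coalescent summaries; zero MADs fall back to 1).

Scenario choice: the *direct* estimate is the scenario frequency among the k
nearest rows in normalised Euclidean distance (default k = 500 at 10⁴ rows,
the 1–5% neighbourhood of the DIYABC tradition); the *logistic* estimate
fits a near-unpenalised multinomial logistic regression of the scenario
indicator on summary differences over the closest fraction of rows
(Epanechnikov weights) and evaluates it at zero difference, falling back to
the direct estimate with a warning on degenerate designs. Parameter
estimation applies the local-linear regression adjustment to the retained
draws of one scenario, on log scale for the strictly positive parameters,
and reports mean, median and the 2.5/97.5% quantiles; fewer than 50 retained
rows is an error advising a larger table. Type I/II error rates for a
target scenario come from pseudo-observed datasets simulated from the priors
and classified with the direct estimate; the posterior predictive error
re-classifies datasets simulated at posterior draws. Prior pre-evaluation
reports the midpoint quantile of each observed statistic within the
simulated cloud (flags outside [0.5%, 99.5%]); posterior-predictive model
checking reports per-statistic midpoint p-values (two-sided flags at 0.025).
Midpoint quantiles are used because many summaries are integer-valued.

Default priors place the "recent" scenario's split times inside
(20–781 ka for t1, 5–126 ka for t2) and the "ancient" scenario's beyond
(781–2000 ka and 126–781 ka), i.e. on the two sides of the mid- and
Late-Pleistocene boundaries at one generation per year; sizes are
log-uniform (10⁴–10⁶ for populations, 10–10⁴ for founders), the clock is
log-uniform on (1–3)×10⁻⁸ substitutions/site/year, and t_db is uniform on
0.1–4.9 ka. Every bound is plain data and must be overridden when a specific
study's prior table is to be matched exactly.

## The synthetic-data generator

`generate_study_like` emulates the statistical structure of a two-species
phylogeographic barcode survey at 456 bp: a structured species whose three
populations (samples of 20/20/15) descend from one source under the
recent-colonization scenario (defaults N1 = 1.5×10⁵, N2 = 1.2×10⁵,
N3 = 10⁶, founders 100 and 1500 for 5 kgen, splits at 143 and 65 kgen); a
star-like species (n = 39) from a single-deme sudden expansion (8×10³ →
4×10⁵ at 196 kgen); and a three-sequence outgroup species. Species roots
are placed on a shared ancestor by substituting disjoint site sets (7.2% and
8.5% of sites), so interspecific distances stay ≥ 6% while intraspecific
variation remains ≤ ~2–3% — the barcoding gap exists by construction. The
mutation model is HKY (κ = 8, AT-rich insect-mtDNA base composition
0.31/0.15/0.14/0.40, gamma shape 1.1) at 1.77×10⁻⁸ substitutions/site/year
and one generation per year. Under these defaults the bottlenecked
populations show the large-h/small-π signature (h ≈ 0.55–0.70, π ≈
0.2–0.3%) in over 70% of replicates, the source and star populations show
large-h/large-π (h > 0.85, π > 0.5%), and the star population yields
strongly negative neutrality statistics — the qualitative pattern such
surveys report.

What the generator does **not** emulate: codon structure and
third-position rate layering beyond a single gamma shape, sequencing error,
missing data and heterogeneous record lengths (all sequences are complete),
within-population geographic substructure, and selection. Tests passing on
generator output therefore validate the statistical machinery, not the
handling of dirty real-world barcode records beyond what the trimming and
pairwise-deletion paths cover.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale: reference tables
of 10⁴ rows (4×10³ for the null-calibration problem), 200 pseudo-observed
datasets for classification accuracy, 50 repetitions for credible-interval
coverage, 2000–2500 replicates for coalescent calibration checks, and
100–200 parametric-bootstrap replicates for mismatch P-values. These sizes
keep every experiment reproducible in minutes on one core while leaving the
Monte-Carlo error well inside the asserted tolerances; all of them are
parameters, and study-scale runs (e.g. 2×10⁶-row tables) only require
changing `n_sims`.

Known limitations: the spatial-expansion expectation is the infinite-island
approximation with a single θ for demes and ancestral population (no
separate θ₀/θ₁); the logistic scenario posterior relies on scikit-learn's
regularised solver rather than the exact conditional-logit of the original
ABC literature (the C = 10⁶ setting makes the penalty negligible); the MJ
implementation omits the optional maximum-parsimony post-processing step of
the desktop program; and Fu's Fs P-values for very large samples become
slow before they become inaccurate (exact Stirling integers grow large).
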