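# barcodepop

Population-genetic and phylogeographic analysis of mitochondrial DNA
barcodes (COI-type fragments), for researchers who study the history of
widespread species from single-locus data: species delimitation by the
barcoding gap, haplotype networks, within-population demography, and
model-based dating of colonization events.

Given an aligned FASTA plus a metadata table (sequence id, species,
population, locality), the package provides:

* **Haplotype collapsing and trimming** — merge identical sequences,
  cut heterogeneous records to their common window.
* **Uncorrected p-distances** — pairwise matrices, between-group
  divergences with site-bootstrap standard errors, and barcoding-gap
  analysis (max intraspecific vs min interspecific distance, threshold,
  histogram).
* **Median-joining haplotype networks** (Bandelt-style quasi-median
  construction under a Steiner cost criterion) with group-separation
  queries and GML export.
* **Diversity and neutrality statistics** — haplotype diversity
  h = n/(n−1)(1 − Σp²), nucleotide diversity π, segregating sites S,
  Tajima's D and Fu's Fs with coalescent-simulation P-values, and the
  Grant–Bowen (h, π) four-quadrant reading.
* **Mismatch distributions** — sudden- and spatial-expansion fits by least
  squares (τ, θ, M), SSD and raggedness P-values by parametric bootstrap,
  and the expansion-age conversion t = τ/(2u).
* **Coalescent scenario simulation** (msprime genealogies + an HKY+Γ
  sequence engine) for three-population colonization histories with founder
  bottlenecks.
* **ABC scenario choice** — reference tables over parameter priors,
  direct (k-nearest) and logistic-regression scenario posteriors,
  local-linear parameter estimation, type I/II error rates and posterior
  predictive model checking.
* **A synthetic-data generator** that emulates a full study-like survey
  (structured species + star-like species + outgroup) with known truth, so
  the entire pipeline is testable offline.

The models and their assumptions are documented in
[docs/methods.md](docs/methods.md).

## Worked example

```python
from barcodepop import popgen, sequence_io, distances, synthetic_data

# a study-like synthetic survey: 3 species, 456-bp barcodes, known truth
aln, truth = synthetic_data.generate_study_like(seed=1)
print(f"{aln.n} sequences x {aln.length} bp, "
      f"{len(sequence_io.collapse_haplotypes(aln).haplotypes)} haplotypes")

gap = distances.barcoding_gap(distances.p_distance_matrix(aln), aln.species_of())
print(f"barcoding gap: max intra {100*gap.max_intra:.2f}% | "
      f"min inter {100*gap.min_inter:.2f}% -> gap exists: {gap.gap_exists}")

aus = aln.by_species()["structured_sp"].by_population()["Australia"]
d = popgen.diversity(aus)
print(f"Australia: n={d.n} h={d.h:.3f} pi={100*d.pi:.2f}% -> {d.grant_bowen}")

fit = popgen.fit_expansion(popgen.mismatch_observed(aus), n=aus.n,
                           model="spatial", n_boot=200, seed=7)
et = popgen.expansion_time(fit.tau, mu_site_year=1.77e-8, L=aus.length)
print(f"tau={fit.tau:.2f} (SSD P={fit.p_ssd:.2f}, raggedness P={fit.p_raggedness:.2f})"
      f" -> expansion ~{et.t_years/1000:.0f} ka")
```

prints

```
97 sequences x 456 bp, 33 haplotypes
barcoding gap: max intra 2.41% | min inter 7.68% -> gap exists: True
Australia: n=15 h=0.800 pi=0.26% -> large-h/small-pi
tau=1.29 (SSD P=0.19, raggedness P=0.24) -> expansion ~80 ka
```

Reading the output: the three species are cleanly separated by an empty
distance interval (the barcoding gap) between ~2.4% and ~7.7%. The
Australian sample combines high haplotype diversity with low nucleotide
diversity — the classic signature of a founder bottleneck followed by
growth — and its mismatch distribution is compatible with a spatial
expansion (non-significant SSD and raggedness); at the COI clock of
1.77×10⁻⁸ substitutions/site/year its fitted τ dates the expansion to
roughly 80 ka, close to the 65 ka colonization time this dataset was
actually simulated with (`truth["scenario"]`).

A CLI mirrors the library (`barcodepop collapse | distance | gap | network
| popgen | mismatch | simulate | abc | run`); `barcodepop run config.yaml`
executes the whole pipeline from one YAML config and writes per-stage
artifacts plus a JSON/Markdown report.

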