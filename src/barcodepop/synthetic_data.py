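"""Study-like synthetic barcode datasets with known ground truth.

The generator emulates the statistical structure of a typical two-species
phylogeographic barcode survey: one geographically structured species whose
three populations descend from a single source with founder bottlenecks
(simulated under the three-population colonization scenario), one widespread
species with a star-like haplotype cloud produced by a recent single-deme
expansion, and a small outgroup-like species.  Species roots are placed at
controlled divergences (>= 6% uncorrected p-distance) on a shared ancestral
sequence, so the barcoding gap exists by construction while the within- vs
between-species scales match the study system (intraspecific <= 2%).

Every dataset ships with a truth record (all parameters and seeds) so that
recovery experiments are self-describing.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .abc_inference import Prior, PriorSet
from .demog_sim import (
    DemographicScenario,
    MutationModel,
    decode_sequences,
    evolve_sequences,
    simulate_dataset,
    simulate_single_population,
)
from .sequence_io import LabeledAlignment, Record, write_fasta, write_metadata

#: insect-mtDNA-like base composition (AT rich)
DEFAULT_BASE_FREQS = (0.31, 0.15, 0.14, 0.40)
#: per-site per-year COI rate used throughout (mid-Aegean calibration scale)
DEFAULT_MU_YEAR = 1.77e-8


@dataclass
class StudyTemplate:
    """Parameters of the study-like generator (defaults = study conditions)."""

    L: int = 456
    mu_site_year: float = DEFAULT_MU_YEAR
    generations_per_year: float = 1.0
    kappa: float = 8.0
    gamma_shape: float = 1.1
    base_freqs: tuple[float, float, float, float] = DEFAULT_BASE_FREQS
    # structured species: three populations from one source, recent-expansion
    # scenario with founder bottlenecks (sample sizes mirror the study)
    structured_species: str = "structured_sp"
    structured_pops: tuple[str, str, str] = (
        "SoutheastAsia",
        "ArabiaSouthAsia",
        "Australia",
    )
    structured_n: tuple[int, int, int] = (20, 20, 15)
    scenario: DemographicScenario = field(
        default_factory=lambda: DemographicScenario(
            name="2-CG",
            N1=150_000,
            N2=120_000,
            N3=1_000_000,
            N2b=100,
            N3b=1_500,
            t1=143_000,
            t2=65_000,
            t_db=5_000,
        )
    )
    # star-like species: single deme, sudden expansion
    star_species: str = "starlike_sp"
    star_pop: str = "Eurasia"
    star_n: int = 39
    star_N_present: float = 400_000
    star_N_ancestral: float = 8_000
    star_t_expansion: float = 196_000
    # small outgroup-like species
    outgroup_species: str = "outgroup_sp"
    outgroup_pop: str = "Outgroup"
    outgroup_n: int = 3
    outgroup_N: float = 30_000
    # root divergences (proportion of sites substituted from the ancestor)
    star_root_divergence: float = 0.072
    outgroup_root_divergence: float = 0.085

    def mutation_model(self) -> MutationModel:
        return MutationModel(
            kappa=self.kappa,
            base_freqs=self.base_freqs,
            gamma_shape=self.gamma_shape,
            L=self.L,
            rate=self.mu_site_year / self.generations_per_year,
        )


def _divergent_root(
    ancestor: np.ndarray,
    n_subs: int,
    rng: np.random.Generator,
    forbidden: set[int],
) -> tuple[np.ndarray, set[int]]:
    """Substitute ``n_subs`` sites of the ancestor, avoiding ``forbidden``
    sites so that species-root differences do not overlap (keeps pairwise
    root divergences additive and controllable)."""
    free = np.array(sorted(set(range(len(ancestor))) - forbidden))
    sites = rng.choice(free, size=n_subs, replace=False)
    root = ancestor.copy()
    for s in sites:
        root[s] = rng.choice([b for b in range(4) if b != root[s]])
    return root, set(int(s) for s in sites)


def generate_study_like(
    template: StudyTemplate | None = None, seed: int = 0
) -> tuple[LabeledAlignment, dict]:
    """Generate a labelled multi-species alignment plus its truth record."""
    t = template or StudyTemplate()
    rng = np.random.default_rng(seed)
    model = t.mutation_model()
    ancestor = rng.choice(4, size=t.L, p=np.asarray(t.base_freqs))

    used: set[int] = set()
    star_root, sites = _divergent_root(
        ancestor, int(round(t.star_root_divergence * t.L)), rng, used
    )
    used |= sites
    out_root, sites = _divergent_root(
        ancestor, int(round(t.outgroup_root_divergence * t.L)), rng, used
    )
    used |= sites

    records: list[Record] = []

    # structured species via the three-population scenario
    sub_seed = int(rng.integers(1, 2**30))
    ds = simulate_dataset(
        t.scenario,
        model,
        *t.structured_n,
        seed=sub_seed,
        species=t.structured_species,
        root=ancestor,
    )
    pop_map = dict(zip(("pop1", "pop2", "pop3"), t.structured_pops))
    counters: dict[str, int] = {}
    for r in ds.alignment.records:
        pop = pop_map[r.population]
        counters[pop] = counters.get(pop, 0) + 1
        records.append(
            Record(
                id=f"{t.structured_species}_{pop}_{counters[pop]:03d}",
                sequence=r.sequence,
                species=t.structured_species,
                population=pop,
                locality=pop,
            )
        )

    # star-like species: recent sudden expansion in a single deme
    star_seed = int(rng.integers(1, 2**30))
    ts = simulate_single_population(
        t.star_n,
        t.star_N_present,
        seed=star_seed,
        size_changes=[(t.star_t_expansion, t.star_N_ancestral)],
    )
    mat, _ = evolve_sequences(ts, model, seed=star_seed + 1, root=star_root)
    for i, s in enumerate(decode_sequences(mat), start=1):
        records.append(
            Record(
                id=f"{t.star_species}_{t.star_pop}_{i:03d}",
                sequence=s,
                species=t.star_species,
                population=t.star_pop,
                locality=t.star_pop,
            )
        )

    # small outgroup-like species, constant size
    out_seed = int(rng.integers(1, 2**30))
    ts = simulate_single_population(t.outgroup_n, t.outgroup_N, seed=out_seed)
    mat, _ = evolve_sequences(ts, model, seed=out_seed + 1, root=out_root)
    for i, s in enumerate(decode_sequences(mat), start=1):
        records.append(
            Record(
                id=f"{t.outgroup_species}_{i:03d}",
                sequence=s,
                species=t.outgroup_species,
                population=t.outgroup_pop,
                locality=t.outgroup_pop,
            )
        )

    truth = {
        "seed": seed,
        "L": t.L,
        "mu_site_year": t.mu_site_year,
        "generations_per_year": t.generations_per_year,
        "kappa": t.kappa,
        "gamma_shape": t.gamma_shape,
        "base_freqs": list(t.base_freqs),
        "scenario": asdict(t.scenario),
        "structured_n": list(t.structured_n),
        "star": {
            "n": t.star_n,
            "N_present": t.star_N_present,
            "N_ancestral": t.star_N_ancestral,
            "t_expansion": t.star_t_expansion,
            "root_divergence": t.star_root_divergence,
        },
        "outgroup": {
            "n": t.outgroup_n,
            "N": t.outgroup_N,
            "root_divergence": t.outgroup_root_divergence,
        },
        "component_seeds": {
            "structured": sub_seed,
            "star": star_seed,
            "outgroup": out_seed,
        },
    }
    return LabeledAlignment(records), truth


def write_study_dataset(
    aln: LabeledAlignment, truth: dict, outdir: str | Path
) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(aln, out / "sequences.fasta")
    write_metadata(aln, out / "metadata.tsv")
    (out / "truth.json").write_text(json.dumps(truth, indent=2))


def study_priors(
    mu_low: float = 1.0e-8,
    mu_high: float = 3.0e-8,
    kappa: float = 8.0,
    gamma_shape: float | None = 1.1,
    size_high: float = 2e6,
    t_db_high: float = 10_000,
) -> dict[str, PriorSet]:
    """Default prior sets for the two colonization scenarios.

    Scenario "1-CG" places both splits before the Late Pleistocene (old
    divergences); "2-CG" allows recent, Late-Pleistocene colonizations.
    Bounds follow the mid-/Late-Pleistocene boundaries (~781 and ~126 ka,
    one generation per year); all bounds are plain data and fully
    overridable when a specific study's prior table must be matched.
    """
    shared = {
        "N1": Prior("loguniform", 1e4, size_high),
        "N2": Prior("loguniform", 1e4, size_high),
        "N3": Prior("loguniform", 1e4, size_high),
        "N2b": Prior("loguniform", 10, 1e4),
        "N3b": Prior("loguniform", 10, 1e4),
        "t_db": Prior("uniform", 100, t_db_high),
        "mu": Prior("loguniform", mu_low, mu_high),
    }
    recent = {
        **shared,
        "t1": Prior("uniform", 20_000, 781_000),
        "t2": Prior("uniform", 5_000, 126_000),
    }
    ancient = {
        **shared,
        "t1": Prior("uniform", 781_000, 2_000_000),
        "t2": Prior("uniform", 126_000, 781_000),
    }
    return {
        "1-CG": PriorSet(params=ancient, kappa=kappa, gamma_shape=gamma_shape),
        "2-CG": PriorSet(params=recent, kappa=kappa, gamma_shape=gamma_shape),
    }


def worked_toy() -> dict:
    """Tiny deterministic fixtures with hand-verifiable statistics.

    Returns a dict of named fixtures; each entry holds a LabeledAlignment
    and the hand-computed expected values used by the test suite.
    """
    def aln(species: str, seqs: list[str]) -> LabeledAlignment:
        return LabeledAlignment(
            [
                Record(
                    id=f"{species}{i+1}",
                    sequence=s,
                    species=species,
                    population="toy",
                )
                for i, s in enumerate(seqs)
            ]
        )

    base = "ACGTACGTACGTACGTACGT"
    identical = aln("ident", [base] * 4)

    hap_a = "AAAACCCCGGGGTTTTACGT"
    hap_b = "TAAAGCCCAGGGTTTTACGT"  # differs from hap_a at sites 0, 4, 8
    two_haps = aln("pair", [hap_a, hap_a, hap_b, hap_b])

    centre = "AAAAAAAAAAAA"
    s1 = "TAAAAAAAAAAA"
    s2 = "ATAAAAAAAAAA"
    s3 = "AATAAAAAAAAA"
    triangle = aln("tri", [s1, s2, s3])

    return {
        "identical": {
            "alignment": identical,
            "expected": {"h": 0.0, "pi": 0.0, "S": 0, "mismatch": {0: 6}},
        },
        "two_haplotypes": {
            "alignment": two_haps,
            "expected": {
                "h": 2.0 / 3.0,
                "S": 3,
                "mean_pairwise_diff": 2.0,
                "mismatch": {0: 2, 3: 4},
            },
        },
        "triangle": {
            "alignment": triangle,
            "expected": {
                "pairwise_hamming": 2,
                "median_vector": centre,
                "n_medians": 1,
                "edge_weights": [1, 1, 1],
            },
        },
    }
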