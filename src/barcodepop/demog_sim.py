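"""Coalescent simulation of three-population colonization scenarios.

The demographic object of interest is a source population (Pop1) from which
two daughter populations (Pop2 and Pop3) were independently founded, each
passing through a founder bottleneck of reduced effective size (N2b, N3b)
lasting ``t_db`` generations immediately after colonization.  Looking
backward in time, Pop3 has size N3 until ``t2 - t_db``, size N3b on
``[t2 - t_db, t2)``, and merges into Pop1 at ``t2``; Pop2 behaves
analogously at ``t1``.  There is no migration after the splits.  All sizes
are haploid effective numbers (maternally inherited mtDNA) and all times are
in generations; conversion to years happens only at reporting boundaries.

Genealogies are generated with msprime (``ploidy=1``); sequence evolution is
a bespoke HKY + discrete-gamma engine so that a user-supplied root sequence
can be evolved (needed to place several species at controlled divergences).
Mutations are placed by uniformization of the HKY rate matrix: per site with
relative rate r, a branch of b generations receives Poisson(b * mu * r *
lambda) candidate events, each resolved through the uniformized transition
matrix I + Q/lambda (self-transitions allowed), which samples the CTMC
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np

from .sequence_io import LabeledAlignment, Record

BASES = "ACGT"


class ScenarioError(ValueError):
    """Raised for demographic parameter combinations that violate geometry."""


@dataclass(frozen=True)
class DemographicScenario:
    """Three-population split-with-founder-bottleneck demography."""

    name: str
    N1: float
    N2: float
    N3: float
    N2b: float
    N3b: float
    t1: float  # Pop2 split, generations
    t2: float  # Pop3 split, generations
    t_db: float  # founder-bottleneck duration, generations

    def __post_init__(self) -> None:
        for attr in ("N1", "N2", "N3", "N2b", "N3b"):
            if getattr(self, attr) < 1:
                raise ScenarioError(f"{attr} must be >= 1")
        if not (self.t1 > self.t2 > 0):
            raise ScenarioError(
                f"split times must satisfy t1 > t2 > 0 (got t1={self.t1}, t2={self.t2})"
            )
        if not (0 <= self.t_db < min(self.t1, self.t2)):
            raise ScenarioError("t_db must satisfy 0 <= t_db < min(t1, t2)")
        if self.N2b > self.N2 or self.N3b > self.N3:
            raise ScenarioError("founder sizes must not exceed the descendant sizes")


def make_scenario(name: str, **params: float) -> DemographicScenario:
    """Validated scenario constructor; see DemographicScenario for geometry."""
    return DemographicScenario(name=name, **params)


@dataclass(frozen=True)
class MutationModel:
    """HKY substitution model with optional discrete-site gamma rates.

    ``rate`` is in substitutions per site per generation (already averaged
    over the gamma rates, which have mean 1).  ``gamma_shape=None`` means
    rate-homogeneous sites.
    """

    kappa: float = 2.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: float | None = None
    L: int = 456
    rate: float = 1e-8

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.rate < 0 or self.L <= 0:
            raise ValueError("kappa, rate and L must be positive")
        f = np.asarray(self.base_freqs, dtype=float)
        if (f < 0).any() or abs(f.sum() - 1.0) > 1e-8:
            raise ValueError("base_freqs must be non-negative and sum to 1")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")

    def rate_matrix(self) -> np.ndarray:
        """HKY generator normalised to one expected substitution per unit time."""
        pi = np.asarray(self.base_freqs, dtype=float)
        Q = np.zeros((4, 4))
        transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                Q[i, j] = pi[j] * (self.kappa if (i, j) in transitions else 1.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mean_rate = float(-np.sum(pi * np.diag(Q)))
        return Q / mean_rate


def _msprime_seed(seed: int | None) -> int | None:
    if seed is None:
        return None
    return int(seed) % (2**31 - 1) + 1


def scenario_demography(scn: DemographicScenario) -> msprime.Demography:
    demog = msprime.Demography()
    demog.add_population(name="pop1", initial_size=scn.N1)
    demog.add_population(name="pop2", initial_size=scn.N2)
    demog.add_population(name="pop3", initial_size=scn.N3)
    if scn.t_db > 0:
        demog.add_population_parameters_change(
            time=scn.t1 - scn.t_db, population="pop2", initial_size=scn.N2b
        )
        demog.add_population_parameters_change(
            time=scn.t2 - scn.t_db, population="pop3", initial_size=scn.N3b
        )
    # pop1 persists to the present, so the colonizations are expressed as
    # backward lineage movements rather than population splits (which would
    # deactivate the ancestral deme at sampling time)
    demog.add_mass_migration(time=scn.t2, source="pop3", dest="pop1", proportion=1.0)
    demog.add_mass_migration(time=scn.t1, source="pop2", dest="pop1", proportion=1.0)
    demog.sort_events()
    return demog


def simulate_genealogy(
    scn: DemographicScenario,
    n1: int,
    n2: int,
    n3: int,
    seed: int | None = None,
):
    """Genealogy (tskit TreeSequence, one non-recombining tree) of a sample
    of n1/n2/n3 haploid sequences from the three populations."""
    if min(n1, n2, n3) < 1:
        raise ValueError("sample sizes must be >= 1")
    return msprime.sim_ancestry(
        samples={"pop1": n1, "pop2": n2, "pop3": n3},
        demography=scenario_demography(scn),
        ploidy=1,
        sequence_length=1,
        random_seed=_msprime_seed(seed),
    )


def simulate_single_population(
    n: int,
    N_present: float,
    seed: int | None = None,
    size_changes: list[tuple[float, float]] | None = None,
):
    """Single-deme genealogy with optional backward size changes.

    ``size_changes`` is a list of (time_generations, size) applied backward
    in time, e.g. ``[(t_exp, N_ancestral)]`` for a sudden expansion that
    happened ``t_exp`` generations ago.
    """
    demog = msprime.Demography()
    demog.add_population(name="pop0", initial_size=N_present)
    for t, size in size_changes or []:
        demog.add_population_parameters_change(
            time=t, population="pop0", initial_size=size
        )
    demog.sort_events()
    return msprime.sim_ancestry(
        samples={"pop0": n},
        demography=demog,
        ploidy=1,
        sequence_length=1,
        random_seed=_msprime_seed(seed),
    )


def evolve_sequences(
    ts,
    model: MutationModel,
    seed: int | None = None,
    root: np.ndarray | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Evolve sequences down a genealogy under HKY (+ gamma rates).

    Returns an integer-coded (samples, L) matrix in the order of
    ``ts.samples()`` and the per-sample population names.  ``root`` may fix
    the ancestral sequence (codes 0..3); otherwise it is drawn from the
    model's base frequencies.
    """
    rng = np.random.default_rng(seed)
    L = model.L
    if model.gamma_shape is None:
        rel = np.ones(L)
    else:
        rel = rng.gamma(model.gamma_shape, 1.0 / model.gamma_shape, size=L)
    site_rate = model.rate * rel  # substitutions/site/generation
    Q = model.rate_matrix()
    lam = float(np.max(-np.diag(Q)))
    U = np.eye(4) + Q / lam
    U = np.clip(U, 0.0, None)
    U /= U.sum(axis=1, keepdims=True)

    pi = np.asarray(model.base_freqs)
    tree = ts.first()
    node_time = ts.tables.nodes.time

    seqs: dict[int, np.ndarray] = {}
    roots = list(tree.roots)
    if len(roots) != 1:
        raise ValueError("genealogy must have a single root")
    root_node = roots[0]
    if root is None:
        seqs[root_node] = rng.choice(4, size=L, p=pi)
    else:
        seqs[root_node] = np.asarray(root, dtype=np.int64).copy()

    event_rate = site_rate * lam
    stack = [root_node]
    order = []
    while stack:
        u = stack.pop()
        order.append(u)
        stack.extend(tree.children(u))
    for u in order:
        if u == root_node:
            continue
        parent = tree.parent(u)
        b = float(node_time[parent] - node_time[u])
        seq = seqs[parent].copy()
        ks = rng.poisson(b * event_rate)
        for i in np.nonzero(ks)[0]:
            state = seq[i]
            for _ in range(ks[i]):
                state = rng.choice(4, p=U[state])
            seq[i] = state
        seqs[u] = seq
    samples = list(ts.samples())
    mat = np.vstack([seqs[int(u)] for u in samples])
    pop_names = []
    for u in samples:
        pid = ts.node(int(u)).population
        meta = ts.population(pid).metadata
        pop_names.append(meta.get("name", f"pop{pid}") if meta else f"pop{pid}")
    return mat, pop_names


def decode_sequences(mat: np.ndarray) -> list[str]:
    lut = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    return [bytes(lut[row]).decode() for row in np.asarray(mat, dtype=np.int64)]


@dataclass
class SimulatedDataset:
    """Alignment simulated under a known demographic scenario."""

    alignment: LabeledAlignment
    scenario: DemographicScenario
    model: MutationModel
    seed: int | None
    sample_sizes: tuple[int, int, int]
    extras: dict = field(default_factory=dict)


def simulate_dataset(
    scn: DemographicScenario,
    model: MutationModel,
    n1: int,
    n2: int,
    n3: int,
    seed: int | None = None,
    species: str = "simulated",
    root: np.ndarray | None = None,
) -> SimulatedDataset:
    """Simulate a labelled three-population alignment under a scenario."""
    ts = simulate_genealogy(scn, n1, n2, n3, seed=seed)
    mat, pops = evolve_sequences(
        ts, model, seed=None if seed is None else seed + 101, root=root
    )
    seqs = decode_sequences(mat)
    counters: dict[str, int] = {}
    records = []
    for s, pop in zip(seqs, pops):
        counters[pop] = counters.get(pop, 0) + 1
        records.append(
            Record(
                id=f"{pop}_{counters[pop]:03d}",
                sequence=s,
                species=species,
                population=pop,
                locality=pop,
            )
        )
    return SimulatedDataset(
        alignment=LabeledAlignment(records),
        scenario=scn,
        model=model,
        seed=seed,
        sample_sizes=(n1, n2, n3),
    )
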