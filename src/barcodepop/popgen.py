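"""Diversity indexes, neutrality tests and mismatch-distribution fitting.

This module covers the within-population toolkit for barcode data:

* haplotype diversity *h*, nucleotide diversity *pi*, segregating sites *S*
  and the mean number of pairwise differences;
* Tajima's *D* and Fu's *Fs* with P-values obtained from neutral
  constant-size coalescent simulations conditioned on the observed sample
  size and estimated theta;
* the mismatch distribution (pairwise-difference spectrum), least-squares
  fitting of sudden- and spatial-expansion models with parametric-bootstrap
  P-values for the SSD and Harpending's raggedness statistics;
* conversion of the fitted expansion age tau (mutational time units) to
  generations and years, t = tau / (2u) with u the per-sequence
  per-generation mutation rate.

Time inside the fitting/bootstrap machinery is measured in "tau units"
(units of 1/(2u) generations): a pair of lineages whose ancestries have been
separate for t tau-units accumulates Poisson(t) differences, and a single
branch of duration t carries Poisson(t/2) mutations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from .distances import encode, p_distance_matrix
from .sequence_io import LabeledAlignment

__all__ = [
    "DiversitySummary",
    "MismatchFit",
    "ExpansionTime",
    "diversity",
    "tajimas_d",
    "tajima_constants",
    "fus_fs",
    "ewens_k_tail",
    "grant_bowen_class",
    "mismatch_observed",
    "expected_mismatch",
    "raggedness",
    "fit_expansion",
    "expansion_time",
    "pairwise_diff_matrix",
    "simulate_coalescent_diffs",
]


def _sequences(sample: LabeledAlignment | Sequence[str]) -> list[str]:
    if isinstance(sample, LabeledAlignment):
        return sample.sequences
    return list(sample)


def pairwise_diff_matrix(sample: LabeledAlignment | Sequence[str]) -> np.ndarray:
    """Absolute pairwise nucleotide differences under pairwise deletion."""
    seqs = _sequences(sample)
    enc = encode(seqs)
    valid = enc < 4
    n = len(seqs)
    out = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        d = ((enc[i] != enc[i + 1 :]) & both).sum(axis=1)
        out[i, i + 1 :] = d
    return out + out.T


def segregating_sites(sample: LabeledAlignment | Sequence[str]) -> int:
    """Number of polymorphic columns (>= 2 distinct valid bases)."""
    enc = encode(_sequences(sample))
    s = 0
    for col in enc.T:
        bases = np.unique(col[col < 4])
        if len(bases) >= 2:
            s += 1
    return s


# ------------------------------------------------------------ diversity --


@dataclass
class DiversitySummary:
    n: int
    S: int
    h: float
    pi: float  # per site
    mean_pairwise_diff: float  # per sequence
    grant_bowen: str


def grant_bowen_class(h: float, pi: float) -> str:
    """Four-quadrant h/pi classification (thresholds h = 0.5, pi = 0.5%).

    Values exactly on a threshold are assigned to the "small" side.
    Categories: large haplotype diversity with small nucleotide diversity is
    the classic bottleneck-then-rapid-growth signature; large/large suggests
    a large stable population or secondary contact.
    """
    hcat = "large-h" if h > 0.5 else "small-h"
    pcat = "large-pi" if pi > 0.005 else "small-pi"
    return f"{hcat}/{pcat}"


def diversity(sample: LabeledAlignment | Sequence[str]) -> DiversitySummary:
    """Haplotype diversity, nucleotide diversity, S and mean differences.

    h = n/(n-1) * (1 - sum p_i^2) over haplotype frequencies; pi is the mean
    pairwise p-distance per site; differences use pairwise deletion.
    """
    seqs = _sequences(sample)
    n = len(seqs)
    if n < 2:
        raise ValueError("diversity requires at least two sequences")
    counts: dict[str, int] = {}
    for s in seqs:
        counts[s] = counts.get(s, 0) + 1
    freqs = np.array(list(counts.values())) / n
    h = n / (n - 1) * (1.0 - float(np.sum(freqs**2)))
    if isinstance(sample, LabeledAlignment):
        aln = sample
    else:
        from .sequence_io import Record

        aln = LabeledAlignment(
            [Record(id=f"s{i}", sequence=s, species="", population="") for i, s in enumerate(seqs)]
        )
    dm = p_distance_matrix(aln)
    iu = np.triu_indices(n, k=1)
    pi = float(np.mean(dm.values[iu]))
    diffs = pairwise_diff_matrix(seqs)
    kbar = float(np.mean(diffs[iu]))
    return DiversitySummary(
        n=n,
        S=segregating_sites(seqs),
        h=h,
        pi=pi,
        mean_pairwise_diff=kbar,
        grant_bowen=grant_bowen_class(h, pi),
    )


# -------------------------------------------------------------- Tajima D --


def tajima_constants(n: int) -> dict[str, float]:
    """The standard a1..e2 normalising constants for a sample of size n."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def _tajima_d_from(kbar: float, S: int, n: int) -> float:
    c = tajima_constants(n)
    denom = math.sqrt(c["e1"] * S + c["e2"] * S * (S - 1))
    if denom == 0:
        return math.nan
    return (kbar - S / c["a1"]) / denom


def tajimas_d(
    sample: LabeledAlignment | Sequence[str],
    n_sims: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Tajima's D with a P-value from neutral coalescent simulation.

    P is the fraction of neutral constant-size replicates (conditioned on n,
    with theta_W = S/a1) whose D is <= the observed D.  Returns (nan, nan)
    when the statistic is undefined (S = 0 or n < 4).
    """
    seqs = _sequences(sample)
    n = len(seqs)
    S = segregating_sites(seqs)
    if n < 4 or S == 0:
        return (math.nan, math.nan)
    diffs = pairwise_diff_matrix(seqs)
    kbar = float(np.mean(diffs[np.triu_indices(n, k=1)]))
    d_obs = _tajima_d_from(kbar, S, n)
    theta_w = S / tajima_constants(n)["a1"]
    rng = np.random.default_rng(seed)
    count = 0
    used = 0
    for _ in range(n_sims):
        dsim, s_sim = _sim_stats(n, theta_w, rng)
        if s_sim == 0:
            continue
        used += 1
        kb = float(np.mean(dsim[np.triu_indices(n, k=1)]))
        if _tajima_d_from(kb, s_sim, n) <= d_obs:
            count += 1
    p = count / used if used else math.nan
    return d_obs, p


# --------------------------------------------------------------- Fu's Fs --


def _stirling_row(n: int) -> list[int]:
    """Unsigned Stirling numbers of the first kind |s(n, k)|, k = 0..n."""
    row = [1]  # n = 0
    for m in range(n):
        new = [0] * (len(row) + 1)
        for k, v in enumerate(row):
            new[k] += m * v
            new[k + 1] += v
        row = new
    return row


def ewens_k_tail(n: int, k_obs: int, theta: float) -> float:
    """P(K >= k_obs) for the number of alleles under the Ewens distribution.

    P(K = k) = |s(n,k)| theta^k / theta^(n) with theta^(n) the rising
    factorial; computed in log space.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    row = _stirling_row(n)
    log_rise = float(np.sum(np.log(theta + np.arange(n))))
    logs = [
        math.log(row[k]) + k * math.log(theta) - log_rise for k in range(k_obs, n + 1)
    ]
    return float(np.exp(special.logsumexp(logs)))


def _fs_from(n: int, k: int, theta: float) -> float:
    sp = ewens_k_tail(n, k, theta)
    sp = min(max(sp, 1e-300), 1 - 1e-16)
    return math.log(sp / (1 - sp))


def fus_fs(
    sample: LabeledAlignment | Sequence[str],
    n_sims: int = 1000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Fu's Fs with a P-value from neutral coalescent simulation.

    Fs = ln(S'/(1-S')) where S' = P(K >= observed haplotype count) under the
    Ewens sampling distribution at theta = mean pairwise differences.
    P is the fraction of neutral replicates with Fs <= observed (the
    conventional one-sided test; an excess of rare haplotypes drives Fs
    negative).  Returns (nan, nan) when theta-hat = 0.
    """
    seqs = _sequences(sample)
    n = len(seqs)
    if n < 2:
        raise ValueError("Fu's Fs requires at least two sequences")
    diffs = pairwise_diff_matrix(seqs)
    iu = np.triu_indices(n, k=1)
    theta = float(np.mean(diffs[iu]))
    if theta == 0:
        return (math.nan, math.nan)
    k_obs = len(set(seqs))
    fs_obs = _fs_from(n, k_obs, theta)
    rng = np.random.default_rng(seed)
    count = 0
    used = 0
    for _ in range(n_sims):
        dsim, _ = _sim_stats(n, theta, rng)
        th = float(np.mean(dsim[iu]))
        if th == 0:
            continue
        k_sim = _haplotype_count_from_diffs(dsim)
        used += 1
        if _fs_from(n, k_sim, th) <= fs_obs:
            count += 1
    p = count / used if used else math.nan
    return fs_obs, p


def _haplotype_count_from_diffs(diffs: np.ndarray) -> int:
    n = diffs.shape[0]
    seen: list[int] = []
    for i in range(n):
        if not any(diffs[i, j] == 0 for j in seen):
            seen.append(i)
    return len(seen)


# ------------------------------------------------- coalescent simulators --


def simulate_coalescent_diffs(
    n: int,
    theta: float,
    rng: np.random.Generator,
    model: str = "constant",
    tau: float = 0.0,
    M: float = 0.0,
) -> tuple[np.ndarray, int]:
    """One coalescent replicate under the infinite-sites model.

    Returns the pairwise-difference matrix together with the total number of
    mutations placed (= segregating sites, since every mutation falls below
    the sample MRCA and hits a fresh site).

    Time is in tau-units; mutations fall on branches at rate 1/2 per unit so
    an equilibrium pair shows Geometric(mean theta) differences.

    models:
      constant -- single panmictic deme, scaled size theta, for all time;
      sudden   -- no coalescence during the most recent tau units (the
                  post-expansion population is effectively infinite), then a
                  panmictic ancestral deme of scaled size theta;
      spatial  -- infinite-island phase during the most recent tau units
                  (all n lineages sampled from one deme; within-deme pair
                  coalescence rate 1/theta, per-lineage emigration rate
                  M/theta, emigrants land in empty demes), then a panmictic
                  ancestral deme of scaled size theta.
    """
    masks = [np.zeros(n, dtype=bool) for _ in range(n)]
    for i in range(n):
        masks[i][i] = True
    diffs = np.zeros((n, n), dtype=np.int64)
    n_mut = 0

    def drop_mutations(active: list[int], dt: float) -> None:
        nonlocal n_mut
        for li in active:
            k = rng.poisson(dt / 2.0)
            if k:
                n_mut += k
                m = masks[li]
                cross = m[:, None] ^ m[None, :]
                diffs[cross] += k

    active = list(range(n))
    if model == "sudden":
        drop_mutations(active, tau)
    elif model == "spatial":
        # migrants always land in fresh, empty demes, so a lineage that is
        # alone in its deme can neither coalesce nor be joined: its further
        # migrations are distributionally irrelevant and are skipped, which
        # bounds the phase at O(n) events even for tiny theta
        deme = {li: 0 for li in active}
        next_deme = 1
        t = 0.0
        while len(active) > 1:
            by_deme: dict[int, list[int]] = {}
            for li in active:
                by_deme.setdefault(deme[li], []).append(li)
            multi = {d: ls for d, ls in by_deme.items() if len(ls) >= 2}
            coal_rates = {
                d: len(ls) * (len(ls) - 1) / 2.0 / theta for d, ls in multi.items()
            }
            coal_total = sum(coal_rates.values())
            movable = [li for ls in multi.values() for li in ls]
            mig_total = len(movable) * M / theta
            total = coal_total + mig_total
            if total <= 0:
                drop_mutations(active, tau - t)
                t = tau
                break
            dt = rng.exponential(1.0 / total)
            if t + dt >= tau:
                drop_mutations(active, tau - t)
                t = tau
                break
            drop_mutations(active, dt)
            t += dt
            if rng.random() < coal_total / total:
                ds = list(coal_rates)
                w = np.array([coal_rates[d] for d in ds])
                d = ds[rng.choice(len(ds), p=w / w.sum())]
                ls = multi[d]
                i, j = rng.choice(len(ls), size=2, replace=False)
                a, b = ls[i], ls[j]
                masks[a] = masks[a] | masks[b]
                active.remove(b)
            else:
                li = movable[rng.integers(len(movable))]
                deme[li] = next_deme
                next_deme += 1
    elif model != "constant":
        raise ValueError(f"unknown model {model!r}")

    # panmictic (ancestral) phase: Kingman, pair rate 1/theta
    while len(active) > 1:
        k = len(active)
        rate = k * (k - 1) / 2.0 / theta
        dt = rng.exponential(1.0 / rate)
        drop_mutations(active, dt)
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        masks[a] = masks[a] | masks[b]
        active.remove(b)
    return diffs, n_mut


def _sim_stats(n: int, theta: float, rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """One neutral constant-size replicate: (diff matrix, segregating sites)."""
    return simulate_coalescent_diffs(n, theta, rng, model="constant")


# ------------------------------------------------ mismatch distributions --


def mismatch_observed(sample: LabeledAlignment | Sequence[str]) -> np.ndarray:
    """Counts of sequence pairs by number of nucleotide differences.

    Index j holds the number of pairs differing at exactly j sites; the
    vector sums to n(n-1)/2.
    """
    diffs = pairwise_diff_matrix(sample)
    n = diffs.shape[0]
    if n < 2:
        raise ValueError("mismatch distribution requires at least two sequences")
    vals = diffs[np.triu_indices(n, k=1)]
    out = np.bincount(vals)
    return out


def _conv_pois_geom(tau: float, theta: float, jmax: int) -> np.ndarray:
    """Convolution of Poisson(tau) with Geometric(theta): the sudden model."""
    j = np.arange(jmax + 1)
    pois = stats.poisson.pmf(j, tau) if tau > 0 else np.where(j == 0, 1.0, 0.0)
    geom = (theta**j) / (1.0 + theta) ** (j + 1)
    return np.convolve(pois, geom)[: jmax + 1]


def expected_mismatch(
    model: str, params: Sequence[float], n_classes: int
) -> np.ndarray:
    """Expected mismatch probabilities F_0..F_{n_classes-1}.

    sudden: params = (tau, theta); the population is effectively infinite
    after the expansion, so pairs carry Poisson(tau) recent mutations on top
    of an equilibrium Geometric(theta) ancestral difference.  At tau = 0 this
    is the equilibrium form F_j = theta^j / (theta+1)^(j+1).

    spatial: params = (tau, theta, M); infinite-island model where the two
    lineages of a within-deme pair may coalesce locally (rate 1/theta) or
    separate by migration (pair rate 2M/theta) before the expansion time tau,
    beyond which a panmictic ancestral deme of size theta applies:
    F_j = A_j + w * sudden_j(tau, theta), with A_j the within-deme recent
    coalescence term and w the probability of reaching the ancestral phase.
    """
    jmax = n_classes - 1
    if model == "sudden":
        tau, theta = params
        return _conv_pois_geom(tau, theta, jmax)
    if model == "spatial":
        tau, theta, M = params
        j = np.arange(jmax + 1)
        b = (1.0 + 2.0 * M) / theta
        A = (1.0 / theta) * (1.0 + b) ** -(j + 1) * special.gammainc(j + 1, (1.0 + b) * tau)
        w = math.exp(-b * tau) + (2.0 * M / (1.0 + 2.0 * M)) * (1.0 - math.exp(-b * tau))
        return A + w * _conv_pois_geom(tau, theta, jmax)
    raise ValueError(f"unknown model {model!r}")


def raggedness(freqs: Sequence[float]) -> float:
    """Harpending's raggedness index of a (relative) mismatch distribution."""
    x = np.asarray(freqs, dtype=float)
    x = np.append(x, 0.0)
    return float(np.sum(np.diff(x) ** 2))


@dataclass
class MismatchFit:
    """Least-squares expansion fit to an observed mismatch distribution."""

    observed: np.ndarray
    model: str
    tau: float
    theta: float
    M: float
    ssd: float
    raggedness: float
    expected: np.ndarray
    n: int
    p_ssd: float = math.nan
    p_raggedness: float = math.nan
    converged: bool = True
    n_boot: int = 0


def _lumped_expected(model: str, params: Sequence[float], n_classes: int) -> np.ndarray:
    f = expected_mismatch(model, params, n_classes)
    f = np.clip(f, 0.0, 1.0)
    tail = max(0.0, 1.0 - float(np.sum(f[:-1])))
    f = f.copy()
    f[-1] = tail
    return f


def _fit_once(p_obs: np.ndarray, model: str, mbar: float, full: bool = True):
    n_classes = len(p_obs)

    # keep the search inside a numerically safe box; the box is far wider
    # than any biologically sensible estimate
    lo = np.log([1e-4, 1e-3, 1e-4])[: 2 if model == "sudden" else 3]
    hi = np.log([1e3, 1e3, 1e4])[: 2 if model == "sudden" else 3]

    def ssd_of(logp: np.ndarray) -> float:
        params = np.exp(np.clip(logp, lo, hi))
        f = _lumped_expected(model, params, n_classes)
        return float(np.sum((p_obs - f) ** 2))

    taus = [0.5 * max(mbar, 0.5), max(mbar, 0.5), 2.0 * max(mbar, 0.5)]
    thetas = [0.05 * mbar + 0.02, max(mbar, 0.2)]
    Ms = [0.5, 5.0, 50.0]
    if not full:
        taus = taus[1:2] + taus[0:1]
        Ms = Ms[:2]
    starts = []
    for t in taus:
        for th in thetas:
            if model == "sudden":
                starts.append(np.log([t, th]))
            else:
                for m in Ms:
                    starts.append(np.log([t, th, m]))
    best = None
    for x0 in starts:
        res = optimize.minimize(
            ssd_of, x0, method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    params = np.exp(np.clip(best.x, lo, hi))
    return params, float(best.fun), bool(best.success)


def fit_expansion(
    observed: Sequence[int],
    n: int | None = None,
    model: str = "spatial",
    n_boot: int = 0,
    seed: int | None = None,
) -> MismatchFit:
    """Fit a demographic-expansion model to an observed mismatch distribution.

    Minimises the sum of squared deviations (SSD) between the observed
    relative mismatch frequencies and the model expectation (expected mass
    beyond the last observed class is lumped into that class), using
    multi-start Nelder-Mead on log-parameters.

    With ``n_boot`` > 0, P-values for SSD and raggedness come from a
    parametric bootstrap: ``n_boot`` coalescent replicates are simulated
    under the fitted model, each is refitted, and the P-value is the
    fraction of replicates with simulated SSD (resp. raggedness) at least as
    large as observed.
    """
    obs = np.asarray(observed, dtype=float)
    total = float(obs.sum())
    if total <= 0:
        raise ValueError("observed mismatch vector is empty")
    if n is None:
        n = int(round((1 + math.sqrt(1 + 8 * total)) / 2))
    p_obs = obs / total
    mbar = float(np.sum(np.arange(len(obs)) * p_obs))
    params, ssd, ok = _fit_once(p_obs, model, mbar)
    tau, theta = float(params[0]), float(params[1])
    M = float(params[2]) if model == "spatial" else math.nan
    fit = MismatchFit(
        observed=obs.astype(int),
        model=model,
        tau=tau,
        theta=theta,
        M=M,
        ssd=ssd,
        raggedness=raggedness(p_obs),
        expected=_lumped_expected(model, params, len(obs)),
        n=n,
        converged=ok,
        n_boot=n_boot,
    )
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        ssd_ge = 0
        rag_ge = 0
        # keep refits on a bounded class range even if a replicate under an
        # extreme fit produces very large pairwise differences
        cap = max(2 * len(obs), 40)
        for _ in range(n_boot):
            diffs, _ = simulate_coalescent_diffs(
                n, theta, rng, model=model, tau=tau, M=0.0 if math.isnan(M) else M
            )
            vals = np.minimum(diffs[np.triu_indices(n, k=1)], cap)
            sim_counts = np.bincount(vals)
            p_sim = sim_counts / sim_counts.sum()
            mb = float(np.sum(np.arange(len(p_sim)) * p_sim))
            _, ssd_sim, _ = _fit_once(p_sim, model, mb, full=False)
            if ssd_sim >= ssd:
                ssd_ge += 1
            if raggedness(p_sim) >= fit.raggedness:
                rag_ge += 1
        fit.p_ssd = ssd_ge / n_boot
        fit.p_raggedness = rag_ge / n_boot
    return fit


# -------------------------------------------------------- expansion time --


@dataclass
class ExpansionTime:
    tau: float
    mu_site_year: float
    L: int
    generations_per_year: float
    t_generations: float
    t_years: float


def expansion_time(
    tau: float,
    mu_site_year: float,
    L: int,
    generations_per_year: float = 1.0,
) -> ExpansionTime:
    """Convert a mismatch tau to time since expansion, t = tau / (2u).

    u is the mutation rate per sequence per generation, assembled from the
    per-site per-year rate, the sequence length L and the number of
    generations per year; t_years = t_generations / generations_per_year.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    if mu_site_year <= 0 or L <= 0 or generations_per_year <= 0:
        raise ValueError("rate, length and generations/year must be positive")
    u = mu_site_year * L / generations_per_year
    t_gen = tau / (2.0 * u)
    return ExpansionTime(
        tau=tau,
        mu_site_year=mu_site_year,
        L=L,
        generations_per_year=generations_per_year,
        t_generations=t_gen,
        t_years=t_gen / generations_per_year,
    )


# ---------------------------------------------------------- full summary --


def population_summary(
    sample: LabeledAlignment,
    n_sims: int = 1000,
    seed: int | None = None,
    mismatch_model: str = "spatial",
    n_boot: int = 0,
) -> dict:
    """One-population summary: diversity, neutrality tests and mismatch fit."""
    div = diversity(sample)
    d, d_p = tajimas_d(sample, n_sims=n_sims, seed=seed)
    fs, fs_p = fus_fs(sample, n_sims=n_sims, seed=None if seed is None else seed + 1)
    obs = mismatch_observed(sample)
    fit = fit_expansion(
        obs, n=div.n, model=mismatch_model, n_boot=n_boot,
        seed=None if seed is None else seed + 2,
    )
    return {
        "n": div.n,
        "S": div.S,
        "h": div.h,
        "pi": div.pi,
        "mean_pairwise_diff": div.mean_pairwise_diff,
        "grant_bowen": div.grant_bowen,
        "tajima_D": d,
        "tajima_P": d_p,
        "fu_Fs": fs,
        "fu_P": fs_p,
        "tau": fit.tau,
        "theta": fit.theta,
        "M": fit.M,
        "ssd": fit.ssd,
        "p_ssd": fit.p_ssd,
        "raggedness": fit.raggedness,
        "p_raggedness": fit.p_raggedness,
    }
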