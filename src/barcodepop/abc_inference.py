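"""Approximate Bayesian computation over demographic scenarios.

Workflow: draw a scenario and a parameter vector from priors, simulate a
three-population dataset with :mod:`barcodepop.demog_sim`, reduce it to a
fixed vector of summary statistics, and store everything in a reference
table.  Scenario choice then uses either the *direct* estimate (scenario
frequencies among the k nearest simulations in normalised summary space) or
a polychotomous *logistic regression* of the scenario indicator on summary
differences over the closest fraction of rows, evaluated at zero difference.
Parameter estimation applies the classic local-linear regression adjustment
to the retained draws (log scale for the strictly positive parameters).

Summary statistics (DIYABC-style one- and two-sample set): per population
the haplotype count, segregating sites, mean and variance of pairwise
differences, Tajima's D (0 with an NA indicator when undefined) and private
segregating sites; per population pair the mean between-population pairwise
difference, Fst and the shared-haplotype count.  Statistics are normalised
by their median absolute deviation over the reference table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .demog_sim import (
    DemographicScenario,
    MutationModel,
    ScenarioError,
    evolve_sequences,
    simulate_genealogy,
)
from .popgen import _tajima_d_from
from .sequence_io import LabeledAlignment
from .distances import encode

DEFAULT_BASE_FREQS = (0.25, 0.25, 0.25, 0.25)
PARAM_ORDER = ["N1", "N2", "N3", "N2b", "N3b", "t1", "t2", "t_db", "mu"]


@dataclass(frozen=True)
class Prior:
    """Uniform or log-uniform prior on one scalar parameter."""

    kind: str  # "uniform" | "loguniform" | "fixed"
    low: float
    high: float = math.nan

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "loguniform", "fixed"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if self.kind != "fixed":
            if not (math.isfinite(self.low) and math.isfinite(self.high)):
                raise ValueError("prior bounds must be finite")
            if not self.low < self.high:
                raise ValueError("prior bounds must be ordered low < high")
            if self.kind == "loguniform" and self.low <= 0:
                raise ValueError("loguniform prior requires positive bounds")

    def draw(self, rng: np.random.Generator) -> float:
        if self.kind == "fixed":
            return self.low
        if self.kind == "uniform":
            return float(rng.uniform(self.low, self.high))
        return float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))


@dataclass
class PriorSet:
    """Per-parameter priors for one scenario.

    Must contain the demographic parameters N1, N2, N3, N2b, N3b, t1, t2,
    t_db and the per-site per-generation mutation rate ``mu``; ``kappa`` and
    ``gamma_shape`` may be given as priors too, otherwise the fixed defaults
    apply.
    """

    params: dict[str, Prior]
    kappa: float = 2.0
    gamma_shape: float | None = None

    def __post_init__(self) -> None:
        missing = [p for p in PARAM_ORDER if p not in self.params]
        if missing:
            raise ValueError(f"priors missing for parameters: {missing}")

    def draw(self, rng: np.random.Generator) -> dict[str, float]:
        return {name: prior.draw(rng) for name, prior in self.params.items()}


# ----------------------------------------------------- summary statistics --


def _pop_pair_diffs(sub: np.ndarray) -> np.ndarray:
    valid = sub < 4
    n = sub.shape[0]
    out = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        out[i, i + 1 :] = ((sub[i] != sub[i + 1 :]) & both).sum(axis=1)
    return out + out.T


def _seg_sites_mask(sub: np.ndarray) -> np.ndarray:
    """Boolean mask over columns that are polymorphic within ``sub``."""
    valid = sub < 4
    vmin = np.where(valid, sub, 10).min(axis=0)
    vmax = np.where(valid, sub, -1).max(axis=0)
    return (vmax > vmin) & (vmin < 4)


def summary_statistic_names(pop_names: list[str]) -> list[str]:
    names = []
    for p in pop_names:
        names += [
            f"{p}:K",
            f"{p}:S",
            f"{p}:mean_pairdiff",
            f"{p}:var_pairdiff",
            f"{p}:tajima_D",
            f"{p}:tajima_D_na",
            f"{p}:private_S",
        ]
    for i, a in enumerate(pop_names):
        for b in pop_names[i + 1 :]:
            names += [f"{a}-{b}:between_mean", f"{a}-{b}:fst", f"{a}-{b}:shared_K"]
    return names


def summary_statistics(
    mat: np.ndarray, pops: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Summary vector of an integer-coded alignment with population labels."""
    pop_names = sorted(set(pops))
    idx = {p: [i for i, q in enumerate(pops) if q == p] for p in pop_names}
    values: list[float] = []
    seg_masks: dict[str, np.ndarray] = {p: _seg_sites_mask(mat[idx[p]]) for p in pop_names}
    within_mean: dict[str, float] = {}
    hap_sets: dict[str, set[bytes]] = {}
    for p in pop_names:
        sub = mat[idx[p]]
        n = sub.shape[0]
        diffs = _pop_pair_diffs(sub)
        iu = np.triu_indices(n, k=1)
        vals = diffs[iu]
        kbar = float(vals.mean()) if vals.size else 0.0
        kvar = float(vals.var(ddof=1)) if vals.size > 1 else 0.0
        S = int(seg_masks[p].sum())
        haps = {row.tobytes() for row in sub}
        hap_sets[p] = haps
        within_mean[p] = kbar
        if n >= 4 and S >= 1:
            d = _tajima_d_from(kbar, S, n)
            d_val, d_na = (0.0, 1.0) if math.isnan(d) else (d, 0.0)
        else:
            d_val, d_na = 0.0, 1.0
        others = [i for q in pop_names if q != p for i in idx[q]]
        other_poly = _seg_sites_mask(mat[others]) if others else np.zeros(mat.shape[1], bool)
        private = int((seg_masks[p] & ~other_poly).sum())
        values += [len(haps), S, kbar, kvar, d_val, d_na, private]
    for i, a in enumerate(pop_names):
        for b in pop_names[i + 1 :]:
            sa, sb = mat[idx[a]], mat[idx[b]]
            va, vb = sa < 4, sb < 4
            cross = np.zeros((sa.shape[0], sb.shape[0]), dtype=np.int64)
            for r in range(sa.shape[0]):
                both = va[r] & vb
                cross[r] = ((sa[r] != sb) & both).sum(axis=1)
            between = float(cross.mean())
            pw = 0.5 * (within_mean[a] + within_mean[b])
            fst = 0.0 if between <= 0 else max(0.0, 1.0 - pw / between)
            shared = len(hap_sets[a] & hap_sets[b])
            values += [between, fst, shared]
    return np.asarray(values, dtype=float), summary_statistic_names(pop_names)


def summarize_alignment(
    aln: LabeledAlignment, roles: dict[str, str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Summary vector of a labelled alignment (populations from metadata).

    ``roles`` maps population labels onto the demographic roles used by the
    reference table ("pop1" = source, "pop2"/"pop3" = daughter populations).
    It is required whenever the observed vector will be compared against a
    reference table, because statistics are ordered by population name and a
    mismatched ordering silently compares the wrong populations.
    """
    mat = encode(aln.sequences).astype(np.int64)
    pops = [r.population for r in aln.records]
    if roles is not None:
        missing = sorted(set(pops) - set(roles))
        if missing:
            raise ValueError(f"no role assigned to populations: {missing}")
        pops = [roles[p] for p in pops]
    return summary_statistics(mat, pops)


# --------------------------------------------------------- reference table --


@dataclass
class ReferenceTable:
    """Simulated parameter draws and summary vectors, plus normalisation."""

    df: pd.DataFrame
    param_names: list[str]
    stat_names: list[str]
    mad: np.ndarray
    sample_sizes: tuple[int, int, int]
    L: int
    base_freqs: tuple[float, float, float, float]
    n_rejected: int = 0

    @property
    def scenarios(self) -> list[str]:
        return sorted(self.df["scenario"].unique())

    def stats_matrix(self) -> np.ndarray:
        return self.df[self.stat_names].to_numpy(dtype=float)

    def normalized_stats(self) -> np.ndarray:
        return self.stats_matrix() / self.mad

    def normalize(self, vec: np.ndarray) -> np.ndarray:
        return np.asarray(vec, dtype=float) / self.mad

    def write_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def _simulate_row(
    scenario_name: str,
    params: dict[str, float],
    sample_sizes: tuple[int, int, int],
    L: int,
    base_freqs,
    kappa: float,
    gamma_shape: float | None,
    seed: int,
) -> tuple[np.ndarray, list[str]]:
    scn = DemographicScenario(
        name=scenario_name,
        N1=params["N1"],
        N2=params["N2"],
        N3=params["N3"],
        N2b=params["N2b"],
        N3b=params["N3b"],
        t1=params["t1"],
        t2=params["t2"],
        t_db=params["t_db"],
    )
    model = MutationModel(
        kappa=params.get("kappa", kappa),
        base_freqs=tuple(base_freqs),
        gamma_shape=params.get("gamma_shape", gamma_shape),
        L=L,
        rate=params["mu"],
    )
    ts = simulate_genealogy(scn, *sample_sizes, seed=seed)
    return evolve_sequences(ts, model, seed=seed + 7)


def build_reference(
    priors_by_scenario: dict[str, PriorSet],
    n_sims: int,
    sample_sizes: tuple[int, int, int] = (20, 20, 15),
    L: int = 456,
    base_freqs: tuple[float, float, float, float] = DEFAULT_BASE_FREQS,
    seed: int | None = None,
    scenario_probs: dict[str, float] | None = None,
) -> ReferenceTable:
    """Simulate ``n_sims`` datasets from the scenario/parameter priors.

    Parameter draws violating scenario geometry (e.g. t2 >= t1) are rejected
    and redrawn; the rejection count is recorded on the returned table.
    Per-row seeds are derived by counter from the master seed, so tables are
    reproducible.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    names = sorted(priors_by_scenario)
    if scenario_probs is None:
        probs = np.full(len(names), 1.0 / len(names))
    else:
        probs = np.array([scenario_probs[n] for n in names], dtype=float)
        probs /= probs.sum()
    rng = np.random.default_rng(seed)
    row_seeds = rng.integers(1, 2**30, size=n_sims)
    rows = []
    n_rejected = 0
    stat_names: list[str] | None = None
    for r in range(n_sims):
        name = names[int(rng.choice(len(names), p=probs))]
        prior = priors_by_scenario[name]
        params = None
        for _ in range(1000):
            cand = prior.draw(rng)
            try:
                DemographicScenario(
                    name=name,
                    N1=cand["N1"], N2=cand["N2"], N3=cand["N3"],
                    N2b=cand["N2b"], N3b=cand["N3b"],
                    t1=cand["t1"], t2=cand["t2"], t_db=cand["t_db"],
                )
                params = cand
                break
            except ScenarioError:
                n_rejected += 1
        if params is None:
            raise ScenarioError(
                f"priors for scenario {name!r} almost never satisfy the "
                "scenario geometry; adjust the bounds"
            )
        mat, pops = _simulate_row(
            name, params, sample_sizes, L, base_freqs,
            prior.kappa, prior.gamma_shape, int(row_seeds[r]),
        )
        stats, stat_names = summary_statistics(mat, pops)
        row = {"scenario": name}
        row.update({p: params[p] for p in PARAM_ORDER})
        row.update(dict(zip(stat_names, stats)))
        rows.append(row)
    df = pd.DataFrame(rows)
    stats_mat = df[stat_names].to_numpy(dtype=float)
    med = np.median(stats_mat, axis=0)
    mad = np.median(np.abs(stats_mat - med), axis=0)
    mad[mad == 0] = 1.0
    return ReferenceTable(
        df=df,
        param_names=list(PARAM_ORDER),
        stat_names=list(stat_names),
        mad=mad,
        sample_sizes=tuple(sample_sizes),
        L=L,
        base_freqs=tuple(base_freqs),
        n_rejected=n_rejected,
    )


# ---------------------------------------------------------- scenario choice --


def _distances_to(ref: ReferenceTable, obs: np.ndarray) -> np.ndarray:
    z = ref.normalized_stats() - ref.normalize(obs)
    return np.sqrt(np.sum(z**2, axis=1))


def scenario_posterior_direct(
    ref: ReferenceTable, obs: np.ndarray, k: int = 500
) -> dict[str, float]:
    """Scenario frequencies among the k nearest reference rows."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(ref.df):
        raise ValueError("k exceeds the number of reference rows")
    d = _distances_to(ref, obs)
    nearest = np.argsort(d, kind="stable")[:k]
    labels = ref.df["scenario"].to_numpy()[nearest]
    return {s: float(np.mean(labels == s)) for s in ref.scenarios}


def scenario_posterior_logistic(
    ref: ReferenceTable,
    obs: np.ndarray,
    closest_fraction: float = 0.01,
) -> dict[str, float]:
    """Polychotomous logistic regression estimate of scenario probabilities.

    The scenario indicator is regressed on (summary - observed) differences
    over the closest fraction of reference rows with Epanechnikov weights,
    and the fit is evaluated at zero difference.  Falls back to the direct
    estimate (with a warning) on degenerate designs.
    """
    if not 0 < closest_fraction <= 1:
        raise ValueError("closest_fraction must lie in (0, 1]")
    n = len(ref.df)
    m = max(int(math.ceil(closest_fraction * n)), 20)
    m = min(m, n)
    d = _distances_to(ref, obs)
    nearest = np.argsort(d, kind="stable")[:m]
    y = ref.df["scenario"].to_numpy()[nearest]
    present = sorted(set(y))
    if len(present) < 2:
        warnings.warn(
            "only one scenario among retained rows; falling back to direct estimate",
            stacklevel=2,
        )
        return scenario_posterior_direct(ref, obs, k=m)
    X = ref.normalized_stats()[nearest] - ref.normalize(obs)
    dmax = float(d[nearest].max()) or 1.0
    w = 1.0 - (d[nearest] / (dmax * (1 + 1e-9))) ** 2
    try:
        clf = LogisticRegression(C=1e6, max_iter=5000)
        clf.fit(X, y, sample_weight=w)
        probs = clf.predict_proba(np.zeros((1, X.shape[1])))[0]
        out = {s: 0.0 for s in ref.scenarios}
        for cls, p in zip(clf.classes_, probs):
            out[cls] = float(p)
        return out
    except Exception as exc:  # pragma: no cover - degenerate designs
        warnings.warn(f"logistic fit failed ({exc}); using direct estimate", stacklevel=2)
        return scenario_posterior_direct(ref, obs, k=m)


# ------------------------------------------------------ parameter estimation --


def estimate_parameters(
    ref: ReferenceTable,
    obs: np.ndarray,
    scenario: str,
    closest_fraction: float = 0.01,
    min_retained: int = 50,
    adjust: bool = True,
) -> dict:
    """Local-linear regression-adjusted posterior for one scenario.

    Retains the closest fraction of that scenario's rows, regresses
    log-parameters on normalised summary differences with Epanechnikov
    weights, and shifts the retained draws to zero difference.  Reports
    mean, median and the 2.5%/97.5% quantiles per parameter.  With
    ``adjust=False`` the retained draws are reported unadjusted (plain
    rejection sampling; with closest_fraction = 1 this returns the prior).
    """
    sub = ref.df[ref.df["scenario"] == scenario]
    if len(sub) == 0:
        raise ValueError(f"scenario {scenario!r} absent from the reference table")
    d_all = np.sqrt(
        np.sum(
            (sub[ref.stat_names].to_numpy(dtype=float) / ref.mad - ref.normalize(obs))
            ** 2,
            axis=1,
        )
    )
    m = int(math.ceil(closest_fraction * len(sub)))
    if m < min_retained:
        raise ValueError(
            f"only {m} rows would be retained (< {min_retained}); "
            "increase the reference table size or the closest fraction"
        )
    nearest = np.argsort(d_all, kind="stable")[:m]
    X = sub[ref.stat_names].to_numpy(dtype=float)[nearest] / ref.mad - ref.normalize(obs)
    theta = np.log(
        np.clip(sub[ref.param_names].to_numpy(dtype=float)[nearest], 1e-12, None)
    )
    d = d_all[nearest]
    dmax = float(d.max()) or 1.0
    w = 1.0 - (d / (dmax * (1 + 1e-9))) ** 2
    if adjust:
        design = np.hstack([np.ones((m, 1)), X])
        sw = np.sqrt(np.clip(w, 1e-12, None))
        beta, *_ = np.linalg.lstsq(design * sw[:, None], theta * sw[:, None], rcond=None)
        adjusted = np.exp(theta - X @ beta[1:])
    else:
        adjusted = np.exp(theta)
    samples = pd.DataFrame(adjusted, columns=ref.param_names)
    summary = pd.DataFrame(
        {
            "mean": samples.mean(),
            "median": samples.median(),
            "q2.5": samples.quantile(0.025),
            "q97.5": samples.quantile(0.975),
        }
    )
    return {
        "scenario": scenario,
        "samples": samples,
        "summary": summary,
        "weights": w,
        "n_retained": m,
    }


# ------------------------------------------------------- error evaluation --


def _classify(ref: ReferenceTable, obs: np.ndarray, k: int) -> str:
    post = scenario_posterior_direct(ref, obs, k=k)
    return max(sorted(post), key=lambda s: post[s])


def _simulate_pod(
    scenario: str,
    prior: PriorSet,
    ref: ReferenceTable,
    rng: np.random.Generator,
) -> np.ndarray:
    while True:
        params = prior.draw(rng)
        try:
            DemographicScenario(
                name=scenario,
                N1=params["N1"], N2=params["N2"], N3=params["N3"],
                N2b=params["N2b"], N3b=params["N3b"],
                t1=params["t1"], t2=params["t2"], t_db=params["t_db"],
            )
        except ScenarioError:
            continue
        mat, pops = _simulate_row(
            scenario, params, ref.sample_sizes, ref.L, ref.base_freqs,
            prior.kappa, prior.gamma_shape, int(rng.integers(1, 2**30)),
        )
        stats, _ = summary_statistics(mat, pops)
        return stats


def scenario_confidence(
    ref: ReferenceTable,
    priors_by_scenario: dict[str, PriorSet],
    n_pods: int = 100,
    k: int = 500,
    seed: int | None = None,
    target: str | None = None,
    obs: np.ndarray | None = None,
    closest_fraction: float = 0.1,
) -> dict:
    """Type I / type II error rates for scenario choice, via pseudo-observed
    datasets (pods) simulated from the priors and classified with the direct
    approach.  Type I: fraction of target-scenario pods not assigned to the
    target.  Type II: fraction of other-scenario pods assigned to the
    target.  When ``obs`` is given, a posterior predictive error is also
    computed: pods are simulated at parameter draws from the regression
    posterior of the scenario chosen for ``obs`` and the error is the
    fraction not re-assigned to that scenario.
    """
    names = sorted(priors_by_scenario)
    if target is None:
        target = names[0]
    rng = np.random.default_rng(seed)
    assigned: dict[str, list[str]] = {}
    for name in names:
        res = []
        for _ in range(n_pods):
            stats = _simulate_pod(name, priors_by_scenario[name], ref, rng)
            res.append(_classify(ref, stats, k))
        assigned[name] = res
    type1 = float(np.mean([a != target for a in assigned[target]]))
    others = [a for name in names if name != target for a in assigned[name]]
    type2 = float(np.mean([a == target for a in others])) if others else math.nan
    out = {
        "target": target,
        "type1": type1,
        "type2": type2,
        "assignments": assigned,
        "posterior_predictive_error": math.nan,
    }
    if obs is not None:
        chosen = _classify(ref, obs, k)
        est = estimate_parameters(ref, obs, chosen, closest_fraction=closest_fraction)
        prior = priors_by_scenario[chosen]
        samples = est["samples"]
        errs = 0
        for _ in range(n_pods):
            row = samples.iloc[int(rng.integers(len(samples)))].to_dict()
            try:
                DemographicScenario(
                    name=chosen,
                    N1=row["N1"], N2=row["N2"], N3=row["N3"],
                    N2b=min(row["N2b"], row["N2"]), N3b=min(row["N3b"], row["N3"]),
                    t1=row["t1"], t2=row["t2"],
                    t_db=min(row["t_db"], 0.999 * min(row["t1"], row["t2"])),
                )
            except ScenarioError:
                errs += 1
                continue
            mat, pops = _simulate_row(
                chosen,
                {
                    **row,
                    "N2b": min(row["N2b"], row["N2"]),
                    "N3b": min(row["N3b"], row["N3"]),
                    "t_db": min(row["t_db"], 0.999 * min(row["t1"], row["t2"])),
                },
                ref.sample_sizes, ref.L, ref.base_freqs,
                prior.kappa, prior.gamma_shape, int(rng.integers(1, 2**30)),
            )
            stats, _ = summary_statistics(mat, pops)
            if _classify(ref, stats, k) != chosen:
                errs += 1
        out["chosen"] = chosen
        out["posterior_predictive_error"] = errs / n_pods
    return out


# ----------------------------------------------------------- model checking --


def prior_preevaluation(ref: ReferenceTable, obs: np.ndarray) -> pd.DataFrame:
    """Quantile of each observed statistic within the simulated cloud.

    Statistics outside [0.5%, 99.5%] are flagged: the priors then fail to
    reproduce that aspect of the data.
    """
    stats = ref.stats_matrix()
    obs = np.asarray(obs, dtype=float)
    rows = []
    for i, name in enumerate(ref.stat_names):
        # midpoint quantile: well calibrated for discrete-valued statistics
        q = float(
            0.5 * (np.mean(stats[:, i] < obs[i]) + np.mean(stats[:, i] <= obs[i]))
        )
        rows.append(
            {"stat": name, "observed": obs[i], "quantile": q, "flag": q < 0.005 or q > 0.995}
        )
    return pd.DataFrame(rows)


def model_check(
    samples: pd.DataFrame,
    scenario: str,
    obs: np.ndarray,
    ref: ReferenceTable,
    prior: PriorSet,
    n_rep: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Posterior predictive check: simulate from posterior draws and report,
    per summary statistic, p = fraction of simulated values <= observed
    (two-sided flag at 0.025)."""
    if len(samples) == 0:
        raise ValueError("posterior sample set is empty")
    rng = np.random.default_rng(seed)
    sims = []
    for _ in range(n_rep):
        row = samples.iloc[int(rng.integers(len(samples)))].to_dict()
        row = {
            **row,
            "N2b": min(row["N2b"], row["N2"]),
            "N3b": min(row["N3b"], row["N3"]),
            "t_db": min(row["t_db"], 0.999 * min(row["t1"], row["t2"])),
        }
        mat, pops = _simulate_row(
            scenario, row, ref.sample_sizes, ref.L, ref.base_freqs,
            prior.kappa, prior.gamma_shape, int(rng.integers(1, 2**30)),
        )
        stats, _ = summary_statistics(mat, pops)
        sims.append(stats)
    sim_mat = np.vstack(sims)
    obs = np.asarray(obs, dtype=float)
    rows = []
    for i, name in enumerate(ref.stat_names):
        p = float(
            0.5 * (np.mean(sim_mat[:, i] < obs[i]) + np.mean(sim_mat[:, i] <= obs[i]))
        )
        rows.append({"stat": name, "p": p, "flag": p < 0.025 or p > 0.975})
    return pd.DataFrame(rows)
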