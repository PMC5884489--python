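"""Uncorrected p-distances, group divergences and barcoding-gap analysis.

The p-distance between two aligned sequences is the proportion of differing
nucleotides among the sites comparable in both (sites with ``N`` or ``-`` in
either sequence are excluded — pairwise deletion, the convention of the
standard distance tools for heterogeneous-coverage barcode data).  Complete
deletion (drop every column containing any missing character before
comparing) is available as a switch.

Between-group divergences carry bootstrap standard errors obtained by
resampling alignment columns with replacement and recomputing the mean
between-group distance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_io import LabeledAlignment

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}


class DistanceError(ValueError):
    """Raised when a distance is undefined (no comparable sites)."""


def encode(sequences: Sequence[str]) -> np.ndarray:
    """Encode sequences as a (n, L) uint8 matrix; 4/5 mark N and gap."""
    arr = np.empty((len(sequences), len(sequences[0])), dtype=np.uint8)
    for i, s in enumerate(sequences):
        arr[i] = np.frombuffer(s.encode(), dtype=np.uint8)
    out = np.full_like(arr, 255)
    for ch, code in _CODE.items():
        out[arr == ord(ch)] = code
    if (out == 255).any():
        raise DistanceError("illegal character in sequence")
    return out


def p_distance(a: str, b: str) -> tuple[float, int]:
    """Uncorrected p-distance and the number of comparable sites."""
    if len(a) != len(b):
        raise DistanceError("sequences have unequal lengths")
    comp = 0
    mism = 0
    for x, y in zip(a, b):
        if x in "N-" or y in "N-":
            continue
        comp += 1
        if x != y:
            mism += 1
    if comp == 0:
        raise DistanceError("no comparable sites between sequences")
    return mism / comp, comp


@dataclass
class DistanceMatrix:
    """Symmetric matrix of uncorrected p-distances (proportions)."""

    ids: list[str]
    values: np.ndarray
    comparable_sites: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path)


def p_distance_matrix(
    aln: LabeledAlignment, deletion: str = "pairwise"
) -> DistanceMatrix:
    """All pairwise uncorrected p-distances.

    deletion: "pairwise" (default) or "complete".
    """
    enc = encode(aln.sequences)
    valid = enc < 4
    if deletion == "complete":
        keep = valid.all(axis=0)
        enc = enc[:, keep]
        valid = valid[:, keep]
        if enc.shape[1] == 0:
            raise DistanceError("complete deletion removed every site")
    elif deletion != "pairwise":
        raise ValueError(f"unknown deletion mode {deletion!r}")
    n = aln.n
    comp = np.zeros((n, n), dtype=np.int64)
    vals = np.zeros((n, n), dtype=float)
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        c = both.sum(axis=1)
        m = ((enc[i] != enc[i + 1 :]) & both).sum(axis=1)
        if (c == 0).any():
            j = int(np.where(c == 0)[0][0]) + i + 1
            raise DistanceError(
                f"no comparable sites between {aln.ids[i]} and {aln.ids[j]}"
            )
        comp[i, i + 1 :] = c
        vals[i, i + 1 :] = m / c
    comp = comp + comp.T
    np.fill_diagonal(comp, valid.sum(axis=1))
    vals = vals + vals.T
    return DistanceMatrix(ids=list(aln.ids), values=vals, comparable_sites=comp)


def group_divergence(
    aln: LabeledAlignment,
    groups: Mapping[str, str],
    n_boot: int = 1000,
    seed: int | None = None,
    deletion: str = "pairwise",
) -> pd.DataFrame:
    """Mean between-group p-distance with bootstrap standard errors.

    ``groups`` maps sequence id -> group label.  The mean is taken over all
    between-group sequence pairs; the SE is the standard deviation of that
    mean over ``n_boot`` replicates in which alignment columns are resampled
    with replacement (site bootstrap).
    """
    labels = sorted(set(groups.values()))
    members = {g: [i for i, sid in enumerate(aln.ids) if groups.get(sid) == g] for g in labels}
    for g, idx in members.items():
        if not idx:
            raise ValueError(f"group {g!r} has no members in the alignment")
    enc = encode(aln.sequences)
    valid = enc < 4
    if deletion == "complete":
        keep = valid.all(axis=0)
        enc = enc[:, keep]
        valid = valid[:, keep]
    rng = np.random.default_rng(seed)
    L = enc.shape[1]
    rows = []
    for ai, ga in enumerate(labels):
        for gb in labels[ai + 1 :]:
            pairs = [(i, j) for i in members[ga] for j in members[gb]]
            mism = np.empty((len(pairs), L), dtype=bool)
            comp = np.empty((len(pairs), L), dtype=bool)
            for p, (i, j) in enumerate(pairs):
                both = valid[i] & valid[j]
                comp[p] = both
                mism[p] = (enc[i] != enc[j]) & both
            csum = comp.sum(axis=1)
            if (csum == 0).any():
                raise DistanceError(f"pair with no comparable sites in {ga} vs {gb}")
            mean_dist = float(np.mean(mism.sum(axis=1) / csum))
            if n_boot > 0:
                boots = np.empty(n_boot)
                mism_f = mism.astype(np.float32)
                comp_f = comp.astype(np.float32)
                for b in range(n_boot):
                    cols = rng.integers(0, L, size=L)
                    cs = comp_f[:, cols].sum(axis=1)
                    ms = mism_f[:, cols].sum(axis=1)
                    ok = cs > 0
                    boots[b] = float(np.mean(ms[ok] / cs[ok]))
                se = float(np.std(boots, ddof=1))
            else:
                se = float("nan")
            rows.append(
                {
                    "group_a": ga,
                    "group_b": gb,
                    "mean_distance": mean_dist,
                    "bootstrap_se": se,
                    "n_pairs": len(pairs),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class GapReport:
    """Outcome of a barcoding-gap analysis on a distance matrix."""

    intra: pd.DataFrame  # columns id_a, id_b, distance
    inter: pd.DataFrame
    max_intra: float
    min_inter: float
    gap_exists: bool
    threshold: float | None
    histogram: pd.DataFrame  # bin_low, bin_high, intra_count, inter_count
    singleton_species: list[str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "max_intra": self.max_intra,
            "min_inter": self.min_inter,
            "gap_exists": self.gap_exists,
            "threshold": self.threshold,
            "n_intra_pairs": int(len(self.intra)),
            "n_inter_pairs": int(len(self.inter)),
            "singleton_species": self.singleton_species,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def barcoding_gap(
    dm: DistanceMatrix,
    species: Mapping[str, str],
    bin_width: float = 0.005,
) -> GapReport:
    """Partition pairwise distances into intra- vs inter-specific sets.

    Reports the largest intraspecific and smallest interspecific distance,
    whether an empty interval (the barcoding gap) separates them, the
    midpoint threshold when it does, and a shared histogram of both
    distributions (default bin width 0.5%).
    """
    ids = dm.ids
    n = len(ids)
    if n < 2:
        raise ValueError("need at least two sequences")
    sp = [species.get(i) for i in ids]
    if any(s is None for s in sp):
        missing = [i for i, s in zip(ids, sp) if s is None]
        raise ValueError(f"no species label for: {missing}")
    intra_rows, inter_rows = [], []
    for i in range(n):
        for j in range(i + 1, n):
            row = {"id_a": ids[i], "id_b": ids[j], "distance": float(dm.values[i, j])}
            (intra_rows if sp[i] == sp[j] else inter_rows).append(row)
    counts: dict[str, int] = {}
    for s in sp:
        counts[s] = counts.get(s, 0) + 1
    singletons = sorted(s for s, c in counts.items() if c == 1)
    intra = pd.DataFrame(intra_rows, columns=["id_a", "id_b", "distance"])
    inter = pd.DataFrame(inter_rows, columns=["id_a", "id_b", "distance"])
    max_intra = float(intra["distance"].max()) if len(intra) else 0.0
    min_inter = float(inter["distance"].min()) if len(inter) else float("inf")
    gap = len(inter) > 0 and min_inter > max_intra
    threshold = (max_intra + min_inter) / 2 if gap else None
    top = max(
        max_intra,
        0.0 if not len(inter) else float(inter["distance"].max()),
        bin_width,
    )
    edges = np.arange(0.0, top + 2 * bin_width, bin_width)
    intra_h, _ = np.histogram(intra["distance"], bins=edges) if len(intra) else (
        np.zeros(len(edges) - 1, dtype=int),
        edges,
    )
    inter_h, _ = np.histogram(inter["distance"], bins=edges) if len(inter) else (
        np.zeros(len(edges) - 1, dtype=int),
        edges,
    )
    hist = pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "intra_count": intra_h,
            "inter_count": inter_h,
        }
    )
    return GapReport(
        intra=intra,
        inter=inter,
        max_intra=max_intra,
        min_inter=min_inter,
        gap_exists=bool(gap),
        threshold=threshold,
        histogram=hist,
        singleton_species=singletons,
    )
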