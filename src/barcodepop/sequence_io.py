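"""Reading, validation, trimming and haplotype collapsing of aligned barcodes.

The universal input of the package is a :class:`LabeledAlignment`: a set of
pre-aligned mitochondrial barcode sequences (COI or similar) together with a
per-sequence metadata table carrying at least an id, a species label and a
population label.  Sequences are strings over ``{A, C, G, T, N, -}``; ``N``
is missing data and ``-`` an alignment gap (barcode fragments are normally
indel-free, but gaps are tolerated and treated like missing data).

Alignment columns are 0-based half-open internally; any human-facing report
uses 1-based coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_CHARS = frozenset("ACGTN-")
#: characters that carry no information at a site
MISSING_CHARS = frozenset("N-")


class AlignmentError(ValueError):
    """Raised for malformed alignments or metadata."""


@dataclass(frozen=True)
class Record:
    """One aligned sequence with its metadata."""

    id: str
    sequence: str
    species: str
    population: str
    locality: str = ""
    extra: Mapping[str, str] = field(default_factory=dict)


@dataclass
class LabeledAlignment:
    """Aligned sequences plus per-sequence species/population metadata.

    Invariants (checked on construction): all sequences have the same
    positive length, characters are in ``{A,C,G,T,N,-}`` and ids are unique.
    """

    records: list[Record]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment has no records")
        length = len(self.records[0].sequence)
        if length == 0:
            raise AlignmentError("alignment length is zero")
        bad = [r.id for r in self.records if len(r.sequence) != length]
        if bad:
            raise AlignmentError(
                f"sequences with length differing from {length}: {', '.join(bad)}"
            )
        for r in self.records:
            illegal = set(r.sequence) - VALID_CHARS
            if illegal:
                raise AlignmentError(
                    f"sequence {r.id!r} contains illegal characters {sorted(illegal)}"
                )
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {', '.join(dupes)}")

    @property
    def length(self) -> int:
        return len(self.records[0].sequence)

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def species_of(self) -> dict[str, str]:
        return {r.id: r.species for r in self.records}

    def population_of(self) -> dict[str, str]:
        return {r.id: r.population for r in self.records}

    def subset(self, ids: Iterable[str]) -> "LabeledAlignment":
        wanted = set(ids)
        kept = [r for r in self.records if r.id in wanted]
        missing = wanted - {r.id for r in kept}
        if missing:
            raise AlignmentError(f"unknown ids in subset: {sorted(missing)}")
        return LabeledAlignment(kept)

    def by_population(self) -> dict[str, "LabeledAlignment"]:
        groups: dict[str, list[Record]] = {}
        for r in self.records:
            groups.setdefault(r.population, []).append(r)
        return {k: LabeledAlignment(v) for k, v in sorted(groups.items())}

    def by_species(self) -> dict[str, "LabeledAlignment"]:
        groups: dict[str, list[Record]] = {}
        for r in self.records:
            groups.setdefault(r.species, []).append(r)
        return {k: LabeledAlignment(v) for k, v in sorted(groups.items())}


@dataclass(frozen=True)
class Haplotype:
    hap_id: str
    sequence: str
    count: int
    member_ids: tuple[str, ...]


@dataclass
class HaplotypeSet:
    """Unique sequences with frequencies and a membership map."""

    haplotypes: list[Haplotype]
    length: int

    def __post_init__(self) -> None:
        seqs = [h.sequence for h in self.haplotypes]
        if len(set(seqs)) != len(seqs):
            raise AlignmentError("haplotype sequences are not pairwise distinct")
        for h in self.haplotypes:
            if h.count != len(h.member_ids):
                raise AlignmentError(f"haplotype {h.hap_id}: count != members")

    @property
    def total(self) -> int:
        return sum(h.count for h in self.haplotypes)

    @property
    def counts(self) -> list[int]:
        return [h.count for h in self.haplotypes]

    def membership(self) -> dict[str, str]:
        """Map each member id to its haplotype id."""
        out: dict[str, str] = {}
        for h in self.haplotypes:
            for m in h.member_ids:
                out[m] = h.hap_id
        return out


REQUIRED_META_COLUMNS = ("id", "species", "population")


def read_alignment(fasta_path: str | Path, metadata_path: str | Path) -> LabeledAlignment:
    """Read an aligned FASTA and a TSV metadata table into a LabeledAlignment.

    The metadata table must contain columns ``id``, ``species`` and
    ``population``; ``locality`` and any further columns are preserved.
    Every FASTA id must appear in the table (hard error otherwise);
    metadata rows without a matching sequence produce a warning only.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not seqs:
        raise AlignmentError(f"no sequences parsed from {fasta_path}")
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("")
    missing_cols = [c for c in REQUIRED_META_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise AlignmentError(f"metadata lacks required columns: {missing_cols}")
    meta_by_id = {row["id"]: row for _, row in meta.iterrows()}
    absent = [sid for sid in seqs if sid not in meta_by_id]
    if absent:
        raise AlignmentError(f"sequences missing from metadata: {', '.join(absent)}")
    unmatched = [mid for mid in meta_by_id if mid not in seqs]
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} metadata rows without a sequence: "
            + ", ".join(unmatched[:10]),
            stacklevel=2,
        )
    core = set(REQUIRED_META_COLUMNS) | {"locality"}
    records = []
    for sid, seq in seqs.items():
        row = meta_by_id[sid]
        extra = {c: row[c] for c in meta.columns if c not in core}
        records.append(
            Record(
                id=sid,
                sequence=seq,
                species=row["species"],
                population=row["population"],
                locality=row.get("locality", ""),
                extra=extra,
            )
        )
    return LabeledAlignment(records)


def _informative_span(seq: str) -> tuple[int, int]:
    """0-based half-open window from the first to last informative site."""
    first = next((i for i, c in enumerate(seq) if c not in MISSING_CHARS), None)
    if first is None:
        return (0, 0)
    last = next(i for i, c in enumerate(reversed(seq)) if c not in MISSING_CHARS)
    return (first, len(seq) - last)


def trim_to_common_length(
    aln: LabeledAlignment, min_keep: int
) -> tuple[LabeledAlignment, list[str]]:
    """Drop short records and cut the alignment to the common covered window.

    A record's informative length is the extent between its first and last
    non-missing site (terminal runs of ``N``/``-`` do not count).  Records
    shorter than ``min_keep`` are dropped and reported; the survivors are
    truncated to the intersection of their informative windows, so the output
    length equals the minimal retained informative length.

    Returns the trimmed alignment and the list of dropped ids.
    """
    if min_keep > aln.length:
        raise AlignmentError(
            f"min_keep={min_keep} exceeds alignment length {aln.length}"
        )
    spans = {r.id: _informative_span(r.sequence) for r in aln.records}
    dropped = [rid for rid, (a, b) in spans.items() if b - a < min_keep]
    kept = [r for r in aln.records if r.id not in set(dropped)]
    if not kept:
        raise AlignmentError("no sequence meets the min_keep length requirement")
    start = max(spans[r.id][0] for r in kept)
    stop = min(spans[r.id][1] for r in kept)
    if stop <= start:
        raise AlignmentError("retained sequences have no common overlapping window")
    trimmed = [replace(r, sequence=r.sequence[start:stop]) for r in kept]
    if dropped:
        warnings.warn(
            f"{len(dropped)} shorter sequences removed: {', '.join(sorted(dropped))}",
            stacklevel=2,
        )
    return LabeledAlignment(trimmed), sorted(dropped)


def _compatible(a: str, b: str) -> bool:
    """True if a and b agree at every site where both are informative."""
    return all(
        x == y or x in MISSING_CHARS or y in MISSING_CHARS for x, y in zip(a, b)
    )


def collapse_haplotypes(
    aln: LabeledAlignment, merge_ambiguous: bool = False
) -> HaplotypeSet:
    """Merge identical sequences into haplotypes.

    By default collapsing uses strict string identity, so sequences that
    differ only at ``N`` positions stay separate (the behaviour of the usual
    FASTA collapsing tools).  With ``merge_ambiguous=True``, sequences that
    are identical at all mutually informative sites are merged and the member
    with the fewest missing sites represents the haplotype.

    Haplotype ids are assigned deterministically: groups are ordered by their
    lexicographically smallest member id and named ``H1``, ``H2``, ...
    """
    groups: list[list[Record]] = []
    if not merge_ambiguous:
        index: dict[str, int] = {}
        for r in aln.records:
            if r.sequence in index:
                groups[index[r.sequence]].append(r)
            else:
                index[r.sequence] = len(groups)
                groups.append([r])
    else:
        # union-find over compatibility; transitive closure is intentional
        parent = list(range(aln.n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        recs = aln.records
        for i in range(aln.n):
            for j in range(i + 1, aln.n):
                if _compatible(recs[i].sequence, recs[j].sequence):
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
        by_root: dict[int, list[Record]] = {}
        for i, r in enumerate(recs):
            by_root.setdefault(find(i), []).append(r)
        groups = list(by_root.values())

    groups.sort(key=lambda g: min(r.id for r in g))
    haplotypes = []
    for i, g in enumerate(groups, start=1):
        rep = min(g, key=lambda r: (sum(c in MISSING_CHARS for c in r.sequence), r.id))
        haplotypes.append(
            Haplotype(
                hap_id=f"H{i}",
                sequence=rep.sequence,
                count=len(g),
                member_ids=tuple(sorted(r.id for r in g)),
            )
        )
    return HaplotypeSet(haplotypes=haplotypes, length=aln.length)


# ---------------------------------------------------------------- output --


def write_fasta(aln: LabeledAlignment, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in aln.records
    ]
    SeqIO.write(recs, str(path), "fasta")


def write_metadata(aln: LabeledAlignment, path: str | Path) -> None:
    rows = []
    for r in aln.records:
        row = {
            "id": r.id,
            "species": r.species,
            "population": r.population,
            "locality": r.locality,
        }
        row.update(r.extra)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_haplotype_table(haps: HaplotypeSet, path: str | Path) -> None:
    pd.DataFrame(
        {
            "hap_id": [h.hap_id for h in haps.haplotypes],
            "count": [h.count for h in haps.haplotypes],
            "member_ids": [";".join(h.member_ids) for h in haps.haplotypes],
        }
    ).to_csv(path, sep="\t", index=False)


def haplotype_fasta(haps: HaplotypeSet, path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(h.sequence), id=h.hap_id, description=f"n={h.count}")
        for h in haps.haplotypes
    ]
    SeqIO.write(recs, str(path), "fasta")
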