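"""Shared-taxa statistics: per-pair shared ASV counts, the shared proportion
with the human sample's richness as denominator, and multi-set Venn partitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd

from .asv_tables import AsvTable, SampleRecord, HUMAN_TYPES


@dataclass
class SharedTaxaRecord:
    subject_id: str
    timepoint: str
    human_type: str
    shared_count: int
    human_richness: int
    mat_richness: int
    shared_asv_ids: frozenset[str]

    @property
    def proportion(self) -> float:
        return self.shared_count / self.human_richness

    @property
    def proportion_exact(self) -> Fraction:
        return Fraction(self.shared_count, self.human_richness)

    def __post_init__(self) -> None:
        if self.human_richness < 1:
            raise ValueError("human richness must be positive")
        if self.shared_count > min(self.human_richness, self.mat_richness):
            raise ValueError("shared count exceeds a set size")


@dataclass
class VennPartition:
    """Exact disjoint region membership for 2-4 labeled ASV sets."""

    labels: tuple[str, ...]
    regions: dict[frozenset[str], frozenset[str]]

    def count(self, *labels: str) -> int:
        return len(self.regions.get(frozenset(labels), frozenset()))

    def counts(self) -> dict[frozenset[str], int]:
        return {region: len(ids) for region, ids in self.regions.items()}

    def total(self) -> int:
        return sum(len(ids) for ids in self.regions.values())


def presence_set(table: AsvTable, sample_id: str) -> set[str]:
    """ASVs with a positive count in the sample (presence = >= 1 read)."""
    row = table.row(sample_id)
    return {a for a, c in zip(table.asv_ids, row) if c > 0}


@dataclass
class PairReport:
    pairs: list[tuple[str, str, str, str, str]]  # human_id, mat_id, subject, tp, type
    unpaired_human: list[str]
    unpaired_mat: list[str]


def pair_samples(records: Sequence[SampleRecord]) -> PairReport:
    """Pair each human sample with its subject's mat sample at the same timepoint.

    Records must be post-merge (one sample per subject/type/timepoint).
    Human samples without a same-timepoint mat (and mats without any human
    partner) are reported, not dropped silently.
    """
    mats: dict[tuple[str, str], str] = {}
    for r in records:
        if r.sample_type == "mat":
            key = (r.subject_id, r.timepoint)
            if key in mats:
                raise ValueError(
                    f"multiple mat samples for subject {r.subject_id!r} at {r.timepoint!r}; "
                    "merge replicates first"
                )
            mats[key] = r.sample_id
    pairs = []
    unpaired_human = []
    used_mats = set()
    for r in records:
        if r.sample_type not in HUMAN_TYPES:
            continue
        mat_id = mats.get((r.subject_id, r.timepoint))
        if mat_id is None:
            unpaired_human.append(r.sample_id)
        else:
            pairs.append((r.sample_id, mat_id, r.subject_id, r.timepoint, r.sample_type))
            used_mats.add(mat_id)
    unpaired_mat = [m for m in mats.values() if m not in used_mats]
    return PairReport(pairs=pairs, unpaired_human=unpaired_human, unpaired_mat=unpaired_mat)


def shared_statistic(human_set: set[str], mat_set: set[str]) -> tuple[int, int, Fraction]:
    """(shared k, human richness n, proportion k/n); denominator is always the
    human sample's richness."""
    n = len(human_set)
    if n < 1:
        raise ValueError("human sample has zero richness; proportion undefined")
    k = len(human_set & mat_set)
    return k, n, Fraction(k, n)


def shared_table(
    table: AsvTable, records: Sequence[SampleRecord]
) -> list[SharedTaxaRecord]:
    """One SharedTaxaRecord per (subject, timepoint, human type) pair."""
    pairing = pair_samples(records)
    out: list[SharedTaxaRecord] = []
    for human_id, mat_id, subject, tp, htype in pairing.pairs:
        hset = presence_set(table, human_id)
        mset = presence_set(table, mat_id)
        if not hset:
            continue  # richness 0 after rarefaction: proportion undefined
        k, n, _ = shared_statistic(hset, mset)
        out.append(
            SharedTaxaRecord(
                subject_id=subject,
                timepoint=tp,
                human_type=htype,
                shared_count=k,
                human_richness=n,
                mat_richness=len(mset),
                shared_asv_ids=frozenset(hset & mset),
            )
        )
    return out


def shared_records_frame(records: Sequence[SharedTaxaRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "timepoint": [r.timepoint for r in records],
            "human_type": [r.human_type for r in records],
            "shared_count": [r.shared_count for r in records],
            "human_richness": [r.human_richness for r in records],
            "mat_richness": [r.mat_richness for r in records],
            "proportion": [r.proportion for r in records],
        }
    )


def summarize_shared(records: Sequence[SharedTaxaRecord]) -> pd.DataFrame:
    """Per-dataset (human type x timepoint) summaries: N and mean (min-max)
    of human richness, mat richness, shared richness and percent shared."""
    df = shared_records_frame(records)
    rows = []
    for (htype, tp), grp in df.groupby(["human_type", "timepoint"], sort=False):
        pct = 100.0 * grp["proportion"]
        rows.append(
            {
                "human_type": htype,
                "timepoint": tp,
                "N": len(grp),
                "human_richness_mean": grp["human_richness"].mean(),
                "human_richness_min": grp["human_richness"].min(),
                "human_richness_max": grp["human_richness"].max(),
                "mat_richness_mean": grp["mat_richness"].mean(),
                "mat_richness_min": grp["mat_richness"].min(),
                "mat_richness_max": grp["mat_richness"].max(),
                "shared_richness_mean": grp["shared_count"].mean(),
                "shared_richness_min": grp["shared_count"].min(),
                "shared_richness_max": grp["shared_count"].max(),
                "pct_shared_mean": pct.mean(),
                "pct_shared_min": pct.min(),
                "pct_shared_max": pct.max(),
            }
        )
    return pd.DataFrame(rows)


def venn_partition(sets: Mapping[str, set[str]]) -> VennPartition:
    """Exact disjoint region counts for 2-4 labeled sets (all 2^L - 1 regions)."""
    labels = tuple(sets.keys())
    if not 2 <= len(labels) <= 4:
        raise ValueError("venn_partition requires 2-4 labeled sets")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    regions: dict[frozenset[str], frozenset[str]] = {}
    for r in range(1, len(labels) + 1):
        for inside in combinations(labels, r):
            region = set.intersection(*(set(sets[l]) for l in inside))
            for outside in labels:
                if outside not in inside:
                    region -= set(sets[outside])
            regions[frozenset(inside)] = frozenset(region)
    return VennPartition(labels=labels, regions=regions)


def union_sets_by_type(
    table: AsvTable,
    records: Sequence[SampleRecord],
    timepoint: str,
    complete_case: bool = True,
) -> dict[str, set[str]]:
    """Per-sample-type ASV unions at one timepoint, optionally restricted to
    subjects with all four sample types available at that timepoint."""
    by_type: dict[str, dict[str, str]] = {}  # type -> subject -> sample_id
    for r in records:
        if r.timepoint != timepoint or r.subject_id is None:
            continue
        if not table.has_sample(r.sample_id):
            continue
        by_type.setdefault(r.sample_type, {})[r.subject_id] = r.sample_id
    types = [t for t in ("mat",) + HUMAN_TYPES if t in by_type]
    if complete_case:
        subjects = set.intersection(*(set(by_type[t]) for t in types)) if types else set()
    else:
        subjects = set.union(*(set(by_type[t]) for t in types)) if types else set()
    out: dict[str, set[str]] = {}
    for t in types:
        ids = [sid for subj, sid in by_type[t].items() if subj in subjects]
        u: set[str] = set()
        for sid in ids:
            u |= presence_set(table, sid)
        out[t] = u
    return out
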