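"""Post-classification filtering chain and library-size normalization.

The pipeline order is fixed: lineage blacklist removal, global-singleton
removal, negative-control ASV removal, replicate merging, then hypergeometric
rarefaction.  Each step emits a :class:`FilterReport` so removals are
auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .asv_tables import AsvTable, SampleRecord, TaxonomyTable

DEFAULT_BLACKLIST = frozenset(
    {"Chloroplast", "Mitochondria", "unknown", "Archaea", "Eukaryota"}
)


@dataclass
class FilterReport:
    step: str
    asvs_removed: int = 0
    samples_removed: int = 0
    reads_removed: int = 0
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.asvs_removed, self.samples_removed, self.reads_removed) < 0:
            raise ValueError("filter report counters must be non-negative")


def _report(step: str, before: AsvTable, after: AsvTable, **details) -> FilterReport:
    return FilterReport(
        step=step,
        asvs_removed=before.n_asvs - after.n_asvs,
        samples_removed=before.n_samples - after.n_samples,
        reads_removed=int(before.counts.sum() - after.counts.sum()),
        details=details,
    )


def remove_by_lineage(
    table: AsvTable,
    taxonomy: TaxonomyTable,
    blacklist: Iterable[str] = DEFAULT_BLACKLIST,
) -> tuple[AsvTable, FilterReport]:
    """Drop ASVs whose lineage contains any blacklisted label.

    Matching is case-insensitive and exact per label (no substring match).
    """
    missing = [a for a in table.asv_ids if a not in taxonomy]
    if missing:
        raise ValueError(f"ASVs missing from taxonomy: {missing[:10]}")
    black = {b.lower() for b in blacklist}
    removed = [
        a
        for a in table.asv_ids
        if any(label.lower() in black for label in taxonomy.lineage(a))
    ]
    out = table.drop_asvs(removed)
    return out, _report("remove_by_lineage", table, out, removed_asvs=removed)


def remove_global_singletons(table: AsvTable) -> tuple[AsvTable, FilterReport]:
    """Drop ASVs with a whole-dataset total of exactly 1 read (and empty columns)."""
    totals = table.counts.sum(axis=0)
    removed = [a for a, t in zip(table.asv_ids, totals) if t <= 1]
    out = table.drop_asvs(removed)
    return out, _report("remove_global_singletons", table, out, removed_asvs=removed)


def remove_control_asvs(
    table: AsvTable, control_sample_ids: Iterable[str]
) -> tuple[AsvTable, FilterReport]:
    """Drop every ASV detected in any negative control, then the controls.

    This is the strict presence-based rule: a single read in a single
    control condemns the ASV in all samples.
    """
    controls = list(control_sample_ids)
    unknown = [c for c in controls if not table.has_sample(c)]
    if unknown:
        raise ValueError(f"unknown control sample IDs: {unknown}")
    if not controls:
        return table, _report("remove_control_asvs", table, table, control_asvs=[])
    rows = np.array([table.sample_ids.index(c) for c in controls])
    present = table.counts[rows].sum(axis=0) > 0
    control_asvs = [a for a, p in zip(table.asv_ids, present) if p]
    out = table.drop_asvs(control_asvs)
    out = out.subset_samples(s for s in out.sample_ids if s not in set(controls))
    return out, _report("remove_control_asvs", table, out, control_asvs=control_asvs)


def merge_replicates(
    table: AsvTable, records: Sequence[SampleRecord]
) -> tuple[AsvTable, list[SampleRecord]]:
    """Sum replicate samples elementwise into one sample per
    (subject, sample_type, timepoint).

    Groups with a single replicate keep their sample ID; merged groups get a
    deterministic ``subject.type.timepoint`` ID with replicate=1.
    """
    rec_by_id = {r.sample_id: r for r in records}
    groups: dict[tuple, list[str]] = {}
    order: list[tuple] = []
    for sid in table.sample_ids:
        rec = rec_by_id.get(sid)
        if rec is None or rec.subject_id is None:
            key = ("__single__", sid)
        else:
            key = (rec.subject_id, rec.sample_type, rec.timepoint)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(sid)

    new_ids: list[str] = []
    new_rows: list[np.ndarray] = []
    new_records: list[SampleRecord] = []
    for key in order:
        members = groups[key]
        summed = table.counts[[table.sample_ids.index(s) for s in members]].sum(axis=0)
        if len(members) == 1:
            sid = members[0]
            rec = rec_by_id.get(sid)
            new_rec = (
                SampleRecord(sid, rec.subject_id, rec.sample_type, rec.timepoint, 1)
                if rec is not None
                else None
            )
        else:
            subject, stype, tp = key
            sid = f"{subject}.{stype}.{tp}"
            new_rec = SampleRecord(sid, subject, stype, tp, 1)
        new_ids.append(sid)
        new_rows.append(summed)
        if new_rec is not None:
            new_records.append(new_rec)
        elif sid in rec_by_id:
            new_records.append(rec_by_id[sid])
    merged = AsvTable(new_ids, list(table.asv_ids), np.vstack(new_rows))
    return merged, new_records


def rarefy(
    table: AsvTable,
    depth: int | str,
    records: Sequence[SampleRecord] | None = None,
    seed: int = 0,
) -> tuple[AsvTable, FilterReport]:
    """Subsample each sample to a fixed depth without replacement.

    Each sample's reads are drawn by a single multivariate-hypergeometric
    draw.  ``depth="auto_per_type"`` computes the depth separately within
    each sample type as the minimum post-filter library size of that type
    (requires ``records``).  Samples below their applicable depth are
    dropped and reported.
    """
    rng = np.random.default_rng(seed)
    lib = table.library_sizes()
    if depth == "auto_per_type":
        if records is None:
            raise ValueError("auto_per_type rarefaction requires sample records")
        rec_by_id = {r.sample_id: r for r in records}
        type_depth: dict[str, int] = {}
        for sid, size in zip(table.sample_ids, lib):
            rec = rec_by_id.get(sid)
            if rec is None:
                continue
            t = rec.sample_type
            type_depth[t] = min(type_depth.get(t, np.iinfo(np.int64).max), int(size))
        depths = np.array(
            [
                type_depth.get(rec_by_id[sid].sample_type, 0)
                if sid in rec_by_id
                else 0
                for sid in table.sample_ids
            ]
        )
        if np.any(depths < 1):
            bad = [s for s, d in zip(table.sample_ids, depths) if d < 1]
            raise ValueError(f"cannot determine rarefaction depth for samples: {bad}")
    else:
        depth = int(depth)
        if depth < 1:
            raise ValueError("rarefaction depth must be >= 1")
        depths = np.full(table.n_samples, depth)

    keep_rows = []
    dropped = []
    new_counts = []
    for i, sid in enumerate(table.sample_ids):
        if lib[i] < depths[i]:
            dropped.append(sid)
            continue
        row = table.counts[i]
        if lib[i] == depths[i]:
            new_counts.append(row.copy())
        else:
            new_counts.append(
                rng.multivariate_hypergeometric(row, int(depths[i])).astype(np.int64)
            )
        keep_rows.append(i)
    if not keep_rows:
        raise ValueError("rarefaction dropped every sample")
    out = AsvTable(
        [table.sample_ids[i] for i in keep_rows], list(table.asv_ids), np.vstack(new_counts)
    )
    report = _report(
        "rarefy",
        table,
        out,
        seed=seed,
        dropped_samples=dropped,
        depths={table.sample_ids[i]: int(depths[i]) for i in keep_rows},
    )
    return out, report


def run_filter_pipeline(
    table: AsvTable,
    taxonomy: TaxonomyTable,
    records: Sequence[SampleRecord],
    blacklist: Iterable[str] = DEFAULT_BLACKLIST,
    depth: int | str = "auto_per_type",
    seed: int = 0,
    merge: bool = True,
) -> tuple[AsvTable, AsvTable, list[SampleRecord], list[FilterReport]]:
    """Run the fixed filter chain; returns (rarefied, filtered, records, reports)."""
    reports: list[FilterReport] = []
    table, rep = remove_by_lineage(table, taxonomy, blacklist)
    reports.append(rep)
    table, rep = remove_global_singletons(table)
    reports.append(rep)
    control_ids = [
        r.sample_id
        for r in records
        if r.sample_type == "negative_control" and table.has_sample(r.sample_id)
    ]
    table, rep = remove_control_asvs(table, control_ids)
    reports.append(rep)
    records = [r for r in records if r.sample_type != "negative_control"]
    if merge:
        table, records = merge_replicates(table, records)
    filtered = table
    rarefied, rep = rarefy(table, depth, records=records, seed=seed)
    reports.append(rep)
    records = [r for r in records if rarefied.has_sample(r.sample_id)]
    return rarefied, filtered, records, reports
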