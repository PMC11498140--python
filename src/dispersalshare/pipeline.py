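"""End-to-end orchestration: filter -> rarefy -> shared taxa -> ordination and
dispersion tests -> GLMMs, with a JSON run manifest recording seeds and
row/ASV counts at every stage."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .asv_tables import (
    HUMAN_TYPES,
    TIMEPOINTS,
    align,
    read_count_table,
    read_metadata,
    read_taxonomy,
)
from .distance import distance_matrix, pcoa, permanova, permdisp
from .filtering import DEFAULT_BLACKLIST, run_filter_pipeline
from .glmm import (
    assemble_model_data,
    forward_select,
    per_timepoint_models,
    simulate_residuals,
    COVARIATE_KINDS,
)
from .shared import (
    shared_records_frame,
    shared_table,
    summarize_shared,
    union_sets_by_type,
    venn_partition,
)

logger = logging.getLogger("dispersalshare")


@dataclass
class PipelineConfig:
    counts: str
    metadata: str
    taxonomy: str
    out_dir: str
    counts_dialect: str = "plain_tsv"
    blacklist: tuple[str, ...] = tuple(sorted(DEFAULT_BLACKLIST))
    rarefaction_depth: int | str = "auto_per_type"
    rarefaction_seed: int = 0
    distances: tuple[str, ...] = ("sorensen",)
    n_perm: int = 999
    permutation_seed: int = 0
    candidates: tuple[str, ...] = tuple(COVARIATE_KINDS)
    n_sim_diagnostics: int = 250
    diagnostics_seed: int = 0
    exclude_antibiotics: bool = True
    complete_case_venn: bool = True
    venn_timepoint: str = "S"

    def validate(self) -> None:
        for name in ("counts", "metadata", "taxonomy"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        for c in self.candidates:
            if c not in COVARIATE_KINDS:
                raise ValueError(f"unknown candidate covariate: {c!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("blacklist", "distances", "candidates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _region_name(region: frozenset[str]) -> str:
    return "&".join(sorted(region))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dict.

    Any stage error aborts with a stage-named message; partial outputs stay
    on disk next to a FAILED marker.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "dispersalshare",
        "version": __version__,
        "seeds": {
            "rarefaction": config.rarefaction_seed,
            "permutation": config.permutation_seed,
            "diagnostics": config.diagnostics_seed,
        },
        "stages": [],
        "warnings": [],
    }
    stage = "load"
    try:
        table = read_count_table(config.counts, dialect=config.counts_dialect)
        taxonomy = read_taxonomy(config.taxonomy)
        records, covariates = read_metadata(config.metadata)
        table, records, align_report = align(table, records)
        if not align_report.empty:
            manifest["warnings"].append(
                f"align: dropped table-only={align_report.table_only} "
                f"metadata-only={align_report.metadata_only}"
            )
        manifest["stages"].append(
            {"stage": stage, "samples": table.n_samples, "asvs": table.n_asvs}
        )

        stage = "filter"
        rarefied, filtered, records, reports = run_filter_pipeline(
            table,
            taxonomy,
            records,
            blacklist=config.blacklist,
            depth=config.rarefaction_depth,
            seed=config.rarefaction_seed,
        )
        filtered.write_tsv(out / "filtered_counts.tsv")
        rarefied.write_tsv(out / "rarefied_counts.tsv")
        pd.DataFrame(
            [
                {
                    "step": r.step,
                    "asvs_removed": r.asvs_removed,
                    "samples_removed": r.samples_removed,
                    "reads_removed": r.reads_removed,
                }
                for r in reports
            ]
        ).to_csv(out / "filter_report.tsv", sep="\t", index=False)
        for r in reports:
            logger.info(
                "%s: removed %d ASVs, %d samples, %d reads",
                r.step, r.asvs_removed, r.samples_removed, r.reads_removed,
            )
        manifest["stages"].append(
            {"stage": stage, "samples": rarefied.n_samples, "asvs": rarefied.n_asvs,
             "reports": [r.step for r in reports]}
        )

        stage = "shared"
        shared_recs = shared_table(rarefied, records)
        shared_records_frame(shared_recs).to_csv(out / "shared.tsv", sep="\t", index=False)
        summarize_shared(shared_recs).to_csv(
            out / "data_characteristics.tsv", sep="\t", index=False
        )
        sets = union_sets_by_type(
            rarefied, records, config.venn_timepoint, complete_case=config.complete_case_venn
        )
        if len(sets) >= 2:
            venn = venn_partition(sets)
            pd.DataFrame(
                [
                    {"region": _region_name(reg), "n_asvs": len(ids)}
                    for reg, ids in venn.regions.items()
                ]
            ).to_csv(out / "venn_regions.tsv", sep="\t", index=False)
        else:
            manifest["warnings"].append("venn: fewer than 2 sample types available")
        manifest["stages"].append({"stage": stage, "pairs": len(shared_recs)})

        stage = "ordination"
        rec_by_id = {r.sample_id: r for r in records}
        type_of = [rec_by_id[s].sample_type for s in rarefied.sample_ids]
        permdisp_rows = []
        for metric in config.distances:
            D = distance_matrix(rarefied, metric=metric)
            ordn = pcoa(D)
            coords = pd.DataFrame(
                ordn.coordinates,
                index=ordn.ids,
                columns=[f"PCo{i + 1}" for i in range(ordn.coordinates.shape[1])],
            )
            coords.index.name = "sample_id"
            coords.to_csv(out / f"pcoa_{metric}.tsv", sep="\t")
            np.savetxt(
                out / f"eigenvalues_{metric}.tsv", ordn.eigenvalues, delimiter="\t"
            )
            res = permanova(
                D, type_of, n_perm=config.n_perm, seed=config.permutation_seed
            )
            manifest.setdefault("permanova", {})[metric] = {
                "pseudo_F": res.statistic,
                "p": res.permutation_p,
            }
            # Table-1-shaped PERMDISP: each human type vs mat, per timepoint
            for htype in HUMAN_TYPES:
                for tp in TIMEPOINTS:
                    ids = [
                        s
                        for s in rarefied.sample_ids
                        if rec_by_id[s].timepoint == tp
                        and rec_by_id[s].sample_type in (htype, "mat")
                    ]
                    groups = [rec_by_id[s].sample_type for s in ids]
                    if len(set(groups)) < 2 or min(
                        groups.count("mat"), len(groups) - groups.count("mat")
                    ) < 2:
                        continue
                    keep = [rarefied.sample_ids.index(s) for s in ids]
                    sub = D.submatrix(keep)
                    pres = permdisp(
                        sub, groups, n_perm=config.n_perm, seed=config.permutation_seed
                    )
                    permdisp_rows.append(
                        {
                            "metric": metric,
                            "human_type": htype,
                            "timepoint": tp,
                            "avg_dist_to_median_mat": pres.group_means.get("mat"),
                            "avg_dist_to_median_human": pres.group_means.get(htype),
                            "df_groups": pres.df_groups,
                            "df_residual": pres.df_residual,
                            "sum_sq_groups": pres.ss_groups,
                            "sum_sq_residual": pres.ss_residual,
                            "F": pres.f_statistic,
                            "Pr_gt_F": pres.f_p_value,
                            "perm_p": pres.permutation.permutation_p,
                        }
                    )
        pd.DataFrame(permdisp_rows).to_csv(out / "permdisp.tsv", sep="\t", index=False)
        manifest["stages"].append({"stage": stage, "metrics": list(config.distances)})

        stage = "models"
        model_rows = []
        traces: dict = {}
        for htype in HUMAN_TYPES:
            mdata = assemble_model_data(
                shared_recs, covariates, htype, exclude_antibiotics=config.exclude_antibiotics
            )
            if len(mdata) < 10 or mdata["subject"].nunique() < 2:
                manifest["warnings"].append(
                    f"models: skipped {htype} (only {len(mdata)} observations)"
                )
                continue
            fit, trace = forward_select(list(config.candidates), mdata)
            diag = None
            if fit.converged:
                diag = simulate_residuals(
                    fit, n_sim=config.n_sim_diagnostics, seed=config.diagnostics_seed
                )
            for name, (est, se, z, p) in fit.coefficients.items():
                model_rows.append(
                    {
                        "human_type": htype,
                        "timepoints": "all",
                        "term": name,
                        "estimate": est,
                        "se": se,
                        "z": z,
                        "p": p,
                        "n_obs": fit.n_obs,
                        "aic": fit.aic,
                        "random_sd": fit.random_intercept_sd,
                        "ks_p": None if diag is None else diag.ks_p,
                        "dispersion_p": None if diag is None else diag.dispersion_p,
                    }
                )
            tp_results, skipped = per_timepoint_models(list(config.candidates), mdata)
            for tp, reason in skipped.items():
                manifest["warnings"].append(f"models: {htype}/{tp} skipped: {reason}")
            for tp, (tp_fit, tp_trace) in tp_results.items():
                for name, (est, se, z, p) in tp_fit.coefficients.items():
                    model_rows.append(
                        {
                            "human_type": htype,
                            "timepoints": tp,
                            "term": name,
                            "estimate": est,
                            "se": se,
                            "z": z,
                            "p": p,
                            "n_obs": tp_fit.n_obs,
                            "aic": tp_fit.aic,
                            "random_sd": tp_fit.random_intercept_sd,
                            "ks_p": None,
                            "dispersion_p": None,
                        }
                    )
                traces[f"{htype}/{tp}"] = tp_trace.to_dict()
            traces[f"{htype}/all"] = trace.to_dict()
        pd.DataFrame(model_rows).to_csv(out / "glmm_models.tsv", sep="\t", index=False)
        (out / "selection_traces.json").write_text(
            json.dumps(traces, indent=2, default=float), encoding="utf-8"
        )
        manifest["stages"].append({"stage": stage, "models": len(traces)})

        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=float), encoding="utf-8"
        )
        return manifest
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}: {exc}\n", encoding="utf-8")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
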