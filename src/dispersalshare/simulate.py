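"""Generative model of a doormat/human shared-taxa study.

Subjects live in an urban or rural stratum, each stratum with its own
regional environmental taxon pool.  Every human body site carries a
subject-specific core community.  A per-observation dispersal probability
``d`` — a logistic function of subject covariates and timepoint — mixes the
environmental profile into human samples; mats mix a fraction ``h`` of
human-shed taxa into the environmental profile.  Reads are multinomial;
contaminant taxa are injected into samples and negative controls so that
the strict control filter can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from scipy.special import expit

from .asv_tables import (
    AsvTable,
    SampleRecord,
    SubjectCovariates,
    TaxonomyTable,
    HUMAN_TYPES,
    write_metadata,
    write_taxonomy,
)

_SITES = ("saliva", "skin", "feces")


@dataclass
class SimulationConfig:
    n_subjects: int = 24
    proportion_urban: float = 0.5
    timepoints: tuple[str, ...] = ("S", "A", "W")
    n_env_taxa: int = 300  # per urban/rural regional pool
    n_core_taxa: dict = field(
        default_factory=lambda: {"saliva": 60, "skin": 90, "feces": 70}
    )
    n_contaminant_taxa: int = 20
    n_offtarget_taxa: int = 0  # chloroplast/mitochondria-like lineages
    env_lognormal_mu: float = 0.0
    env_lognormal_sigma: float = 1.5
    # dispersal coefficients on the logit scale
    beta: dict = field(
        default_factory=lambda: {
            "intercept": -3.0,
            "built": 0.03,
            "outdoor": 0.0,
            "gardening": 0.0,
            "pets": 0.0,
            "handwashing": 0.0,
            "number_of_persons": 0.0,
            "real_mat_days": 0.0,
            "timepoint_A": 0.1,
            "timepoint_W": 0.9,
        }
    )
    human_shedding_rate: float = 0.005
    library_sizes: dict = field(
        default_factory=lambda: {
            "mat": (3000, 5000),
            "saliva": (1000, 2500),
            "skin": (1000, 2500),
            "feces": (1000, 2500),
        }
    )
    n_mat_replicates: int = 2
    n_negative_controls: int = 4
    missing_fraction: float = 0.02
    antibiotics_prevalence: float = 0.05
    contaminant_mean_count: float = 3.0
    contaminant_sample_fraction: float = 0.15
    control_crosstalk: bool = False  # real taxa leaking into controls
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.proportion_urban <= 1:
            raise ValueError("proportion_urban must be in [0,1]")
        if not 0 <= self.human_shedding_rate <= 1:
            raise ValueError("human_shedding_rate must be in [0,1]")
        if self.n_env_taxa < 1 or any(v < 1 for v in self.n_core_taxa.values()):
            raise ValueError("taxon pool sizes must be >= 1")
        if not 1 <= self.n_mat_replicates <= 3:
            raise ValueError("n_mat_replicates must be in 1..3")
        unknown_tp = set(self.timepoints) - {"S", "A", "W"}
        if unknown_tp:
            raise ValueError(f"unknown timepoints: {unknown_tp}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.pop("schema_version", None)
        if "timepoints" in raw:
            raw["timepoints"] = tuple(raw["timepoints"])
        if "library_sizes" in raw:
            raw["library_sizes"] = {
                k: tuple(v) for k, v in raw["library_sizes"].items()
            }
        defaults = cls()
        for key in ("n_core_taxa", "beta", "library_sizes"):
            if key in raw:
                merged = dict(getattr(defaults, key))
                merged.update(raw[key])
                raw[key] = merged
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["timepoints"] = list(self.timepoints)
        payload["library_sizes"] = {k: list(v) for k, v in self.library_sizes.items()}
        payload["schema_version"] = 1
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


@dataclass
class SimulatedStudy:
    table: AsvTable
    records: list[SampleRecord]
    covariates: list[SubjectCovariates]
    taxonomy: TaxonomyTable
    origin: dict[str, str]  # asv_id -> environmental | human_core | contaminant | offtarget
    true_dispersal: dict[tuple[str, str], float]  # (subject, timepoint) -> d
    config: SimulationConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table.write_tsv(outdir / "counts.tsv")
        write_metadata(outdir / "metadata.tsv", self.records, self.covariates)
        write_taxonomy(outdir / "taxonomy.tsv", self.taxonomy)
        rows = ["asv_id\torigin"] + [f"{a}\t{o}" for a, o in self.origin.items()]
        (outdir / "origin.tsv").write_text("\n".join(rows) + "\n", encoding="utf-8")
        disp = ["subject_id\ttimepoint\ttrue_dispersal"] + [
            f"{s}\t{t}\t{d:.8f}" for (s, t), d in self.true_dispersal.items()
        ]
        (outdir / "true_dispersal.tsv").write_text("\n".join(disp) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# covariates and dispersal
# ---------------------------------------------------------------------------


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    vals = rng.normal(mean, sd, size=size)
    return np.clip(vals, lo, hi)


def draw_covariates(config: SimulationConfig, seed: int | None = None) -> list[SubjectCovariates]:
    """Subjects with Table-3-like covariate distributions; a configurable
    fraction of covariate cells is blanked to exercise missing-data paths."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_subjects
    n_urban = int(round(config.proportion_urban * n))
    urban_flags = np.array(["u"] * n_urban + ["r"] * (n - n_urban))
    covs: list[SubjectCovariates] = []
    for i in range(n):
        urban = str(urban_flags[i])
        built = float(
            _truncnorm(rng, 70, 15, 0, 100) if urban == "u" else _truncnorm(rng, 15, 10, 0, 100)
        )
        cov = SubjectCovariates(
            subject_id=f"{urban}{i + 1:02d}",
            built=round(built, 1),
            outdoor=round(float(_truncnorm(rng, 1.0, 0.4, 0.0, 1.91)), 2),
            gardening="at_least_monthly" if rng.random() < 0.5 else "rarely",
            pets="yes" if rng.random() < 0.15 else "no",
            handwashing="many_times_a_day" if rng.random() < 0.7 else "max_once_a_day",
            number_of_persons=int(rng.integers(1, 6)),
            urban=urban,
            real_mat_days={
                tp: int(np.clip(round(rng.normal(14, 4)), 3, 30))
                for tp in config.timepoints
            },
            antibiotics_last_6mo={
                tp: bool(rng.random() < config.antibiotics_prevalence)
                for tp in config.timepoints
            },
        )
        if config.missing_fraction > 0:
            for name in ("built", "outdoor", "gardening", "pets", "handwashing",
                         "number_of_persons"):
                if rng.random() < config.missing_fraction:
                    setattr(cov, name, None)
            for tp in list(cov.real_mat_days):
                if rng.random() < config.missing_fraction:
                    del cov.real_mat_days[tp]
        covs.append(cov)
    return covs


_COV_NUMERIC = {
    "gardening": {"rarely": 0.0, "at_least_monthly": 1.0},
    "pets": {"no": 0.0, "yes": 1.0},
    "handwashing": {"max_once_a_day": 0.0, "many_times_a_day": 1.0},
}


def true_dispersal(
    cov: SubjectCovariates, timepoint: str, beta: Mapping[str, float]
) -> float:
    """Deterministic logistic dispersal probability for one observation."""
    eta = beta.get("intercept", 0.0)
    for name in ("built", "outdoor", "number_of_persons"):
        b = beta.get(name, 0.0)
        if b != 0.0:
            val = getattr(cov, name)
            if val is None:
                raise ValueError(
                    f"subject {cov.subject_id!r}: covariate {name!r} missing but has "
                    "a nonzero dispersal coefficient"
                )
            eta += b * float(val)
    b = beta.get("real_mat_days", 0.0)
    if b != 0.0:
        if timepoint not in cov.real_mat_days:
            raise ValueError(
                f"subject {cov.subject_id!r}: real_mat_days missing at {timepoint!r}"
            )
        eta += b * cov.real_mat_days[timepoint]
    for name, coding in _COV_NUMERIC.items():
        b = beta.get(name, 0.0)
        if b != 0.0:
            val = getattr(cov, name)
            if val is None:
                raise ValueError(
                    f"subject {cov.subject_id!r}: covariate {name!r} missing but has "
                    "a nonzero dispersal coefficient"
                )
            eta += b * coding[val]
    eta += beta.get(f"timepoint_{timepoint}", 0.0)
    return float(expit(eta))


# ---------------------------------------------------------------------------
# community profiles and sampling
# ---------------------------------------------------------------------------


def _lognormal_profile(rng, size, mu, sigma) -> np.ndarray:
    w = rng.lognormal(mu, sigma, size=size)
    return w / w.sum()


def simulate_sample(
    kind: str,
    env_profile: np.ndarray,
    core_profile: np.ndarray,
    d: float,
    h: float,
    library_size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Multinomial read counts over the full taxon axis.

    Human samples: (1-d) * subject core + d * regional environment.
    Mat samples:   (1-h) * regional environment + h * subject shed profile.
    """
    if library_size < 1:
        raise ValueError("library_size must be >= 1")
    if env_profile.sum() <= 0 or core_profile.sum() <= 0:
        raise ValueError("empty taxon pool")
    if kind == "mat":
        comp = (1.0 - h) * env_profile + h * core_profile
    else:
        comp = (1.0 - d) * core_profile + d * env_profile
    comp = comp / comp.sum()
    return rng.multinomial(library_size, comp)


def inject_contamination(
    study: SimulatedStudy, config: SimulationConfig, seed: int | None = None
) -> SimulatedStudy:
    """Add contaminant ASVs with small Poisson counts to a random subset of
    all samples and to every negative control at least once."""
    if config.n_contaminant_taxa == 0:
        return study
    rng = np.random.default_rng((config.seed if seed is None else seed) + 7_777)
    n_cont = config.n_contaminant_taxa
    cont_ids = [f"CONT_{i + 1:04d}" for i in range(n_cont)]
    table = study.table
    extra = np.zeros((table.n_samples, n_cont), dtype=np.int64)
    control_rows = [
        i
        for i, sid in enumerate(table.sample_ids)
        if any(r.sample_id == sid and r.sample_type == "negative_control" for r in study.records)
    ]
    for j in range(n_cont):
        hit = rng.random(table.n_samples) < config.contaminant_sample_fraction
        counts = rng.poisson(config.contaminant_mean_count, size=table.n_samples)
        extra[:, j] = np.where(hit, np.maximum(counts, 1), 0)
    # every control sees every contaminant at least once in expectation;
    # guarantee each contaminant is present in >= 1 control
    for j in range(n_cont):
        row = control_rows[int(rng.integers(len(control_rows)))]
        if extra[row, j] == 0:
            extra[row, j] = max(1, int(rng.poisson(config.contaminant_mean_count)))
    new_counts = np.hstack([table.counts, extra])
    new_table = AsvTable(list(table.sample_ids), list(table.asv_ids) + cont_ids, new_counts)
    origin = dict(study.origin)
    lineages = dict(study.taxonomy.lineages)
    for cid in cont_ids:
        origin[cid] = "contaminant"
        lineages[cid] = ("Bacteria", "Proteobacteria", "Contaminantia", f"Genus_{cid}")
    return SimulatedStudy(
        table=new_table,
        records=study.records,
        covariates=study.covariates,
        taxonomy=TaxonomyTable(lineages),
        origin=origin,
        true_dispersal=study.true_dispersal,
        config=config,
    )


_PHYLA = ("Proteobacteria", "Bacteroidetes", "Actinobacteria", "Firmicutes", "Acidobacteria")


def _synthetic_lineage(rng, asv_id: str) -> tuple[str, ...]:
    phylum = _PHYLA[int(rng.integers(len(_PHYLA)))]
    return (
        "Bacteria",
        phylum,
        f"Class_{phylum[:4]}",
        f"Order_{int(rng.integers(40)) + 1}",
        f"Family_{int(rng.integers(120)) + 1}",
        f"Genus_{asv_id}",
    )


def generate_study(config: SimulationConfig) -> SimulatedStudy:
    """Full factorial subjects x timepoints x sample types (no skin in
    winter), mat replicates, negative controls, contaminants, ground truth.
    Bit-reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    covs = draw_covariates(config, seed=config.seed + 1)

    # --- taxon axis -------------------------------------------------------
    env_ids = {
        "u": [f"ENVU_{i + 1:04d}" for i in range(config.n_env_taxa)],
        "r": [f"ENVR_{i + 1:04d}" for i in range(config.n_env_taxa)],
    }
    core_ids = {
        site: [f"CORE_{site}_{i + 1:04d}" for i in range(config.n_core_taxa[site])]
        for site in _SITES
    }
    off_ids = [f"OFF_{i + 1:04d}" for i in range(config.n_offtarget_taxa)]
    all_ids = env_ids["u"] + env_ids["r"] + sum(core_ids.values(), []) + off_ids
    index = {a: i for i, a in enumerate(all_ids)}
    n_taxa = len(all_ids)

    origin = {a: "environmental" for a in env_ids["u"] + env_ids["r"]}
    for site in _SITES:
        origin.update({a: "human_core" for a in core_ids[site]})
    origin.update({a: "offtarget" for a in off_ids})

    lineages = {a: _synthetic_lineage(rng, a) for a in all_ids if not a.startswith("OFF_")}
    _off_kinds = ("Chloroplast", "Mitochondria", "Eukaryota")
    for i, a in enumerate(off_ids):
        kind = _off_kinds[i % len(_off_kinds)]
        if kind == "Chloroplast":
            lineages[a] = ("Bacteria", "Cyanobacteria", "Chloroplast", f"Genus_{a}")
        elif kind == "Mitochondria":
            lineages[a] = ("Bacteria", "Proteobacteria", "Rickettsiales", "Mitochondria")
        else:
            lineages[a] = ("Eukaryota", "Fungi", f"Genus_{a}")

    # --- profiles over the full axis -------------------------------------
    env_profile = {}
    for stratum in ("u", "r"):
        p = np.zeros(n_taxa)
        cols = [index[a] for a in env_ids[stratum]]
        p[cols] = _lognormal_profile(
            rng, len(cols), config.env_lognormal_mu, config.env_lognormal_sigma
        )
        if off_ids:  # off-target reads ride along with environmental material
            ocols = [index[a] for a in off_ids]
            p[ocols] = 0.02 / len(ocols)
            p /= p.sum()
        env_profile[stratum] = p

    core_profile: dict[tuple[str, str], np.ndarray] = {}
    shed_profile: dict[str, np.ndarray] = {}
    for cov in covs:
        combined = np.zeros(n_taxa)
        for site in _SITES:
            p = np.zeros(n_taxa)
            cols = [index[a] for a in core_ids[site]]
            p[cols] = _lognormal_profile(rng, len(cols), 0.0, 1.0)
            core_profile[(cov.subject_id, site)] = p
            combined += p
        shed_profile[cov.subject_id] = combined / combined.sum()

    # --- samples ----------------------------------------------------------
    sample_ids: list[str] = []
    records: list[SampleRecord] = []
    rows: list[np.ndarray] = []
    true_d: dict[tuple[str, str], float] = {}
    h = config.human_shedding_rate
    beta_full = {**SimulationConfig().beta, **config.beta}

    def lib(kind: str) -> int:
        lo, hi = config.library_sizes[kind]
        return int(rng.integers(lo, hi + 1))

    for cov in covs:
        for tp in config.timepoints:
            try:
                d = true_dispersal(cov, tp, beta_full)
            except ValueError:
                # missing covariate with nonzero coefficient: fall back to the
                # population-typical value so the sample still exists
                d = float(expit(beta_full["intercept"] + beta_full.get(f"timepoint_{tp}", 0.0)))
            true_d[(cov.subject_id, tp)] = d
            env = env_profile[cov.urban]
            for site in _SITES:
                if site == "skin" and tp == "W":
                    continue  # no winter skin sampling in the emulated design
                sid = f"{cov.subject_id}_{site}_{tp}"
                counts = simulate_sample(
                    site, env, core_profile[(cov.subject_id, site)], d, h, lib(site), rng
                )
                sample_ids.append(sid)
                records.append(SampleRecord(sid, cov.subject_id, site, tp, 1))
                rows.append(counts)
            for rep in range(1, config.n_mat_replicates + 1):
                sid = f"{cov.subject_id}_mat_{tp}_r{rep}"
                counts = simulate_sample(
                    "mat", env, shed_profile[cov.subject_id], d, h, lib("mat"), rng
                )
                sample_ids.append(sid)
                records.append(SampleRecord(sid, cov.subject_id, "mat", tp, rep))
                rows.append(counts)

    for i in range(config.n_negative_controls):
        sid = f"NC{i + 1:02d}"
        counts = np.zeros(n_taxa, dtype=np.int64)
        if config.control_crosstalk:
            donor = rng.integers(len(rows))
            hop = rng.binomial(rows[donor], 0.001)
            counts = counts + hop
        sample_ids.append(sid)
        records.append(SampleRecord(sid, None, "negative_control", "S", i + 1))
        rows.append(counts)

    table = AsvTable(sample_ids, all_ids, np.vstack(rows))
    study = SimulatedStudy(
        table=table,
        records=records,
        covariates=covs,
        taxonomy=TaxonomyTable(lineages),
        origin=origin,
        true_dispersal=true_d,
        config=config,
    )
    return inject_contamination(study, config)
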