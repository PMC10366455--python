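"""Seeded synthetic cohort generator.

Produces a full three-group cohort (control / CAP admission / CAP
recovery) with the statistical structure the analysis pipeline assumes:

- negative-binomial RNA counts with lognormal library sizes and a
  mean-dispersion trend ``phi(mu) = a / mu + phi0``
- planted co-expression modules: blocks of genes sharing a standard-normal
  latent factor (per-gene loading, on the log2-mean scale) whose mean is
  shifted in admission samples and partially restored in recovery
- planted differential expression concentrated in named pathways
- a GMT gene-set collection containing the planted pathways plus random
  null sets
- a lognormal metabolite matrix with additive group shifts on the log scale
- a plasma biomarker and ex vivo stimulated-MPO phenotypes generated as
  (monotone transforms of) linear functions of the first module's latent
  factor plus noise, so pathway-phenotype correlations are planted with a
  known coefficient

Every random draw comes from one ``numpy`` Generator seeded from the
config, so identical seeds give bit-identical outputs. The ground truth of
each draw (DE genes, module labels, latent factors, planted effects) is
returned alongside the data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CountMatrix,
    GeneSetCollection,
    SampleTable,
    write_counts,
    write_gmt,
    write_metabolites,
)

logger = logging.getLogger(__name__)


@dataclass
class ModuleSpec:
    """One planted co-expression module.

    loading : per-gene coefficient on the shared latent factor (log2 scale)
    group_shift : additive shift of the factor mean in admission samples,
        in factor SD units; recovery samples get ``group_shift *
        recovery_attenuation``.
    """

    name: str
    size: int
    loading: float = 1.0
    group_shift: float = 0.0


@dataclass
class DESpec:
    """Planted differential expression within one named pathway."""

    pathway: str
    log2fc: float
    fraction: float = 1.0


@dataclass
class SimulationConfig:
    seed: int = 0
    n_control: int = 29
    n_admission: int = 64
    n_recovery: int = 34
    n_genes: int = 5000
    baseline_log_mean: float = np.log(150.0)
    baseline_log_sd: float = 1.2
    planted_modules: list[ModuleSpec] = field(default_factory=lambda: [
        ModuleSpec("neutrophil_degranulation", size=80, loading=1.0, group_shift=2.0),
        ModuleSpec("innate_immune_system", size=80, loading=1.0, group_shift=1.0),
        ModuleSpec("tca_cycle", size=60, loading=1.0, group_shift=0.0),
    ])
    de_spec: list[DESpec] = field(default_factory=lambda: [
        DESpec("glycolysis", log2fc=1.5, fraction=0.8),
        DESpec("amino_acid_metabolism", log2fc=-1.5, fraction=0.8),
    ])
    extra_pathways: list[str] = field(default_factory=lambda: [
        "glycolysis", "glycogenolysis", "amino_acid_metabolism", "lipid_metabolism",
        "tlr_cascades",
    ])
    genes_per_pathway: int = 50
    n_null_sets: int = 5
    recovery_attenuation: float = 0.1
    dispersion_a: float = 3.0
    dispersion_phi0: float = 0.1
    libsize_log_mean: float = np.log(1e6)
    libsize_log_sd: float = 0.3
    n_metabolites: int = 40
    n_met_shifted: int = 5
    metabolite_shift_sd: float = 1.5
    metabolite_log_sd: float = 0.5
    n_met_control: int = 26
    n_met_admission: int = 50
    biomarker_rho: float = 0.7       # planted factor-biomarker correlation (Pearson, latent scale)
    mpo_factor_coef: float = 0.4
    frac_severe: float = 0.3

    def validate(self) -> None:
        if min(self.n_control, self.n_admission, self.n_recovery) < 2:
            raise ValueError("each group needs at least 2 samples")
        if not 0.0 <= self.recovery_attenuation <= 1.0:
            raise ValueError("recovery_attenuation must lie in [0, 1]")
        for d in self.de_spec:
            if not 0.0 <= d.fraction <= 1.0:
                raise ValueError("DE fraction must lie in [0, 1]")
        if abs(self.biomarker_rho) > 1.0:
            raise ValueError("biomarker_rho must lie in [-1, 1]")
        if self.biomarker_rho != 0.0 and not self.planted_modules:
            raise ValueError(
                "planted biomarker correlation requires at least one planted module"
            )
        if self.n_met_control > self.n_control or self.n_met_admission > self.n_admission:
            raise ValueError("metabolome subset larger than cohort group")
        needed = sum(m.size for m in self.planted_modules)
        needed += self.genes_per_pathway * len(self.extra_pathways)
        if needed > self.n_genes:
            raise ValueError("planted structures need more genes than n_genes")


@dataclass
class SyntheticTruth:
    """Ground truth of one generative draw."""

    de_genes: dict[str, dict[str, float]]       # pathway -> {gene: log2fc}
    module_labels: pd.Series                    # gene -> module name or "none"
    factors: pd.DataFrame                       # modules x samples latent factors
    metabolite_effects: dict[str, float]        # metabolite -> shift (SD units)
    biomarker_rho: float                        # planted factor-biomarker correlation
    biomarker_pathway: str | None               # pathway whose factor drives the biomarker


@dataclass
class SyntheticCohort:
    counts: CountMatrix
    samples: SampleTable
    sets: GeneSetCollection
    metabolites: pd.DataFrame
    biomarkers: pd.DataFrame
    stimulation: pd.DataFrame
    truth: SyntheticTruth
    config: SimulationConfig


def _sample_ids(cfg: SimulationConfig) -> tuple[list[str], list[str], list[str]]:
    ctrl = [f"ctrl_{i + 1:03d}" for i in range(cfg.n_control)]
    adm = [f"adm_{i + 1:03d}" for i in range(cfg.n_admission)]
    rec = [f"rec_{i + 1:03d}" for i in range(cfg.n_recovery)]
    return ctrl, adm, rec


def simulate_cohort(cfg: SimulationConfig) -> SyntheticCohort:
    """Draw one full synthetic cohort (see module docstring for the model)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    ctrl, adm, rec = _sample_ids(cfg)
    sample_ids = ctrl + adm + rec
    n = len(sample_ids)
    is_adm = np.array([s.startswith("adm") for s in sample_ids], dtype=float)
    is_rec = np.array([s.startswith("rec") for s in sample_ids], dtype=float)

    gene_ids = [f"g{i + 1:05d}" for i in range(cfg.n_genes)]

    # --- sample metadata (recovery subjects are re-sampled admission subjects)
    subj = ([f"subj_c{i + 1:03d}" for i in range(cfg.n_control)]
            + [f"subj_p{i + 1:03d}" for i in range(cfg.n_admission)]
            + [f"subj_p{i + 1:03d}" for i in range(cfg.n_recovery)])
    severe = np.zeros(n, dtype=bool)
    adm_slice = slice(cfg.n_control, cfg.n_control + cfg.n_admission)
    severe[adm_slice] = rng.random(cfg.n_admission) < cfg.frac_severe
    samples = SampleTable(pd.DataFrame({
        "sample_id": sample_ids,
        "subject_id": subj,
        "group": (["control"] * cfg.n_control + ["cap_admission"] * cfg.n_admission
                  + ["cap_recovery"] * cfg.n_recovery),
        "severe": severe,
    }))

    # --- gene block layout: modules first, then extra pathways, rest background
    module_labels = pd.Series("none", index=gene_ids, dtype=object)
    sets: dict[str, tuple[str, list[str]]] = {}
    cursor = 0
    module_gene_idx: dict[str, np.ndarray] = {}
    for m in cfg.planted_modules:
        idx = np.arange(cursor, cursor + m.size)
        cursor += m.size
        genes = [gene_ids[i] for i in idx]
        module_labels.iloc[idx] = m.name
        module_gene_idx[m.name] = idx
        sets[m.name] = (f"planted module {m.name}", genes)
    pathway_gene_idx: dict[str, np.ndarray] = dict(module_gene_idx)
    for pw in cfg.extra_pathways:
        idx = np.arange(cursor, cursor + cfg.genes_per_pathway)
        cursor += cfg.genes_per_pathway
        pathway_gene_idx[pw] = idx
        sets[pw] = (f"planted pathway {pw}", [gene_ids[i] for i in idx])
    background = np.arange(cursor, cfg.n_genes)
    for k in range(cfg.n_null_sets):
        size = min(cfg.genes_per_pathway, background.size)
        if size < 2:
            break
        pick = np.sort(rng.choice(background, size=size, replace=False))
        sets[f"null_set_{k + 1}"] = ("random null set", [gene_ids[i] for i in pick])

    # --- latent factors per module: N(0,1) + group shift on the mean
    factors = {}
    for m in cfg.planted_modules:
        f = rng.standard_normal(n)
        f = f + m.group_shift * is_adm + m.group_shift * cfg.recovery_attenuation * is_rec
        factors[m.name] = f
    factors_df = pd.DataFrame(factors, index=sample_ids).T

    # --- log2-scale effect matrix
    effect = np.zeros((cfg.n_genes, n))
    de_truth: dict[str, dict[str, float]] = {}
    for d in cfg.de_spec:
        if d.pathway not in pathway_gene_idx:
            raise ValueError(f"de_spec names unknown pathway {d.pathway!r}")
        idx = pathway_gene_idx[d.pathway]
        n_aff = int(round(d.fraction * idx.size))
        affected = idx[:n_aff]
        if d.log2fc != 0.0 and n_aff:
            effect[np.ix_(affected, np.flatnonzero(is_adm))] += d.log2fc
            effect[np.ix_(affected, np.flatnonzero(is_rec))] += (
                d.log2fc * cfg.recovery_attenuation)
            de_truth.setdefault(d.pathway, {}).update(
                {gene_ids[i]: d.log2fc for i in affected})
    for m in cfg.planted_modules:
        idx = module_gene_idx[m.name]
        if m.loading != 0.0:
            effect[idx, :] += m.loading * factors_df.loc[m.name].to_numpy()[None, :]
        if m.group_shift != 0.0 and m.loading != 0.0:
            lfc = m.loading * m.group_shift
            de_truth.setdefault(m.name, {}).update({gene_ids[i]: lfc for i in idx})

    # --- NB counts
    baseline = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=cfg.n_genes)
    libsize = rng.lognormal(cfg.libsize_log_mean, cfg.libsize_log_sd, size=n)
    libsize = libsize * (1e6 / np.median(libsize))
    mu = (libsize[None, :] / 1e6) * baseline[:, None] * np.exp2(effect)
    phi = cfg.dispersion_a / np.maximum(baseline, 1e-8) + cfg.dispersion_phi0
    r = 1.0 / np.maximum(phi, 1e-8)
    p = r[:, None] / (r[:, None] + mu)
    counts = rng.negative_binomial(r[:, None], p)
    cm = CountMatrix(gene_ids, sample_ids, counts)

    # --- metabolites: lognormal with additive group shift on the log scale
    met_ids = [f"met_{i + 1:03d}" for i in range(cfg.n_metabolites)]
    met_samples = ctrl[: cfg.n_met_control] + adm[: cfg.n_met_admission]
    m_is_adm = np.array([s.startswith("adm") for s in met_samples], dtype=float)
    met_effects = {mid: 0.0 for mid in met_ids}
    for mid in met_ids[: cfg.n_met_shifted]:
        met_effects[mid] = cfg.metabolite_shift_sd
    base_log = rng.normal(np.log(1e4), 1.0, size=cfg.n_metabolites)
    shifts = np.array([met_effects[mid] for mid in met_ids])
    log_int = (base_log[:, None]
               + cfg.metabolite_log_sd * shifts[:, None] * m_is_adm[None, :]
               + cfg.metabolite_log_sd * rng.standard_normal((cfg.n_metabolites, len(met_samples))))
    metabolites = pd.DataFrame(np.exp(log_int), index=met_ids, columns=met_samples)

    # --- biomarker tied to the first planted module's latent factor
    bm_rows = []
    if cfg.planted_modules:
        driver = cfg.planted_modules[0].name
        f = factors_df.loc[driver].to_numpy()
        fz = (f - f.mean()) / (f.std() or 1.0)
        latent = (cfg.biomarker_rho * fz
                  + np.sqrt(max(0.0, 1.0 - cfg.biomarker_rho ** 2)) * rng.standard_normal(n))
    else:
        driver = None
        latent = rng.standard_normal(n)
    il6 = 20.0 * np.exp(0.8 * latent)
    lloq, uloq = 5.0, 500.0
    for sid, v in zip(sample_ids, il6):
        bm_rows.append({"sample_id": sid, "analyte": "il6",
                        "value": float(v), "lloq": lloq, "uloq": uloq})
    crp = 30.0 * np.exp(0.5 * (0.4 * latent + rng.standard_normal(n)))
    for sid, v in zip(sample_ids, crp):
        bm_rows.append({"sample_id": sid, "analyte": "crp",
                        "value": float(v), "lloq": 1.0, "uloq": 2000.0})
    biomarkers = pd.DataFrame(bm_rows)

    # --- ex vivo stimulation MPO (vehicle / LPS / K. pneumoniae)
    veh = 100.0 * np.exp(0.3 * rng.standard_normal(n))
    d_lps = np.maximum(
        200.0 + 120.0 * is_adm + 80.0 * cfg.mpo_factor_coef * latent
        + 60.0 * rng.standard_normal(n), 5.0)
    d_kp = np.maximum(
        150.0 + 100.0 * is_adm + 60.0 * cfg.mpo_factor_coef * latent
        + 50.0 * rng.standard_normal(n), 5.0)
    stim_rows = []
    for i, sid in enumerate(sample_ids):
        stim_rows.append({"sample_id": sid, "condition": "vehicle", "mpo": float(veh[i])})
        stim_rows.append({"sample_id": sid, "condition": "lps", "mpo": float(veh[i] + d_lps[i])})
        stim_rows.append({"sample_id": sid, "condition": "kpneu", "mpo": float(veh[i] + d_kp[i])})
    stimulation = pd.DataFrame(stim_rows)

    truth = SyntheticTruth(
        de_genes=de_truth,
        module_labels=module_labels,
        factors=factors_df,
        metabolite_effects=met_effects,
        biomarker_rho=cfg.biomarker_rho if driver else 0.0,
        biomarker_pathway=driver,
    )
    return SyntheticCohort(cm, samples, GeneSetCollection(sets), metabolites,
                           biomarkers, stimulation, truth, cfg)


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A cohort config with every planted effect switched off.

    Module latent factors are kept (co-expression without any group
    association) but their group shifts, all DE fold changes and all
    metabolite/biomarker effects are zero.
    """
    cfg = SimulationConfig(seed=seed, **overrides)
    cfg.planted_modules = [dataclasses.replace(m, group_shift=0.0)
                           for m in cfg.planted_modules]
    cfg.de_spec = []
    cfg.n_met_shifted = 0
    cfg.biomarker_rho = 0.0
    return cfg


def make_worked_fixture() -> SyntheticCohort:
    """Deterministic micro-cohort: 20 genes, 3 groups x 4 samples, 2 gene sets.

    Used in documentation and exact-value tests; always generated with the
    same fixed configuration and seed.
    """
    cfg = SimulationConfig(
        seed=12345,
        n_control=4, n_admission=4, n_recovery=4,
        n_genes=20,
        planted_modules=[ModuleSpec("mini_module", size=6, loading=1.0, group_shift=2.0)],
        de_spec=[DESpec("mini_pathway", log2fc=1.0, fraction=1.0)],
        extra_pathways=["mini_pathway"],
        genes_per_pathway=6,
        n_null_sets=0,
        n_metabolites=6,
        n_met_shifted=2,
        n_met_control=4,
        n_met_admission=4,
        libsize_log_sd=0.1,
    )
    return simulate_cohort(cfg)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, str]:
    """Write every cohort table plus truth.json into a directory.

    Returns a mapping of logical names to file paths. All outputs are plain
    text with deterministic formatting, so identical seeds give
    byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"seed={cohort.config.seed}"
    paths = {
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.csv",
        "gene_sets": outdir / "gene_sets.gmt",
        "metabolites": outdir / "metabolites.tsv",
        "biomarkers": outdir / "biomarkers.csv",
        "stimulation": outdir / "stimulation.csv",
        "truth": outdir / "truth.json",
    }
    write_counts(cohort.counts, paths["counts"], comment=tag)
    cohort.samples.frame.to_csv(paths["samples"], index=False, lineterminator="\n")
    write_gmt(cohort.sets, paths["gene_sets"])
    write_metabolites(cohort.metabolites, paths["metabolites"], comment=tag)
    cohort.biomarkers.to_csv(paths["biomarkers"], index=False, lineterminator="\n")
    cohort.stimulation.to_csv(paths["stimulation"], index=False, lineterminator="\n")
    truth = {
        "seed": cohort.config.seed,
        "de_genes": cohort.truth.de_genes,
        "module_labels": {g: m for g, m in cohort.truth.module_labels.items()
                          if m != "none"},
        "factors": {m: [round(float(v), 10) for v in cohort.truth.factors.loc[m]]
                    for m in cohort.truth.factors.index},
        "factor_sample_ids": list(cohort.truth.factors.columns),
        "metabolite_effects": cohort.truth.metabolite_effects,
        "biomarker_rho": cohort.truth.biomarker_rho,
        "biomarker_pathway": cohort.truth.biomarker_pathway,
    }
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}
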