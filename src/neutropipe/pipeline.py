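"""Config-driven orchestration of the full analysis.

``run_all`` executes (optional) simulation → differential expression →
pathway scoring → GSEA → co-expression network → trajectory clustering →
metabolomics → phenotype association in dependency order, writing one TSV
per result and a ``manifest.json`` recording the seed, package version,
config hash and a SHA-256 digest of every input and output. Validation
errors (unknown keys, missing files, both-or-neither input modes) are all
collected and reported before any stage runs; a failing stage halts its
dependents but leaves completed outputs in place.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__, association, diffexpr, enrichment, metabolomics
from . import network as net
from . import scoring, trajectories
from .io import (
    clean_biomarkers,
    read_biomarkers,
    read_counts,
    read_gmt,
    read_metabolites,
    read_samples,
    read_stimulation,
    write_table,
)
from .simulate import DESpec, ModuleSpec, SimulationConfig, simulate_cohort, write_cohort

logger = logging.getLogger(__name__)

_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "output_dir", "log_level", "simulation", "inputs", "de", "scoring",
         "gsea", "wgcna", "trajectories", "metabolomics", "association"},
    "inputs": {"counts", "samples", "gmt", "metabolites", "biomarkers", "stimulation"},
    "simulation": {f.name for f in dataclasses.fields(SimulationConfig)}
                  | {"planted_modules", "de_spec"},
    "de": {"contrast", "min_nonzero"},
    "scoring": {"fit_contrast", "weights_mode"},
    "gsea": {"n_perm", "min_size", "max_size", "weight"},
    "wgcna": {"variance_fraction", "min_size", "merge_threshold", "mm_cutoff",
              "network", "beta", "hub_top_n"},
    "trajectories": {"alpha", "min_genes", "k_min", "k_max"},
    "metabolomics": {"contrast", "transform", "welch"},
    "association": {"stratify"},
}


def load_config(source: str | Path | dict[str, Any]) -> dict[str, Any]:
    """Load and validate a pipeline config from YAML (or an equivalent dict).

    All problems are collected and raised together so a user can fix a
    config in one pass.
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh) or {}
        base = Path(source).parent
    else:
        cfg = dict(source)
        base = Path(".")
    errors: list[str] = []
    unknown = set(cfg) - _SCHEMA[""]
    for k in sorted(unknown):
        errors.append(f"unknown top-level key: {k!r}")
    for section, allowed in _SCHEMA.items():
        if not section or section not in cfg:
            continue
        block = cfg[section]
        if not isinstance(block, dict):
            errors.append(f"section {section!r} must be a mapping")
            continue
        for k in sorted(set(block) - allowed):
            errors.append(f"unknown key {section}.{k}")
    has_sim = "simulation" in cfg
    has_inputs = "inputs" in cfg
    if has_sim == has_inputs:
        errors.append("config must contain exactly one of 'simulation' or 'inputs'")
    if has_inputs and isinstance(cfg.get("inputs"), dict):
        for name, p in cfg["inputs"].items():
            path = Path(p)
            if not path.is_absolute():
                path = base / path
            if not path.exists():
                errors.append(f"inputs.{name}: file not found: {path}")
            cfg["inputs"][name] = str(path)
    if "output_dir" not in cfg:
        errors.append("config must set output_dir")
    if errors:
        raise ValueError("invalid pipeline config:\n  " + "\n  ".join(errors))
    cfg.setdefault("seed", 0)
    cfg.setdefault("log_level", "INFO")
    return cfg


def _sim_config(block: dict[str, Any], seed: int) -> SimulationConfig:
    block = dict(block)
    block.setdefault("seed", seed)
    if "planted_modules" in block:
        block["planted_modules"] = [ModuleSpec(**m) for m in block["planted_modules"]]
    if "de_spec" in block:
        block["de_spec"] = [DESpec(**d) for d in block["de_spec"]]
    return SimulationConfig(**block)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(cfg: dict[str, Any]) -> str:
    # output_dir and log_level are execution details, not analysis parameters
    core = {k: v for k, v in cfg.items() if k not in ("output_dir", "log_level")}
    return hashlib.sha256(
        json.dumps(core, sort_keys=True, default=str).encode()).hexdigest()[:16]


# stage -> stages it needs to have succeeded
_DEPS = {
    "simulate": [],
    "de": [], "scoring": [], "wgcna": [],
    "gsea": ["de"],
    "trajectories": ["de"],
    "metabolomics": [],
    "association": ["scoring"],
}


def run_all(source: str | Path | dict[str, Any]) -> dict[str, Any]:
    """Run the whole pipeline; returns the manifest dictionary."""
    cfg = load_config(source)
    outdir = Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, str(cfg["log_level"]).upper(), logging.INFO))
    fh = logging.FileHandler(outdir / "pipeline.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logging.getLogger().addHandler(fh)
    seed = int(cfg["seed"])
    tag = f"seed={seed} config={_config_hash(cfg)}"

    manifest: dict[str, Any] = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": _config_hash(cfg),
        "inputs": {},
        "stages": {},
    }
    outputs: dict[str, list[str]] = {}
    failed: set[str] = set()

    def record(stage: str, files: list[Path], status: str = "ok", error: str = "") -> None:
        rel = [str(f.relative_to(outdir)) for f in files]
        entry: dict[str, Any] = {"status": status, "outputs": {}}
        for r, f in zip(rel, files):
            if f.exists():
                entry["outputs"][r] = _sha256(f)
        if error:
            entry["error"] = error
        manifest["stages"][stage] = entry
        outputs[stage] = rel

    def blocked(stage: str) -> bool:
        bad = [d for d in _DEPS[stage] if d in failed]
        if bad:
            logger.error("stage %s skipped: dependency failed (%s)", stage, bad)
            manifest["stages"][stage] = {"status": "skipped",
                                         "blocked_by": bad, "outputs": {}}
            failed.add(stage)
            return True
        return False

    # ----- inputs
    if "simulation" in cfg:
        sim_cfg = _sim_config(cfg["simulation"], seed)
        cohort = simulate_cohort(sim_cfg)
        sim_dir = outdir / "cohort"
        paths = write_cohort(cohort, sim_dir)
        record("simulate", [Path(p) for p in paths.values()])
        counts, samples, sets = cohort.counts, cohort.samples, cohort.sets
        metab, biom, stim = cohort.metabolites, cohort.biomarkers, cohort.stimulation
        manifest["inputs"] = {k: _sha256(Path(v)) for k, v in paths.items()}
    else:
        ip = cfg["inputs"]
        counts = read_counts(ip["counts"])
        samples = read_samples(ip["samples"])
        sets = read_gmt(ip["gmt"])
        metab = read_metabolites(ip["metabolites"]) if "metabolites" in ip else None
        biom = read_biomarkers(ip["biomarkers"]) if "biomarkers" in ip else None
        stim = read_stimulation(ip["stimulation"]) if "stimulation" in ip else None
        manifest["inputs"] = {k: _sha256(Path(v)) for k, v in ip.items()}
    samples.require_samples(counts.sample_ids)
    expr = diffexpr.log_norm_expression(counts)

    de_table = None
    score_matrix = None

    # ----- differential expression
    de_cfg = cfg.get("de", {})
    contrast = tuple(de_cfg.get("contrast", ("cap_admission", "control")))
    try:
        de_table = diffexpr.fit_de(counts, samples, groups=contrast,
                                   min_nonzero=int(de_cfg.get("min_nonzero", 3)))
        f = outdir / "de.tsv"
        write_table(de_table, f, comment=tag)
        record("de", [f])
    except Exception as exc:  # noqa: BLE001 - stage isolation is deliberate
        logger.exception("DE stage failed")
        record("de", [], status="failed", error=str(exc))
        failed.add("de")

    # ----- pathway scoring
    sc_cfg = cfg.get("scoring", {})
    try:
        scalings = scoring.fit_scalings(
            expr, samples,
            contrast=tuple(sc_cfg.get("fit_contrast", ("cap_admission", "control"))),
            weights_mode=sc_cfg.get("weights_mode", "balanced"))
        psm = scoring.pathway_scores(expr, scalings, sets)
        score_matrix = psm.scores
        tests = scoring.score_group_test(psm, samples)
        f1, f2, f3 = outdir / "scalings.tsv", outdir / "scores.tsv", outdir / "score_tests.tsv"
        write_table(scalings, f1, comment=tag)
        sm = psm.scores.reset_index().rename(columns={"index": "pathway"})
        write_table(sm, f2, comment=tag)
        write_table(tests, f3, comment=tag)
        record("scoring", [f1, f2, f3])
    except Exception as exc:  # noqa: BLE001
        logger.exception("scoring stage failed")
        record("scoring", [], status="failed", error=str(exc))
        failed.add("scoring")

    # ----- GSEA
    if not blocked("gsea"):
        g_cfg = cfg.get("gsea", {})
        try:
            rank = de_table.dropna(subset=["wald_stat"]).set_index("gene_id")["wald_stat"]
            gsea = enrichment.gsea_preranked(
                rank, sets, n_perm=int(g_cfg.get("n_perm", 1000)), seed=seed,
                weight=float(g_cfg.get("weight", 1.0)),
                min_size=int(g_cfg.get("min_size", 10)),
                max_size=int(g_cfg.get("max_size", 500)))
            f = outdir / "gsea.tsv"
            write_table(gsea, f, comment=tag)
            record("gsea", [f])
        except Exception as exc:  # noqa: BLE001
            logger.exception("GSEA stage failed")
            record("gsea", [], status="failed", error=str(exc))
            failed.add("gsea")

    # ----- co-expression network
    w_cfg = cfg.get("wgcna", {})
    try:
        wres = net.run_wgcna(
            expr, samples,
            variance_fraction=float(w_cfg.get("variance_fraction", 0.10)),
            min_size=int(w_cfg.get("min_size", 40)),
            merge_threshold=float(w_cfg.get("merge_threshold", 0.75)),
            mm_cutoff=float(w_cfg.get("mm_cutoff", 0.7)),
            network=w_cfg.get("network", "unsigned"),
            beta=w_cfg.get("beta"),
            hub_top_n=int(w_cfg.get("hub_top_n", 20)))
        d = wres.decomposition
        mod_df = pd.DataFrame({"gene_id": d.labels.index, "module": d.labels.to_numpy()})
        if d.mm is not None and not d.mm.empty:
            own = [d.mm.loc[g, m] if m in d.mm.columns else np.nan
                   for g, m in zip(d.labels.index, d.labels.to_numpy())]
            mod_df["mm_own_module"] = own
        if d.gs is not None:
            mod_df["gs"] = d.gs.loc[mod_df["gene_id"]].to_numpy()
        files = []
        f = outdir / "modules.tsv"
        write_table(mod_df, f, comment=tag)
        files.append(f)
        f = outdir / "eigengenes.tsv"
        eg = d.eigengenes.reset_index().rename(columns={"index": "module"})
        write_table(eg, f, comment=tag)
        files.append(f)
        f = outdir / "softthreshold.tsv"
        write_table(wres.scan.to_frame(), f, comment=tag)
        files.append(f)
        f = outdir / "module_trait.tsv"
        write_table(wres.trait_stats, f, comment=tag)
        files.append(f)
        f = outdir / "hubs.tsv"
        write_table(wres.hubs, f, comment=tag)
        files.append(f)
        # SIF-like edge list of the thresholded module graphs
        edges = []
        gi = {g: i for i, g in enumerate(wres.kept_genes)}
        for m in d.modules():
            genes = d.module_genes(m)
            if len(genes) < 3:
                continue
            idx = np.array([gi[g] for g in genes])
            sub = wres.tom[np.ix_(idx, idx)]
            cut = np.quantile(sub[np.triu_indices(len(genes), k=1)], 0.95)
            ii, jj = np.nonzero(np.triu(sub >= cut, k=1))
            for i, j in zip(ii, jj):
                edges.append({"gene1": genes[i], "gene2": genes[j],
                              "module": m, "tom": sub[i, j]})
        f = outdir / "edges.tsv"
        write_table(pd.DataFrame(edges, columns=["gene1", "gene2", "module", "tom"]),
                    f, comment=tag)
        files.append(f)
        record("wgcna", files)
    except Exception as exc:  # noqa: BLE001
        logger.exception("network stage failed")
        record("wgcna", [], status="failed", error=str(exc))
        failed.add("wgcna")

    # ----- trajectory clustering
    if not blocked("trajectories"):
        t_cfg = cfg.get("trajectories", {})
        try:
            alpha = float(t_cfg.get("alpha", 0.05))
            degs = list(de_table.loc[de_table["bh_adjusted_p"] < alpha, "gene_id"])
            tc = trajectories.cluster_trajectories(
                expr, samples, degs,
                k_range=range(int(t_cfg.get("k_min", 2)), int(t_cfg.get("k_max", 8)) + 1),
                min_genes=int(t_cfg.get("min_genes", 15)))
            f1 = outdir / "trajectories.tsv"
            write_table(tc.to_frame(), f1, comment=tag)
            f2 = outdir / "trajectory_profiles.tsv"
            prof = tc.profiles.reset_index().rename(columns={"index": "cluster"})
            write_table(prof, f2, comment=tag)
            record("trajectories", [f1, f2])
        except Exception as exc:  # noqa: BLE001
            logger.exception("trajectory stage failed")
            record("trajectories", [], status="failed", error=str(exc))
            failed.add("trajectories")

    # ----- metabolomics
    if metab is not None:
        m_cfg = cfg.get("metabolomics", {})
        try:
            panel = metabolomics.metabolite_panel(
                metab, samples,
                contrast=tuple(m_cfg.get("contrast", ("cap_admission", "control"))),
                transform=m_cfg.get("transform", "boxcox"),
                welch=bool(m_cfg.get("welch", False)))
            f = outdir / "metabolite_effects.tsv"
            write_table(panel, f, comment=tag)
            record("metabolomics", [f])
        except Exception as exc:  # noqa: BLE001
            logger.exception("metabolomics stage failed")
            record("metabolomics", [], status="failed", error=str(exc))
            failed.add("metabolomics")

    # ----- association
    if not blocked("association"):
        a_cfg = cfg.get("association", {})
        try:
            pheno = pd.DataFrame(index=counts.sample_ids)
            if stim is not None:
                deltas = association.stimulation_delta(stim)
                pheno = pheno.join(deltas)
            if biom is not None:
                cleaned = clean_biomarkers(biom)
                wide = cleaned.pivot(index="sample_id", columns="analyte", values="value")
                pheno = pheno.join(wide)
            variables = score_matrix.T.join(pheno)
            strata = (pd.Series({s: samples.group_of(s) for s in variables.index})
                      if a_cfg.get("stratify", True) else None)
            mats = association.correlation_matrix(variables, strata=strata)
            long = association.correlation_long(mats)
            f = outdir / "correlations.tsv"
            write_table(long, f, comment=tag)
            record("association", [f])
        except Exception as exc:  # noqa: BLE001
            logger.exception("association stage failed")
            record("association", [], status="failed", error=str(exc))
            failed.add("association")

    with open(outdir / "manifest.json", "w", encoding="utf-8") as out:
        json.dump(manifest, out, indent=1, sort_keys=True)
        out.write("\n")
    logging.getLogger().removeHandler(fh)
    fh.close()
    return manifest
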