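"""End-to-end orchestration of the longitudinal microbiome analysis.

Stages run in order simulate -> diversity -> ordinate -> associate ->
pathways -> enrich, each writing plain TSV/JSON outputs stamped with the
producing stage and config hash.  A machine-readable run report records
the config (defaults echoed), seeds, per-stage row counts and warnings.
Identical config + seed gives byte-identical stage outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import analyze_table, results_frame, summarize_families
from .config import RunConfig
from .diversity import (fit_diversity_trend, fit_rarefaction_trend,
                        gene_richness, rarefaction_table, shannon_per_sample)
from .enrichment import enrich_directions
from .ordination import jsd_matrix, pcoa
from .parsimony import parsimony_pathways
from .simulate import CohortSpec, default_effect_spec, simulate_cohort, write_cohort
from .tables import (FeatureTable, StudyDesign, read_design,
                     read_feature_table, read_hierarchy, to_relative_abundance)

__all__ = ["run_all", "load_inputs"]

log = logging.getLogger(__name__)


def _tag(cfg: RunConfig, stage: str) -> str:
    return f"stage={stage} config={cfg.config_hash()} seed={cfg.seed}"


def _write(df: pd.DataFrame, path: Path, tag: str, index: bool = True) -> int:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# {tag}\n")
        df.to_csv(fh, sep="\t", index=index)
    return len(df)


def load_inputs(input_dir):
    """Read design, genus/KO counts, hierarchy and gene sets from a directory."""
    d = Path(input_dir)
    design = read_design(d / "design.tsv")
    genus = read_feature_table(d / "genus_counts.tsv", "genus")
    ko = read_feature_table(d / "ko_counts.tsv", "KO")
    hier = read_hierarchy(d / "hierarchy.tsv")
    gene_sets = None
    gs = d / "gene_sets.json"
    if gs.exists():
        gene_sets = {s: frozenset(v) for s, v in json.loads(gs.read_text()).items()}
    return design, genus, ko, hier, gene_sets


def run_all(cfg: RunConfig) -> dict:
    """Execute the configured stages; return (and write) the run report."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "stages": {},
        "warnings": [],
    }
    design = genus = ko = hier = gene_sets = None

    if cfg.input_dir:
        design, genus, ko, hier, gene_sets = load_inputs(cfg.input_dir)

    def stage_on(name):
        return name in cfg.stages

    if stage_on("simulate") and not cfg.input_dir:
        reads = (23_000_000, 91_000_000) if cfg.full_scale else (23_000, 91_000)
        cohort = simulate_cohort(
            seed=cfg.seed,
            cohort=CohortSpec(seed=cfg.seed, reads_range=reads),
            effects=default_effect_spec(seed=cfg.seed, theta=cfg.theta,
                                        kitten_sd=cfg.kitten_sd, n_ko=cfg.n_ko),
            n_pathway=cfg.n_pathway)
        write_cohort(cohort, out / "simulated", _tag(cfg, "simulate"))
        design, genus, ko = cohort.design, cohort.genus_counts, cohort.ko_counts
        hier, gene_sets = cohort.hierarchy, cohort.gene_sets
        report["stages"]["simulate"] = {
            "status": "completed", "n_samples": design.n_samples,
            "n_genera": genus.n_features, "n_kos": ko.n_features,
        }

    if design is None and any(stage_on(s) for s in
                              ("diversity", "ordinate", "associate",
                               "pathways", "enrich")):
        if not cfg.input_dir:
            raise RuntimeError("no inputs: enable the simulate stage or set input_dir")

    genus_prop = to_relative_abundance(genus) if genus is not None else None
    ko_prop = to_relative_abundance(ko) if ko is not None else None

    if stage_on("diversity"):
        shannon = shannon_per_sample(genus)
        _write(shannon.to_frame(), out / "shannon.tsv", _tag(cfg, "diversity"))
        rt = rarefaction_table(genus, "scaled", cfg.rarefaction_replicates,
                               seed=cfg.seed)
        n_rows = _write(rt, out / "rarefaction.tsv", _tag(cfg, "diversity"),
                        index=False)
        trend = fit_diversity_trend(shannon, design)
        rtrend = fit_rarefaction_trend(rt, design)
        stage = {"status": "completed", "n_rarefaction_rows": n_rows,
                 "shannon_trend": trend, "rarefaction_trend": rtrend}
        if gene_sets:
            per_sample, per_age = gene_richness(gene_sets, design)
            _write(per_sample.to_frame(), out / "gene_richness.tsv",
                   _tag(cfg, "diversity"))
            stage["gene_richness_per_age"] = {int(k): int(v)
                                              for k, v in per_age.items()}
        (out / "trend_report.json").write_text(json.dumps(stage, indent=2,
                                                          default=str))
        report["stages"]["diversity"] = {"status": "completed",
                                         "n_rarefaction_rows": n_rows}

    if stage_on("ordinate"):
        dm = jsd_matrix(genus_prop)
        _write(dm.to_frame(), out / "distances.tsv", _tag(cfg, "ordinate"))
        ordn = pcoa(dm, n_axes=cfg.n_axes)
        _write(ordn.coordinates, out / "pcoa_coords.tsv", _tag(cfg, "ordinate"))
        eig = pd.DataFrame({
            "eigenvalue": ordn.eigenvalues,
            "proportion": list(ordn.proportion_explained) +
            [np.nan] * (len(ordn.eigenvalues) - len(ordn.proportion_explained)),
        })
        _write(eig, out / "pcoa_eigen.tsv", _tag(cfg, "ordinate"), index=False)
        n_neg = int((ordn.eigenvalues < -1e-12).sum())
        if n_neg:
            report["warnings"].append(
                f"ordinate: {n_neg} negative eigenvalues (raw JSD is not "
                "guaranteed Euclidean); reported, not corrected")
        report["stages"]["ordinate"] = {
            "status": "completed",
            "axis1_proportion": float(ordn.proportion_explained[0]),
            "n_negative_eigenvalues": n_neg,
        }

    assoc_results = {}
    if stage_on("associate"):
        for label, table, rule in (("genus", genus, cfg.taxa_direction_rule),
                                   ("KO", ko, cfg.ko_direction_rule)):
            res, flog, thr = analyze_table(
                table, design, family=label, alpha=cfg.alpha,
                max_zero_prop=cfg.max_zero_prop, direction_rule=rule,
                working_corr=cfg.working_corr)
            assoc_results[label] = res
            _write(results_frame(res), out / f"association_{label}.tsv",
                   _tag(cfg, "associate"), index=False)
            _write(flog, out / f"filter_log_{label}.tsv",
                   _tag(cfg, "associate"), index=False)
            n_nc = sum("non_convergence" in r.flags for r in res)
            if n_nc:
                report["warnings"].append(
                    f"associate[{label}]: {n_nc} features did not converge")
            report["stages"].setdefault("associate", {"status": "completed"})[label] = {
                "analysed": len(res),
                "sidak_threshold": thr,
                "significant": int(sum(r.significant for r in res)),
            }
        summary = summarize_families(
            assoc_results,
            identified={"genus": genus.n_features, "KO": ko.n_features})
        _write(summary, out / "family_summary.tsv", _tag(cfg, "associate"))

    parsim = None
    if stage_on("pathways"):
        observed = [f for f in ko.feature_ids
                    if (ko.data.loc[f] > 0).any()]
        parsim = parsimony_pathways(observed, hier, solver=cfg.parsimony_solver)
        rows = pd.DataFrame({
            "pathway_id": parsim.retained + parsim.removed,
            "status": (["retained"] * len(parsim.retained)
                       + ["removed"] * len(parsim.removed)),
        })
        rows["n_kos_observed"] = rows["pathway_id"].map(parsim.explained)
        _write(rows, out / "parsimony.tsv", _tag(cfg, "pathways"), index=False)
        report["stages"]["pathways"] = {
            "status": "completed", "solver": parsim.solver,
            "retained": len(parsim.retained), "removed": len(parsim.removed),
        }

    if stage_on("enrich"):
        if "KO" not in assoc_results:
            raise RuntimeError("enrich stage needs the associate stage")
        res = assoc_results["KO"]
        universe = [r.feature_id for r in res]
        up = [r.feature_id for r in res if r.direction == "up"]
        down = [r.feature_id for r in res if r.direction == "down"]
        enr = enrich_directions(universe, up, down, hier,
                                n_perm=cfg.n_perm, seed=cfg.seed,
                                alpha=cfg.alpha,
                                universe_mode=cfg.universe_mode)
        retained = set(parsim.retained) if parsim is not None else None
        for label, frame in (("up", enr.up), ("down", enr.down)):
            if retained is not None:
                frame = frame.loc[[p for p in frame.index if p in retained]]
            _write(frame, out / f"enrichment_{label}.tsv", _tag(cfg, "enrich"))
        report["warnings"].extend(enr.notes)
        report["stages"]["enrich"] = {
            "status": "completed", "universe": enr.universe_size,
            "n_up": len(up), "n_down": len(down),
            "enriched_up": int(enr.up["enriched"].sum()),
            "enriched_down": int(enr.down["enriched"].sum()),
        }

    (out / "run_report.json").write_text(json.dumps(report, indent=2,
                                                    default=str))
    return report
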