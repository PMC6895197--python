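"""Rarefaction / down-sampling robustness harnesses and pipeline orchestration.

Landmark studies of rare organisms often have few, unevenly distributed
specimens; the harnesses here quantify how much the conclusions depend on
that sampling.  ``rarefy_run`` redraws the dataset to one specimen per
species ``nreps`` times; ``downsample_run`` additionally keeps only a
fraction of the species in each group.  Every replicate re-runs the full
requested workflow (Procrustes alignment onward) and the summary reports
mean CR / p / z per hypothesis and group, the proportion of replicates with
significant modularity at alpha = 0.05, best-model counts from the
likelihood comparison, fastest-module counts from the rate test, and
per-species regime-shift inclusion proportions.

``run_pipeline`` executes the end-to-end workflow from a config mapping
(YAML-compatible): impute -> GPA -> species means -> per-group modularity ->
effect-size comparison -> model selection -> phylogenetic analyses ->
robustness, writing TSV/JSON results.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .emmli import build_model_set, congruence_matrix, emmli_fit
from .hypotheses import builtin_hypotheses
from .io_formats import LandmarkTable, ModuleHypothesis, read_landmarks, read_module_map, read_tree
from .missing_landmarks import estimate_missing
from .modularity import compare_modularity, modularity_test, phylo_modularity
from .phylocomp import detect_shifts, fit_trait_models, kmult, module_rates
from .procrustes import gpa, shape_pca, species_means
from .synthetic_data import SimSpec, simulate_dataset
from .trees import Tree

__all__ = ["ResampleSummary", "rarefy_run", "downsample_run", "run_pipeline",
           "ALPHA", "analyze_once"]

log = logging.getLogger("floramorph")

#: significance threshold used for "proportion of replicates significant"
ALPHA = 0.05

ALL_ANALYSES = ("modularity", "compare", "emmli", "kmult", "rates", "trait_models", "shifts")


@dataclass
class ResampleSummary:
    """Aggregate of per-replicate analysis outcomes."""

    nreps: int
    seed: int | None
    records: pd.DataFrame  # one row per rep x hypothesis x group (modularity)
    cr_summary: pd.DataFrame  # mean CR/p/z + proportion significant
    best_model_counts: dict = field(default_factory=dict)  # group -> {hypothesis: count}
    fastest_module_counts: dict = field(default_factory=dict)  # hypothesis -> {module: count}
    shift_inclusion: dict = field(default_factory=dict)  # species -> proportion of reps
    compare_records: pd.DataFrame | None = None


def _summarize(records: pd.DataFrame, nreps: int, seed) -> ResampleSummary:
    if len(records):
        g = records.groupby(["hypothesis", "group"], sort=False)
        cr_summary = g.agg(mean_cr=("cr", "mean"), mean_p=("p", "mean"),
                           mean_z=("z", "mean"),
                           prop_significant=("p", lambda s: float((s <= ALPHA).mean()))
                           ).reset_index()
    else:
        cr_summary = pd.DataFrame()
    return ResampleSummary(nreps=nreps, seed=seed, records=records, cr_summary=cr_summary)


def _one_per_species(table: LandmarkTable, species: list[str], rng) -> LandmarkTable:
    chosen = []
    for sp in species:
        cands = [s for s, x in zip(table.specimen_ids, table.species_ids) if x == sp]
        chosen.append(cands[int(rng.integers(len(cands)))])
    return table.subset(chosen)


def analyze_once(sub: LandmarkTable, tree: Tree | None, hypotheses: list[ModuleHypothesis],
                 analyses, nperm: int, rng, records: list, rep: int,
                 best_model: dict, fastest: dict, shifts_seen: dict, compare_rows: list,
                 max_shifts: int = 6):
    """Run the requested analyses on one (resampled) dataset, appending outcomes."""
    fit = gpa(sub)
    groups = [g for g in dict.fromkeys(fit.groups or []) if g]
    means = species_means(fit)
    by_group = {}
    if "modularity" in analyses or "compare" in analyses:
        for hyp in hypotheses:
            per_hyp = {}
            for grp in groups:
                rows = [i for i, g in enumerate(fit.groups) if g == grp]
                if len(rows) < 3:
                    continue
                res = modularity_test(fit.aligned[rows], hyp, nperm=nperm,
                                      seed=int(rng.integers(2**31)),
                                      landmark_labels=fit.landmark_labels, label=grp)
                per_hyp[grp] = res
                records.append({"rep": rep, "hypothesis": hyp.name, "group": grp,
                                "cr": res.cr_obs, "p": res.p, "z": res.z})
            if tree is not None and len(set(means.specimen_ids)) >= 4:
                res = phylo_modularity(means, tree.prune(means.specimen_ids), hyp,
                                       nperm=nperm, seed=int(rng.integers(2**31)))
                records.append({"rep": rep, "hypothesis": hyp.name, "group": "all",
                                "cr": res.cr_obs, "p": res.p, "z": res.z})
            if "compare" in analyses and len(per_hyp) >= 2:
                comp = compare_modularity(list(per_hyp.values()), list(per_hyp))
                for row in comp.table:
                    compare_rows.append(dict(row, rep=rep, hypothesis=hyp.name))
            by_group[hyp.name] = per_hyp
    if "emmli" in analyses:
        models = build_model_set(hypotheses)
        for grp in groups:
            rows = [i for i, g in enumerate(fit.groups) if g == grp]
            if len(rows) < 5:
                continue
            corr = congruence_matrix(fit.aligned[rows], fit.landmark_labels)
            tab = emmli_fit(corr, models)
            winner = tab.best["hypothesis"] or "null"
            best_model.setdefault(grp, {}).setdefault(winner, 0)
            best_model[grp][winner] += 1
    if tree is not None:
        sub_tree = tree.prune(means.specimen_ids) if set(means.specimen_ids) != set(
            tree.tip_labels) else tree
        if "kmult" in analyses:
            res = kmult(means, sub_tree, nperm=min(nperm, 499), seed=int(rng.integers(2**31)))
            records.append({"rep": rep, "hypothesis": "kmult", "group": "all",
                            "cr": res.k_mult, "p": res.p, "z": np.nan})
        if "rates" in analyses:
            for hyp in hypotheses:
                rr = module_rates(means, sub_tree, hyp, nsim=min(nperm, 499),
                                  seed=int(rng.integers(2**31)))
                top = max(rr.sigma2, key=rr.sigma2.get)
                fastest.setdefault(hyp.name, {}).setdefault(top, 0)
                fastest[hyp.name][top] += 1
        if "trait_models" in analyses or "shifts" in analyses:
            scores = shape_pca(means).scores
            trait = {sp: float(scores[i, 0]) for i, sp in enumerate(means.specimen_ids)}
            if "trait_models" in analyses:
                fits = fit_trait_models(sub_tree, trait)
                winner = min(fits, key=lambda f: f.AICc).model
                best_model.setdefault("trait_model", {}).setdefault(winner, 0)
                best_model["trait_model"][winner] += 1
            if "shifts" in analyses:
                cfg = detect_shifts(sub_tree, trait,
                                    max_shifts=min(max_shifts, sub_tree.n_tips - 2))
                for sp, reg in cfg.regimes.items():
                    if reg != 0:
                        shifts_seen.setdefault(sp, 0)
                        shifts_seen[sp] += 1
    return by_group


def rarefy_run(table: LandmarkTable, tree: Tree | None, hypotheses: list[ModuleHypothesis],
               analyses=("modularity",), nreps: int = 100, seed: int | None = None,
               nperm: int = 199) -> ResampleSummary:
    """Rarefy to one specimen per species, nreps times, re-running the analyses."""
    if table.has_missing:
        raise ValueError("impute missing landmarks before resampling")
    bad = [a for a in analyses if a not in ALL_ANALYSES]
    if bad:
        raise ValueError(f"unknown analyses {bad}; choose from {ALL_ANALYSES}")
    if tree is None and any(a in ("kmult", "rates", "trait_models", "shifts") for a in analyses):
        raise ValueError("these analyses require a tree")
    rng = np.random.default_rng(seed)
    species = list(dict.fromkeys(table.species_ids))
    records: list = []
    best_model: dict = {}
    fastest: dict = {}
    shifts_seen: dict = {}
    compare_rows: list = []
    for rep in range(nreps):
        t0 = time.perf_counter()
        sub = _one_per_species(table, species, rng)
        analyze_once(sub, tree, hypotheses, analyses, nperm, rng, records,
                     rep, best_model, fastest, shifts_seen, compare_rows)
        log.info("rarefaction rep %d/%d done in %.2fs", rep + 1, nreps,
                 time.perf_counter() - t0)
    out = _summarize(pd.DataFrame(records), nreps, seed)
    out.best_model_counts = best_model
    out.fastest_module_counts = fastest
    out.shift_inclusion = {sp: cnt / nreps for sp, cnt in shifts_seen.items()}
    out.compare_records = pd.DataFrame(compare_rows)
    return out


def downsample_run(table: LandmarkTable, tree: Tree | None, hypotheses: list[ModuleHypothesis],
                   analyses=("modularity",), fraction: float = 0.5, min_per_group: int = 4,
                   nreps: int = 100, seed: int | None = None, nperm: int = 199) -> ResampleSummary:
    """Down-sample to ceil(fraction) of species per group (at least ``min_per_group``),
    one specimen each, nreps times."""
    if table.has_missing:
        raise ValueError("impute missing landmarks before resampling")
    rng = np.random.default_rng(seed)
    species = list(dict.fromkeys(table.species_ids))
    group_of = {}
    for sp, g in zip(table.species_ids, table.groups):
        group_of[sp] = g
    by_group: dict[str, list[str]] = {}
    for sp in species:
        by_group.setdefault(group_of[sp], []).append(sp)
    for g, sps in by_group.items():
        if len(sps) < min_per_group:
            raise ValueError(f"group {g!r} has {len(sps)} species < min_per_group={min_per_group}")
    records: list = []
    best_model: dict = {}
    fastest: dict = {}
    shifts_seen: dict = {}
    compare_rows: list = []
    for rep in range(nreps):
        keep: list[str] = []
        for g, sps in by_group.items():
            k = max(min_per_group, math.ceil(fraction * len(sps)))
            k = min(k, len(sps))
            sel = rng.choice(len(sps), size=k, replace=False)
            keep.extend(sps[i] for i in sel)
        keepset = set(keep)
        sub_all = table.subset([s for s, sp in zip(table.specimen_ids, table.species_ids)
                                if sp in keepset])
        # canonical species order so resampled datasets are order-stable
        keep_ordered = [sp for sp in species if sp in keepset]
        sub = _one_per_species(sub_all, keep_ordered, rng)
        analyze_once(sub, tree, hypotheses, analyses, nperm, rng, records,
                     rep, best_model, fastest, shifts_seen, compare_rows)
    out = _summarize(pd.DataFrame(records), nreps, seed)
    out.best_model_counts = best_model
    out.fastest_module_counts = fastest
    out.shift_inclusion = {sp: cnt / nreps for sp, cnt in shifts_seen.items()}
    out.compare_records = pd.DataFrame(compare_rows)
    return out


# ---------------------------------------------------------------------------
# end-to-end pipeline


def _load_inputs(config: dict):
    if "simulate" in config:
        sim_kw = dict(config["simulate"])
        sim_kw.pop("hypothesis", None)
        if "seed" not in sim_kw:
            sim_kw["seed"] = int(config.get("seed", 0))
        if "specimens_per_species" in sim_kw and isinstance(sim_kw["specimens_per_species"], list):
            sim_kw["specimens_per_species"] = tuple(sim_kw["specimens_per_species"])
        spec = SimSpec(**sim_kw)
        table, tree, means, truth = simulate_dataset(spec)
        return table, tree, spec.hypothesis
    inputs = config["inputs"]
    table = read_landmarks(inputs["landmarks"], format=inputs.get("format", "csv-long"))
    tree = read_tree(inputs["tree"]) if "tree" in inputs else None
    return table, tree, None


def _load_hypotheses(config: dict, table: LandmarkTable,
                     sim_hypothesis: ModuleHypothesis | None = None) -> list[ModuleHypothesis]:
    src = config.get("hypotheses", "builtin")
    if src == "builtin":
        if table.n_landmarks == 37:
            hyps = builtin_hypotheses()
        elif sim_hypothesis is not None:
            hyps = [sim_hypothesis]  # simulated study: test the true partition
        else:
            raise ValueError("builtin hypotheses need the 37-landmark scheme; "
                             "supply a module-map config")
    else:
        hyps = read_module_map(src)
    for h in hyps:
        h.validate_against(table.landmark_labels)
    return hyps


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute the full workflow described by a config mapping or YAML path.

    Returns a results bundle (also written to ``out_dir`` as TSV/JSON when
    given).  Re-running with the same config and seed reproduces the bundle.
    """
    if not isinstance(config, dict):
        with open(config, "r", encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    seed = int(config.get("seed", 0))
    nperm = int(config.get("nperm", 999))
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir or config.get("out_dir", "results/pipeline"))
    analyses = tuple(config.get("analyses", list(ALL_ANALYSES)))

    t0 = time.perf_counter()
    table, tree, sim_hyp = _load_inputs(config)
    hypotheses = _load_hypotheses(config, table, sim_hyp)
    log.info("loaded %d specimens, %d landmarks", table.n_specimens, table.n_landmarks)

    if table.has_missing:
        table = estimate_missing(table, method=config.get("imputation", "TPS"))
        log.info("imputed missing landmarks (TPS)")

    records: list = []
    best_model: dict = {}
    fastest: dict = {}
    shifts_seen: dict = {}
    compare_rows: list = []
    analyze_once(table, tree, hypotheses, analyses, nperm, rng, records,
                 0, best_model, fastest, shifts_seen, compare_rows)
    full = _summarize(pd.DataFrame(records), 1, seed)
    bundle = {
        "seed": seed,
        "nperm": nperm,
        "modularity": full.cr_summary.to_dict(orient="records"),
        "comparisons": compare_rows,
        "best_model_counts": best_model,
        "fastest_module_counts": fastest,
        "shift_inclusion": shifts_seen,
    }

    resampling = config.get("resampling", {})
    if "rarefy" in resampling:
        rr = rarefy_run(table, tree, hypotheses, analyses=analyses, nperm=nperm,
                        seed=seed + 1, **resampling["rarefy"])
        bundle["rarefaction"] = rr.cr_summary.to_dict(orient="records")
        bundle["rarefaction_best_model"] = rr.best_model_counts
    if "downsample" in resampling:
        dd = downsample_run(table, tree, hypotheses, analyses=analyses, nperm=nperm,
                            seed=seed + 2, **resampling["downsample"])
        bundle["downsampling"] = dd.cr_summary.to_dict(orient="records")

    bundle["wall_time_s"] = time.perf_counter() - t0
    bundle = _jsonable(bundle)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        full.cr_summary.to_csv(out_dir / "modularity.tsv", sep="\t", index=False)
        if compare_rows:
            pd.DataFrame(compare_rows).to_csv(out_dir / "comparisons.tsv", sep="\t", index=False)
        with open(out_dir / "bundle.json", "w", encoding="utf-8") as fh:
            json.dump(_jsonable(bundle), fh, indent=2)
    return bundle


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj
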