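"""Run configuration: defaults, validation, and the pipeline orchestrator.

A single YAML (or dict) configuration drives the full analysis.  Defaults
follow the study design the toolkit implements: missingness 0.2 and MAF 0.01
filters, LD pruning at r^2 > 0.5 in 5 kb windows, sNMF over K = 1..15 with
10 repetitions, |Z| > 2 and Q < 0.01 adaptive classification, and
500-tree gradient forests.

:func:`run_pipeline` executes the stages in order — filter, environment
preparation and PCNM, ancestry/K selection, association scan and
classification, gradient forests on the adaptive and neutral SNP sets,
spatial projection and Procrustes comparison, genomic offset with
cross-scenario scaling, and an optional seed-source similarity map — and
writes a JSON manifest with the parameters, seed, and SHA-256 checksum of
every artifact, so reruns are verifiably reproducible.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ancestry, envlayers, gea, genotype, gradient, offset, synthetic

logger = logging.getLogger(__name__)

__all__ = ["DEFAULTS", "validate_config", "run_pipeline", "demo_config"]

DEFAULTS: dict = {
    "seed": 0,
    "filter": {"max_missing": 0.2, "maf": 0.01, "ld_r2": 0.5,
               "ld_window": 5000, "impute_mode": "per_locality_frequency"},
    "env": {"corr_threshold": 0.7, "pcnm_truncation": None},
    "structure": {"k_min": 1, "k_max": 15, "reps": 10, "alpha": 10.0,
                  "max_iter": 200, "mask_fraction": 0.05, "plateau_tol": 0.01},
    "gea": {"k_latent": None, "reps": 3, "z_thresh": 2.0, "q_thresh": 0.01},
    "gf": {"n_trees": 500, "min_leaf": 2, "corr_threshold": 0.5,
           "n_perm_trees": 150},
    "offset": {"sqrt": True, "aggregate": "mean"},
    "similarity": {"site": None},
}

_RANGES = {
    ("filter", "max_missing"): (0.0, 1.0),
    ("filter", "maf"): (0.0, 1.0),
    ("filter", "ld_r2"): (0.0, 1.0),
    ("env", "corr_threshold"): (0.0, 1.0),
    ("gea", "q_thresh"): (0.0, 1.0),
    ("structure", "mask_fraction"): (0.0, 0.99),
}


def validate_config(cfg: dict | str | Path) -> tuple[dict, list[str]]:
    """Merge defaults into a config and sanity-check it.

    Returns the fully defaulted config and a list of warnings naming every
    injected default and every unknown key.  Out-of-range settings raise.
    """
    if not isinstance(cfg, dict):
        cfg = yaml.safe_load(Path(cfg).read_text()) or {}
    cfg = copy.deepcopy(cfg)
    warnings: list[str] = []
    known_top = set(DEFAULTS) | {"simulate", "paths"}
    for key in cfg:
        if key not in known_top:
            warnings.append(f"unknown config key ignored: {key}")
    for section, defaults in DEFAULTS.items():
        if not isinstance(defaults, dict):
            if section not in cfg:
                cfg[section] = defaults
                warnings.append(f"default injected: {section} = {defaults}")
            continue
        sub = cfg.setdefault(section, {})
        for key in sub:
            if key not in defaults:
                warnings.append(f"unknown config key ignored: {section}.{key}")
        for key, val in defaults.items():
            if key not in sub:
                sub[key] = val
                warnings.append(f"default injected: {section}.{key} = {val}")
    for (section, key), (lo, hi) in _RANGES.items():
        v = cfg[section][key]
        if not (lo <= v <= hi):
            raise ValueError(f"{section}.{key} = {v} outside [{lo}, {hi}]")
    if cfg["filter"]["ld_window"] <= 0:
        raise ValueError("filter.ld_window must be positive")
    if cfg["structure"]["k_min"] < 1 or cfg["structure"]["k_max"] < cfg["structure"]["k_min"]:
        raise ValueError("structure k range invalid")
    if "paths" in cfg:
        missing = [str(p) for p in map(Path, cfg["paths"].values())
                   if not Path(p).exists()]
        if missing:
            raise ValueError(f"missing input path(s): {missing}")
    return cfg, warnings


def demo_config() -> dict:
    """Small self-contained synthetic demo configuration."""
    return {
        "seed": 42,
        "simulate": {
            "grid_rows": 24, "grid_cols": 24, "n_env": 3,
            "autocorr_range": 3.0,
            "n_pops": 20, "n_per_pop": 8,
            "n_neutral": 400, "n_adaptive": 20,
            "effect_size": 3.0, "causal_env": ["env1"],
            "ancestral_K": 3, "target_fst": 0.15, "missing_rate": 0.05,
            "scenarios": {"mid": {"env1": 0.5}, "late": {"env1": 1.0}},
        },
        "structure": {"k_min": 1, "k_max": 5, "reps": 3, "max_iter": 100},
        "gf": {"n_trees": 100, "n_perm_trees": 50},
        "similarity": {"site": [12.5, 12.5], "scenario": "late"},
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


class _Manifest:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.stages: list[dict] = []

    def add(self, stage: str, outputs: list[Path], params: dict, seed) -> None:
        self.stages.append({
            "stage": stage,
            "outputs": [{"path": str(p.relative_to(self.outdir)),
                         "sha256": _sha256(p)} for p in outputs],
            "params": params,
            "seed": seed,
        })

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps({"stages": self.stages}, indent=2,
                                   default=str) + "\n")
        return path


def run_pipeline(cfg: dict | str | Path, outdir: str | Path,
                 stop_after: str | None = None) -> dict:
    """Run the analysis stages in order from a validated configuration.

    Returns the manifest as a dict; artifacts and ``manifest.json`` are
    written under ``outdir``.  ``stop_after`` ends the run after the named
    stage.  A stage failure raises with the stage name.
    """
    cfg, warnings = validate_config(cfg)
    for w in warnings:
        logger.info("config: %s", w)
    if "simulate" not in cfg and "paths" not in cfg:
        raise ValueError("config must provide either a 'simulate' section or "
                         "a 'paths' section with input files")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir)
    seed = int(cfg["seed"])
    state: dict = {}

    stages = [
        ("simulate", _stage_simulate), ("filter", _stage_filter),
        ("env", _stage_env), ("structure", _stage_structure),
        ("gea", _stage_gea), ("gf", _stage_gf),
        ("project", _stage_project), ("offset", _stage_offset),
    ]
    if stop_after is not None and stop_after not in [s for s, _ in stages]:
        raise ValueError(f"unknown stage {stop_after!r}")
    for name, fn in stages:
        try:
            fn(cfg, seed, outdir, state, manifest)
        except Exception as e:
            raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e
        if name == stop_after:
            break
    manifest.write()
    return {"stages": manifest.stages}


def _stage_simulate(cfg, seed, outdir, state, manifest):
    if "simulate" not in cfg:
        paths = cfg["paths"]
        state["gm"] = genotype.read_vcf(paths["vcf"], paths.get("samples"))
        state["current"] = envlayers.EnvStack.from_dir(paths["env_dir"])
        state["futures"] = {
            name: envlayers.EnvStack.from_dir(p)
            for name, p in cfg["paths"].get("future_dirs", {}).items()}
        return
    sim = cfg["simulate"]
    spec = synthetic.LandscapeSpec(
        grid_rows=sim["grid_rows"], grid_cols=sim["grid_cols"],
        n_env=sim["n_env"], autocorr_range=sim.get("autocorr_range", 5.0),
        seed=seed)
    shifts = {name: dict(sh) for name, sh in sim.get("scenarios", {}).items()}
    current, futures = synthetic.simulate_landscape(spec, shifts or None)
    samples = synthetic.simulate_samples(sim["n_pops"], sim["n_per_pop"],
                                         current, seed=seed + 1)
    truth = synthetic.TruthTable.template(
        sim["n_adaptive"], sim.get("causal_env", current.names),
        effect_size=sim.get("effect_size", 2.0),
        ancestral_K=sim.get("ancestral_K", 3),
        target_fst=sim.get("target_fst", 0.15))
    gm, realized = synthetic.simulate_genotypes(
        samples, current, sim["n_neutral"], sim["n_adaptive"], truth=truth,
        missing_rate=sim.get("missing_rate", 0.0), seed=seed + 2)
    vcf = outdir / "genotypes.vcf"
    genotype.write_vcf(gm, vcf)
    stsv = outdir / "samples.tsv"
    _write_tsv(samples, stsv)
    tjson = outdir / "truth.json"
    realized.to_json(tjson)
    current.to_dir(outdir / "rasters" / "current")
    raster_files = sorted((outdir / "rasters" / "current").glob("*.asc"))
    for name, stack in futures.items():
        stack.to_dir(outdir / "rasters" / f"future_{name}")
        raster_files += sorted((outdir / "rasters" / f"future_{name}").glob("*.asc"))
    state.update(gm=gm, truth=realized, current=current, futures=futures)
    manifest.add("simulate", [vcf, stsv, tjson] + raster_files,
                 dict(cfg["simulate"]), seed)


def _stage_filter(cfg, seed, outdir, state, manifest):
    f = cfg["filter"]
    gm, rep1 = genotype.filter_genotypes(state["gm"], f["max_missing"], f["maf"])
    gm = genotype.impute_missing(gm, f["impute_mode"], seed=seed + 3)
    gm, rep2 = genotype.ld_prune(gm, f["ld_r2"], f["ld_window"])
    report = genotype.FilterReport(
        n_input=rep1.n_input, n_removed_missing=rep1.n_removed_missing,
        n_removed_maf=rep1.n_removed_maf, n_removed_ld=rep2.n_removed_ld,
        n_output=rep2.n_output)
    rpath = outdir / "filter_report.json"
    report.to_json(rpath)
    vcf = outdir / "filtered.vcf"
    genotype.write_vcf(gm, vcf)
    state["gm_filtered"] = gm
    manifest.add("filter", [rpath, vcf], dict(f), seed + 3)


def _stage_env(cfg, seed, outdir, state, manifest):
    gm = state["gm_filtered"]
    current = state["current"]
    loc = gm.sample_meta.groupby("locality", sort=True)[["lon", "lat"]].first()
    site_tab = envlayers.extract_at_points(current, loc.to_numpy())
    site_tab = site_tab.drop(columns="in_mask")
    pruned, removed = envlayers.prune_correlated(site_tab,
                                                 cfg["env"]["corr_threshold"])
    sv = envlayers.pcnm(loc.to_numpy(), cfg["env"]["pcnm_truncation"])
    pop_idx = gm.sample_meta.groupby("locality", sort=True).ngroup().to_numpy()
    sample_env = envlayers.extract_at_points(
        current, gm.sample_meta[["lon", "lat"]].to_numpy())[pruned.columns]
    state.update(site_env=pruned, removed_env=removed, spatial=sv,
                 pop_idx=pop_idx, sample_env=sample_env, site_coords=loc.to_numpy())
    e1 = outdir / "env_sites.tsv"
    _write_tsv(pruned.assign(locality=loc.index.to_numpy()), e1)
    e2 = outdir / "pcnm.tsv"
    _write_tsv(sv.as_frame().assign(locality=loc.index.to_numpy()), e2)
    manifest.add("env", [e1, e2],
                 {**cfg["env"], "removed_variables": removed}, seed)


def _stage_structure(cfg, seed, outdir, state, manifest):
    s = cfg["structure"]
    gm = state["gm_filtered"]
    res = ancestry.select_k(gm, k_range=range(s["k_min"], s["k_max"] + 1),
                            reps=s["reps"], alpha=s["alpha"],
                            max_iter=s["max_iter"],
                            mask_fraction=s["mask_fraction"], seed=seed + 4,
                            plateau_tol=s["plateau_tol"])
    state["select_k"] = res
    model = res.best_models[res.chosen_k]
    state["ancestry"] = model
    q1 = outdir / "q_matrix.tsv"
    qdf = pd.DataFrame(model.Q, columns=[f"Q{i + 1}" for i in range(model.K)])
    _write_tsv(qdf.assign(id=gm.sample_meta["id"].to_numpy()), q1)
    c1 = outdir / "cross_entropy.tsv"
    _write_tsv(res.curve, c1)
    if model.K > 1:
        out = ancestry.fst_outliers(model, gm, q_thresh=cfg["gea"]["q_thresh"])
        f1 = outdir / "fst_outliers.tsv"
        _write_tsv(out, f1)
        files = [q1, c1, f1]
    else:
        files = [q1, c1]
    manifest.add("structure", files, {**s, "chosen_k": res.chosen_k}, seed + 4)


def _stage_gea(cfg, seed, outdir, state, manifest):
    g = cfg["gea"]
    gm = state["gm_filtered"]
    env_sample = state["sample_env"].reset_index(drop=True)
    k_latent = g["k_latent"]
    if k_latent is None:
        k_latent = state["select_k"].chosen_k
    result = gea.run_gea(gm, env_sample, k_latent=k_latent, reps=g["reps"],
                         seed=seed + 5, z_thresh=g["z_thresh"],
                         q_thresh=g["q_thresh"])
    state["gea"] = result
    tab = pd.concat([
        gm.snp_meta[["id", "chrom", "pos"]].reset_index(drop=True),
        result.z.add_prefix("z_").reset_index(drop=True),
        result.q.add_prefix("q_").reset_index(drop=True),
        result.flags.add_prefix("adaptive_").reset_index(drop=True),
    ], axis=1)
    tab["adaptive_any"] = result.adaptive_any.to_numpy()
    t1 = outdir / "gea_results.tsv"
    _write_tsv(tab, t1)
    l1 = outdir / "lambda.tsv"
    _write_tsv(result.lam.rename("lambda").rename_axis("variable").reset_index(), l1)
    manifest.add("gea", [t1, l1], {**g, "k_latent_used": int(k_latent)}, seed + 5)


def _build_predictors(state) -> pd.DataFrame:
    sv = state["spatial"]
    pc_sample = sv.vectors[state["pop_idx"]]
    return pd.concat([state["sample_env"].reset_index(drop=True),
                      pd.DataFrame(pc_sample, columns=sv.names)], axis=1)


def _stage_gf(cfg, seed, outdir, state, manifest):
    gf_cfg = cfg["gf"]
    gm = state["gm_filtered"]
    flags = state["gea"].adaptive_any.to_numpy()
    if flags.sum() == 0:
        raise ValueError("no adaptive SNPs classified; cannot fit the "
                         "adaptive-set gradient forest")
    if (~flags).sum() == 0:
        raise ValueError("no neutral SNPs left after classification")
    predictors = _build_predictors(state)
    models = {}
    files = []
    for label, index in (("adaptive", np.flatnonzero(flags)),
                         ("neutral", np.flatnonzero(~flags))):
        model = gradient.fit_gradient_forest(
            gm.take_snps(index), predictors, n_trees=gf_cfg["n_trees"],
            seed=seed + 6, min_leaf=gf_cfg["min_leaf"],
            corr_threshold=gf_cfg["corr_threshold"],
            n_perm_trees=gf_cfg["n_perm_trees"], snp_set_label=label)
        models[label] = model
        path = outdir / f"turnover_{label}.json"
        model.to_json(path)
        files.append(path)
    state["gf_models"] = models
    state["predictors"] = predictors
    manifest.add("gf", files, dict(gf_cfg), seed + 6)


def _stage_project(cfg, seed, outdir, state, manifest):
    current = state["current"]
    sv = state["spatial"]
    extra = gradient.pcnm_surfaces(sv.vectors, state["site_coords"], current)
    state["pcnm_surfaces"] = extra
    grids = {}
    files = []
    for label, model in state["gf_models"].items():
        tg = gradient.project_turnover(model, current, extra_layers=extra)
        grids[label] = tg
        for i in range(tg.pcs.shape[1]):
            p = outdir / f"turnover_{label}_pc{i + 1}.asc"
            envlayers.write_ascii_grid(p, tg.pc_grid(i), current.grid)
            files.append(p)
    resid = gradient.procrustes_residuals(grids["adaptive"], grids["neutral"])
    rp = outdir / "procrustes_residuals.asc"
    envlayers.write_ascii_grid(rp, resid, current.grid)
    files.append(rp)
    state["turnover_current"] = grids
    manifest.add("project", files, {}, seed)


def _stage_offset(cfg, seed, outdir, state, manifest):
    current_grid = state["turnover_current"]["adaptive"]
    model = state["gf_models"]["adaptive"]
    extra = state["pcnm_surfaces"]
    maps = []
    files = []
    for name, stack in state["futures"].items():
        tg_fut = gradient.project_turnover(model, stack, extra_layers=extra)
        om = offset.genomic_offset(current_grid, tg_fut,
                                   sqrt=cfg["offset"]["sqrt"])
        om.name = name
        maps.append(om)
    if maps:
        offset.scale_offsets(maps)
        for om in maps:
            p = outdir / f"offset_{om.name}.asc"
            envlayers.write_ascii_grid(p, om.scaled, state["current"].grid)
            files.append(p)
    sim_cfg = cfg["similarity"]
    if sim_cfg.get("site"):
        scen = sim_cfg.get("scenario")
        fut_stack = (state["futures"][scen] if scen
                     else next(iter(state["futures"].values())))
        sim = offset.similarity_map(tuple(sim_cfg["site"]), model,
                                    state["current"], fut_stack,
                                    extra_layers=extra,
                                    sqrt=cfg["offset"]["sqrt"])
        p = outdir / "similarity.asc"
        envlayers.write_ascii_grid(p, sim, state["current"].grid)
        files.append(p)
    state["offsets"] = maps
    manifest.add("offset", files, dict(cfg["offset"]), seed)
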