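"""End-to-end orchestration of the analysis stages.

Stage order: (optional) simulate → prevalence filter / rarefy → diversity →
longitudinal → differential abundance → co-occurrence networks → outcome
models.  Every stage writes plain-text TSV outputs into the run directory
and records its parameters, seeds and timing in ``manifest.json``; a rerun
with the same config and seed is bit-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import conet, diff_abundance, diversity, longitudinal, outcomes
from .core_io import (
    collapse_taxonomy,
    prevalence_filter,
    read_feature_table,
    read_metadata,
    read_taxonomy,
    read_tree,
)
from .simulate import SimulationConfig, simulate_cohort, write_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_inputs"]


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline settings; defaults reproduce the study's stated choices."""

    # input paths (ignored when simulate=True)
    feature_table: str = ""
    tree: str = ""
    taxonomy: str = ""
    metadata: str = ""
    simulate: bool = False
    n_udca: int = 198
    n_placebo: int = 203
    n_features: int = 150
    # analysis settings
    rarefaction_depth: int = 900
    mantel_check_depth: int = 2000
    prevalence_fraction: float = 0.33
    prevalence_after_rarefaction: bool = True
    p_threshold: float = 0.001
    n_perm: int = 999
    sparcc_resamples: int = 20
    ancom_alpha: float = 0.05
    ancom_detect_quantile: float = 0.7
    ancom_max_features: int = 60
    panel: tuple[str, ...] = diff_abundance.DEFAULT_PANEL
    stratify_by_sex: bool = True
    diff_mode: str = "abs"
    seed: int = 0
    # stage toggles
    run_diversity: bool = True
    run_longitudinal: bool = True
    run_abundance: bool = True
    run_network: bool = True
    run_outcomes: bool = True

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Parse a flat ``key = value`` config file."""
        fields = {f.name: f.type for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            default = getattr(cls, key, None)
            if key == "panel":
                kwargs[key] = tuple(v.strip() for v in val.split(",") if v.strip())
            elif isinstance(default, bool):
                kwargs[key] = val.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                kwargs[key] = int(val)
            elif isinstance(default, float):
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)


def load_inputs(cfg: PipelineConfig, outdir: Path):
    """Load the four inputs, or simulate them into ``outdir/inputs``."""
    if cfg.simulate:
        sim = SimulationConfig(
            n_udca=cfg.n_udca, n_placebo=cfg.n_placebo,
            n_features=cfg.n_features, seed=cfg.seed,
        )
        table, tree, tax, meta, truth = simulate_cohort(sim)
        write_cohort(outdir / "inputs", table, tree, tax, meta, truth)
        return table, tree, tax, meta
    for name in ("feature_table", "tree", "taxonomy", "metadata"):
        path = getattr(cfg, name)
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"input {name!r} missing: {path!r}")
    return (
        read_feature_table(cfg.feature_table),
        read_tree(cfg.tree),
        read_taxonomy(cfg.taxonomy),
        read_metadata(cfg.metadata),
    )


def _write(df: pd.DataFrame, path: Path, index_label=None, root: Path | None = None) -> str:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", lineterminator="\n",
              index_label=index_label)
    # manifests record paths relative to the run dir so reruns are identical
    return str(path.relative_to(root)) if root else str(Path(*path.parts[-2:]))


def stage_diversity(table, tree, cfg: PipelineConfig, outdir: Path):
    """Rarefy, compute alpha/beta diversity, PCoA and the Mantel depth check."""
    rare = diversity.rarefy(table, cfg.rarefaction_depth, seed=cfg.seed + 1)
    alphas = {
        m: diversity.alpha_diversity(rare, m, tree=tree)
        for m in diversity.ALPHA_METRICS
    }
    betas = {
        m: diversity.beta_diversity(rare, m, tree=tree)
        for m in diversity.BETA_METRICS
    }
    ords = {m: diversity.pcoa(d) for m, d in betas.items()}
    mantel_rows = []
    try:
        rare_hi = diversity.rarefy(table, cfg.mantel_check_depth, seed=cfg.seed + 2)
        common = [s for s in rare.sample_ids if s in rare_hi.sample_ids]
        for m in diversity.BETA_METRICS:
            d_lo = diversity.beta_diversity(
                rare.select_samples(common), m, tree=tree)
            d_hi = diversity.beta_diversity(
                rare_hi.select_samples(common), m, tree=tree)
            rho, p = diversity.mantel(d_lo, d_hi, n_perm=199, seed=cfg.seed + 3)
            mantel_rows.append({"metric": m, "rho": rho, "p": p, "n": len(common)})
    except ValueError:
        logger.warning("mantel depth check skipped: too few deep samples")
    out = {}
    alpha_df = pd.DataFrame(alphas)
    out["alpha"] = _write(alpha_df, outdir / "diversity" / "alpha.tsv",
                          index_label="#sample_id")
    for m, d in betas.items():
        diversity.distance_matrix_to_tsv(d, outdir / "diversity" / f"beta_{m}.tsv")
    for m, o in ords.items():
        diversity.ordination_to_tsv(o, outdir / "diversity" / f"pcoa_{m}.tsv")
    if mantel_rows:
        out["mantel"] = _write(pd.DataFrame(mantel_rows),
                               outdir / "diversity" / "mantel_depth_check.tsv")
    return rare, alphas, betas, ords, out


def stage_longitudinal(rare, alphas, betas, ords, meta, cfg, outdir: Path):
    deltas = {}
    for m, o in ords.items():
        oriented = longitudinal.orient_pc1(o, rare)
        deltas[f"{m}_pc1"] = longitudinal.paired_deltas(oriented, meta)
    for m, a in alphas.items():
        deltas[m] = longitudinal.paired_deltas(a, meta)
    shift_arm = longitudinal.one_sample_shift_tests(deltas, by_sex=False)
    tables = {"shift_tests_arm": shift_arm}
    if cfg.stratify_by_sex:
        tables["shift_tests_arm_sex"] = longitudinal.one_sample_shift_tests(
            deltas, by_sex=True)
    mag_rows, icc_rows = [], []
    for m, d in betas.items():
        u, p, _ = longitudinal.magnitude_comparison(d, meta.select(list(d.ids)))
        mag_rows.append({"metric": m, "U": u, "p": p})
        oriented = longitudinal.orient_pc1(ords[m], rare)
        r = longitudinal.icc(oriented.pc1(), meta.select(list(d.ids)), metric=f"{m}_pc1")
        icc_rows.append({"metric": r.metric, "sigma2_between": r.sigma2_between,
                         "sigma2_within": r.sigma2_within, "icc": r.icc})
    for m, a in alphas.items():
        r = longitudinal.icc(a, meta.select(list(a.index)), metric=m)
        icc_rows.append({"metric": r.metric, "sigma2_between": r.sigma2_between,
                         "sigma2_within": r.sigma2_within, "icc": r.icc})
    tables["magnitude_comparison"] = pd.DataFrame(mag_rows)
    tables["icc"] = pd.DataFrame(icc_rows)
    paths = {name: _write(df, outdir / "longitudinal" / f"{name}.tsv")
             for name, df in tables.items()}
    return tables, paths


def stage_abundance(rare, tax, meta, cfg: PipelineConfig, outdir: Path):
    tables = {}
    genus = collapse_taxonomy(rare, tax, "genus")
    for arm in ("UDCA", "placebo"):
        target = genus
        if target.n_features > cfg.ancom_max_features:
            # restrict to the most prevalent taxa to bound the O(D^2) tests
            prev = (target.data > 0).sum(axis=0).sort_values(ascending=False)
            target = target.select_features(
                sorted(prev.index[: cfg.ancom_max_features]))
        tables[f"ancom_{arm}"] = diff_abundance.ancom_paired(
            target, meta.select([s for s in target.sample_ids]), arm,
            alpha=cfg.ancom_alpha, detect_quantile=cfg.ancom_detect_quantile,
        )
    tables["panel"] = diff_abundance.panel_wilcoxon(rare, tax, meta, panel=cfg.panel)
    tables["fb_ratio"] = diff_abundance.fb_ratio_test(rare, tax, meta)
    paths = {name: _write(df, outdir / "abundance" / f"{name}.tsv")
             for name, df in tables.items()}
    return tables, paths


def stage_network(rare, meta, cfg: PipelineConfig, outdir: Path,
                  unrarefied=None):
    """Post-treatment networks per arm, ensemble edges, differential modules.

    Feature membership comes from the prevalence filter on the rarefied
    table by default; with ``prevalence_after_rarefaction = False`` the
    filter is evaluated on the unrarefied counts instead (the counts used
    for estimation stay rarefied either way).
    """
    nets, ests = {}, {}
    end_meta = meta.data[meta.data["timepoint"] == "end"]
    for arm in ("UDCA", "placebo"):
        ids = [s for s in end_meta.index[end_meta["arm"] == arm]
               if s in rare.data.index]
        sub = rare.select_samples(ids)
        if cfg.prevalence_after_rarefaction or unrarefied is None:
            filtered, _ = prevalence_filter(sub, cfg.prevalence_fraction)
        else:
            raw_sub = unrarefied.select_samples(ids)
            raw_filtered, _ = prevalence_filter(raw_sub, cfg.prevalence_fraction)
            filtered = sub.select_features(raw_filtered.feature_ids)
        est = conet.sparcc(filtered, n_resample=cfg.sparcc_resamples,
                           seed=cfg.seed + 10)
        est = conet.edge_pvalues(filtered, est, n_perm=cfg.n_perm,
                                 seed=cfg.seed + 11)
        ests[arm] = est
        nets[arm] = conet.build_network(est, p_threshold=cfg.p_threshold)
    # restrict both to the common node set
    common = [f for f in nets["placebo"].feature_ids
              if f in set(nets["UDCA"].feature_ids)]
    def _sub(net):
        e = net.edges
        keep = e["node_i"].isin(common) & e["node_j"].isin(common)
        return conet.CoNetwork(common, e[keep].reset_index(drop=True))
    base, pert = _sub(nets["placebo"]), _sub(nets["UDCA"])
    dm = conet.differential_modularity(base, pert, seed=cfg.seed + 12)
    diff = conet.differential_network(
        _estimate_subset(ests["UDCA"], common),
        _estimate_subset(ests["placebo"], common),
        mode=cfg.diff_mode,
    )
    lv = conet.louvain_partition(diff, seed=cfg.seed + 13)
    hubs = conet.hub_ranking(diff)
    paths = {}
    for arm, net in nets.items():
        paths[f"edges_{arm}"] = _write(net.edges, outdir / "network" / f"edges_{arm}.tsv")
    paths["differential_edges"] = _write(
        diff.edges, outdir / "network" / "differential_edges.tsv")
    mod_df = pd.DataFrame({
        "module": dm.modules, "contribution": dm.contributions,
    })
    mod_df["rank"] = mod_df["contribution"].rank(ascending=False, method="first")
    paths["differential_modules"] = _write(
        mod_df, outdir / "network" / "differential_modules.tsv",
        index_label="#node")
    lv_df = pd.DataFrame({"module": lv.modules, "contribution": lv.contributions})
    paths["louvain_modules"] = _write(
        lv_df, outdir / "network" / "louvain_modules.tsv", index_label="#node")
    paths["hub_ranking"] = _write(
        hubs.to_frame(), outdir / "network" / "hub_ranking.tsv",
        index_label="#node")
    return {"diffmod": dm, "louvain": lv, "hubs": hubs,
            "networks": nets, "differential": diff}, paths


def _estimate_subset(est: conet.CorrelationEstimate, ids):
    idx = [est.feature_ids.index(f) for f in ids]
    sel = np.ix_(idx, idx)
    return conet.CorrelationEstimate(
        feature_ids=list(ids),
        rho=est.rho[sel],
        basis_variances=est.basis_variances[idx],
        logratio_variances=est.logratio_variances[sel],
    )


def stage_outcomes(rare, tax, meta, cfg: PipelineConfig, outdir: Path,
                   alphas=None):
    """Hub-species outcome models, arm comparisons and storage checks."""
    tables = {}
    frac = rare.relative_abundance()
    species_cols = {}
    for fid in rare.feature_ids:
        lin = tax.lineage(fid)
        sp = f"{lin[-2]} {lin[-1]}".strip()
        if sp in ("Faecalibacterium prausnitzii", "Ruminococcus gnavus"):
            species_cols.setdefault(sp, []).append(fid)
    glm_rows = []
    info = meta.subject_info()
    for sp, feats in species_cols.items():
        ab = frac[feats].sum(axis=1)
        deltas, baselines = {}, {}
        for subj in meta.paired_subjects():
            try:
                b = meta.sample_for(subj, "baseline")
                e = meta.sample_for(subj, "end")
            except KeyError:
                continue
            if b in ab.index and e in ab.index:
                deltas[subj] = float(ab[e] - ab[b])
                baselines[subj] = float(ab[b])
        delta = pd.Series(deltas)
        base = pd.Series(baselines)
        for arm in ("UDCA", "placebo"):
            males = [s for s in delta.index
                     if info.loc[s, "arm"] == arm and info.loc[s, "sex"] == "M"]
            if len(males) < 10:
                continue
            res = outcomes.outcome_regression(
                delta, meta, family="log_binomial",
                covariates=("age", "aspirin", "baseline_level"),
                extra={"baseline_level": base}, subset=males,
            )
            glm_rows.append({
                "species": sp, "arm": arm, "sex": "M", "family": res.family,
                "n": res.n, "converged": res.converged,
                "delta_estimate": res.estimate("delta") if res.converged else np.nan,
                "delta_p": res.pvalue("delta") if res.converged else np.nan,
            })
    tables["outcome_models"] = pd.DataFrame(glm_rows)
    comp_rows = []
    for var in ("sex", "aspirin"):
        tab = np.zeros((2, 2))
        for g, arm in enumerate(("UDCA", "placebo")):
            sub = info[info["arm"] == arm]
            yes = (sub["sex"] == "M").sum() if var == "sex" else (sub["aspirin"] == 1).sum()
            tab[g] = [yes, len(sub) - yes]
        r = outcomes.cohort_comparison(var, "UDCA vs placebo", counts=tab)
        comp_rows.append({"variable": r.variable, "groups": r.groups,
                          "test": r.test, "statistic": r.statistic, "p": r.p})
    tables["cohort_comparisons"] = pd.DataFrame(comp_rows)
    measures = dict(alphas or {})
    arm_model, cors = outcomes.storage_time_checks(meta, measures)
    tables["storage_arm_model"] = arm_model
    tables["storage_correlations"] = cors
    paths = {name: _write(df, outdir / "outcomes" / f"{name}.tsv")
             for name, df in tables.items()}
    return tables, paths


def run_pipeline(cfg: PipelineConfig, outdir) -> Path:
    """Execute the configured stages; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in asdict(cfg).items()},
                "stages": {}}
    t0 = time.time()

    def _record(name, paths):
        # timings go to the log, not the manifest, so reruns stay bit-identical
        logger.info("stage %s done at %.2fs", name, time.time() - t0)
        manifest["stages"][name] = {"outputs": paths}

    table, tree, tax, meta = load_inputs(cfg, outdir)
    _record("inputs", {"n_samples": table.n_samples,
                       "n_features": table.n_features})
    rare = alphas = betas = ords = None
    if cfg.run_diversity:
        try:
            rare, alphas, betas, ords, paths = stage_diversity(
                table, tree, cfg, outdir)
        except Exception as exc:
            raise RuntimeError(f"stage diversity failed: {exc}") from exc
        meta_r = meta.select(rare.sample_ids)
        _record("diversity", paths)
    if cfg.run_longitudinal:
        if rare is None:
            raise RuntimeError("stage longitudinal requires diversity outputs")
        _, paths = stage_longitudinal(rare, alphas, betas, ords, meta_r, cfg, outdir)
        _record("longitudinal", paths)
    if cfg.run_abundance:
        if rare is None:
            raise RuntimeError("stage abundance requires diversity outputs")
        _, paths = stage_abundance(rare, tax, meta_r, cfg, outdir)
        _record("abundance", paths)
    if cfg.run_network:
        if rare is None:
            raise RuntimeError("stage network requires diversity outputs")
        _, paths = stage_network(rare, meta_r, cfg, outdir, unrarefied=table)
        _record("network", paths)
    if cfg.run_outcomes:
        if rare is None:
            raise RuntimeError("stage outcomes requires diversity outputs")
        _, paths = stage_outcomes(rare, tax, meta_r, cfg, outdir, alphas=alphas)
        _record("outcomes", paths)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir
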