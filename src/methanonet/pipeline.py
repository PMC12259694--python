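"""End-to-end pipeline: data -> flux -> community -> networks -> linkage.

One config drives the full chain.  Every stage derives its own seed from
the global seed plus a stable hash of the stage name, so stages are
independently reproducible; every written file is checksummed into a run
manifest.  Outputs are write-once per run directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community, flux, linkage, network, synth

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "stage_seed"]

SOIL_COLUMNS = ["pH", "EC", "SWC", "TOC", "TN", "TP", "NO3", "NH4"]


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage seed: global seed folded with a CRC of the stage name."""
    return (seed ^ zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """All knobs of the full analysis chain.

    If ``input_dir`` is set, the count table / sample sheet / incubation
    records are read from it; otherwise a synthetic dataset is generated
    from ``synth`` settings.
    """

    output_dir: str = "methanonet_run"
    seed: int = 0
    input_dir: str | None = None
    synth: synth.SynthConfig = field(default_factory=synth.SynthConfig)
    min_reads: int = 10
    rarefaction_depth: int = 1016
    r_threshold: float = 0.6
    p_threshold: float = 0.01
    min_occurrence_frac: float = 0.2
    n_perm: int = 999
    n_boot: int = 1000
    forest_trees: int = 200
    forest_null: int = 50
    community_pc2: bool = True
    complexity_scope: str = "habitat"   # min-max scope: "habitat" or "pooled"
    overwrite: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth_raw = raw.pop("synth", {})
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if synth_raw:
            if "depths" in synth_raw:
                synth_raw["depths"] = tuple(synth_raw["depths"])
            cfg.synth = synth.SynthConfig(**synth_raw)
        return cfg


@dataclass
class PipelineResult:
    manifest: dict
    run_dir: Path
    tables: dict


def _write(df: pd.DataFrame, path: Path, manifest: dict, **kwargs) -> None:
    df.to_csv(path, **kwargs)
    manifest[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages in dependency order; returns the run manifest.

    Raises with the failing stage named; the manifest lists every file
    written with its sha256.
    """
    run_dir = Path(config.output_dir)
    if run_dir.exists() and any(run_dir.iterdir()) and not config.overwrite:
        raise FileExistsError(
            f"run directory {run_dir} is not empty (outputs are write-once); "
            "choose a fresh directory or set overwrite")
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "files": {}}
    files = manifest["files"]
    tables: dict = {}

    def stage(name: str, params: dict):
        manifest["stages"][name] = {"params": params, "seed": stage_seed(config.seed, name)}
        log.info("stage %s: %s", name, params)

    # ------------------------------------------------------------- stage: data
    stage("data", {"source": config.input_dir or "synthetic"})
    if config.input_dir:
        data_dir = Path(config.input_dir)
        counts = community.read_count_table(data_dir / "counts.tsv")
        samples = pd.read_csv(data_dir / "samples.csv", index_col=0)
        records = flux.read_incubation_csv(data_dir / "incubation.csv")
        truth = None
        missing = [c for c in ["site"] + SOIL_COLUMNS + ["mcrA_copies"]
                   if c not in samples.columns]
        if missing:
            raise ValueError(f"sample sheet is missing columns: {missing}")
    else:
        syn_cfg = synth.SynthConfig(**{
            **asdict(config.synth), "seed": stage_seed(config.seed, "data")})
        counts, samples, records, truth = synth.generate_dataset(syn_cfg)
        synth.write_dataset(counts, samples, records, truth, run_dir / "data")
        for name in ("counts.tsv", "samples.csv", "incubation.csv",
                     "ground_truth.json"):
            p = run_dir / "data" / name
            files[f"data/{name}"] = hashlib.sha256(p.read_bytes()).hexdigest()

    mismatch = set(counts.index).symmetric_difference(samples.index)
    if mismatch:
        raise ValueError(
            f"count table and sample sheet disagree on samples: {sorted(mismatch)}")

    # ------------------------------------------------------------- stage: flux
    stage("flux", {"blank_subtract": "auto"})
    flux_table = flux.batch_pmpr(records)
    extra = set(flux_table.index).symmetric_difference(samples.index)
    if extra:
        raise ValueError(f"incubation records and sample sheet disagree: {sorted(extra)}")
    samples = samples.copy()
    samples["pmpr_measured"] = flux_table["pmpr"].reindex(samples.index)
    _write(flux_table, run_dir / "flux.csv", files)

    # -------------------------------------------------------- stage: community
    stage("community", {"min_reads": config.min_reads,
                        "rarefaction_depth": config.rarefaction_depth,
                        "n_perm": config.n_perm})
    counts_f = community.filter_rare_asvs(counts, config.min_reads)
    rare = community.rarefy(counts_f, config.rarefaction_depth,
                            seed=stage_seed(config.seed, "rarefy"))
    samples = samples.loc[rare.index]
    diversity = community.alpha_diversity(rare)
    _write(diversity, run_dir / "diversity.csv", files)
    dist = community.bray_curtis(rare)
    _write(dist, run_dir / "bray_curtis.csv", files)
    perm = community.permanova(dist, samples["site"].to_numpy(),
                               n_perm=config.n_perm,
                               seed=stage_seed(config.seed, "permanova"))
    env = samples[SOIL_COLUMNS]
    cap = community.forward_select_dbrda(
        dist, env, n_perm=config.n_perm, seed=stage_seed(config.seed, "dbrda"))
    if not cap.axes.empty:
        _write(cap.axes, run_dir / "cap_axes.csv", files)
    pca_scores, explained = community.community_pca(rare)
    _write(pca_scores, run_dir / "community_pca.csv", files)

    # --------------------------------------------------------- stage: networks
    stage("network", {"r_threshold": config.r_threshold,
                      "p_threshold": config.p_threshold,
                      "min_occurrence_frac": config.min_occurrence_frac})
    networks: dict[str, network.CoocNetwork] = {}
    profiles: dict[str, network.TopologyProfile] = {}
    zipi_tables = []
    site_topology = {}
    for site in sorted(samples["site"].unique()):
        site_counts = rare.loc[samples.index[samples["site"] == site]]
        try:
            rho, pmat = network.spearman_matrix(
                site_counts, min_occurrence_frac=config.min_occurrence_frac)
        except ValueError as exc:
            warnings.warn(f"site {site}: correlation stage skipped ({exc})",
                          stacklevel=2)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net = network.build_network(rho, pmat, config.r_threshold,
                                        config.p_threshold,
                                        n_samples=site_counts.shape[0])
        networks[site] = net
        site_topology[site] = network.topology(net)
        net.edges().to_csv(run_dir / f"network_{site}.tsv", sep="\t", index=False)
        files[f"network_{site}.tsv"] = hashlib.sha256(
            (run_dir / f"network_{site}.tsv").read_bytes()).hexdigest()
        if net.n_edges > 0:
            zp = network.zi_pi(net)
            zp = zp.assign(site=site)
            zipi_tables.append(zp)
        for sid in site_counts.index:
            profiles[sid] = network.topology(
                network.sample_subnetwork(net, site_counts.loc[sid]))

    if zipi_tables:
        zipi_all = pd.concat(zipi_tables)
        _write(zipi_all, run_dir / "zipi.csv", files)
    else:
        zipi_all = pd.DataFrame()

    total_edges = sum(n.n_edges for n in networks.values())
    if total_edges == 0 or len(profiles) < 2:
        warnings.warn("all site networks are empty; complexity and network-"
                      "dependent linkage stages skipped", stacklevel=2)
        complexity = pd.DataFrame()
    else:
        if config.complexity_scope == "habitat":
            # metrics of subnetworks from different habitat networks are not
            # on a common scale; standardize within each habitat
            parts = []
            for site in sorted(samples["site"].unique()):
                ids = [s for s in samples.index[samples["site"] == site]
                       if s in profiles]
                if len(ids) >= 2:
                    parts.append(network.complexity_index(
                        {s: profiles[s] for s in ids}))
            complexity = pd.concat(parts) if parts else pd.DataFrame()
        elif config.complexity_scope == "pooled":
            complexity = network.complexity_index(profiles)
        else:
            raise ValueError(f"unknown complexity_scope {config.complexity_scope!r}")
        complexity = complexity.reindex(samples.index)
        _write(complexity, run_dir / "complexity.csv", files)

    # ---------------------------------------------------------- stage: linkage
    stage("linkage", {"n_boot": config.n_boot,
                      "forest_trees": config.forest_trees,
                      "forest_null": config.forest_null})
    frame = samples.copy()
    frame["log10_mcrA"] = np.log10(frame["mcrA_copies"])
    frame = frame.join(diversity).join(pca_scores)
    response = "pmpr_measured"

    results: dict = {
        "permanova_site": asdict(perm),
        "cap_selected": cap.selected,
        "cap_f_values": cap.f_values,
        "cap_p_values": cap.p_values,
        "pca_explained_variance": list(map(float, explained)),
        "site_topology": {s: asdict(t) for s, t in site_topology.items()},
        "keystones": (
            zipi_all[zipi_all["category"] != "peripheral"].reset_index()
            [["asv_id", "site", "category", "zi", "pi"]]
            .to_dict(orient="records") if len(zipi_all) else []),
    }

    reg_abund = linkage.fit_regression(frame["mcrA_copies"], frame[response],
                                       x_transform="log10")
    results["regression_mcra_pmpr"] = asdict(reg_abund)

    if not complexity.empty:
        frame["complexity"] = complexity["complexity"]
        reg_cx = linkage.fit_regression(frame["complexity"], frame[response])
        results["regression_complexity_pmpr"] = asdict(reg_cx)

        feature_cols = SOIL_COLUMNS + ["log10_mcrA", "richness", "PC1",
                                       "complexity"]
        imp = linkage.forest_importance(
            frame[feature_cols], frame[response],
            n_trees=config.forest_trees, n_null=config.forest_null,
            seed=stage_seed(config.seed, "forest"))
        _write(imp, run_dir / "forest_importance.csv", files)

        biotic = frame[["log10_mcrA", "richness", "shannon", "PC1", "PC2",
                        "complexity"]]
        abiotic = frame[SOIL_COLUMNS]
        vpa = linkage.variation_partition(frame[response], biotic, abiotic)
        results["vpa"] = {"pure_biotic": vpa.pure_a, "pure_abiotic": vpa.pure_b,
                          "shared": vpa.shared, "unexplained": vpa.unexplained}

        plspm_data = frame.rename(columns={response: "pmpr"})[
            ["TOC", "TN", "pH", "EC", "log10_mcrA", "richness", "shannon",
             "PC1", "PC2", "complexity", "pmpr"]]
        spec = linkage.default_path_spec(community_pc2=config.community_pc2)
        path_model = linkage.fit_plspm(
            plspm_data, spec, n_boot=config.n_boot,
            seed=stage_seed(config.seed, "plspm"))
        _write(path_model.path_coefficients, run_dir / "plspm_paths.csv",
               files, index=False)
        _write(path_model.effects, run_dir / "plspm_effects.csv", files,
               index=False)
        results["plspm"] = {
            "gof": path_model.gof,
            "r_squared": path_model.r_squared,
            "paths_to_ch4": {
                r.source: r.coefficient
                for r in path_model.path_coefficients.itertuples()
                if r.target == "ch4"},
        }
        tables["plspm"] = path_model
        tables["forest_importance"] = imp
        tables["vpa"] = vpa

    with open(run_dir / "results.json", "w") as fh:
        json.dump(results, fh, indent=1, sort_keys=True, default=str)
    files["results.json"] = hashlib.sha256(
        (run_dir / "results.json").read_bytes()).hexdigest()

    tables.update({
        "samples": frame, "counts_rarefied": rare, "diversity": diversity,
        "networks": networks, "complexity": complexity, "results": results,
        "truth": truth, "zipi": zipi_all,
    })

    manifest["config"] = asdict(config)
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return PipelineResult(manifest, run_dir, tables)
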