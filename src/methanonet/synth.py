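"""Synthetic wetland-methanogen datasets with planted ground truth.

The generator emulates the post-bioinformatics state of a four-wetland
survey: 4 sites x 8 plots x 4 depth layers (128 samples), a few hundred
ASVs, site-specific dominant taxa, and planted structure at every level
the downstream pipeline is meant to recover:

* correlated ASV blocks ("modules") per site, built from a Gaussian
  copula with known within-module rank correlation (a positive majority
  and a small anti-correlated minority per block), pushed through a
  rank-preserving log-normal abundance map and multinomial sequencing;
* conditionally-present "associate" taxa riding each module's factor
  with a steep abundance map, so whole groups of network members bloom
  in and out of individual samples;
* one star-shaped keystone block per site (a hub ASV correlated with a
  ring of satellites) planted as a module-hub keystone;
* a per-sample network-complexity driver: the number of planted-network
  taxa realized in the sample, standardized within its site;
* potential methane production rates generated as a linear combination
  of log10 mcrA abundance, soil nutrition (TOC/TN) and the complexity
  driver plus Gaussian noise, and incubation vial records back-computed
  so the flux equation reproduces each rate exactly.

Identical config + seed gives bit-identical output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import community, flux, network

__all__ = ["SynthConfig", "GroundTruth", "generate_dataset", "write_dataset",
           "read_ground_truth"]

_SITE_NAMES = ["MQ", "LQ", "ZY", "SGH"]

#: per-site soil-property means: peatlands (MQ, LQ) are organic-rich and
#: slightly acidic; desert wetlands (ZY, SGH) are saline-alkaline and
#: carbon-poor.  Units: pH (-), EC (mS/cm), SWC (%), TOC/TN (g/kg),
#: TP (g/kg), NO3/NH4 (mg/kg), mcrA (log10 copies per g soil).
DEFAULT_SITE_EFFECTS = {
    "MQ": {"pH": 6.2, "EC": 0.35, "SWC": 65.0, "TOC": 180.0, "TN": 9.5,
           "TP": 0.90, "NO3": 6.0, "NH4": 12.0, "log10_mcrA": 1.86},
    "LQ": {"pH": 6.6, "EC": 0.45, "SWC": 60.0, "TOC": 150.0, "TN": 8.0,
           "TP": 0.80, "NO3": 5.0, "NH4": 10.0, "log10_mcrA": 1.78},
    "ZY": {"pH": 8.6, "EC": 2.50, "SWC": 35.0, "TOC": 25.0, "TN": 2.0,
           "TP": 0.70, "NO3": 8.0, "NH4": 6.0, "log10_mcrA": 1.82},
    "SGH": {"pH": 8.9, "EC": 3.20, "SWC": 30.0, "TOC": 18.0, "TN": 1.5,
            "TP": 0.60, "NO3": 9.0, "NH4": 5.0, "log10_mcrA": 1.73},
}

DEFAULT_DEPTHS = ("0-5", "5-10", "10-20", "20-40")


@dataclass(frozen=True)
class SynthConfig:
    """Study design, planted effect sizes and nuisance parameters.

    The defaults reproduce the survey design the package targets
    (4 sites x 8 plots x 4 depths, rarefaction-compatible sequencing
    depths around 2,000 reads) and plant effects strong enough that a
    competent analysis recovers them at n = 128.
    """

    n_sites: int = 4
    plots_per_site: int = 8
    depths: tuple[str, ...] = DEFAULT_DEPTHS
    n_asvs: int = 300
    n_modules: int = 4                 # plain correlated blocks per site
    module_size: int = 10
    within_module_rho: float = 0.75    # planted rank correlation inside a block
    cross_module_rho: float = 0.0      # optional site-wide activity factor share
    n_neg_members: int = 3             # members loading negatively per module
    n_neg_satellites: int = 3          # negative-loading satellites (spread over factions)
    site_module_offsets: dict = field(
        default_factory=lambda: {"MQ": -1, "LQ": -1, "SGH": -2})
    n_cond_per_module: int = 2         # conditionally-present associates per module
    cond_core_rho: float = 0.75        # planted rank corr of an associate with core members
    cond_weight: float = 35.0          # baseline weight of conditional members
    cond_sigma: float = 1.6            # steep abundance map: on/off blooms
    nutrient_coupling: float = 0.0     # module activity follows within-site TOC
    keystones_per_site: int = 1        # star (hub) blocks per site
    n_satellites: int = 10             # satellites per keystone hub
    n_sat_groups: int = 1              # satellite factions around each hub
    hub_member_rho: float = 0.66       # planted hub-satellite rank correlation
    sat_group_rho: float = 0.50        # rank correlation among satellites
    lognormal_sigma: float = 1.2       # abundance heterogeneity (log scale)
    depth_min: int = 1800              # sequencing depth range (uniform)
    depth_max: int = 2200
    site_effects: dict = field(default_factory=lambda: {
        s: dict(v) for s, v in DEFAULT_SITE_EFFECTS.items()})
    beta_abund: float = 10.0           # PMPR per SD of log10 mcrA
    beta_nutrition: float = 6.0        # PMPR per SD of the TOC/TN score
    beta_complexity: float = 5.6       # PMPR per SD of the complexity driver
    noise_sd: float = 9.0              # residual PMPR SD (ng g^-1 d^-1)
    pmpr_base: float = 65.0            # grand-mean PMPR (ng g^-1 d^-1)
    drop_samples: int = 0              # mimic failed libraries (7 -> 121 usable)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_sites", "plots_per_site", "n_asvs", "n_modules",
                     "module_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if len(self.depths) < 1:
            raise ValueError("need at least one depth layer")
        if not 0.0 < self.within_module_rho < 1.0:
            raise ValueError("within_module_rho must be strictly in (0, 1)")
        if not 0.0 <= self.cross_module_rho < self.within_module_rho:
            raise ValueError("cross_module_rho must be in [0, within_module_rho)")
        if not 0 <= self.n_neg_members < self.module_size:
            raise ValueError("n_neg_members must be in [0, module_size)")
        if not 0 <= self.n_neg_satellites < max(self.n_satellites, 1):
            raise ValueError("n_neg_satellites must be in [0, n_satellites)")
        if not 0.0 < self.hub_member_rho < 1.0:
            raise ValueError("hub_member_rho must be strictly in (0, 1)")
        if not 0.0 < self.sat_group_rho < 1.0:
            raise ValueError("sat_group_rho must be strictly in (0, 1)")
        if self.keystones_per_site and self.n_satellites % self.n_sat_groups:
            raise ValueError("n_satellites must divide evenly into n_sat_groups")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.depth_min < 1016 or self.depth_max < self.depth_min:
            raise ValueError("sequencing depth range must satisfy 1016 <= depth_min <= depth_max")
        if self.n_cond_per_module < 0:
            raise ValueError("n_cond_per_module must be >= 0")
        if not 0.0 < self.cond_core_rho < 1.0:
            raise ValueError("cond_core_rho must be strictly in (0, 1)")
        if not 0.0 <= self.nutrient_coupling < 1.0:
            raise ValueError("nutrient_coupling must be in [0, 1)")
        total = sum(
            self.modules_for(site) * (self.module_size + self.n_cond_per_module)
            + self.keystones_per_site * (1 + self.n_satellites)
            for site in self.site_names)
        if total > self.n_asvs:
            raise ValueError(
                f"planted structure needs {total} ASVs but n_asvs = {self.n_asvs}")
        if self.drop_samples < 0:
            raise ValueError("drop_samples must be >= 0")

    def modules_for(self, site: str) -> int:
        """Planted module count for a site: base count plus the site offset.

        The offsets plant a between-site network-complexity gradient (some
        wetlands carry richer interaction structure than others), which the
        complexity index is meant to resolve.
        """
        return max(1, self.n_modules + int(self.site_module_offsets.get(site, 0)))

    @property
    def site_names(self) -> list[str]:
        names = list(_SITE_NAMES)
        while len(names) < self.n_sites:
            names.append(f"W{len(names) + 1}")
        return names[: self.n_sites]

    @property
    def n_samples(self) -> int:
        return self.n_sites * self.plots_per_site * len(self.depths)


@dataclass
class GroundTruth:
    """What was planted, for recovery scoring."""

    true_edges: set[frozenset]                 # planted strong pairs
    true_edges_by_site: dict[str, set[frozenset]]
    module_assignment: dict[str, str]          # ASV -> "SITE.m3" / "SITE.hub1"
    planted_keystones: set[str]                # hub ASVs
    true_path_coefficients: dict[str, float]   # standardized, realized
    raw_betas: dict[str, float]
    complexity_driver: pd.Series               # per-sample planted driver (z)
    pmpr: pd.Series                            # planted rates, ng g^-1 d^-1

    def to_json_dict(self) -> dict:
        return {
            "true_edges": sorted(sorted(e) for e in self.true_edges),
            "true_edges_by_site": {
                s: sorted(sorted(e) for e in edges)
                for s, edges in self.true_edges_by_site.items()
            },
            "module_assignment": self.module_assignment,
            "planted_keystones": sorted(self.planted_keystones),
            "true_path_coefficients": self.true_path_coefficients,
            "raw_betas": self.raw_betas,
            "complexity_driver": self.complexity_driver.round(10).to_dict(),
            "pmpr": self.pmpr.round(10).to_dict(),
        }


# ------------------------------------------------------------------ helpers

def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=0)


def _gauss_from_rank(rho_s: float) -> float:
    """Gaussian copula correlation giving rank (Spearman) correlation rho_s."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def _rank_from_gauss(rho_g: float) -> float:
    return (6.0 / np.pi) * np.arcsin(rho_g / 2.0)


def _member_signs(cfg: SynthConfig) -> np.ndarray:
    """Loading signs within a module: a positive majority plus a small
    anti-correlated minority (competing guild)."""
    s = np.ones(cfg.module_size)
    if cfg.n_neg_members:
        s[-cfg.n_neg_members:] = -1.0
    return s


def _sat_signs(cfg: SynthConfig) -> np.ndarray:
    """Satellite loading signs, negatives spread evenly over the factions."""
    q = cfg.n_satellites // cfg.n_sat_groups
    neg_per_group = cfg.n_neg_satellites // cfg.n_sat_groups
    s = np.ones(cfg.n_satellites)
    for grp in range(cfg.n_sat_groups):
        if neg_per_group:
            s[grp * q + q - neg_per_group: (grp + 1) * q] = -1.0
    return s


def _sat_group_of(cfg: SynthConfig, k: int) -> int:
    return k // (cfg.n_satellites // cfg.n_sat_groups)


def _true_network(cfg: SynthConfig, structure: dict) -> network.CoocNetwork:
    """The planted network: signed module blocks plus hub-satellite stars."""
    ids = structure["all_asvs"]
    pos = {a: i for i, a in enumerate(ids)}
    rho = np.zeros((len(ids), len(ids)))
    msign = _member_signs(cfg)
    ssign = _sat_signs(cfg)
    for site in cfg.site_names:
        for members in structure["modules"][site]:
            for i, a in enumerate(members):
                for j in range(i + 1, len(members)):
                    v = cfg.within_module_rho * msign[i] * msign[j]
                    rho[pos[a], pos[members[j]]] = rho[pos[members[j]], pos[a]] = v
        # conditional associates: edges to every core member of their module
        # (signed by the member's loading) and among themselves
        assoc_assoc = _rank_from_gauss(
            _gauss_from_rank(cfg.cond_core_rho) ** 2
            / _gauss_from_rank(cfg.within_module_rho))
        for members, assoc in zip(structure["modules"][site],
                                  structure["associates"][site]):
            for ca in assoc:
                for k, m in enumerate(members):
                    v = cfg.cond_core_rho * msign[k]
                    rho[pos[ca], pos[m]] = rho[pos[m], pos[ca]] = v
            for i, ca in enumerate(assoc):
                for cb in assoc[i + 1:]:
                    rho[pos[ca], pos[cb]] = rho[pos[cb], pos[ca]] = assoc_assoc
        for hub, sats in structure["stars"][site]:
            for j, s in enumerate(sats):
                v = cfg.hub_member_rho * ssign[j]
                rho[pos[hub], pos[s]] = rho[pos[s], pos[hub]] = v
                for k in range(j + 1, len(sats)):
                    if _sat_group_of(cfg, j) == _sat_group_of(cfg, k):
                        w = cfg.sat_group_rho * ssign[j] * ssign[k]
                        rho[pos[s], pos[sats[k]]] = rho[pos[sats[k]], pos[s]] = w
    return network.CoocNetwork(list(ids), rho, {"planted": True})


def _plan_structure(cfg: SynthConfig) -> dict:
    """Assign ASV identifiers to plain modules, stars and background."""
    width = len(str(cfg.n_asvs))
    all_asvs = [f"ASV{i + 1:0{width}d}" for i in range(cfg.n_asvs)]
    cursor = 0
    modules: dict[str, list[list[str]]] = {}
    associates: dict[str, list[list[str]]] = {}   # per module, in step
    stars: dict[str, list[tuple[str, list[str]]]] = {}
    for site in cfg.site_names:
        modules[site] = []
        associates[site] = []
        for _ in range(cfg.modules_for(site)):
            modules[site].append(all_asvs[cursor: cursor + cfg.module_size])
            cursor += cfg.module_size
            associates[site].append(all_asvs[cursor: cursor + cfg.n_cond_per_module])
            cursor += cfg.n_cond_per_module
        stars[site] = []
        for _ in range(cfg.keystones_per_site):
            hub = all_asvs[cursor]
            sats = all_asvs[cursor + 1: cursor + 1 + cfg.n_satellites]
            stars[site].append((hub, sats))
            cursor += 1 + cfg.n_satellites
    background = all_asvs[cursor:]
    return {"all_asvs": all_asvs, "modules": modules,
            "associates": associates, "stars": stars,
            "background": background}


# ----------------------------------------------------------------- generator

def generate_dataset(
    config: SynthConfig = SynthConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame, list[flux.IncubationRecord], GroundTruth]:
    """Generate (count table, sample frame, incubation records, ground truth).

    See the module docstring for the generative model.  Deterministic for a
    given config (the seed is part of the config).
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    structure = _plan_structure(cfg)
    sites = cfg.site_names
    n_per_site = cfg.plots_per_site * len(cfg.depths)

    sample_rows = []
    for site in sites:
        for plot in range(1, cfg.plots_per_site + 1):
            for depth in cfg.depths:
                sample_rows.append(
                    {"sample_id": f"{site}.P{plot:02d}.D{depth}",
                     "site": site, "plot": f"P{plot:02d}", "depth": depth})
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    n_samples = len(samples)

    # Planted correlations are rank (Spearman) targets; the Gaussian copula
    # correlation giving rank correlation rho_s is 2 sin(pi rho_s / 6).
    copula_rho = _gauss_from_rank

    # latent loadings (unit-variance construction):
    #   member   z = s * a f_module + c g_site + b eps
    #   hub      z = a_h F_star + c g_site + b_h eps
    #   sat k of faction q: z = s_k * a_g f_q + c g_site + b_s eps,
    #                       f_q = alpha F_star + sqrt(1-alpha^2) h_q
    # so |member-member corr| = a^2 + c^2, |hub-sat| = a_h a_g alpha,
    # |within-faction| = a_g^2, cross-faction = a_g^2 alpha^2 (weak by
    # construction: factions are tied together only through the hub).
    c2 = copula_rho(cfg.cross_module_rho)
    rho_w = copula_rho(cfg.within_module_rho)
    if rho_w <= c2:
        raise ValueError("within_module_rho must exceed cross_module_rho")
    c = np.sqrt(c2)
    a = np.sqrt(rho_w - c2)
    b = np.sqrt(1.0 - rho_w)
    a_g = np.sqrt(copula_rho(cfg.sat_group_rho))
    if a_g**2 + c2 >= 1.0:
        raise ValueError("sat_group_rho incompatible with cross_module_rho")
    b_s = np.sqrt(1.0 - a_g**2 - c2)
    a_h = np.sqrt(0.9025 - c2)  # hub loads 0.95 on its star factor
    b_h = np.sqrt(1.0 - a_h**2 - c2)
    alpha = copula_rho(cfg.hub_member_rho) / (a_h * a_g)
    if not 0.0 < alpha < 1.0:
        raise ValueError("hub_member_rho incompatible with sat_group_rho")
    # conditional associates load on their module's factor
    a_c = copula_rho(cfg.cond_core_rho) / a
    if a_c**2 + c2 >= 1.0:
        raise ValueError("cond_core_rho incompatible with within_module_rho")
    b_c = np.sqrt(1.0 - a_c**2 - c2)

    asv_index = {asv: i for i, asv in enumerate(structure["all_asvs"])}
    z = rng.standard_normal((n_samples, cfg.n_asvs))  # iid base, overwritten

    # baseline background weights, shared shape across sites with
    # site-specific log offsets (site-specific composition)
    bg_idx = np.array([asv_index[a] for a in structure["background"]], dtype=int)
    # bimodal background: a common half (few zeros) and a rare half (mostly
    # absent, removed by the occurrence filter); intermediate-presence taxa
    # are avoided because heavy zero-ties make rank correlations unstable
    n_common = min(20, bg_idx.size)
    bg_base = np.concatenate([
        np.exp(rng.uniform(np.log(5.0), np.log(10.0), size=n_common)),
        np.exp(rng.uniform(np.log(0.05), np.log(0.3), size=bg_idx.size - n_common)),
    ])
    bg_site_offset = {
        site: rng.normal(0.0, 0.8, size=bg_idx.size) for site in sites
    }

    site_of_sample = samples["site"].to_numpy()

    # ---------------------------------------------------- soil properties
    # (generated before the community so module activity can follow the
    # sample's organic carbon)
    # within-site log-scale spreads: organic pools vary strongly with depth
    # and microtopography; salinity moderately; the rest are tighter
    soil_sd = {"EC": 0.15, "SWC": 0.15, "TOC": 0.45, "TP": 0.08,
               "NO3": 0.10, "NH4": 0.10}
    for col in ("pH", "EC", "SWC", "TOC", "TN", "TP", "NO3", "NH4"):
        vals = np.empty(n_samples)
        for site in sites:
            rows = np.nonzero(site_of_sample == site)[0]
            mean = cfg.site_effects[site][col]
            if col == "pH":
                vals[rows] = mean + rng.normal(0.0, 0.25, rows.size)
            elif col == "TN":
                # TN tracks TOC within a site (organic matter stoichiometry)
                ratio = mean / cfg.site_effects[site]["TOC"]
                vals[rows] = (samples["TOC"].to_numpy()[rows] * ratio
                              * np.exp(rng.normal(0.0, 0.05, rows.size)))
            else:
                vals[rows] = mean * np.exp(rng.normal(0.0, soil_sd[col], rows.size))
        samples[col] = vals

    # within-site standardized log TOC drives module activity (substrate
    # availability activates cooperative guilds)
    log_toc = np.log(samples["TOC"].to_numpy())
    toc_z = np.empty(n_samples)
    for site in sites:
        rows = np.nonzero(site_of_sample == site)[0]
        toc_z[rows] = (log_toc[rows] - log_toc[rows].mean()) / log_toc[rows].std()
    delta = cfg.nutrient_coupling
    d_resid = np.sqrt(1.0 - delta**2)

    weights_matrix = np.zeros((n_samples, cfg.n_asvs))
    module_weights = np.full(cfg.module_size, 100.0)

    for site in sites:
        rows = np.nonzero(site_of_sample == site)[0]
        g = rng.standard_normal(rows.size)   # optional site-wide factor
        # plain modules (mixed-sign loadings)
        msign = _member_signs(cfg)
        ssign = _sat_signs(cfg)
        for members, assoc in zip(structure["modules"][site],
                                  structure["associates"][site]):
            f = delta * toc_z[rows] + d_resid * rng.standard_normal(rows.size)
            for k, asv in enumerate(members):
                j = asv_index[asv]
                z[rows, j] = (msign[k] * a * f + c * g
                              + b * rng.standard_normal(rows.size))
            # conditional associates ride the same module factor with a
            # steep abundance map: present (blooming) when the module is
            # active, absent otherwise
            for asv in assoc:
                j = asv_index[asv]
                z[rows, j] = (a_c * f + c * g
                              + b_c * rng.standard_normal(rows.size))
        # keystone connector stars: hub factor F, faction factors mix in F
        for hub, sats in structure["stars"][site]:
            big_f = rng.standard_normal(rows.size)
            fq = [alpha * big_f + np.sqrt(1 - alpha**2) * rng.standard_normal(rows.size)
                  for _ in range(cfg.n_sat_groups)]
            j = asv_index[hub]
            z[rows, j] = a_h * big_f + c * g + b_h * rng.standard_normal(rows.size)
            for k, asv in enumerate(sats):
                j = asv_index[asv]
                z[rows, j] = (ssign[k] * a_g * fq[_sat_group_of(cfg, k)] + c * g
                              + b_s * rng.standard_normal(rows.size))
        # per-site weight profile
        w_site = np.full(cfg.n_asvs, 0.05)
        for members in structure["modules"][site]:
            for asv, w in zip(members, module_weights):
                w_site[asv_index[asv]] = w
        for assoc in structure["associates"][site]:
            for asv in assoc:
                w_site[asv_index[asv]] = cfg.cond_weight
        for hub, sats in structure["stars"][site]:
            w_site[asv_index[hub]] = 100.0
            for asv in sats:
                w_site[asv_index[asv]] = 60.0
        w_site[bg_idx] = bg_base * np.exp(bg_site_offset[site])
        weights_matrix[rows] = w_site

    # per-ASV abundance map steepness: conditional taxa get a steep map so
    # they are either solidly present (blooming) or truly absent
    sigma_vec = np.full(cfg.n_asvs, cfg.lognormal_sigma)
    for site in sites:
        for assoc in structure["associates"][site]:
            for asv in assoc:
                sigma_vec[asv_index[asv]] = cfg.cond_sigma
    abundance = weights_matrix * np.exp(sigma_vec[None, :] * z)
    rel = abundance / abundance.sum(axis=1, keepdims=True)
    seq_depth = rng.integers(cfg.depth_min, cfg.depth_max + 1, size=n_samples)
    counts = np.vstack([
        rng.multinomial(seq_depth[i], rel[i]) for i in range(n_samples)
    ])
    count_table = pd.DataFrame(counts, index=samples.index,
                               columns=structure["all_asvs"])

    log_mcra = np.empty(n_samples)
    for site in sites:
        rows = np.nonzero(site_of_sample == site)[0]
        log_mcra[rows] = rng.normal(cfg.site_effects[site]["log10_mcrA"], 0.12,
                                    rows.size)
    samples["mcrA_copies"] = 10.0 ** log_mcra

    # --------------------------------------------- planted complexity driver
    # the driver is the sample's realized share of the planted network: the
    # number of planted-network taxa present in its counts (z-scored).  A
    # sample hosting more of the interaction network realizes a more complex
    # subnetwork, which is what the complexity index measures downstream.
    truth_net = _true_network(cfg, structure)
    degree = truth_net.adjacency.sum(axis=0)
    net_cols = [a for a, d in zip(truth_net.asv_ids, degree) if d > 0]
    present_nn = (count_table.loc[:, net_cols] > 0).sum(axis=1).to_numpy(float)
    # standardized within site: the driver is the sample's realized share of
    # its own habitat's planted network, on a scale comparable across sites
    driver_vals = np.empty(n_samples)
    for site in sites:
        rows = np.nonzero(site_of_sample == site)[0]
        driver_vals[rows] = _zscore(present_nn[rows])
    driver = pd.Series(driver_vals, index=samples.index,
                       name="complexity_driver")

    # ------------------------------------------------------------------ PMPR
    z_abund = _zscore(log_mcra)
    z_nutr = 0.5 * (_zscore(samples["TOC"].to_numpy())
                    + _zscore(samples["TN"].to_numpy()))
    pmpr = (cfg.pmpr_base
            + cfg.beta_abund * z_abund
            + cfg.beta_nutrition * z_nutr
            + cfg.beta_complexity * driver.to_numpy()
            + rng.normal(0.0, cfg.noise_sd, n_samples))
    samples["pmpr"] = pmpr

    # ------------------------------------------------- incubation records
    records: list[flux.IncubationRecord] = []
    for sid, rate in zip(samples.index, pmpr):
        template = flux.IncubationRecord(
            sample_id=sid, c_t0=0.05, c_t1=0.05, t0=1.0, t1=15.0,
            vh=0.115, pa=70.0, ws=5.0, temp_c=25.0)
        dc_dt = flux.invert_dc_dt(rate, template)
        c_t1 = template.c_t0 + dc_dt * (template.t1 - template.t0)
        if c_t1 < 0:
            raise RuntimeError(f"negative headspace mixing ratio for {sid}")
        for _ in range(3):
            records.append(flux.IncubationRecord(
                sample_id=sid, c_t0=template.c_t0, c_t1=c_t1,
                t0=template.t0, t1=template.t1, vh=template.vh,
                pa=template.pa, ws=template.ws, temp_c=template.temp_c))
        records.append(flux.IncubationRecord(
            sample_id=sid, c_t0=template.c_t0, c_t1=template.c_t0,
            t0=template.t0, t1=template.t1, vh=template.vh, pa=template.pa,
            ws=template.ws, temp_c=template.temp_c, is_control=True))

    # --------------------------------------------------------- ground truth
    true_edges_by_site: dict[str, set[frozenset]] = {}
    module_assignment: dict[str, str] = {}
    keystones: set[str] = set()
    for site in sites:
        edges: set[frozenset] = set()
        for m, (members, assoc) in enumerate(
                zip(structure["modules"][site], structure["associates"][site]),
                start=1):
            for asv in members:
                module_assignment[asv] = f"{site}.m{m}"
            for asv in assoc:
                module_assignment[asv] = f"{site}.m{m}c"
            for i, x in enumerate(members):
                for y in members[i + 1:]:
                    edges.add(frozenset((x, y)))
            for ca in assoc:
                for m_asv in members:
                    edges.add(frozenset((ca, m_asv)))
            for i, ca in enumerate(assoc):
                for cb in assoc[i + 1:]:
                    edges.add(frozenset((ca, cb)))
        for h, (hub, sats) in enumerate(structure["stars"][site], start=1):
            module_assignment[hub] = f"{site}.hub{h}"
            keystones.add(hub)
            for asv in sats:
                module_assignment[asv] = f"{site}.hub{h}"
            for s in sats:
                edges.add(frozenset((hub, s)))
        true_edges_by_site[site] = edges

    sd_pmpr = float(np.std(pmpr, ddof=0))
    truth = GroundTruth(
        true_edges=set().union(*true_edges_by_site.values()),
        true_edges_by_site=true_edges_by_site,
        module_assignment=module_assignment,
        planted_keystones=keystones,
        true_path_coefficients={
            "abundance->ch4": cfg.beta_abund / sd_pmpr,
            "nutrition->ch4": cfg.beta_nutrition / sd_pmpr,
            "complexity->ch4": cfg.beta_complexity / sd_pmpr,
        },
        raw_betas={"abundance": cfg.beta_abund, "nutrition": cfg.beta_nutrition,
                   "complexity": cfg.beta_complexity},
        complexity_driver=driver,
        pmpr=pd.Series(pmpr, index=samples.index, name="pmpr"),
    )

    if cfg.drop_samples:
        dropped = rng.choice(samples.index.to_numpy(), size=cfg.drop_samples,
                             replace=False)
        keep = ~samples.index.isin(dropped)
        samples = samples.loc[keep]
        count_table = count_table.loc[keep]
        records = [r for r in records if r.sample_id in set(samples.index)]

    return count_table, samples, records, truth


# ------------------------------------------------------------------- output

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_dataset(
    count_table: pd.DataFrame,
    samples: pd.DataFrame,
    records: list[flux.IncubationRecord],
    truth: GroundTruth,
    directory,
) -> dict[str, str]:
    """Write the dataset to a directory; returns {filename: sha256}.

    Files: counts.tsv (samples x ASVs), samples.csv, incubation.csv,
    ground_truth.json, plus a manifest.json listing the checksums.
    Round-trips losslessly through the community/flux readers.
    """
    if count_table.shape[0] == 0:
        raise ValueError("refusing to write an empty sample set")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    community.write_count_table(count_table, directory / "counts.tsv")
    samples.to_csv(directory / "samples.csv")
    flux.write_incubation_csv(records, directory / "incubation.csv")
    with open(directory / "ground_truth.json", "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)
    manifest = {
        name: _sha256(directory / name)
        for name in ("counts.tsv", "samples.csv", "incubation.csv",
                     "ground_truth.json")
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def read_ground_truth(path) -> dict:
    """Load the ground-truth JSON back into python sets/dicts."""
    with open(path) as fh:
        raw = json.load(fh)
    raw["true_edges"] = {frozenset(e) for e in raw["true_edges"]}
    raw["true_edges_by_site"] = {
        s: {frozenset(e) for e in edges}
        for s, edges in raw["true_edges_by_site"].items()
    }
    raw["planted_keystones"] = set(raw["planted_keystones"])
    return raw
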