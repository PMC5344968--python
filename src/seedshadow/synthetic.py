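"""Synthetic study generator with known ground truth.

Emulates the field design that motivates the pipeline: wedge-shaped
17-trap seed-trap arrays around focal trees at 13 sites across four islands
(four on the no-bird island, three on each bird island), mapped conspecific
stands with lognormal site fecundity, negative-binomially overdispersed
trap counts generated from a known dispersal kernel, logistic
distance-dependent bird ingestion (identically zero where birds are
absent), treatment-dependent nursery germination, near/far outplanted
seedling survival with a canopy-openness covariate, and 50-seed seed
-addition plots near and far from conspecific adults.

Every dataset is produced from a single seed that fans out deterministically
to per-component generators, and the configuration records the generating
parameters so that estimation stages can be tested for recovery.  The true
seed-to-seedling survival ratio implied by the generating parameters is
computed at generation time (by quadrature, cross-checked by the
forward-simulation oracle) and stored alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .kernels import POWER_EXPONENTIAL, KernelSpec
from .recruitment import (
    DEFAULT_FAR_M,
    DEFAULT_NEAR_M,
    RecruitmentResult,
    ScenarioConfig,
    forward_simulate_phi,
    seed_to_seedling,
)
from .seed_shadow import (
    ISLANDS,
    FecundityParams,
    NBDispersion,
    StandData,
    TrapRecord,
    TreeRecord,
    simulate_trap_counts,
)

__all__ = ["WorldConfig", "World", "generate_stand", "generate_trap_array", "simulate_world"]

BIRD_ISLANDS = ("Rota", "Saipan", "Tinian")

#: trap distances (m) spanning near-canopy to ~20 m, denser near the source
DEFAULT_TRAP_DISTANCES = (
    1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0,
    9.0, 10.0, 12.0, 14.0, 16.0, 18.0, 20.0,
)


@dataclass
class WorldConfig:
    """Generating parameters for one synthetic species-level study."""

    seed: int = 0

    # --- trap-array design -------------------------------------------------
    array_sites: dict[str, int] = field(
        default_factory=lambda: {"Guam": 4, "Rota": 3, "Saipan": 3, "Tinian": 3}
    )
    trees_per_site: int = 8
    stand_extent_m: float = 40.0
    dbh_log_mean: float = math.log(15.0)   # cm
    dbh_log_sd: float = 0.4
    trap_distances: Sequence[float] = DEFAULT_TRAP_DISTANCES
    wedge_angle_deg: float = 60.0
    trap_area_m2: float = 0.5

    # --- true dispersal model ---------------------------------------------
    kernel_family: str = POWER_EXPONENTIAL
    a_guam: float = 0.5
    a_birds: float = 3.4
    mu_beta: float = math.log(2e5)  # seeds per m^2 basal area per season
    sigma_beta: float = 0.5
    k1: float = 0.5
    k2: float = 0.2

    # --- ingestion (bird islands; zero where birds are absent) -------------
    ingestion_intercept: float = -0.5
    ingestion_distance_slope: float = 0.3   # per metre of nearest-conspecific distance
    ingestion_island_offsets: dict[str, float] = field(
        default_factory=lambda: {"Rota": 0.0, "Saipan": 0.0, "Tinian": 0.0}
    )

    # --- nursery germination -----------------------------------------------
    germination_n: dict[str, int] = field(
        default_factory=lambda: {"whole_fruit": 117, "depulped": 104, "ingested": 150}
    )
    germination_p: dict[str, float] = field(
        default_factory=lambda: {"whole_fruit": 0.12, "depulped": 0.22, "ingested": 0.40}
    )

    # --- outplanted seedling survival ---------------------------------------
    outplant_sites: dict[str, int] = field(
        default_factory=lambda: {"Guam": 5, "Rota": 3, "Saipan": 3, "Tinian": 3}
    )
    plots_per_site: int = 8            # half near, half far
    seedlings_per_plot: int = 10
    survival_logit_near: float = -0.6  # no-birds reference, mean openness
    survival_far_effect: float = 0.8
    survival_birds_effect: float = 0.0
    survival_birds_far_interaction: float = 0.0
    survival_openness_slope: float = 0.05   # per percentage point of openness
    survival_openness_far_interaction: float = 0.0
    survival_site_sd: float = 0.3
    openness_mean: float = 10.0
    openness_sd: float = 3.0

    # --- seed-addition experiment (germination + early survival) ------------
    addition_sites: int = 3
    addition_plots_per_distance: int = 6   # per site
    addition_seeds_per_plot: int = 50
    addition_germ_p_near: float = 0.20
    addition_germ_p_far: float = 0.45
    addition_early_surv_p_near: float = 0.30
    addition_early_surv_p_far: float = 0.67

    # --- near/far representative distances used for ground-truth phi --------
    near_m: float = DEFAULT_NEAR_M
    far_m: float = DEFAULT_FAR_M

    def kernel(self, island: str) -> KernelSpec:
        a = self.a_guam if island == "Guam" else self.a_birds
        return KernelSpec(self.kernel_family, a)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["trap_distances"] = list(self.trap_distances)
        return d


@dataclass
class World:
    """One synthetic dataset plus its generating truth."""

    config: WorldConfig
    trees: pd.DataFrame
    traps: pd.DataFrame
    germination: pd.DataFrame
    survival_plots: pd.DataFrame
    seed_addition: pd.DataFrame
    ground_truth: dict

    def stand(self) -> StandData:
        return StandData(self.trees, self.traps)


def generate_stand(
    config: WorldConfig, site_id: str, island: str, rng: np.random.Generator
) -> pd.DataFrame:
    """Mapped conspecific trees for one site: positions uniform over the
    stand extent, lognormal dbh, the largest tree flagged focal."""
    n = config.trees_per_site
    half = config.stand_extent_m / 2.0
    x = rng.uniform(-half, half, size=n)
    y = rng.uniform(-half, half, size=n)
    dbh = rng.lognormal(config.dbh_log_mean, config.dbh_log_sd, size=n)
    df = pd.DataFrame(
        {
            "tree_id": [f"{site_id}-T{i:02d}" for i in range(n)],
            "site_id": site_id,
            "island": island,
            "x_m": x,
            "y_m": y,
            "dbh_cm": dbh,
            "focal": False,
        }
    )
    if n:
        df.loc[df.dbh_cm.idxmax(), "focal"] = True
    return df


def generate_trap_array(
    config: WorldConfig,
    site_id: str,
    island: str,
    focal_x: float,
    focal_y: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """A wedge of 17 seed traps radiating from the focal tree.

    Distances follow the configured sequence (near-canopy to ~20 m); each
    trap's bearing is drawn within a sector of the configured opening angle,
    the sector itself randomly oriented per site."""
    dists = np.asarray(config.trap_distances, dtype=float)
    orientation = rng.uniform(0.0, 2.0 * math.pi)
    half_sector = math.radians(config.wedge_angle_deg) / 2.0
    angles = orientation + rng.uniform(-half_sector, half_sector, size=len(dists))
    return pd.DataFrame(
        {
            "trap_id": [f"{site_id}-K{i:02d}" for i in range(len(dists))],
            "site_id": site_id,
            "island": island,
            "x_m": focal_x + dists * np.cos(angles),
            "y_m": focal_y + dists * np.sin(angles),
            "area_m2": config.trap_area_m2,
        }
    )


def _nearest_distance(traps: pd.DataFrame, trees: pd.DataFrame) -> np.ndarray:
    out = np.empty(len(traps))
    trees_by_site = dict(tuple(trees.groupby("site_id")))
    for i, row in enumerate(traps.itertuples()):
        tt = trees_by_site[row.site_id]
        d = np.hypot(tt.x_m.to_numpy() - row.x_m, tt.y_m.to_numpy() - row.y_m)
        out[i] = d.min()
    return out


def _true_scenarios(config: WorldConfig) -> tuple[ScenarioConfig, ScenarioConfig]:
    """Scenario pair implied by the generating parameters."""
    g_un = float(logit(config.germination_p["whole_fruit"]))
    g_in = float(logit(config.germination_p["ingested"]))
    germ_far = float(
        logit(config.addition_germ_p_far) - logit(config.addition_germ_p_near)
    )
    s1_logit = float(logit(config.addition_early_surv_p_near))
    s1_far = float(
        logit(config.addition_early_surv_p_far) - logit(config.addition_early_surv_p_near)
    )
    ingestion = [
        (config.ingestion_intercept + config.ingestion_island_offsets.get(isl, 0.0),
         config.ingestion_distance_slope)
        for isl in BIRD_ISLANDS
    ]
    common = dict(
        germ_logit_uningested=g_un,
        germ_logit_ingested=g_in,
        germ_far_coef=germ_far,
        s1_logit=s1_logit,
        s1_far_coef=s1_far,
        near_m=config.near_m,
        far_m=config.far_m,
    )
    present = ScenarioConfig(
        birds_present=True,
        kernel=config.kernel("Rota"),
        ingestion=ingestion,
        s2_logit=config.survival_logit_near + config.survival_birds_effect,
        s2_far_coef=config.survival_far_effect + config.survival_birds_far_interaction,
        **common,
    )
    absent = ScenarioConfig(
        birds_present=False,
        kernel=config.kernel("Guam"),
        ingestion=[],
        s2_logit=config.survival_logit_near,
        s2_far_coef=config.survival_far_effect,
        **common,
    )
    return present, absent


def simulate_world(config: WorldConfig | None = None, oracle_seeds: int = 200_000) -> World:
    """Generate the full synthetic study from a single seed.

    Returns the mapped trees, trap counts with ingestion classification,
    nursery germination trials, outplanted survival plots and seed-addition
    plots, together with the generating parameters and the true
    seed-to-seedling survival ratio (quadrature value plus a
    forward-simulated cross-check on ``oracle_seeds`` seeds per scenario).
    """
    config = config or WorldConfig()
    ss = np.random.SeedSequence(config.seed)
    (
        ss_stand, ss_counts, ss_ingest, ss_germ, ss_surv, ss_add, ss_oracle,
    ) = ss.spawn(7)
    rng_stand = np.random.default_rng(ss_stand)
    rng_counts = np.random.default_rng(ss_counts)
    rng_ingest = np.random.default_rng(ss_ingest)
    rng_germ = np.random.default_rng(ss_germ)
    rng_surv = np.random.default_rng(ss_surv)
    rng_add = np.random.default_rng(ss_add)
    rng_oracle = np.random.default_rng(ss_oracle)

    # --- stands and trap arrays -------------------------------------------
    tree_frames, trap_frames = [], []
    beta_s: dict[str, float] = {}
    for island in ISLANDS:
        for s in range(config.array_sites.get(island, 0)):
            site_id = f"{island[:2].upper()}{s + 1}"
            trees = generate_stand(config, site_id, island, rng_stand)
            focal = trees[trees.focal].iloc[0]
            traps = generate_trap_array(
                config, site_id, island, focal.x_m, focal.y_m, rng_stand
            )
            tree_frames.append(trees)
            trap_frames.append(traps)
            beta_s[site_id] = float(
                rng_stand.lognormal(config.mu_beta, config.sigma_beta)
            )
    trees = pd.concat(tree_frames, ignore_index=True)
    traps = pd.concat(trap_frames, ignore_index=True)

    # --- trap counts from the seed-shadow model ----------------------------
    fec = FecundityParams(config.mu_beta, config.sigma_beta, beta_s)
    disp = NBDispersion(config.k1, config.k2)
    tree_records = [
        TreeRecord(r.tree_id, r.site_id, r.island, r.x_m, r.y_m, r.dbh_cm)
        for r in trees.itertuples()
    ]
    counts = np.empty(len(traps), dtype=np.int64)
    for island in ISLANDS:
        sel = (traps.island == island).to_numpy()
        if not sel.any():
            continue
        trap_records = [
            TrapRecord(r.trap_id, r.site_id, r.island, r.x_m, r.y_m, r.area_m2)
            for r in traps[sel].itertuples()
        ]
        counts[sel] = simulate_trap_counts(
            trap_records, tree_records, config.kernel(island), fec, disp, rng_counts
        )
    traps["seed_count"] = counts
    traps["nearest_conspecific_distance"] = _nearest_distance(traps, trees)

    # --- ingestion classification ------------------------------------------
    total = traps.seed_count.to_numpy()
    p_ing = np.zeros(len(traps))
    for isl in BIRD_ISLANDS:
        sel = (traps.island == isl).to_numpy()
        eta = (
            config.ingestion_intercept
            + config.ingestion_island_offsets.get(isl, 0.0)
            + config.ingestion_distance_slope
            * traps.nearest_conspecific_distance.to_numpy()[sel]
        )
        p_ing[sel] = expit(eta)
    traps["total_classified"] = total
    traps["ingested_count"] = rng_ingest.binomial(total, p_ing)

    # --- nursery germination trials ----------------------------------------
    rows = []
    for treatment, n in config.germination_n.items():
        germ = rng_germ.binomial(1, config.germination_p[treatment], size=n)
        for g in germ:
            rows.append({"treatment": treatment, "germinated": int(g)})
    germination = pd.DataFrame(rows)

    # --- outplanted seedling survival ---------------------------------------
    rows = []
    for island in ISLANDS:
        birds = 0 if island == "Guam" else 1
        for s in range(config.outplant_sites.get(island, 0)):
            site_id = f"OP-{island[:2].upper()}{s + 1}"
            site_eff = rng_surv.normal(0.0, config.survival_site_sd)
            for p in range(config.plots_per_site):
                far = p >= config.plots_per_site // 2
                openness = rng_surv.normal(config.openness_mean, config.openness_sd)
                eta = (
                    config.survival_logit_near
                    + birds * config.survival_birds_effect
                    + far * config.survival_far_effect
                    + birds * far * config.survival_birds_far_interaction
                    + config.survival_openness_slope * (openness - config.openness_mean)
                    + config.survival_openness_far_interaction
                    * far
                    * (openness - config.openness_mean)
                    + site_eff
                )
                n_surv = rng_surv.binomial(config.seedlings_per_plot, expit(eta))
                rows.append(
                    {
                        "site_id": site_id,
                        "island": island,
                        "birds_present": birds,
                        "distance_class": "far" if far else "near",
                        "n_planted": config.seedlings_per_plot,
                        "n_survived": int(n_surv),
                        "canopy_openness": openness,
                    }
                )
    survival_plots = pd.DataFrame(rows)

    # --- seed-addition plots -------------------------------------------------
    rows = []
    for s in range(config.addition_sites):
        site_id = f"SA{s + 1}"
        for distance_class, p_g, p_s1 in (
            ("near", config.addition_germ_p_near, config.addition_early_surv_p_near),
            ("far", config.addition_germ_p_far, config.addition_early_surv_p_far),
        ):
            for _ in range(config.addition_plots_per_distance):
                openness = rng_add.normal(config.openness_mean, config.openness_sd)
                n_g = rng_add.binomial(config.addition_seeds_per_plot, p_g)
                n_s = rng_add.binomial(n_g, p_s1)
                rows.append(
                    {
                        "site_id": site_id,
                        "distance_class": distance_class,
                        "n_sown": config.addition_seeds_per_plot,
                        "n_germinated": int(n_g),
                        "n_surviving": int(n_s),
                        "canopy_openness": openness,
                    }
                )
    seed_addition = pd.DataFrame(rows)

    # --- ground truth --------------------------------------------------------
    present, absent = _true_scenarios(config)
    phi_p = seed_to_seedling(present)
    phi_a = seed_to_seedling(absent)
    phi_p_mc, se_p = forward_simulate_phi(present, oracle_seeds, rng_oracle)
    phi_a_mc, se_a = forward_simulate_phi(absent, oracle_seeds, rng_oracle)
    ground_truth = {
        "config": config.to_dict(),
        "beta_s": beta_s,
        "phi_present": phi_p,
        "phi_absent": phi_a,
        "ratio": phi_a / phi_p,
        "phi_present_mc": phi_p_mc,
        "phi_absent_mc": phi_a_mc,
        "ratio_mc": phi_a_mc / phi_p_mc,
        "oracle_seeds": oracle_seeds,
    }

    return World(
        config=config,
        trees=trees,
        traps=traps,
        germination=germination,
        survival_plots=survival_plots,
        seed_addition=seed_addition,
        ground_truth=ground_truth,
    )
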