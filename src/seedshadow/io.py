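"""Reading, validating and writing the pipeline's tabular interchange files.

All inputs are small site-keyed CSVs with explicit headers; fitted objects
are serialized as JSON.  Coordinates are planar metres (UTM-like) with no
CRS handling — the sites are tens of metres across.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .seed_shadow import ISLANDS, StandData

__all__ = [
    "SchemaError",
    "RunConfig",
    "read_trees",
    "read_traps",
    "read_tables",
    "nearest_conspecific_distance",
    "write_world",
    "read_world",
]

TREE_COLUMNS = ["tree_id", "site_id", "island", "x_m", "y_m", "dbh_cm"]
TRAP_COLUMNS = [
    "trap_id", "site_id", "island", "x_m", "y_m", "area_m2",
    "seed_count", "ingested_count", "total_classified",
]
GERMINATION_COLUMNS = ["treatment", "germinated"]
SURVIVAL_COLUMNS = [
    "site_id", "island", "birds_present", "distance_class",
    "n_planted", "n_survived", "canopy_openness",
]
ADDITION_COLUMNS = [
    "site_id", "distance_class", "n_sown", "n_germinated",
    "n_surviving", "canopy_openness",
]


class SchemaError(ValueError):
    """An input table does not match its declared schema."""


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing columns {missing}")


def _reject_rows(mask: pd.Series, name: str, reason: str) -> None:
    if mask.any():
        rows = [int(i) for i in mask[mask].index[:20]]
        raise SchemaError(f"{name}: {reason} in rows {rows}")


def read_trees(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, TREE_COLUMNS, "trees")
    _reject_rows(~df.island.isin(ISLANDS), "trees", "unknown island")
    _reject_rows(df.dbh_cm <= 0, "trees", "non-positive dbh")
    _reject_rows(
        ~np.isfinite(df.x_m) | ~np.isfinite(df.y_m), "trees", "non-finite coordinates"
    )
    return df[[c for c in df.columns if c in TREE_COLUMNS + ["focal"]]]


def read_traps(path, trees: pd.DataFrame | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, TRAP_COLUMNS, "traps")
    _reject_rows(~df.island.isin(ISLANDS), "traps", "unknown island")
    _reject_rows(df.area_m2 <= 0, "traps", "non-positive trap area")
    _reject_rows(df.seed_count < 0, "traps", "negative seed count")
    _reject_rows(
        df.seed_count != df.seed_count.astype(int), "traps", "non-integral seed count"
    )
    _reject_rows(
        (df.ingested_count < 0) | (df.ingested_count > df.total_classified),
        "traps",
        "ingested_count outside [0, total_classified]",
    )
    df = df.copy()
    if trees is not None:
        df["nearest_conspecific_distance"] = nearest_conspecific_distance(df, trees)
    return df


def nearest_conspecific_distance(
    traps: pd.DataFrame, trees: pd.DataFrame
) -> np.ndarray:
    """Distance from each trap to the nearest mapped conspecific at its
    site; exact ties are broken toward the lowest tree_id (the distance is
    the same either way, the tie-break fixes which tree is reported)."""
    out = np.empty(len(traps))
    trees_sorted = trees.sort_values("tree_id", kind="mergesort")
    by_site = dict(tuple(trees_sorted.groupby("site_id")))
    for i, row in enumerate(traps.itertuples()):
        tt = by_site.get(row.site_id)
        if tt is None or len(tt) == 0:
            raise SchemaError(f"traps: no mapped trees for site {row.site_id!r}")
        d = np.hypot(tt.x_m.to_numpy() - row.x_m, tt.y_m.to_numpy() - row.y_m)
        out[i] = d[np.argmin(d)]  # argmin takes the first (lowest tree_id) tie
    return out


def read_germination(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, GERMINATION_COLUMNS, "germination")
    _reject_rows(~df.germinated.isin([0, 1]), "germination", "germinated not 0/1")
    return df


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, SURVIVAL_COLUMNS, "survival")
    _reject_rows(
        (df.n_survived < 0) | (df.n_survived > df.n_planted),
        "survival",
        "n_survived outside [0, n_planted]",
    )
    return df


def read_addition(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ADDITION_COLUMNS, "seed_addition")
    _reject_rows(
        (df.n_germinated < 0) | (df.n_germinated > df.n_sown),
        "seed_addition",
        "n_germinated outside [0, n_sown]",
    )
    _reject_rows(
        (df.n_surviving < 0) | (df.n_surviving > df.n_germinated),
        "seed_addition",
        "n_surviving outside [0, n_germinated]",
    )
    return df


def read_tables(paths: dict) -> dict:
    """Load and validate every table named in ``paths`` (keys: trees,
    traps, germination, survival, seed_addition).  Returns a dict with a
    ``stand`` (StandData) plus the stage DataFrames."""
    trees = read_trees(paths["trees"])
    traps = read_traps(paths["traps"], trees=trees)
    out = {"trees": trees, "traps": traps, "stand": StandData(trees, traps)}
    if "germination" in paths:
        out["germination"] = read_germination(paths["germination"])
    if "survival" in paths:
        out["survival"] = read_survival(paths["survival"])
    if "seed_addition" in paths:
        out["seed_addition"] = read_addition(paths["seed_addition"])
    return out


def write_world(world, outdir) -> dict[str, Path]:
    """Write a synthetic world's tables (CSV) and ground truth (JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "trees": outdir / "trees.csv",
        "traps": outdir / "traps.csv",
        "germination": outdir / "germination.csv",
        "survival": outdir / "survival.csv",
        "seed_addition": outdir / "seed_addition.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    world.trees.to_csv(paths["trees"], index=False)
    world.traps.to_csv(paths["traps"], index=False)
    world.germination.to_csv(paths["germination"], index=False)
    world.survival_plots.to_csv(paths["survival"], index=False)
    world.seed_addition.to_csv(paths["seed_addition"], index=False)
    with open(paths["ground_truth"], "w") as fh:
        json.dump(world.ground_truth, fh, indent=2, default=float)
    return paths


def read_world(outdir) -> dict:
    outdir = Path(outdir)
    tables = read_tables(
        {
            "trees": outdir / "trees.csv",
            "traps": outdir / "traps.csv",
            "germination": outdir / "germination.csv",
            "survival": outdir / "survival.csv",
            "seed_addition": outdir / "seed_addition.csv",
        }
    )
    gt = outdir / "ground_truth.json"
    if gt.exists():
        with open(gt) as fh:
            tables["ground_truth"] = json.load(fh)
    return tables


_RUNCONFIG_KEYS = {
    "inputs", "kernel", "hypothesis", "mcmc", "stages", "scenario", "outdir", "seed",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (YAML or JSON on disk)."""

    inputs: dict = field(default_factory=dict)
    kernel: str = "both"              # pexp | 2dt | both
    hypothesis: str = "all"           # shared | guam | distinct | all
    mcmc: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)
    scenario: dict = field(default_factory=dict)
    outdir: str = "seedshadow_out"
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) if path.suffix in {".yml", ".yaml"} else json.load(fh)
        return cls.from_dict(raw or {})

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _RUNCONFIG_KEYS
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if cfg.kernel not in {"pexp", "2dt", "both"}:
            raise SchemaError(f"kernel must be pexp|2dt|both, got {cfg.kernel!r}")
        if cfg.hypothesis not in {"shared", "guam", "distinct", "all"}:
            raise SchemaError(
                f"hypothesis must be shared|guam|distinct|all, got {cfg.hypothesis!r}"
            )
        return cfg

    def families(self) -> list[str]:
        from .kernels import POWER_EXPONENTIAL, T2D

        return {
            "pexp": [POWER_EXPONENTIAL],
            "2dt": [T2D],
            "both": [POWER_EXPONENTIAL, T2D],
        }[self.kernel]

    def hypotheses(self) -> list[str]:
        return {
            "shared": ["shared"],
            "guam": ["guam_vs_rest"],
            "distinct": ["all_distinct"],
            "all": ["shared", "guam_vs_rest", "all_distinct"],
        }[self.hypothesis]
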