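"""End-to-end pipeline orchestration from a declarative config.

Stages run in order — simulate (optional), prep-climate, clean-occ, fit,
project, aggregate, report — with every intermediate artifact written under
the run directory, a run log, and a manifest recording the seed, package
versions and SHA-256 hashes of all table outputs. All randomness flows from
the single root seed through named substreams, so re-running with the same
config reproduces every CSV bit-identically.

Run layout::

    <output_dir>/
      inputs/        simulated or staged raw inputs
      env/current/   PC-score stack of the current climate
      transform.json fitted climate transform
      tables/        CSV artifacts of every stage
      figures/       beanplots (PNG + SVG) and their plotted-data CSV
      maps/          optional bootstrap-mean niche maps
      manifest.json, run.log
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import climniche
from climniche._rng import substream
from climniche.climate_space import (
    ClimateTransform,
    fit_climate_transform,
    to_env_space,
)
from climniche.grids import BioclimStack, GridSpec, PCStack, read_stack, write_stack
from climniche.niche import BootstrapEnsemble, bootstrap_niches
from climniche.occurrences import (
    CleanOccurrences,
    apply_min_records,
    clean_occurrences,
    read_occurrences,
)
from climniche.projection import mean_niche_map, scenario_area_table, scenario_label
from climniche.reporting import render_change_beans
from climniche.services import (
    ChangeDistribution,
    area_percentages,
    change_distributions,
    changes_to_frame,
    read_catalogue,
    summarize_changes,
)
from climniche.synthetic import (
    FutureDeltaSpec,
    TrueNiche,
    generate_current_climate,
    generate_future_ensemble,
    generate_service_catalogue,
    generate_virtual_species,
    write_truth,
)

__all__ = ["PipelineConfig", "run_pipeline", "ALL_STAGES"]

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "simulate",
    "prep-climate",
    "clean-occ",
    "fit",
    "project",
    "aggregate",
    "report",
)


@dataclass
class SimulateConfig:
    """Synthetic-input section: grid, futures, virtual species, catalogue."""

    n_rows: int = 60
    n_cols: int = 60
    cell_area: float = 1.0
    nodata_fraction: float = 0.05
    n_species: int = 12
    n_occurrences: int = 120
    periods: tuple[int, ...] = (2050, 2070)
    rcps: tuple[float, ...] = (2.6, 4.5, 6.0, 8.5)
    n_gcms: int = 10
    gcm_noise_sd: float = 0.4
    mean_offset: dict | None = None
    seasonality_inflation: dict | None = None

    def delta_spec(self) -> FutureDeltaSpec:
        def keyed(d):
            # YAML configs use "period,rcp" string keys; Python may pass tuples
            if d is None:
                return None
            out = {}
            for key, v in d.items():
                p, r = key.split(",") if isinstance(key, str) else key
                out[(int(p), float(r))] = float(v)
            return out

        return FutureDeltaSpec(
            periods=tuple(self.periods),
            rcps=tuple(self.rcps),
            n_gcms=self.n_gcms,
            gcm_noise_sd=self.gcm_noise_sd,
            mean_offset=keyed(self.mean_offset),
            seasonality_inflation=keyed(self.seasonality_inflation),
        )


@dataclass
class PipelineConfig:
    """Everything a run needs: paths, parameters, flags and the root seed."""

    output_dir: str | Path = "climniche_run"
    seed: int = 0
    k: int = 3
    log_vars: tuple[str, ...] | None = None  # None -> precipitation bioclims
    min_n: int = 20
    B: int = 1000
    p_levels: tuple[float, ...] = (0.9, 0.5, 0.1)
    max_elev_diff: float = 500.0
    drop_on_elevation_flag: bool = False
    export_maps: bool = False
    study_area: float | None = None  # km²; None -> valid cells x cell_area
    bounds: tuple[float, float, float, float] | None = None
    simulate: SimulateConfig | None = None
    # real-data inputs (used when simulate is None)
    current_dir: str | Path | None = None
    futures_dir: str | Path | None = None
    occurrences: str | Path | None = None
    catalogue: str | Path | None = None
    mask: str | Path | None = None

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be at least 1")
        if not 1 <= self.k <= 19:
            raise ValueError("k must lie in 1..19")
        for p in (self.current_dir, self.futures_dir, self.occurrences,
                  self.catalogue, self.mask):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = SimulateConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        d = {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in self.__dict__.items()
            if k != "simulate"
        }
        if self.simulate is not None:
            sim = dict(self.simulate.__dict__)
            for key in ("mean_offset", "seasonality_inflation"):
                if sim.get(key):
                    sim[key] = {
                        (k if isinstance(k, str) else f"{k[0]},{k[1]}"): v
                        for k, v in sim[key].items()
                    }
            d["simulate"] = sim
        return d

    @property
    def out(self) -> Path:
        return Path(self.output_dir)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _setup_logging(out: Path) -> logging.Handler:
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="a")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    root = logging.getLogger("climniche")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    return handler


class _RunState:
    """Lazy artifact loader shared by the stages.

    Every stage consumes the artifacts its predecessors wrote to disk (not
    in-memory objects), so a full ``run-all`` and a stage-at-a-time run
    follow the identical numeric path — including the float32 raster
    round-trip — and produce bit-identical tables.
    """

    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.current: BioclimStack | None = None
        self.futures: dict[tuple[int, float, str], BioclimStack] | None = None
        self.transform: ClimateTransform | None = None
        self.env_current: PCStack | None = None
        self.clean: CleanOccurrences | None = None
        self.ensembles: dict[str, BootstrapEnsemble] | None = None
        self.areas: pd.DataFrame | None = None
        self.dists: dict[int, list[ChangeDistribution]] | None = None

    # ---- input loading -------------------------------------------------
    def _futures_root(self) -> Path:
        cfg = self.cfg
        if cfg.simulate is not None:
            return cfg.out / "inputs" / "futures"
        return Path(cfg.futures_dir)

    def get_current(self) -> BioclimStack:
        if self.current is None:
            root = (
                self.cfg.out / "inputs" / "current"
                if self.cfg.simulate is not None
                else Path(self.cfg.current_dir)
            )
            self.current = read_stack(root, kind=BioclimStack)
        return self.current

    def get_futures(self) -> dict[tuple[int, float, str], BioclimStack]:
        if self.futures is None:
            root = self._futures_root()
            futures: dict[tuple[int, float, str], BioclimStack] = {}
            for scen_dir in sorted(root.iterdir()):
                if not scen_dir.is_dir():
                    continue
                period_s, rcp_s = scen_dir.name.split("_rcp")
                for gcm_dir in sorted(scen_dir.iterdir()):
                    if not gcm_dir.is_dir():
                        continue
                    futures[(int(period_s), float(rcp_s), gcm_dir.name)] = read_stack(
                        gcm_dir, kind=BioclimStack
                    )
            if not futures:
                raise FileNotFoundError(f"no future stacks under {root}")
            self.futures = futures
        return self.futures

    def get_transform(self) -> ClimateTransform:
        if self.transform is None:
            self.transform = ClimateTransform.from_json(self.cfg.out / "transform.json")
        return self.transform

    def get_env_current(self) -> PCStack:
        if self.env_current is None:
            env = read_stack(self.cfg.out / "env" / "current", kind=PCStack)
            env.transform = self.get_transform()
            self.env_current = env
        return self.env_current

    def get_clean(self) -> CleanOccurrences:
        if self.clean is None:
            table = pd.read_csv(self.cfg.out / "tables" / "clean_occurrences.csv")
            per_species = {
                str(sp): grp.drop(columns="species").reset_index(drop=True)
                for sp, grp in table.groupby("species", sort=False)
            }
            report = pd.read_csv(self.cfg.out / "tables" / "cleaning_report.csv")
            self.clean = CleanOccurrences(per_species=per_species, report=report)
        return self.clean

    def get_ensembles(self) -> dict[str, BootstrapEnsemble]:
        if self.ensembles is None:
            table = pd.read_csv(self.cfg.out / "tables" / "ensembles.csv")
            self.ensembles = {
                str(sp): BootstrapEnsemble.from_frame(grp)
                for sp, grp in table.groupby("species", sort=False)
            }
        return self.ensembles

    def get_areas(self) -> pd.DataFrame:
        if self.areas is None:
            self.areas = pd.read_csv(self.cfg.out / "tables" / "areas.csv")
        return self.areas

    def get_catalogue_path(self) -> Path:
        if self.cfg.simulate is not None:
            return self.cfg.out / "inputs" / "catalogue.csv"
        return Path(self.cfg.catalogue)

    def get_occurrences_path(self) -> Path:
        if self.cfg.simulate is not None:
            return self.cfg.out / "inputs" / "occurrences.csv"
        return Path(self.cfg.occurrences)

    def study_area_km2(self) -> float:
        if self.cfg.study_area is not None:
            return float(self.cfg.study_area)
        env = self.get_env_current()
        return env.n_valid * env.grid.cell_area


# ---- stages -----------------------------------------------------------


def _stage_simulate(state: _RunState) -> None:
    cfg = state.cfg
    sim = cfg.simulate
    if sim is None:
        logger.info("no simulate section: using configured real inputs")
        return
    inputs = cfg.out / "inputs"
    spec = GridSpec(
        n_rows=sim.n_rows,
        n_cols=sim.n_cols,
        cell_area=sim.cell_area,
        nodata_fraction=sim.nodata_fraction,
    )
    current = generate_current_climate(spec, seed=cfg.seed)
    write_stack(current, inputs / "current")
    deltas = sim.delta_spec()
    futures = generate_future_ensemble(current, deltas, seed=cfg.seed)
    for (period, rcp, gcm), stack in futures.items():
        write_stack(stack, inputs / "futures" / scenario_label(period, rcp) / gcm)

    # virtual species live in the PC space of the simulated current climate
    transform = fit_climate_transform(current, k=cfg.k)
    env = to_env_space(current, transform)
    rng = substream(cfg.seed, "species-truth")
    scores = env.scores()
    center = scores.mean(axis=0)
    sd = scores.std(axis=0, ddof=1)
    niches = []
    for i in range(sim.n_species):
        mu = center + rng.normal(scale=0.8, size=cfg.k) * sd
        a = rng.normal(scale=0.35, size=(cfg.k, cfg.k))
        sigma = np.diag((0.5 * sd) ** 2) + a @ a.T
        niches.append(
            TrueNiche(
                species_id=f"species_{i + 1:02d}",
                mu_true=tuple(mu),
                sigma_true=tuple(map(tuple, sigma)),
                n_occurrences=sim.n_occurrences,
            )
        )
    occ = generate_virtual_species(env, niches, seed=cfg.seed)
    occ.to_csv(inputs / "occurrences.csv", index=False)
    write_truth(niches, inputs / "truth.csv")
    catalogue = generate_service_catalogue(
        [n.species_id for n in niches], seed=cfg.seed
    )
    catalogue.to_csv(inputs / "catalogue.csv", index=False)
    logger.info(
        "simulated %d species x %d occurrences on a %dx%d grid, %d future stacks",
        sim.n_species, sim.n_occurrences, sim.n_rows, sim.n_cols, len(futures),
    )


def _stage_prep_climate(state: _RunState) -> None:
    cfg = state.cfg
    current = state.get_current()
    mask = None
    if cfg.mask is not None:
        mask = read_stack(Path(cfg.mask)).mask
    log_vars = cfg.log_vars
    transform = fit_climate_transform(
        current,
        mask=mask,
        k=cfg.k,
        **({} if log_vars is None else {"log_vars": tuple(log_vars)}),
    )
    transform.to_json(cfg.out / "transform.json")
    env = to_env_space(current, transform)
    write_stack(env, cfg.out / "env" / "current")
    logger.info(
        "retained k=%d components, cumulative variance fraction %.3f",
        cfg.k, transform.cumulative_fraction,
    )


def _stage_clean(state: _RunState) -> None:
    cfg = state.cfg
    env = state.get_env_current()
    occ = read_occurrences(state.get_occurrences_path())
    clean = clean_occurrences(
        occ,
        env,
        bounds=cfg.bounds,
        max_elev_diff=cfg.max_elev_diff,
        drop_on_elevation_flag=cfg.drop_on_elevation_flag,
    )
    clean = apply_min_records(clean, min_n=cfg.min_n)
    tables = cfg.out / "tables"
    tables.mkdir(parents=True, exist_ok=True)
    clean.to_frame().to_csv(tables / "clean_occurrences.csv", index=False)
    clean.report.to_csv(tables / "cleaning_report.csv", index=False)
    clean.excluded.to_csv(tables / "excluded_species.csv", index=False)
    logger.info(
        "cleaned occurrences: %d species retained, %d excluded below min_n=%d",
        len(clean.per_species), len(clean.excluded), cfg.min_n,
    )


def _stage_fit(state: _RunState) -> None:
    cfg = state.cfg
    clean = state.get_clean()
    ensembles = {}
    for sp in clean.species:
        pts = clean.points(sp)
        ensembles[sp] = bootstrap_niches(
            pts, B=cfg.B, seed=cfg.seed, species_id=sp
        )
        logger.info("fitted %d bootstrap niches for %s (n=%d)", cfg.B, sp, len(pts))
    frames = [e.to_frame() for e in ensembles.values()]
    pd.concat(frames, ignore_index=True).to_csv(
        cfg.out / "tables" / "ensembles.csv", index=False
    )


def _stage_project(state: _RunState) -> None:
    cfg = state.cfg
    transform = state.get_transform()
    # derive the current-climate PC stack through the same code path as the
    # futures, so a future bit-identical to current yields identical areas
    env = to_env_space(state.get_current(), transform)
    futures_env = {
        key: to_env_space(stack, transform)
        for key, stack in state.get_futures().items()
    }
    ensembles = state.get_ensembles()
    area_frames, log_frames = [], []
    for sp, ens in ensembles.items():
        areas, log = scenario_area_table(ens, env, futures_env, seed=cfg.seed)
        area_frames.append(areas)
        log_frames.append(log)
        logger.info("projected %s across %d scenario rows", sp, len(areas))
    areas = pd.concat(area_frames, ignore_index=True)
    areas = area_percentages(areas, state.study_area_km2())
    areas.to_csv(cfg.out / "tables" / "areas.csv", index=False)
    pd.concat(log_frames, ignore_index=True).to_csv(
        cfg.out / "tables" / "gcm_draws.csv", index=False
    )
    if cfg.export_maps:
        maps_dir = cfg.out / "maps"
        for sp, ens in ensembles.items():
            m = mean_niche_map(ens, env)
            stack = PCStack(
                names=("probability",),
                data=m.probs[None],
                mask=m.mask,
                grid=env.grid,
            )
            write_stack(stack, maps_dir / sp / "current")


def _stage_aggregate(state: _RunState) -> None:
    cfg = state.cfg
    areas = state.get_areas()
    catalogue = read_catalogue(state.get_catalogue_path())
    dists = {
        level: change_distributions(areas, catalogue, level=level)
        for level in (1, 2)
    }
    tables = cfg.out / "tables"
    for level, dlist in dists.items():
        changes_to_frame(dlist).to_csv(
            tables / f"changes_level{level}.csv", index=False
        )
    summary = pd.concat(
        [summarize_changes(dists[1]), summarize_changes(dists[2])],
        ignore_index=True,
    )
    summary.to_csv(tables / "change_summary.csv", index=False)
    logger.info(
        "pooled change distributions: %d level-1, %d level-2 beans",
        len(dists[1]), len(dists[2]),
    )


def _load_dists(path: Path, level: int) -> list[ChangeDistribution]:
    table = pd.read_csv(path)
    out = []
    for (name, scen), grp in table.groupby(["es_name", "scenario"], sort=True):
        out.append(
            ChangeDistribution(
                es_level=level,
                es_name=str(name),
                scenario=str(scen),
                values=grp["delta_pp"].to_numpy(),
                n_species=grp["species"].nunique()
                if level == 2
                else len(grp) // max(grp["bootstrap_id"].nunique(), 1),
                per_species=grp[["species", "bootstrap_id", "delta_pp"]],
            )
        )
    return out


def _stage_report(state: _RunState) -> None:
    cfg = state.cfg
    figures = cfg.out / "figures"
    for level in (1, 2):
        dlist = _load_dists(
            cfg.out / "tables" / f"changes_level{level}.csv", level
        )
        render_change_beans(dlist, figures, basename=f"beans_level{level}")
    logger.info("rendered beanplot figures to %s", figures)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "prep-climate": _stage_prep_climate,
    "clean-occ": _stage_clean,
    "fit": _stage_fit,
    "project": _stage_project,
    "aggregate": _stage_aggregate,
    "report": _stage_report,
}


def run_pipeline(
    config: PipelineConfig, stages: tuple[str, ...] | None = None
) -> dict:
    """Execute pipeline stages in order and write the run manifest.

    Returns the manifest dict. Any stage failure marks the manifest
    incomplete (with the failing stage and message) and re-raises.
    """
    cfg = config
    stages = tuple(stages) if stages is not None else ALL_STAGES
    unknown = [s for s in stages if s not in _STAGE_FUNCS]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}")
    handler = _setup_logging(cfg.out)
    (cfg.out / "tables").mkdir(parents=True, exist_ok=True)
    state = _RunState(cfg)
    manifest: dict = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "versions": {
            "climniche": climniche.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
        "stages_completed": [],
        "status": "incomplete",
    }
    try:
        for stage in ALL_STAGES:
            if stage not in stages:
                continue
            logger.info("=== stage: %s ===", stage)
            _STAGE_FUNCS[stage](state)
            manifest["stages_completed"].append(stage)
        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = "incomplete"
        manifest["error"] = {"stage": stage, "message": str(exc)}
        raise
    finally:
        manifest["artifacts"] = {
            str(p.relative_to(cfg.out)): _sha256(p)
            for pattern in ("tables/*.csv", "figures/*_data.csv", "*.json")
            for p in sorted(cfg.out.glob(pattern))
            if p.name != "manifest.json"
        }
        (cfg.out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        logging.getLogger("climniche").removeHandler(handler)
        handler.close()
    return manifest
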