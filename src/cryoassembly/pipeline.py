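"""Pipeline orchestration: simulate/load -> rarefy -> diversity -> decay ->
assembly -> drivers, with a manifest recording parameters, seeds, and outputs.

A single master seed deterministically spawns one sub-seed per stage (by
stage name, in fixed order), so any stage can be rerun in isolation and the
whole run is reproducible byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skbio import DistanceMatrix

from cryoassembly import assembly as asm
from cryoassembly import biogeography as geo
from cryoassembly import diversity as div
from cryoassembly import drivers as drv
from cryoassembly import io as tio
from cryoassembly import phylo
from cryoassembly.synthetic import ScenarioConfig, simulate_metacommunity

log = logging.getLogger("cryoassembly")

STAGES = ("simulate", "rarefy", "diversity", "decay", "assembly", "drivers")


@dataclass
class RunConfig:
    """Configuration of a pipeline run.

    Either ``scenario`` (synthetic mode) or the three input paths must be
    provided. ``stages`` defaults to every applicable stage.
    """

    output_dir: str = "out"
    seed: int = 0
    scenario: ScenarioConfig | None = None
    table_path: str | None = None
    tree_path: str | None = None
    metadata_path: str | None = None
    rarefaction_depth: int | None = None
    n_null: int = 999
    n_perm: int = 999
    unit_km: float = 60.0
    min_pairs: int = 5
    weighted: bool = True
    rf_trees: int = 500
    stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_null", "n_perm", "min_pairs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.unit_km <= 0:
            raise ValueError("unit_km must be positive")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.scenario is None and "simulate" in self.stages:
            self.stages = tuple(s for s in self.stages if s != "simulate")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "scenario" in raw and raw["scenario"] is not None:
            raw["scenario"] = ScenarioConfig(**raw["scenario"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _stage_seeds(master: int) -> dict[str, int]:
    rng = np.random.default_rng(master)
    return {s: int(rng.integers(2**31)) for s in STAGES}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_dm(dm: DistanceMatrix, path: Path) -> None:
    pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(path, sep="\t")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    out_root = Path(config.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "parameters": {
            k: v for k, v in asdict(config).items() if k not in ("scenario",)
        },
        "scenario": asdict(config.scenario) if config.scenario else None,
        "stages": [],
        "inputs": {},
        "outputs": {},
    }

    table = tree = metadata = None
    patristic = None
    geo_dm = None
    pairs = None
    alpha = None
    bc = None

    def record(stage: str, outputs: dict[str, Path], t0: float) -> None:
        manifest["stages"].append(stage)
        manifest["outputs"][stage] = {k: str(v) for k, v in outputs.items()}
        log.info("stage %-9s done in %.2fs  seed=%d", stage, time.perf_counter() - t0, seeds[stage])

    # --- load external inputs if not simulating -----------------------------
    if "simulate" not in config.stages:
        for name, path in (("table", config.table_path), ("tree", config.tree_path), ("metadata", config.metadata_path)):
            if path is None:
                continue
            p = Path(path)
            if not p.exists():
                raise FileNotFoundError(f"{name} input not found: {p}")
            manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(p)}
        if config.table_path:
            table = tio.read_feature_table(config.table_path)
        if config.tree_path:
            tree = phylo.read_tree(config.tree_path)
        if config.metadata_path:
            metadata = tio.read_metadata(config.metadata_path)

    for stage in [s for s in STAGES if s in config.stages]:
        t0 = time.perf_counter()
        out = out_root / stage
        out.mkdir(parents=True, exist_ok=True)

        if stage == "simulate":
            scenario = ScenarioConfig(**{**asdict(config.scenario), "seed": seeds["simulate"]})
            ds = simulate_metacommunity(scenario)
            ds.write(out)
            table, tree, metadata = ds.table, ds.tree, ds.metadata
            record(stage, {"table": out / "table.tsv", "tree": out / "tree.nwk", "metadata": out / "metadata.csv"}, t0)

        elif stage == "rarefy":
            if table is None:
                raise FileNotFoundError("rarefy stage requires a feature table (table_path or simulate stage)")
            res = tio.rarefy(table, depth=config.rarefaction_depth, seed=seeds["rarefy"])
            table = res.table
            if metadata is not None:
                metadata = metadata.loc[table.sample_ids]
            tio.write_feature_table(table, out / "rarefied.tsv")
            (out / "report.json").write_text(
                json.dumps({"depth": res.depth, "dropped_samples": res.dropped_samples}, indent=2)
            )
            record(stage, {"rarefied": out / "rarefied.tsv", "report": out / "report.json"}, t0)

        elif stage == "diversity":
            if table is None:
                raise FileNotFoundError("diversity stage requires a feature table")
            alpha = div.alpha_diversity(table, warn_unequal=False)
            alpha.to_csv(out / "alpha.csv")
            bc = div.bray_curtis(table)
            _write_dm(bc, out / "bray_curtis.tsv")
            soren = div.sorensen(table)
            _write_dm(soren, out / "sorensen.tsv")
            ord_res = div.pcoa(soren, k=min(4, len(table.sample_ids) - 1))
            ord_res.coordinates.to_csv(out / "pcoa.csv")
            summary = {
                "pcoa_proportion_explained": ord_res.proportion_explained.tolist(),
                "pcoa_negative_eigenvalue_magnitude": ord_res.negative_eigenvalue_magnitude,
            }
            if metadata is not None and metadata["continent"].nunique() >= 2:
                for metric in ("richness", "shannon"):
                    kw = div.kruskal_wallis_dunn(alpha[metric].to_numpy(), metadata["continent"].to_numpy())
                    kw.dunn.to_csv(out / f"dunn_{metric}.csv", index=False)
                    summary[metric] = {"h": kw.h_statistic, "p": kw.p_value, "letters": kw.letters}
            (out / "summary.json").write_text(json.dumps(summary, indent=2))
            record(stage, {"alpha": out / "alpha.csv", "bray_curtis": out / "bray_curtis.tsv", "summary": out / "summary.json"}, t0)

        elif stage == "decay":
            if metadata is None or bc is None:
                raise FileNotFoundError("decay stage requires metadata and the diversity stage")
            geo_dm = geo.geographic_distance_matrix(metadata)
            _write_dm(geo_dm, out / "geographic_km.tsv")
            fits = geo.distance_decay(bc, geo_dm, metadata["continent"], n_permutations=config.n_perm, seed=seeds["decay"])
            fits.to_csv(out / "decay.csv", index=False)
            record(stage, {"geographic": out / "geographic_km.tsv", "decay": out / "decay.csv"}, t0)

        elif stage == "assembly":
            if table is None or tree is None:
                missing = "tree" if table is not None else "feature table"
                raise FileNotFoundError(f"assembly stage requires a {missing} ({config.tree_path or 'simulate stage'})")
            if patristic is None:
                patristic = phylo.patristic_distance_matrix(tree, table.taxon_ids)
            if geo_dm is None and metadata is not None:
                geo_dm = geo.geographic_distance_matrix(metadata)
            pairs = asm.assemble_pairs(
                table, patristic, geo_dm=geo_dm, n_null=config.n_null, seed=seeds["assembly"], weighted=config.weighted
            )
            pairs.to_csv(out / "pairs.csv", index=False)
            grouping = None
            if metadata is not None:
                cont = metadata["continent"]
                same = pairs["sample_a"].map(cont) == pairs["sample_b"].map(cont)
                grouping = pairs["sample_a"].map(cont).where(same, "between")
            fracs = asm.process_fractions(pairs, grouping)
            fracs.to_csv(out / "fractions.csv")
            try:
                trend = asm.scale_trend(pairs, unit_km=config.unit_km, min_pairs=config.min_pairs)
                trend.units.to_csv(out / "scale_units.csv", index=False)
                trend.fits.to_csv(out / "scale_fits.csv", index=False)
            except ValueError as exc:
                log.warning("scale trend skipped: %s", exc)
            if metadata is not None:
                pnst = asm.pnst(table, patristic, metadata["continent"], n_null=config.n_null, seed=seeds["assembly"], weighted=config.weighted)
                pnst.to_csv(out / "pnst.csv")
            record(stage, {"pairs": out / "pairs.csv", "fractions": out / "fractions.csv"}, t0)

        elif stage == "drivers":
            if metadata is None or bc is None or alpha is None:
                raise FileNotFoundError("drivers stage requires metadata and the diversity stage")
            glacier = metadata["glacier_id"]
            g_dm = drv.aggregate_by_glacier(bc, glacier)
            g_meta = metadata.groupby(glacier).first().loc[list(g_dm.ids)]
            g_alpha = alpha.join(glacier).groupby("glacier_id").mean().loc[list(g_dm.ids)]
            rng = np.random.default_rng(seeds["drivers"])
            sub_seeds = {k: int(rng.integers(2**31)) for k in ("mantel", "permanova", "anosim", "dbrda", "rf")}

            mantel_res = drv.mantel_factors(g_dm, g_meta, n_permutations=config.n_perm, seed=sub_seeds["mantel"])
            mantel_res.to_csv(out / "mantel.csv", index=False)
            summary = {}
            if metadata["continent"].nunique() >= 2:
                summary["permanova"] = drv.permanova(bc, metadata["continent"], config.n_perm, sub_seeds["permanova"])
                summary["anosim"] = drv.anosim(bc, metadata["continent"], config.n_perm, sub_seeds["anosim"])
            predictors = g_meta[list(tio.COVARIATE_COLUMNS)]
            rda = drv.dbrda(g_dm, predictors, n_permutations=config.n_perm, seed=sub_seeds["dbrda"])
            rda.site_scores.to_csv(out / "dbrda_axes.csv")
            summary["dbrda"] = {
                "constrained_proportion": rda.constrained_proportion,
                "axis_proportions": rda.axis_proportions.tolist(),
                "adjusted_r_squared": rda.adjusted_r_squared,
                "p_value": rda.p_value,
            }
            rf = drv.rf_importance(
                rda.site_scores.iloc[:, 0], predictors, n_trees=config.rf_trees,
                n_permutations=min(config.n_perm, 100), seed=sub_seeds["rf"],
            )
            rf.importance.to_csv(out / "importance.csv", index=False)
            summary["rf_model_r_squared"] = rf.model_r_squared
            fits = drv.diversity_factor_fits(g_alpha, g_meta)
            summary["richness_latitude_fit"] = fits.latitude
            summary["richness_hdi_fit"] = fits.hdi
            (out / "summary.json").write_text(json.dumps(summary, indent=2))
            record(stage, {"mantel": out / "mantel.csv", "importance": out / "importance.csv", "summary": out / "summary.json"}, t0)

    (out_root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
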