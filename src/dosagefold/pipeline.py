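"""End-to-end orchestration: simulate -> filter -> diffabund -> celldensity
-> drymass -> dosage, with a machine-readable run manifest.

Each stage reads/writes the plain-text artifacts of :mod:`dosagefold.io`;
the manifest records the config hash, the seeds handed to every stage, all
artifact paths, and the headline summary scalars (per-step feature counts,
per-strain posterior means, per-strain median FCdm/FCcell), so a run is
reproducible and auditable from the manifest alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import diffabund, dosage, filtering, io, simulate
from .containers import FeatureTable

logger = logging.getLogger("dosagefold")

DEFAULT_PLATFORMS = {"ESI-": None, "ESI+": None, "GCMS": 120}


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stage_seeds: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)
    summaries: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True, default=str)

    @classmethod
    def from_json(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage substream seed below 2**31 from the global seed."""
    ss = np.random.SeedSequence([seed, abs(hash_stage(stage))])
    return int(ss.generate_state(1)[0] % (2**31))


def hash_stage(stage: str) -> int:
    import zlib

    return zlib.crc32(stage.encode()) & 0x7FFFFFFF


def run_pipeline(
    config: simulate.SimulationConfig | str | Path,
    outdir: str | Path,
    platforms: dict | None = None,
    mcmc_iterations: int = 2000,
    mcmc_warmup: int = 1000,
    n_rcd_draws: int = 500,
) -> RunManifest:
    """Run every stage on synthetic inputs and emit all declared artifacts.

    ``platforms`` maps platform label to a feature count (``None`` keeps the
    config's ``n_features``).  Identical config + seed give identical
    manifest scalars.
    """
    if not isinstance(config, simulate.SimulationConfig):
        config = io.read_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = io.config_hash(config)
    manifest = RunManifest(config_hash=chash, seed=config.seed)
    platforms = platforms or dict(DEFAULT_PLATFORMS)

    io.write_config(config, outdir / "config.yaml")
    manifest.paths["config"] = str(outdir / "config.yaml")

    # --- simulate -----------------------------------------------------------
    logger.info("stage simulate")
    tables = {}
    for platform, n_feat in platforms.items():
        cfg = config if n_feat is None else _with_features(config, n_feat)
        table = simulate.simulate_feature_table(cfg, platform)
        tables[platform] = table
        tag = platform.replace("+", "pos").replace("-", "neg")
        path = outdir / f"features_{tag}.tsv"
        io.write_feature_table(table, path, seed=config.seed, chash=chash)
        manifest.paths[f"features_{platform}"] = str(path)
    flow = simulate.simulate_flow_observations(config)
    io.write_flow_observations(flow, outdir / "flow.csv", config.seed, chash)
    manifest.paths["flow"] = str(outdir / "flow.csv")
    mass = simulate.simulate_all_mass_observations(config)
    io.write_mass_observations(mass, outdir / "mass.csv", config.seed, chash)
    manifest.paths["mass"] = str(outdir / "mass.csv")

    # --- filter -------------------------------------------------------------
    logger.info("stage filter")
    filtered, reports = {}, {}
    for platform, table in tables.items():
        ftab, report = filtering.filter_pipeline(table)
        filtered[platform] = ftab
        reports[platform] = report
        tag = platform.replace("+", "pos").replace("-", "neg")
        io.write_feature_table(
            ftab, outdir / f"filtered_{tag}.tsv", config.seed, chash
        )
        with open(outdir / f"filter_report_{tag}.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
        manifest.paths[f"filtered_{platform}"] = str(outdir / f"filtered_{tag}.tsv")
    manifest.summaries["filter_counts"] = {
        platform: [list(c) for c in report.counts]
        for platform, report in reports.items()
    }

    # --- differential abundance --------------------------------------------
    logger.info("stage diffabund")
    daf_summary = {}
    for platform, ftab in filtered.items():
        contrasts = diffabund.contrast_tests(ftab)
        anova = diffabund.two_way_anova_classify(ftab)
        upset = diffabund.daf_intersections(contrasts.daf_sets())
        daf_summary[platform] = {
            "daf_counts": {
                name: int(tab["is_daf"].sum())
                for name, tab in contrasts.tables.items()
            },
            "venn": anova.venn_partition(),
            "shared_all_strains": upset.regions[
                frozenset(ftab.strains())
            ],
        }
    manifest.summaries["diffabund"] = daf_summary

    # --- cell density (Model 1) ---------------------------------------------
    logger.info("stage celldensity")
    cd_seed = stage_seed(config.seed, "celldensity")
    manifest.stage_seeds["celldensity"] = cd_seed
    cell_model = dosage.CellDensityModel(flow)
    cell_res = cell_model.fit(
        iterations=mcmc_iterations, warmup=mcmc_warmup, seed=cd_seed
    )
    io.write_draws(cell_res.posterior, outdir / "celldensity_draws.json")
    cell_res.summary().to_csv(outdir / "celldensity_summary.csv")
    manifest.paths["celldensity_draws"] = str(outdir / "celldensity_draws.json")
    manifest.summaries["rcd_posterior_mean"] = {
        s: cell_res.rcd_mean(s) for s in cell_res.strains
    }

    # --- dry mass (Model 2) ---------------------------------------------------
    logger.info("stage drymass")
    dm_seed = stage_seed(config.seed, "drymass")
    manifest.stage_seeds["drymass"] = dm_seed
    mass_model = dosage.DryMassModel(mass)
    mass_res = mass_model.fit(
        iterations=mcmc_iterations, warmup=mcmc_warmup, seed=dm_seed
    )
    mass_res.summary().to_csv(outdir / "drymass_summary.csv")
    manifest.summaries["f_dry_posterior_mean"] = {
        f"{s}:{p}": mass_res.f_dry_mean(s, p) for (s, p) in sorted(mass_res.posterior)
    }

    # --- dosage conversion ----------------------------------------------------
    logger.info("stage dosage")
    comb_seed = stage_seed(config.seed, "combine")
    manifest.stage_seeds["combine"] = comb_seed
    rcd_dm = dosage.combine_rcd_dm(cell_res, mass_res, n_draws=n_rcd_draws, seed=comb_seed)
    manifest.summaries["mean_rcd_dm"] = {
        s: float(np.mean(d)) for s, d in rcd_dm.items()
    }

    # per-cell fold changes on the raw (unfiltered) primary platform
    primary = next(iter(tables))
    raw = tables[primary]
    lfc_by_strain = {}
    for strain in raw.strains():
        pair = dosage.pair_presence_filter(raw, strain)
        sel = (pair.sample_meta["strain"] == strain).to_numpy()
        logged = FeatureTable(
            np.log2(pair.data.loc[sel]), pair.sample_meta.loc[sel], pair.platform,
            pair.attrs, scale="log2",
        )
        lfc_by_strain[strain] = diffabund.log2_fold_changes(logged, strain)
    fc = dosage.fc_per_cell(lfc_by_strain, rcd_dm)
    fc.table.to_csv(outdir / "fold_changes.tsv", sep="\t", index=False)
    fc.summary.to_csv(outdir / "fold_change_summary.csv")
    manifest.paths["fold_changes"] = str(outdir / "fold_changes.tsv")
    manifest.summaries["median_FCdm"] = fc.summary["median_FCdm"].to_dict()
    manifest.summaries["median_FCcell"] = fc.summary["median_FCcell"].to_dict()

    manifest.to_json(outdir / "manifest.json")
    manifest.paths["manifest"] = str(outdir / "manifest.json")
    return manifest


def _with_features(config: simulate.SimulationConfig, n_features: int):
    d = config.to_dict()
    d["n_features"] = n_features
    return simulate.SimulationConfig.from_dict(d)
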