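"""End-to-end pipeline: simulate (or load), analyze, and report.

A single YAML config plus a master seed drives the whole run; every stage
writes tidy CSV, and a manifest records the config snapshot, the seed, the
sign/intercept/weighting conventions applied, and a checksum for every
output so a run is verifiable and exactly repeatable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .covariance import boxs_m_test, group_covariances_from_tidy
from .pedigree import Line, read_pedigree
from .selection import (
    Direction,
    heritability_table,
    line_means_table,
    percent_change,
    response_series_from_tables,
)
from .simulate import SimConfig, SimResult, final_generation_traits, simulate_experiment

log = logging.getLogger(__name__)

_SIM_KEYS = {f.name for f in dataclasses.fields(SimConfig)}
_TOP_KEYS = {"simulate", "inputs", "analysis"}
_ANALYSIS_KEYS = {"trait", "through_origin", "negate_bottom", "final_traits"}
_INPUT_KEYS = {"pedigree", "phenotypes", "contributions"}


class ConfigError(ValueError):
    pass


@dataclass
class RunManifest:
    """Record of one pipeline run: config, seed, conventions, outputs."""

    config: dict
    seed: int
    version: str
    conventions: dict
    outputs: dict[str, dict] = field(default_factory=dict)  # name -> {path, sha256}
    stages: list[str] = field(default_factory=list)

    def add_output(self, name: str, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.outputs[name] = {"path": str(path), "sha256": digest}

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "simulate" in cfg and "inputs" in cfg:
        raise ConfigError("config must give either 'simulate' or 'inputs', not both")
    if "simulate" not in cfg and "inputs" not in cfg:
        raise ConfigError("config must give 'simulate' parameters or 'inputs' paths")
    if "simulate" in cfg:
        bad = set(cfg["simulate"]) - _SIM_KEYS
        if bad:
            raise ConfigError(f"unknown simulate keys: {sorted(bad)}")
    if "inputs" in cfg:
        bad = set(cfg["inputs"]) - _INPUT_KEYS
        if bad:
            raise ConfigError(f"unknown inputs keys: {sorted(bad)}")
    bad = set(cfg.get("analysis", {})) - _ANALYSIS_KEYS
    if bad:
        raise ConfigError(f"unknown analysis keys: {sorted(bad)}")
    return cfg


def _equal_contributions_from_pedigree(ped) -> pd.DataFrame:
    """Fallback: credit each offspring to both parents with equal weight."""
    rows: dict[tuple, int] = {}
    for rec in ped:
        if rec.is_founder:
            continue
        for parent in (rec.sire_id, rec.dam_id):
            key = (parent, rec.generation - 1, rec.line.value, rec.replicate)
            rows[key] = rows.get(key, 0) + 1
    return pd.DataFrame(
        [(*k, v) for k, v in rows.items()],
        columns=["parent", "generation", "line", "replicate", "progeny_count"],
    )


def run_pipeline(
    config_path: str | Path,
    out_dir: str | Path,
    seed: int | None = None,
) -> RunManifest:
    """Execute simulate (optional) -> differentials -> responses -> h² -> Box's M."""
    cfg = load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    analysis = cfg.get("analysis", {})
    conventions = {
        "differential": "S = sum_i (d_i - mu) p_i, p_i = measured progeny share; "
        "each progeny credits both parents",
        "response": "R = X_selected - X_control, same replicate and generation",
        "cumulative": "cumulative S = prefix sum of |S|; response at generation g "
        "paired with rounds 0..g-1",
        "bottom_sign": "negated" if analysis.get("negate_bottom", True) else "signed",
        "intercept": "origin" if analysis.get("through_origin", False) else "free",
    }
    master_seed = int(seed if seed is not None else cfg.get("simulate", {}).get("seed", 0))
    manifest = RunManifest(
        config=cfg, seed=master_seed, version=__version__, conventions=conventions
    )

    stage = "simulate"
    try:
        sim: SimResult | None = None
        if "simulate" in cfg:
            sim_kwargs = dict(cfg["simulate"])
            sim_kwargs["seed"] = master_seed
            sim_cfg = SimConfig(**sim_kwargs)
            sim = simulate_experiment(sim_cfg)
            log.info("simulated experiment: %d individuals", len(sim.pedigree))
            phenotypes, contributions = sim.phenotypes, sim.contributions
            for name, df in [
                ("pedigree", sim.pedigree.to_frame()),
                ("phenotypes", phenotypes),
                ("contributions", contributions),
                ("truth_differentials", sim.truth["differentials"]),
                ("truth_line_means", sim.truth["line_means"]),
            ]:
                p = out / f"{name}.csv"
                df.to_csv(p, index=False, float_format="%.12g")
                manifest.add_output(name, p)
            manifest.stages.append(stage)
        else:
            inputs = cfg["inputs"]
            phenotypes = pd.read_csv(inputs["phenotypes"])
            ped = read_pedigree(inputs["pedigree"]) if "pedigree" in inputs else None
            if "contributions" in inputs:
                contributions = pd.read_csv(inputs["contributions"])
            elif ped is not None:
                log.warning(
                    "no contributions table supplied; falling back to "
                    "equal-contribution differentials derived from the pedigree"
                )
                contributions = _equal_contributions_from_pedigree(ped)
                conventions["differential"] += " (equal-contribution fallback)"
            else:
                raise ConfigError(
                    "inputs must include 'contributions' or a 'pedigree' to "
                    "derive equal contributions from"
                )

        stage = "differentials"
        from .selection import differentials_table

        trait = analysis.get("trait")
        diffs = differentials_table(phenotypes, contributions, trait)
        p = out / "differentials.csv"
        diffs.to_csv(p, index=False, float_format="%.12g")
        manifest.add_output("differentials", p)
        manifest.stages.append(stage)

        stage = "responses"
        means = line_means_table(phenotypes, trait)
        p = out / "line_means.csv"
        means.to_csv(p, index=False, float_format="%.12g")
        manifest.add_output("line_means", p)
        manifest.stages.append(stage)

        stage = "heritability"
        h2 = heritability_table(
            phenotypes,
            contributions,
            trait,
            through_origin=analysis.get("through_origin", False),
            negate_bottom=analysis.get("negate_bottom", True),
        )
        p = out / "heritability.csv"
        h2.to_csv(p, index=False, float_format="%.12g")
        manifest.add_output("heritability", p)
        manifest.stages.append(stage)

        if analysis.get("final_traits", True) and sim is not None:
            stage = "final_traits"
            traits = final_generation_traits(sim)
            p = out / "final_traits.csv"
            traits.to_csv(p, index=False, float_format="%.12g")
            manifest.add_output("final_traits", p)
            gc = group_covariances_from_tidy(traits)
            result = boxs_m_test(gc)
            p = out / "boxm.json"
            p.write_text(json.dumps(dataclasses.asdict(result), indent=2))
            manifest.add_output("boxm", p)
            manifest.stages.append(stage)
    except Exception as e:
        partial = out / "manifest.partial.json"
        manifest.write(partial)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    manifest_path = out / "manifest.json"
    manifest.write(manifest_path)
    return manifest


def summarize_run(manifest: RunManifest | str | Path) -> pd.DataFrame:
    """One-page summary: per line x replicate h², percent changes, Box's M."""
    if not isinstance(manifest, RunManifest):
        manifest = RunManifest.read(manifest)
    if not manifest.outputs:
        raise ValueError("manifest lists no outputs")
    missing = [
        n for n, o in manifest.outputs.items() if not Path(o["path"]).exists()
    ]
    if missing:
        raise FileNotFoundError(f"manifest outputs missing on disk: {missing}")

    rows = []
    h2 = pd.read_csv(manifest.outputs["heritability"]["path"])
    for r in h2.itertuples(index=False):
        rows.append(
            {"quantity": f"h2_{r.line}_rep{r.replicate}", "value": r.h2,
             "units": ""}
        )
    rows.append({"quantity": "h2_mean", "value": float(h2["h2"].mean()), "units": ""})

    means = pd.read_csv(manifest.outputs["line_means"]["path"])
    g0 = means[means["generation"] == 0]["mean"].mean()
    gmax = means["generation"].max()
    fin = means[means["generation"] == gmax]
    for line in ("top", "bottom"):
        sub = fin[fin["line"] == line]
        if not sub.empty and np.isfinite(g0):
            rows.append(
                {"quantity": f"percent_change_{line}_vs_gen0",
                 "value": percent_change(g0, float(sub["mean"].mean())),
                 "units": "%"}
            )
    top = fin[fin["line"] == "top"]["mean"].mean()
    bot = fin[fin["line"] == "bottom"]["mean"].mean()
    if np.isfinite(top) and np.isfinite(bot):
        rows.append(
            {"quantity": "percent_change_top_vs_bottom",
             "value": percent_change(bot, top), "units": "%"}
        )

    if "boxm" in manifest.outputs:
        bm = json.loads(Path(manifest.outputs["boxm"]["path"]).read_text())
        rows.append({"quantity": "boxm_chi2", "value": bm["statistic"], "units": ""})
        rows.append({"quantity": "boxm_df", "value": bm["df"], "units": "df"})
        rows.append({"quantity": "boxm_p", "value": bm["p_value"], "units": ""})
    return pd.DataFrame(rows)


def heritability_recovery(
    base: SimConfig,
    n_experiments: int,
    master_seed: int = 0,
    *,
    progress: bool = False,
) -> pd.DataFrame:
    """Realized-h² estimates over repeated simulated experiments.

    Each experiment is simulated with a seed derived from ``master_seed``,
    analyzed with the table-level estimator pipeline, and summarized as the
    mean slope over its line x replicate series.
    """
    seeds = np.random.SeedSequence(master_seed).generate_state(n_experiments) % (2**31)
    rows = []
    for i, s in enumerate(seeds):
        cfg = dataclasses.replace(base, seed=int(s))
        sim = simulate_experiment(cfg)
        h2 = heritability_table(sim.phenotypes, sim.contributions)
        rows.append(
            {"experiment": i, "seed": int(s), "h2_mean": float(h2["h2"].mean()),
             **{f"h2_{r.line}_rep{r.replicate}": r.h2 for r in h2.itertuples(index=False)}}
        )
        if progress and (i + 1) % 20 == 0:
            log.info("recovery: %d/%d experiments", i + 1, n_experiments)
    return pd.DataFrame(rows)
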