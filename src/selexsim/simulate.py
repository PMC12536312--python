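"""Synthetic multi-generation divergent-selection experiments with known truth.

The generator emulates a replicated truncation-selection design on an
outcrossing annual: a founder pool per replicate is phenotyped, the largest
10% ("top"), smallest 10% ("bottom") and a random 10% ("control") are chosen
as parents, each parent is crossed with up to ten distinct partners assigned
to minimize mean relatedness, progeny contributions per cross are unequal,
and selection continues within line for several generations while a shared
environmental trend (by default negative, depressing the control line)
drifts all lines.

Genetics follow the additive infinitesimal model: founder breeding values
are N(0, h² σ²_P); offspring breeding values are midparent plus a Mendelian
deviation N(0, ½ h² σ²_P (1 - F̄_parents)), with parental inbreeding F
accumulating through the pedigree; phenotype = mean + g·trend + A + E with
E ~ N(0, (1-h²) σ²_P).  Kinship among the selected parents is propagated
recursively each generation and feeds both the Mendelian-sampling shrinkage
and the minimum-kinship mate allocation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from . import crosses as crosses_mod
from .pedigree import Line, Pedigree, PedigreeRecord, RelationshipMatrix

__all__ = ["SimConfig", "SimResult", "simulate_experiment", "final_generation_traits",
           "default_trait_covariance"]

TRAIT = "flower_diameter"
FINAL_TRAITS = ("flower_diameter", "petal_height", "anther_height", "stigma_height")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated selection experiment.

    Defaults mirror the emulated study design: ~500 plants per replicate per
    generation, divergent 10% truncation plus a random control, up to ten
    crosses per selected plant, four generations, flower diameter in mm with
    base mean 11.5 and phenotypic SD 1.9.
    """

    n_per_line: int = 500
    h2_true: float = 0.25
    pheno_mean: float = 11.5  # mm
    pheno_sd: float = 1.9  # mm
    select_fraction: float = 0.10
    k_crosses: int = 10
    n_generations: int = 4
    n_replicates: int = 2
    env_trend_per_gen: float = -0.1  # mm per generation; negative = decline
    contribution_dispersion: float = 1.0  # 0 = equal progeny per cross
    missing_fraction: float = 0.0  # plants that never flowered
    n_traits_final: int = 4
    trait_cov_by_group: Mapping[tuple[str, int], np.ndarray] | None = None
    inbreeding_adjust: bool = True  # shrink Mendelian variance by parental F
    designer_restarts: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.select_fraction <= 0.5):
            raise ValueError("select_fraction must be in (0, 0.5]")
        if self.pheno_sd <= 0:
            raise ValueError("pheno_sd must be positive")
        if self.n_per_line < 20:
            raise ValueError("n_per_line must be at least 20")
        if not (0 <= self.h2_true <= 1):
            raise ValueError("h2_true must be in [0, 1]")
        if self.contribution_dispersion < 0:
            raise ValueError("contribution_dispersion must be >= 0")
        if not (0 <= self.missing_fraction < 1):
            raise ValueError("missing_fraction must be in [0, 1)")


@dataclass
class SimResult:
    """Simulated experiment: pedigree, tidy tables, and recorded ground truth."""

    pedigree: Pedigree
    phenotypes: pd.DataFrame  # individual, generation, line, replicate, trait, value
    contributions: pd.DataFrame  # parent, generation, line, replicate, progeny_count
    truth: dict
    config: SimConfig


@dataclass
class _Cohort:
    """One generation of one line x replicate, with its genetic bookkeeping."""

    ids: np.ndarray  # individual id strings
    bv: np.ndarray  # breeding values
    pheno: np.ndarray  # measured phenotypes (NaN if not flowered)
    F: np.ndarray  # inbreeding coefficients
    sires: np.ndarray | None  # indices into previous selected parents
    dams: np.ndarray | None
    parent_kinship: np.ndarray | None  # kinship among previous selected parents


def _offspring_kinship(
    sires: np.ndarray, dams: np.ndarray, parent_kin: np.ndarray, F_off: np.ndarray
) -> np.ndarray:
    """Kinship among offspring from parent kinship and parent assignments.

    f(o, o') = 1/4 [f(s,s') + f(s,d') + f(d,s') + f(d,d')] for o != o';
    f(o, o)  = 1/2 (1 + F_o).
    """
    K = 0.25 * (
        parent_kin[np.ix_(sires, sires)]
        + parent_kin[np.ix_(sires, dams)]
        + parent_kin[np.ix_(dams, sires)]
        + parent_kin[np.ix_(dams, dams)]
    )
    np.fill_diagonal(K, 0.5 * (1.0 + F_off))
    return K


def _select(pheno: np.ndarray, n_sel: int, how: str, rng: np.random.Generator,
            exclude: np.ndarray | None = None) -> np.ndarray:
    """Indices of selected individuals; ties broken by seeded random jitter."""
    measured = np.flatnonzero(np.isfinite(pheno))
    if exclude is not None:
        measured = np.setdiff1d(measured, exclude, assume_unique=False)
    if len(measured) < n_sel:
        raise ValueError("fewer measured plants than the selection quota")
    if how == "control":
        return rng.choice(measured, size=n_sel, replace=False)
    jitter = rng.random(len(measured)) * 1e-9
    keys = pheno[measured] + jitter
    order = np.argsort(keys, kind="stable")
    if how == "top":
        order = order[::-1]
    elif how != "bottom":
        raise ValueError(f"unknown selection rule {how!r}")
    return measured[order[:n_sel]]


def _progeny_counts(n_crosses: int, n_offspring: int, dispersion: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Offspring per cross: equal split, or Dirichlet-multinomial if dispersed."""
    if dispersion == 0:
        base = np.full(n_crosses, n_offspring // n_crosses, dtype=int)
        base[: n_offspring - base.sum()] += 1
        return base
    w = rng.dirichlet(np.full(n_crosses, 1.0 / dispersion))
    return rng.multinomial(n_offspring, w)


def simulate_experiment(cfg: SimConfig) -> SimResult:
    """Run one full experiment; bit-reproducible given ``cfg.seed``."""
    master = np.random.SeedSequence(cfg.seed)
    rep_seeds = master.spawn(cfg.n_replicates)

    ped_records: list[PedigreeRecord] = []
    pheno_rows: list[tuple] = []
    contrib_rows: list[tuple] = []
    truth_s: list[dict] = []
    truth_means: list[dict] = []

    sigma_a = np.sqrt(cfg.h2_true) * cfg.pheno_sd
    sigma_e = np.sqrt(1.0 - cfg.h2_true) * cfg.pheno_sd
    n_sel = max(2, int(round(cfg.select_fraction * cfg.n_per_line)))

    for rep_i, rep_seed in enumerate(rep_seeds, start=1):
        rng = np.random.default_rng(rep_seed)

        # --- generation-0 founder pool -------------------------------------
        ids0 = np.array(
            [f"r{rep_i}-g0-{i:04d}" for i in range(cfg.n_per_line)]
        )
        bv0 = rng.normal(0.0, sigma_a, cfg.n_per_line)
        pheno0 = cfg.pheno_mean + bv0 + rng.normal(0.0, sigma_e, cfg.n_per_line)
        if cfg.missing_fraction > 0:
            miss = rng.random(cfg.n_per_line) < cfg.missing_fraction
            pheno0 = np.where(miss, np.nan, pheno0)
        base = _Cohort(ids0, bv0, pheno0, np.zeros(cfg.n_per_line), None, None, None)
        for i, iid in enumerate(ids0):
            ped_records.append(PedigreeRecord(iid, None, None, 0, Line.BASE, rep_i))
            if np.isfinite(pheno0[i]):
                pheno_rows.append((iid, 0, Line.BASE.value, rep_i, TRAIT, pheno0[i]))

        # disjoint selection of the three lines from the common pool
        top_idx = _select(base.pheno, n_sel, "top", rng)
        bot_idx = _select(base.pheno, n_sel, "bottom", rng, exclude=top_idx)
        ctl_idx = _select(
            base.pheno, n_sel, "control", rng,
            exclude=np.concatenate([top_idx, bot_idx]),
        )
        founder_kin = 0.5 * np.eye(cfg.n_per_line)

        cohorts: dict[Line, _Cohort] = {}
        selected: dict[Line, np.ndarray] = {
            Line.TOP: top_idx, Line.BOTTOM: bot_idx, Line.CONTROL: ctl_idx,
        }
        pools: dict[Line, _Cohort] = {ln: base for ln in selected}
        pool_kinship: dict[Line, np.ndarray] = {ln: founder_kin for ln in selected}

        for gen in range(1, cfg.n_generations + 1):
            for line, sel_idx in selected.items():
                pool = pools[line]
                kin_pool = pool_kinship[line]
                parent_ids = pool.ids[sel_idx]
                parent_bv = pool.bv[sel_idx]
                parent_pheno = pool.pheno[sel_idx]
                parent_F = pool.F[sel_idx]
                kin_sel = kin_pool[np.ix_(sel_idx, sel_idx)]

                # mate allocation minimizing mean additive relationship
                A_sel = RelationshipMatrix(tuple(parent_ids), 2.0 * kin_sel)
                plan = crosses_mod.minimize_relatedness(
                    list(parent_ids), A_sel, cfg.k_crosses,
                    restarts=cfg.designer_restarts, swaps=0,
                    rng_seed=int(rng.integers(2**31 - 1)),
                )
                pid_index = {pid: i for i, pid in enumerate(parent_ids)}
                edge_s = np.array([pid_index[a] for a, b in plan.crosses])
                edge_d = np.array([pid_index[b] for a, b in plan.crosses])

                counts = _progeny_counts(
                    len(plan.crosses), cfg.n_per_line,
                    cfg.contribution_dispersion, rng,
                )
                sires = np.repeat(edge_s, counts)
                dams = np.repeat(edge_d, counts)

                F_off = kin_sel[sires, dams]
                if cfg.inbreeding_adjust:
                    fbar = 0.5 * (parent_F[sires] + parent_F[dams])
                else:
                    fbar = np.zeros(cfg.n_per_line)
                mend_sd = np.sqrt(
                    np.maximum(0.0, 0.5 * sigma_a**2 * (1.0 - fbar))
                )
                bv = 0.5 * (parent_bv[sires] + parent_bv[dams]) + rng.normal(
                    0.0, 1.0, cfg.n_per_line
                ) * mend_sd
                pheno = (
                    cfg.pheno_mean
                    + gen * cfg.env_trend_per_gen
                    + bv
                    + rng.normal(0.0, sigma_e, cfg.n_per_line)
                )
                if cfg.missing_fraction > 0:
                    miss = rng.random(cfg.n_per_line) < cfg.missing_fraction
                    pheno = np.where(miss, np.nan, pheno)

                ids = np.array(
                    [f"r{rep_i}-g{gen}-{line.value[0]}{i:04d}"
                     for i in range(cfg.n_per_line)]
                )
                for i, iid in enumerate(ids):
                    ped_records.append(
                        PedigreeRecord(
                            iid, str(parent_ids[sires[i]]), str(parent_ids[dams[i]]),
                            gen, line, rep_i,
                        )
                    )
                    if np.isfinite(pheno[i]):
                        pheno_rows.append((iid, gen, line.value, rep_i, TRAIT, pheno[i]))

                # measured-progeny contributions: each measured offspring
                # credits both of its parents
                measured = np.isfinite(pheno)
                per_parent = np.zeros(len(parent_ids))
                np.add.at(per_parent, sires[measured], 1)
                np.add.at(per_parent, dams[measured], 1)
                for i, pid in enumerate(parent_ids):
                    contrib_rows.append(
                        (str(pid), gen - 1, line.value, rep_i, int(per_parent[i]))
                    )

                # truth: the weighted differential on the realized contributions
                pool_measured = np.isfinite(pool.pheno)
                mu = float(pool.pheno[pool_measured].mean())
                p = per_parent / per_parent.sum()
                s_true = float(np.sum((parent_pheno - mu) * p))
                truth_s.append(
                    {"generation": gen - 1, "line": line.value,
                     "replicate": rep_i, "S": s_true}
                )

                cohorts[line] = _Cohort(
                    ids, bv, pheno, F_off, sires, dams, kin_sel
                )

            for line, coh in cohorts.items():
                m = np.isfinite(coh.pheno)
                truth_means.append(
                    {"generation": gen, "line": line.value, "replicate": rep_i,
                     "mean": float(coh.pheno[m].mean())}
                )

            # next round: select within each line's new cohort
            if gen < cfg.n_generations:
                new_selected = {}
                new_pools = {}
                new_kin = {}
                for line, coh in cohorts.items():
                    how = {"top": "top", "bottom": "bottom", "control": "control"}[
                        line.value
                    ]
                    sel = _select(coh.pheno, n_sel, how, rng)
                    kin_off = _offspring_kinship(
                        coh.sires, coh.dams, coh.parent_kinship, coh.F
                    )
                    new_selected[line] = sel
                    new_pools[line] = coh
                    new_kin[line] = kin_off
                selected, pools, pool_kinship = new_selected, new_pools, new_kin
                cohorts = {}

    pedigree = Pedigree(ped_records)
    phenotypes = pd.DataFrame(
        pheno_rows,
        columns=["individual", "generation", "line", "replicate", "trait", "value"],
    )
    contributions = pd.DataFrame(
        contrib_rows,
        columns=["parent", "generation", "line", "replicate", "progeny_count"],
    )
    means_df = pd.DataFrame(truth_means)
    wide = means_df.pivot_table(
        index=["generation", "replicate"], columns="line", values="mean"
    ).reset_index()
    responses = pd.DataFrame(
        {
            "generation": wide["generation"],
            "replicate": wide["replicate"],
            "R_TC": wide["top"] - wide["control"],
            "R_BC": wide["bottom"] - wide["control"],
        }
    )
    truth = {
        "h2_true": cfg.h2_true,
        "differentials": pd.DataFrame(truth_s),
        "line_means": means_df,
        "responses": responses,
    }
    return SimResult(pedigree, phenotypes, contributions, truth, cfg)


def default_trait_covariance(scale: float = 1.0, rho: float = 0.6) -> np.ndarray:
    """A realistic 4-trait floral-size covariance: moderate positive correlation.

    Variances (mm²) reflect diameter being the most variable trait; ``rho``
    is the common correlation.
    """
    sd = np.array([1.9, 1.5, 1.2, 1.2]) * scale
    corr = np.full((4, 4), rho)
    np.fill_diagonal(corr, 1.0)
    return corr * np.outer(sd, sd)


def final_generation_traits(
    res: SimResult,
    cfg: SimConfig | None = None,
    *,
    seed: int | None = None,
) -> pd.DataFrame:
    """Correlated floral-size traits for every final-generation individual.

    Each line x replicate group draws from a multivariate normal centered on
    the group's simulated mean flower diameter (other traits offset below it)
    with the group's covariance from ``cfg.trait_cov_by_group`` (a common
    default covariance if unset).  Reproducible given the seed.
    """
    cfg = cfg or res.config
    if cfg.n_traits_final != len(FINAL_TRAITS):
        raise ValueError(f"n_traits_final must be {len(FINAL_TRAITS)}")
    rng = np.random.default_rng(
        np.random.SeedSequence(cfg.seed if seed is None else seed).spawn(1)[0]
    )
    final_gen = int(res.phenotypes["generation"].max())
    fin = res.phenotypes[
        (res.phenotypes["generation"] == final_gen)
        & (res.phenotypes["trait"] == TRAIT)
    ]
    offsets = np.array([0.0, -2.0, -4.0, -3.5])  # trait means relative to diameter
    rows = []
    for (line, rep), grp in fin.groupby(["line", "replicate"], observed=True):
        key = (str(line), int(rep))
        cov = (
            np.asarray(cfg.trait_cov_by_group[key], dtype=float)
            if cfg.trait_cov_by_group is not None
            else default_trait_covariance()
        )
        if cov.shape != (4, 4) or not np.allclose(cov, cov.T):
            raise ValueError(f"covariance for group {key} is not symmetric 4x4")
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            raise ValueError(
                f"covariance for group {key} is not positive definite"
            ) from None
        mean_vec = float(grp["value"].mean()) + offsets
        draws = rng.multivariate_normal(
            mean_vec, cov, size=len(grp), method="cholesky"
        )
        for iid, vals in zip(grp["individual"], draws):
            for t, v in zip(FINAL_TRAITS, vals):
                rows.append((iid, final_gen, line, rep, t, float(v)))
    return pd.DataFrame(
        rows,
        columns=["individual", "generation", "line", "replicate", "trait", "value"],
    )
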