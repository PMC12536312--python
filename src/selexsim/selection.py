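"""Selection differentials, control-adjusted responses, and realized heritability.

The per-generation selection differential is weighted by each parent's share
of measured progeny,

    S = sum_i (d_i - mu) p_i ,

where ``d_i`` is the mean trait value of the *i*-th selected parent, ``mu``
the mean of the pool of possible parents, and ``p_i`` the proportion of
measured progeny produced by that parent.  The weighting corrects for
unequal parental contributions to the next generation.

Responses are control-adjusted within replicate and generation,
``R_TC = X_T - X_C`` and ``R_BC = X_B - X_C``, which removes shared
environmental drift.  Realized heritability is the ordinary-least-squares
slope of the response on the cumulative absolute differential.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .pedigree import Line

__all__ = [
    "Direction",
    "SelectionRecord",
    "LineMeans",
    "ResponseSeries",
    "HeritabilityEstimate",
    "weighted_selection_differential",
    "response_to_selection",
    "cumulative_differential",
    "realized_heritability",
    "percent_change",
    "collapse_repeated_measures",
    "line_means_table",
    "differentials_table",
    "response_series_from_tables",
    "heritability_table",
]


class Direction(str, Enum):
    TOP_MINUS_CONTROL = "top_minus_control"
    BOTTOM_MINUS_CONTROL = "bottom_minus_control"

    @property
    def selected_line(self) -> Line:
        return Line.TOP if self is Direction.TOP_MINUS_CONTROL else Line.BOTTOM


@dataclass(frozen=True)
class SelectionRecord:
    """A weighted selection differential with its full audit trail."""

    parent_means: dict[str, float]
    pool_mean: float
    contributions: dict[str, float]  # p_i, summing to 1
    progeny_counts: dict[str, float]  # raw counts as supplied
    differential: float  # S, trait units
    generation: int | None = None
    line: Line | None = None
    replicate: int | None = None

    def __post_init__(self) -> None:
        total = sum(self.contributions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"contributions sum to {total}, expected 1")


@dataclass(frozen=True)
class LineMeans:
    """Per-generation, per-replicate mean trait values of the three lines."""

    generation: int
    replicate: int
    mean_top: float
    mean_bottom: float
    mean_control: float


@dataclass(frozen=True)
class ResponseSeries:
    """Paired (cumulative |S|, response) points for one line x replicate."""

    cumulative_s: tuple[float, ...]
    response: tuple[float, ...]
    direction: Direction
    generations: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.cumulative_s) != len(self.response):
            raise ValueError("cumulative_s and response differ in length")
        if np.any(np.diff(self.cumulative_s) < 0):
            raise ValueError("cumulative differential must be non-decreasing")


@dataclass(frozen=True)
class HeritabilityEstimate:
    slope: float  # h^2, dimensionless
    intercept: float  # trait units; 0.0 when fit through the origin
    slope_se: float
    n_points: int


def weighted_selection_differential(
    parent_means: Mapping[str, float],
    pool_mean: float,
    progeny_counts: Mapping[str, float],
    *,
    generation: int | None = None,
    line: Line | None = None,
    replicate: int | None = None,
) -> SelectionRecord:
    """Contribution-weighted selection differential S = sum (d_i - mu) p_i.

    ``progeny_counts`` are raw measured-progeny counts per parent; weights
    ``p_i`` are the counts normalized to sum to one over the parent set.
    """
    counts = {str(k): float(v) for k, v in progeny_counts.items()}
    if any(c < 0 for c in counts.values()):
        raise ValueError("progeny counts must be non-negative")
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("all progeny counts are zero")
    missing = [k for k, c in counts.items() if c > 0 and k not in parent_means]
    if missing:
        raise ValueError(f"parents with progeny but no trait mean: {missing}")
    p = {k: c / total for k, c in counts.items()}
    s = sum((parent_means[k] - pool_mean) * w for k, w in p.items() if w > 0)
    return SelectionRecord(
        parent_means={k: float(parent_means[k]) for k in counts if p[k] > 0},
        pool_mean=float(pool_mean),
        contributions=p,
        progeny_counts=counts,
        differential=float(s),
        generation=generation,
        line=line,
        replicate=replicate,
    )


def response_to_selection(means: LineMeans, direction: Direction) -> float:
    """Control-adjusted response: X_T - X_C or X_B - X_C."""
    if not np.isfinite(means.mean_control):
        raise ValueError(
            f"missing control mean for generation {means.generation}, "
            f"replicate {means.replicate}"
        )
    sel = (
        means.mean_top
        if direction is Direction.TOP_MINUS_CONTROL
        else means.mean_bottom
    )
    if not np.isfinite(sel):
        raise ValueError(
            f"missing {direction.selected_line.value} mean for generation "
            f"{means.generation}, replicate {means.replicate}"
        )
    return float(sel - means.mean_control)


def cumulative_differential(
    records: Sequence[SelectionRecord | float],
) -> list[float]:
    """Prefix sums of |S| for one line x replicate, sorted by generation."""
    s_values = []
    gens = []
    for r in records:
        if isinstance(r, SelectionRecord):
            s_values.append(r.differential)
            gens.append(r.generation)
        else:
            s_values.append(float(r))
            gens.append(None)
    known = [g for g in gens if g is not None]
    if known:
        if len(known) != len(gens):
            raise ValueError("mixed records with and without generation labels")
        if sorted(known) != known or len(set(known)) != len(known):
            raise ValueError("records must be sorted by generation without duplicates")
        if known != list(range(known[0], known[0] + len(known))):
            raise ValueError("generation sequence has gaps")
    return list(np.cumsum(np.abs(s_values)))


def realized_heritability(
    series: ResponseSeries,
    *,
    through_origin: bool = False,
    negate_bottom: bool = True,
    include_origin_point: bool = False,
) -> HeritabilityEstimate:
    """OLS slope of response on cumulative |S|; the slope is realized h².

    Bottom-line responses are negative while cumulative |S| is positive, so
    by default they are negated (``negate_bottom``) to put both directions on
    a common positive-slope scale.  The fit includes an intercept unless
    ``through_origin``; ``include_origin_point`` prepends the (0, 0) point.
    """
    x = np.asarray(series.cumulative_s, dtype=float)
    y = np.asarray(series.response, dtype=float)
    if negate_bottom and series.direction is Direction.BOTTOM_MINUS_CONTROL:
        y = -y
    if include_origin_point:
        x = np.concatenate([[0.0], x])
        y = np.concatenate([[0.0], y])
    if len(x) < 2:
        raise ValueError("need at least 2 points to fit a slope")
    if np.ptp(x) == 0:
        raise ValueError("cumulative differential has zero variance")
    design = x[:, None] if through_origin else sm.add_constant(x)
    fit = sm.OLS(y, design).fit()
    slope = float(fit.params[-1])
    intercept = 0.0 if through_origin else float(fit.params[0])
    # SE undefined with zero residual degrees of freedom (saturated fit)
    se = float(fit.bse[-1]) if fit.df_resid > 0 else float("nan")
    return HeritabilityEstimate(
        slope=slope,
        intercept=intercept,
        slope_se=se,
        n_points=len(x),
    )


def percent_change(reference: float, value: float) -> float:
    """Percent change of ``value`` relative to ``reference`` (full precision)."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return 100.0 * (value - reference) / reference


# ---------------------------------------------------------------------------
# table-level drivers: tidy phenotype / contribution frames -> estimates
# ---------------------------------------------------------------------------

PHENO_COLS = ["individual", "generation", "line", "replicate", "trait", "value"]
CONTRIB_COLS = ["parent", "generation", "line", "replicate", "progeny_count"]


def collapse_repeated_measures(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Average repeated measurements (e.g. two flowers) into one value per plant."""
    keys = [c for c in PHENO_COLS if c != "value"]
    return phenotypes.groupby(keys, as_index=False, observed=True)["value"].mean()


def line_means_table(phenotypes: pd.DataFrame, trait: str | None = None) -> pd.DataFrame:
    """Mean trait value per generation x line x replicate (tidy)."""
    df = phenotypes
    if trait is not None:
        df = df[df["trait"] == trait]
    df = collapse_repeated_measures(df)
    return (
        df.groupby(["generation", "line", "replicate"], as_index=False, observed=True)["value"]
        .mean()
        .rename(columns={"value": "mean"})
    )


def differentials_table(
    phenotypes: pd.DataFrame,
    contributions: pd.DataFrame,
    trait: str | None = None,
) -> pd.DataFrame:
    """Weighted selection differentials per (generation, line, replicate).

    ``contributions`` rows carry the parent's generation and the line its
    progeny were selected into.  The parent pool for generation g is that
    line's generation-g cohort (the base pool at generation 0).
    """
    pheno = phenotypes if trait is None else phenotypes[phenotypes["trait"] == trait]
    pheno = collapse_repeated_measures(pheno)
    value_by_id = pheno.set_index(["replicate", "individual"])["value"]

    rows = []
    for (gen, line, rep), grp in contributions.groupby(
        ["generation", "line", "replicate"], observed=True
    ):
        pool_line = line if gen > 0 else Line.BASE.value
        pool = pheno[
            (pheno["generation"] == gen)
            & (pheno["replicate"] == rep)
            & (pheno["line"] == pool_line)
        ]["value"]
        if pool.empty:
            raise ValueError(
                f"no parent pool phenotypes for generation {gen}, line {line}, "
                f"replicate {rep}"
            )
        counts = dict(zip(grp["parent"].astype(str), grp["progeny_count"]))
        means = {
            pid: float(value_by_id[(rep, pid)])
            for pid in counts
            if (rep, pid) in value_by_id.index
        }
        rec = weighted_selection_differential(
            means, float(pool.mean()), counts,
            generation=int(gen), line=Line(line), replicate=int(rep),
        )
        rows.append(
            {"generation": int(gen), "line": line, "replicate": int(rep),
             "S": rec.differential}
        )
    return pd.DataFrame(rows).sort_values(
        ["line", "replicate", "generation"], ignore_index=True
    )


def response_series_from_tables(
    phenotypes: pd.DataFrame,
    contributions: pd.DataFrame,
    direction: Direction,
    replicate: int,
    trait: str | None = None,
) -> ResponseSeries:
    """Build the (cumulative |S|, control-adjusted R) series for one line x rep.

    The response at generation g is paired with the cumulative differential of
    the selection rounds applied before g (parent generations 0..g-1).
    """
    sel_line = direction.selected_line.value
    means = line_means_table(phenotypes, trait)
    diffs = differentials_table(phenotypes, contributions, trait)
    diffs = diffs[(diffs["line"] == sel_line) & (diffs["replicate"] == replicate)]
    diffs = diffs.sort_values("generation")
    cum = cumulative_differential(list(diffs["S"]))

    gens, xs, ys = [], [], []
    for k, parent_gen in enumerate(diffs["generation"]):
        g = int(parent_gen) + 1  # offspring generation measured for response
        row = means[(means["generation"] == g) & (means["replicate"] == replicate)]
        sel = row[row["line"] == sel_line]["mean"]
        ctl = row[row["line"] == Line.CONTROL.value]["mean"]
        if sel.empty or ctl.empty:
            continue
        lm = LineMeans(
            generation=g,
            replicate=replicate,
            mean_top=float(sel.iloc[0]) if sel_line == "top" else np.nan,
            mean_bottom=float(sel.iloc[0]) if sel_line == "bottom" else np.nan,
            mean_control=float(ctl.iloc[0]),
        )
        gens.append(g)
        xs.append(cum[k])
        ys.append(response_to_selection(lm, direction))
    return ResponseSeries(
        cumulative_s=tuple(xs), response=tuple(ys),
        direction=direction, generations=tuple(gens),
    )


def heritability_table(
    phenotypes: pd.DataFrame,
    contributions: pd.DataFrame,
    trait: str | None = None,
    *,
    through_origin: bool = False,
    negate_bottom: bool = True,
) -> pd.DataFrame:
    """Realized h² per line x replicate from tidy experiment tables."""
    rows = []
    for direction in Direction:
        line = direction.selected_line.value
        for rep in sorted(contributions["replicate"].unique()):
            series = response_series_from_tables(
                phenotypes, contributions, direction, int(rep), trait
            )
            est = realized_heritability(
                series, through_origin=through_origin, negate_bottom=negate_bottom
            )
            rows.append(
                {"line": line, "replicate": int(rep), "h2": est.slope,
                 "intercept": est.intercept, "slope_se": est.slope_se,
                 "n_points": est.n_points}
            )
    return pd.DataFrame(rows)
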