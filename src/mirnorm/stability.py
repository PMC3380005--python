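"""Expression-stability ranking of candidate reference genes.

Three independently implemented algorithms, each scoring candidates by a
different notion of stability:

* **geNorm** — pairwise model.  A gene's M value is the mean, over all other
  candidates, of the standard deviation of the pairwise log2 expression
  ratio; the least stable gene (highest M) is removed stepwise.  The
  pairwise-variation series V(n/n+1) between normalization factors built
  from the top n and n+1 genes decides how many references are needed
  (V < 0.15 by convention).

* **NormFinder** — variance-decomposition (ANOVA-type) model on the log2
  scale.  After removing the per-sample (loading) effect, each gene's
  intragroup variance is bias-corrected, its intergroup difference is
  shrunken towards zero, and the stability value combines the absolute
  shrunken bias with the intragroup standard error, averaged over groups.

* **BestKeeper** — descriptive statistics directly on the Cq scale.  Genes
  are scored by the mean absolute deviation (MAD) of their Cq around the
  arithmetic mean (genes with SD > 1 cycle are deemed inconsistent), and by
  Pearson correlation with the BestKeeper index, the per-sample geometric
  mean Cq of the retained genes.

A consensus table merges the three reports, one row per gene plus
best-single / best-combination rows per method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import RQMatrix

__all__ = ["StabilityReport", "genorm", "normfinder", "bestkeeper", "consensus_table"]


@dataclass
class StabilityReport:
    """Per-method stability scores, ranks and recommendations.

    ``table`` is indexed by gene with at least ``score`` and ``rank``
    columns (rank NaN where a method excluded the gene).  ``extras`` holds
    method-specific diagnostics: geNorm's elimination order and V series,
    BestKeeper's descriptive statistics and index correlations, NormFinder's
    per-group components.
    """

    method: str
    table: pd.DataFrame
    best_single: str
    best_pair: tuple[str, str] | None = None
    recommended_set: tuple[str, ...] | None = None
    extras: dict = field(default_factory=dict)


def _as_frame(rq: RQMatrix | pd.DataFrame) -> pd.DataFrame:
    return rq.rq if isinstance(rq, RQMatrix) else rq


# ---------------------------------------------------------------------------
# geNorm
# ---------------------------------------------------------------------------

def _genorm_m(logx: np.ndarray) -> np.ndarray:
    """M value per gene: mean over other genes of SD(log2 ratio), ddof=1."""
    diff = logx[:, None, :] - logx[None, :, :]
    v = diff.std(axis=2, ddof=1)
    k = logx.shape[0]
    return v.sum(axis=1) / (k - 1)


def genorm(rq: RQMatrix | pd.DataFrame, v_cutoff: float = 0.15) -> StabilityReport:
    """geNorm stability ranking with stepwise elimination and V series.

    Requires at least 3 genes, 2 samples and strictly positive relative
    quantities.  The two genes surviving elimination form the joint
    most-stable pair and share rank 1.  The recommended set is the smallest
    top-n (n >= 2) whose V(n/n+1) falls below ``v_cutoff``; when no V does,
    no set is recommended — an outcome the method itself produces on
    sufficiently heterogeneous panels.
    """
    frame = _as_frame(rq)
    genes = list(frame.index)
    if len(genes) < 3:
        raise ValueError("geNorm requires at least 3 candidate genes")
    if frame.shape[1] < 2:
        raise ValueError("geNorm requires at least 2 samples")
    vals = frame.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
        raise ValueError("geNorm requires strictly positive, finite RQ values")
    logx = np.log2(vals)

    full_m = pd.Series(_genorm_m(logx), index=genes, name="M")

    remaining = list(genes)
    sub = logx.copy()
    eliminated: list[str] = []
    m_trace: list[pd.Series] = []
    while len(remaining) > 2:
        m = pd.Series(_genorm_m(sub), index=remaining)
        m_trace.append(m)
        worst_m = m.max()
        # tie on max M: eliminate the lexicographically last gene
        worst = max(g for g in remaining if m[g] == worst_m)
        idx = remaining.index(worst)
        eliminated.append(worst)
        remaining = remaining[:idx] + remaining[idx + 1 :]
        sub = np.delete(sub, idx, axis=0)
    final_pair = tuple(sorted(remaining))

    rank = pd.Series(index=genes, dtype=float)
    for pos, g in enumerate(eliminated):
        rank[g] = len(genes) - pos
    for g in final_pair:
        rank[g] = 1  # joint most-stable pair

    stability_order = list(final_pair) + list(reversed(eliminated))
    log_order = np.stack([logx[genes.index(g)] for g in stability_order])
    v_rows = []
    log_nf_prev = log_order[:2].mean(axis=0)
    for n in range(2, len(genes)):
        log_nf_next = log_order[: n + 1].mean(axis=0)
        v = float(np.std(log_nf_prev - log_nf_next, ddof=1))
        v_rows.append({"n": n, "V": v})
        log_nf_prev = log_nf_next
    v_series = pd.DataFrame(v_rows)
    rec_n = None
    below = v_series[v_series["V"] < v_cutoff]
    if len(below):
        rec_n = int(below["n"].iloc[0])

    table = pd.DataFrame({"score": full_m, "rank": rank}).loc[genes]
    return StabilityReport(
        method="genorm",
        table=table,
        best_single=stability_order[0],
        best_pair=final_pair,
        recommended_set=tuple(stability_order[:rec_n]) if rec_n else None,
        extras={
            "elimination_order": eliminated,
            "stability_order": stability_order,
            "v_series": v_series,
            "v_cutoff": v_cutoff,
            "recommended_n": rec_n,
            "m_trace": m_trace,
        },
    )


# ---------------------------------------------------------------------------
# NormFinder
# ---------------------------------------------------------------------------

def _nf_intragroup_var(
    x: pd.DataFrame, members: dict[str, pd.Index]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Raw, bias-corrected (untruncated) and truncated intragroup variances.

    The correction removes the contribution of the subtracted sample mean:
    sigma2_ig = (s2_ig - sum_i' s2_i'g / (k(k-1))) * k/(k-2), truncated at 0
    for use downstream.  Needs k >= 3 genes.
    """
    k = x.shape[0]
    raw = pd.DataFrame(
        {g: x[cols].var(axis=1, ddof=1) for g, cols in members.items()}
    )
    corrected = (raw.sub(raw.sum(axis=0) / (k * (k - 1)), axis=1)) * (k / (k - 2))
    return raw, corrected, corrected.clip(lower=0.0)


def normfinder(
    data: RQMatrix | pd.DataFrame,
    groups: pd.Series | None = None,
    ddof_d: int = 1,
) -> StabilityReport:
    """NormFinder-style model-based stability estimation.

    With group labels, each gene's stability value is the group-averaged sum
    of its absolute shrunken intergroup bias and its intragroup standard
    error; the best pair minimizes the same score for the averaged
    pseudo-gene.  Without groups (or with a single group) the model reduces
    to ranking by the bias-corrected overall variance, and the stability
    value is its square root.
    """
    frame = _as_frame(data)
    genes = list(frame.index)
    k = len(genes)
    if k < 3:
        raise ValueError(
            "NormFinder requires >= 3 genes: the intragroup variance "
            "bias-correction divides by (k - 2)"
        )
    vals = frame.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
        raise ValueError("NormFinder requires strictly positive, finite RQ values")
    if groups is None and isinstance(data, RQMatrix) and data.meta is not None:
        groups = data.meta["group"]

    y = pd.DataFrame(np.log2(vals), index=genes, columns=frame.columns)
    x = y.sub(y.mean(axis=0), axis=1)  # remove per-sample (loading) effect

    grouped = groups is not None and groups.loc[list(frame.columns)].nunique() > 1
    if not grouped:
        members = {"all": frame.columns}
        _, _, sigma2 = _nf_intragroup_var(x, members)
        rho = np.sqrt(sigma2["all"])
        order = rho.sort_values(kind="stable").index
        table = pd.DataFrame({"score": rho, "rank": np.nan})
        table.loc[order, "rank"] = np.arange(1, k + 1)
        pair = tuple(order[:2])
        return StabilityReport(
            method="normfinder",
            table=table.loc[genes],
            best_single=order[0],
            best_pair=(pair[0], pair[1]),
            extras={"mode": "ungrouped", "sigma2": sigma2},
        )

    glab = groups.loc[list(frame.columns)]
    levels = sorted(glab.unique())
    members = {g: glab.index[glab == g] for g in levels}
    n_g = pd.Series({g: len(cols) for g, cols in members.items()})
    if (n_g < 2).any():
        small = list(n_g.index[n_g < 2])
        raise ValueError(f"each group needs >= 2 samples; too small: {small}")

    raw_s2, sigma2_untruncated, sigma2 = _nf_intragroup_var(x, members)
    xbar = pd.DataFrame({g: x[cols].mean(axis=1) for g, cols in members.items()})
    d = xbar.sub(xbar.mean(axis=1), axis=0)  # intergroup difference, rows sum to 0

    se2 = sigma2.div(n_g, axis=1)  # sigma2_ig / n_g
    gamma2 = max(0.0, float(np.var(d.to_numpy(), ddof=ddof_d)) - float(se2.mean().mean()))

    def _score(d_g: pd.DataFrame, se2_g: pd.DataFrame) -> pd.Series:
        if gamma2 == 0.0:
            d_shrunk = d_g * 0.0
        else:
            d_shrunk = d_g * (gamma2 / (gamma2 + se2_g))
        return (d_shrunk.abs() + np.sqrt(se2_g)).mean(axis=1)

    rho = _score(d, se2).rename("score")
    order = rho.sort_values(kind="stable").index
    table = pd.DataFrame({"score": rho, "rank": np.nan})
    table.loc[order, "rank"] = np.arange(1, k + 1)

    # best pair: exhaustive search over averaged pseudo-genes
    best_pair, best_pair_rho = None, np.inf
    for a, b in combinations(sorted(genes), 2):
        d_p = pd.DataFrame({g: (d.loc[a, g] + d.loc[b, g]) / 2.0 for g in levels}, index=[0])
        s2_p = pd.DataFrame(
            {g: (sigma2.loc[a, g] + sigma2.loc[b, g]) / 4.0 for g in levels}, index=[0]
        )
        rho_p = float(_score(d_p, s2_p.div(n_g, axis=1)).iloc[0])
        if rho_p < best_pair_rho:
            best_pair, best_pair_rho = (a, b), rho_p

    return StabilityReport(
        method="normfinder",
        table=table.loc[genes],
        best_single=order[0],
        best_pair=best_pair,
        extras={
            "mode": "grouped",
            "raw_s2": raw_s2,
            "sigma2": sigma2,
            "sigma2_untruncated": sigma2_untruncated,
            "d": d,
            "gamma2": gamma2,
            "best_pair_score": best_pair_rho,
            "group_sizes": n_g,
        },
    )


# ---------------------------------------------------------------------------
# BestKeeper
# ---------------------------------------------------------------------------

def bestkeeper(
    cq: pd.DataFrame,
    efficiencies: pd.Series | float = 1.0,
    max_genes: int = 10,
    sd_cutoff: float = 1.0,
    compat_limit: bool = False,
) -> StabilityReport:
    """BestKeeper descriptive-statistics ranking on the Cq scale.

    ``cq`` is a gene × sample matrix of replicate-mean Cq values.  The
    dispersion driving the ranking and the inconsistency rule is the mean
    absolute deviation around the arithmetic mean (the original tool's
    "SD"); the classical standard deviation is also emitted.  ``x_fold``
    converts the dispersion to a fold range via ``(1+E)**MAD``.

    ``compat_limit=True`` reproduces the original spreadsheet's 10-gene
    limit and rejects larger panels (the historical workaround is to drop
    the worst-ranked genes first); natively there is no limit.
    """
    genes = list(cq.index)
    if len(genes) < 2:
        raise ValueError("BestKeeper requires at least 2 genes")
    if compat_limit and len(genes) > max_genes:
        raise ValueError(
            f"compatibility mode handles at most {max_genes} genes simultaneously; "
            "drop the worst-ranked genes first (e.g. by geNorm M) and rerun"
        )
    eff = (
        pd.Series(efficiencies, dtype=float).reindex(genes)
        if isinstance(efficiencies, pd.Series)
        else pd.Series(float(efficiencies), index=genes)
    )
    if eff.isna().any():
        raise ValueError(f"missing efficiencies for: {list(eff.index[eff.isna()])}")

    vals = cq.to_numpy(dtype=float)
    am = vals.mean(axis=1)
    mad = np.abs(vals - am[:, None]).mean(axis=1)
    table = pd.DataFrame(
        {
            "geo_mean_cq": stats.gmean(vals, axis=1),
            "arith_mean_cq": am,
            "min_cq": vals.min(axis=1),
            "max_cq": vals.max(axis=1),
            "sd_mad": mad,
            "sd_classic": vals.std(axis=1, ddof=1),
            "cv_pct": 100.0 * mad / am,
            "x_fold": (1.0 + eff.to_numpy()) ** mad,
        },
        index=genes,
    )
    table["inconsistent"] = table["sd_mad"] > sd_cutoff
    retained = [g for g in genes if not table.loc[g, "inconsistent"]]
    if not retained:
        raise ValueError(f"all genes exceed the SD cutoff of {sd_cutoff} cycles")

    index_s = pd.Series(
        stats.gmean(cq.loc[retained].to_numpy(dtype=float), axis=0),
        index=cq.columns,
        name="bestkeeper_index",
    )
    r_vals, p_vals = {}, {}
    index_const = np.ptp(index_s.to_numpy()) == 0
    for g in genes:
        gv = cq.loc[g].to_numpy(dtype=float)
        if index_const or np.ptp(gv) == 0:
            r_vals[g], p_vals[g] = np.nan, np.nan
        else:
            r, p = stats.pearsonr(gv, index_s.to_numpy())
            r_vals[g], p_vals[g] = float(r), float(p)
    table["r_index"] = pd.Series(r_vals)
    table["p_index"] = pd.Series(p_vals)

    order = sorted(
        retained,
        key=lambda g: (
            table.loc[g, "sd_mad"],
            -(table.loc[g, "r_index"] if np.isfinite(table.loc[g, "r_index"]) else -np.inf),
            g,
        ),
    )
    table["score"] = table["sd_mad"]
    table["rank"] = np.nan
    table.loc[order, "rank"] = np.arange(1, len(order) + 1)

    return StabilityReport(
        method="bestkeeper",
        table=table.loc[genes],
        best_single=order[0],
        best_pair=None,
        extras={
            "index": index_s,
            "excluded": [g for g in genes if table.loc[g, "inconsistent"]],
            "sd_cutoff": sd_cutoff,
        },
    )


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

def consensus_table(reports: list[StabilityReport]) -> pd.DataFrame:
    """Merge per-method reports into one gene × (score, rank) table.

    Genes missing from a method (e.g. BestKeeper exclusions) get blank
    cells.  geNorm's joint top pair is displayed with distinct ranks broken
    lexicographically.  Two trailing rows carry each method's best single
    gene and best combination.
    """
    genes = sorted({g for r in reports for g in r.table.index})
    out = pd.DataFrame(index=genes)
    for r in reports:
        score = r.table["score"].reindex(genes)
        rank = r.table["rank"].reindex(genes)
        if r.method == "genorm" and r.best_pair is not None:
            a, b = sorted(r.best_pair)
            rank = rank.copy()
            rank[a], rank[b] = 1, 2  # display tie-break by name
        out[f"{r.method}_score"] = score.round(4)
        out[f"{r.method}_rank"] = rank
    best = pd.DataFrame("", index=["Best gene", "Best combination"], columns=out.columns,
                        dtype=object)
    for r in reports:
        combo = r.recommended_set or r.best_pair
        best.loc["Best gene", f"{r.method}_score"] = r.best_single
        best.loc["Best combination", f"{r.method}_score"] = (
            ", ".join(combo) if combo else "-"
        )
    return pd.concat([out.astype(object), best])
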