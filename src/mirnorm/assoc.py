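"""Co-expression screening and clinical association of candidate normalizers.

Candidate reference genes should ideally be independent of each other (the
pairwise geNorm model favors co-regulated genes) and of clinical variables.
This module screens all gene pairs by Spearman rank correlation, flagging
pairs above a co-expression threshold, and tests each candidate's expression
against age (Spearman), sex and malignancy/grade contrasts (Mann-Whitney U),
and tumor stage (Kruskal-Wallis with Dunn's pairwise follow-up when the
global test is significant).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import RQMatrix

__all__ = [
    "AssociationReport",
    "coexpression_screen",
    "clinical_association",
    "dunn_test",
    "mann_whitney",
]

# exact Mann-Whitney p below this combined sample size (no ties permitting)
EXACT_MWU_MAX_N = 20


@dataclass
class AssociationReport:
    """Spearman matrices, co-expressed pairs and clinical test results."""

    spearman_r: pd.DataFrame | None = None
    spearman_p: pd.DataFrame | None = None
    coexpressed_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    clinical: pd.DataFrame | None = None
    posthoc: pd.DataFrame | None = None
    threshold: float | None = None


def _as_frame(rq: RQMatrix | pd.DataFrame) -> pd.DataFrame:
    return rq.rq if isinstance(rq, RQMatrix) else rq


def coexpression_screen(
    rq: RQMatrix | pd.DataFrame, threshold: float = 0.60
) -> AssociationReport:
    """Spearman correlation for every gene pair; pairs with r >= threshold flagged.

    Constant genes have undefined rank correlation; their entries are NaN
    (off-diagonal) and they can never be flagged.
    """
    frame = _as_frame(rq)
    if frame.shape[1] < 3:
        raise ValueError("co-expression screen requires at least 3 samples")
    genes = list(frame.index)
    k = len(genes)
    r = np.eye(k)
    p = np.zeros((k, k))
    vals = frame.to_numpy(dtype=float)
    const = np.ptp(vals, axis=1) == 0
    for i, j in combinations(range(k), 2):
        if const[i] or const[j]:
            r[i, j] = r[j, i] = np.nan
            p[i, j] = p[j, i] = np.nan
        else:
            res = stats.spearmanr(vals[i], vals[j])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    r_df = pd.DataFrame(r, index=genes, columns=genes)
    p_df = pd.DataFrame(p, index=genes, columns=genes)
    np.fill_diagonal(p_df.values, 0.0)
    pairs = [
        (genes[i], genes[j], float(r[i, j]))
        for i, j in combinations(range(k), 2)
        if np.isfinite(r[i, j]) and r[i, j] >= threshold
    ]
    return AssociationReport(
        spearman_r=r_df, spearman_p=p_df, coexpressed_pairs=pairs, threshold=threshold
    )


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U, exact for small tie-free samples.

    The exact null distribution is used when the combined sample size is at
    most ``EXACT_MWU_MAX_N`` and there are no ties; otherwise the normal
    approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= EXACT_MWU_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def dunn_test(
    values: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Dunn's pairwise rank comparisons after a Kruskal-Wallis test.

    Uses midranks over the pooled sample with the standard tie correction;
    z statistics are referred to the normal distribution, two-sided.  P
    values are reported raw; ``adjust`` optionally adds a family-wise
    adjustment column ('bonferroni' or 'holm' — the choice of whether to
    adjust is left to the analyst and is off by default).
    """
    values = np.asarray(values, dtype=float)
    glab = np.asarray(groups)
    levels = sorted(pd.unique(glab))
    n = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    rows = []
    for a, b in combinations(levels, 2):
        ra = ranks[glab == a]
        rb = ranks[glab == b]
        se = np.sqrt(var_base * (1.0 / len(ra) + 1.0 / len(rb)))
        z = (ra.mean() - rb.mean()) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_value": p})
    out = pd.DataFrame(rows)
    if adjust is not None:
        m = len(out)
        if adjust == "bonferroni":
            out["p_adjusted"] = np.minimum(out["p_value"] * m, 1.0)
        elif adjust == "holm":
            order = np.argsort(out["p_value"].to_numpy())
            adj = np.empty(m)
            running = 0.0
            for rank_i, idx in enumerate(order):
                running = max(running, (m - rank_i) * out["p_value"].iloc[idx])
                adj[idx] = min(running, 1.0)
            out["p_adjusted"] = adj
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")
    return out


def clinical_association(
    rq: RQMatrix | pd.DataFrame,
    meta: pd.DataFrame | None = None,
    alpha: float = 0.05,
    adjust: str | None = None,
) -> AssociationReport:
    """Test each gene's expression against the study's clinical variables.

    Per gene: age → Spearman; sex, malignant-vs-nonmalignant and
    low-vs-high grade → two-sided Mann-Whitney U; tumor stage (Ta/T1/T2/T3)
    → Kruskal-Wallis, with Dunn's pairwise comparisons appended to the
    posthoc table when the global p falls below ``alpha``.  Levels with no
    samples are dropped with a warning.
    """
    frame = _as_frame(rq)
    if meta is None and isinstance(rq, RQMatrix):
        meta = rq.meta
    if meta is None:
        raise ValueError("sample metadata is required")
    missing = [s for s in frame.columns if s not in meta.index]
    if missing:
        raise ValueError(f"metadata does not cover samples: {missing}")
    meta = meta.loc[list(frame.columns)]

    rows = []
    posthoc_rows = []

    def _two_level(series: pd.Series, gene: str, expr: pd.Series, name: str) -> None:
        levels = [l for l in pd.unique(series.dropna()) if (series == l).sum() > 0]
        if len(levels) != 2:
            warnings.warn(f"variable {name!r} does not have two populated levels; skipped",
                          stacklevel=3)
            return
        a = expr[series == levels[0]].to_numpy()
        b = expr[series == levels[1]].to_numpy()
        u, p = mann_whitney(a, b)
        rows.append(
            {"gene": gene, "variable": name, "test": "mann_whitney_u",
             "statistic": u, "p_value": p}
        )

    malignant = meta["group"].map(lambda g: "nonmalignant" if g == "nonmalignant" else "malignant")
    for gene in frame.index:
        expr = frame.loc[gene]
        if "age" in meta.columns:
            age = pd.to_numeric(meta["age"], errors="coerce")
            ok = age.notna() & expr.notna()
            res = stats.spearmanr(age[ok], expr[ok])
            rows.append(
                {"gene": gene, "variable": "age", "test": "spearman",
                 "statistic": float(res.statistic), "p_value": float(res.pvalue)}
            )
        if "sex" in meta.columns:
            _two_level(meta["sex"], gene, expr, "sex")
        _two_level(malignant, gene, expr, "malignancy")
        if "grade" in meta.columns:
            grade = meta["grade"]
            tumors = grade.notna()
            _two_level(grade[tumors], gene, expr[tumors], "grade")
        if "stage" in meta.columns:
            stage = meta["stage"]
            staged = stage.notna()
            levels = [l for l in pd.unique(stage[staged])]
            samples_per_level = [expr[staged][stage[staged] == l].to_numpy() for l in levels]
            samples_per_level = [s for s in samples_per_level if len(s) > 0]
            if len(samples_per_level) >= 3:
                try:
                    h, p = stats.kruskal(*samples_per_level)
                except ValueError:  # all values identical
                    h, p = 0.0, 1.0
                rows.append(
                    {"gene": gene, "variable": "stage", "test": "kruskal_wallis",
                     "statistic": float(h), "p_value": float(p)}
                )
                if p < alpha:
                    dn = dunn_test(
                        expr[staged].to_numpy(), stage[staged].to_numpy(), adjust=adjust
                    )
                    dn.insert(0, "gene", gene)
                    dn.insert(1, "variable", "stage")
                    posthoc_rows.append(dn)

    clinical = pd.DataFrame(rows)
    posthoc = pd.concat(posthoc_rows, ignore_index=True) if posthoc_rows else None
    return AssociationReport(clinical=clinical, posthoc=posthoc)
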