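"""Microarray-based selection of candidate reference miRNAs.

Candidate normalizers are genes that (a) carry a "present" detection call in
every array, (b) show absolute fold changes below a threshold between the
nonmalignant group and each tumor group, and (c) show no significant
difference across the three groups.  The filter is run twice — on
percentile-shift-normalized data and on raw intensities — and the union of
the two selections (labels N, R, NR) forms the candidate panel, guarding
against artifacts of the array normalization itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "CandidateSelectionResult",
    "percentile_shift_normalize",
    "filter_present_all",
    "candidate_filter",
    "select_union",
]

GROUPS = ("nonmalignant", "low_grade", "high_grade")


@dataclass
class ExpressionMatrix:
    """Gene × sample intensity matrix with detection flags and group labels.

    ``scale`` marks whether intensities are linear (raw) or log2
    (post-normalization); fold changes are always computed on the linear
    scale.
    """

    intensities: pd.DataFrame
    flags: pd.DataFrame
    groups: pd.Series
    scale: Literal["linear", "log2"] = "linear"

    def __post_init__(self) -> None:
        if self.intensities.shape != self.flags.shape:
            raise ValueError("flags must have the same shape as intensities")
        if not self.intensities.index.equals(self.flags.index) or not (
            self.intensities.columns.equals(self.flags.columns)
        ):
            raise ValueError("flags must share gene and sample labels with intensities")
        vals = self.intensities.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("intensities must be finite")
        if self.scale == "linear" and np.any(vals < 0):
            raise ValueError("linear-scale intensities must be non-negative")
        missing = [s for s in self.intensities.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        unknown = set(self.groups.loc[list(self.intensities.columns)]) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")

    @property
    def genes(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    def linear_intensities(self) -> pd.DataFrame:
        """Intensities on the linear scale regardless of storage scale."""
        if self.scale == "log2":
            return 2.0**self.intensities
        return self.intensities


@dataclass
class CandidateSelectionResult:
    """Outcome of the candidate-reference filter.

    ``table`` has one row per gene with columns ``present_in_all``,
    ``fc_low_grade``, ``fc_high_grade``, ``p_value``, ``selected`` and — for
    union results — ``label`` (N, R or NR).
    """

    table: pd.DataFrame
    selected_set: set[str] = field(default_factory=set)
    labels: dict[str, str] = field(default_factory=dict)


def percentile_shift_normalize(
    m: ExpressionMatrix, percentile: float = 0.90, floor: float = 1.0
) -> ExpressionMatrix:
    """Per-sample percentile-shift normalization of a linear intensity matrix.

    Each intensity is floored, log2-transformed, and shifted per sample so
    that the sample's chosen percentile of log2 values becomes zero.  This
    removes a common multiplicative (loading) factor per array.  Detection
    flags are unchanged; output is marked log2-scale.
    """
    if not 0 < percentile < 1:
        raise ValueError("percentile must lie in (0, 1)")
    if not floor > 0:
        raise ValueError("floor must be positive")
    if m.intensities.size == 0:
        raise ValueError("cannot normalize an empty matrix")
    logx = np.log2(m.intensities.clip(lower=floor))
    shift = logx.quantile(percentile, axis=0)
    return ExpressionMatrix(
        intensities=logx.sub(shift, axis=1),
        flags=m.flags,
        groups=m.groups,
        scale="log2",
    )


def filter_present_all(m: ExpressionMatrix) -> set[str]:
    """Genes whose detection flag is "present" in every sample."""
    present = m.flags.astype(bool).all(axis=1)
    return set(present.index[present])


def _group_pvalue(values: pd.DataFrame, groups: pd.Series, test: str) -> pd.Series:
    """Across-3-group p-value per gene; zero-variance genes get p = 1."""
    cols = {g: values.columns[groups.loc[list(values.columns)] == g] for g in GROUPS}
    pvals = np.ones(len(values))
    arr = {g: values[c].to_numpy(dtype=float) for g, c in cols.items()}
    for i in range(len(values)):
        samples = [arr[g][i] for g in GROUPS]
        flat = np.concatenate(samples)
        if np.ptp(flat) == 0:
            pvals[i] = 1.0  # cannot reject equality on constant input
            continue
        if test == "kruskal_wallis":
            pvals[i] = stats.kruskal(*samples).pvalue
        elif test == "anova":
            pvals[i] = stats.f_oneway(*samples).pvalue
        else:
            raise ValueError(f"unknown group test {test!r}")
    return pd.Series(pvals, index=values.index, name="p_value")


def candidate_filter(
    m: ExpressionMatrix,
    fc_threshold: float = 1.2,
    alpha: float = 0.05,
    test: str = "kruskal_wallis",
) -> CandidateSelectionResult:
    """Filter present-in-all genes by fold change and group significance.

    Fold change for each tumor group vs nonmalignant is the linear-scale
    ratio of group means folded to be >= 1 (``max(r, 1/r)``); a gene is
    selected when it is present in all samples, both fold changes are below
    ``fc_threshold``, and the across-group p-value exceeds ``alpha`` (large p
    is the pass condition — invariance, not deregulation, is sought).
    """
    groups = m.groups.loc[m.samples]
    counts = groups.value_counts()
    if set(GROUPS) - set(counts.index):
        raise ValueError(f"all three groups required, found {sorted(counts.index)}")
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"groups with fewer than 2 samples: {small}")

    present = m.flags.astype(bool).all(axis=1)
    lin = m.linear_intensities()
    means = {g: lin.loc[:, groups[groups == g].index].mean(axis=1) for g in GROUPS}

    def _folded(ratio: pd.Series) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            r = ratio.to_numpy(dtype=float)
            out = np.where(r >= 1, r, np.where(r > 0, 1.0 / r, np.inf))
            out[~np.isfinite(r)] = np.inf
        return pd.Series(out, index=ratio.index)

    fc_low = _folded(means["low_grade"] / means["nonmalignant"])
    fc_high = _folded(means["high_grade"] / means["nonmalignant"])

    table = pd.DataFrame(
        {
            "present_in_all": present,
            "fc_low_grade": fc_low,
            "fc_high_grade": fc_high,
            "p_value": np.nan,
            "selected": False,
        }
    )
    kept = present[present].index
    if len(kept):
        table.loc[kept, "p_value"] = _group_pvalue(m.intensities.loc[kept], groups, test)
    table["selected"] = (
        table["present_in_all"]
        & (table["fc_low_grade"] < fc_threshold)
        & (table["fc_high_grade"] < fc_threshold)
        & (table["p_value"] > alpha)
    )
    return CandidateSelectionResult(
        table=table, selected_set=set(table.index[table["selected"]])
    )


def select_union(
    raw: ExpressionMatrix,
    fc_threshold: float = 1.2,
    alpha: float = 0.05,
    test: str = "kruskal_wallis",
    percentile: float = 0.90,
    floor: float = 1.0,
) -> CandidateSelectionResult:
    """Candidate filter on normalized (N) and raw (R) data, unioned (NR).

    Running the same present/fold-change/significance criteria on both the
    percentile-shift-normalized matrix and the raw intensities and taking the
    union protects the candidate panel against normalization artifacts.
    """
    if raw.scale != "linear":
        raise ValueError("select_union expects a linear-scale (raw) matrix")
    res_n = candidate_filter(
        percentile_shift_normalize(raw, percentile=percentile, floor=floor),
        fc_threshold=fc_threshold,
        alpha=alpha,
        test=test,
    )
    res_r = candidate_filter(raw, fc_threshold=fc_threshold, alpha=alpha, test=test)
    labels: dict[str, str] = {}
    for g in res_n.selected_set | res_r.selected_set:
        in_n = g in res_n.selected_set
        in_r = g in res_r.selected_set
        labels[g] = "NR" if (in_n and in_r) else ("N" if in_n else "R")

    table = res_r.table.rename(
        columns={c: f"{c}_raw" for c in ("fc_low_grade", "fc_high_grade", "p_value", "selected")}
    ).join(
        res_n.table[["fc_low_grade", "fc_high_grade", "p_value", "selected"]].rename(
            columns=lambda c: f"{c}_norm"
        )
    )
    table["label"] = pd.Series(labels).reindex(table.index).fillna("")
    table["selected"] = table["label"] != ""
    return CandidateSelectionResult(
        table=table, selected_set=set(labels), labels=labels
    )
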