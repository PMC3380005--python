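"""Efficiency-corrected relative quantification of RT-qPCR data.

Turns replicate-level quantification-cycle (Cq) measurements into
inter-run-calibrated, efficiency-corrected relative quantities (RQ) on the
linear scale, following the standard multi-reference quantification model:

    RQ_as = (1 + E_a) ** (Cq_ref(a) - Cq_as)

where ``E_a`` is the per-assay amplification efficiency (E = 1 means perfect
per-cycle doubling) and ``Cq_ref(a)`` is a per-assay reference point — by
default the across-sample mean Cq, so the geometric mean RQ of every assay
equals 1 ("arbitrary units").  Inter-run offsets are removed beforehand using
inter-run calibrator (IRC) wells repeated on every run.

Also implements the pre-screens applied before stability analysis: exclusion
of assays too weakly expressed for reliable quantification (pool Cq above a
cutoff) and de-duplication of -5p/-3p hairpin arms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CqDataset",
    "StandardCurve",
    "RQMatrix",
    "efficiency_from_slope",
    "slope_from_efficiency",
    "fit_standard_curve",
    "aggregate_replicates",
    "prescreen_measurable",
    "dedup_hairpin_arms",
    "interrun_calibrate",
    "relative_quantities",
    "normalization_factor",
    "normalize_targets",
]

WELL_COLUMNS = ["assay", "sample", "replicate", "run", "is_irc", "cq"]


@dataclass
class CqDataset:
    """Replicate-level Cq measurements with assay efficiencies and metadata.

    Parameters
    ----------
    wells
        Tidy table with columns ``assay, sample, replicate, run, is_irc, cq``.
        ``cq`` may be NaN ("no amplification"); finite values must lie in
        (0, 45).
    efficiencies
        Per-assay amplification efficiency, each in (0, 1].
    meta
        Per-sample metadata indexed by sample identifier; expected columns
        include ``group`` (nonmalignant / low_grade / high_grade) and,
        optionally, ``age``, ``sex``, ``stage``, ``grade``.
    """

    wells: pd.DataFrame
    efficiencies: pd.Series
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        missing = [c for c in WELL_COLUMNS if c not in self.wells.columns]
        if missing:
            raise ValueError(f"wells table missing columns: {missing}")
        cq = self.wells["cq"].to_numpy(dtype=float)
        finite = np.isfinite(cq)
        if np.any((cq[finite] <= 0) | (cq[finite] >= 45)):
            raise ValueError("cq values must lie in (0, 45) or be missing (NaN)")
        eff = pd.Series(self.efficiencies, dtype=float)
        if ((eff <= 0) | (eff > 1)).any():
            raise ValueError("efficiencies must lie in (0, 1]")
        self.efficiencies = eff

    @property
    def assays(self) -> list[str]:
        return sorted(self.wells["assay"].unique())

    @property
    def samples(self) -> list[str]:
        mask = ~self.wells["is_irc"].astype(bool)
        return sorted(self.wells.loc[mask, "sample"].unique())

    def groups(self) -> pd.Series:
        """Sample → group labels from the metadata table."""
        return self.meta["group"]


@dataclass
class StandardCurve:
    """Dilution-series regression of Cq on log10 input amount."""

    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    points: pd.DataFrame | None = None


@dataclass
class RQMatrix:
    """Assay × sample relative quantities on the linear scale."""

    rq: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.rq.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if np.any(finite <= 0):
            raise ValueError("relative quantities must be strictly positive")

    @property
    def genes(self) -> list[str]:
        return list(self.rq.index)

    @property
    def samples(self) -> list[str]:
        return list(self.rq.columns)


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency from a standard-curve slope.

    ``E = 10**(-1/slope) - 1``; a slope of −3.3219 cycles per log10 dilution
    corresponds to perfect doubling (E = 1).
    """
    if not slope < 0:
        raise ValueError(f"standard-curve slope must be negative, got {slope}")
    return 10.0 ** (-1.0 / slope) - 1.0


def slope_from_efficiency(efficiency: float) -> float:
    """Inverse of :func:`efficiency_from_slope`."""
    if not efficiency > 0:
        raise ValueError(f"efficiency must be positive, got {efficiency}")
    return -1.0 / np.log10(1.0 + efficiency)


def fit_standard_curve(points: Sequence[tuple[float, float]] | pd.DataFrame) -> StandardCurve:
    """Fit a dilution-series calibration curve by ordinary least squares.

    ``points`` are (log10 input amount, Cq) pairs; at least three distinct
    input levels are required.  A non-negative slope signals a failed assay
    and is rejected.
    """
    if isinstance(points, pd.DataFrame):
        df = points.iloc[:, :2].copy()
        df.columns = ["log10_input", "cq"]
    else:
        df = pd.DataFrame(points, columns=["log10_input", "cq"])
    if df["log10_input"].nunique() < 3:
        raise ValueError("standard curve requires >= 3 distinct input levels")
    fit = stats.linregress(df["log10_input"], df["cq"])
    if not fit.slope < 0:
        raise ValueError(
            f"standard-curve slope must be negative (got {fit.slope:.4g}); assay failed"
        )
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        efficiency=efficiency_from_slope(float(fit.slope)),
        points=df,
    )


def aggregate_replicates(
    d: CqDataset, include_irc: bool = False, outlier_rule: bool = False
) -> pd.DataFrame:
    """Mean Cq and percent CV per (assay, sample) across replicate wells.

    Missing wells are ignored; an (assay, sample) whose wells are all missing
    aggregates to NaN (missingness is data, not an error).  The optional
    outlier rule drops a single replicate deviating by more than 0.5 cycles
    from the replicate median; it is off by default.
    """
    wells = d.wells
    if not include_irc:
        wells = wells.loc[~wells["is_irc"].astype(bool)]

    def _agg(g: pd.Series) -> pd.Series:
        vals = g.dropna().to_numpy(dtype=float)
        if outlier_rule and len(vals) >= 3:
            dev = np.abs(vals - np.median(vals))
            worst = int(np.argmax(dev))
            if dev[worst] > 0.5:
                vals = np.delete(vals, worst)
        if len(vals) == 0:
            return pd.Series({"mean_cq": np.nan, "cv_pct": np.nan, "n_replicates": 0})
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        return pd.Series(
            {"mean_cq": mean, "cv_pct": 100.0 * sd / mean, "n_replicates": len(vals)}
        )

    out = wells.groupby(["assay", "sample"])["cq"].apply(_agg).unstack()
    out["n_replicates"] = out["n_replicates"].astype(int)
    return out


def prescreen_measurable(
    d: CqDataset, pools: Iterable[str], cq_cutoff: float = 35.0
) -> tuple[set[str], pd.DataFrame]:
    """Exclude assays whose mean Cq across pool samples exceeds the cutoff.

    Pools are pre-screening samples (e.g. equal-amount RNA mixes of the study
    samples); assays amplifying only beyond ``cq_cutoff`` cycles there cannot
    be quantified reliably and are dropped before validation.

    Returns the retained assay set and a report table listing every assay
    with its pool Cq and verdict.
    """
    pools = list(pools)
    if not pools:
        raise ValueError("pools must be a nonempty set of sample identifiers")
    present = set(d.wells["sample"].unique())
    absent = [p for p in pools if p not in present]
    if absent:
        raise ValueError(f"pool samples absent from dataset: {absent}")
    wells = d.wells[d.wells["sample"].isin(pools)]
    pool_cq = wells.groupby("assay")["cq"].mean()
    report = pd.DataFrame(
        {"pool_mean_cq": pool_cq, "excluded": pool_cq > cq_cutoff}
    ).sort_index()
    retained = set(report.index[~report["excluded"]])
    return retained, report


def dedup_hairpin_arms(
    candidates: Iterable[str],
    arms: Mapping[str, str],
    expression: Mapping[str, float] | pd.Series,
) -> set[str]:
    """Keep only the higher-expressed mature arm per pre-miRNA hairpin.

    The -5p and -3p arms of one hairpin are processed from the same precursor
    and carry redundant information; among candidate arms of a shared hairpin
    only the one with the lower mean Cq (higher expression) is retained.
    Exact Cq ties keep the lexicographically first assay name.
    """
    candidates = set(candidates)
    missing = candidates - set(arms)
    if missing:
        raise ValueError(f"arm map does not cover candidates: {sorted(missing)}")
    expr = pd.Series(dict(expression) if not isinstance(expression, pd.Series) else expression)
    kept: set[str] = set()
    by_hairpin: dict[str, list[str]] = {}
    for a in candidates:
        by_hairpin.setdefault(arms[a], []).append(a)
    for members in by_hairpin.values():
        # lower Cq wins; lexicographic name breaks exact ties deterministically
        best = min(members, key=lambda a: (expr[a], a))
        kept.add(best)
    return kept


def interrun_calibrate(d: CqDataset) -> CqDataset:
    """Remove run-to-run Cq offsets using the inter-run calibrator wells.

    For each assay, every Cq in run *r* is shifted by (grand mean IRC Cq −
    run-*r* mean IRC Cq), aligning all runs' calibrators to their common
    mean.  The operation is idempotent.
    """
    wells = d.wells.copy()
    irc = wells.loc[wells["is_irc"].astype(bool)]
    if irc.empty:
        raise ValueError("dataset contains no inter-run calibrator wells")
    runs_used = set(wells["run"].unique())
    for assay, grp in wells.groupby("assay"):
        irc_a = grp.loc[grp["is_irc"].astype(bool)]
        missing_runs = runs_used & set(grp["run"].unique()) - set(irc_a["run"].unique())
        if missing_runs:
            raise ValueError(
                f"assay {assay!r} has no IRC wells in runs {sorted(missing_runs)}"
            )
        run_means = irc_a.groupby("run")["cq"].mean()
        grand = run_means.mean()
        shift = (grand - run_means).rename("shift")
        mask = wells["assay"] == assay
        wells.loc[mask, "cq"] = (
            wells.loc[mask, "cq"] + wells.loc[mask, "run"].map(shift).to_numpy()
        )
    return CqDataset(wells=wells, efficiencies=d.efficiencies, meta=d.meta)


def relative_quantities(
    d: CqDataset,
    mode: str = "mean_center",
    calibrator: str | None = None,
    interrun: bool | None = None,
) -> RQMatrix:
    """Efficiency-corrected relative quantities from replicate-level Cq data.

    Replicates are averaged, inter-run calibration is applied when IRC wells
    exist (or as forced by ``interrun``), and each assay's mean Cq is
    converted to RQ via ``(1+E)**(Cq_ref - Cq)``.

    ``mode='mean_center'`` (default) uses the across-sample mean Cq of each
    assay as the reference point, so per-assay geometric mean RQ equals 1;
    ``mode='calibrator'`` references a named calibrator sample, whose RQ is 1.
    """
    if mode not in ("mean_center", "calibrator"):
        raise ValueError(f"unknown calibration mode {mode!r}")
    if mode == "calibrator" and calibrator is None:
        raise ValueError("calibrator mode requires a calibrator sample name")
    missing_eff = [a for a in d.assays if a not in d.efficiencies.index]
    if missing_eff:
        raise ValueError(f"assays without efficiency: {missing_eff}")

    has_irc = bool(d.wells["is_irc"].astype(bool).any())
    if interrun is None:
        interrun = has_irc
    dd = interrun_calibrate(d) if interrun else d

    agg = aggregate_replicates(dd)
    cq = agg["mean_cq"].unstack("sample")
    if mode == "mean_center":
        ref = cq.mean(axis=1)
    else:
        if calibrator not in cq.columns:
            raise ValueError(f"calibrator sample {calibrator!r} not in dataset")
        ref = cq[calibrator]
    base = 1.0 + d.efficiencies.reindex(cq.index)
    rq = base.to_numpy()[:, None] ** (ref.to_numpy()[:, None] - cq.to_numpy())
    rq = pd.DataFrame(rq, index=cq.index, columns=cq.columns)
    meta = d.meta.loc[d.meta.index.intersection(rq.columns)] if len(d.meta) else None
    return RQMatrix(
        rq=rq,
        provenance={
            "calibration_mode": mode,
            "calibrator": calibrator,
            "interrun_calibrated": bool(interrun),
        },
        meta=meta,
    )


def _as_rq_frame(rq: RQMatrix | pd.DataFrame) -> pd.DataFrame:
    return rq.rq if isinstance(rq, RQMatrix) else rq


def normalization_factor(rq: RQMatrix | pd.DataFrame, refs: Iterable[str]) -> pd.Series:
    """Per-sample normalization factor: geometric mean RQ of the reference set.

    Samples missing any reference RQ are dropped with a warning rather than
    imputed.
    """
    frame = _as_rq_frame(rq)
    refs = sorted(set(refs))
    if not refs:
        raise ValueError("reference set must be nonempty")
    missing = [r for r in refs if r not in frame.index]
    if missing:
        raise ValueError(f"reference assays not in RQ matrix: {missing}")
    sub = frame.loc[refs]
    ok = sub.notna().all(axis=0)
    if not ok.all():
        dropped = list(sub.columns[~ok])
        warnings.warn(
            f"samples dropped from normalization factor (missing reference RQ): {dropped}",
            stacklevel=2,
        )
    sub = sub.loc[:, ok]
    return pd.Series(
        np.exp(np.log(sub.to_numpy(dtype=float)).mean(axis=0)),
        index=sub.columns,
        name="NF",
    )


def normalize_targets(
    rq: RQMatrix | pd.DataFrame, targets: Iterable[str], refs: Iterable[str]
) -> pd.DataFrame:
    """Divide each target assay's RQ by the reference-set normalization factor."""
    frame = _as_rq_frame(rq)
    targets = list(targets)
    missing = [t for t in targets if t not in frame.index]
    if missing:
        raise ValueError(f"target assays not in RQ matrix: {missing}")
    nf = normalization_factor(frame, refs)
    return frame.loc[targets, nf.index].div(nf, axis=1)
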