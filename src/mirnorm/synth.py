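"""Synthetic microarray and RT-qPCR data with planted ground truth.

Emulates the statistical structure of a reference-miRNA validation study in
tumor vs. nonmalignant tissue: a three-group design (nonmalignant, low-grade,
high-grade), per-sample RNA loading variation shared by all assays, run/plate
offsets corrected by inter-run calibrators, per-assay amplification
efficiencies below perfect doubling, and replicate noise expressed as a
percent CV on the Cq scale.  A majority of planted invariant assays plus a
few planted group-deregulated assays give every downstream stage a known
truth to recover.

The generative model for a sample well is

    Cq = base_a - (loading_s + log2fc_a(group_s)) / log2(1 + E_a)
         + run_offset_r + eps,    eps ~ N(0, (cv_a/100) * mu)

so one log2 unit of extra template lowers Cq by ``1/log2(1+E)`` cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .arrayselect import ExpressionMatrix, GROUPS
from .quantify import CqDataset

__all__ = ["SimulationConfig", "PlantedTruth", "simulate_cq_dataset", "simulate_microarray"]

TUMOR_GROUPS = ("low_grade", "high_grade")


def _default_assays(n: int) -> list[str]:
    """11 miRNA-like + 3 small-RNA-like names by default, extended as needed."""
    mirs = [f"miR-sim-{i:02d}" for i in range(1, max(1, n - 3) + 1)]
    smalls = [f"RNU-sim-{c}" for c in "ABC"][: max(0, n - len(mirs))]
    return (mirs + smalls)[:n]


def _default_deregulated(assays: list[str], n_stable: int) -> dict[str, dict[str, float]]:
    """Deregulate the trailing miRNA-like assays at |log2FC| in {0.5, 1}."""
    n_dereg = len(assays) - n_stable
    shifts = [1.0, -1.0, 0.5, -0.5, 2.0, -2.0]
    dereg: dict[str, dict[str, float]] = {}
    mir_like = [a for a in assays if a.startswith("miR")]
    chosen = mir_like[-n_dereg:] if n_dereg else []
    for i, a in enumerate(chosen):
        s = shifts[i % len(shifts)]
        dereg[a] = {"low_grade": s, "high_grade": s}
    return dereg


@dataclass
class SimulationConfig:
    """Study-design parameters for the simulators.

    Defaults mirror the validation-study design: 8/8/8 arrays for candidate
    selection, 17/20/21 samples for RT-qPCR validation, triplicate wells, two
    inter-plate calibrators per run, per-assay efficiencies in [0.81, 0.88],
    mean Cq levels in [22, 28], and replicate precision of 0.15–0.35 percent
    CV on the Cq scale.
    """

    n_genes_array: int = 723
    group_sizes_array: tuple[int, int, int] = (8, 8, 8)
    group_sizes_qpcr: tuple[int, int, int] = (17, 20, 21)
    n_candidate_assays: int = 14
    n_stable: int = 10
    deregulated_spec: Mapping[str, Mapping[str, float]] | None = None
    efficiency_range: tuple[float, float] = (0.81, 0.88)
    base_cq_range: tuple[float, float] = (22.0, 28.0)
    loading_sd: float = 0.5
    replicate_cv_pct_range: tuple[float, float] = (0.15, 0.35)
    n_runs: int = 3
    run_offset_sd: float = 0.3
    ircs_per_run: int = 2
    n_deregulated_array: int = 150
    array_noise_sd: float = 0.25
    present_fraction: float = 0.14
    detection_floor: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_genes_array",
            "n_candidate_assays",
            "n_stable",
            "n_runs",
            "ircs_per_run",
        ):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("group_sizes_array", "group_sizes_qpcr"):
            sizes = getattr(self, name)
            if len(sizes) != 3 or any(int(s) < 1 for s in sizes):
                raise ValueError(f"{name} must give three counts >= 1")
        lo, hi = self.efficiency_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("efficiency_range must lie within (0, 1]")
        lo, hi = self.base_cq_range
        if not (0 < lo <= hi < 45):
            raise ValueError("base_cq_range must lie within (0, 45)")
        lo, hi = self.replicate_cv_pct_range
        if not (0 < lo <= hi):
            raise ValueError("replicate_cv_pct_range must be positive")
        if self.loading_sd < 0:
            raise ValueError("loading_sd must be >= 0")
        if self.run_offset_sd < 0:
            raise ValueError("run_offset_sd must be >= 0")
        if not 0 <= self.present_fraction <= 1:
            raise ValueError("present_fraction must lie in [0, 1]")
        if self.n_deregulated_array < 0:
            raise ValueError("n_deregulated_array must be >= 0")
        if self.array_noise_sd < 0:
            raise ValueError("array_noise_sd must be >= 0")

        self.assays = _default_assays(self.n_candidate_assays)
        if self.deregulated_spec is None:
            self.deregulated_spec = _default_deregulated(self.assays, self.n_stable)
        dereg = set(self.deregulated_spec)
        unknown = dereg - set(self.assays)
        if unknown:
            raise ValueError(f"deregulated_spec names unknown assays: {sorted(unknown)}")
        if len(self.assays) - len(dereg) != self.n_stable:
            raise ValueError(
                "n_stable inconsistent with deregulated_spec: "
                f"{len(self.assays)} assays - {len(dereg)} deregulated != {self.n_stable}"
            )
        for a, per_group in self.deregulated_spec.items():
            bad = set(per_group) - set(GROUPS)
            if bad:
                raise ValueError(f"deregulated_spec[{a!r}] has unknown groups: {sorted(bad)}")

    @property
    def stable_assays(self) -> list[str]:
        return [a for a in self.assays if a not in self.deregulated_spec]


@dataclass
class PlantedTruth:
    """Latent values the simulator drew, for recovery testing."""

    stable_assays: set[str]
    planted_log2fc: dict[tuple[str, str], float]
    loading_effects: dict[str, float]
    true_efficiency: dict[str, float] = field(default_factory=dict)
    base_cq: dict[str, float] = field(default_factory=dict)
    run_offsets: dict[str, float] = field(default_factory=dict)
    replicate_cv_pct: dict[str, float] = field(default_factory=dict)
    detection_floor: float | None = None


def _sample_frame(group_sizes, prefix: str, rng: np.random.Generator) -> pd.DataFrame:
    """Sample metadata (group, age, sex, stage, grade) for a 3-group design."""
    rows = []
    i = 0
    stage_pool = {
        "nonmalignant": [pd.NA],
        "low_grade": ["Ta", "Ta", "T1"],
        "high_grade": ["T1", "T2", "T3"],
    }
    for g, n in zip(GROUPS, group_sizes):
        for _ in range(int(n)):
            i += 1
            rows.append(
                {
                    "sample": f"{prefix}{i:03d}",
                    "group": g,
                    "age": int(rng.integers(47, 87)),
                    "sex": "F" if rng.random() < 0.2 else "M",
                    "stage": stage_pool[g][int(rng.integers(len(stage_pool[g])))],
                    "grade": {"nonmalignant": pd.NA, "low_grade": "low", "high_grade": "high"}[g],
                }
            )
    return pd.DataFrame(rows).set_index("sample")


def simulate_cq_dataset(config: SimulationConfig) -> tuple[CqDataset, PlantedTruth]:
    """Generate a replicate-level Cq dataset plus its planted truth.

    Samples are measured in triplicate; each run additionally measures
    ``ircs_per_run`` inter-run calibrator samples in triplicate for every
    assay.  Identical configs and seeds give identical output.
    """
    rng = np.random.default_rng(config.seed)
    assays = config.assays
    meta = _sample_frame(config.group_sizes_qpcr, "S", rng)
    samples = list(meta.index)

    base = dict(zip(assays, rng.uniform(*config.base_cq_range, len(assays))))
    eff = dict(zip(assays, rng.uniform(*config.efficiency_range, len(assays))))
    cv = dict(zip(assays, rng.uniform(*config.replicate_cv_pct_range, len(assays))))
    loading = dict(zip(samples, rng.normal(0.0, config.loading_sd, len(samples))))
    runs = [f"run{r + 1}" for r in range(config.n_runs)]
    run_offset = dict(zip(runs, rng.normal(0.0, config.run_offset_sd, len(runs))))
    # samples interleaved across runs; every run sees every group
    run_of = {s: runs[i % len(runs)] for i, s in enumerate(samples)}

    log2fc: dict[tuple[str, str], float] = {
        (a, g): 0.0 for a in assays for g in GROUPS
    }
    for a, per_group in config.deregulated_spec.items():
        for g, fc in per_group.items():
            log2fc[(a, g)] = float(fc)

    # IRC samples: fixed calibrator aliquots with fixed latent abundance
    irc_names = [f"IRC-{i + 1}" for i in range(config.ircs_per_run)]
    irc_level = {name: -float(i) for i, name in enumerate(irc_names)}  # log2 units

    rows: list[tuple] = []
    n_rep = 3
    for a in assays:
        slope = 1.0 / np.log2(1.0 + eff[a])
        for s in samples:
            g = meta.loc[s, "group"]
            mu = base[a] - (loading[s] + log2fc[(a, g)]) * slope + run_offset[run_of[s]]
            noise = rng.normal(0.0, cv[a] / 100.0 * mu, n_rep)
            for rep in range(n_rep):
                rows.append((a, s, rep + 1, run_of[s], False, mu + noise[rep]))
        for run in runs:
            for irc in irc_names:
                mu = base[a] - irc_level[irc] * slope + run_offset[run]
                noise = rng.normal(0.0, cv[a] / 100.0 * mu, n_rep)
                for rep in range(n_rep):
                    rows.append((a, irc, rep + 1, run, True, mu + noise[rep]))

    wells = pd.DataFrame(
        rows, columns=["assay", "sample", "replicate", "run", "is_irc", "cq"]
    )
    dataset = CqDataset(
        wells=wells, efficiencies=pd.Series(eff, name="efficiency"), meta=meta
    )
    truth = PlantedTruth(
        stable_assays=set(config.stable_assays),
        planted_log2fc=log2fc,
        loading_effects=loading,
        true_efficiency=eff,
        base_cq=base,
        run_offsets=run_offset,
        replicate_cv_pct=cv,
    )
    return dataset, truth


def simulate_microarray(config: SimulationConfig) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Generate a one-color microarray matrix with detection flags and truth.

    Intensities are log-normal: per-gene baseline plus the shared per-sample
    loading shift, plus group shifts for planted deregulated genes, plus
    Gaussian log2 noise.  The candidate qPCR panel is embedded as
    high-expressed array genes (stable ones invariant, deregulated ones with
    their planted fold change); ``n_deregulated_array`` additional background
    genes get random tumor shifts.  A spot is flagged present when its
    intensity exceeds the detection floor; by default the floor is set so
    that about ``present_fraction`` of genes are present in all samples.
    """
    rng = np.random.default_rng(config.seed + 1)
    meta = _sample_frame(config.group_sizes_array, "A", rng)
    samples = list(meta.index)
    panel = config.assays
    n_bg = max(0, config.n_genes_array - len(panel))
    genes = panel + [f"gene-{i + 1:04d}" for i in range(n_bg)]

    baseline = pd.Series(rng.uniform(2.0, 14.0, len(genes)), index=genes)
    # the candidate panel sits in the upper expression range: detectable by design
    baseline.loc[panel] = rng.uniform(12.5, 14.0, len(panel))
    loading = dict(zip(samples, rng.normal(0.0, config.loading_sd, len(samples))))

    log2fc: dict[tuple[str, str], float] = {}
    for a, per_group in config.deregulated_spec.items():
        for g in GROUPS:
            log2fc[(a, g)] = float(per_group.get(g, 0.0))
    bg_pool = [g for g in genes if g not in panel]
    n_dereg_bg = min(config.n_deregulated_array, len(bg_pool))
    dereg_bg = list(rng.choice(bg_pool, size=n_dereg_bg, replace=False))
    for g in dereg_bg:
        for grp in TUMOR_GROUPS:
            mag = rng.uniform(0.5, 3.0) * (1 if rng.random() < 0.5 else -1)
            log2fc[(g, grp)] = mag

    shift = pd.DataFrame(0.0, index=genes, columns=samples)
    for (g, grp), fc in log2fc.items():
        cols = meta.index[meta["group"] == grp]
        shift.loc[g, cols] += fc
    load_row = pd.Series(loading).reindex(samples)
    log2x = (
        baseline.to_numpy()[:, None]
        + load_row.to_numpy()[None, :]
        + shift.to_numpy()
        + rng.normal(0.0, config.array_noise_sd, (len(genes), len(samples)))
    )
    intensities = pd.DataFrame(2.0**log2x, index=genes, columns=samples)

    floor = config.detection_floor
    if floor is None:
        per_gene_min = intensities.min(axis=1)
        floor = float(np.quantile(per_gene_min, 1.0 - config.present_fraction))
        # never call the planted candidate panel absent: it models the genes
        # that did pass the vendor detection criterion on every array
        floor = min(floor, 0.999 * float(per_gene_min.loc[panel].min()))
    flags = intensities > floor

    matrix = ExpressionMatrix(
        intensities=intensities,
        flags=flags,
        groups=meta["group"],
        scale="linear",
    )
    stable = {g for g in genes if all(log2fc.get((g, grp), 0.0) == 0.0 for grp in GROUPS)}
    truth = PlantedTruth(
        stable_assays=stable,
        planted_log2fc={(g, grp): log2fc.get((g, grp), 0.0) for g in genes for grp in GROUPS},
        loading_effects=loading,
        detection_floor=floor,
    )
    return matrix, truth
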