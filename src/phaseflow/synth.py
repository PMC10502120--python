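"""Synthetic donor time series with known ground-truth growth phases.

Emulates a dense stool-metagenomics time series (3–5 samples per week,
dozens of time points) in which each taxon lives on its own internal
stochastic logistic growth curve and every stool sample reads the taxon at
a time drawn from the window of its true phase.  Per sample the generator
emits Poisson sequencing counts proportional to the realized abundance and
a log2(PTR) tied to the population's position along its growth program:

    log2ptr = b0 + b1 * g_det + noise,   g_det = (dx/dt) / (r K / 4) in [0, 1]

with g_det the normalized effective growth rate of the deterministic curve
at the sampled time.  b0 (default 0.30) is the replication-rate baseline at
zero net growth — the bottom of the in vitro E. coli log2(PTR) range — and
b1 is calibrated per taxon so that the mid-log-window mean log2(PTR) hits
the in vitro mid-log anchor of 1.25.  With that calibration stationary taxa
average ~0.30–0.31, safely below the 0.358 stationary threshold, while the
in-vitro-style stationary-window mean (which includes early-stationary
residual replication) sits near the 0.358 anchor.  The deterministic rate
(rather than the noise-realized one) is used because replication machinery
tracks the growth program, not instantaneous abundance fluctuations; a
realized-rate mapping would impose a spurious negative PTR–abundance
correlation at steady state, contradicting the null stationary association
seen in vitro.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .logistic import (
    GrowthParams,
    GrowthPhase,
    compute_phase_boundaries,
    logistic_rate,
)
from .simulate import SLGEConfig, simulate_slge
from .stats import TaxonSeries, clr_transform

__all__ = [
    "MIDLOG_PTR_ANCHOR",
    "TaxonSpec",
    "DonorSpec",
    "DonorData",
    "default_donor_spec",
    "sample_days",
    "sample_phase_time",
    "generate_taxon_series",
    "generate_donor",
]

#: In vitro mid-log mean log2(PTR) used to calibrate the PTR slope.
MIDLOG_PTR_ANCHOR = 1.25


@dataclass
class TaxonSpec:
    """Ground-truth description of one simulated taxon.

    ptr_intercept (b0) is the log2(PTR) at zero net growth; ptr_slope (b1)
    is the log2(PTR) gain per unit normalized growth rate and, when None,
    is calibrated so that the mid-log-window mean equals
    :data:`MIDLOG_PTR_ANCHOR`.  mean_depth is the expected read count at
    carrying capacity.
    """

    taxon: str
    true_phase: GrowthPhase
    growth: GrowthParams = field(default_factory=lambda: GrowthParams(r=1.2, K=100.0, x0=1.0))
    sigma: float = 0.1
    ptr_intercept: float = 0.30
    ptr_slope: float | None = None
    ptr_noise_sd: float = 0.06
    mean_depth: float = 1e5

    def __post_init__(self) -> None:
        self.true_phase = GrowthPhase(self.true_phase)
        if self.ptr_noise_sd < 0:
            raise ValueError("ptr_noise_sd must be >= 0")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.ptr_slope is None:
            m_mid = _window_mean_rate(self.growth, GrowthPhase.MIDLOG)
            self.ptr_slope = (MIDLOG_PTR_ANCHOR - self.ptr_intercept) / m_mid
        if self.ptr_slope <= 0:
            raise ValueError("ptr_slope must be > 0")


@dataclass
class DonorSpec:
    """A donor's worth of taxa plus the sampling calendar parameters."""

    donor: str
    taxa: list[TaxonSpec]
    n_timepoints: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 10:
            raise ValueError("n_timepoints must be >= 10")
        if not self.taxa:
            raise ValueError("need at least one taxon")


@dataclass
class DonorData:
    """In-memory result of one donor simulation."""

    counts: pd.DataFrame
    ptr: pd.DataFrame
    metadata: pd.DataFrame
    truth: pd.DataFrame
    series: list[TaxonSeries]


def _normalized_rate(growth: GrowthParams, t) -> np.ndarray:
    """Effective growth rate of the deterministic curve, scaled to [0, 1]."""
    return np.asarray(logistic_rate(growth, t)) / (growth.r * growth.K / 4.0)


def _phase_window(growth: GrowthParams, phase: GrowthPhase) -> tuple[float, float]:
    """Sampling window of a phase, in time-since-start coordinates.

    Growth phases use the half-max/half-min windows; the acceleration window
    starts at 0 (lag folded in).  Stationary taxa are sampled one full
    growth-transient width past s4, where the population has reached its
    steady state — the regime the flow-through gut model assumes stool
    sampling captures.
    """
    b = compute_phase_boundaries(growth)
    phase = GrowthPhase(phase)
    if phase is GrowthPhase.ACCELERATION:
        return (0.0, b.s2)
    if phase is GrowthPhase.MIDLOG:
        return (b.s2, b.s3)
    if phase is GrowthPhase.DECELERATION:
        return (b.s3, b.s4)
    start = b.s4 + (b.s4 - b.s1)
    return (start, start + (b.s4 - b.s3))


def _window_mean_rate(growth: GrowthParams, phase: GrowthPhase, n: int = 2001) -> float:
    lo, hi = _phase_window(growth, phase)
    grid = np.linspace(lo, hi, n)
    return float(np.mean(_normalized_rate(growth, grid)))


def default_donor_spec(
    donor: str = "synth",
    n_taxa: int = 12,
    n_timepoints: int = 60,
    seed: int = 0,
    ptr_noise_sd: float = 0.06,
) -> DonorSpec:
    """Default donor: taxa split evenly across the four phases.

    Growth rates cycle over 1.0–2.2 per day-equivalent, K = 100, x0 = 1 and
    sLGE noise 0.1 (the representative simulation conditions); sequencing
    depths are log-spaced so taxa occupy distinct abundance strata.
    """
    phases = [
        GrowthPhase.ACCELERATION,
        GrowthPhase.MIDLOG,
        GrowthPhase.DECELERATION,
        GrowthPhase.STATIONARY,
    ]
    rs = [1.0, 1.6, 2.2]
    depths = np.geomspace(3e4, 3e5, num=max(n_taxa, 2))
    taxa = []
    for i in range(n_taxa):
        phase = phases[i % 4]
        taxa.append(
            TaxonSpec(
                taxon=f"taxon_{i:02d}_{phase.value}",
                true_phase=phase,
                growth=GrowthParams(r=rs[(i // 4) % len(rs)], K=100.0, x0=1.0),
                sigma=0.1,
                ptr_noise_sd=ptr_noise_sd,
                mean_depth=float(depths[i]),
            )
        )
    return DonorSpec(donor=donor, taxa=taxa, n_timepoints=n_timepoints, seed=seed)


def sample_days(n_timepoints: int, rng: np.random.Generator) -> np.ndarray:
    """Collection days following a 3–5-samples-per-week calendar.

    Per week, 3–5 distinct weekdays are drawn, producing mostly 1–2-day gaps
    with occasional 3+-day (weekend-like) gaps, until ``n_timepoints`` days
    are collected.  Days are 0-based integers since the first sample.
    """
    days: list[int] = []
    week = 0
    while len(days) < n_timepoints:
        k = int(rng.integers(3, 6))
        chosen = np.sort(rng.choice(7, size=k, replace=False))
        days.extend(int(7 * week + d) for d in chosen)
        week += 1
    days = days[:n_timepoints]
    return np.asarray(days, dtype=int) - days[0]


def sample_phase_time(spec: TaxonSpec, rng: np.random.Generator) -> float:
    """One sampling time drawn uniformly from the taxon's true-phase window."""
    lo, hi = _phase_window(spec.growth, spec.true_phase)
    return float(rng.uniform(lo, hi))


@dataclass
class SimulatedTaxon:
    """Latent per-day state of one simulated taxon (pre-compositional)."""

    spec: TaxonSpec
    days: np.ndarray
    sample_times: np.ndarray
    abundance: np.ndarray
    counts: np.ndarray
    log2ptr: np.ndarray


def generate_taxon_series(
    spec: TaxonSpec, days: np.ndarray, rng: np.random.Generator
) -> SimulatedTaxon:
    """Simulate one taxon across the stool days.

    Each stool day runs an independent seeded sLGE iteration of the taxon's
    internal curve, read out at a time drawn from the true-phase window (the
    window is fixed per taxon; the within-window time is re-drawn each day).
    Counts are Poisson around mean_depth * x/K and log2(PTR) is the affine
    map of the deterministic normalized growth rate plus Gaussian noise.
    """
    days = np.asarray(days, dtype=int)
    n = len(days)
    t_s = np.array([sample_phase_time(spec, rng) for _ in range(n)])
    cfg = SLGEConfig(
        params=spec.growth,
        sigma=spec.sigma,
        t0=0.0,
        t_final=float(np.max(t_s)) + 0.02,
        n_steps=100,
        n_iter=n,
        seed=int(rng.integers(2**31)),
    )
    ens = simulate_slge(cfg)
    x = np.array([ens.abundances[i, ens.index_of(t_s[i])] for i in range(n)])
    g = _normalized_rate(spec.growth, t_s)
    log2ptr = spec.ptr_intercept + spec.ptr_slope * g + rng.normal(0.0, spec.ptr_noise_sd, n)
    counts = rng.poisson(spec.mean_depth * x / spec.growth.K).astype(int)
    return SimulatedTaxon(
        spec=spec, days=days, sample_times=t_s, abundance=x, counts=counts, log2ptr=log2ptr
    )


def generate_donor(spec: DonorSpec, outdir: str | Path | None = None) -> DonorData:
    """Generate one donor's abundance, PTR, metadata and truth tables.

    Counts per sample form a composition across the donor's taxa; the CLR
    transform of that table feeds the per-taxon series.  Fully determined by
    ``spec.seed``.  When ``outdir`` is given, writes abundance.tsv, ptr.csv,
    meta.tsv and truth.tsv in the dialects the pipeline reads.
    """
    rng = np.random.default_rng(spec.seed)
    days = sample_days(spec.n_timepoints, rng)
    sample_ids = [f"{spec.donor}_d{d:03d}" for d in days]
    sims = [generate_taxon_series(t, days, rng) for t in spec.taxa]

    counts = pd.DataFrame(
        np.stack([s.counts for s in sims]),
        index=[t.taxon for t in spec.taxa],
        columns=sample_ids,
    )
    counts.index.name = "taxon"
    ptr = pd.DataFrame(
        np.stack([s.log2ptr for s in sims]),
        index=[t.taxon for t in spec.taxa],
        columns=sample_ids,
    )
    ptr.index.name = "taxon"
    metadata = pd.DataFrame(
        {"sample_id": sample_ids, "donor_id": spec.donor, "day": days}
    )
    truth = pd.DataFrame(
        {
            "taxon": [t.taxon for t in spec.taxa],
            "true_phase": [t.true_phase.value for t in spec.taxa],
            "r": [t.growth.r for t in spec.taxa],
            "K": [t.growth.K for t in spec.taxa],
            "x0": [t.growth.x0 for t in spec.taxa],
            "sigma": [t.sigma for t in spec.taxa],
            "ptr_intercept": [t.ptr_intercept for t in spec.taxa],
            "ptr_slope": [t.ptr_slope for t in spec.taxa],
            "mean_depth": [t.mean_depth for t in spec.taxa],
        }
    )

    clr = clr_transform(counts)
    series = [
        TaxonSeries(
            taxon=t.taxon,
            donor=spec.donor,
            days=days,
            clr=clr.loc[t.taxon].to_numpy(),
            log2ptr=ptr.loc[t.taxon].to_numpy(),
        )
        for t in spec.taxa
    ]

    if outdir is not None:
        from . import io  # local import to avoid a cycle at module load

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_abundance_table(counts, outdir / "abundance.tsv")
        io.write_ptr_table(ptr, outdir / "ptr.csv")
        io.write_metadata(metadata, outdir / "meta.tsv")
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)

    return DonorData(counts=counts, ptr=ptr, metadata=metadata, truth=truth, series=series)
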