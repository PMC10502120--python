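"""Rule-based in situ growth-phase classification.

A taxon with more than ``min_points`` matched (CLR, log2 PTR) days is
assigned a phase by, in order:

1. mean log2(PTR) below the empirical stationary threshold (default 0.358,
   from in vitro E. coli stationary-phase replication rates) -> stationary;
2. FDR-adjusted regression p below alpha with positive slope -> acceleration;
3. FDR-adjusted regression p below alpha with negative slope -> deceleration;
4. otherwise -> midlog_or_indeterminate (likely mid-log, but possibly an
   underpowered acceleration/deceleration call).

The stationary threshold is applied first; a below-threshold taxon that
nevertheless shows a significant slope keeps the stationary label and the
conflict is flagged in the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stats import RegressionResult, TaxonSeries, bh_adjust, ptr_abundance_regression

__all__ = [
    "PHASE_LABELS",
    "ClassifierConfig",
    "PhaseCall",
    "classify_taxon",
    "classify_donor",
]

STATIONARY = "stationary"
ACCELERATION = "acceleration"
DECELERATION = "deceleration"
MIDLOG_OR_INDETERMINATE = "midlog_or_indeterminate"
INELIGIBLE = "ineligible"

PHASE_LABELS = (STATIONARY, ACCELERATION, DECELERATION, MIDLOG_OR_INDETERMINATE, INELIGIBLE)


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the phase-calling rule.

    stationary_threshold: mean log2(PTR) cutoff below which a taxon is called
    stationary (an experimentally determined constant, not a fitted value).
    alpha: FDR significance level for the signed slope test.  min_points:
    a taxon needs strictly more than this many matched days.
    """

    stationary_threshold: float = 0.358
    alpha: float = 0.05
    min_points: int = 5

    def __post_init__(self) -> None:
        if self.stationary_threshold < 0:
            raise ValueError("stationary_threshold must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_points < 1:
            raise ValueError("min_points must be >= 1")


@dataclass
class PhaseCall:
    """Classifier output for one taxon in one donor."""

    taxon: str
    donor: str
    phase: str
    mean_log2ptr: float
    slope: float
    p: float
    q: float
    n: int
    flag: str | None = field(default=None)


def classify_taxon(
    result: RegressionResult | None,
    mean_log2ptr: float,
    config: ClassifierConfig = ClassifierConfig(),
    taxon: str = "",
    donor: str = "",
) -> PhaseCall:
    """Apply the decision rule to one taxon's regression summary.

    ``result`` must carry a batch-adjusted q (FDR step already applied) —
    a missing q is a contract error.  ``result=None`` marks an ineligible
    taxon and yields an ``ineligible`` call rather than an exception.
    """
    if result is None:
        return PhaseCall(
            taxon=taxon,
            donor=donor,
            phase=INELIGIBLE,
            mean_log2ptr=float(mean_log2ptr),
            slope=float("nan"),
            p=float("nan"),
            q=float("nan"),
            n=0,
        )
    if result.q is None:
        raise ValueError(
            f"taxon {taxon or '<unnamed>'}: q is missing — apply the batch FDR "
            "adjustment (classify_donor) before classification"
        )
    significant = result.q < config.alpha
    if mean_log2ptr < config.stationary_threshold:
        phase = STATIONARY
        flag = "significant_slope_below_stationary_threshold" if significant else None
    elif significant and result.slope > 0:
        phase, flag = ACCELERATION, None
    elif significant and result.slope < 0:
        phase, flag = DECELERATION, None
    else:
        phase, flag = MIDLOG_OR_INDETERMINATE, None
    return PhaseCall(
        taxon=taxon,
        donor=donor,
        phase=phase,
        mean_log2ptr=float(mean_log2ptr),
        slope=result.slope,
        p=result.p,
        q=result.q,
        n=result.n,
        flag=flag,
    )


def classify_donor(
    series_list: list[TaxonSeries], config: ClassifierConfig = ClassifierConfig()
) -> list[PhaseCall]:
    """Phase calls for every taxon of one donor.

    Runs the per-taxon CLR-vs-log2(PTR) regression, Benjamini–Hochberg
    adjusts the p-values across the donor's eligible taxa (the FDR family is
    the donor), then applies the decision rule.  Output order equals input
    order; ineligible taxa are carried through with phase='ineligible'.
    """
    results = [ptr_abundance_regression(s, config.min_points) for s in series_list]
    eligible = [i for i, r in enumerate(results) if r is not None]
    if eligible:
        qs = bh_adjust([results[i].p for i in eligible])
        for i, q in zip(eligible, qs):
            results[i].q = float(q)
    return [
        classify_taxon(res, s.mean_log2ptr, config, taxon=s.taxon, donor=s.donor)
        for s, res in zip(series_list, results)
    ]
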