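"""File dialects of the pipeline.

Abundance tables are TSV (taxa rows × sample columns, integer counts),
replication-rate tables are CSV in the style of COPTR exports (taxa ×
samples, real log2(PTR), blank cells for missing estimates), metadata is a
TSV of sample_id / donor_id / day, and phase calls are written as TSV with
a JSON sidecar of per-phase counts.  Everything the package writes, the
package can read back identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import PHASE_LABELS, ClassifierConfig, PhaseCall
from .stats import TaxonSeries, clr_transform

logger = logging.getLogger("phaseflow")

__all__ = [
    "PipelineConfig",
    "read_metadata",
    "read_abundance_table",
    "read_ptr_table",
    "write_metadata",
    "write_abundance_table",
    "write_ptr_table",
    "align_samples",
    "build_donor_series",
    "write_phase_calls",
    "read_phase_calls",
]

CALL_COLUMNS = ["taxon", "donor", "phase", "mean_log2ptr", "slope", "p", "q", "n"]


@dataclass
class PipelineConfig:
    """Resolved configuration of one stats/classify run."""

    abundance: Path
    ptr: Path
    metadata: Path
    donor: str
    out: Path
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    pseudocount: float = 0.5
    max_gap: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("abundance", "ptr", "metadata"):
            p = Path(getattr(self, name))
            setattr(self, name, p)
            if not p.exists():
                raise FileNotFoundError(f"{name} file does not exist: {p}")
        self.out = Path(self.out)

    def log(self) -> None:
        logger.info("pipeline config: %s", self)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV with columns sample_id, donor_id, day (integer)."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "donor_id": str})
    missing = {"sample_id", "donor_id", "day"} - set(meta.columns)
    if missing:
        raise ValueError(f"{path}: metadata is missing columns {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicated sample_id {dup!r}")
    try:
        meta["day"] = meta["day"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: 'day' column must be integer") from exc
    return meta


def _read_cells(path: str | Path, sep: str) -> pd.DataFrame:
    table = pd.read_csv(path, sep=sep, dtype=str, index_col=0, keep_default_na=False)
    if table.index.duplicated().any():
        dup = table.index[table.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated taxon id {dup!r}")
    return table

def read_abundance_table(path: str | Path, metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    """Taxa × samples integer count table (TSV).

    Malformed cells are reported with their taxon/sample coordinates;
    duplicate taxon ids are rejected; when ``metadata`` is given, every
    sample column must appear in it.
    """
    raw = _read_cells(path, sep="\t")
    out = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        for taxon, val in raw[col].items():
            try:
                out.at[taxon, col] = int(val)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: row {taxon!r}, column {col!r}: {val!r} is not an integer count"
                ) from None
    out = out.astype(int)
    out.index.name = raw.index.name or "taxon"
    if (out < 0).any().any():
        raise ValueError(f"{path}: negative counts are not allowed")
    if metadata is not None:
        known = set(metadata["sample_id"])
        for col in out.columns:
            if col not in known:
                raise ValueError(f"{path}: sample {col!r} is absent from the metadata")
    return out


def read_ptr_table(path: str | Path) -> pd.DataFrame:
    """Taxa × samples log2(PTR) table (CSV, blanks preserved as missing).

    Negative log2(PTR) values (a known estimator artifact for PTR < 1) are
    allowed but counted in a logged warning.
    """
    raw = _read_cells(path, sep=",")
    out = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        for taxon, val in raw[col].items():
            if val.strip() == "":
                out.at[taxon, col] = np.nan
                continue
            try:
                out.at[taxon, col] = float(val)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: row {taxon!r}, column {col!r}: {val!r} is not numeric"
                ) from None
    out.index.name = raw.index.name or "taxon"
    n_neg = int((out < 0).sum().sum())
    if n_neg:
        logger.warning("%s: %d negative log2(PTR) values (PTR < 1 estimator artifact)", path, n_neg)
    return out


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def write_abundance_table(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")


def write_ptr_table(ptr: pd.DataFrame, path: str | Path) -> None:
    ptr.to_csv(path, sep=",")


def align_samples(counts: pd.DataFrame, ptr: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict both tables to their shared sample columns, logging the drops."""
    common = [c for c in counts.columns if c in set(ptr.columns)]
    dropped = (len(counts.columns) - len(common), len(ptr.columns) - len(common))
    if any(dropped):
        logger.info(
            "sample intersection: %d shared, %d abundance-only, %d PTR-only",
            len(common), dropped[0], dropped[1],
        )
    return counts[common], ptr[common]


def build_donor_series(
    counts: pd.DataFrame,
    ptr: pd.DataFrame,
    metadata: pd.DataFrame,
    donor: str,
    pseudocount: float = 0.5,
) -> list[TaxonSeries]:
    """Assemble per-taxon longitudinal series for one donor.

    Selects the donor's samples (ordered by day), CLR-transforms the full
    count table for those samples, and aligns log2(PTR) values by sample id
    (days without a PTR estimate stay missing — they drop out of PTR
    regressions but not of delta computations).
    """
    sub = metadata[metadata["donor_id"] == donor].sort_values("day")
    if sub.empty:
        raise ValueError(f"donor {donor!r} has no samples in the metadata")
    if sub["day"].duplicated().any():
        raise ValueError(f"donor {donor!r} has duplicate collection days")
    samples = [s for s in sub["sample_id"] if s in counts.columns]
    if not samples:
        raise ValueError(f"donor {donor!r}: none of its samples appear in the abundance table")
    days = sub.set_index("sample_id").loc[samples, "day"].to_numpy()
    clr = clr_transform(counts[samples], pseudocount=pseudocount)
    ptr_aligned = ptr.reindex(index=counts.index, columns=samples)
    return [
        TaxonSeries(
            taxon=str(taxon),
            donor=donor,
            days=days,
            clr=clr.loc[taxon].to_numpy(),
            log2ptr=ptr_aligned.loc[taxon].to_numpy(),
        )
        for taxon in counts.index
    ]


def _calls_frame(calls: list[PhaseCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "taxon": c.taxon,
                "donor": c.donor,
                "phase": c.phase,
                "mean_log2ptr": c.mean_log2ptr,
                "slope": c.slope,
                "p": c.p,
                "q": c.q,
                "n": c.n,
            }
            for c in calls
        ],
        columns=CALL_COLUMNS,
    )


def write_phase_calls(calls: list[PhaseCall], path: str | Path) -> tuple[Path, Path]:
    """Write phase calls as TSV plus a JSON sidecar of per-phase counts.

    Returns the two paths written; the sidecar replaces the TSV suffix with
    ``.summary.json``.
    """
    path = Path(path)
    frame = _calls_frame(calls)
    frame.to_csv(path, sep="\t", index=False)
    summary = {label: int((frame["phase"] == label).sum()) for label in PHASE_LABELS}
    sidecar = path.with_suffix(".summary.json")
    sidecar.write_text(json.dumps(summary, indent=2) + "\n")
    return path, sidecar


def read_phase_calls(path: str | Path) -> pd.DataFrame:
    """Read a phase-call TSV back (round-trip of :func:`write_phase_calls`)."""
    frame = pd.read_csv(path, sep="\t", dtype={"taxon": str, "donor": str, "phase": str})
    missing = set(CALL_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: phase-call table is missing columns {sorted(missing)}")
    return frame[CALL_COLUMNS]
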