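"""Percent-spliced-in (PSI) from junction reads and significance filters.

For skipped-exon (SE) and mutually-exclusive-exon (MXE) events, inclusion
is supported by two junctions and skipping by one, so inclusion counts are
effective-length corrected: PSI = (I/2) / ((I/2) + S). Alternative 5'/3'
splice-site events use a one-vs-one junction ratio.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

__all__ = [
    "compute_psi",
    "isoform_junction_fraction",
    "correlate_psi",
    "filter_significant_events",
    "event_type_summary",
]

TWO_JUNCTION_TYPES = {"SE", "MXE"}
FDR_CUTOFF = 0.05
DPSI_CUTOFF = 0.1


def compute_psi(inclusion_reads: float, skipping_reads: float,
                event_type: str = "SE") -> float:
    """PSI for one event from summed inclusion- and skipping-junction reads.

    Returns NaN when no reads support either form.
    """
    if event_type not in TWO_JUNCTION_TYPES | {"A3SS", "A5SS"}:
        raise ValueError(f"unknown event type {event_type!r}")
    if inclusion_reads < 0 or skipping_reads < 0:
        raise ValueError("negative junction read counts")
    inc = inclusion_reads / 2.0 if event_type in TWO_JUNCTION_TYPES else float(inclusion_reads)
    tot = inc + skipping_reads
    if tot == 0:
        return float("nan")
    return inc / tot


def isoform_junction_fraction(reads_by_isoform: dict[str, float]) -> pd.Series:
    """Fraction of junction reads from a shared exon assigned to each
    isoform; NA for all when the total is zero."""
    s = pd.Series(reads_by_isoform, dtype=float)
    if (s < 0).any():
        raise ValueError("negative junction read counts")
    total = s.sum()
    if total == 0:
        return pd.Series(np.nan, index=s.index)
    return s / total


def correlate_psi(psi_a: pd.Series, psi_b: pd.Series):
    """Pearson correlation of two PSI vectors over shared, defined events.

    Returns (r, p, slope, intercept); NA with a warning when either vector
    is constant. Requires >= 3 shared events.
    """
    shared = psi_a.index.intersection(psi_b.index)
    a = psi_a.reindex(shared).astype(float)
    b = psi_b.reindex(shared).astype(float)
    ok = a.notna() & b.notna()
    a, b = a[ok].to_numpy(), b[ok].to_numpy()
    if len(a) < 3:
        raise ValueError("need >= 3 shared events with defined PSI")
    if np.std(a) == 0 or np.std(b) == 0:
        log.warning("zero variance in a PSI vector; correlation undefined")
        return float("nan"), float("nan"), float("nan"), float("nan")
    r, p = sps.pearsonr(a, b)
    slope, intercept = np.polyfit(a, b, 1)
    return float(r), float(p), float(slope), float(intercept)


def filter_significant_events(events: pd.DataFrame,
                              fdr_cutoff: float = FDR_CUTOFF,
                              dpsi_cutoff: float = DPSI_CUTOFF) -> pd.DataFrame:
    """Keep events with FDR < ``fdr_cutoff`` and |dPSI| > ``dpsi_cutoff``,
    labeling each by the compartment with higher inclusion (positive dPSI =
    neuropil-included). Events missing either field are skipped and
    logged."""
    df = events.copy()
    missing = df["FDR"].isna() | df["dPSI"].isna()
    if missing.any():
        log.warning("%d events missing FDR or dPSI; skipped", int(missing.sum()))
        df = df.loc[~missing]
    keep = (df["FDR"] < fdr_cutoff) & (df["dPSI"].abs() > dpsi_cutoff)
    out = df.loc[keep].copy()
    out["included_in"] = np.where(out["dPSI"] > 0, "NP", "CB")
    return out.reset_index(drop=True)


def event_type_summary(events: pd.DataFrame) -> pd.DataFrame:
    """Counts and half-up-rounded percentages of kept events by type."""
    from .clip import percent_round

    counts = events["type"].value_counts()
    total = int(counts.sum())
    return pd.DataFrame({
        "count": counts,
        "percent": [percent_round(c, total) for c in counts],
    })
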