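"""Detection gaps, invasion/extinction calling, and dietary resilience.

Persistent gut populations occasionally fall below the sequencing detection
limit, producing short runs of zero counts; genuine invasion or extinction
events instead show a long all-absent phase abutting a long reliably-present
phase.  The caller here finds, per OTU, the single changepoint that best
separates such phases, subject to minimum run lengths and an abundance floor
so that single-sample blips never qualify.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import RelAbundanceTable

__all__ = [
    "GapStats",
    "EventCall",
    "ResilienceResult",
    "gap_stats",
    "call_events",
    "resilience",
]


@dataclass(frozen=True)
class GapStats:
    """Absence-run statistics of one OTU's ordered presence series."""

    otu_id: str
    subject: str
    max_consecutive_absences: int
    gap_lengths: Counter  # run length -> number of runs


@dataclass(frozen=True)
class EventCall:
    """A called invasion (absent phase then present phase) or extinction
    (mirrored).  ``boundary_index`` is the index of the first sample after
    the state change; ``present_mean`` is the mean relative abundance
    (percent) within the present phase."""

    otu_id: str
    subject: str
    kind: str  # "invasion" | "extinction"
    boundary_index: int
    pre_run: int
    post_run: int
    present_mean: float


@dataclass(frozen=True)
class ResilienceResult:
    otu_id: str
    fold_change: float
    recovered: bool
    baseline_mean: float
    baseline_sd: float
    treatment_mean: float
    washout_mean: float


def gap_stats(presence: Sequence, otu_id: str = "", subject: str = "") -> GapStats:
    """Run-length statistics of the absence runs in a presence vector."""
    vec = np.asarray(presence, dtype=bool)
    if vec.size == 0:
        raise ValueError("empty presence vector")
    runs: Counter = Counter()
    run = 0
    for p in vec:
        if not p:
            run += 1
        elif run:
            runs[run] += 1
            run = 0
    if run:
        runs[run] += 1
    return GapStats(
        otu_id=otu_id,
        subject=subject,
        max_consecutive_absences=max(runs) if runs else 0,
        gap_lengths=runs,
    )


def _best_boundary(x: np.ndarray, m: int, p: float, a_min: float):
    """Best qualifying changepoint for one series, or None.

    Scans boundaries b (start of the second phase) with both phases of
    length >= m.  Invasion needs an all-absent first phase and a second
    phase with presence fraction >= p and mean abundance >= a_min;
    extinction is the mirror.  The score is the presence-fraction contrast
    between phases; ties break toward the earliest boundary.
    """
    n = x.size
    present = x > 0
    best = None  # (score, b, kind)
    csum_pres = np.concatenate([[0], np.cumsum(present)])
    csum_x = np.concatenate([[0.0], np.cumsum(x)])
    for b in range(m, n - m + 1):
        pre_pres = csum_pres[b] / b
        post_pres = (csum_pres[n] - csum_pres[b]) / (n - b)
        if csum_pres[b] == 0:  # invasion candidate
            post_mean = (csum_x[n] - csum_x[b]) / (n - b)
            if post_pres >= p and post_mean >= a_min:
                score = post_pres - pre_pres
                if best is None or score > best[0]:
                    best = (score, b, "invasion")
        if csum_pres[n] - csum_pres[b] == 0:  # extinction candidate
            pre_mean = csum_x[b] / b
            if pre_pres >= p and pre_mean >= a_min:
                score = pre_pres - post_pres
                if best is None or score > best[0]:
                    best = (score, b, "extinction")
    return best


def call_events(
    rel: RelAbundanceTable,
    samples: Sequence,
    subject: str = "",
    m: int = 5,
    p: float = 0.8,
    a_min: float = 0.1,
) -> list[EventCall]:
    """Call at most one invasion/extinction event per OTU on a subject's
    chronologically ordered samples.

    Parameters
    ----------
    m : minimum run length of each phase (samples).
    p : minimum presence fraction of the present phase.
    a_min : minimum mean relative abundance (percent) of the present phase.
    """
    if m < 1 or not 0 < p <= 1 or a_min < 0:
        raise ValueError("invalid event parameters")
    samples = list(samples)
    sub = rel.select_samples(samples)
    calls = []
    for otu in sub.otu_ids:
        x = sub.values[otu].to_numpy(dtype=float)
        hit = _best_boundary(x, m, p, a_min)
        if hit is None:
            continue
        _, b, kind = hit
        n = x.size
        if kind == "invasion":
            present_mean = float(x[b:].mean())
        else:
            present_mean = float(x[:b].mean())
        calls.append(
            EventCall(
                otu_id=str(otu),
                subject=subject,
                kind=kind,
                boundary_index=b,
                pre_run=b,
                post_run=n - b,
                present_mean=present_mean,
            )
        )
    return calls


def resilience(
    rel: RelAbundanceTable,
    phases: Mapping[str, str],
    otu_id: str,
) -> ResilienceResult:
    """Treatment fold-change and recovery flag for one OTU.

    ``phases`` maps sample id to ``baseline`` / ``treatment`` / ``washout``
    (samples mapped to other labels are ignored).  The fold-change is the
    treatment-phase mean over the baseline mean; the population counts as
    recovered when the washout mean lies within baseline mean +/- 2 baseline
    SD.
    """
    series = rel.values[otu_id]
    phase = pd.Series({s: phases.get(s) for s in series.index})
    groups = {}
    for name in ("baseline", "treatment", "washout"):
        vals = series[phase == name]
        if len(vals) < 2:
            raise ValueError(f"need >=2 samples in phase {name!r}, got {len(vals)}")
        groups[name] = vals
    base_mean = float(groups["baseline"].mean())
    base_sd = float(groups["baseline"].std(ddof=1))
    treat_mean = float(groups["treatment"].mean())
    wash_mean = float(groups["washout"].mean())
    if base_mean == 0:
        raise ValueError("baseline mean is zero; fold-change undefined")
    return ResilienceResult(
        otu_id=str(otu_id),
        fold_change=treat_mean / base_mean,
        recovered=abs(wash_mean - base_mean) <= 2 * base_sd,
        baseline_mean=base_mean,
        baseline_sd=base_sd,
        treatment_mean=treat_mean,
        washout_mean=wash_mean,
    )
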