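"""Ks-distribution construction, modal-peak detection and per-class comparison.

Paralog Ks values pile up into peaks at the ages of duplication bursts
(e.g. whole-genome duplications); the modal bin of a fixed-width histogram
is the primary peak, and secondary local maxima reveal older events that
survive only in subsets of genes (for instance, a ~2.5 peak confined to
leaf-specific duplicates on top of a genome-wide ~0.65 peak).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .molevo import ClockParams, KaKsResult, divergence_time_ma

DEFAULT_KS_CAP = 3.5  # NG86 saturates beyond ~3; just above the oldest expected peak
DEFAULT_BIN_WIDTH = 0.1
MIN_VALUES_FOR_PEAK = 20
SECONDARY_FRACTION = 0.25
MIN_PEAK_SEPARATION_BINS = 3


@dataclass
class KsDistribution:
    """Histogram of retained Ks values for one labelled gene set."""

    label: str
    values: np.ndarray
    bin_width: float = DEFAULT_BIN_WIDTH
    counts: np.ndarray = field(default=None, repr=False)
    edges: np.ndarray = field(default=None, repr=False)
    peaks: list[tuple[float, float]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.values)


def filter_ks(results: list[KaKsResult], ks_cap: float = DEFAULT_KS_CAP) -> np.ndarray:
    """Retain finite Ks values not exceeding ``ks_cap``; drop undefined ones."""
    values = [r.Ks for r in results if r.Ks is not None and math.isfinite(r.Ks)]
    return np.array([v for v in values if 0 <= v <= ks_cap], dtype=float)


def histogram_peaks(
    values: np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH,
    secondary_fraction: float = SECONDARY_FRACTION,
    min_separation: int = MIN_PEAK_SEPARATION_BINS,
    min_values: int = MIN_VALUES_FOR_PEAK,
) -> tuple[np.ndarray, np.ndarray, list[tuple[float, float]]]:
    """Fixed-width histogram plus detected peak intervals.

    Bins are [k·w, (k+1)·w).  The primary peak is the modal bin (first such
    bin on ties).  Secondary peaks are local maxima with at least
    ``secondary_fraction`` of the modal count, at least ``min_separation``
    bins away from every already-accepted peak, accepted in descending
    count order.  With fewer than ``min_values`` values the histogram is
    still returned but no peaks are reported.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return np.array([], dtype=int), np.array([0.0]), []
    n_bins = int(np.floor(values.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    idx = np.minimum(np.floor(values / bin_width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    if values.size < min_values:
        return counts, edges, []
    modal = int(np.argmax(counts))
    threshold = secondary_fraction * counts[modal]
    local_maxima = [
        i
        for i in range(n_bins)
        if counts[i] > 0
        and (i == 0 or counts[i] >= counts[i - 1])
        and (i == n_bins - 1 or counts[i] >= counts[i + 1])
    ]
    accepted = [modal]
    for i in sorted(local_maxima, key=lambda i: (-counts[i], i)):
        if counts[i] < threshold:
            continue
        if all(abs(i - j) >= min_separation for j in accepted):
            accepted.append(i)
    peaks = [(edges[i], edges[i + 1]) for i in sorted(accepted)]
    return counts, edges, peaks


def build_distribution(
    label: str,
    results: list[KaKsResult],
    ks_cap: float = DEFAULT_KS_CAP,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> KsDistribution:
    values = filter_ks(results, ks_cap=ks_cap)
    counts, edges, peaks = histogram_peaks(values, bin_width=bin_width)
    return KsDistribution(label, values, bin_width, counts, edges, peaks)


def pair_class(class_of: dict[str, str], id1: str, id2: str) -> str:
    """A pair takes a class only when both members share it; else "mixed"."""
    c1 = class_of.get(id1, "unclassified")
    c2 = class_of.get(id2, "unclassified")
    return c1 if c1 == c2 else "mixed"


def class_ks_compare(
    results: list[KaKsResult],
    gene_classes: dict[str, str],
    ks_cap: float = DEFAULT_KS_CAP,
    bin_width: float = DEFAULT_BIN_WIDTH,
    clock: ClockParams = ClockParams(),
) -> tuple[dict[str, KsDistribution], pd.DataFrame]:
    """Per-class Ks distributions plus a peak table (with dated peaks).

    Classes partition the pairs: both-member classes, "mixed" for
    discordant pairs, and a "whole" distribution over everything.  The
    peak table reports each peak's interval, its midpoint and the
    midpoint-derived age T = Ks/2λ in Ma.
    """
    by_class: dict[str, list[KaKsResult]] = {}
    for r in results:
        by_class.setdefault(pair_class(gene_classes, r.id1, r.id2), []).append(r)
    labels = ["whole", *sorted(by_class)]
    dists = {"whole": build_distribution("whole", results, ks_cap, bin_width)}
    for label in sorted(by_class):
        dists[label] = build_distribution(label, by_class[label], ks_cap, bin_width)
    rows = []
    for label in labels:
        d = dists[label]
        for lo, hi in d.peaks:
            mid = (lo + hi) / 2.0
            rows.append(
                {
                    "class": label,
                    "peak_lo": round(lo, 10),
                    "peak_hi": round(hi, 10),
                    "peak_midpoint": round(mid, 10),
                    "T_ma_midpoint": divergence_time_ma(mid, clock),
                    "n_values": d.n,
                }
            )
    return dists, pd.DataFrame(rows, columns=[
        "class", "peak_lo", "peak_hi", "peak_midpoint", "T_ma_midpoint", "n_values",
    ])
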