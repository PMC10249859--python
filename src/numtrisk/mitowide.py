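"""Mitogenome-wide NUMT counting and the COI-vs-genome-wide regression.

If every part of the mitogenome is equally prone to nuclear integration,
the NUMT count for the 658 bp COI barcode should predict the mean count
over barcode-sized windows of the whole (annotated) mitogenome with a
log-log slope of 1. Windows are laid on the concatenation of the annotated
gene regions (13 protein-coding genes + 2 rRNAs, in genome order); the
trailing remainder shorter than one window is dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import EstimationError
from .homsearch import AlignmentScoring, find_hits
from .numtclass import filter_residual_hits
from .seqio import ScaffoldSet
from .simgen import BARCODE_LENGTH, Mitogenome

#: A window is a list of (start, end) fragments on the mitogenome; a window
#: spans a gene boundary when the concatenated coordinate does.
Window = list[tuple[int, int]]


def partition_windows(mitogenome: Mitogenome,
                      window: int = BARCODE_LENGTH) -> list[Window]:
    """Non-overlapping barcode-sized windows over the concatenated genes.

    Returns floor(total_gene_length / window) windows, each mapped back to
    one or more mitogenome intervals. An annotation totalling less than one
    window yields an empty list with a warning.
    """
    segments = [(start, end) for _name, start, end, _s in mitogenome.genes]
    total = sum(e - s for s, e in segments)
    n_windows = total // window
    if n_windows == 0:
        warnings.warn("annotated gene regions shorter than one window")
        return []
    windows: list[Window] = []
    seg_iter = iter(segments)
    cur_start, cur_end = next(seg_iter)
    for _ in range(n_windows):
        need = window
        frags: Window = []
        while need > 0:
            avail = cur_end - cur_start
            take = min(avail, need)
            frags.append((cur_start, cur_start + take))
            cur_start += take
            need -= take
            if cur_start == cur_end and need > 0:
                cur_start, cur_end = next(seg_iter)
        windows.append(frags)
    return windows


def window_sequence(mitogenome: Mitogenome, window: Window) -> str:
    return "".join(mitogenome.sequence[s:e] for s, e in window)


@dataclass
class WindowCounts:
    windows: list[Window]
    counts: list[int]
    coi_count: int
    mean_count: float


def windowed_counts(assembly: ScaffoldSet, mitogenome: Mitogenome,
                    windows: list[Window] | None = None,
                    scoring: AlignmentScoring | None = None,
                    **search_kwargs) -> WindowCounts:
    """Count NUMTs per window and for the COI barcode query.

    Each window sequence is searched independently (so a NUMT straddling
    two windows may be counted in both) and the residual-mitochondrial hit
    filter is applied per window. The assembly is expected to be
    mito-screened already.
    """
    if windows is None:
        windows = partition_windows(mitogenome)
    counts = []
    for i, win in enumerate(windows):
        q = window_sequence(mitogenome, win)
        hits = find_hits(q, assembly, scoring=scoring,
                         query_id=f"window_{i}", **search_kwargs)
        counts.append(len(filter_residual_hits(hits, query_len=len(q))))
    barcode = mitogenome.barcode
    coi_hits = find_hits(barcode, assembly, scoring=scoring,
                         query_id="barcode", **search_kwargs)
    coi_count = len(filter_residual_hits(coi_hits, query_len=len(barcode)))
    mean_count = float(np.mean(counts)) if counts else float("nan")
    return WindowCounts(windows=windows, counts=counts,
                        coi_count=coi_count, mean_count=mean_count)


def log2_regression(x, y, drop_zero: bool = True) -> tuple[float, float, float]:
    """OLS of log2(mean window count) on log2(COI count) across species.

    Pairs where either value is zero are dropped (log-undefined) when
    ``drop_zero``. Returns (slope, intercept, r_squared); fewer than three
    usable pairs raise EstimationError.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if drop_zero:
        keep = (x > 0) & (y > 0)
        x, y = x[keep], y[keep]
    if len(x) < 3:
        raise EstimationError(
            f"only {len(x)} usable pairs after dropping zeros; need >= 3")
    res = stats.linregress(np.log2(x), np.log2(y))
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)
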