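"""Read-depth aneuploidy calling.

Chromosome copy number is inferred from windowed depth against a robust
genome-wide baseline: the median of per-chromosome median depths, with one
pruning round that drops chromosomes whose ratio to the initial baseline
falls outside [0.75, 1.25] (so aneuploid chromosomes do not inflate the
baseline) before recomputing.  ``expected_copies`` states what a normal
chromosome carries: 1 when reads were mapped to a phased diploid assembly
(each haplotype chromosome is one copy), 2 against a collapsed haploid
reference.  Partial aneuploidy is located by recursive binary segmentation
on window means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import tile_windows

__all__ = [
    "windowed_coverage",
    "call_chromosome_copy_number",
    "segment_partial_aneuploidy",
    "CopyNumberCall",
]

MODE_EXPECTED = {"phased": 1, "collapsed": 2}


@dataclass
class CopyNumberCall:
    chrom: str
    median_depth: float
    baseline: float
    ratio: float
    copies: int
    mode: str
    confidence: float
    segments: list[tuple[int, int, int]] = field(default_factory=list)


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def windowed_coverage(depth: np.ndarray, window_size: int = 20_000, chrom: str = "chr") -> pd.DataFrame:
    """Arithmetic mean depth per tiling window; short last tile flagged."""
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    depth = np.asarray(depth, dtype=float)
    tiles = tile_windows(len(depth), window_size)
    sums = np.add.reduceat(depth, tiles[:, 0])
    widths = tiles[:, 1] - tiles[:, 0]
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": tiles[:, 0],
            "end": tiles[:, 1],
            "mean_depth": sums / widths,
            "short": widths < window_size,
        }
    )


def _compute_baseline(medians: pd.Series) -> float:
    initial = float(medians.median())
    if initial <= 0:
        raise ValueError("non-positive initial baseline; no usable coverage")
    ratio = medians / initial
    kept = medians[(ratio >= 0.75) & (ratio <= 1.25)]
    if kept.empty:
        raise ValueError("all chromosomes pruned; baseline undefined")
    return float(kept.median())


def call_chromosome_copy_number(
    windows: pd.DataFrame,
    mode: str = "phased",
    expected_copies: int | None = None,
) -> list[CopyNumberCall]:
    """Integer copy number per chromosome from windowed depth.

    copies = round(expected_copies * median_depth / baseline), ties rounded
    half away from zero.  Confidence is the fraction of the chromosome's
    windows whose individually implied integer equals the call.
    """
    if mode not in MODE_EXPECTED:
        raise ValueError(f"mode must be one of {sorted(MODE_EXPECTED)}")
    if expected_copies is None:
        expected_copies = MODE_EXPECTED[mode]
    counts = windows.groupby("chrom", sort=False).size()
    if (counts < 5).any():
        few = counts[counts < 5].index.tolist()
        raise ValueError(f"need >= 5 windows per chromosome; too few on {few}")

    medians = windows.groupby("chrom", sort=False)["mean_depth"].median()
    baseline = _compute_baseline(medians)

    calls = []
    for chrom, med in medians.items():
        ratio = float(med) / baseline
        copies = round_half_away(expected_copies * ratio)
        per_window = windows.loc[windows["chrom"] == chrom, "mean_depth"]
        implied = np.array(
            [round_half_away(expected_copies * d / baseline) for d in per_window]
        )
        calls.append(
            CopyNumberCall(
                chrom=str(chrom),
                median_depth=float(med),
                baseline=baseline,
                ratio=ratio,
                copies=copies,
                mode=mode,
                confidence=float(np.mean(implied == copies)),
            )
        )
    return calls


def _best_split(values: np.ndarray, min_seg: int) -> tuple[int | None, float]:
    """Exhaustive best binary split by residual sum-of-squares reduction.

    Returns (split index k so segments are [:k] and [k:], |mean difference|),
    or (None, 0.0) when no split satisfies the minimum segment size.
    """
    n = len(values)
    if n < 2 * min_seg:
        return None, 0.0
    cums = np.cumsum(values)
    total = cums[-1]
    ks = np.arange(min_seg, n - min_seg + 1)
    left_mean = cums[ks - 1] / ks
    right_mean = (total - cums[ks - 1]) / (n - ks)
    # SSE reduction of a two-mean fit: (nl*nr/n) * diff^2
    gain = ks * (n - ks) / n * (left_mean - right_mean) ** 2
    best = int(np.argmax(gain))
    return int(ks[best]), float(abs(left_mean[best] - right_mean[best]))


def segment_partial_aneuploidy(
    windows: pd.DataFrame,
    baseline: float,
    mode: str = "phased",
    expected_copies: int | None = None,
    min_seg_windows: int = 5,
    min_effect: float = 0.25,
) -> pd.DataFrame:
    """Recursive binary segmentation of one chromosome's window means.

    A split is accepted iff both sides have at least ``min_seg_windows``
    windows and the absolute mean difference reaches
    ``min_effect * baseline``.  Each resulting segment receives an integer
    copies call from its median depth against the baseline.
    """
    if expected_copies is None:
        expected_copies = MODE_EXPECTED[mode]
    values = windows["mean_depth"].to_numpy(dtype=float)
    starts = windows["start"].to_numpy()
    ends = windows["end"].to_numpy()

    boundaries: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        k, diff = _best_split(values[lo:hi], min_seg_windows)
        if k is None or diff < min_effect * baseline:
            return
        boundaries.append(lo + k)
        recurse(lo, lo + k)
        recurse(lo + k, hi)

    recurse(0, len(values))
    cuts = [0] + sorted(boundaries) + [len(values)]
    rows = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        med = float(np.median(values[a:b]))
        rows.append(
            {
                "chrom": windows["chrom"].iloc[0],
                "start": int(starts[a]),
                "end": int(ends[b - 1]),
                "n_windows": b - a,
                "median_depth": med,
                "copies": round_half_away(expected_copies * med / baseline),
            }
        )
    return pd.DataFrame(rows)
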