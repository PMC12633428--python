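"""Loss-of-heterozygosity (LOH) tract calling, classification and comparison.

An LOH tract is a maximal stretch with no heterozygous sites whose interior
length reaches ``min_len`` (default 1 kb).  Tract boundaries exclude the
flanking heterozygous sites: between consecutive het sites at 0-based
positions p and q the candidate tract is [p+1, q), of length q - p - 1.
Tracts touching one chromosome end are terminal, both ends whole-chromosome,
neither interstitial.  Because unalignable or highly divergent regions can
masquerade as homozygous, a callable-fraction guard is applied (set
``min_callable_fraction=0`` to disable it and call on raw het spacing only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import as_intervals, pairwise_overlap, total_length, intersect_intervals

__all__ = [
    "LOHTract",
    "call_loh_tracts",
    "classify_tract",
    "summarize_loh",
    "compare_strain_tracts",
    "tracts_to_frame",
]

CLS_INTERSTITIAL = "interstitial"
CLS_TERMINAL_LEFT = "terminal_left"
CLS_TERMINAL_RIGHT = "terminal_right"
CLS_WHOLE = "whole_chromosome"


@dataclass(frozen=True)
class LOHTract:
    chrom: str
    start: int  # 0-based half-open
    end: int
    n_callable: int
    cls: str

    @property
    def length(self) -> int:
        return self.end - self.start


def classify_tract(start: int, end: int, chrom_length: int) -> str:
    """Terminal/interstitial/whole-chromosome label from end contact."""
    left = start == 0
    right = end == chrom_length
    if left and right:
        return CLS_WHOLE
    if left:
        return CLS_TERMINAL_LEFT
    if right:
        return CLS_TERMINAL_RIGHT
    return CLS_INTERSTITIAL


def call_loh_tracts(
    het_positions,
    callable_mask,
    chrom_length: int,
    chrom: str = "chr",
    min_len: int = 1_000,
    min_callable_fraction: float = 0.5,
) -> list[LOHTract]:
    """Call maximal het-free tracts on one chromosome.

    ``het_positions`` are 0-based positions of heterozygous sites;
    ``callable_mask`` a sorted-disjoint interval set of callable bases.
    A chromosome with no het site yields one whole-chromosome tract.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    pos = np.unique(np.asarray(het_positions, dtype=np.int64))
    if len(pos) and (pos.min() < 0 or pos.max() >= chrom_length):
        raise ValueError("het position outside chromosome bounds")
    mask = as_intervals(callable_mask)

    # candidate gaps: [0, first), (p_i, p_{i+1}) interiors, (last, L)
    starts = np.concatenate([[0], pos + 1])
    ends = np.concatenate([pos, [chrom_length]])

    tracts: list[LOHTract] = []
    for s, e in zip(starts, ends):
        length = e - s
        if length < min_len:
            continue
        n_callable = total_length(intersect_intervals(mask, [[s, e]]))
        if n_callable / length < min_callable_fraction:
            continue
        tracts.append(
            LOHTract(chrom, int(s), int(e), n_callable, classify_tract(int(s), int(e), chrom_length))
        )
    return tracts


def summarize_loh(tracts: list[LOHTract], genome_length: int) -> dict:
    """Per-class counts/lengths and the genome fraction homozygous.

    The genome fraction is also reported rounded to one decimal percent
    (``percent_homozygous``), the precision at which such genome-wide
    figures are usually quoted.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    by_chrom: dict[str, list[LOHTract]] = {}
    for t in sorted(tracts, key=lambda t: (t.chrom, t.start)):
        prev = by_chrom.setdefault(t.chrom, [])
        if prev and t.start < prev[-1].end:
            raise ValueError(f"overlapping tracts on {t.chrom} at {t.start}")
        prev.append(t)

    per_class = {}
    for cls in (CLS_INTERSTITIAL, CLS_TERMINAL_LEFT, CLS_TERMINAL_RIGHT, CLS_WHOLE):
        lens = [t.length for t in tracts if t.cls == cls]
        per_class[cls] = {
            "count": len(lens),
            "total_length": int(sum(lens)),
            "mean_length": float(np.mean(lens)) if lens else None,
            "max_length": int(max(lens)) if lens else None,
        }
    total = sum(t.length for t in tracts)
    fraction = total / genome_length
    return {
        "per_class": per_class,
        "n_tracts": len(tracts),
        "total_length": int(total),
        "genome_fraction_homozygous": fraction,
        "percent_homozygous": round(100.0 * fraction, 1),
    }


def compare_strain_tracts(
    tracts_a: list[LOHTract],
    tracts_b: list[LOHTract],
    reciprocal_overlap: float = 0.5,
) -> dict:
    """Partition two strains' tract sets into shared and unique.

    A pair is shared iff the overlap covers at least ``reciprocal_overlap``
    of BOTH tract lengths; matching is greedy on decreasing overlap and
    each tract is matched at most once.
    """
    candidates = []
    for i, ta in enumerate(tracts_a):
        for j, tb in enumerate(tracts_b):
            if ta.chrom != tb.chrom:
                continue
            ov = pairwise_overlap(ta.start, ta.end, tb.start, tb.end)
            if ov == 0:
                continue
            if ov >= reciprocal_overlap * ta.length and ov >= reciprocal_overlap * tb.length:
                candidates.append((ov, i, j))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    shared = []
    for ov, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        shared.append((tracts_a[i], tracts_b[j], ov))
    return {
        "shared": shared,
        "unique_a": [t for i, t in enumerate(tracts_a) if i not in used_a],
        "unique_b": [t for j, t in enumerate(tracts_b) if j not in used_b],
    }


def tracts_to_frame(tracts: list[LOHTract]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": t.chrom,
                "start": t.start,
                "end": t.end,
                "length": t.length,
                "n_callable": t.n_callable,
                "cls": t.cls,
            }
            for t in tracts
        ],
        columns=["chrom", "start", "end", "length", "n_callable", "cls"],
    )
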