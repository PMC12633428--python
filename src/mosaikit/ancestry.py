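"""Parent-of-origin painting of hybrid haplotypes and switch typing.

Each 10-kb window of a hybrid haplotype is compared to the two candidate
parental references: a window whose divergence to parent P is comparable to
within-species heterozygosity while its divergence to parent S sits at
between-species levels is assigned to P, and vice versa.  The decision
statistic is the signed difference d_S - d_P against a symmetric threshold
``delta`` placed between the two regimes.  Runs of same-label windows are
smoothed into segments; label changes shared reciprocally by the two
haplotypes are mitotic crossovers, one-sided changes entering homozygous
(LOH) sequence are non-reciprocal LOH, and the rest stay unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import hetwin
from .intervals import pairwise_overlap

__all__ = [
    "parent_divergence_windows",
    "label_windows",
    "segment_labels",
    "detect_switches",
    "SwitchEvent",
    "AncestrySegment",
]

LABEL_P = "P"
LABEL_S = "S"
LABEL_AMBIGUOUS = "ambiguous"
LABEL_UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class AncestrySegment:
    haplotype: str
    chrom: str
    start: int
    end: int
    label: str
    n_windows: int
    mean_d_p: float
    mean_d_s: float


@dataclass(frozen=True)
class SwitchEvent:
    chrom: str
    start: int  # interval containing the switch (window-boundary region)
    end: int
    haplotypes: tuple[str, ...]
    type: str  # reciprocal_crossover | nonreciprocal_LOH | unclassified


def _mismatch_variants(hap: np.ndarray, ref: np.ndarray, chrom: str) -> pd.DataFrame:
    if len(hap) != len(ref):
        raise ValueError("haplotype and reference must share coordinates")
    pos = np.flatnonzero(hap != ref)
    return pd.DataFrame(
        {"chrom": chrom, "pos": pos, "zygosity": hetwin.ZYGOSITY_HOM_DIFF, "quality": np.nan}
    )


def parent_divergence_windows(
    hap: dict[str, np.ndarray],
    ref_p: dict[str, np.ndarray],
    ref_s: dict[str, np.ndarray],
    mask: dict[str, np.ndarray] | None = None,
    window_size: int = 10_000,
    min_aligned: int = 2_000,
) -> pd.DataFrame:
    """Windowed divergence of one haplotype to each parental reference.

    Sequences are coordinate-aligned encoded arrays (substitution-only
    simulation or projected alignments).  Returns one row per window with
    d_P, d_S and an ``ok`` flag requiring sufficient aligned sites in both
    comparisons.
    """
    chrom_lengths = {c: len(s) for c, s in hap.items()}
    if mask is None:
        mask = {c: np.array([[0, n]], dtype=np.int64) for c, n in chrom_lengths.items()}
    frames = {}
    for tag, ref in (("P", ref_p), ("S", ref_s)):
        var = pd.concat(
            [_mismatch_variants(hap[c], ref[c], c) for c in chrom_lengths],
            ignore_index=True,
        )
        frames[tag] = hetwin.windowed_divergence(
            var, mask, chrom_lengths, window_size=window_size, min_aligned=min_aligned
        )
    wp, ws = frames["P"], frames["S"]
    out = wp[["chrom", "start", "end"]].copy()
    out["d_P"] = wp["value"]
    out["d_S"] = ws["value"]
    out["n_aligned"] = wp["n_aligned"]
    out["ok"] = (wp["status"] == "ok") & (ws["status"] == "ok")
    return out


def label_windows(windows: pd.DataFrame, delta: float = 0.01) -> pd.DataFrame:
    """Assign P/S/ambiguous/unassigned to each divergence window.

    P iff d_S - d_P >= delta; S iff d_P - d_S >= delta; ambiguous when the
    difference is smaller; unassigned when either comparison lacked
    aligned sites.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    diff = windows["d_S"] - windows["d_P"]
    label = np.where(
        diff >= delta, LABEL_P, np.where(-diff >= delta, LABEL_S, LABEL_AMBIGUOUS)
    )
    ok = windows["ok"] if "ok" in windows.columns else ~(
        windows["d_P"].isna() | windows["d_S"].isna()
    )
    out = windows.copy()
    out["label"] = np.where(ok, label, LABEL_UNASSIGNED)
    return out


def _runs(labels: list[str]) -> list[list]:
    runs = []
    for lab in labels:
        if runs and runs[-1][0] == lab:
            runs[-1][1] += 1
        else:
            runs.append([lab, 1])
    return runs


def _smooth(labels: list[str], min_run: int) -> list[str]:
    """Iterative run smoothing until fixpoint (deterministic)."""
    informative = {LABEL_P, LABEL_S}
    while True:
        runs = _runs(labels)
        changed = False
        for i, (lab, _n) in enumerate(runs):
            left = runs[i - 1][0] if i > 0 else None
            right = runs[i + 1][0] if i + 1 < len(runs) else None
            if lab in (LABEL_AMBIGUOUS, LABEL_UNASSIGNED):
                flanks = {x for x in (left, right) if x in informative}
                if len(flanks) == 1 and (
                    (left in informative or left is None)
                    and (right in informative or right is None)
                ):
                    runs[i][0] = next(iter(flanks))
                    changed = True
                    break
        if not changed:
            for i, (lab, n) in enumerate(runs):
                if lab in informative and n < min_run:
                    left = runs[i - 1][0] if i > 0 else None
                    right = runs[i + 1][0] if i + 1 < len(runs) else None
                    other = LABEL_S if lab == LABEL_P else LABEL_P
                    if left == other and right == other:
                        runs[i][0] = other
                        changed = True
                        break
        if not changed:
            return [lab for lab, n in runs for _ in range(n)]
        labels = [lab for lab, n in runs for _ in range(n)]


def segment_labels(
    windows: pd.DataFrame,
    min_run: int = 3,
    haplotype: str = "A",
) -> list[AncestrySegment]:
    """Merge labeled windows into maximal same-label ancestry segments.

    Ambiguous/unassigned runs bounded by a single informative label are
    absorbed into it; informative runs shorter than ``min_run`` flanked on
    both sides by the same other label are flipped.  Adjacent equal labels
    then merge into segments.
    """
    segments: list[AncestrySegment] = []
    for chrom, grp in windows.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        labels = _smooth(list(grp["label"]), min_run)
        grp = grp.assign(_label=labels)
        run_id = (grp["_label"] != grp["_label"].shift()).cumsum()
        for _, seg in grp.groupby(run_id):
            segments.append(
                AncestrySegment(
                    haplotype=haplotype,
                    chrom=str(chrom),
                    start=int(seg["start"].iloc[0]),
                    end=int(seg["end"].iloc[-1]),
                    label=seg["_label"].iloc[0],
                    n_windows=len(seg),
                    mean_d_p=float(seg["d_P"].mean()),
                    mean_d_s=float(seg["d_S"].mean()),
                )
            )
    return segments


def _boundaries(segments: list[AncestrySegment]) -> list[dict]:
    """Label-change points between consecutive informative segments."""
    informative = [s for s in segments if s.label in (LABEL_P, LABEL_S)]
    out = []
    for a, b in zip(informative[:-1], informative[1:]):
        if a.chrom != b.chrom or a.label == b.label:
            continue
        out.append(
            {
                "chrom": a.chrom,
                "start": a.end,
                "end": max(b.start, a.end),
                "from": a.label,
                "to": b.label,
                "haplotype": a.haplotype,
            }
        )
    return out


def detect_switches(
    segments_a: list[AncestrySegment],
    segments_b: list[AncestrySegment],
    loh_tracts=None,
    window_size: int = 10_000,
    tolerance_windows: int = 1,
) -> list[SwitchEvent]:
    """Classify ancestry-label switches on a pair of haplotypes.

    A pair of boundaries, one per haplotype, within ``tolerance_windows``
    windows of each other and with opposite label transitions is a
    reciprocal crossover.  An unpaired boundary whose flank enters a
    region where both haplotypes carry the same label, or that falls in a
    called LOH tract, is typed non-reciprocal LOH; anything else is
    unclassified.
    """
    chroms_a = {s.chrom for s in segments_a}
    chroms_b = {s.chrom for s in segments_b}
    ba = _boundaries(segments_a)
    bb = _boundaries(segments_b)
    tol = tolerance_windows * window_size
    loh_tracts = loh_tracts or []

    used_b: set[int] = set()
    events: list[SwitchEvent] = []
    unpaired: list[dict] = []
    for a in ba:
        match = None
        for j, b in enumerate(bb):
            if j in used_b or b["chrom"] != a["chrom"]:
                continue
            if abs(b["start"] - a["start"]) <= tol and (b["from"], b["to"]) == (
                a["to"],
                a["from"],
            ):
                match = j
                break
        if match is not None:
            used_b.add(match)
            b = bb[match]
            events.append(
                SwitchEvent(
                    chrom=a["chrom"],
                    start=min(a["start"], b["start"]),
                    end=max(a["end"], b["end"]),
                    haplotypes=(a["haplotype"], b["haplotype"]),
                    type="reciprocal_crossover",
                )
            )
        else:
            unpaired.append(a)
    unpaired.extend(b for j, b in enumerate(bb) if j not in used_b)

    def label_at(segments, chrom, pos):
        for s in segments:
            if s.chrom == chrom and s.start <= pos < s.end:
                return s.label
        return None

    for u in unpaired:
        in_loh = any(
            t.chrom == u["chrom"]
            and pairwise_overlap(t.start, t.end, u["start"] - tol, u["end"] + tol) > 0
            for t in loh_tracts
        )
        # does the boundary enter/leave a region where both haplotypes agree?
        left = (
            label_at(segments_a, u["chrom"], u["start"] - 1),
            label_at(segments_b, u["chrom"], u["start"] - 1),
        )
        right = (
            label_at(segments_a, u["chrom"], u["end"]),
            label_at(segments_b, u["chrom"], u["end"]),
        )
        shared_flank = (left[0] == left[1] and left[0] is not None) or (
            right[0] == right[1] and right[0] is not None
        )
        kind = "nonreciprocal_LOH" if (in_loh or shared_flank) else "unclassified"
        events.append(
            SwitchEvent(
                chrom=u["chrom"],
                start=u["start"],
                end=u["end"],
                haplotypes=(u["haplotype"],),
                type=kind,
            )
        )
    events.sort(key=lambda e: (e.chrom, e.start))
    return events
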