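"""Windowed heterozygosity and divergence, and site-degeneracy classes.

Heterozygosity here is the fraction of alignable sites per window at which
the two haplotypes of one individual differ.  Divergence of a strain from a
reference is computed with the half-weight rule: a site where only one of
the strain's two haplotypes differs from the reference contributes half as
much as a site where both differ.  Coding positions are additionally
classified by degeneracy (0/2/3/4-fold) so heterozygosity can be contrasted
between selectively constrained and neutral site classes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .intervals import (
    coverage_in_windows,
    positions_in_intervals,
    tile_windows,
)
from .sequtil import CODON_TABLE

__all__ = [
    "windowed_heterozygosity",
    "windowed_divergence",
    "classify_degeneracy",
    "degeneracy_genome_table",
    "het_by_site_class",
    "ZYGOSITY_HET",
    "ZYGOSITY_HOM_DIFF",
]

ZYGOSITY_HET = "heterozygous"
ZYGOSITY_HOM_DIFF = "homozygous_diff"

WINDOW_COLUMNS = ["chrom", "start", "end", "n_aligned", "n_variant", "value", "status"]


def _validate_variants(variants: pd.DataFrame) -> pd.DataFrame:
    required = {"chrom", "pos", "zygosity"}
    missing = required - set(variants.columns)
    if missing:
        raise ValueError(f"variant table lacks columns: {sorted(missing)}")
    bad = set(variants["zygosity"].unique()) - {ZYGOSITY_HET, ZYGOSITY_HOM_DIFF}
    if bad:
        raise ValueError(f"unknown zygosity values: {sorted(bad)}")
    if len(variants) and (variants["pos"] < 0).any():
        raise ValueError("negative variant position (internal coordinates are 0-based)")
    return variants


def _apply_quality_filter(variants: pd.DataFrame, min_quality: float) -> pd.DataFrame:
    if "quality" not in variants.columns:
        warnings.warn(
            "variant table has no quality column; all sites treated as passing",
            stacklevel=3,
        )
        return variants
    qual = variants["quality"]
    keep = qual.isna() | (qual >= min_quality)
    return variants[keep]


def _windowed(
    variants: pd.DataFrame,
    mask: dict[str, np.ndarray],
    chrom_lengths: dict[str, int],
    window_size: int,
    min_aligned: int,
    min_quality: float,
    weights: dict[str, float],
) -> pd.DataFrame:
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    variants = _validate_variants(variants)
    variants = _apply_quality_filter(variants, min_quality)

    rows = []
    for chrom, length in chrom_lengths.items():
        tiles = tile_windows(length, window_size)
        iv = mask.get(chrom, np.empty((0, 2), dtype=np.int64))
        n_aligned = coverage_in_windows(iv, length, window_size)

        sub = variants[variants["chrom"] == chrom]
        pos = sub["pos"].to_numpy(dtype=np.int64)
        if len(pos) and pos.max() >= length:
            raise ValueError(f"variant position beyond chromosome {chrom} length {length}")
        w = sub["zygosity"].map(weights).to_numpy(dtype=float)
        inside = positions_in_intervals(pos, iv)
        n_variant = np.bincount(
            pos[inside] // window_size, weights=w[inside], minlength=len(tiles)
        )[: len(tiles)]

        ok = n_aligned >= min_aligned
        value = np.divide(n_variant, n_aligned, out=np.full(len(tiles), np.nan), where=ok)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": tiles[:, 0],
                    "end": tiles[:, 1],
                    "n_aligned": n_aligned,
                    "n_variant": n_variant,
                    "value": value,
                    "status": np.where(ok, "ok", "excluded"),
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=WINDOW_COLUMNS)
    return pd.concat(rows, ignore_index=True)


def windowed_heterozygosity(
    variants: pd.DataFrame,
    mask: dict[str, np.ndarray],
    chrom_lengths: dict[str, int],
    window_size: int = 10_000,
    min_aligned: int = 2_000,
    min_quality: float = 60,
) -> pd.DataFrame:
    """Per-window heterozygosity: qualifying variant sites / alignable sites.

    Windows tile each chromosome end to end (last window may be short);
    windows with fewer than ``min_aligned`` alignable sites are excluded and
    carry no value.  In heterozygosity mode every qualifying site counts
    with weight 1 (a self-comparison of two haplotypes has only
    heterozygous sites).
    """
    weights = {ZYGOSITY_HET: 1.0, ZYGOSITY_HOM_DIFF: 1.0}
    return _windowed(variants, mask, chrom_lengths, window_size, min_aligned, min_quality, weights)


def windowed_divergence(
    variants: pd.DataFrame,
    mask: dict[str, np.ndarray],
    chrom_lengths: dict[str, int],
    window_size: int = 10_000,
    min_aligned: int = 2_000,
    min_quality: float = 0,
) -> pd.DataFrame:
    """Per-window divergence from a reference, averaged over both haplotypes.

    A site where only one of the strain's haplotypes differs from the
    reference (heterozygous) contributes weight 0.5; a site where both
    differ (homozygous_diff) contributes 1.
    """
    weights = {ZYGOSITY_HET: 0.5, ZYGOSITY_HOM_DIFF: 1.0}
    return _windowed(variants, mask, chrom_lengths, window_size, min_aligned, min_quality, weights)


def classify_degeneracy(cds: str) -> np.ndarray:
    """Degeneracy class per CDS position (standard genetic code).

    Class k means k nucleotides at that codon position encode the same
    amino acid, except that a position where only the original base works
    is reported as class 0 (the conventional "0-fold" label); possible
    values are therefore {0, 2, 3, 4}.  Positions in codons containing a
    non-ACGT base are labeled -1 (unknown) and excluded downstream.
    """
    if len(cds) % 3:
        raise ValueError("CDS length must be divisible by 3")
    cds = cds.upper()
    classes = np.empty(len(cds), dtype=np.int8)
    bases = "ACGT"
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if any(b not in bases for b in codon):
            classes[i : i + 3] = -1
            continue
        aa = CODON_TABLE[codon]
        if aa == "*" and i + 3 < len(cds):
            raise ValueError(f"internal stop codon at CDS position {i}")
        for offset in range(3):
            n_syn = sum(
                1
                for b in bases
                if b != codon[offset]
                and CODON_TABLE[codon[:offset] + b + codon[offset + 1 :]] == aa
            )
            classes[i + offset] = 0 if n_syn == 0 else n_syn + 1
    return classes


def degeneracy_genome_table(transcripts, genome: dict[str, np.ndarray]) -> pd.DataFrame:
    """Map CDS degeneracy classes onto genome coordinates.

    ``transcripts`` is an iterable of objects exposing ``chrom``, ``strand``
    and ``cds`` (list of 0-based half-open genomic intervals); ``genome``
    maps chromosome name to an encoded uint8 sequence.  Returns a table
    with columns ``chrom, pos, fold`` (one row per coding position;
    positions covered by several transcripts keep the first annotation).
    """
    from .sequtil import decode, revcomp

    frames = []
    for t in transcripts:
        if not t.cds:
            continue
        seq_codes = np.concatenate(
            [genome[t.chrom][s:e] for s, e in sorted(t.cds)]
        )
        gpos = np.concatenate(
            [np.arange(s, e, dtype=np.int64) for s, e in sorted(t.cds)]
        )
        if t.strand == "-":
            seq_codes = revcomp(seq_codes)
            gpos = gpos[::-1]
        classes = classify_degeneracy(decode(seq_codes))
        frames.append(pd.DataFrame({"chrom": t.chrom, "pos": gpos, "fold": classes}))
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "fold"])
    table = pd.concat(frames, ignore_index=True)
    table = table[table["fold"] >= 0]
    return table.drop_duplicates(subset=["chrom", "pos"], keep="first").reset_index(drop=True)


def het_by_site_class(
    variants: pd.DataFrame,
    degeneracy: pd.DataFrame,
    mask: dict[str, np.ndarray],
    min_quality: float = 0,
) -> pd.DataFrame:
    """Heterozygosity stratified by degeneracy class.

    For each class: (# heterozygous sites of that class) / (# callable
    sites of that class).  Classes with no callable sites are reported with
    a missing value.
    """
    variants = _validate_variants(variants)
    if "quality" in variants.columns:
        variants = _apply_quality_filter(variants, min_quality)

    callable_parts = []
    for chrom, grp in degeneracy.groupby("chrom", sort=False):
        iv = mask.get(chrom, np.empty((0, 2), dtype=np.int64))
        inside = positions_in_intervals(grp["pos"].to_numpy(), iv)
        callable_parts.append(grp[inside])
    callable_sites = (
        pd.concat(callable_parts, ignore_index=True)
        if callable_parts
        else degeneracy.iloc[0:0]
    )

    het = variants[variants["zygosity"] == ZYGOSITY_HET][["chrom", "pos"]]
    merged = callable_sites.merge(het.assign(is_het=True), on=["chrom", "pos"], how="left")
    merged["is_het"] = merged["is_het"].notna()

    rows = []
    for cls in (0, 2, 3, 4):
        sub = merged[merged["fold"] == cls]
        n_callable = len(sub)
        n_het = int(sub["is_het"].sum())
        rows.append(
            {
                "fold": cls,
                "n_callable": n_callable,
                "n_het": n_het,
                "value": n_het / n_callable if n_callable else np.nan,
            }
        )
    return pd.DataFrame(rows)
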