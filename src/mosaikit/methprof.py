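"""TSS-anchored metaprofiles of DNA base modifications (5mC CpG, 6mA ApT).

Per-site modification fractions are anchored at transcription start sites
with the TSS at offset 0 and downstream positive regardless of strand:
offset = pos - tss on the + strand and tss - pos on the - strand.  The
profile value at an offset is the median fraction over all contributing
(gene, site) pairs pooled across genes (an alternative per-gene-median
reduction is available via ``per_gene=True``).  A simple autocorrelation
statistic estimates the dominant downstream periodicity that nucleosome
linker methylation produces.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "filter_mod_sites",
    "tss_metaprofile",
    "estimate_periodicity",
]

MOD_COLUMNS = ["chrom", "pos", "context", "n_reads", "n_modified"]
CONTEXTS = ("CpG", "ApT")


def filter_mod_sites(sites: pd.DataFrame, min_reads: int = 5) -> pd.DataFrame:
    """Drop sites with fewer than ``min_reads`` mapped reads."""
    missing = set(MOD_COLUMNS) - set(sites.columns)
    if missing:
        raise ValueError(f"modification table lacks columns: {sorted(missing)}")
    if len(sites) and ((sites["n_reads"] < 0).any() or (sites["n_modified"] < 0).any()):
        raise ValueError("negative read or modification counts")
    if len(sites) and (sites["n_modified"] > sites["n_reads"]).any():
        raise ValueError("n_modified exceeds n_reads")
    return sites[sites["n_reads"] >= min_reads].reset_index(drop=True)


def tss_metaprofile(
    sites: pd.DataFrame,
    tss_records: pd.DataFrame,
    context: str,
    flank_up: int = 1_000,
    flank_down: int = 3_000,
    high_confidence_only: bool = True,
    per_gene: bool = False,
) -> pd.DataFrame:
    """Median modification fraction per offset relative to the TSS.

    ``tss_records`` needs columns chrom, pos, strand, gene_id and
    optionally high_confidence.  Duplicated (chrom, pos, strand) TSS
    records are deduplicated so a gene annotated twice does not weight the
    median.  Offsets with no contributing site are absent from the output.
    """
    if context not in CONTEXTS:
        raise ValueError(f"context must be one of {CONTEXTS}")
    present = set(sites["context"].unique()) if len(sites) else set()
    if present and context not in present:
        raise ValueError(f"requested context {context!r} absent from table ({sorted(present)})")
    sites = sites[sites["context"] == context]

    tss = tss_records.drop_duplicates(subset=["chrom", "pos", "strand"])
    if high_confidence_only and "high_confidence" in tss.columns:
        tss = tss[tss["high_confidence"].astype(bool)]

    pieces = []
    for chrom, tgrp in tss.groupby("chrom", sort=False):
        sub = sites[sites["chrom"] == chrom]
        if sub.empty:
            continue
        pos = sub["pos"].to_numpy(dtype=np.int64)
        order = np.argsort(pos)
        pos = pos[order]
        frac = (sub["n_modified"].to_numpy(dtype=float) / sub["n_reads"].to_numpy(dtype=float))[order]
        for _, rec in tgrp.iterrows():
            if rec["strand"] == "+":
                lo, hi = rec["pos"] - flank_up, rec["pos"] + flank_down
            else:
                lo, hi = rec["pos"] - flank_down, rec["pos"] + flank_up
            i, j = np.searchsorted(pos, [lo, hi + 1])
            if i == j:
                continue
            offs = pos[i:j] - rec["pos"] if rec["strand"] == "+" else rec["pos"] - pos[i:j]
            pieces.append(
                pd.DataFrame({"offset": offs, "frac": frac[i:j], "gene_id": rec["gene_id"]})
            )
    if not pieces:
        return pd.DataFrame(columns=["offset", "median_frac", "n_sites"])
    pairs = pd.concat(pieces, ignore_index=True)
    if per_gene:
        pairs = (
            pairs.groupby(["offset", "gene_id"], sort=False)["frac"].median().reset_index()
        )
    prof = (
        pairs.groupby("offset")["frac"]
        .agg(median_frac="median", n_sites="size")
        .reset_index()
        .sort_values("offset", ignore_index=True)
    )
    return prof


def estimate_periodicity(
    profile: pd.DataFrame,
    lag_range: tuple[int, int] = (50, 500),
    min_autocorr: float = 0.2,
    offset_range: tuple[int, int] | None = None,
) -> dict:
    """Dominant period of the downstream profile by autocorrelation peak.

    The profile is restricted to ``offset_range`` (default: all
    non-negative offsets), linearly interpolated onto every integer offset,
    mean-centered, and the normalized autocorrelation is evaluated at each
    lag in ``lag_range``.  The lag maximizing it is returned only if the
    autocorrelation there reaches ``min_autocorr``; otherwise period=None.
    """
    lo_lag, hi_lag = lag_range
    sub = profile.dropna(subset=["median_frac"])
    if offset_range is None:
        sub = sub[sub["offset"] >= 0]
    else:
        sub = sub[(sub["offset"] >= offset_range[0]) & (sub["offset"] <= offset_range[1])]
    if len(sub) < 3:
        return {"period": None, "autocorr": 0.0}
    offsets = sub["offset"].to_numpy()
    grid = np.arange(offsets.min(), offsets.max() + 1)
    y = np.interp(grid, offsets, sub["median_frac"].to_numpy(dtype=float))
    if hi_lag >= len(grid):
        raise ValueError("lag_range exceeds the available profile span")
    y = y - y.mean()
    denom = float(np.dot(y, y))
    if denom == 0.0:
        return {"period": None, "autocorr": 0.0}
    lags = np.arange(lo_lag, hi_lag + 1)
    ac = np.array([np.dot(y[:-k], y[k:]) / denom for k in lags])
    best = int(np.argmax(ac))
    if ac[best] < min_autocorr:
        return {"period": None, "autocorr": float(ac[best])}
    return {"period": int(lags[best]), "autocorr": float(ac[best])}
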