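"""Readers and writers for the plain-text genomics formats the toolkit uses.

Conventions: internal coordinates are 0-based half-open everywhere;
conversion happens here and only here (VCF and GFF3 are 1-based inclusive
on disk, BED/bedGraph 0-based half-open).  Only uncompressed text files are
handled — every binary-adjacent format has a plain-TSV fallback so nothing
ever requires an index.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .sequtil import decode, encode
from .txrules import TranscriptModel

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_vcf",
    "write_vcf",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_modsites",
    "write_modsites",
    "read_gff3",
    "write_gff3",
    "read_variants_tsv",
    "read_bundle",
    "DatasetBundle",
]


def _header_lines(params: dict | None) -> list[str]:
    lines = [f"# mosaikit {__version__}"]
    if params:
        lines.append("# params: " + json.dumps(params, sort_keys=True, default=str))
    return lines


# --------------------------------------------------------------------- FASTA


def read_fasta(path) -> dict[str, np.ndarray]:
    seqs: dict[str, np.ndarray] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = encode("".join(chunks))
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = encode("".join(chunks))
    return seqs


def write_fasta(path, seqs: dict[str, np.ndarray], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, codes in seqs.items():
            fh.write(f">{name}\n")
            s = decode(codes)
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ----------------------------------------------------------------------- VCF

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##source=mosaikit {version}\n"
    '##INFO=<ID=ZYG,Number=1,Type=String,Description="Zygosity class">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def write_vcf(path, variants: pd.DataFrame, seqs: dict[str, np.ndarray] | None = None) -> None:
    """Variant table (internal 0-based) to a minimal uncompressed VCF."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(version=__version__))
        for row in variants.itertuples(index=False):
            ref = "N"
            if seqs is not None and row.chrom in seqs:
                code = seqs[row.chrom][row.pos]
                ref = decode(np.array([code], dtype=np.uint8))
            qual = getattr(row, "quality", ".")
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t.\t{ref}\t.\t{qual}\t.\tZYG={row.zygosity}\n"
            )


def read_vcf(path) -> pd.DataFrame:
    """Minimal VCF reader; skips indels/multi-allelic records (counted).

    Returns the internal variant table (chrom, pos 0-based, zygosity,
    quality).  Zygosity comes from the ZYG INFO key when present, else
    from the GT of the first sample (0/1 -> heterozygous, 1/1 ->
    homozygous_diff); records without either default to heterozygous.
    """
    rows = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8:
                raise ValueError(f"{path}:{lineno}: malformed VCF record")
            chrom, pos_s, _id, ref, alt, qual, _filt, info = parts[:8]
            pos = int(pos_s)
            if pos < 1:
                raise ValueError(f"{path}:{lineno}: VCF position {pos} is not 1-based")
            if len(ref) != 1 or ("," in alt) or (alt not in (".", "*") and len(alt) != 1):
                n_skipped += 1
                continue
            zyg = None
            for kv in info.split(";"):
                if kv.startswith("ZYG="):
                    zyg = kv[4:]
            if zyg is None and len(parts) >= 10 and "GT" in parts[8]:
                gt = parts[9].split(":")[0].replace("|", "/")
                alleles = set(gt.split("/"))
                zyg = "heterozygous" if len(alleles) > 1 else "homozygous_diff"
            rows.append(
                {
                    "chrom": chrom,
                    "pos": pos - 1,
                    "zygosity": zyg or "heterozygous",
                    "quality": float(qual) if qual not in (".", "") else np.nan,
                }
            )
    df = pd.DataFrame(rows, columns=["chrom", "pos", "zygosity", "quality"])
    df.attrs["n_skipped"] = n_skipped
    return df


def read_variants_tsv(path) -> pd.DataFrame:
    """chrom, pos (1-based), zygosity[, quality] TSV fallback."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df["pos"] = df["pos"].astype(int) - 1
    return df


# ----------------------------------------------------------------------- BED


def read_bed(path) -> pd.DataFrame:
    """BED3+ -> DataFrame (chrom, start, end[, name]); bad records dropped."""
    rows = []
    n_bad = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            start, end = int(parts[1]), int(parts[2])
            if end <= start:
                n_bad += 1
                continue
            rows.append(
                {"chrom": parts[0], "start": start, "end": end,
                 "name": parts[3] if len(parts) > 3 else "."}
            )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    df.attrs["n_rejected"] = n_bad
    return df


def write_bed(path, frame: pd.DataFrame, params: dict | None = None) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(params):
            fh.write(line + "\n")
        cols = [c for c in ("chrom", "start", "end", "name", "score", "strand") if c in frame.columns]
        frame[cols].to_csv(fh, sep="\t", header=False, index=False)


def bed_to_mask(frame: pd.DataFrame) -> dict[str, np.ndarray]:
    from .intervals import merge_intervals

    return {
        str(chrom): merge_intervals(grp[["start", "end"]].to_numpy())
        for chrom, grp in frame.groupby("chrom", sort=False)
    }


# ------------------------------------------------------------------ bedGraph


def write_bedgraph(path, tracks: dict[str, np.ndarray]) -> None:
    """Per-base depth compressed into constant-value runs."""
    with open(path, "w") as fh:
        for chrom, depth in tracks.items():
            depth = np.asarray(depth)
            change = np.flatnonzero(np.diff(depth)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(depth)]])
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{depth[s]:g}\n")


def read_bedgraph(path, chrom_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Expand a bedGraph back to per-base tracks (missing bases = 0)."""
    tracks = {c: np.zeros(L) for c, L in chrom_lengths.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.split("\t")
            if chrom in tracks:
                tracks[chrom][int(s) : int(e)] = float(v)
    return tracks


# ------------------------------------------------------------------ ModSites


def write_modsites(path, sites: pd.DataFrame) -> None:
    sites.to_csv(path, sep="\t", index=False)


def read_modsites(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# --------------------------------------------------------------------- GFF3


def write_gff3(path, transcripts: list[TranscriptModel], extra_attrs: dict | None = None) -> None:
    """Transcript models to GFF3 with read_count attributes.

    '-'-strand transcript starts are read back from the rightmost exon
    end, so coordinate order on disk is genomic regardless of strand.
    """
    extra_attrs = extra_attrs or {}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"#!mosaikit {__version__}\n")
        by_gene: dict[str, list[TranscriptModel]] = {}
        for t in transcripts:
            by_gene.setdefault(t.gene_id, []).append(t)
        for gene_id, ts in by_gene.items():
            chrom, strand = ts[0].chrom, ts[0].strand
            g_start = min(t.span[0] for t in ts)
            g_end = max(t.span[1] for t in ts)
            fh.write(
                f"{chrom}\tmosaikit\tgene\t{g_start + 1}\t{g_end}\t.\t{strand}\t.\tID={gene_id}\n"
            )
            for t in ts:
                attrs = f"ID={t.id};Parent={gene_id};read_count={t.read_count}"
                for k, v in extra_attrs.get(t.id, {}).items():
                    attrs += f";{k}={v}"
                fh.write(
                    f"{chrom}\tmosaikit\tmRNA\t{t.span[0] + 1}\t{t.span[1]}\t.\t{strand}\t.\t{attrs}\n"
                )
                for s, e in t.exons:
                    fh.write(
                        f"{chrom}\tmosaikit\texon\t{s + 1}\t{e}\t.\t{strand}\t.\tParent={t.id}\n"
                    )
                for s, e in t.cds:
                    fh.write(
                        f"{chrom}\tmosaikit\tCDS\t{s + 1}\t{e}\t.\t{strand}\t.\tParent={t.id}\n"
                    )


def _parse_attrs(s: str) -> dict[str, str]:
    out = {}
    for kv in s.strip().split(";"):
        if "=" in kv:
            k, v = kv.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path) -> list[TranscriptModel]:
    """GFF3 -> TranscriptModel list (mRNA/exon/CDS features)."""
    mrna: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: GFF3 record needs 9 columns")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs_s = parts
            attrs = _parse_attrs(attrs_s)
            iv = (int(start) - 1, int(end))
            if ftype in ("mRNA", "transcript", "lnc_RNA"):
                mrna[attrs["ID"]] = {
                    "gene_id": attrs.get("Parent", attrs["ID"]),
                    "chrom": chrom,
                    "strand": strand,
                    "read_count": int(attrs.get("read_count", 0)),
                    "exons": [],
                    "cds": [],
                }
            elif ftype == "exon":
                mrna[attrs["Parent"]]["exons"].append(iv)
            elif ftype == "CDS":
                mrna[attrs["Parent"]]["cds"].append(iv)
    return [
        TranscriptModel(
            id=tid,
            gene_id=d["gene_id"],
            chrom=d["chrom"],
            strand=d["strand"],
            exons=tuple(d["exons"]),
            cds=tuple(d["cds"]),
            read_count=d["read_count"],
        )
        for tid, d in mrna.items()
    ]


# -------------------------------------------------------------------- bundle


class DatasetBundle:
    """Parsed handles for a simulator output directory."""

    def __init__(self, directory):
        d = Path(directory)
        self.directory = d
        self.config = json.loads((d / "config.json").read_text()) if (d / "config.json").exists() else None
        self.truth = json.loads((d / "truth.json").read_text()) if (d / "truth.json").exists() else None
        self.hybrid_a = read_fasta(d / "hybrid_A.fasta") if (d / "hybrid_A.fasta").exists() else None
        self.hybrid_b = read_fasta(d / "hybrid_B.fasta") if (d / "hybrid_B.fasta").exists() else None
        self.variants = read_vcf(d / "variants.vcf") if (d / "variants.vcf").exists() else None
        self.mask = (
            bed_to_mask(read_bed(d / "mask.bed")) if (d / "mask.bed").exists() else None
        )
        self.modsites = read_modsites(d / "modsites.tsv") if (d / "modsites.tsv").exists() else None
        self.transcripts = read_gff3(d / "transcripts.gff3") if (d / "transcripts.gff3").exists() else None
        self._validate()

    def _validate(self):
        names = []
        if self.hybrid_a:
            names.append(("hybrid_A.fasta", set(self.hybrid_a)))
        if self.hybrid_b:
            names.append(("hybrid_B.fasta", set(self.hybrid_b)))
        if self.variants is not None and len(self.variants):
            names.append(("variants.vcf", set(self.variants["chrom"].unique())))
        if len(names) > 1:
            ref_file, ref = names[0]
            for fname, s in names[1:]:
                if not (s & ref):
                    raise ValueError(
                        f"chromosome names in {fname} do not match {ref_file}"
                    )


def read_bundle(directory) -> DatasetBundle:
    return DatasetBundle(directory)
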