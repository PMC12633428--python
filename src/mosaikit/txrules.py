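"""Transcript-curation rules for long-read derived gene models.

Isoform collapse pipelines over-merge neighbouring genes whose isoforms
overlap on the same strand, emit spurious 5'-truncated isoforms, and often
annotate translation initiation at an internal ATG.  This module implements
the curation logic that repairs each of these:

* ``decouple_genes`` — split a merged gene wherever isoforms share no
  coding sequence (connected components of CDS overlap);
* ``filter_isoforms`` — drop isoforms with <5 supporting reads or <5% of
  the gene's total reads;
* ``select_primary_isoform`` — abundance/CDS-length cascade choosing one
  representative isoform per gene;
* ``build_kozak_model`` / ``extend_orf`` — a position weight matrix of the
  start-codon (Kozak) context trained on non-extendable ORFs, used to move
  annotated starts to qualifying upstream in-frame ATGs;
* ``classify_antisense`` — antisense lncRNA / mRNA overlap calls with
  promoter-architecture labels.

Genomic coordinates are 0-based half-open; transcript coordinates are
strand-aware (0 = 5' end of the spliced transcript).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .intervals import pairwise_overlap
from .sequtil import STOP_CODONS, decode, revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptModel",
    "KozakModel",
    "AntisenseCall",
    "decouple_genes",
    "filter_isoforms",
    "select_primary_isoform",
    "build_kozak_model",
    "extend_orf",
    "classify_antisense",
    "DEFAULT_KOZAK_OFFSETS",
]

DEFAULT_KOZAK_OFFSETS = tuple(range(-9, 0)) + (3, 4, 5)

_BASES = "ACGT"


@dataclass(frozen=True)
class TranscriptModel:
    """One isoform: exon/CDS structure plus full-length read support."""

    id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()
    read_count: int = 0

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.id}: strand must be '+' or '-'")
        exons = tuple(sorted(tuple(e) for e in self.exons))
        object.__setattr__(self, "exons", exons)
        object.__setattr__(self, "cds", tuple(sorted(tuple(c) for c in self.cds)))
        prev_end = -1
        for s, e in exons:
            if e <= s:
                raise ValueError(f"{self.id}: empty exon [{s}, {e})")
            if s < prev_end:
                raise ValueError(f"{self.id}: overlapping exons")
            prev_end = e
        for s, e in self.cds:
            if not any(s >= xs and e <= xe for xs, xe in exons):
                raise ValueError(f"{self.id}: CDS interval [{s}, {e}) not inside an exon")
        if self.cds and self.cds_length % 3:
            raise ValueError(f"{self.id}: CDS length {self.cds_length} not divisible by 3")

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def tss(self) -> int:
        """Genomic position of the transcript start (strand-aware)."""
        return self.exons[0][0] if self.strand == "+" else self.exons[-1][1] - 1

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    # --- transcript <-> genome coordinate maps -------------------------
    def exon_positions(self) -> np.ndarray:
        """Genomic position of every transcript base, 5'->3' order."""
        parts = [np.arange(s, e, dtype=np.int64) for s, e in self.exons]
        pos = np.concatenate(parts)
        return pos[::-1] if self.strand == "-" else pos

    def spliced_sequence(self, genome: dict[str, np.ndarray]) -> np.ndarray:
        seq = np.concatenate([genome[self.chrom][s:e] for s, e in self.exons])
        return revcomp(seq) if self.strand == "-" else seq

    def cds_start_in_transcript(self) -> int | None:
        """Transcript coordinate of the first CDS base (A of the ATG)."""
        if not self.cds:
            return None
        gpos = self.exon_positions()
        first = self.cds[-1][1] - 1 if self.strand == "-" else self.cds[0][0]
        idx = np.flatnonzero(gpos == first)
        if len(idx) != 1:
            raise ValueError(f"{self.id}: CDS start not on an exon")
        return int(idx[0])

    def transcript_interval_to_genomic(self, t_start: int, t_end: int) -> tuple[tuple[int, int], ...]:
        """Map a transcript interval to a sorted tuple of genomic intervals."""
        gpos = np.sort(self.exon_positions()[t_start:t_end])
        breaks = np.flatnonzero(np.diff(gpos) != 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [len(gpos)]])
        return tuple((int(gpos[a]), int(gpos[b - 1]) + 1) for a, b in zip(starts, ends))


def _cds_overlap(a: TranscriptModel, b: TranscriptModel) -> int:
    return sum(
        pairwise_overlap(s1, e1, s2, e2) for s1, e1 in a.cds for s2, e2 in b.cds
    )


def _exon_overlap(a: TranscriptModel, b: TranscriptModel) -> int:
    return sum(
        pairwise_overlap(s1, e1, s2, e2) for s1, e1 in a.exons for s2, e2 in b.exons
    )


def decouple_genes(isoforms: list[TranscriptModel]) -> list[list[TranscriptModel]]:
    """Split an over-merged gene into connected components of CDS overlap.

    Two isoforms belong to the same gene iff they are joined by a chain of
    pairwise same-strand CDS genomic overlaps (>= 1 bp).  A coding-free
    isoform inside a coding group is attached to the component with the
    largest exonic overlap.
    """
    if not isoforms:
        return []
    chroms = {(t.chrom, t.strand) for t in isoforms}
    if len(chroms) > 1:
        raise ValueError("isoforms of one merged gene must share chromosome and strand")

    coding = [t for t in isoforms if t.cds]
    noncoding = [t for t in isoforms if not t.cds]

    parent = list(range(len(coding)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(coding)):
        for j in range(i + 1, len(coding)):
            if _cds_overlap(coding[i], coding[j]) >= 1:
                parent[find(i)] = find(j)

    comps: dict[int, list[TranscriptModel]] = {}
    for i, t in enumerate(coding):
        comps.setdefault(find(i), []).append(t)
    components = [sorted(c, key=lambda t: t.id) for c in comps.values()]
    components.sort(key=lambda c: min(t.span[0] for t in c))

    for t in noncoding:
        if not components:
            components.append([t])
            continue
        overlaps = [max(_exon_overlap(t, m) for m in comp) for comp in components]
        k = int(np.argmax(overlaps))
        logger.info("non-coding isoform %s attached to component %d by exon overlap", t.id, k)
        components[k].append(t)
    return components


def filter_isoforms(
    isoforms: list[TranscriptModel],
    min_reads: int = 5,
    min_fraction: float = 0.05,
) -> list[TranscriptModel]:
    """Drop weakly supported isoforms of one gene.

    An isoform is retained iff read_count >= min_reads AND
    read_count / total >= min_fraction, where total is the gene's read sum
    BEFORE filtering.  If nothing survives, the most abundant isoform is
    rescued (ties broken by id) so every gene keeps a model.
    """
    if not isoforms:
        return []
    total = sum(t.read_count for t in isoforms)
    if total == 0:
        raise ValueError("all isoform read counts are zero")
    kept = [
        t
        for t in isoforms
        if t.read_count >= min_reads and t.read_count / total >= min_fraction
    ]
    if not kept:
        rescue = max(isoforms, key=lambda t: (t.read_count, t.id))
        logger.info("gene %s: no isoform passed filters; rescued %s", rescue.gene_id, rescue.id)
        kept = [rescue]
    return kept


def select_primary_isoform(isoforms: list[TranscriptModel]) -> tuple[str, int]:
    """Choose one representative isoform per gene; returns (id, rule).

    Cascade: (1) the longest-CDS isoform is also the most abundant -> pick
    it (equal CDS lengths: most abundant; remaining ties: lexicographic
    id); (2) else pick the longest-CDS isoform if its reads reach 50% of
    the most abundant isoform's; (3) else pick the most abundant isoform
    if its CDS reaches 80% of the longest CDS; (4) else the longest-CDS
    isoform, so very short (likely 5'-truncated) models never win by
    abundance alone.
    """
    if not isoforms:
        raise ValueError("empty isoform set")
    longest = min(isoforms, key=lambda t: (-t.cds_length, -t.read_count, t.id))
    most_reads = max(t.read_count for t in isoforms)
    abundant = min(
        (t for t in isoforms if t.read_count == most_reads),
        key=lambda t: (-t.cds_length, t.id),
    )
    if longest.read_count == most_reads:
        return longest.id, 1
    if longest.read_count >= 0.5 * most_reads:
        return longest.id, 2
    if abundant.cds_length >= 0.8 * longest.cds_length:
        return abundant.id, 3
    return longest.id, 4


@dataclass
class KozakModel:
    """Additive log-odds model of the start-codon context.

    ``log_odds[offset]`` is a 4-vector (A,C,G,T) of base-2 log-odds of the
    training frequency (pseudocount 1) against the genomic background;
    positions 0..2 are the invariant ATG and are not scored.
    """

    offsets: tuple[int, ...]
    log_odds: dict[int, np.ndarray]
    background: np.ndarray
    training_scores: np.ndarray
    training_ids: tuple[str, ...] = ()
    p25: float = field(init=False)

    def __post_init__(self):
        self.p25 = float(np.percentile(self.training_scores, 25)) if len(
            self.training_scores
        ) else float("nan")

    def score(self, seq_codes: np.ndarray, atg_pos: int) -> float | None:
        """Score the context around an ATG at transcript position atg_pos.

        Returns None when the window extends outside the sequence.
        """
        vals = []
        for off in self.offsets:
            p = atg_pos + off
            if p < 0 or p >= len(seq_codes) or seq_codes[p] > 3:
                return None
            vals.append(self.log_odds[off][seq_codes[p]])
        return float(sum(vals))


def genome_background(genome: dict[str, np.ndarray]) -> np.ndarray:
    counts = np.zeros(4, dtype=np.int64)
    for seq in genome.values():
        counts += np.bincount(seq[seq < 4], minlength=4)
    return counts / counts.sum()


def upstream_start_candidates(
    transcript: TranscriptModel, genome: dict[str, np.ndarray]
) -> list[int]:
    """Transcript positions of upstream in-frame ATGs reachable stop-free.

    A candidate is an ATG in the 5' UTR, in frame with the annotated start,
    with no in-frame stop codon between it and the annotated start (a stop
    would terminate the extended ORF before reaching the annotated CDS).
    """
    c0 = transcript.cds_start_in_transcript()
    if c0 is None:
        return []
    seq = transcript.spliced_sequence(genome)
    out = []
    for u in range(c0 % 3, c0, 3):
        codon = decode(seq[u : u + 3])
        if codon != "ATG":
            continue
        stop_free = all(
            decode(seq[k : k + 3]) not in STOP_CODONS for k in range(u + 3, c0, 3)
        )
        if stop_free:
            out.append(u)
    return out


def build_kozak_model(
    transcripts: list[TranscriptModel],
    genome: dict[str, np.ndarray],
    offsets: tuple[int, ...] = DEFAULT_KOZAK_OFFSETS,
    background: np.ndarray | None = None,
) -> KozakModel:
    """Train the Kozak PWM on primary transcripts with non-extendable ORFs.

    Training transcripts are those with an annotated CDS and no reachable
    upstream in-frame ATG; transcripts whose context window falls outside
    the transcript are skipped (logged).  Per-offset counts use pseudocount
    1; log-odds are base 2 against ``background`` (default: genomic
    nucleotide frequencies).
    """
    if background is None:
        background = genome_background(genome)
    counts = {off: np.ones(4, dtype=float) for off in offsets}  # pseudocount 1
    contexts: list[tuple[str, np.ndarray, int]] = []
    for t in transcripts:
        if not t.cds:
            continue
        if upstream_start_candidates(t, genome):
            continue
        seq = t.spliced_sequence(genome)
        c0 = t.cds_start_in_transcript()
        if c0 + min(offsets) < 0 or c0 + max(offsets) >= len(seq):
            logger.info("transcript %s skipped: context window outside transcript", t.id)
            continue
        window = seq[[c0 + off for off in offsets]]
        if np.any(window > 3):
            logger.info("transcript %s skipped: ambiguous base in context", t.id)
            continue
        contexts.append((t.id, seq, c0))
        for off in offsets:
            counts[off][seq[c0 + off]] += 1
    if not contexts:
        raise ValueError("empty Kozak training set")
    n = len(contexts)
    log_odds = {
        off: np.log2((counts[off] / (n + 4)) / background) for off in offsets
    }
    model = KozakModel(
        offsets=tuple(offsets),
        log_odds=log_odds,
        background=np.asarray(background, dtype=float),
        training_scores=np.empty(0),
        training_ids=tuple(tid for tid, _, _ in contexts),
    )
    model.training_scores = np.array(
        [model.score(seq, c0) for _, seq, c0 in contexts], dtype=float
    )
    model.p25 = float(np.percentile(model.training_scores, 25))
    return model


def extend_orf(
    transcript: TranscriptModel,
    model: KozakModel,
    genome: dict[str, np.ndarray],
    choose: str = "first",
) -> tuple[TranscriptModel, dict]:
    """Move the annotated start to a qualifying upstream in-frame ATG.

    A candidate qualifies when its Kozak score exceeds the model's training
    25th percentile OR the score of the annotated start.  With
    ``choose='first'`` the 5'-most qualifying candidate wins (maximal
    extension); ``choose='best'`` takes the highest-scoring one.  The
    decision record carries the scores of every candidate.
    """
    if choose not in ("first", "best"):
        raise ValueError("choose must be 'first' or 'best'")
    record = {
        "transcript_id": transcript.id,
        "extended": False,
        "annotated_score": None,
        "candidates": [],
        "chosen": None,
    }
    if not transcript.cds:
        return transcript, record
    seq = transcript.spliced_sequence(genome)
    c0 = transcript.cds_start_in_transcript()
    annotated_score = model.score(seq, c0)
    record["annotated_score"] = annotated_score

    qualifying = []
    for u in upstream_start_candidates(transcript, genome):
        s = model.score(seq, u)
        ok = s is not None and (
            s > model.p25 or (annotated_score is not None and s > annotated_score)
        )
        record["candidates"].append({"t_pos": u, "score": s, "qualifies": bool(ok)})
        if ok:
            qualifying.append((u, s))
    if not qualifying:
        return transcript, record
    if choose == "first":
        u, s = qualifying[0]
    else:
        u, s = max(qualifying, key=lambda c: (c[1], -c[0]))

    cds_end_t = c0 + transcript.cds_length
    new_cds = transcript.transcript_interval_to_genomic(u, cds_end_t)
    extended = replace(transcript, cds=new_cds)
    record.update(extended=True, chosen={"t_pos": u, "score": s})
    return extended, record


@dataclass(frozen=True)
class AntisenseCall:
    mrna_id: str
    lncrna_id: str
    overlap_fraction: float
    promoter_class: str


def classify_antisense(
    mrnas: list[TranscriptModel],
    lncrnas: list[TranscriptModel],
    min_overlap: float = 0.30,
    promoter_window: int = 300,
) -> list[AntisenseCall]:
    """Call antisense lncRNA / protein-coding gene pairs.

    overlap_fraction = antisense exonic overlap / mRNA transcript length;
    a call is made iff it reaches ``min_overlap`` (i.e. >= 30% of the
    coding transcript by default).  The promoter class reflects where the
    lncRNA starts: inside the mRNA gene body with a sense-isoform TSS of
    the same gene within ``promoter_window`` bp -> bidirectional_internal;
    inside the body otherwise -> unidirectional_internal; within the
    window of the body -> adjacent; anything farther -> distal.
    """
    for t in list(mrnas) + list(lncrnas):
        if t.strand not in "+-":
            raise ValueError(f"{t.id}: missing strand")
    bodies: dict[str, tuple[int, int]] = {}
    sense_tss: dict[str, list[int]] = {}
    for m in mrnas:
        s, e = m.span
        if m.gene_id in bodies:
            bs, be = bodies[m.gene_id]
            bodies[m.gene_id] = (min(bs, s), max(be, e))
        else:
            bodies[m.gene_id] = (s, e)
        sense_tss.setdefault(m.gene_id, []).append(m.tss)

    calls = []
    for m in mrnas:
        for l in lncrnas:
            if l.chrom != m.chrom or l.strand == m.strand:
                continue
            ov = _exon_overlap(m, l)
            frac = ov / m.transcript_length
            if frac < min_overlap:
                continue
            body = bodies[m.gene_id]
            tss = l.tss
            inside = body[0] <= tss < body[1]
            if inside and any(
                abs(tss - st) <= promoter_window for st in sense_tss[m.gene_id]
            ):
                cls = "bidirectional_internal"
            elif inside:
                cls = "unidirectional_internal"
            elif body[0] - promoter_window <= tss < body[1] + promoter_window:
                cls = "adjacent"
            else:
                cls = "distal"
            calls.append(AntisenseCall(m.id, l.id, frac, cls))
    return calls
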