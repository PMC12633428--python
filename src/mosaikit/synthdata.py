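"""Synthetic allodiploid hybrid genomes with planted, logged events.

The generator emulates the structure the analysis modules assume: two
parental lineages diverged ~2.7% at the nucleotide level, each carrying
within-lineage heterozygosity in the 0.6-1.4% range, hybridized into a
diploid whose haplotypes A and B then experience mitotic crossovers,
interstitial/terminal/whole-chromosome LOH and (partial) aneuploidy.
Substitutions only — no indels — so the ancestor, parents and hybrid share
one coordinate system and windowed statistics operate on exactly aligned
sites.  Every planted event is recorded in a :class:`TruthLog`, the
recovery target for all downstream tests.

The hybrid is founded from haplotypes P1 and S1; the *other* haplotype of
each parent (P2, S2) is kept as that parent's reference genome, so the
divergence of a hybrid window to its own parental species equals
within-species heterozygosity rather than zero — the regime real strain
comparisons sit in.

Observables: a heterozygous-site variant table (with configurable
false-negative/false-positive rates standing in for upstream variant
calling), per-base depth tracks (negative binomial, Poisson at dispersion
0), per-site base-modification tables with hypomethylated promoters and
periodic downstream 6mA/5mC, and transcript models with designed isoform
read-count mixtures and Kozak contexts of known strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequtil import encode, mutate_positions, random_sequence, revcomp
from .txrules import TranscriptModel

__all__ = [
    "SimulationConfig",
    "EventSpec",
    "TruthLog",
    "simulate_parent_haplotypes",
    "apply_hybrid_events",
    "emit_variant_table",
    "emit_coverage_track",
    "methylation_template",
    "emit_methylation",
    "emit_transcripts",
]

EVENT_KINDS = (
    "crossover",
    "loh_interstitial",
    "loh_terminal",
    "loh_whole_chromosome",
    "aneuploidy_whole",
    "aneuploidy_partial",
)


@dataclass(frozen=True)
class EventSpec:
    """One planted event.

    ``haplotype`` is the recipient for LOH (its sequence is overwritten by
    the other haplotype's) and the duplicated haplotype for aneuploidy;
    ``copies`` is the resulting copy count of that haplotype
    chromosome/segment (normal = 1).  ``start`` is the crossover position
    for crossovers; LOH and partial aneuploidy use [start, end).
    """

    kind: str
    chrom: str
    start: int | None = None
    end: int | None = None
    haplotype: str = "A"
    copies: int = 2

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.haplotype not in ("A", "B"):
            raise ValueError("haplotype must be 'A' or 'B'")


@dataclass
class SimulationConfig:
    chrom_lengths: dict[str, int]
    gc_content: float = 0.64
    div_p: float = 0.0136  # per-site substitution from the ancestor, parent P
    div_s: float = 0.0136
    het_p: float = 0.006  # within-parent heterozygosity layers
    het_s: float = 0.0135
    event_specs: list[EventSpec] = field(default_factory=list)
    depth_mean: float = 50.0  # expected depth per chromosome copy
    depth_dispersion: float = 0.0  # NB overdispersion; 0 = Poisson
    meth_period: int = 180  # bp between linker methylation peaks
    meth_plateau: float = 0.95  # maximum gene-body 5mC fraction
    meth_sigma: float = 20.0  # peak width (bp) on the fraction scale
    amp_6ma: float = 0.75  # height of the 6mA linker peaks
    reads_per_site_mean: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.chrom_lengths, (list, tuple)):
            self.chrom_lengths = {
                f"chr{i + 1:02d}": int(L) for i, L in enumerate(self.chrom_lengths)
            }
        for name, L in self.chrom_lengths.items():
            if L <= 0:
                raise ValueError(f"zero-length chromosome {name}")
        for p in (self.gc_content, self.div_p, self.div_s, self.het_p, self.het_s):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.meth_period <= 0:
            raise ValueError("meth_period must be positive")
        if not 0.0 <= self.meth_plateau <= 1.0:
            raise ValueError("meth_plateau must lie in [0, 1]")
        if self.depth_mean < 0:
            raise ValueError("depth_mean must be non-negative")
        for ev in self.event_specs:
            L = self.chrom_lengths.get(ev.chrom)
            if L is None:
                raise ValueError(f"event on unknown chromosome {ev.chrom}")
            if ev.kind == "crossover":
                if not 0 < ev.start < L:
                    raise ValueError(f"crossover position outside {ev.chrom}")
            elif ev.kind != "loh_whole_chromosome" and ev.kind != "aneuploidy_whole":
                if not (0 <= ev.start < ev.end <= L):
                    raise ValueError(f"event interval outside {ev.chrom}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TruthLog:
    """Ground truth for every planted feature of one simulated genome."""

    parent_intervals: dict = field(default_factory=dict)  # (hap, chrom) -> [(s, e, label)]
    loh_tracts: list = field(default_factory=list)  # dicts: chrom/start/end/recipient
    crossovers: list = field(default_factory=list)  # (chrom, pos)
    copy_numbers: dict = field(default_factory=dict)  # (hap, chrom) -> [(s, e, copies)]
    meth_params: dict = field(default_factory=dict)
    genes: list = field(default_factory=list)  # per-gene transcript truth dicts

    def validate(self, chrom_lengths: dict[str, int]) -> None:
        """Check that parent intervals tile each haplotype chromosome."""
        for (hap, chrom), ivs in self.parent_intervals.items():
            L = chrom_lengths[chrom]
            pos = 0
            for s, e, _lab in ivs:
                if s != pos or e <= s:
                    raise AssertionError(f"truth intervals do not tile {hap}/{chrom}")
                pos = e
            if pos != L:
                raise AssertionError(f"truth intervals do not reach the end of {hap}/{chrom}")

    def to_dict(self) -> dict:
        return {
            "parent_intervals": {
                f"{hap}:{chrom}": [list(iv) for iv in ivs]
                for (hap, chrom), ivs in self.parent_intervals.items()
            },
            "loh_tracts": self.loh_tracts,
            "crossovers": [list(c) for c in self.crossovers],
            "copy_numbers": {
                f"{hap}:{chrom}": [list(seg) for seg in segs]
                for (hap, chrom), segs in self.copy_numbers.items()
            },
            "meth_params": self.meth_params,
            "genes": self.genes,
        }


# ---------------------------------------------------------------------------
# parental genomes


def simulate_parent_haplotypes(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict, dict]:
    """Ancestor plus four parental haplotypes (P1, P2, S1, S2).

    Each parent's first haplotype is the ancestor mutated at its divergence
    rate; the second haplotype adds an independent substitution layer at
    the within-parent heterozygosity rate.
    """
    rng = config.rng() if rng is None else rng
    ancestor: dict[str, np.ndarray] = {}
    parents: dict[str, dict[str, np.ndarray]] = {k: {} for k in ("P1", "P2", "S1", "S2")}
    for chrom, L in config.chrom_lengths.items():
        anc = random_sequence(rng, L, config.gc_content)
        ancestor[chrom] = anc
        p1, _ = mutate_positions(rng, anc, config.div_p)
        p2, _ = mutate_positions(rng, p1, config.het_p)
        s1, _ = mutate_positions(rng, anc, config.div_s)
        s2, _ = mutate_positions(rng, s1, config.het_s)
        parents["P1"][chrom] = p1
        parents["P2"][chrom] = p2
        parents["S1"][chrom] = s1
        parents["S2"][chrom] = s2
    return ancestor, parents


# ---------------------------------------------------------------------------
# hybrid events


def _split_intervals(ivs: list, x: int) -> list:
    out = []
    for s, e, lab in ivs:
        if s < x < e:
            out.extend([(s, x, lab), (x, e, lab)])
        else:
            out.append((s, e, lab))
    return out


def _merge_adjacent(ivs: list) -> list:
    out = []
    for s, e, lab in ivs:
        if out and out[-1][2] == lab and out[-1][1] == s:
            out[-1] = (out[-1][0], e, lab)
        else:
            out.append((s, e, lab))
    return out


def apply_hybrid_events(
    parents: dict, config: SimulationConfig
) -> tuple[dict, TruthLog]:
    """Found the hybrid (A from P1, B from S1) and apply planted events.

    Crossovers reciprocally exchange the suffixes of A and B; LOH copies
    the other haplotype's sequence onto the recipient interval; aneuploidy
    only changes the truth copy numbers (the sequence of an extra copy is
    identical).  Events are applied in list order; overlapping LOH
    intervals on one chromosome are rejected as conflicting.
    """
    hybrid = {
        "A": {c: parents["P1"][c].copy() for c in config.chrom_lengths},
        "B": {c: parents["S1"][c].copy() for c in config.chrom_lengths},
    }
    truth = TruthLog()
    for chrom, L in config.chrom_lengths.items():
        truth.parent_intervals[("A", chrom)] = [(0, L, "P")]
        truth.parent_intervals[("B", chrom)] = [(0, L, "S")]
        truth.copy_numbers[("A", chrom)] = [(0, L, 1)]
        truth.copy_numbers[("B", chrom)] = [(0, L, 1)]

    loh_seen: dict[str, list] = {}
    for ev in config.event_specs:
        L = config.chrom_lengths[ev.chrom]
        if ev.kind == "crossover":
            x = ev.start
            a, b = hybrid["A"][ev.chrom], hybrid["B"][ev.chrom]
            a_suf = a[x:].copy()
            a[x:] = b[x:]
            b[x:] = a_suf
            ia = _split_intervals(truth.parent_intervals[("A", ev.chrom)], x)
            ib = _split_intervals(truth.parent_intervals[("B", ev.chrom)], x)
            truth.parent_intervals[("A", ev.chrom)] = _merge_adjacent(
                [iv for iv in ia if iv[1] <= x] + [iv for iv in ib if iv[0] >= x]
            )
            truth.parent_intervals[("B", ev.chrom)] = _merge_adjacent(
                [iv for iv in ib if iv[1] <= x] + [iv for iv in ia if iv[0] >= x]
            )
            truth.crossovers.append((ev.chrom, x))
        elif ev.kind.startswith("loh"):
            s, e = (0, L) if ev.kind == "loh_whole_chromosome" else (ev.start, ev.end)
            if ev.kind == "loh_terminal" and not (s == 0 or e == L):
                raise ValueError("terminal LOH must touch a chromosome end")
            for ps, pe in loh_seen.get(ev.chrom, []):
                if max(ps, s) < min(pe, e):
                    raise ValueError(f"conflicting overlapping LOH events on {ev.chrom}")
            loh_seen.setdefault(ev.chrom, []).append((s, e))
            recipient, donor = ev.haplotype, ("B" if ev.haplotype == "A" else "A")
            hybrid[recipient][ev.chrom][s:e] = hybrid[donor][ev.chrom][s:e]
            riv = _split_intervals(
                _split_intervals(truth.parent_intervals[(recipient, ev.chrom)], s), e
            )
            div = _split_intervals(
                _split_intervals(truth.parent_intervals[(donor, ev.chrom)], s), e
            )
            truth.parent_intervals[(recipient, ev.chrom)] = _merge_adjacent(
                [iv for iv in riv if iv[1] <= s]
                + [iv for iv in div if s <= iv[0] and iv[1] <= e]
                + [iv for iv in riv if iv[0] >= e]
            )
            truth.loh_tracts.append(
                {"chrom": ev.chrom, "start": int(s), "end": int(e), "recipient": recipient}
            )
        elif ev.kind == "aneuploidy_whole":
            truth.copy_numbers[(ev.haplotype, ev.chrom)] = [(0, L, ev.copies)]
        elif ev.kind == "aneuploidy_partial":
            segs = truth.copy_numbers[(ev.haplotype, ev.chrom)]
            segs = _split_intervals(
                _split_intervals([(s, e, c) for s, e, c in segs], ev.start), ev.end
            )
            truth.copy_numbers[(ev.haplotype, ev.chrom)] = [
                (s, e, ev.copies if ev.start <= s and e <= ev.end else c)
                for s, e, c in segs
            ]
    truth.validate(config.chrom_lengths)
    return hybrid, truth


# ---------------------------------------------------------------------------
# observables


def emit_variant_table(
    hybrid: dict,
    false_negative_rate: float = 0.0,
    false_positive_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    quality: int = 60,
) -> pd.DataFrame:
    """Heterozygous VariantSites wherever haplotypes A and B differ.

    True sites are dropped with probability ``false_negative_rate``;
    spurious heterozygous sites are added at ``false_positive_rate`` per
    base.  Positions are 0-based (converted at the VCF boundary).
    """
    for r in (false_negative_rate, false_positive_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(0)
    frames = []
    for chrom in hybrid["A"]:
        a, b = hybrid["A"][chrom], hybrid["B"][chrom]
        pos = np.flatnonzero(a != b)
        if false_negative_rate > 0 and len(pos):
            pos = pos[rng.random(len(pos)) >= false_negative_rate]
        if false_positive_rate > 0:
            n_fp = rng.binomial(len(a), false_positive_rate)
            fp = rng.choice(len(a), size=n_fp, replace=False)
            fp = np.setdiff1d(fp, np.flatnonzero(a != b))
            pos = np.union1d(pos, fp)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": np.sort(pos),
                    "zygosity": "heterozygous",
                    "quality": quality,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def emit_coverage_track(
    truth: TruthLog,
    config: SimulationConfig,
    mode: str = "phased",
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Per-base depth with mean depth_mean x (true copies at that base).

    ``phased`` emits one track per haplotype chromosome (keys like
    ``chr01_A``); ``collapsed`` sums the copy numbers of both haplotypes
    into one track per chromosome.  Depth is negative binomial with the
    configured overdispersion, exactly Poisson at dispersion 0.
    """
    if rng is None:
        rng = config.rng()
    if config.depth_mean < 0:
        raise ValueError("depth_mean must be non-negative")

    def draw(mean_per_base: np.ndarray) -> np.ndarray:
        m = mean_per_base
        if config.depth_dispersion == 0:
            return rng.poisson(m)
        r = 1.0 / config.depth_dispersion
        p = r / (r + m)
        return rng.negative_binomial(r, p)

    tracks: dict[str, np.ndarray] = {}
    if mode == "phased":
        for (hap, chrom), segs in sorted(truth.copy_numbers.items()):
            copies = np.zeros(segs[-1][1], dtype=float)
            for s, e, c in segs:
                copies[s:e] = c
            tracks[f"{chrom}_{hap}"] = draw(config.depth_mean * copies)
    elif mode == "collapsed":
        chroms = sorted({chrom for _, chrom in truth.copy_numbers})
        for chrom in chroms:
            L = truth.copy_numbers[("A", chrom)][-1][1]
            copies = np.zeros(L, dtype=float)
            for hap in ("A", "B"):
                for s, e, c in truth.copy_numbers[(hap, chrom)]:
                    copies[s:e] += c
            tracks[chrom] = draw(config.depth_mean * copies)
    else:
        raise ValueError("mode must be 'phased' or 'collapsed'")
    return tracks


# ---------------------------------------------------------------------------
# methylation


def methylation_template(
    offsets: np.ndarray,
    context: str,
    period: int = 180,
    plateau: float = 0.95,
    sigma: float = 20.0,
    amp_6ma: float = 0.75,
    n_5mc_peaks: int = 12,
) -> np.ndarray:
    """True modification fraction as a function of TSS offset.

    Promoters are hypomethylated: the template is ~0 upstream and at the
    TSS.  6mA forms linker peaks at offsets ``period`` and ``2 x period``;
    5mC rises from ``3 x period`` onward in periodic bumps approaching
    ``plateau``.  Peaks are Gaussian with width ``sigma`` on the fraction
    scale, clipped to [0, 1].
    """
    offsets = np.asarray(offsets, dtype=float)
    f = np.zeros_like(offsets)
    if context == "ApT":
        for k in (1, 2):
            f += amp_6ma * np.exp(-0.5 * ((offsets - k * period) / sigma) ** 2)
    elif context == "CpG":
        for k in range(3, 3 + n_5mc_peaks):
            height = plateau * min(1.0, (k - 2) / 3.0)
            f += height * np.exp(-0.5 * ((offsets - k * period) / sigma) ** 2)
    else:
        raise ValueError("context must be 'CpG' or 'ApT'")
    return np.clip(f, 0.0, 1.0)


def emit_methylation(
    config: SimulationConfig,
    n_genes: int = 2_000,
    flank_up: int = 1_000,
    flank_down: int = 3_000,
    site_density: float = 0.05,
    rng: np.random.Generator | None = None,
    chrom: str = "methchr",
) -> tuple[pd.DataFrame, pd.DataFrame, TruthLog]:
    """Per-site ModSite table plus TSS records for a set of placed genes.

    Genes are laid head-to-tail on one coordinate axis with alternating
    strands; candidate CpG/ApT sites occur independently at density
    ``site_density`` per base within the profiled flank, read counts are
    Poisson around ``reads_per_site_mean`` and modified counts binomial at
    the template fraction for the site's TSS offset.
    """
    rng = config.rng() if rng is None else rng
    # TSSs far enough apart that no gene's flank window reaches a neighbour's
    spacing = 2 * max(flank_up, flank_down) + 200
    offsets_axis = np.arange(-flank_up, flank_down + 1)
    rows = []
    tss_rows = []
    for g in range(n_genes):
        strand = "+" if g % 2 == 0 else "-"
        tss = flank_up + 100 + g * spacing
        tss_rows.append(
            {
                "chrom": chrom,
                "pos": tss,
                "strand": strand,
                "gene_id": f"G{g:05d}",
                "high_confidence": True,
            }
        )
        for context in ("CpG", "ApT"):
            hit = rng.random(len(offsets_axis)) < site_density
            offs = offsets_axis[hit]
            frac = methylation_template(
                offs,
                context,
                period=config.meth_period,
                plateau=config.meth_plateau,
                sigma=config.meth_sigma,
                amp_6ma=config.amp_6ma,
            )
            n_reads = rng.poisson(config.reads_per_site_mean, size=len(offs))
            n_mod = rng.binomial(np.maximum(n_reads, 1), frac)
            n_mod = np.where(n_reads == 0, 0, n_mod)
            pos = tss + offs if strand == "+" else tss - offs
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos,
                        "context": context,
                        "n_reads": n_reads,
                        "n_modified": n_mod,
                    }
                )
            )
    sites = pd.concat(rows, ignore_index=True).sort_values(["pos", "context"], ignore_index=True)
    tss_records = pd.DataFrame(tss_rows)
    truth = TruthLog()
    truth.meth_params = {
        "period": config.meth_period,
        "plateau": config.meth_plateau,
        "sigma": config.meth_sigma,
        "amp_6ma": config.amp_6ma,
        "n_genes": n_genes,
    }
    return sites, tss_records, truth


# ---------------------------------------------------------------------------
# transcripts with designed Kozak contexts


_KOZAK_CONSENSUS = {  # strong-context consensus per offset
    -9: "G", -8: "C", -7: "C", -6: "G", -5: "C", -4: "C", -3: "A", -2: "C", -1: "C",
    3: "G", 4: "C", 5: "G",
}
_ANTI_CONSENSUS = {off: {"A": "T", "C": "A", "G": "T", "T": "G"}[b] for off, b in _KOZAK_CONSENSUS.items()}

_SAFE_CODONS = [  # no stop, not ATG, not trivially creating stops across joins
    "GCT", "GCC", "GGT", "GGC", "CTG", "CCG", "GAG", "AAG", "GTC", "ACC",
]


def _draw_context(rng: np.random.Generator, table: dict[int, str], fidelity: float) -> dict[int, str]:
    bases = "ACGT"
    return {
        off: (b if rng.random() < fidelity else bases[rng.integers(4)])
        for off, b in table.items()
    }


def _random_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(_SAFE_CODONS[i] for i in rng.integers(len(_SAFE_CODONS), size=n))


def emit_transcripts(
    config: SimulationConfig,
    n_genes: int = 200,
    rng: np.random.Generator | None = None,
    chrom: str = "txchr",
    context_fidelity: float = 0.85,
) -> tuple[dict[str, np.ndarray], list[TranscriptModel], TruthLog]:
    """Gene models with designed isoform mixtures and Kozak contexts.

    Gene classes (cycled): ``training`` genes have a strong Kozak context
    at the annotated start and no upstream in-frame ATG; ``extended``
    genes carry a weak annotated context plus a strong in-frame upstream
    ATG with no intervening in-frame stop (the true start); ``negative``
    genes must never be extended — half have a clean UTR, half an upstream
    in-frame ATG blocked by an in-frame stop.  Most genes get a minor
    5'-truncated isoform; some truncated isoforms are designed to fall
    below the read-support filters.  Returns the genome of the dedicated
    transcript chromosome, all isoform models, and the truth log.
    """
    rng = config.rng() if rng is None else rng
    utr5, utr3 = 60, 40
    spacing = 50
    pieces: list[np.ndarray] = []
    transcripts: list[TranscriptModel] = []
    truth = TruthLog()
    cursor = 0

    classes = ["training", "training", "training", "extended", "negative"]
    for g in range(n_genes):
        cls = classes[g % len(classes)]
        gene_id = f"TG{g:04d}"
        strand = "+" if g % 2 == 0 else "-"
        n_codons = int(rng.integers(60, 120))

        # build the transcript (sense) sequence
        utr = _random_codons(rng, utr5 // 3)
        cds = "ATG" + _random_codons(rng, n_codons - 2) + "TAA"
        tail = _random_codons(rng, utr3 // 3)
        t_seq = list(utr + cds + tail)
        c0 = len(utr)

        if cls == "training":
            ctx = _draw_context(rng, _KOZAK_CONSENSUS, context_fidelity)
        elif cls == "extended":
            ctx = _draw_context(rng, _ANTI_CONSENSUS, context_fidelity)
        else:  # negative
            ctx = _draw_context(rng, _KOZAK_CONSENSUS, 0.5)
        for off, b in ctx.items():
            t_seq[c0 + off] = b
        # context randomization may have created an in-frame upstream ATG;
        # scrub the UTR so only deliberately planted starts exist
        for k in range(c0 % 3, c0, 3):
            if "".join(t_seq[k : k + 3]) == "ATG":
                t_seq[k + 1] = "C"

        true_start_t = None
        if cls == "extended":
            # plant a strong in-frame upstream ATG, stop-free to the CDS,
            # far enough in for the full scoring window
            u = c0 % 3 + 3 * int(rng.integers(3, 9))
            t_seq[u : u + 3] = "ATG"
            for k in range(u + 3, c0, 3):
                t_seq[k : k + 3] = _SAFE_CODONS[int(rng.integers(len(_SAFE_CODONS)))]
            strong = _draw_context(rng, _KOZAK_CONSENSUS, 1.0)
            for off, b in strong.items():
                t_seq[u + off] = b  # never overlaps the annotated context (u <= 24 << c0 - 9)
            true_start_t = u
        elif cls == "negative" and g % 2 == 1:
            # upstream in-frame ATG made unreachable by an in-frame stop
            u = c0 % 3
            t_seq[u : u + 3] = "ATG"
            t_seq[u + 3 : u + 6] = "TGA"

        t_str = "".join(t_seq)
        glen = len(t_str)
        gstart = cursor + spacing
        gseq = encode(t_str) if strand == "+" else revcomp(encode(t_str))
        pad = random_sequence(rng, spacing, config.gc_content)
        pieces.extend([pad, gseq])
        cursor = gstart + glen

        exons = ((gstart, gstart + glen),)
        if strand == "+":
            cds_iv = ((gstart + c0, gstart + c0 + 3 * n_codons),)
        else:
            cds_iv = ((gstart + glen - c0 - 3 * n_codons, gstart + glen - c0),)
        primary_reads = int(rng.integers(40, 200))
        primary = TranscriptModel(
            id=f"{gene_id}.1",
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            exons=exons,
            cds=cds_iv,
            read_count=primary_reads,
        )
        transcripts.append(primary)

        minor_id = None
        minor_filtered = False
        if g % 3 != 2:
            # 5'-truncated minor isoform sharing the CDS 3' end
            trunc_codons = max(10, n_codons // 2)
            if g % 6 in (0, 1):
                minor_reads = max(5, int(0.10 * primary_reads))
            else:
                minor_reads = int(rng.integers(1, 4))  # below the read filter
            if strand == "+":
                mstart = gstart + c0 + 3 * (n_codons - trunc_codons)
                mexons = ((mstart, gstart + glen),)
                mcds = ((mstart, gstart + c0 + 3 * n_codons),)
            else:
                mend = gstart + glen - c0 - 3 * (n_codons - trunc_codons)
                mexons = ((gstart, mend),)
                mcds = ((gstart + glen - c0 - 3 * n_codons, mend),)
            minor_id = f"{gene_id}.2"
            transcripts.append(
                TranscriptModel(
                    id=minor_id,
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    exons=mexons,
                    cds=mcds,
                    read_count=minor_reads,
                )
            )
            total = minor_reads + primary_reads
            minor_filtered = minor_reads < 5 or minor_reads / total < 0.05

        if strand == "+":
            true_start_g = gstart + true_start_t if true_start_t is not None else None
        else:
            true_start_g = gstart + glen - 1 - true_start_t if true_start_t is not None else None
        truth.genes.append(
            {
                "gene_id": gene_id,
                "class": cls,
                "strand": strand,
                "primary": f"{gene_id}.1",
                "minor": minor_id,
                "minor_should_filter": minor_filtered,
                "true_start_t": true_start_t,
                "true_start_genomic": true_start_g,
                "cds_start_t": c0,
            }
        )

    genome = {chrom: np.concatenate(pieces + [random_sequence(rng, spacing, config.gc_content)])}
    return genome, transcripts, truth
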