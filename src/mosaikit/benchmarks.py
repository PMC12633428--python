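"""Truth-recovery benchmarks on synthetic genomes.

Each function simulates a dataset with the generator's planted-event truth
log, runs the corresponding analysis module on the emitted observables,
and scores recovery.  They are the package's own quality gates: LOH tract
detection, ancestry painting and switch typing, integer copy-number
calling, metaprofile/periodicity recovery, and the transcript-rule
decisions against independent brute-force oracles.
"""

from __future__ import annotations

import itertools
import statistics

import numpy as np
import pandas as pd

from . import ancestry, hetwin, loh, methprof, ploidy, synthdata, txrules

__all__ = [
    "loh_recovery",
    "ancestry_recovery",
    "aneuploidy_benchmark",
    "methylation_benchmark",
    "transcript_benchmark",
    "degeneracy_agreement",
]


# --------------------------------------------------------------------- LOH


def loh_recovery(seed: int = 0) -> dict:
    """Plant 20 LOH tracts in 10 Mb at ~2.7% heterozygosity and recall them.

    17 interstitial tracts of 1-40 kb, 2 terminal, 1 whole chromosome.
    Reports the detection rate of tracts >= 1 kb, the count of false
    tracts, and the median boundary error in bp.
    """
    rng = np.random.default_rng(seed)
    n_chrom, L = 10, 1_000_000
    lengths = [L] * n_chrom
    events = []
    # 17 interstitial tracts spread over chromosomes 1-8
    sizes = np.linspace(1_000, 40_000, 17).astype(int)
    for i, size in enumerate(sizes):
        chrom = f"chr{i % 8 + 1:02d}"
        # deterministic non-overlapping slots, jittered within each slot
        start = 100_000 + (i // 8) * 300_000 + int(rng.integers(0, 50_000))
        events.append(
            synthdata.EventSpec("loh_interstitial", chrom, start=start, end=start + int(size))
        )
    events.append(synthdata.EventSpec("loh_terminal", "chr09", start=0, end=120_000))
    events.append(
        synthdata.EventSpec("loh_terminal", "chr09", start=L - 80_000, end=L, haplotype="B")
    )
    events.append(synthdata.EventSpec("loh_whole_chromosome", "chr10"))

    config = synthdata.SimulationConfig(chrom_lengths=lengths, event_specs=events, seed=seed)
    sim_rng = config.rng()
    _anc, parents = synthdata.simulate_parent_haplotypes(config, sim_rng)
    hybrid, truth = synthdata.apply_hybrid_events(parents, config)
    variants = synthdata.emit_variant_table(hybrid, rng=sim_rng)

    called: list[loh.LOHTract] = []
    for chrom, length in config.chrom_lengths.items():
        pos = variants.loc[variants["chrom"] == chrom, "pos"].to_numpy()
        called.extend(
            loh.call_loh_tracts(pos, [[0, length]], length, chrom, min_callable_fraction=0.0)
        )

    detected = 0
    boundary_errors = []
    matched_calls = set()
    for planted in truth.loh_tracts:
        hits = [
            (i, t)
            for i, t in enumerate(called)
            if t.chrom == planted["chrom"] and t.start < planted["end"] and t.end > planted["start"]
        ]
        if hits:
            detected += 1
            i, t = max(hits, key=lambda h: min(h[1].end, planted["end"]) - max(h[1].start, planted["start"]))
            matched_calls.add(i)
            boundary_errors.append(abs(t.start - planted["start"]))
            boundary_errors.append(abs(t.end - planted["end"]))
    false_tracts = len(called) - len(matched_calls)
    return {
        "n_planted": len(truth.loh_tracts),
        "detection_rate_pct": 100.0 * detected / len(truth.loh_tracts),
        "false_tracts": false_tracts,
        "median_boundary_error_bp": float(np.median(boundary_errors)),
        "genome_mb": n_chrom * L / 1e6,
    }


# ----------------------------------------------------------------- ancestry


def _truth_window_labels(truth, hap, chrom, tiles) -> np.ndarray:
    labels = []
    for s, e in tiles:
        best, best_len = None, 0
        for ts, te, lab in truth.parent_intervals[(hap, chrom)]:
            ov = min(te, e) - max(ts, s)
            if ov > best_len:
                best, best_len = lab, ov
        labels.append(best)
    return np.array(labels)


def ancestry_recovery(seed: int = 0, window_size: int = 10_000) -> dict:
    """Paint a 5-Mb hybrid with 5 crossovers and 5 LOH switches.

    Parents at ~2.7% divergence with within-parent heterozygosity 0.6%
    (P) and 1.35% (S).  Reports the fraction of informative windows with
    the true parent label and switch recovery/typing.
    """
    L = 1_000_000
    events = []
    xovers = {f"chr{c:02d}": 200_000 + 80_000 * c for c in range(1, 6)}
    for chrom, x in xovers.items():
        events.append(synthdata.EventSpec("crossover", chrom, start=x))
    loh_bounds = {f"chr{c:02d}": L - 150_000 - 30_000 * c for c in range(1, 6)}
    for i, (chrom, s) in enumerate(loh_bounds.items()):
        events.append(
            synthdata.EventSpec("loh_terminal", chrom, start=s, end=L, haplotype="A" if i % 2 == 0 else "B")
        )
    config = synthdata.SimulationConfig(
        chrom_lengths=[L] * 5, het_p=0.006, het_s=0.0135, event_specs=events, seed=seed
    )
    rng = config.rng()
    _anc, parents = synthdata.simulate_parent_haplotypes(config, rng)
    hybrid, truth = synthdata.apply_hybrid_events(parents, config)

    n_correct = n_informative = 0
    segs = {}
    for hap in ("A", "B"):
        win = ancestry.parent_divergence_windows(
            hybrid[hap], parents["P2"], parents["S2"], window_size=window_size
        )
        lab = ancestry.label_windows(win)
        segs[hap] = ancestry.segment_labels(lab, haplotype=hap)
        for chrom in config.chrom_lengths:
            sub = lab[lab["chrom"] == chrom]
            tiles = sub[["start", "end"]].to_numpy()
            truth_lab = _truth_window_labels(truth, hap, chrom, tiles)
            informative = sub["label"].isin(["P", "S"]).to_numpy()
            n_informative += int(informative.sum())
            n_correct += int((sub["label"].to_numpy()[informative] == truth_lab[informative]).sum())

    variants = synthdata.emit_variant_table(hybrid, rng=rng)
    tracts = []
    for chrom, length in config.chrom_lengths.items():
        pos = variants.loc[variants["chrom"] == chrom, "pos"].to_numpy()
        tracts.extend(loh.call_loh_tracts(pos, [[0, length]], length, chrom, min_callable_fraction=0.0))
    events_found = []
    for chrom in config.chrom_lengths:
        sa = [s for s in segs["A"] if s.chrom == chrom]
        sb = [s for s in segs["B"] if s.chrom == chrom]
        events_found.extend(
            ancestry.detect_switches(sa, sb, [t for t in tracts if t.chrom == chrom], window_size)
        )

    n_xover_ok = 0
    for chrom, x in xovers.items():
        if any(
            e.chrom == chrom
            and e.type == "reciprocal_crossover"
            and abs((e.start + e.end) / 2 - x) <= window_size
            for e in events_found
        ):
            n_xover_ok += 1
    n_loh_ok = 0
    for chrom, s in loh_bounds.items():
        if any(
            e.chrom == chrom and e.type == "nonreciprocal_LOH" and abs((e.start + e.end) / 2 - s) <= window_size
            for e in events_found
        ):
            n_loh_ok += 1
    return {
        "window_label_accuracy_pct": 100.0 * n_correct / n_informative,
        "n_informative_windows": n_informative,
        "crossovers_recovered": n_xover_ok,
        "loh_switches_recovered": n_loh_ok,
        "n_planted_crossovers": len(xovers),
        "n_planted_loh_switches": len(loh_bounds),
    }


# ------------------------------------------------------------------- ploidy


def aneuploidy_benchmark(seed: int = 0, n_genomes: int = 100) -> dict:
    """Whole-chromosome and partial copy-number recovery across seeds.

    Each genome: five disomic 150-kb chromosomes plus a 2-Mb chromosome
    with a 900-kb terminal duplication; haplotype A of chr02 is duplicated
    (2 copies) and of chr03 triplicated (3 copies).  Poisson depth,
    mean 50 per copy, 20-kb windows, phased mode.
    """
    rng = np.random.default_rng(seed)
    n_correct = n_calls = 0
    breakpoint_errors = []
    window_size = 20_000
    part_start = 1_100_000
    for g in range(n_genomes):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        config = synthdata.SimulationConfig(
            chrom_lengths=[150_000] * 5 + [2_000_000], seed=sub_seed
        )
        # depth depends only on the truth copy numbers, not sequence content
        truth = synthdata.TruthLog()
        for chrom, L in config.chrom_lengths.items():
            truth.copy_numbers[("A", chrom)] = [(0, L, 1)]
            truth.copy_numbers[("B", chrom)] = [(0, L, 1)]
        truth.copy_numbers[("A", "chr02")] = [(0, 150_000, 2)]
        truth.copy_numbers[("A", "chr03")] = [(0, 150_000, 3)]
        truth.copy_numbers[("A", "chr06")] = [
            (0, part_start, 1),
            (part_start, 2_000_000, 2),
        ]
        tracks = synthdata.emit_coverage_track(truth, config, mode="phased", rng=config.rng())
        windows = pd.concat(
            [ploidy.windowed_coverage(t, window_size, c) for c, t in tracks.items()],
            ignore_index=True,
        )
        calls = ploidy.call_chromosome_copy_number(windows, mode="phased")
        expected = {f"{c}_{h}": 1 for c in config.chrom_lengths for h in "AB"}
        expected["chr02_A"] = 2
        expected["chr03_A"] = 3
        # chr06_A median sits on the disomic part (55 of 100 windows)
        for call in calls:
            n_calls += 1
            n_correct += int(call.copies == expected[call.chrom])
        segs = ploidy.segment_partial_aneuploidy(
            windows[windows["chrom"] == "chr06_A"], calls[0].baseline
        )
        two = segs[segs["copies"] == 2]
        if len(two) == 1:
            breakpoint_errors.append(abs(int(two["start"].iloc[0]) - part_start) / window_size)
        else:
            breakpoint_errors.append(np.inf)
    return {
        "n_genomes": n_genomes,
        "whole_chromosome_accuracy_pct": 100.0 * n_correct / n_calls,
        "partial_breakpoint_max_error_windows": float(np.max(breakpoint_errors)),
        "partial_breakpoint_median_error_windows": float(np.median(breakpoint_errors)),
    }


# --------------------------------------------------------------- methylation


def methylation_benchmark(seed: int = 0, n_genes: int = 2_000) -> dict:
    """Metaprofile vs brute-force medians, and periodicity recovery."""
    config = synthdata.SimulationConfig(chrom_lengths=[10_000], seed=seed)
    sites, tss, truth = synthdata.emit_methylation(config, n_genes=n_genes, rng=config.rng())
    sites = methprof.filter_mod_sites(sites, min_reads=5)

    results = {"true_period": truth.meth_params["period"], "n_genes": n_genes}
    for context in ("ApT", "CpG"):
        prof = methprof.tss_metaprofile(sites, tss, context)
        # independent brute-force median per offset
        pools: dict[int, list[float]] = {}
        sub = sites[sites["context"] == context].sort_values("pos")
        pos_arr = sub["pos"].to_numpy()
        frac_arr = (sub["n_modified"] / sub["n_reads"]).to_numpy()
        for rec in tss.itertuples(index=False):
            lo, hi = np.searchsorted(pos_arr, [rec.pos - 3_001, rec.pos + 3_001])
            for p, f in zip(pos_arr[lo:hi], frac_arr[lo:hi]):
                off = p - rec.pos if rec.strand == "+" else rec.pos - p
                if -1_000 <= off <= 3_000:
                    pools.setdefault(int(off), []).append(float(f))
        brute = {off: statistics.median(v) for off, v in pools.items()}
        prof_map = dict(zip(prof["offset"], prof["median_frac"]))
        agree = all(
            abs(prof_map[o] - m) < 1e-12 for o, m in brute.items()
        ) and set(prof_map) == set(brute)
        period = methprof.estimate_periodicity(prof)
        results[f"{context}_median_matches_bruteforce"] = bool(agree)
        results[f"{context}_period_estimate"] = period["period"]
    return results


# --------------------------------------------------------------- transcripts


class _Iso:
    """Minimal isoform stub for the rule-grid oracles."""

    def __init__(self, iid, cds_length, read_count):
        self.id = iid
        self.cds_length = cds_length
        self.read_count = read_count


def _cascade_oracle(isoforms) -> str:
    """Direct re-statement of the primary-isoform cascade, coded separately."""
    by_len = sorted(isoforms, key=lambda t: (-t.cds_length, -t.read_count, t.id))
    longest = by_len[0]
    max_reads = max(t.read_count for t in isoforms)
    by_reads = sorted(
        [t for t in isoforms if t.read_count == max_reads],
        key=lambda t: (-t.cds_length, t.id),
    )
    abundant = by_reads[0]
    if longest.read_count == max_reads:
        return longest.id
    if longest.read_count >= 0.5 * max_reads:
        return longest.id
    if abundant.cds_length >= 0.8 * longest.cds_length:
        return abundant.id
    return longest.id


def _filter_oracle(read_counts, min_reads=5, min_fraction=0.05):
    total = sum(read_counts)
    return [
        i
        for i, r in enumerate(read_counts)
        if r >= min_reads and r / total >= min_fraction
    ]


def transcript_benchmark(seed: int = 0, n_genes: int = 500) -> dict:
    """Rule-grid oracle agreement plus Kozak extension recovery.

    The cascade is checked against an independently coded oracle over all
    4-isoform genes with CDS lengths from {100, 200, 300, 400} and read
    counts from {1, 10, 50, 100}; the filter over all read-count
    assignments from the same grid.  Extension recovery runs on simulated
    genes with designed strong/weak Kozak contexts.
    """
    lengths = [100, 200, 300, 400]
    reads = [1, 10, 50, 100]
    n_grid = n_agree = 0
    for cds_combo in itertools.product(lengths, repeat=4):
        for read_combo in itertools.product(reads, repeat=4):
            isoforms = [_Iso(f"i{k}", c, r) for k, (c, r) in enumerate(zip(cds_combo, read_combo))]
            n_grid += 1
            got, _rule = txrules.select_primary_isoform(isoforms)
            if got == _cascade_oracle(isoforms):
                n_agree += 1
    cascade_agreement = n_agree / n_grid

    n_fgrid = n_fagree = 0
    for read_combo in itertools.product(reads, repeat=4):
        models = [
            txrules.TranscriptModel(
                id=f"i{k}", gene_id="g", chrom="c", strand="+", exons=((0, 30),),
                cds=((0, 30),), read_count=r,
            )
            for k, r in enumerate(read_combo)
        ]
        kept = txrules.filter_isoforms(models)
        want = {f"i{k}" for k in _filter_oracle(read_combo)} or {
            max(models, key=lambda t: (t.read_count, t.id)).id
        }
        n_fgrid += 1
        n_fagree += int({t.id for t in kept} == want)
    filter_agreement = n_fagree / n_fgrid

    config = synthdata.SimulationConfig(chrom_lengths=[10_000], seed=seed)
    genome, transcripts, truth = synthdata.emit_transcripts(
        config, n_genes=n_genes, rng=config.rng()
    )
    by_gene: dict[str, list] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    primaries = {}
    for gene in truth.genes:
        kept = txrules.filter_isoforms(by_gene[gene["gene_id"]])
        pid, _ = txrules.select_primary_isoform(kept)
        primaries[gene["gene_id"]] = next(t for t in kept if t.id == pid)
    model = txrules.build_kozak_model(list(primaries.values()), genome)

    n_ext = n_ext_ok = n_neg = n_false = 0
    for gene in truth.genes:
        t = primaries[gene["gene_id"]]
        new_t, rec = txrules.extend_orf(t, model, genome)
        if gene["class"] == "extended":
            n_ext += 1
            if rec["extended"]:
                got = sorted(new_t.cds)[0][0] if t.strand == "+" else sorted(new_t.cds)[-1][1] - 1
                n_ext_ok += int(got == gene["true_start_genomic"])
        elif gene["class"] == "negative":
            n_neg += 1
            n_false += int(rec["extended"])
    return {
        "cascade_oracle_agreement": cascade_agreement,
        "filter_oracle_agreement": filter_agreement,
        "n_grid": n_grid,
        "extension_recovery_pct": 100.0 * n_ext_ok / n_ext,
        "false_extensions": n_false,
        "n_extension_genes": n_ext,
        "n_negative_genes": n_neg,
        "kozak_p25_bits": model.p25,
    }


# --------------------------------------------------------------- degeneracy


def degeneracy_agreement() -> dict:
    """Compare degeneracy classes to the 9-substitution brute-force table.

    The oracle translates with Bio.Seq so the genetic code itself is
    independent of the package's table.
    """
    from Bio.Seq import Seq

    bases = "ACGT"
    n_codons = n_agree = 0
    for codon in ("".join(c) for c in itertools.product(bases, repeat=3)):
        if str(Seq(codon).translate()) == "*":
            continue
        n_codons += 1
        got = hetwin.classify_degeneracy(codon)
        want = []
        for i in range(3):
            syn = sum(
                1
                for b in bases
                if b != codon[i]
                and str(Seq(codon[:i] + b + codon[i + 1 :]).translate())
                == str(Seq(codon).translate())
            )
            want.append(0 if syn == 0 else syn + 1)
        n_agree += int(list(got) == want)
    return {"n_sense_codons": n_codons, "n_agree": n_agree}
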