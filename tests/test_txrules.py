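import numpy as np
import pytest

from mosaikit import txrules
from mosaikit.sequtil import encode, revcomp_str


def iso(iid, gene="g", cds=((0, 30),), exons=None, reads=10, strand="+", chrom="c"):
    exons = exons or cds
    return txrules.TranscriptModel(
        id=iid, gene_id=gene, chrom=chrom, strand=strand, exons=exons, cds=cds, read_count=reads
    )


class TestTranscriptModel:
    def test_validation(self):
        with pytest.raises(ValueError):
            iso("t", cds=((0, 31),))  # CDS not divisible by 3
        with pytest.raises(ValueError):
            txrules.TranscriptModel(
                id="t", gene_id="g", chrom="c", strand="+",
                exons=((0, 10), (5, 20)), cds=(),
            )
        with pytest.raises(ValueError):
            iso("t", cds=((0, 30),), exons=((0, 20),))  # CDS outside exons

    def test_tss_strand_aware(self):
        t = iso("t", exons=((100, 200),), cds=((110, 140),))
        assert t.tss == 100
        t = iso("t", exons=((100, 200),), cds=((110, 140),), strand="-")
        assert t.tss == 199

    def test_transcript_interval_mapping_spliced(self):
        t = iso("t", exons=((0, 10), (20, 30)), cds=((0, 9),))
        assert t.transcript_interval_to_genomic(5, 15) == ((5, 10), (20, 25))


class TestDecouple:
    def test_single_isoform(self):
        parts = txrules.decouple_genes([iso("a")])
        assert len(parts) == 1

    def test_transitive_components(self):
        a = iso("a", cds=((0, 30),))
        b = iso("b", cds=((15, 45),))
        c = iso("c", cds=((40, 70),))
        parts = txrules.decouple_genes([a, b, c])
        assert len(parts) == 1 and {t.id for t in parts[0]} == {"a", "b", "c"}

    def test_disjoint_cds_split(self):
        a = iso("a", cds=((0, 30),))
        b = iso("b", cds=((100, 130),))
        parts = txrules.decouple_genes([a, b])
        assert len(parts) == 2

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        isoforms = []
        for k in range(12):
            s = int(rng.integers(0, 500)) * 3
            isoforms.append(iso(f"t{k}", cds=((s, s + 30),)))
        parts = txrules.decouple_genes(isoforms)
        ids = [t.id for p in parts for t in p]
        assert sorted(ids) == sorted(t.id for t in isoforms)

    def test_noncoding_attached_by_exon_overlap(self):
        a = iso("a", cds=((0, 30),))
        b = iso("b", cds=((100, 130),))
        nc = txrules.TranscriptModel(
            id="nc", gene_id="g", chrom="c", strand="+", exons=((95, 140),), cds=()
        )
        parts = txrules.decouple_genes([a, b, nc])
        target = next(p for p in parts if any(t.id == "b" for t in p))
        assert any(t.id == "nc" for t in target)


class TestFilterIsoforms:
    def test_below_read_minimum(self):
        kept = txrules.filter_isoforms([iso("a", reads=100), iso("b", reads=4)])
        assert [t.id for t in kept] == ["a"]

    def test_fraction_boundary(self):
        # 5/105 = 4.76% < 5% -> removed
        kept = txrules.filter_isoforms([iso("a", reads=100), iso("b", reads=5)])
        assert [t.id for t in kept] == ["a"]
        # 5/100 = 5% exactly -> retained
        kept = txrules.filter_isoforms([iso("a", reads=95), iso("b", reads=5)])
        assert [t.id for t in kept] == ["a", "b"]

    def test_rescue_most_abundant(self):
        kept = txrules.filter_isoforms([iso("a", reads=3), iso("b", reads=2)])
        assert [t.id for t in kept] == ["a"]

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            txrules.filter_isoforms([iso("a", reads=0)])


class TestPrimarySelection:
    def mk(self, specs):
        return [
            iso(f"i{k}", cds=((0, c),), exons=((0, max(c, 3)),), reads=r)
            for k, (c, r) in enumerate(specs)
        ]

    @pytest.mark.parametrize(
        "specs,want,rule",
        [
            ([(300, 50), (201, 10)], "i0", 1),  # longest is most abundant
            ([(300, 30), (249, 50)], "i0", 2),  # longest has >= 50% of top reads
            ([(300, 10), (279, 100)], "i1", 3),  # abundant CDS >= 80% of longest
            ([(300, 20), (201, 50)], "i0", 4),  # fallback to longest
        ],
    )
    def test_cascade_branches(self, specs, want, rule):
        got, got_rule = txrules.select_primary_isoform(self.mk(specs))
        assert (got, got_rule) == (want, rule)

    def test_equal_cds_ties_by_abundance_then_id(self):
        got, rule = txrules.select_primary_isoform(self.mk([(300, 10), (300, 50)]))
        assert got == "i1" and rule == 1
        got, _ = txrules.select_primary_isoform(self.mk([(300, 50), (300, 50)]))
        assert got == "i0"

    def test_exhaustive_grid_matches_independent_oracle(self):
        from mosaikit.benchmarks import transcript_benchmark

        res = transcript_benchmark(seed=0, n_genes=50)
        assert res["cascade_oracle_agreement"] == 1.0
        assert res["filter_oracle_agreement"] == 1.0


KOZAK_STRONG = "GCCGCCACC"  # offsets -9..-1


def build_fixture_genome(utr_prefix="", ctx=KOZAK_STRONG, post="GCG"):
    """Single-exon plus-strand transcript: UTR + ATG + CDS body."""
    seq = utr_prefix + ctx + "ATG" + post + "GCTGCTGCTTAA"
    return {"c": encode(seq)}, len(utr_prefix) + len(ctx)


class TestKozakModel:
    def train(self, n=6, ctx=KOZAK_STRONG):
        genome = {}
        transcripts = []
        seqs = []
        for k in range(n):
            g, c0 = build_fixture_genome("GGC" * 4, ctx)
            chrom = f"c{k}"
            genome[chrom] = g["c"]
            L = len(g["c"])
            transcripts.append(
                txrules.TranscriptModel(
                    id=f"t{k}", gene_id=f"g{k}", chrom=chrom, strand="+",
                    exons=((0, L),), cds=((c0, L),), read_count=10,
                )
            )
        return genome, transcripts

    def test_uniform_counts_uniform_background_scores_zero(self):
        genome, transcripts = self.train(n=4)
        offsets = (-3, -2, -1)
        # four training transcripts, one per base at each offset
        for k, base in enumerate("ACGT"):
            g = genome[f"c{k}"]
            for off in offsets:
                c0 = 12 + 9
                g[c0 + off] = "ACGT".index(base)
        model = txrules.build_kozak_model(
            transcripts, genome, offsets=offsets, background=np.full(4, 0.25)
        )
        for off in offsets:
            assert np.allclose(model.log_odds[off], 0.0)
        assert np.allclose(model.training_scores, 0.0)

    def test_pseudocount_arithmetic(self):
        # 4 training sequences all A at offset -3, uniform background:
        # log2(((4+1)/(4+4)) / 0.25) = log2(2.5)
        genome, transcripts = self.train(n=4)
        for k in range(4):
            genome[f"c{k}"][12 + 9 - 3] = 0  # A at offset -3
        model = txrules.build_kozak_model(
            transcripts, genome, offsets=(-3,), background=np.full(4, 0.25)
        )
        assert model.log_odds[-3][0] == pytest.approx(np.log2(2.5))

    def test_p25_linear_interpolation(self):
        model = txrules.KozakModel(
            offsets=(-1,),
            log_odds={-1: np.zeros(4)},
            background=np.full(4, 0.25),
            training_scores=np.array([1.0, 2.0, 3.0, 4.0]),
        )
        assert model.p25 == pytest.approx(1.75)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            txrules.build_kozak_model([], {"c": encode("ACGT" * 10)})


class TestExtendOrf:
    def make_extendable(self, upstream_ctx=KOZAK_STRONG, block_stop=False):
        # UTR: 9 bases of context + upstream ATG + linker codons, then
        # weak-context annotated ATG
        linker = "TGA" if block_stop else "GCC"
        utr = upstream_ctx + "ATG" + linker + "GCC" + "TTTTTTTTT"
        genome, c0 = build_fixture_genome(utr, ctx="TTTATTTTA")
        L = len(genome["c"])
        t = txrules.TranscriptModel(
            id="t", gene_id="g", chrom="c", strand="+",
            exons=((0, L),), cds=((c0, L),), read_count=10,
        )
        return genome, t, c0

    def model_from_training(self):
        trainer = TestKozakModel()
        genome, transcripts = trainer.train(n=8)
        return txrules.build_kozak_model(transcripts, genome)

    def test_no_upstream_atg_unchanged(self):
        genome, transcripts = TestKozakModel().train(n=2)
        model = self.model_from_training()
        new_t, rec = txrules.extend_orf(transcripts[0], model, genome)
        assert not rec["extended"] and new_t == transcripts[0]

    def test_strong_upstream_candidate_extends_in_frame(self):
        model = self.model_from_training()
        genome, t, c0 = self.make_extendable()
        new_t, rec = txrules.extend_orf(t, model, genome)
        assert rec["extended"]
        old_len, new_len = t.cds_length, new_t.cds_length
        assert new_len > old_len and (new_len - old_len) % 3 == 0
        assert sorted(new_t.cds)[0][0] == 9  # extended to the planted ATG

    def test_candidate_beyond_stop_ineligible(self):
        model = self.model_from_training()
        genome, t, _ = self.make_extendable(block_stop=True)
        new_t, rec = txrules.extend_orf(t, model, genome)
        assert not rec["extended"] and rec["candidates"] == []

    def test_idempotent_and_never_shortens(self):
        model = self.model_from_training()
        genome, t, _ = self.make_extendable()
        once, _ = txrules.extend_orf(t, model, genome)
        twice, rec = txrules.extend_orf(once, model, genome)
        assert not rec["extended"] and twice == once
        assert once.cds_length >= t.cds_length

    def test_recovery_on_designed_simulated_genes(self, tx_dataset):
        genome, truth = tx_dataset["genome"], tx_dataset["truth"]
        by_gene = tx_dataset["by_gene"]
        primaries = []
        for gene in truth.genes:
            kept = txrules.filter_isoforms(by_gene[gene["gene_id"]])
            pid, _ = txrules.select_primary_isoform(kept)
            assert pid == gene["primary"]
            primaries.append((gene, next(t for t in kept if t.id == pid)))
        model = txrules.build_kozak_model([t for _, t in primaries], genome)
        for gene, t in primaries:
            new_t, rec = txrules.extend_orf(t, model, genome)
            if gene["class"] == "extended":
                assert rec["extended"], gene
                got = sorted(new_t.cds)[0][0] if t.strand == "+" else sorted(new_t.cds)[-1][1] - 1
                assert got == gene["true_start_genomic"]
            elif gene["class"] == "negative":
                assert not rec["extended"], gene


class TestAntisense:
    def mrna(self, iid="m", gene="gm", start=1_000, end=4_000, strand="+"):
        return txrules.TranscriptModel(
            id=iid, gene_id=gene, chrom="c", strand=strand,
            exons=((start, end),), cds=((start + 99, start + 999),), read_count=10,
        )

    def lnc(self, iid="l", start=2_000, end=3_500, strand="-"):
        return txrules.TranscriptModel(
            id=iid, gene_id="gl", chrom="c", strand=strand, exons=((start, end),), cds=()
        )

    def test_zero_overlap_no_call(self):
        calls = txrules.classify_antisense([self.mrna()], [self.lnc(start=10_000, end=11_000)])
        assert calls == []

    def test_overlap_threshold_boundary(self):
        m = self.mrna()  # length 3000
        # 870/3000 = 29% -> no call; 900/3000 = 30% -> call
        assert txrules.classify_antisense([m], [self.lnc(start=1_000, end=1_870)]) == []
        calls = txrules.classify_antisense([m], [self.lnc(start=1_000, end=1_900)])
        assert len(calls) == 1 and calls[0].overlap_fraction == pytest.approx(0.30)

    def test_same_strand_never_called(self):
        calls = txrules.classify_antisense([self.mrna()], [self.lnc(strand="+")])
        assert calls == []

    def test_bidirectional_internal_promoter(self):
        # lncRNA TSS (its '-' strand start = right end) inside the gene body,
        # 150 bp from an internal sense isoform TSS
        m1 = self.mrna("m1", start=1_000, end=4_000)
        m2 = self.mrna("m2", gene="gm", start=2_150, end=4_000)
        l = self.lnc(start=1_000, end=2_300)  # TSS at 2_299, 149 bp from 2_150
        calls = txrules.classify_antisense([m1, m2], [l])
        assert any(c.promoter_class == "bidirectional_internal" for c in calls)

    def test_unidirectional_internal(self):
        m = self.mrna()
        l = self.lnc(start=1_000, end=2_300)  # TSS 2_299 internal, no sense TSS nearby
        calls = txrules.classify_antisense([m], [l])
        assert calls[0].promoter_class == "unidirectional_internal"

    def test_adjacent_promoter(self):
        m = self.mrna()  # body 1_000-4_000
        l = self.lnc(start=1_100, end=4_200)  # '-' TSS at 4_199... inside; use one beyond
        l = self.lnc(start=1_000, end=4_250)  # TSS 4_249, 249 bp beyond body end
        calls = txrules.classify_antisense([m], [l])
        assert calls[0].promoter_class == "adjacent"
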