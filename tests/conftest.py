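import numpy as np
import pytest

from mosaikit import synthdata


@pytest.fixture(scope="session")
def small_sim():
    """A 2-chromosome hybrid with one crossover, one LOH, one trisomy."""
    config = synthdata.SimulationConfig(
        chrom_lengths=[300_000, 200_000],
        seed=11,
        event_specs=[
            synthdata.EventSpec("crossover", "chr01", start=150_000),
            synthdata.EventSpec("loh_interstitial", "chr02", start=50_000, end=90_000, haplotype="A"),
            synthdata.EventSpec("aneuploidy_whole", "chr02", haplotype="B", copies=2),
        ],
    )
    rng = config.rng()
    ancestor, parents = synthdata.simulate_parent_haplotypes(config, rng)
    hybrid, truth = synthdata.apply_hybrid_events(parents, config)
    return {
        "config": config,
        "ancestor": ancestor,
        "parents": parents,
        "hybrid": hybrid,
        "truth": truth,
        "rng": rng,
    }


@pytest.fixture(scope="session")
def tx_dataset():
    """Simulated transcript genome with designed Kozak contexts."""
    config = synthdata.SimulationConfig(chrom_lengths=[10_000], seed=23)
    genome, transcripts, truth = synthdata.emit_transcripts(config, n_genes=100, rng=config.rng())
    by_gene = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    return {"genome": genome, "transcripts": transcripts, "truth": truth, "by_gene": by_gene}


@pytest.fixture()
def full_mask():
    def make(lengths):
        return {c: np.array([[0, L]], dtype=np.int64) for c, L in lengths.items()}

    return make
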