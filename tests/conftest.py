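import pandas as pd
import pytest

from isgland import (
    CountMatrix,
    SimConfig,
    simulate_counts,
    simulate_known_isg_reference,
    simulate_promoters,
)
from isgland.motifs import load_default_motifs


@pytest.fixture(scope="session")
def motif_set():
    return load_default_motifs()


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_genes=400, n_reps=3, seed=7, n_peaks=300)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    """One small simulated study shared by read-only tests."""
    counts, design, truth = simulate_counts(small_config)
    promoters, tss, truth = simulate_promoters(small_config, truth)
    known = simulate_known_isg_reference(truth, 0.43, seed=small_config.seed)
    return {
        "config": small_config,
        "counts": counts,
        "design": design,
        "truth": truth,
        "promoters": promoters,
        "tss": tss,
        "known": known,
        "cm": CountMatrix(counts, design),
    }


def make_counts(rows, samples, genotypes, treatments) -> CountMatrix:
    """Tiny hand-built count matrix helper for unit tests."""
    counts = pd.DataFrame(rows, columns=samples)
    counts.index = [f"g{i}" for i in range(len(counts))]
    design = pd.DataFrame(
        {"genotype": genotypes, "treatment": treatments},
        index=pd.Index(samples, name="sample"),
    )
    return CountMatrix(counts, design)
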