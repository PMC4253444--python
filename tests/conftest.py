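import numpy as np
import pandas as pd
import pytest

from hepmeth import simulate as sim

MANIFEST_COLS = [
    "probe_id",
    "chromosome",
    "position",
    "strand",
    "gene",
    "genic_feature",
    "island_relation",
]


def make_manifest(rows):
    """Hand-built manifest from (probe, chrom, pos, strand, gene, feature, island) tuples."""
    df = pd.DataFrame(rows, columns=MANIFEST_COLS).set_index("probe_id")
    return df


def make_diff(probes, deltas, p_values=None, fdrs=None):
    """Minimal differential table for DMR / call-set tests."""
    deltas = np.asarray(deltas, dtype=float)
    p = np.asarray(p_values, dtype=float) if p_values is not None else np.zeros(len(deltas))
    fdr = np.asarray(fdrs, dtype=float) if fdrs is not None else p
    return pd.DataFrame(
        {
            "mean_a": 0.5 - deltas / 2,
            "mean_b": 0.5 + deltas / 2,
            "delta_beta": deltas,
            "p_value": p,
            "fdr": fdr,
            "n_a": 10,
            "n_b": 10,
        },
        index=pd.Index(probes, name="probe_id"),
    )


@pytest.fixture(scope="session")
def small_manifest():
    """2,000-probe manifest on 2 chromosomes, shared across tests."""
    design = sim.SimDesign(n_probes=2000, n_chromosomes=2)
    manifest, genes = sim.simulate_manifest(design, 424242)
    return manifest, genes, design


@pytest.fixture(scope="session")
def recovery_sim():
    """20,000-probe cohort with planted CpGs and DMR runs (one seed)."""
    design = sim.recovery_design(n_probes=20000)
    manifest, genes = sim.simulate_manifest(design, 1)
    cohort = sim.simulate_cohort(manifest, design, 2, gene_models=genes)
    return manifest, design, cohort
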