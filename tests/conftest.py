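import numpy as np
import pytest

import admixscan as ax


def make_snps(positions, chromosome="1", gpos=None, ref="A", alt="G"):
    """SNPTable from raw positions, constant 1 cM/Mb map unless given."""
    positions = np.asarray(positions, dtype=np.int64)
    n = len(positions)
    if np.ndim(chromosome) == 0:
        chroms = np.full(n, chromosome, dtype=object)
    else:
        chroms = np.asarray(chromosome, dtype=object)
    if gpos is None:
        gpos = positions * 1e-8
    return ax.SNPTable(
        snp_id=np.array([f"s{c}_{p}" for c, p in zip(chroms, positions)],
                        dtype=object),
        chromosome=chroms,
        position_bp=positions,
        genetic_pos=np.asarray(gpos, dtype=np.float64),
        ref_allele=np.full(n, ref, dtype=object),
        alt_allele=np.full(n, alt, dtype=object),
    )


def make_matrix(calls, populations, positions=None, chromosome="1"):
    """GenotypeMatrix from a call matrix (snps x individuals)."""
    calls = np.asarray(calls, dtype=np.int8)
    if positions is None:
        positions = np.arange(1, calls.shape[0] + 1) * 1000
    snps = make_snps(positions, chromosome)
    n_ind = calls.shape[1]
    return ax.GenotypeMatrix(
        snps,
        np.array([f"ind{i}" for i in range(n_ind)], dtype=object),
        np.asarray(populations, dtype=object),
        calls,
    )


@pytest.fixture(scope="session")
def neutral_sim():
    """One neutral cohort at default study conditions, shared across tests."""
    return ax.simulate_cohort(ax.SimulationConfig(seed=3))


@pytest.fixture(scope="session")
def neutral_lad(neutral_sim):
    """Estimated-panel LAD track for the shared neutral cohort."""
    gm = ax.filter_sites(neutral_sim.genotypes)
    freqs = ax.compute_frequencies(gm)
    hmm = ax.build_hmm(snps=gm.snps, panel_freqs=freqs)
    track = ax.posterior_dosage(hmm, gm.calls[:, gm.population_mask(ax.ADMIXED)])
    return ax.cohort_lad(track, gm.snps)
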