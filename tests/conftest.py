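import numpy as np
import pandas as pd
import pytest

from aemap import ae_mapping, synthgen
from aemap.ae_core import compute_ae_profiles


@pytest.fixture(scope="session")
def small_config():
    return synthgen.SimConfig(n_samples=60, n_loci=12, snps_per_block=12, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_config):
    """End-to-end small synthetic dataset shared across tests (read-only)."""
    genotypes = synthgen.simulate_haplotypes(small_config)
    truth = synthgen.make_ground_truth(genotypes, small_config)
    sim = synthgen.simulate_ae_intensities(genotypes, truth, small_config)
    profiles = compute_ae_profiles(genotypes, sim)
    return {
        "config": small_config,
        "genotypes": genotypes,
        "truth": truth,
        "sim": sim,
        "profiles": profiles,
    }


def locus_arrays(genotypes, profiles, n_loci):
    """(delta, codes) per locus for permutation-FDR style calls."""
    wide = profiles.pivot_table(
        index="sample", columns="transcript_id", values="delta_het", aggfunc="first"
    ).reindex([f"S{i}" for i in range(genotypes.n_samples)])
    out = []
    for b in range(n_loci):
        tx = f"T{b}"
        if tx not in wide.columns:
            continue
        idx = genotypes.locus_snp_indices(b)
        out.append((wide[tx].to_numpy(float), ae_mapping._encode_matrix(genotypes.haplotypes, idx)))
    return out


@pytest.fixture(scope="session")
def mapped_small(small_sim):
    return ae_mapping.map_locus_from_sim(
        small_sim["genotypes"], small_sim["profiles"], small_sim["sim"].transcripts
    )
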