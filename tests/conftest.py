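import numpy as np
import pytest

from tagarray.panel_io import HaplotypePanel, SiteRecord
from tagarray.synth_panel import SimParams, simulate_panel


def make_panel(alleles, positions=None, pops=None, chrom="1"):
    """Build a biallelic panel from a (haplotypes x sites) 0/1 matrix.

    Rows 2i, 2i+1 form sample i; ``pops`` assigns one population per sample
    (default: all 'EUR').
    """
    alleles = np.asarray(alleles, dtype=np.int8)
    n_hap, n_sites = alleles.shape
    assert n_hap % 2 == 0
    if positions is None:
        positions = [100 * (j + 1) for j in range(n_sites)]
    if pops is None:
        pops = ["EUR"] * (n_hap // 2)
    samples = [(f"s{i}", pops[i]) for i in range(n_hap // 2)]
    return HaplotypePanel.from_arrays(chrom, positions, alleles, samples)


@pytest.fixture
def two_pop_panel():
    """Small seeded synthetic panel: 2 populations x 30 samples, 80 sites."""
    params = SimParams(
        n_sites=80,
        chrom_length=40_000,
        n_samples_per_pop={"AFR": 30, "EUR": 30},
        seed=7,
    )
    panel, _ = simulate_panel(params)
    return panel


@pytest.fixture
def random_site_factory():
    """Factory for random SiteRecords with controllable fields."""

    def make(rng, vid, chrom="1", pos=None, score=None, categories=()):
        return SiteRecord(
            chrom=chrom,
            pos=int(pos if pos is not None else rng.integers(1, 10**6)),
            vid=vid,
            ref="A",
            alts=("C",),
            design_score=score,
            categories=set(categories),
        )

    return make
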