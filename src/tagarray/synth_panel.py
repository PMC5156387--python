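"""Synthetic multi-population phased haplotype panels.

Population allele frequencies diverge from a shared ancestral frequency
under the Balding–Nichols model: given ancestral frequency ``p`` and a
population-specific differentiation parameter ``F`` (an FST analogue), the
population frequency is drawn from ``Beta(p(1−F)/F, (1−p)(1−F)/F)``, whose
mean is ``p`` and variance ``p(1−p)F``.

Haplotypes are founder mosaics: each population carries ``n_founders``
founder haplotypes drawn site-wise from its frequencies, and every sample
haplotype copies a founder whose identity is resampled between adjacent
sites with probability ``1 − exp(−switch_rate · distance)``.  This yields
distance-decaying LD at O(sites × samples) cost; the strength of LD is set
by the founder count and switch rate.  A per-site flip rate adds private
variation.  Panels from any external phased VCF are equally accepted
downstream — this generator only removes the need for one in testing.

Two refinements make the founder pool behave like real haplotypes rather
than frequency noise.  First, founder alleles are thresholded from a shared
latent Gaussian field (``u(h, j)``, one draw per founder × site, AR(1) along
the chromosome with correlation ``exp(−d / founder_ld_scale)``), so each
founder is marginally Bernoulli(pop frequency) but founders carry internal,
distance-decaying LD — without this, pairwise r² between common sites would
collapse to ~``1/n_founders``.  Second, the latent field is shared across
populations, so founder ``h`` is the *same ancestral haplotype* seen through
each population's drifted frequencies: a rare variant rides the same founder
background in every population that carries it, which is what makes
cross-population imputation of low-frequency variation possible at all.
Setting ``founder_ld_scale = 0`` recovers fully independent founder alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .panel_io import DEFAULT_POPULATIONS, DataError, HaplotypePanel

# Differentiation defaults: African-descent panels sit closest to the
# ancestral pool, out-of-Africa panels drift further, matching the ordering
# of continental FST estimates.
DEFAULT_FST = {
    "AAC": 0.05,
    "AFR": 0.05,
    "AMR": 0.10,
    "ASN": 0.15,
    "EUR": 0.12,
    "SAS": 0.12,
}


@dataclass
class SimParams:
    """Parameters of the synthetic panel generator.

    Defaults describe the standard test condition: six populations of 100
    samples on a 200 kb chromosome with 500 segregating sites.
    """

    n_sites: int = 500
    chrom_length: int = 200_000
    n_samples_per_pop: dict[str, int] = field(
        default_factory=lambda: {p: 100 for p in DEFAULT_POPULATIONS}
    )
    fst: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FST))
    beta_shape: tuple[float, float] = (0.5, 0.5)
    n_founders: int = 120
    switch_rate: float = 1e-5
    flip_rate: float = 1e-4
    founder_ld_scale: float = 30_000.0
    seed: int = 0
    chrom: str = "1"

    def __post_init__(self) -> None:
        if self.n_founders < 1:
            raise DataError("n_founders must be >= 1")
        if self.switch_rate < 0 or self.flip_rate < 0 or self.founder_ld_scale < 0:
            raise DataError("rates must be >= 0")
        for pop, f in self.fst.items():
            if not (0.0 < f < 1.0):
                raise DataError(f"fst[{pop}]={f} must lie in (0,1)")
        for pop in self.n_samples_per_pop:
            if pop not in self.fst:
                raise DataError(f"no fst value for population {pop!r}")


def simulate_frequencies(
    params: SimParams, rng: Optional[np.random.Generator] = None
) -> dict[str, np.ndarray]:
    """Draw per-population allele frequencies under Balding–Nichols.

    Returns a map population → frequency vector of length ``n_sites``;
    deterministic given ``params.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    a, b = params.beta_shape
    ancestral = rng.beta(a, b, size=params.n_sites)
    # guard against Beta parameters of exactly 0 at the spectrum edges
    ancestral = np.clip(ancestral, 1e-9, 1 - 1e-9)
    freqs = {}
    for pop in params.n_samples_per_pop:
        f = params.fst[pop]
        scale = (1 - f) / f
        freqs[pop] = rng.beta(ancestral * scale, (1 - ancestral) * scale)
    return freqs


def simulate_haplotypes(
    freqs: Mapping[str, np.ndarray],
    params: SimParams,
    rng: Optional[np.random.Generator] = None,
) -> HaplotypePanel:
    """Generate a phased founder-mosaic panel from population frequencies.

    Positions are drawn uniformly without replacement on
    ``[1, chrom_length]`` and sorted; every site is biallelic A→C.
    """
    if params.n_sites > params.chrom_length:
        raise DataError(
            f"n_sites={params.n_sites} exceeds chrom_length={params.chrom_length}"
        )
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    positions = np.sort(
        rng.choice(params.chrom_length, size=params.n_sites, replace=False) + 1
    )
    dists = np.diff(positions).astype(np.float64)
    p_switch = 1.0 - np.exp(-params.switch_rate * dists)

    # Latent founder field, shared across populations: founder h is one
    # ancestral haplotype viewed through each population's frequencies.
    if params.founder_ld_scale > 0:
        from scipy.special import ndtr

        rho = np.exp(-dists / params.founder_ld_scale)
        z = np.empty((params.n_founders, params.n_sites))
        z[:, 0] = rng.standard_normal(params.n_founders)
        noise = rng.standard_normal((params.n_founders, params.n_sites - 1))
        for j in range(1, params.n_sites):
            r = rho[j - 1]
            z[:, j] = r * z[:, j - 1] + np.sqrt(1.0 - r * r) * noise[:, j - 1]
        u = ndtr(z)
    else:
        u = rng.random((params.n_founders, params.n_sites))

    samples: list[tuple[str, str]] = []
    blocks: list[np.ndarray] = []
    for pop in params.n_samples_per_pop:
        n_hap = 2 * params.n_samples_per_pop[pop]
        founders = (u < freqs[pop]).astype(np.int8)
        # founder-index paths: resample (uniformly, may stay) at each switch
        idx = np.empty((n_hap, params.n_sites), dtype=np.intp)
        idx[:, 0] = rng.integers(params.n_founders, size=n_hap)
        switches = rng.random((n_hap, params.n_sites - 1)) < p_switch
        redraw = rng.integers(params.n_founders, size=(n_hap, params.n_sites - 1))
        for j in range(1, params.n_sites):
            idx[:, j] = np.where(switches[:, j - 1], redraw[:, j - 1], idx[:, j - 1])
        hap = founders[idx, np.arange(params.n_sites)]
        if params.flip_rate > 0:
            flips = rng.random(hap.shape) < params.flip_rate
            hap = np.where(flips, 1 - hap, hap).astype(np.int8)
        blocks.append(hap)
        samples.extend(
            (f"{pop}_{i:04d}", pop) for i in range(params.n_samples_per_pop[pop])
        )

    alleles = np.vstack(blocks)
    return HaplotypePanel.from_arrays(params.chrom, positions, alleles, samples)


def simulate_panel(params: SimParams) -> tuple[HaplotypePanel, dict[str, np.ndarray]]:
    """Convenience wrapper: frequencies then haplotypes from one seed."""
    rng = np.random.default_rng(params.seed)
    freqs = simulate_frequencies(params, rng)
    panel = simulate_haplotypes(freqs, params, rng)
    return panel, freqs
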