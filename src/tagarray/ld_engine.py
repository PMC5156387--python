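"""Pairwise linkage disequilibrium from phased haplotypes.

r² here is the squared correlation between allele indicators on the same
haplotype, computed from phased haplotype counts (the statistic produced by
``vcftools --hap-r2``), not the genotype-composite r².  LD against a site
that is monomorphic in the chosen population is *undefined*, represented by
the :data:`UNDEFINED_LD` sentinel so that callers can treat such targets as
uncoverable rather than silently covered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .panel_io import DataError, HaplotypePanel

_CLIP_TOL = 1e-12


class _UndefinedLD:
    """Singleton marker for LD against a monomorphic site."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNDEFINED_LD"

    def __bool__(self) -> bool:
        return False


UNDEFINED_LD = _UndefinedLD()

LDValue = Union[float, _UndefinedLD]


@dataclass(frozen=True)
class LDResult:
    vid_a: str
    vid_b: str
    population: str
    r2: float
    d_prime: float
    distance_bp: int


def _check_binary(h: np.ndarray, name: str) -> np.ndarray:
    h = np.asarray(h)
    if h.ndim != 1 or h.size < 2:
        raise DataError(f"{name}: need a 1-D haplotype vector of length >= 2")
    if not np.isin(h, (0, 1)).all():
        raise DataError(f"{name}: haplotype vector must be binary (biallelic site)")
    return h.astype(np.float64)


def _haplotype_stats(h_a: np.ndarray, h_b: np.ndarray):
    p_a = h_a.mean()
    p_b = h_b.mean()
    p_ab = (h_a * h_b).mean()
    return p_a, p_b, p_ab - p_a * p_b


def r2_phased(h_a, h_b) -> LDValue:
    """Haplotype r² between two binary allele vectors.

    ``r² = (p_ab − p_a·p_b)² / (p_a(1−p_a) p_b(1−p_b))`` where ``p_ab`` is
    the frequency of the (1,1) haplotype configuration.  Returns
    :data:`UNDEFINED_LD` when either site is monomorphic in the vector.
    """
    h_a = _check_binary(h_a, "h_a")
    h_b = _check_binary(h_b, "h_b")
    if h_a.size != h_b.size:
        raise DataError("haplotype vectors differ in length")
    p_a, p_b, d = _haplotype_stats(h_a, h_b)
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom == 0.0:
        return UNDEFINED_LD
    r2 = d * d / denom
    if r2 > 1.0 + _CLIP_TOL:
        raise DataError(f"numerical failure: r2 = {r2} > 1")
    return float(min(max(r2, 0.0), 1.0))


def d_prime(h_a, h_b) -> LDValue:
    """|D′|: D normalized by its maximum attainable magnitude.

    Equals 1 whenever at least one haplotype configuration is absent.
    """
    h_a = _check_binary(h_a, "h_a")
    h_b = _check_binary(h_b, "h_b")
    if h_a.size != h_b.size:
        raise DataError("haplotype vectors differ in length")
    p_a, p_b, d = _haplotype_stats(h_a, h_b)
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return UNDEFINED_LD
    if d >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    if d_max == 0.0:
        return UNDEFINED_LD
    val = abs(d) / d_max
    return float(min(max(val, 0.0), 1.0))


def maf(panel: HaplotypePanel, vid: str, population: str) -> float:
    """Folded minor-allele frequency of a site within one population.

    For multiallelic sites this is ``1 − freq(most common allele)``.
    """
    if population not in panel.populations():
        raise DataError(
            f"unknown population {population!r}; panel has {panel.populations()}"
        )
    rows = panel.pop_rows(population)
    col = panel.column(vid)[rows]
    site = panel.site(vid)
    if site.is_multiallelic:
        counts = np.bincount(col, minlength=site.n_alleles)
        return float(1.0 - counts.max() / col.size)
    f = float(col.mean())
    return min(f, 1.0 - f)


def windowed_ld(
    panel: HaplotypePanel,
    focal: str,
    window_bp: int,
    population: str,
) -> list[LDResult]:
    """LD of one focal site against every biallelic site within a window.

    Returns one :class:`LDResult` per biallelic same-chromosome site with
    ``|pos − focal_pos| <= window_bp`` (the focal site itself excluded).
    Sites with undefined LD in the population are omitted; the caller can
    compare the output length with the candidate count to see how many.
    """
    if focal not in panel.vid_index:
        raise DataError(f"focal site {focal!r} not in panel")
    fsite = panel.site(focal)
    if fsite.is_multiallelic:
        raise DataError(f"focal site {focal!r} is not biallelic")
    rows = panel.pop_rows(population)
    if rows.size == 0:
        raise DataError(f"population {population!r} has no samples in panel")
    h_f = panel.column(focal)[rows]
    if h_f.min() == h_f.max():
        raise DataError(
            f"focal site {focal!r} is monomorphic in population {population!r}"
        )
    out: list[LDResult] = []
    n_undefined = 0
    for j, s in enumerate(panel.sites):
        if s.vid == focal or s.chrom != fsite.chrom or s.is_multiallelic:
            continue
        dist = abs(s.pos - fsite.pos)
        if dist > window_bp:
            continue
        h = panel.alleles[rows, j]
        r2 = r2_phased(h_f, h)
        if r2 is UNDEFINED_LD:
            n_undefined += 1
            continue
        dp = d_prime(h_f, h)
        out.append(
            LDResult(focal, s.vid, population, r2, float(dp), dist)
        )
    if n_undefined:
        import logging

        logging.getLogger(__name__).debug(
            "windowed_ld(%s, %s): %d monomorphic sites skipped",
            focal, population, n_undefined,
        )
    return out


def r2_matrix(h: np.ndarray) -> np.ndarray:
    """All-pairs haplotype r² for a (haplotypes × sites) binary matrix.

    Monomorphic columns yield ``nan`` rows/columns (undefined LD).  The
    diagonal of polymorphic sites is 1.
    """
    h = np.asarray(h, dtype=np.float64)
    n = h.shape[0]
    p = h.mean(axis=0)
    pab = (h.T @ h) / n
    d = pab - np.outer(p, p)
    var = p * (1 - p)
    denom = np.outer(var, var)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(denom > 0, d * d / denom, np.nan)
    np.clip(r2, 0.0, 1.0, out=r2)
    # exact self-LD for polymorphic sites (guards float associativity)
    diag = np.where(var > 0, 1.0, np.nan)
    r2[np.diag_indices_from(r2)] = diag
    return r2
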