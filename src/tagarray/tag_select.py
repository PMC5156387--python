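"""Greedy cross-population tag-SNP selection over a fixed array scaffold.

Given a phased multi-population panel, a set of priority regions, and the
vids already committed to the array (the fixed scaffold), this module picks
additional tag SNPs by greedy maximum coverage: the coverage unit is a
(population, target) pair, where targets are the biallelic region sites with
population MAF at or above ``tag_min_maf``, and a pair is covered once some
scaffold-or-selected site within ``ld_window_bp`` reaches haplotype r² of at
least ``tag_min_r2`` with the target in that population (a site covers
itself with r² = 1).  Selection stops when no remaining candidate covers any
uncovered pair.

The greedy criterion sums newly covered pairs across populations; optional
per-population weights change that aggregation.  Coverage summaries report
both the fraction of targets at the selection threshold and at the stricter
enhanced-region goal of r² ≥ 0.8.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ld_engine import r2_matrix
from .panel_io import DataError, HaplotypePanel
from .regions import RegionSet

logger = logging.getLogger(__name__)


@dataclass
class DesignParams:
    """Array-design thresholds.

    Defaults encode the published design rules: tags require MAF ≥ 1 % and
    r² ≥ 0.2; the enhanced-region coverage goal is a minimum r² of 0.8
    against the backbone's mean-r²-of-0.6 criterion; fine-mapping proxies
    need r² ≥ 0.6 within a 200 kb window; loci take ±100 kb flanks and genes
    ±50 kb; probes must exceed an Illumina design score of 0.5.
    """

    tag_min_maf: float = 0.01
    tag_min_r2: float = 0.2
    enhanced_min_r2: float = 0.8
    backbone_mean_r2: float = 0.6
    finemap_r2: float = 0.6
    finemap_window_bp: int = 200_000  # total window, ±100 kb around the index
    locus_flank_bp: int = 100_000
    gene_flank_bp: int = 50_000
    design_score_min: float = 0.5
    maf_bin_edges: tuple[float, ...] = (0.005, 0.01, 0.05)
    top_k: int = 500
    ld_window_bp: int = 250_000
    pop_weights: Optional[dict[str, float]] = None
    sd_ddof: int = 1  # sample SD for manifest statistics

    def __post_init__(self) -> None:
        for name in ("tag_min_maf", "tag_min_r2", "enhanced_min_r2",
                     "backbone_mean_r2", "finemap_r2", "design_score_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise DataError(f"{name}={v} outside [0,1]")
        if list(self.maf_bin_edges) != sorted(set(self.maf_bin_edges)):
            raise DataError("maf_bin_edges must be strictly increasing")
        if min(self.finemap_window_bp, self.locus_flank_bp,
               self.gene_flank_bp, self.ld_window_bp) < 0:
            raise DataError("window sizes must be >= 0")


@dataclass
class TagSelectionResult:
    selected: list[str]
    coverage: dict[str, dict[str, float]]  # population -> target vid -> best r2
    summary: pd.DataFrame  # indexed by population


class _RegionLD:
    """Per-population r² and MAF over the biallelic sites inside regions."""

    def __init__(self, panel: HaplotypePanel, regions: RegionSet, ld_window_bp: int):
        panel_chroms = set(panel.chroms)
        region_chroms = {r.chrom for r in regions}
        if region_chroms and not (region_chroms & panel_chroms):
            raise DataError(
                f"regions on chromosomes {sorted(region_chroms)} but panel has "
                f"{sorted(panel_chroms)}"
            )
        self.idx = [
            j
            for j, s in enumerate(panel.sites)
            if not s.is_multiallelic and regions.contains_pos1(s.chrom, s.pos)
        ]
        self.vids = [panel.sites[j].vid for j in self.idx]
        self.pos = np.array([panel.sites[j].pos for j in self.idx], dtype=np.int64)
        chroms = [panel.sites[j].chrom for j in self.idx]
        same_chrom = np.array(
            [[a == b for b in chroms] for a in chroms], dtype=bool
        )
        self.window = same_chrom & (
            np.abs(self.pos[:, None] - self.pos[None, :]) <= ld_window_bp
        )
        self.pops = panel.populations()
        self.r2: dict[str, np.ndarray] = {}
        self.maf: dict[str, np.ndarray] = {}
        for pop in self.pops:
            rows = panel.pop_rows(pop)
            h = panel.alleles[np.ix_(rows, self.idx)]
            f = h.mean(axis=0)
            self.maf[pop] = np.minimum(f, 1 - f)
            self.r2[pop] = r2_matrix(h)  # nan where undefined

    @property
    def n(self) -> int:
        return len(self.idx)

    def mean_maf(self) -> np.ndarray:
        return np.mean([self.maf[p] for p in self.pops], axis=0)


def _empty_result(pops: Sequence[str]) -> TagSelectionResult:
    summary = pd.DataFrame(
        {
            "mean_best_r2": 0.0,
            "frac_ge_min_r2": 0.0,
            "frac_ge_enhanced_r2": 0.0,
            "n_targets": 0,
            "n_uncoverable": 0,
        },
        index=pd.Index(pops, name="population"),
    )
    return TagSelectionResult([], {p: {} for p in pops}, summary)


def _summarize(
    ld: _RegionLD,
    targets: dict[str, np.ndarray],
    onarray_mask: np.ndarray,
    tag_min_r2: float,
    enhanced_min_r2: float,
    uncoverable: Optional[dict[str, int]] = None,
) -> tuple[dict[str, dict[str, float]], pd.DataFrame]:
    """Best-r² coverage of each (population, target) by the on-array mask."""
    coverage: dict[str, dict[str, float]] = {}
    rows = []
    for pop in ld.pops:
        t_idx = np.flatnonzero(targets[pop])
        best = np.zeros(len(t_idx))
        if onarray_mask.any() and len(t_idx):
            r2 = ld.r2[pop][np.ix_(onarray_mask.nonzero()[0], t_idx)].copy()
            r2[~ld.window[np.ix_(onarray_mask.nonzero()[0], t_idx)]] = np.nan
            with np.errstate(invalid="ignore"):
                best = np.nan_to_num(np.nanmax(r2, axis=0), nan=0.0) if r2.size else best
        coverage[pop] = {ld.vids[j]: float(b) for j, b in zip(t_idx, best)}
        n_t = len(t_idx)
        n_unc = (
            uncoverable[pop]
            if uncoverable is not None
            else int((best < tag_min_r2).sum())
        )
        rows.append(
            {
                "population": pop,
                "mean_best_r2": float(best.mean()) if n_t else 0.0,
                "frac_ge_min_r2": float((best >= tag_min_r2).mean()) if n_t else 0.0,
                "frac_ge_enhanced_r2": float((best >= enhanced_min_r2).mean()) if n_t else 0.0,
                "n_targets": n_t,
                "n_uncoverable": n_unc,
            }
        )
    summary = pd.DataFrame(rows).set_index("population")
    return coverage, summary


def select_tags(
    panel: HaplotypePanel,
    regions: RegionSet,
    fixed: set[str],
    params: DesignParams,
) -> TagSelectionResult:
    """Greedily augment a fixed scaffold with tag SNPs in priority regions.

    Ties in coverage gain break by larger mean MAF across populations, then
    smaller position, then vid, making the output order-deterministic.
    """
    missing = fixed - set(panel.vid_index)
    if missing:
        raise DataError(f"fixed vids absent from panel: {sorted(missing)[:5]}")
    ld = _RegionLD(panel, regions, params.ld_window_bp)
    if ld.n == 0 or all(
        np.isnan(ld.r2[p]).all() for p in ld.pops
    ):
        logger.warning("select_tags: no polymorphic biallelic sites in regions")
        return _empty_result(ld.pops)

    targets = {
        pop: ld.maf[pop] >= params.tag_min_maf for pop in ld.pops
    }
    fixed_mask = np.array([v in fixed for v in ld.vids], dtype=bool)
    candidate_mask = ~fixed_mask
    # design-score filter applies only where a score is provided
    for k, j in enumerate(ld.idx):
        score = panel.sites[j].design_score
        if score is not None and score <= params.design_score_min:
            candidate_mask[k] = False
    candidate_mask &= np.any(
        [ld.maf[p] >= params.tag_min_maf for p in ld.pops], axis=0
    )

    weights = params.pop_weights or {}
    # cover[pop][c, t]: candidate-or-fixed site c covers target t in pop
    cover = {}
    uncovered = {}
    for pop in ld.pops:
        r2 = ld.r2[pop]
        cov = (r2 >= params.tag_min_r2) & ld.window
        cov &= ~np.isnan(r2)
        cov &= targets[pop][None, :]
        cover[pop] = cov
        unc = targets[pop].copy()
        if fixed_mask.any():
            unc &= ~cov[fixed_mask].any(axis=0)
        uncovered[pop] = unc

    selected_idx: list[int] = []
    mean_maf = ld.mean_maf()
    avail = candidate_mask.copy()
    while True:
        gain = np.zeros(ld.n)
        for pop in ld.pops:
            w = weights.get(pop, 1.0)
            if uncovered[pop].any():
                gain += w * (cover[pop] & uncovered[pop][None, :]).sum(axis=1)
        gain[~avail] = 0.0
        if not (gain > 0).any():
            break
        best_gain = gain.max()
        tied = np.flatnonzero(gain == best_gain)
        # tie-break: larger mean MAF, smaller pos, vid
        order = sorted(
            tied, key=lambda k: (-mean_maf[k], ld.pos[k], ld.vids[k])
        )
        pick = order[0]
        selected_idx.append(pick)
        avail[pick] = False
        for pop in ld.pops:
            uncovered[pop] &= ~cover[pop][pick]

    onarray = fixed_mask.copy()
    onarray[selected_idx] = True
    uncoverable = {pop: int(uncovered[pop].sum()) for pop in ld.pops}
    coverage, summary = _summarize(
        ld, targets, onarray, params.tag_min_r2, params.enhanced_min_r2, uncoverable
    )
    return TagSelectionResult([ld.vids[k] for k in selected_idx], coverage, summary)


def coverage_report(
    panel: HaplotypePanel,
    regions: RegionSet,
    sites: set[str],
    params: DesignParams,
) -> pd.DataFrame:
    """Coverage of region targets by an arbitrary site set (e.g. a scaffold).

    Per population: mean best r², fraction of targets at the enhanced goal
    (r² ≥ 0.8) and at the selection threshold, plus counts of targets and of
    targets left below the threshold.
    """
    missing = sites - set(panel.vid_index)
    if missing:
        raise DataError(f"sites absent from panel: {sorted(missing)[:5]}")
    ld = _RegionLD(panel, regions, params.ld_window_bp)
    targets = {pop: ld.maf[pop] >= params.tag_min_maf for pop in ld.pops}
    mask = np.array([v in sites for v in ld.vids], dtype=bool)
    _, summary = _summarize(
        ld, targets, mask, params.tag_min_r2, params.enhanced_min_r2
    )
    return summary
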