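"""Fine-mapping proxy selection around GWAS index variants.

A fine-mapping set is the index variant plus every correlated site with
haplotype r² ≥ 0.6 to the index within a 200 kb window (±100 kb), computed
in the LD reference population implied by the discovery ancestry.
Candidate proxies are excluded when triallelic-or-more or when their MAF in
the LD population is below 1 %; both exclusions are counted so the manifest
can report them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ld_engine import UNDEFINED_LD, maf as pop_maf, r2_phased
from .panel_io import DataError, HaplotypePanel
from .prioritize import RankedLocus, pick_ld_population
from .tag_select import DesignParams

logger = logging.getLogger(__name__)


@dataclass
class FinemapSet:
    index_vid: str
    ld_population: str
    members: list[tuple[str, float]]  # (vid, r2 to index); index itself at r2=1
    n_excluded_triallelic: int
    n_excluded_rare: int

    @property
    def n_members(self) -> int:
        return len(self.members)


def select_proxies(
    panel: HaplotypePanel,
    index_vid: str,
    params: DesignParams,
    population: str,
) -> FinemapSet:
    """Index variant plus all r²-qualified proxies within the window.

    The window spans ``±(finemap_window_bp / 2)`` around the index position.
    Exclusion order: triallelic first, then MAF < ``tag_min_maf`` in the LD
    population; surviving candidates are kept when r² to the index reaches
    ``finemap_r2``.  Monomorphic candidates (undefined LD) are never kept.
    """
    if index_vid not in panel.vid_index:
        raise DataError(f"index variant {index_vid!r} not in panel")
    index = panel.site(index_vid)
    if index.is_multiallelic:
        raise DataError(f"index variant {index_vid!r} is triallelic-or-more")
    rows = panel.pop_rows(population)
    if rows.size == 0:
        raise DataError(f"population {population!r} has no samples")
    h_index = panel.column(index_vid)[rows]
    if h_index.min() == h_index.max():
        raise DataError(
            f"index variant {index_vid!r} is monomorphic in {population!r}"
        )
    half_window = params.finemap_window_bp // 2
    members: list[tuple[str, float]] = [(index_vid, 1.0)]
    n_tri = n_rare = 0
    for j, s in enumerate(panel.sites):
        if s.vid == index_vid or s.chrom != index.chrom:
            continue
        if abs(s.pos - index.pos) > half_window:
            continue
        if s.is_multiallelic:
            n_tri += 1
            continue
        if pop_maf(panel, s.vid, population) < params.tag_min_maf:
            n_rare += 1
            continue
        r2 = r2_phased(h_index, panel.alleles[rows, j])
        if r2 is UNDEFINED_LD:
            continue
        if r2 >= params.finemap_r2:
            members.append((s.vid, float(r2)))
    members.sort(key=lambda m: panel.site(m[0]).pos)
    return FinemapSet(index_vid, population, members, n_tri, n_rare)


def finemap_batch(
    panel: HaplotypePanel,
    ranked_loci: Sequence[RankedLocus],
    params: DesignParams,
) -> tuple[list[FinemapSet], dict]:
    """One fine-mapping set per ranked locus, plus a summary manifest.

    Loci whose index variant is absent from the panel are skipped and listed
    in the manifest.  Member counts are summarized with mean and SD (sample
    SD by default, ``params.sd_ddof = 0`` for population SD) together with
    the pooled MAF distribution of all distinct members.
    """
    sets: list[FinemapSet] = []
    skipped: list[str] = []
    for locus in ranked_loci:
        if locus.vid not in panel.vid_index:
            skipped.append(locus.vid)
            continue
        pop = pick_ld_population(locus.ancestry).code
        sets.append(select_proxies(panel, locus.vid, params, pop))
    counts = np.array([s.n_members for s in sets], dtype=float)
    pooled_vids = sorted({vid for s in sets for vid, _ in s.members})
    pooled_maf = []
    for vid in pooled_vids:
        fs = [
            pop_maf(panel, vid, s.ld_population)
            for s in sets
            if vid in {v for v, _ in s.members}
        ]
        pooled_maf.append(float(np.mean(fs)))
    manifest = {
        "n_loci": len(sets),
        "n_skipped": len(skipped),
        "skipped": skipped,
        "counts": counts.astype(int).tolist(),
        "mean_members": float(counts.mean()) if len(counts) else math.nan,
        "sd_members": float(counts.std(ddof=params.sd_ddof))
        if len(counts) > params.sd_ddof
        else math.nan,
        "max_members": int(counts.max()) if len(counts) else 0,
        "n_unique_members": len(pooled_vids),
        "mean_member_maf": float(np.mean(pooled_maf)) if pooled_maf else math.nan,
        "n_excluded_triallelic": sum(s.n_excluded_triallelic for s in sets),
        "n_excluded_rare": sum(s.n_excluded_rare for s in sets),
    }
    if skipped:
        logger.warning("finemap_batch: %d index variants absent from panel", len(skipped))
    return sets, manifest


def write_finemap_tsv(sets: Sequence[FinemapSet], path, header_comment=None) -> None:
    rows = []
    for s in sets:
        for vid, r2 in s.members:
            rows.append(
                {
                    "index_vid": s.index_vid,
                    "ld_population": s.ld_population,
                    "member_vid": vid,
                    "r2": r2,
                }
            )
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        pd.DataFrame(
            rows, columns=["index_vid", "ld_population", "member_vid", "r2"]
        ).to_csv(fh, sep="\t", index=False)
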