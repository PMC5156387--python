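"""Ranking of GWAS-catalog-style associations and locus-window emission.

Associations are ranked by ascending discovery sample size — a small
discovery cohort reaching genome-wide significance implies a larger effect,
so those loci are given priority for refinement — with p-value and variant
id as deterministic tie-breaks.  The top-ranked associations (500 by
default) define the loci taken forward for tag augmentation and
fine-mapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Optional, Sequence

import pandas as pd

from .panel_io import DataError
from .regions import Region, locus_window

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssociationRow:
    vid: str
    trait: str
    discovery_n: int
    p_value: float
    ancestry: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if self.discovery_n < 1:
            raise DataError(f"{self.vid}: discovery_n must be >= 1")
        if not (0 < self.p_value <= 1):
            raise DataError(f"{self.vid}: p_value must lie in (0,1]")


@dataclass(frozen=True)
class RankedLocus:
    rank: int
    vid: str
    trait: str
    discovery_n: int
    p_value: float
    ancestry: frozenset[str]
    region: Optional[Region] = None


class LDPopulation(NamedTuple):
    """LD reference population plus a flag marking rules beyond the core ones."""

    code: str
    extension: bool = False


def rank_associations(
    rows: Sequence[AssociationRow],
    top_k: int = 500,
    positions: Optional[Mapping[str, tuple[str, int]]] = None,
    flank_bp: int = 100_000,
) -> list[RankedLocus]:
    """Deduplicate, rank and truncate an association table.

    Rows are deduplicated by vid (keeping the smallest discovery_n, then the
    smallest p-value), sorted ascending by (discovery_n, p_value, vid), and
    the first ``top_k`` returned with ranks 1..top_k.  When ``positions``
    maps a vid to its (chrom, 1-based pos), each ranked locus carries its
    ±``flank_bp`` window.
    """
    if not rows:
        logger.warning("rank_associations: empty input")
        return []
    best: dict[str, AssociationRow] = {}
    for r in rows:
        cur = best.get(r.vid)
        if cur is None or (r.discovery_n, r.p_value) < (cur.discovery_n, cur.p_value):
            best[r.vid] = r
    ordered = sorted(best.values(), key=lambda r: (r.discovery_n, r.p_value, r.vid))
    out = []
    for rank, r in enumerate(ordered[:top_k], start=1):
        region = None
        if positions is not None and r.vid in positions:
            chrom, pos = positions[r.vid]
            region = locus_window(chrom, pos, flank_bp, label=r.vid)
        out.append(
            RankedLocus(rank, r.vid, r.trait, r.discovery_n, r.p_value, r.ancestry, region)
        )
    return out


_EUROPEAN = {"european", "european-descent", "caucasian", "european american"}
_ASIAN = {
    "east asian", "south asian", "asian", "east asian-descent",
    "south asian-descent", "chinese", "japanese", "korean",
}
_AFRICAN = {"african", "african american", "african-descent", "african ancestry"}
_HISPANIC = {"hispanic", "latino", "hispanic/latino", "hispanic or latino"}


def pick_ld_population(ancestry: frozenset[str] | set[str]) -> LDPopulation:
    """Choose the LD reference super-population for a discovery ancestry set.

    Core rules: any European-descent component → EUR; otherwise an
    East/South-Asian-only discovery → ASN.  As documented extensions
    (``extension=True`` so callers can override), African-descent maps to
    AFR and Hispanic/Latino to AMR.
    """
    if not ancestry:
        raise DataError("pick_ld_population: empty ancestry set")
    norm = {a.strip().lower() for a in ancestry}
    recognized = _EUROPEAN | _ASIAN | _AFRICAN | _HISPANIC
    unknown = sorted(norm - recognized)
    if unknown:
        raise DataError(
            f"unrecognized ancestry labels {unknown}; recognized: "
            f"{sorted(recognized)}"
        )
    if norm & _EUROPEAN:
        return LDPopulation("EUR", False)
    if norm <= _ASIAN:
        return LDPopulation("ASN", False)
    if norm & _AFRICAN:
        return LDPopulation("AFR", True)
    if norm & _HISPANIC:
        return LDPopulation("AMR", True)
    # mixed Asian + (African|Hispanic) without European: Asian present
    return LDPopulation("ASN", True)


def read_association_tsv(path) -> list[AssociationRow]:
    """Read an association table (vid, trait, discovery_n, p_value, ancestry[, source]).

    The ancestry column holds ``;``-separated labels.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"vid": str, "trait": str})
    required = {"vid", "trait", "discovery_n", "p_value", "ancestry"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: association table missing columns {sorted(missing)}")
    rows = []
    for _, r in df.iterrows():
        rows.append(
            AssociationRow(
                vid=str(r["vid"]),
                trait=str(r["trait"]),
                discovery_n=int(r["discovery_n"]),
                p_value=float(r["p_value"]),
                ancestry=frozenset(str(r["ancestry"]).split(";")),
                source=str(r["source"]) if "source" in df.columns and pd.notna(r.get("source")) else "",
            )
        )
    return rows


def write_ranked_tsv(ranked: Sequence[RankedLocus], path, header_comment=None) -> None:
    rows = []
    for r in ranked:
        rows.append(
            {
                "rank": r.rank,
                "vid": r.vid,
                "trait": r.trait,
                "discovery_n": r.discovery_n,
                "p_value": r.p_value,
                "ancestry": ";".join(sorted(r.ancestry)),
                "chrom": r.region.chrom if r.region else "",
                "window_start": r.region.start if r.region else "",
                "window_end": r.region.end if r.region else "",
            }
        )
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
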