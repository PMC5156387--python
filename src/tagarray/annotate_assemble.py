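"""Consequence consolidation, exome-enrichment rules and manifest assembly.

Multiple annotators frequently disagree on a variant's consequence; the
toolkit consolidates them by assigning each variant its most deleterious
reported term under a configurable severity ordering (Sequence-Ontology
style by default, most severe first).  Downstream, the exome-enrichment
rule admits *all* exonic-class variants — synonymous and UTR included, with
no MAF floor, so singletons and doubletons pass — inside priority gene
regions.  Finally the manifest assembler applies the probe design-score
filter and resolves category overlap by precedence so every variant lands
in exactly one content category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .panel_io import DataError, SiteRecord
from .regions import RegionSet

#: Default severity ordering, most severe first.  The relative placement of
#: UTR terms versus missense is a design choice and user-overridable.
DEFAULT_SEVERITY = (
    "stop_gained",
    "frameshift",
    "stop_lost",
    "splice_donor",
    "splice_acceptor",
    "inframe_indel",
    "missense",
    "splice_region",
    "5_prime_utr",
    "3_prime_utr",
    "synonymous",
    "intronic",
    "intergenic",
)

#: Terms counting as exonic-class for the exome-enrichment rule (everything
#: except intronic/intergenic; synonymous and UTRs deliberately included).
EXONIC_TERMS = frozenset(DEFAULT_SEVERITY[:-2])

#: Default category precedence for overlap resolution (manifest row order).
DEFAULT_PRECEDENCE = (
    "snps_in_publications",
    "gwas_catalog",
    "gene_environment",
    "pharmacogenetic",
    "unpublished_gwas",
    "enhanced_gwas",
    "enhanced_exome",
    "finemap",
    "regulatory",
    "priority_trait",
    "targeted_array",
    "clinical",
    "pathway",
)


@dataclass(frozen=True)
class ConsequenceCall:
    vid: str
    source: str
    term: str


class SeverityTable:
    """Ordered consequence vocabulary, most severe first."""

    def __init__(self, terms: Sequence[str] = DEFAULT_SEVERITY):
        if len(set(terms)) != len(terms):
            raise DataError("severity table contains duplicate terms")
        self.terms = tuple(terms)
        self._rank = {t: i for i, t in enumerate(self.terms)}

    def rank(self, term: str) -> int:
        if term not in self._rank:
            raise DataError(
                f"unknown consequence term {term!r}; known terms: {list(self.terms)}"
            )
        return self._rank[term]


@dataclass
class Manifest:
    """Per-category counts before and after design filtering/dedup."""

    n_before_filter: dict[str, int]
    n_on_array: dict[str, int]
    assignment: dict[str, str]  # vid -> final category

    def to_frame(self) -> pd.DataFrame:
        cats = list(self.n_before_filter)
        return pd.DataFrame(
            {
                "category": cats,
                "n_before_filter": [self.n_before_filter[c] for c in cats],
                "n_on_array": [self.n_on_array.get(c, 0) for c in cats],
            }
        )


def consolidate_consequences(
    calls: Iterable[ConsequenceCall], table: Optional[SeverityTable] = None
) -> dict[str, str]:
    """Per vid, the most deleterious term reported by any annotator.

    Invariant to call order and to duplicated calls.
    """
    table = table or SeverityTable()
    best: dict[str, str] = {}
    for call in calls:
        r = table.rank(call.term)
        cur = best.get(call.vid)
        if cur is None or r < table.rank(cur):
            best[call.vid] = call.term
    return best


def exome_inclusion_filter(
    site: SiteRecord,
    gene_regions: RegionSet,
    consolidated_term: str,
    table: Optional[SeverityTable] = None,
) -> Optional[bool]:
    """Exome-enrichment decision inside priority gene regions.

    Returns True when the site lies in ``gene_regions`` and its consolidated
    term is exonic-class (synonymous and UTR included); no MAF floor is
    applied, so singleton and doubleton variants pass.  Returns False for
    non-exonic terms inside the regions, and None (not applicable) outside
    them.
    """
    table = table or SeverityTable()
    table.rank(consolidated_term)  # vocabulary check
    if not gene_regions.contains_pos1(site.chrom, site.pos):
        return None
    return consolidated_term in EXONIC_TERMS


def apply_design_filter(
    sites: Sequence[SiteRecord],
    min_score: float = 0.5,
    keep_unscored: bool = False,
) -> tuple[list[SiteRecord], list[SiteRecord]]:
    """Partition sites by the probe design-score filter (strictly > min_score).

    Sites without a score fail unless ``keep_unscored``.
    """
    passing, failing = [], []
    for s in sites:
        if s.design_score is None:
            (passing if keep_unscored else failing).append(s)
        elif s.design_score > min_score:
            passing.append(s)
        else:
            failing.append(s)
    return passing, failing


def dedup_categories(
    sites: Sequence[SiteRecord],
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> Manifest:
    """Assign each variant to its single highest-precedence category.

    ``n_before_filter`` counts multi-membership (a variant in k categories
    contributes to k rows); ``n_on_array`` counts the unique assignment, so
    after-counts sum to the number of distinct variants.
    """
    order = {c: i for i, c in enumerate(precedence)}
    present = {c for s in sites for c in s.categories}
    missing = present - set(order)
    if missing:
        raise DataError(f"categories missing from precedence list: {sorted(missing)}")
    before = {c: 0 for c in precedence if c in present}
    after = {c: 0 for c in precedence if c in present}
    assignment: dict[str, str] = {}
    for s in sites:
        if not s.categories:
            raise DataError(f"site {s.vid} has no content category")
        for c in s.categories:
            before[c] += 1
        final = min(s.categories, key=order.__getitem__)
        assignment[s.vid] = final
        after[final] += 1
    return Manifest(before, after, assignment)


def read_consequence_tsv(path) -> list[ConsequenceCall]:
    """Read annotator output (columns: vid, source, term)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"vid", "source", "term"}
    if not required <= set(df.columns):
        raise DataError(f"{path}: consequence table needs columns {sorted(required)}")
    return [
        ConsequenceCall(r["vid"], r["source"], r["term"]) for _, r in df.iterrows()
    ]
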