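"""Data model and I/O for phased haplotype panels, site tables and BED files.

The toolkit's in-memory containers are deliberately small:

* :class:`SiteRecord` — one variant site with per-population alternate-allele
  frequencies, an optional array design score, and content-category tags.
* :class:`HaplotypePanel` — a phased allele matrix of shape
  ``(2 * n_samples, n_sites)`` together with sample→population labels.
* :class:`PopulationPanel` — the sample→population assignment table.

Coordinate conventions: VCF and site tables are 1-based; BED files and all
internal region arithmetic are 0-based half-open.  Conversion happens only at
the I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: 1000 Genomes-style super-population codes used as defaults throughout.
DEFAULT_POPULATIONS = ("AAC", "AFR", "AMR", "ASN", "EUR", "SAS")


class DataError(ValueError):
    """Malformed or inconsistent input data (exit code 2 at the CLI)."""


@dataclass
class SiteRecord:
    """One variant site.

    ``pos`` is 1-based as in VCF.  ``pop_af`` maps a population code to the
    frequency of non-reference alleles among that population's haplotypes
    (for a biallelic site this is the alternate-allele frequency).  A site is
    triallelic-or-more iff ``len(alts) >= 2``.
    """

    chrom: str
    pos: int
    vid: str
    ref: str
    alts: tuple[str, ...]
    pop_af: dict[str, float] = field(default_factory=dict)
    design_score: Optional[float] = None
    categories: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.alts = tuple(self.alts)
        if self.pos < 1:
            raise DataError(f"site {self.vid}: pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alts or any(not a for a in self.alts):
            raise DataError(f"site {self.vid}: empty allele")
        if self.ref in self.alts or len(set(self.alts)) != len(self.alts):
            raise DataError(f"site {self.vid}: alleles must be distinct")
        for pop, f in self.pop_af.items():
            if not (0.0 <= f <= 1.0):
                raise DataError(f"site {self.vid}: pop_af[{pop}]={f} outside [0,1]")
        if self.design_score is not None and not (0.0 <= self.design_score <= 1.0):
            raise DataError(f"site {self.vid}: design_score outside [0,1]")

    @property
    def is_multiallelic(self) -> bool:
        return len(self.alts) >= 2

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alts)


class PopulationPanel:
    """Sample→population assignment, validated against a declared set."""

    def __init__(
        self,
        assignments: Mapping[str, str],
        populations: Sequence[str] = DEFAULT_POPULATIONS,
    ) -> None:
        self.populations = tuple(populations)
        unknown = sorted(set(assignments.values()) - set(self.populations))
        if unknown:
            raise DataError(
                f"unknown population codes {unknown}; declared set is {list(self.populations)}"
            )
        self._map = dict(assignments)

    def __getitem__(self, sample_id: str) -> str:
        return self._map[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._map

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()

    @classmethod
    def read_tsv(cls, path, populations: Sequence[str] = DEFAULT_POPULATIONS) -> "PopulationPanel":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        if not {"sample", "population"} <= set(df.columns):
            raise DataError(f"{path}: panel table needs 'sample' and 'population' columns")
        if df["sample"].duplicated().any():
            dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
            raise DataError(f"{path}: duplicate sample ids {dups}")
        return cls(dict(zip(df["sample"], df["population"])), populations)

    def write_tsv(self, path) -> None:
        df = pd.DataFrame(sorted(self._map.items()), columns=["sample", "population"])
        df.to_csv(path, sep="\t", index=False)


class HaplotypePanel:
    """Phased allele matrix with sites sorted by (chrom, pos).

    Row ``2*i`` and ``2*i + 1`` are the two haplotypes of sample ``i``.
    Entries are allele indices (0 = REF, k = k-th ALT); no missing data.
    """

    def __init__(
        self,
        sites: Sequence[SiteRecord],
        samples: Sequence[tuple[str, str]],
        alleles: np.ndarray,
    ) -> None:
        self.sites = list(sites)
        self.samples = list(samples)
        self.alleles = np.asarray(alleles, dtype=np.int8)
        if self.alleles.shape != (2 * len(self.samples), len(self.sites)):
            raise DataError(
                f"allele matrix shape {self.alleles.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        keys = [(s.chrom, s.pos) for s in self.sites]
        if any(k2 <= k1 for k1, k2 in zip(keys, keys[1:])):
            raise DataError("sites must be strictly sorted by (chrom, pos)")
        full = {(s.chrom, s.pos, s.ref, s.alts) for s in self.sites}
        if len(full) != len(self.sites):
            raise DataError("duplicate (chrom, pos, ref, alt) site")
        for j, s in enumerate(self.sites):
            col = self.alleles[:, j]
            if col.min(initial=0) < 0 or col.max(initial=0) > len(s.alts):
                raise DataError(f"site {s.vid}: allele index out of range")
        self.vid_index: dict[str, int] = {s.vid: j for j, s in enumerate(self.sites)}
        if len(self.vid_index) != len(self.sites):
            raise DataError("duplicate site vid")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    @property
    def chroms(self) -> list[str]:
        return [s.chrom for s in self.sites]

    @property
    def vids(self) -> list[str]:
        return [s.vid for s in self.sites]

    def site(self, vid: str) -> SiteRecord:
        return self.sites[self.vid_index[vid]]

    def pop_rows(self, population: str) -> np.ndarray:
        """Haplotype row indices belonging to one population."""
        rows = []
        for i, (_, pop) in enumerate(self.samples):
            if pop == population:
                rows.extend((2 * i, 2 * i + 1))
        return np.array(rows, dtype=np.intp)

    def populations(self) -> list[str]:
        seen: list[str] = []
        for _, pop in self.samples:
            if pop not in seen:
                seen.append(pop)
        return seen

    def column(self, vid: str) -> np.ndarray:
        return self.alleles[:, self.vid_index[vid]]

    def subset_sites(self, indices: Sequence[int]) -> "HaplotypePanel":
        idx = list(indices)
        return HaplotypePanel(
            [self.sites[j] for j in idx], self.samples, self.alleles[:, idx]
        )

    def compute_pop_af(self) -> None:
        """Fill each site's ``pop_af`` with empirical non-reference frequencies."""
        rows_by_pop = {p: self.pop_rows(p) for p in self.populations()}
        nonref = self.alleles > 0
        for j, site in enumerate(self.sites):
            site.pop_af = {
                pop: float(nonref[rows, j].mean()) for pop, rows in rows_by_pop.items()
            }

    @classmethod
    def from_arrays(
        cls,
        chrom: str,
        positions: Sequence[int],
        alleles: np.ndarray,
        samples: Sequence[tuple[str, str]],
        ref: str = "A",
        alt: str = "C",
    ) -> "HaplotypePanel":
        """Build a biallelic single-chromosome panel from raw arrays.

        Convenience constructor for simulations and tests; vids are
        ``chrom:pos:ref:alt``.
        """
        sites = [
            SiteRecord(chrom, int(p), f"{chrom}:{int(p)}:{ref}:{alt}", ref, (alt,))
            for p in positions
        ]
        panel = cls(sites, samples, alleles)
        panel.compute_pop_af()
        return panel


# ----------------------------------------------------------------------
# VCF
# ----------------------------------------------------------------------

def read_phased_vcf(
    path,
    panel: PopulationPanel,
    region=None,
    drop_unlisted: bool = False,
    impute_missing_as_ref: bool = False,
) -> HaplotypePanel:
    """Load phased genotypes from a VCF into a :class:`HaplotypePanel`.

    All retained genotypes must be phased (``|`` separator); an unphased
    genotype is a hard error naming the sample and site.  Missing genotypes
    are rejected unless ``impute_missing_as_ref`` is set, in which case they
    are replaced by the reference allele with a loud log message.

    Parameters
    ----------
    region
        Optional :class:`tagarray.regions.Region`; only sites whose 0-based
        position falls in ``[start, end)`` on ``region.chrom`` are kept.
    drop_unlisted
        Drop VCF samples absent from ``panel`` instead of raising.
    """
    from cyvcf2 import VCF  # deferred: import cost and htslib warnings

    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    keep_idx, samples = [], []
    for i, sid in enumerate(vcf_samples):
        if sid in panel:
            keep_idx.append(i)
            samples.append((sid, panel[sid]))
        elif not drop_unlisted:
            raise DataError(
                f"sample {sid!r} in VCF but absent from population panel "
                "(use drop_unlisted to ignore)"
            )
    if not samples:
        raise DataError(f"{path}: no VCF sample is listed in the population panel")

    sites: list[SiteRecord] = []
    columns: list[np.ndarray] = []
    n_imputed = 0
    for var in vcf:
        if region is not None:
            if var.CHROM != region.chrom:
                continue
            pos0 = var.POS - 1
            if not (region.start <= pos0 < region.end):
                continue
        if not var.ALT:
            raise DataError(f"{var.CHROM}:{var.POS}: site has no ALT allele")
        vid = var.ID if var.ID not in (None, ".") else (
            f"{var.CHROM}:{var.POS}:{var.REF}:{','.join(var.ALT)}"
        )
        gts = var.genotypes  # per sample: [allele_a, allele_b, phased]
        col = np.empty(2 * len(keep_idx), dtype=np.int8)
        for out_i, i in enumerate(keep_idx):
            a, b, phased = gts[i][0], gts[i][1], gts[i][2]
            if a < 0 or b < 0:
                if not impute_missing_as_ref:
                    raise DataError(
                        f"missing genotype for sample {vcf_samples[i]!r} at "
                        f"{var.CHROM}:{var.POS}; rerun with impute_missing_as_ref "
                        "to force-fill with REF"
                    )
                a, b = max(a, 0), max(b, 0)
                n_imputed += 1
            if not phased:
                raise DataError(
                    f"unphased genotype for sample {vcf_samples[i]!r} at "
                    f"{var.CHROM}:{var.POS} (vid {vid}); phased input required"
                )
            col[2 * out_i] = a
            col[2 * out_i + 1] = b
        sites.append(SiteRecord(var.CHROM, var.POS, vid, var.REF, tuple(var.ALT)))
        columns.append(col)

    if n_imputed:
        logger.warning("imputed %d missing genotype calls as REF", n_imputed)
    if not sites:
        raise DataError(f"{path}: no sites loaded (empty file or region)")
    alleles = np.stack(columns, axis=1)
    out = HaplotypePanel(sites, samples, alleles)
    out.compute_pop_af()
    return out


def write_phased_vcf(panel: HaplotypePanel, path, header_comment: Optional[str] = None) -> None:
    """Write a panel as a minimal phased VCF 4.2 file.

    CHROM/POS/ID/REF/ALT and GT fields round-trip byte-identically through
    :func:`read_phased_vcf`.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if header_comment:
            fh.write(f"##tagarray={header_comment}\n")
        for chrom in dict.fromkeys(panel.chroms):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sid for sid, _ in panel.samples)
            + "\n"
        )
        for j, s in enumerate(panel.sites):
            col = panel.alleles[:, j]
            gts = "\t".join(
                f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(panel.n_samples)
            )
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.vid}\t{s.ref}\t{','.join(s.alts)}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


# ----------------------------------------------------------------------
# Site tables (TSV)
# ----------------------------------------------------------------------

def write_site_table(sites: Sequence[SiteRecord], path, header_comment: Optional[str] = None) -> None:
    """Write SiteRecords as a deterministic TSV sorted by (chrom, pos, vid)."""
    if not sites:
        raise DataError("write_site_table: empty site list")
    pops = sorted({p for s in sites for p in s.pop_af})
    ordered = sorted(sites, key=lambda s: (s.chrom, s.pos, s.vid))
    rows = []
    for s in ordered:
        row = {
            "vid": s.vid,
            "chrom": s.chrom,
            "pos": s.pos,
            "ref": s.ref,
            "alt": ",".join(s.alts),
        }
        for p in pops:
            row[f"af_{p}"] = s.pop_af.get(p, "")
        row["design_score"] = "" if s.design_score is None else s.design_score
        row["categories"] = ",".join(sorted(s.categories))
        rows.append(row)
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_site_table(path) -> list[SiteRecord]:
    """Inverse of :func:`write_site_table`."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "vid": str})
    af_cols = [c for c in df.columns if c.startswith("af_")]
    out = []
    for _, r in df.iterrows():
        pop_af = {
            c[3:]: float(r[c]) for c in af_cols if pd.notna(r[c]) and r[c] != ""
        }
        score = r.get("design_score")
        score = None if pd.isna(score) else float(score)
        cats = r.get("categories")
        categories = set() if pd.isna(cats) or cats == "" else set(str(cats).split(","))
        out.append(
            SiteRecord(
                chrom=str(r["chrom"]),
                pos=int(r["pos"]),
                vid=str(r["vid"]),
                ref=str(r["ref"]),
                alts=tuple(str(r["alt"]).split(",")),
                pop_af=pop_af,
                design_score=score,
                categories=categories,
            )
        )
    return out


# ----------------------------------------------------------------------
# BED
# ----------------------------------------------------------------------

def write_bed(regions, path, header_comment: Optional[str] = None) -> None:
    """Write a RegionSet (or iterable of Regions) as sorted BED3(+label)."""
    regs = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for r in regs:
            if r.label:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\n")
            else:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


def read_bed(path):
    """Read BED3(+label) into a list of Regions (0-based half-open, as-is)."""
    from .regions import Region

    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}:{lineno}: BED line has <3 columns")
            label = parts[3] if len(parts) > 3 else ""
            out.append(Region(parts[0], int(parts[1]), int(parts[2]), label))
    return out
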