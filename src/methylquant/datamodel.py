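"""Domain types and IO for restriction-enzyme methylation tag counts.

Methyl-Seq pairs a methylation-insensitive MspI digestion library with a
methylation-sensitive HpaII digestion library at 5'-CCGG-3' sites.  Each
cleavage site carries strand-resolved tag counts; neighbouring sites are
grouped into regions assumed to share one methylation level.

Coordinates are 1-based, fully closed, matching common tag-count exports.
The optional BED export converts explicitly to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SiteCounts",
    "Region",
    "DepthBias",
    "MethylEstimate",
    "collapse_strand",
    "is_assayable",
    "group_sites_by_gap",
    "read_tagcounts",
    "write_tagcounts",
    "read_estimates",
    "write_estimates",
    "read_depth_bias",
    "regions_to_bed",
    "ASSAYABLE_MIN_READS",
]

#: Minimum MspI read count (on either strand) for a site to be assayable.
ASSAYABLE_MIN_READS = 4


class TagCountFormatError(ValueError):
    """Raised when a tag-count table is malformed."""


@dataclass
class SiteCounts:
    """Strand-resolved MspI and HpaII tag counts at one CCGG cleavage site.

    ``mspi_fwd``/``mspi_rev`` come from the single MspI library; the HpaII
    counts are per-library maps keyed by library id.
    """

    site_id: str
    chrom: str
    pos: int
    mspi_fwd: int
    mspi_rev: int
    hpaii_fwd: dict[str, int] = field(default_factory=dict)
    hpaii_rev: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1 (1-based), got {self.pos}")
        for name, v in (("mspi_fwd", self.mspi_fwd), ("mspi_rev", self.mspi_rev)):
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if set(self.hpaii_fwd) != set(self.hpaii_rev):
            raise ValueError(
                "hpaii_fwd and hpaii_rev must cover the same library ids"
            )
        for lib in self.hpaii_fwd:
            if self.hpaii_fwd[lib] < 0 or self.hpaii_rev[lib] < 0:
                raise ValueError(f"negative HpaII count for library {lib!r}")

    @property
    def libraries(self) -> list[str]:
        return sorted(self.hpaii_fwd)

    def mspi_collapsed(self) -> int:
        """Collapsed MspI count: larger of the forward and reverse tags."""
        return collapse_strand(self.mspi_fwd, self.mspi_rev)

    def hpaii_collapsed(self, library_id: str) -> int:
        """Collapsed HpaII count for one library."""
        return collapse_strand(self.hpaii_fwd[library_id], self.hpaii_rev[library_id])


@dataclass
class Region:
    """Ordered group of assayable sites sharing one methylation level."""

    region_id: str
    sites: list[SiteCounts]

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("a region needs at least one site")
        chroms = {s.chrom for s in self.sites}
        if len(chroms) > 1:
            raise ValueError(f"region {self.region_id}: sites span chromosomes {chroms}")
        self.sites = sorted(self.sites, key=lambda s: s.pos)

    @property
    def K(self) -> int:
        return len(self.sites)

    @property
    def chrom(self) -> str:
        return self.sites[0].chrom

    @property
    def libraries(self) -> list[str]:
        return self.sites[0].libraries

    def mspi_counts(self) -> list[int]:
        return [s.mspi_collapsed() for s in self.sites]

    def hpaii_counts(self, library_id: str) -> list[int]:
        return [s.hpaii_collapsed(library_id) for s in self.sites]


@dataclass(frozen=True)
class DepthBias:
    """Effective HpaII-to-MspI sequencing-depth ratio for one HpaII library.

    ``c = 1`` means no bias; ``c < 1`` means the HpaII library was sequenced
    shallower than the MspI reference.
    """

    library_id: str
    c: float

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValueError(f"depth-bias ratio must be positive, got {self.c}")


_METHODS = ("binary", "tpe", "bayes", "rrbs")


@dataclass(frozen=True)
class MethylEstimate:
    """Point estimate of a region's methylation level in one library."""

    region_id: str
    library_id: str
    mu: float
    method: str
    variance: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"mu must lie in [0,1], got {self.mu}")
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}, got {self.method!r}")
        if (self.variance is not None) != (self.method == "bayes"):
            raise ValueError("variance is reported by the bayes method and only by it")
        if self.variance is not None and self.variance < 0:
            raise ValueError("variance must be non-negative")


def collapse_strand(fwd: int, rev: int) -> int:
    """Collapse a site's strand-resolved tag counts to the larger of the two.

    Forward and reverse tags both witness the same digestion event, but one
    strand can be under-sequenced when the next cleavage site is distant, so
    the larger count is the better single-number summary.
    """
    if fwd < 0 or rev < 0:
        raise ValueError(f"tag counts must be non-negative, got ({fwd}, {rev})")
    return max(fwd, rev)


def is_assayable(site: SiteCounts, min_reads: int = ASSAYABLE_MIN_READS) -> bool:
    """True if the site has ``min_reads`` or more MspI tags on either strand."""
    return site.mspi_fwd >= min_reads or site.mspi_rev >= min_reads


def group_sites_by_gap(sites: Iterable[SiteCounts], max_gap: int = 75,
                       prefix: str = "region") -> list[Region]:
    """Group a raw site list into regions by genomic proximity.

    Consecutive sites on the same chromosome within ``max_gap`` bp join the
    same region (digested fragments are mostly 35-75 bp, so the default gap
    is 75).  A stand-in for published region definitions, which should be
    supplied via an explicit region id column when available.
    """
    ordered = sorted(sites, key=lambda s: (s.chrom, s.pos))
    regions: list[Region] = []
    current: list[SiteCounts] = []
    for site in ordered:
        if current and (site.chrom != current[-1].chrom
                        or site.pos - current[-1].pos > max_gap):
            regions.append(Region(f"{prefix}_{len(regions) + 1}", current))
            current = []
        current.append(site)
    if current:
        regions.append(Region(f"{prefix}_{len(regions) + 1}", current))
    return regions


_FIXED_COLUMNS = ["chrom", "pos", "region_id", "site_id",
                  "mspi_fwd", "mspi_rev"]


def _hpaii_libraries(columns: Sequence[str]) -> list[str]:
    libs = []
    for col in columns:
        if col.startswith("hpaii_") and col.endswith("_fwd"):
            libs.append(col[len("hpaii_"):-len("_fwd")])
    return libs


def read_tagcounts(path, *, min_reads: int = ASSAYABLE_MIN_READS,
                   filter_assayable: bool = True) -> list[Region]:
    """Read a tab-delimited tag-count table into regions.

    Expected columns: ``chrom pos region_id site_id mspi_fwd mspi_rev`` then
    ``hpaii_<lib>_fwd`` / ``hpaii_<lib>_rev`` per HpaII library.  Positions
    are 1-based.  Sites failing the assayability rule are dropped, then empty
    regions are dropped; row order within a region is preserved (regions sort
    their sites by position).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "region_id": str,
                                            "site_id": str})
    for col in _FIXED_COLUMNS:
        if col not in df.columns:
            raise TagCountFormatError(f"missing required column {col!r}")
    libs = _hpaii_libraries(df.columns)
    for lib in libs:
        if f"hpaii_{lib}_rev" not in df.columns:
            raise TagCountFormatError(f"missing required column 'hpaii_{lib}_rev'")

    count_cols = (["pos", "mspi_fwd", "mspi_rev"]
                  + [f"hpaii_{lib}_{s}" for lib in libs for s in ("fwd", "rev")])
    for col in count_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round()) | (numeric < (1 if col == "pos" else 0))
        if bad.any():
            # +2: header line plus 1-based line numbering
            line = int(bad.idxmax()) + 2
            raise TagCountFormatError(
                f"column {col!r}, line {line}: {df[col][bad.idxmax()]!r} is not a "
                "valid non-negative integer count"
            )
        df[col] = numeric.astype(int)

    regions: list[Region] = []
    for region_id, grp in df.groupby("region_id", sort=False):
        sites = []
        for row in grp.itertuples(index=False):
            site = SiteCounts(
                site_id=row.site_id, chrom=row.chrom, pos=int(row.pos),
                mspi_fwd=int(row.mspi_fwd), mspi_rev=int(row.mspi_rev),
                hpaii_fwd={lib: int(getattr(row, f"hpaii_{lib}_fwd")) for lib in libs},
                hpaii_rev={lib: int(getattr(row, f"hpaii_{lib}_rev")) for lib in libs},
            )
            if not filter_assayable or is_assayable(site, min_reads):
                sites.append(site)
        if sites:
            regions.append(Region(str(region_id), sites))
    return regions


def write_tagcounts(regions: Iterable[Region], path) -> None:
    """Write regions back to the tab-delimited tag-count dialect."""
    regions = list(regions)
    libs: list[str] = sorted({lib for r in regions for lib in r.libraries})
    rows = []
    for region in regions:
        for s in region.sites:
            row = {"chrom": s.chrom, "pos": s.pos, "region_id": region.region_id,
                   "site_id": s.site_id, "mspi_fwd": s.mspi_fwd,
                   "mspi_rev": s.mspi_rev}
            for lib in libs:
                row[f"hpaii_{lib}_fwd"] = s.hpaii_fwd[lib]
                row[f"hpaii_{lib}_rev"] = s.hpaii_rev[lib]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_estimates(estimates: Iterable[MethylEstimate], path) -> None:
    rows = [{"region_id": e.region_id, "library_id": e.library_id,
             "method": e.method, "mu": e.mu,
             "variance": "" if e.variance is None else e.variance}
            for e in estimates]
    pd.DataFrame(rows, columns=["region_id", "library_id", "method", "mu",
                                "variance"]).to_csv(path, sep="\t", index=False)


def read_estimates(path) -> list[MethylEstimate]:
    df = pd.read_csv(path, sep="\t", dtype={"region_id": str, "library_id": str})
    out = []
    for row in df.itertuples(index=False):
        var = None if pd.isna(row.variance) else float(row.variance)
        out.append(MethylEstimate(region_id=row.region_id,
                                  library_id=row.library_id, mu=float(row.mu),
                                  method=row.method, variance=var))
    return out


def read_depth_bias(path) -> dict[str, DepthBias]:
    """Read a TSV of (library_id, c) depth-bias ratios."""
    df = pd.read_csv(path, sep="\t", dtype={"library_id": str})
    if "library_id" not in df.columns or "c" not in df.columns:
        raise TagCountFormatError("bias table needs columns 'library_id' and 'c'")
    return {row.library_id: DepthBias(row.library_id, float(row.c))
            for row in df.itertuples(index=False)}


def regions_to_bed(regions: Iterable[Region], path) -> None:
    """Export region spans as BED (0-based, half-open) for browser use."""
    with open(path, "w") as fh:
        for r in regions:
            start = r.sites[0].pos - 1  # 1-based closed -> 0-based half-open
            end = r.sites[-1].pos
            fh.write(f"{r.chrom}\t{start}\t{end}\t{r.region_id}\n")
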