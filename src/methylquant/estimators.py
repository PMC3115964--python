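"""Closed-form methylation estimators for Methyl-Seq and RRBS tag counts.

Three estimators are provided:

* the original binary call (a region is unmethylated when its mean collapsed
  HpaII tag count exceeds one);
* the Truncated Proportional Estimate (TPE), the maximum-likelihood estimate
  ``max(0, 1 - (sum y / sum x) / c)`` under the Poisson-thinning count model,
  optionally adjusted for the HpaII-to-MspI sequencing-depth ratio ``c``;
* the RRBS proportional estimate ``sum(C) / sum(C + T)`` for bisulfite counts.

Estimates are always computed per (region, library); no pooling across
libraries.  Sign convention for the depth bias: ``c`` is the HpaII library's
effective depth divided by the MspI library's, so ``c < 1`` (HpaII sequenced
shallower) inflates the raw HpaII deficit and the adjusted TPE divides the
observed count ratio by ``c`` to compensate.  The opposite orientation would
silently invert the correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .datamodel import DepthBias, MethylEstimate, Region

__all__ = [
    "RrbsSiteCounts",
    "UndefinedEstimateError",
    "binary_call",
    "tpe",
    "rrbs_estimate",
    "compute_depth_bias",
    "estimate_regions",
]


class UndefinedEstimateError(ValueError):
    """Raised when the data carry no information for the requested estimate."""


@dataclass(frozen=True)
class RrbsSiteCounts:
    """Bisulfite tag counts at one CpG: 'C' reads (methylated) and 'T' reads."""

    site_id: str
    c_count: int
    t_count: int

    def __post_init__(self) -> None:
        if self.c_count < 0 or self.t_count < 0:
            raise ValueError("RRBS counts must be non-negative")


def binary_call(hpaii_counts: Sequence[int], *, region_id: str = "",
                library_id: str = "") -> MethylEstimate:
    """Original binary region call from collapsed HpaII counts.

    A region with mean HpaII tag count strictly greater than one is called
    unmethylated (mu = 0); otherwise methylated (mu = 1).
    """
    if len(hpaii_counts) == 0:
        raise UndefinedEstimateError("binary_call needs at least one site count")
    mean = sum(hpaii_counts) / len(hpaii_counts)
    return MethylEstimate(region_id=region_id, library_id=library_id,
                          mu=0.0 if mean > 1 else 1.0, method="binary")


def tpe(x: Sequence[int], y: Sequence[int], c: float = 1.0, *,
        region_id: str = "", library_id: str = "") -> MethylEstimate:
    """Truncated Proportional Estimate of a region's methylation level.

    ML estimate under the count model: ``mu = 1 - (sum y / sum x) / c``,
    truncated at zero when sampling noise pushes the HpaII total above the
    (depth-adjusted) MspI total.  ``c = 1`` is the unadjusted estimate.
    """
    if len(x) != len(y) or len(x) == 0:
        raise ValueError("x and y must be equal-length, non-empty count lists")
    if not c > 0:
        raise ValueError(f"depth-bias ratio must be positive, got {c}")
    sx, sy = sum(x), sum(y)
    if sx <= 0:
        raise UndefinedEstimateError(
            "no MspI signal in region (sum x = 0); TPE is undefined")
    mu = max(0.0, 1.0 - (sy / sx) / c)
    return MethylEstimate(region_id=region_id, library_id=library_id,
                          mu=mu, method="tpe")


def rrbs_estimate(sites: Iterable[RrbsSiteCounts], *, region_id: str = "",
                  library_id: str = "") -> MethylEstimate:
    """RRBS proportional estimate: pooled C reads over pooled coverage.

    The single-site methylation level is ``x/(x+y)``; a region pools counts
    over its sites, ``sum x_i / sum (x_i + y_i)``.
    """
    sites = list(sites)
    total_c = sum(s.c_count for s in sites)
    total = total_c + sum(s.t_count for s in sites)
    if total <= 0:
        raise UndefinedEstimateError("zero total RRBS coverage in region")
    return MethylEstimate(region_id=region_id, library_id=library_id,
                          mu=total_c / total, method="rrbs")


def compute_depth_bias(total_mspi_cgg_tags: int, total_hpaii_cgg_tags: int,
                       library_id: str = "") -> DepthBias:
    """Depth-bias ratio from genome-wide CGG-aligned tag totals.

    Per-region depth bias is unobservable, so the genome-wide totals of tags
    aligned to CGG sites serve as the reference: ``c = HpaII total / MspI
    total``.  The HpaII total conflates depth with methylation, so the
    adjustment is approximate.
    """
    if total_mspi_cgg_tags <= 0 or total_hpaii_cgg_tags <= 0:
        raise ValueError("CGG tag totals must both be positive")
    return DepthBias(library_id=library_id,
                     c=total_hpaii_cgg_tags / total_mspi_cgg_tags)


def estimate_regions(regions: Iterable[Region], method: str = "tpe",
                     bias: Mapping[str, DepthBias] | None = None
                     ) -> list[MethylEstimate]:
    """Apply a closed-form estimator to every (region, library) pair.

    ``bias`` maps library ids to their depth-bias ratios; libraries absent
    from the map use c = 1.  Regions whose estimate is undefined (no MspI
    signal) are skipped.
    """
    if method not in ("binary", "tpe"):
        raise ValueError(f"method must be 'binary' or 'tpe', got {method!r}")
    out: list[MethylEstimate] = []
    for region in regions:
        x = region.mspi_counts()
        for lib in region.libraries:
            y = region.hpaii_counts(lib)
            try:
                if method == "binary":
                    est = binary_call(y, region_id=region.region_id,
                                      library_id=lib)
                else:
                    c = bias[lib].c if bias and lib in bias else 1.0
                    est = tpe(x, y, c, region_id=region.region_id,
                              library_id=lib)
            except UndefinedEstimateError:
                continue
            out.append(est)
    return out
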