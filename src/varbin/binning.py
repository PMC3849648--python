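"""Per-site background PLRD distributions and Bin 1-4 assignment.

Each candidate variant is judged independently of all others.  At a given
variant change and position, the PLRD values of all background samples
whose forced-call record *failed* the hard filters (the wild-type /
non-variant group) form an empirical error distribution for that exact
site.  Its median and inter-quartile distance (IQD = Q3 - Q1) summarize
the local error level; 1.38*IQD serves as a proxy for one standard
deviation of a Gaussian background.

The proband's PLRD is then binned against two site-specific thresholds:

* a fixed evidence cutoff: PLRD > 10
* a separation threshold: PLRD > median + 6 proxy SDs (= 8.28 * IQD)

Bin 1 = both conditions hold (most likely a true variant); Bin 2 =
exactly one holds (uncertain); Bin 3 = neither, but PLRD > median +
3 proxy SDs (= 4.14 * IQD); Bin 4 = everything below (most likely a
false positive).  Confidently homozygous-variant proband records are
excluded up front — with many variant-supporting reads they are rarely
false positives.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .hard_filters import (
    DEFAULT_THRESHOLDS,
    FilterThresholds,
    partition_background,
)
from .likelihood import PlrdResult, Zygosity, plrd_result
from .vcf_interop import SiteObservation, VariantKey

__all__ = [
    "Bin",
    "BackgroundDistribution",
    "BinningConfig",
    "BinAssignment",
    "SiteResult",
    "DEFAULT_BINNING",
    "summarize_background",
    "classify_bin",
    "varbin_site",
]


class Bin(enum.Enum):
    """Ordered variant classes, plus the two special states."""

    BIN1 = "Bin1"
    BIN2 = "Bin2"
    BIN3 = "Bin3"
    BIN4 = "Bin4"
    EXCLUDED_HOMOZYGOUS = "ExcludedHomozygous"
    UNCLASSIFIABLE = "Unclassifiable"

    @property
    def rank(self) -> Optional[int]:
        """1 (most likely true) .. 4 (most likely false); None for specials."""
        return {"Bin1": 1, "Bin2": 2, "Bin3": 3, "Bin4": 4}.get(self.value)


@dataclass(frozen=True)
class BackgroundDistribution:
    """Summary of the wild-type/non-variant background PLRD values at a site."""

    values: tuple[float, ...]
    median: Optional[float]
    iqd: Optional[float]
    n: int


@dataclass(frozen=True)
class BinningConfig:
    """Binning constants.

    plrd_cutoff
        Fixed per-read evidence cutoff (Phred ratio per read); default 10.
    sd_proxy_factor
        IQD multiples standing in for one background standard deviation;
        default 1.38.
    k_high, k_low
        Proxy SDs above the background median for the Bin-1/2 and Bin-3/4
        boundaries (defaults 6 and 3, i.e. 8.28*IQD and 4.14*IQD).
    min_background
        Minimum wild-type/non-variant background count required to trust
        the distribution; below it the site is unclassifiable.
    """

    plrd_cutoff: float = 10.0
    sd_proxy_factor: float = 1.38
    k_high: float = 6.0
    k_low: float = 3.0
    min_background: int = 5

    def __post_init__(self) -> None:
        if not (self.k_high > self.k_low > 0):
            raise ValueError("need k_high > k_low > 0")
        if self.sd_proxy_factor <= 0:
            raise ValueError("sd_proxy_factor must be > 0")
        if self.min_background < 1:
            raise ValueError("min_background must be >= 1")

    @property
    def high_multiplier(self) -> float:
        """IQD multiplier of the Bin-1/2 separation threshold (8.28 at defaults)."""
        return self.k_high * self.sd_proxy_factor

    @property
    def low_multiplier(self) -> float:
        """IQD multiplier of the Bin-3/4 boundary (4.14 at defaults)."""
        return self.k_low * self.sd_proxy_factor


DEFAULT_BINNING = BinningConfig()


@dataclass(frozen=True)
class BinAssignment:
    """A bin plus the thresholds and conditions that produced it."""

    bin: Bin
    thr_high: Optional[float] = None
    thr_low: Optional[float] = None
    cond_cutoff: Optional[bool] = None
    cond_separation: Optional[bool] = None
    reason: Optional[str] = None


def summarize_background(plrd_values: Iterable[float]) -> BackgroundDistribution:
    """Median and inter-quartile distance of background PLRD values.

    Quartiles use linear interpolation at positions ``p*(n-1)`` on the
    sorted values (the conventional "linear" definition), so the summary
    is deterministic and permutation-invariant.  An empty input yields an
    ``n = 0`` distribution that downstream classification treats as
    unclassifiable.
    """
    vals = tuple(float(v) for v in plrd_values)
    if any(not np.isfinite(v) for v in vals):
        raise ValueError("background PLRD values must be finite")
    if not vals:
        return BackgroundDistribution(values=(), median=None, iqd=None, n=0)
    arr = np.sort(np.asarray(vals, dtype=float))
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method="linear")
    return BackgroundDistribution(
        values=tuple(arr.tolist()),
        median=float(med),
        iqd=float(q3 - q1),
        n=len(vals),
    )


def classify_bin(
    proband_plrd: float,
    dist: BackgroundDistribution,
    cfg: BinningConfig = DEFAULT_BINNING,
) -> BinAssignment:
    """Assign Bin 1-4 from the proband PLRD and a background distribution.

    All comparisons are strict ``>`` and the Bin-1/Bin-2 rules are
    evaluated before Bin 3/4, so a variant above the cutoff but inside the
    separation threshold is Bin 2 (uncertain), never Bin 3.
    """
    if dist.n < cfg.min_background:
        return BinAssignment(
            bin=Bin.UNCLASSIFIABLE,
            reason=(
                f"background distribution has n={dist.n} < "
                f"min_background={cfg.min_background}"
            ),
        )
    assert dist.median is not None and dist.iqd is not None
    thr_high = dist.median + cfg.high_multiplier * dist.iqd
    thr_low = dist.median + cfg.low_multiplier * dist.iqd
    cond_cutoff = proband_plrd > cfg.plrd_cutoff
    cond_separation = proband_plrd > thr_high
    if cond_cutoff and cond_separation:
        chosen = Bin.BIN1
    elif cond_cutoff or cond_separation:
        chosen = Bin.BIN2
    elif proband_plrd > thr_low:
        chosen = Bin.BIN3
    else:
        chosen = Bin.BIN4
    return BinAssignment(
        bin=chosen,
        thr_high=thr_high,
        thr_low=thr_low,
        cond_cutoff=cond_cutoff,
        cond_separation=cond_separation,
    )


@dataclass(frozen=True)
class SiteResult:
    """Everything computed for one proband site.

    Counts cover the background samples only: how many passed the hard
    filters (and were therefore excluded from the wild-type distribution
    as called variants), how many non-variant records were dropped as
    homozygous or depth-zero, and how many records were unusable.
    """

    key: VariantKey
    proband: Optional[PlrdResult]
    assignment: BinAssignment
    distribution: BackgroundDistribution
    n_background_variant: int = 0
    n_background_hom_excluded: int = 0
    n_background_unusable: int = 0
    background_values_by_sample: tuple[tuple[str, float], ...] = field(default=())


def background_plrd_values(
    background_obs_list: Sequence[SiteObservation],
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
    trust_filter_field: bool = False,
) -> tuple[list[tuple[str, float]], int, int, int]:
    """Wild-type/non-variant background PLRD values at one site.

    Returns ``(values_by_sample, n_variant, n_hom_excluded, n_unusable)``.
    Only usable records that fail the hard filters, are not confidently
    homozygous-variant, and have non-zero depth contribute values.
    """
    variant, nonvariant, unusable = partition_background(
        background_obs_list, thresholds, trust_filter_field=trust_filter_field
    )
    values: list[tuple[str, float]] = []
    n_hom = 0
    n_unusable = len(unusable)
    for obs in nonvariant:
        assert obs.pl is not None and obs.dp is not None
        res = plrd_result(obs.pl, obs.dp)
        if res.zygosity is Zygosity.HOM_VAR:
            n_hom += 1
            continue
        if res.plrd is None:  # depth zero: no per-read evidence to speak of
            n_unusable += 1
            continue
        values.append((obs.sample_id, res.plrd))
    return values, len(variant), n_hom, n_unusable


def varbin_site(
    proband_obs: SiteObservation,
    background_obs_list: Sequence[SiteObservation],
    cfg: BinningConfig = DEFAULT_BINNING,
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
    trust_filter_field: bool = False,
) -> SiteResult:
    """Run the full per-site pipeline for one proband variant.

    Steps: proband PLRD and zygosity (confident homozygous-variant →
    excluded, displayed at 0); hard-filter partition of the background
    records; wild-type/non-variant PLRD distribution; bin classification.
    """
    if any(o.key != proband_obs.key for o in background_obs_list):
        raise ValueError("all observations must share the proband's VariantKey")

    values, n_var, n_hom, n_unusable = background_plrd_values(
        background_obs_list, thresholds, trust_filter_field=trust_filter_field
    )
    dist = summarize_background(v for _, v in values)

    if not proband_obs.usable:
        assignment = BinAssignment(
            bin=Bin.UNCLASSIFIABLE, reason="proband record lacks PL or DP"
        )
        return SiteResult(
            key=proband_obs.key,
            proband=None,
            assignment=assignment,
            distribution=dist,
            n_background_variant=n_var,
            n_background_hom_excluded=n_hom,
            n_background_unusable=n_unusable,
            background_values_by_sample=tuple(values),
        )

    assert proband_obs.pl is not None and proband_obs.dp is not None
    proband = plrd_result(proband_obs.pl, proband_obs.dp)

    if proband.zygosity is Zygosity.HOM_VAR:
        assignment = BinAssignment(
            bin=Bin.EXCLUDED_HOMOZYGOUS,
            reason="confident homozygous-variant genotype",
        )
    elif proband.plrd is None:
        assignment = BinAssignment(
            bin=Bin.UNCLASSIFIABLE, reason="proband depth is zero"
        )
    else:
        assignment = classify_bin(proband.plrd, dist, cfg)

    return SiteResult(
        key=proband_obs.key,
        proband=proband,
        assignment=assignment,
        distribution=dist,
        n_background_variant=n_var,
        n_background_hom_excluded=n_hom,
        n_background_unusable=n_unusable,
        background_values_by_sample=tuple(values),
    )
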