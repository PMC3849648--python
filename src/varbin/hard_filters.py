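"""Hard-filter classification of forced-call records.

Every background record at a candidate site is split into "variant"
(passes the hard filters) versus "wild type / non-variant" (fails at least
one).  The thresholds are the GATK best-practice hard filters that the
upstream pipeline applied; they are re-applied here as a pure
classification step on the INFO annotations, so heterogeneous FILTER
column conventions across input files cannot skew the background split.

SNV rules (a record fails when the annotation is present and violates the
strict inequality as printed):

    QD < 2.0, MQ < 40.0, FS > 60.0, HaplotypeScore > 13.0,
    MQRankSum < -12.5, ReadPosRankSum < -8.0

Indel rules:

    QD < 2.0, ReadPosRankSum < -20.0, FS > 200.0

A missing annotation never fails a rule (the upstream caller only filters
on annotations it computed).  Values exactly at a threshold pass.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Optional

if TYPE_CHECKING:  # pragma: no cover
    from .vcf_interop import SiteObservation

__all__ = [
    "SnvThresholds",
    "IndelThresholds",
    "FilterThresholds",
    "FilterStatus",
    "FilterVerdict",
    "DEFAULT_THRESHOLDS",
    "classify_observation",
    "verdict_from_filter_field",
    "partition_background",
]


@dataclass(frozen=True)
class SnvThresholds:
    qd_min: float = 2.0
    mq_min: float = 40.0
    fs_max: float = 60.0
    haplotype_score_max: float = 13.0
    mq_rank_sum_min: float = -12.5
    read_pos_rank_sum_min: float = -8.0


@dataclass(frozen=True)
class IndelThresholds:
    qd_min: float = 2.0
    read_pos_rank_sum_min: float = -20.0
    fs_max: float = 200.0


@dataclass(frozen=True)
class FilterThresholds:
    """SNV and indel hard-filter threshold sets."""

    snv: SnvThresholds = field(default_factory=SnvThresholds)
    indel: IndelThresholds = field(default_factory=IndelThresholds)


DEFAULT_THRESHOLDS = FilterThresholds()


class FilterStatus(enum.Enum):
    VARIANT = "variant"
    NON_VARIANT = "non_variant"


@dataclass(frozen=True)
class FilterVerdict:
    """Outcome of hard-filtering one record.

    ``failed_rules`` is empty exactly when ``status`` is VARIANT.
    """

    status: FilterStatus
    failed_rules: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.status is FilterStatus.VARIANT) != (len(self.failed_rules) == 0):
            raise ValueError("status VARIANT iff failed_rules is empty")


def _fails_low(value: Optional[float], minimum: float) -> bool:
    return value is not None and value < minimum


def _fails_high(value: Optional[float], maximum: float) -> bool:
    return value is not None and value > maximum


def classify_observation(
    obs: "SiteObservation",
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
) -> FilterVerdict:
    """Apply the SNV or indel hard-filter rule set to one observation.

    The indel set is used when ``obs.is_indel`` (ref and alt lengths
    differ); everything else, including same-length multi-nucleotide
    changes, falls under the SNV set.
    """
    info = obs.info
    failed: list[str] = []
    if obs.is_indel:
        t = thresholds.indel
        if _fails_low(info.qd, t.qd_min):
            failed.append("QD")
        if _fails_low(info.read_pos_rank_sum, t.read_pos_rank_sum_min):
            failed.append("ReadPosRankSum")
        if _fails_high(info.fs, t.fs_max):
            failed.append("FS")
    else:
        s = thresholds.snv
        if _fails_low(info.qd, s.qd_min):
            failed.append("QD")
        if _fails_low(info.mq, s.mq_min):
            failed.append("MQ")
        if _fails_high(info.fs, s.fs_max):
            failed.append("FS")
        if _fails_high(info.haplotype_score, s.haplotype_score_max):
            failed.append("HaplotypeScore")
        if _fails_low(info.mq_rank_sum, s.mq_rank_sum_min):
            failed.append("MQRankSum")
        if _fails_low(info.read_pos_rank_sum, s.read_pos_rank_sum_min):
            failed.append("ReadPosRankSum")
    status = FilterStatus.NON_VARIANT if failed else FilterStatus.VARIANT
    return FilterVerdict(status=status, failed_rules=tuple(failed))


def verdict_from_filter_field(obs: "SiteObservation") -> FilterVerdict:
    """Take the VCF FILTER column verbatim instead of recomputing.

    PASS / '.' / empty count as VARIANT; any named filter counts as
    NON_VARIANT with the FILTER tokens as the failed rules.
    """
    raw = (obs.vcf_filter or ".").strip()
    if raw in (".", "PASS", ""):
        return FilterVerdict(status=FilterStatus.VARIANT)
    return FilterVerdict(
        status=FilterStatus.NON_VARIANT,
        failed_rules=tuple(tok for tok in raw.split(";") if tok),
    )


def partition_background(
    site_obs: Iterable["SiteObservation"],
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
    trust_filter_field: bool = False,
) -> tuple[list["SiteObservation"], list["SiteObservation"], list["SiteObservation"]]:
    """Split observations at one site into (variant, non-variant, unusable).

    Unusable records (missing PL or DP) enter neither group; the first two
    groups are a disjoint, exhaustive split of the usable ones.
    """
    variant: list["SiteObservation"] = []
    nonvariant: list["SiteObservation"] = []
    unusable: list["SiteObservation"] = []
    for obs in site_obs:
        if not obs.usable:
            unusable.append(obs)
            continue
        verdict = (
            verdict_from_filter_field(obs)
            if trust_filter_field
            else classify_observation(obs, thresholds)
        )
        (variant if verdict.status is FilterStatus.VARIANT else nonvariant).append(obs)
    return variant, nonvariant, unusable
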