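"""Cross-sample annotation, rare-variant screening and false-negative flags.

Beyond the bin itself, the cross-sample layout carries information a
reviewer wants next to every candidate: how many background samples carry
the same call (and with what zygosity), whether coverage was too low to
trust a wild-type call, whether the record shows strand / mapping-quality
/ read-position bias, and whether a supposedly de novo variant is really a
missed call in a parent.

The screening rules reproduce a standard rare-disease candidate filter:
adequate depth, low population allele frequency (1000 Genomes and ESP
exomes), absence from unaffected family members, and absence from more
than a few unrelated background families (a catch-all for platform
artifacts and common variation missing from the frequency panels).
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .binning import Bin, BinningConfig, DEFAULT_BINNING, SiteResult, classify_bin
from .hard_filters import (
    DEFAULT_THRESHOLDS,
    FilterStatus,
    FilterThresholds,
    classify_observation,
)
from .likelihood import Zygosity, plrd_result
from .vcf_interop import SiteObservation, VariantKey

__all__ = [
    "SampleZygosity",
    "CrossSampleAnnotation",
    "ScreenConfig",
    "ScreenResult",
    "FalseNegativeCandidate",
    "DEFAULT_SCREEN",
    "bias_flags",
    "annotate_site",
    "screen_candidates",
    "flag_false_negative_candidates",
    "read_maf_table",
]


class SampleZygosity(enum.Enum):
    HET = "het"
    HOM = "hom"
    WT = "wt"
    LOW_DEPTH = "low_depth"
    ABSENT = "absent"


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds for screening, low-depth and bias flags.

    ``min_depth`` is an exclusive lower bound (a kept site needs depth
    strictly greater).  Bias thresholds default to the hard-filter values;
    a base-quality rank-sum bias is part of the flag vocabulary but the
    consumed INFO set carries no base-quality annotation, so that flag is
    never raised from VCF input (see the flag docstring).
    """

    min_depth: int = 3
    max_maf_1kg: float = 0.03
    max_maf_esp: float = 0.02
    max_families_with_variant: int = 3
    low_depth_max: int = 4
    fs_bias: float = 60.0
    mq_bias: float = 40.0
    mq_rank_sum_bias: float = -12.5
    read_pos_rank_sum_bias: float = -8.0

    def __post_init__(self) -> None:
        for name in ("max_maf_1kg", "max_maf_esp"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


DEFAULT_SCREEN = ScreenConfig()


@dataclass(frozen=True)
class CrossSampleAnnotation:
    """Cross-sample summary for one proband site."""

    n_background_variant: int
    background_zygosities: Mapping[str, SampleZygosity]
    n_unrelated_families_with_variant: int
    flags: frozenset[str]


def bias_flags(obs: SiteObservation, cfg: ScreenConfig = DEFAULT_SCREEN) -> frozenset[str]:
    """Flags for one observation, as a pure function of record and config.

    LOW_DEPTH: depth below ``low_depth_max`` (or missing) — a wild-type
    call here may really be a no-call.  STRAND_BIAS: FS above the SNV
    hard-filter level.  MAPQUAL_BIAS: RMS mapping quality below 40 or
    MQRankSum below -12.5.  POSITION_BIAS: ReadPosRankSum below -8.
    BASEQUAL_BIAS is reserved: no base-quality rank annotation is part of
    the consumed INFO keys, so it cannot be derived from VCF input.
    """
    flags: set[str] = set()
    if obs.dp is None or obs.dp < cfg.low_depth_max:
        flags.add("LOW_DEPTH")
    info = obs.info
    if info.fs is not None and info.fs > cfg.fs_bias:
        flags.add("STRAND_BIAS")
    if (info.mq is not None and info.mq < cfg.mq_bias) or (
        info.mq_rank_sum is not None and info.mq_rank_sum < cfg.mq_rank_sum_bias
    ):
        flags.add("MAPQUAL_BIAS")
    if (
        info.read_pos_rank_sum is not None
        and info.read_pos_rank_sum < cfg.read_pos_rank_sum_bias
    ):
        flags.add("POSITION_BIAS")
    return frozenset(flags)


def _sample_zygosity(
    obs: Optional[SiteObservation],
    cfg: ScreenConfig,
    thresholds: FilterThresholds,
) -> SampleZygosity:
    if obs is None:
        return SampleZygosity.ABSENT
    if not obs.usable or (obs.dp is not None and obs.dp < cfg.low_depth_max):
        return SampleZygosity.LOW_DEPTH
    verdict = classify_observation(obs, thresholds)
    if verdict.status is FilterStatus.VARIANT:
        assert obs.pl is not None
        from .likelihood import zygosity_call

        if zygosity_call(obs.pl) is Zygosity.HOM_VAR:
            return SampleZygosity.HOM
        return SampleZygosity.HET
    return SampleZygosity.WT


def annotate_site(
    proband_obs: Optional[SiteObservation],
    background_obs_by_sample: Mapping[str, Optional[SiteObservation]],
    families: Mapping[str, str],
    cfg: ScreenConfig = DEFAULT_SCREEN,
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
) -> CrossSampleAnnotation:
    """Cross-sample annotation at one variant key.

    Parameters
    ----------
    proband_obs
        The proband record (its flags become the site's flags); may be
        ``None`` when the proband record is missing.
    background_obs_by_sample
        Background records keyed by sample id; ``None`` marks a sample
        with no record at this site.
    families
        sample id -> family id, used to count distinct unrelated families
        carrying the variant; samples without an entry count as their own
        singleton family.
    """
    zygosities: dict[str, SampleZygosity] = {}
    n_variant = 0
    variant_families: set[str] = set()
    for sid in sorted(background_obs_by_sample):
        z = _sample_zygosity(background_obs_by_sample[sid], cfg, thresholds)
        zygosities[sid] = z
        if z in (SampleZygosity.HET, SampleZygosity.HOM):
            n_variant += 1
            variant_families.add(families.get(sid, sid))
    flags = bias_flags(proband_obs, cfg) if proband_obs is not None else frozenset({"LOW_DEPTH"})
    return CrossSampleAnnotation(
        n_background_variant=n_variant,
        background_zygosities=zygosities,
        n_unrelated_families_with_variant=len(variant_families),
        flags=flags,
    )


@dataclass(frozen=True)
class ScreenResult:
    """Screening outcome for one proband site; kept iff no drop reasons."""

    key: VariantKey
    kept: bool
    reasons: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kept != (len(self.reasons) == 0):
            raise ValueError("kept iff reasons is empty")


def screen_candidates(
    proband_sites: Sequence[SiteObservation],
    family_obs: Mapping[str, Mapping[VariantKey, SiteObservation]],
    maf_table: Mapping[VariantKey, tuple[Optional[float], Optional[float]]],
    cfg: ScreenConfig = DEFAULT_SCREEN,
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
    annotations: Optional[Mapping[VariantKey, CrossSampleAnnotation]] = None,
) -> list[ScreenResult]:
    """Apply the rare/de-novo candidate screen to the proband's sites.

    Drop reasons (a site is kept iff its reason list is empty):

    * ``DEPTH`` — proband depth not strictly above ``min_depth``
    * ``MAF_1KG`` / ``MAF_ESP`` — population frequency at or above the
      cap (absent frequency passes: unknown variants are the rare case
      of interest)
    * ``FAMILY`` — an unaffected family member carries the variant
      (hard-filter verdict VARIANT)
    * ``COMMON_BACKGROUND`` — present in more than
      ``max_families_with_variant`` unrelated background families
    """
    results: list[ScreenResult] = []
    for obs in proband_sites:
        reasons: list[str] = []
        if obs.dp is None or obs.dp <= cfg.min_depth:
            reasons.append("DEPTH")
        maf_1kg, maf_esp = maf_table.get(obs.key, (None, None))
        if maf_1kg is not None and maf_1kg >= cfg.max_maf_1kg:
            reasons.append("MAF_1KG")
        if maf_esp is not None and maf_esp >= cfg.max_maf_esp:
            reasons.append("MAF_ESP")
        for member in sorted(family_obs):
            fam_o = family_obs[member].get(obs.key)
            if fam_o is None or not fam_o.usable:
                continue
            if classify_observation(fam_o, thresholds).status is FilterStatus.VARIANT:
                reasons.append("FAMILY")
                break
        if annotations is not None:
            ann = annotations.get(obs.key)
            if (
                ann is not None
                and ann.n_unrelated_families_with_variant
                > cfg.max_families_with_variant
            ):
                reasons.append("COMMON_BACKGROUND")
        results.append(
            ScreenResult(key=obs.key, kept=not reasons, reasons=tuple(reasons))
        )
    return results


@dataclass(frozen=True)
class FalseNegativeCandidate:
    sample_id: str
    key: VariantKey
    plrd: float
    bin: Bin


def flag_false_negative_candidates(
    site_results: Mapping[VariantKey, SiteResult],
    family_obs: Mapping[str, Mapping[VariantKey, SiteObservation]],
    cfg: BinningConfig = DEFAULT_BINNING,
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
) -> list[FalseNegativeCandidate]:
    """Family records called non-variant whose own PLRD bins as 1 or 2.

    A family member's forced-call record can fail the hard filters (and
    so read as "wild type") while its likelihood evidence, binned against
    the same background distribution as the proband's, clearly separates
    from the background — the signature of a missed (false-negative)
    call that would make a proband variant falsely appear de novo.
    Unusable records are never flagged: a low-coverage no-call is not
    evidence of a variant.
    """
    out: list[FalseNegativeCandidate] = []
    for member in sorted(family_obs):
        for key in family_obs[member]:
            result = site_results.get(key)
            if result is None:
                continue
            obs = family_obs[member][key]
            if not obs.usable:
                continue
            if classify_observation(obs, thresholds).status is FilterStatus.VARIANT:
                continue  # already called; nothing was missed
            assert obs.pl is not None and obs.dp is not None
            res = plrd_result(obs.pl, obs.dp)
            if res.zygosity is Zygosity.HOM_VAR or res.plrd is None:
                continue
            assignment = classify_bin(res.plrd, result.distribution, cfg)
            if assignment.bin in (Bin.BIN1, Bin.BIN2):
                out.append(
                    FalseNegativeCandidate(
                        sample_id=member, key=key, plrd=res.plrd, bin=assignment.bin
                    )
                )
    return out


def read_maf_table(
    path: str,
) -> dict[VariantKey, tuple[Optional[float], Optional[float]]]:
    """Read a TSV of population allele frequencies.

    Columns: chrom, pos, ref, alt, maf_1kg, maf_esp (header required;
    blank frequency cells mean "absent from that panel").
    """
    table: dict[VariantKey, tuple[Optional[float], Optional[float]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"chrom", "pos", "ref", "alt", "maf_1kg", "maf_esp"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(
                f"MAF table {path!r} must have columns {sorted(required)}"
            )
        for row in reader:
            key = VariantKey(
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref=row["ref"].upper(),
                alt=row["alt"].upper(),
            )
            maf_1kg = float(row["maf_1kg"]) if row["maf_1kg"].strip() else None
            maf_esp = float(row["maf_esp"]) if row["maf_esp"].strip() else None
            table[key] = (maf_1kg, maf_esp)
    return table
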