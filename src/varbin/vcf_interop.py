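"""Reading forced-genotyping VCFs and writing classification reports.

The method consumes VCFs produced by forced genotyping: the caller was
given a fixed list of candidate alleles (the proband's variants of
interest) and made to emit a record, with genotype likelihoods (PL) and
raw depth (DP), at every one of those sites in every sample — whether or
not a variant would have been called there.  This module parses such
files into per-sample :class:`SiteObservation` lists keyed by variant
change and position, aligns them across proband / family / background
samples, and writes the final tab-delimited report.

Parsing is delegated to :mod:`pysam`; records with missing PL or DP are
returned flagged unusable, never silently defaulted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Optional, Sequence

import pysam

from .likelihood import GenotypeLikelihoods

__all__ = [
    "VariantKey",
    "InfoAnnotations",
    "SiteObservation",
    "CohortTable",
    "ReportRow",
    "VcfParseError",
    "VcfConfigError",
    "read_forced_calls",
    "assemble_cohort",
    "emit_forced_call_settings",
    "write_report",
]

_BASES = frozenset("ACGT")

#: INFO keys consumed, in VCF spelling -> InfoAnnotations field name.
INFO_KEYS: Mapping[str, str] = {
    "QD": "qd",
    "MQ": "mq",
    "FS": "fs",
    "HaplotypeScore": "haplotype_score",
    "MQRankSum": "mq_rank_sum",
    "ReadPosRankSum": "read_pos_rank_sum",
}


class VcfParseError(ValueError):
    """A VCF record could not be parsed."""


class VcfConfigError(ValueError):
    """The input or cohort layout violates a structural requirement."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of one variant change: chromosome, position, ref, alt.

    Positions are 1-based VCF coordinates, used as-is: forced calls at a
    shared allele list already agree on representation, so no indel
    normalization is attempted.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name in ("ref", "alt"):
            allele = getattr(self, name)
            if not allele or not set(allele) <= _BASES:
                raise ValueError(
                    f"{name} must be a non-empty uppercase A/C/G/T string, got {allele!r}"
                )
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r})")

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


@dataclass(frozen=True)
class InfoAnnotations:
    """Site-level caller annotations used by the hard filters and bias flags.

    Every field is optional: the caller only emits annotations it could
    compute (e.g. rank-sum tests need both ref and alt reads).
    """

    qd: Optional[float] = None
    mq: Optional[float] = None
    fs: Optional[float] = None
    haplotype_score: Optional[float] = None
    mq_rank_sum: Optional[float] = None
    read_pos_rank_sum: Optional[float] = None

    def __post_init__(self) -> None:
        for name in (
            "qd", "mq", "fs", "haplotype_score", "mq_rank_sum", "read_pos_rank_sum",
        ):
            v = getattr(self, name)
            if v is not None and not math.isfinite(v):
                raise ValueError(f"{name} must be finite when present, got {v!r}")
        if self.fs is not None and self.fs < 0:
            raise ValueError(f"fs must be >= 0, got {self.fs!r}")


@dataclass(frozen=True)
class SiteObservation:
    """One sample's forced-call record at one variant key.

    ``pl`` and ``dp`` are ``None`` when the record lacked them; such
    observations are unusable and are excluded from background
    distributions rather than imputed.
    """

    sample_id: str
    key: VariantKey
    pl: Optional[GenotypeLikelihoods]
    dp: Optional[int]
    vcf_filter: str = "."
    info: InfoAnnotations = field(default_factory=InfoAnnotations)

    def __post_init__(self) -> None:
        if self.dp is not None and self.dp < 0:
            raise ValueError(f"dp must be >= 0, got {self.dp}")

    @property
    def is_indel(self) -> bool:
        return self.key.is_indel

    @property
    def usable(self) -> bool:
        return self.pl is not None and self.dp is not None


@dataclass
class CohortTable:
    """Proband, family and background observations joined on VariantKey.

    ``missing_sites`` records, per sample, the proband sites with no
    observation in that sample's VCF — kept distinct from wild-type calls.
    """

    site_list: list[VariantKey]
    observations: dict[tuple[str, VariantKey], SiteObservation]
    roles: dict[str, str]  # sample_id -> proband | family | background
    missing_sites: dict[str, list[VariantKey]]

    @property
    def proband_id(self) -> str:
        return next(s for s, r in self.roles.items() if r == "proband")

    def samples_with_role(self, role: str) -> list[str]:
        return [s for s, r in self.roles.items() if r == role]

    def get(self, sample_id: str, key: VariantKey) -> Optional[SiteObservation]:
        return self.observations.get((sample_id, key))


def _pl_subtriple_indices(alt_index: int) -> tuple[int, int, int]:
    # Diploid PL ordering per the VCF spec: genotype (j,k), j<=k, sits at
    # index k*(k+1)/2 + j.  For ALT number a (1-based): (0,0), (0,a), (a,a).
    a = alt_index
    return 0, a * (a + 1) // 2, a * (a + 1) // 2 + a


def _scalar(value) -> Optional[float]:
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        value = value[0] if value else None
        if value is None:
            return None
    v = float(value)
    return v if math.isfinite(v) else None


def read_forced_calls(
    vcf_path: str,
    sample_id: Optional[str] = None,
) -> list[SiteObservation]:
    """Read one sample's forced-call records into site observations.

    Parameters
    ----------
    vcf_path : str
        Path to a VCF v4.x file with FORMAT fields PL and DP.
    sample_id : str, optional
        Sample to extract when the file is multi-sample; defaults to the
        only sample present.

    Returns
    -------
    list of SiteObservation
        One observation per biallelic ALT per record, in file order.
        Multi-allelic records are decomposed into one observation per ALT
        with the PL sub-triple for that ALT.  Records with missing PL or
        DP come back flagged unusable.  ALT alleles that are not plain
        A/C/G/T strings (symbolic, spanning-deletion, '.') are skipped.

    Raises
    ------
    VcfConfigError
        If the header lacks the PL FORMAT definition or the requested
        sample is absent.
    VcfParseError
        If a record cannot be parsed (the error names the record).
    """
    try:
        vf = pysam.VariantFile(vcf_path)
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot open VCF {vcf_path!r}: {exc}") from exc
    with vf:
        if "PL" not in vf.header.formats:
            raise VcfConfigError(
                f"{vcf_path!r}: FORMAT field PL is not defined in the header; "
                "input must come from a genotyper emitting genotype likelihoods"
            )
        samples = list(vf.header.samples)
        if sample_id is None:
            if len(samples) != 1:
                raise VcfConfigError(
                    f"{vcf_path!r} has {len(samples)} samples; pass sample_id"
                )
            sample_id = samples[0]
        elif sample_id not in samples:
            raise VcfConfigError(f"sample {sample_id!r} not in {vcf_path!r}")

        out: list[SiteObservation] = []
        record_no = 0
        iterator = iter(vf)
        while True:
            try:
                rec = next(iterator)
            except StopIteration:
                break
            except Exception as exc:  # malformed line inside htslib
                raise VcfParseError(
                    f"{vcf_path!r}: malformed VCF record #{record_no + 1}: {exc}"
                ) from exc
            record_no += 1
            try:
                out.extend(_observations_from_record(rec, sample_id))
            except VcfParseError:
                raise
            except Exception as exc:
                raise VcfParseError(
                    f"{vcf_path!r}: record #{record_no} "
                    f"({rec.chrom}:{rec.pos}): {exc}"
                ) from exc
        return out


def _observations_from_record(rec, sample_id: str) -> list[SiteObservation]:
    alts = rec.alts or ()
    if not alts:
        return []
    info_kwargs = {}
    for key, attr in INFO_KEYS.items():
        try:
            info_kwargs[attr] = _scalar(rec.info.get(key))
        except (KeyError, ValueError):  # key absent / undeclared in header
            info_kwargs[attr] = None
    info = InfoAnnotations(**info_kwargs)
    sample = rec.samples[sample_id]
    raw_pl = sample.get("PL")
    raw_dp = sample.get("DP")
    dp = int(raw_dp) if raw_dp is not None else None
    filter_keys = list(rec.filter.keys())
    vcf_filter = ";".join(filter_keys) if filter_keys else "."

    ref = (rec.ref or "").upper()
    out: list[SiteObservation] = []
    for j, alt in enumerate(alts, start=1):
        alt = (alt or "").upper()
        if not alt or not set(alt) <= _BASES or not set(ref) <= _BASES or alt == ref:
            continue  # symbolic / spanning-deletion / degenerate ALT
        key = VariantKey(chrom=str(rec.chrom), pos=int(rec.pos), ref=ref, alt=alt)
        pl: Optional[GenotypeLikelihoods] = None
        if raw_pl is not None:
            idx = _pl_subtriple_indices(j)
            if max(idx) < len(raw_pl) and all(raw_pl[i] is not None for i in idx):
                pl = GenotypeLikelihoods(
                    pl_aa=float(raw_pl[idx[0]]),
                    pl_ab=float(raw_pl[idx[1]]),
                    pl_bb=float(raw_pl[idx[2]]),
                )
        out.append(
            SiteObservation(
                sample_id=sample_id,
                key=key,
                pl=pl,
                dp=dp,
                vcf_filter=vcf_filter,
                info=info,
            )
        )
    return out


def assemble_cohort(
    proband_obs: Sequence[SiteObservation],
    family_obs_lists: Sequence[Sequence[SiteObservation]] = (),
    background_obs_lists: Sequence[Sequence[SiteObservation]] = (),
) -> CohortTable:
    """Join per-sample observation lists on VariantKey into a cohort table.

    The proband's site order defines the table's site list.  Sites seen in
    a family or background sample but absent from the proband are dropped
    with a warning; proband sites missing from another sample are recorded
    in ``missing_sites`` (distinct from a wild-type call there).

    Raises
    ------
    VcfConfigError
        If there are no background samples, no/duplicate proband sites are
        inconsistent, or a sample_id appears in more than one list.
    """
    if not background_obs_lists:
        raise VcfConfigError("at least one background sample is required")
    if not proband_obs:
        raise VcfConfigError("proband observation list is empty")

    site_list: list[VariantKey] = []
    seen: set[VariantKey] = set()
    for obs in proband_obs:
        if obs.key not in seen:
            seen.add(obs.key)
            site_list.append(obs.key)

    observations: dict[tuple[str, VariantKey], SiteObservation] = {}
    roles: dict[str, str] = {}
    missing_sites: dict[str, list[VariantKey]] = {}

    def _add(obs_list: Sequence[SiteObservation], role: str) -> None:
        if not obs_list:
            raise VcfConfigError(f"empty observation list for role {role!r}")
        sid = obs_list[0].sample_id
        if any(o.sample_id != sid for o in obs_list):
            raise VcfConfigError(
                f"observation list for role {role!r} mixes sample ids"
            )
        if sid in roles:
            raise VcfConfigError(f"duplicate sample id {sid!r} across roles")
        roles[sid] = role
        covered: set[VariantKey] = set()
        for obs in obs_list:
            if obs.key not in seen:
                warnings.warn(
                    f"sample {sid!r}: site {obs.key.chrom}:{obs.key.pos} "
                    f"{obs.key.ref}>{obs.key.alt} absent from proband; dropped",
                    stacklevel=3,
                )
                continue
            observations[(sid, obs.key)] = obs
            covered.add(obs.key)
        missing_sites[sid] = [k for k in site_list if k not in covered]

    _add(proband_obs, "proband")
    for fam in family_obs_lists:
        _add(fam, "family")
    for bg in background_obs_lists:
        _add(bg, "background")

    return CohortTable(
        site_list=site_list,
        observations=observations,
        roles=roles,
        missing_sites=missing_sites,
    )


def emit_forced_call_settings() -> str:
    """Return the nonstandard genotyper settings needed to regenerate input.

    Forced genotyping requires the caller to emit a record at every
    candidate allele in every sample, including confidently wild-type
    sites that a default run would never report.  These UnifiedGenotyper
    settings produce such output; users can apply them verbatim to build
    compatible proband/background VCFs.
    """
    return (
        "# UnifiedGenotyper settings for forced genotype emission at a fixed\n"
        "# candidate-allele list (all other options at their defaults):\n"
        "genotype_likelihoods_model BOTH\n"
        "stand_call_conf 0.0\n"
        "stand_emit_conf 0.0\n"
        "max_deletion_fraction 1.0\n"
        "min_base_quality_score 17\n"
        "genotyping_mode GENOTYPE_GIVEN_ALLELES\n"
        "output_mode EMIT_ALL_SITES\n"
        "# supply the candidate variants via the 'alleles' option (VCF of the\n"
        "# proband's variants of interest)\n"
    )


@dataclass(frozen=True)
class ReportRow:
    """One proband site's classification result for the TSV report."""

    key: VariantKey
    proband_plrd: Optional[float]
    bg_median: Optional[float]
    bg_iqd: Optional[float]
    bg_n_wildtype: int
    bg_n_variant: int
    bin_label: str
    flags: tuple[str, ...] = ()


_REPORT_COLUMNS = (
    "chrom", "pos", "ref", "alt", "proband_plrd", "bg_median", "bg_iqd",
    "bg_n_wildtype", "bg_n_variant", "bin", "flags",
)


def _fmt(value: Optional[float]) -> str:
    if value is None:
        return "NA"
    return format(float(value), ".6g")


def write_report(rows: Iterable[ReportRow], sink: IO[str]) -> int:
    """Write the per-site classification report as TSV; returns row count.

    Deterministic: floats at six significant digits, rows in input order,
    header always present.
    """
    sink.write("\t".join(_REPORT_COLUMNS) + "\n")
    n = 0
    for row in rows:
        k = row.key
        sink.write(
            "\t".join(
                (
                    k.chrom,
                    str(k.pos),
                    k.ref,
                    k.alt,
                    _fmt(row.proband_plrd),
                    _fmt(row.bg_median),
                    _fmt(row.bg_iqd),
                    str(row.bg_n_wildtype),
                    str(row.bg_n_variant),
                    row.bin_label,
                    ",".join(row.flags) if row.flags else ".",
                )
            )
            + "\n"
        )
        n += 1
    return n
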