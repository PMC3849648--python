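"""Synthetic forced-call cohorts with the statistics the method assumes.

The generator emulates what a forced-genotyping caller emits over a fixed
candidate-site list, using a minimal diploid read model: at each site and
sample, depth is Poisson, the alt-read count is binomial, and per-read
base calls err with probability ``e = 10**(-Q/10)`` (uniform over the
three wrong bases).  Genotype likelihoods follow directly, which places

* clean wild-type records near -3 PLRD (each matching read contributes
  about ``-10*log10((1-e)/((1-e)/2 + e/6)) ≈ -3.01`` Phred at Q30),
* balanced heterozygotes above +10 PLRD on average (~+14.4 at Q30),

the two clusters the binning heuristic is built around.

Systematic error-prone sites get a latent alt-read fraction drawn once
per site and shared across all samples (with per-sample jitter) —
the simplest mechanism for sequence-specific errors that recur in every
sample run on the same platform and chemistry — plus elevated strand-bias
and read-position-bias annotations with configurable probability, so most
of those records fail the hard filters and broaden the background
wild-type/non-variant distribution exactly as real error-prone sites do.

Outputs are one plain-text VCF per sample plus a truth table; the VCFs
round-trip through :func:`varbin.vcf_interop.read_forced_calls` and are
byte-identical for a fixed spec and seed.
"""

from __future__ import annotations

import enum
import math
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .hard_filters import DEFAULT_THRESHOLDS, classify_observation
from .likelihood import GenotypeLikelihoods
from .vcf_interop import InfoAnnotations, SiteObservation, VariantKey

__all__ = [
    "SiteKind",
    "SiteModel",
    "CohortSpec",
    "SimulatedCohort",
    "genotype_likelihoods_from_reads",
    "simulate_cohort",
    "make_site_models",
]


class SiteKind(enum.Enum):
    TRUE_HET = "true_het"
    WILD_TYPE = "wild_type"
    SYSTEMATIC_ERROR = "systematic_error"


@dataclass(frozen=True)
class SiteModel:
    """Generative model for one candidate site.

    alt_fraction is the expected alt-read fraction in the proband: 0.5
    for a true heterozygote, 0 for wild type, and a small value (default
    0.15) for systematic error sites, where it applies to every sample.
    """

    kind: SiteKind
    depth_mean: float = 30.0
    base_quality: float = 30.0
    alt_fraction: Optional[float] = None
    shared_error: bool = True
    bias_probability: float = 0.9

    def __post_init__(self) -> None:
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        af = self.effective_alt_fraction
        if not 0.0 <= af <= 1.0:
            raise ValueError(f"alt_fraction must be in [0, 1], got {af}")

    @property
    def effective_alt_fraction(self) -> float:
        if self.alt_fraction is not None:
            return self.alt_fraction
        return {
            SiteKind.TRUE_HET: 0.5,
            SiteKind.WILD_TYPE: 0.0,
            SiteKind.SYSTEMATIC_ERROR: 0.15,
        }[self.kind]

    @property
    def error_rate(self) -> float:
        return 10.0 ** (-self.base_quality / 10.0)


@dataclass(frozen=True)
class CohortSpec:
    """A reproducible cohort: same spec and seed give byte-identical files."""

    n_background: int
    site_models: Sequence[tuple[VariantKey, SiteModel]]
    seed: int
    n_family: int = 0

    def __post_init__(self) -> None:
        if self.n_background < 1:
            raise ValueError("n_background must be >= 1")
        if self.n_family < 0:
            raise ValueError("n_family must be >= 0")
        if not self.site_models:
            raise ValueError("site_models must be non-empty")


@dataclass(frozen=True)
class SimulatedCohort:
    """Paths of the generated per-sample VCFs and the truth table."""

    proband_path: str
    family_paths: tuple[str, ...]
    background_paths: tuple[str, ...]
    truth_path: str
    sample_ids: tuple[str, ...]


def genotype_likelihoods_from_reads(
    n_ref: int, n_alt: int, e: float
) -> GenotypeLikelihoods:
    """Diploid genotype likelihoods from ref/alt read counts.

    Per read and genotype ``g``, ``P(read | g) = mean over alleles a in g
    of P(read | a)`` with ``P(match) = 1 - e`` and ``P(specific
    mismatch) = e/3``.  Log-likelihoods are summed over reads, converted
    to the Phred scale and normalized so the minimum PL is 0.  With no
    reads all three PLs are 0 (uninformative).
    """
    if n_ref < 0 or n_alt < 0:
        raise ValueError("read counts must be >= 0")
    if not 0.0 < e < 0.75:
        raise ValueError(f"per-read error probability must be in (0, 0.75), got {e}")
    if n_ref == 0 and n_alt == 0:
        return GenotypeLikelihoods(0.0, 0.0, 0.0)
    p_match = 1.0 - e
    p_mismatch = e / 3.0
    p_half = 0.5 * p_match + 0.5 * p_mismatch
    log10 = math.log10
    ll = {
        "AA": n_ref * log10(p_match) + n_alt * log10(p_mismatch),
        "AB": n_ref * log10(p_half) + n_alt * log10(p_half),
        "BB": n_ref * log10(p_mismatch) + n_alt * log10(p_match),
    }
    best = max(ll.values())
    return GenotypeLikelihoods(
        pl_aa=-10.0 * (ll["AA"] - best),
        pl_ab=-10.0 * (ll["AB"] - best),
        pl_bb=-10.0 * (ll["BB"] - best),
    )


def make_site_models(
    n_true_het: int,
    n_wild_type: int,
    n_systematic: int,
    depth_mean: float = 30.0,
    base_quality: float = 30.0,
    error_alt_fraction: float = 0.15,
    chrom: str = "1",
    start_pos: int = 10_000,
    spacing: int = 100,
) -> list[tuple[VariantKey, SiteModel]]:
    """Deterministic site list: true-het, then wild-type, then error sites."""
    changes = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))
    models: list[tuple[VariantKey, SiteModel]] = []
    kinds = (
        [SiteKind.TRUE_HET] * n_true_het
        + [SiteKind.WILD_TYPE] * n_wild_type
        + [SiteKind.SYSTEMATIC_ERROR] * n_systematic
    )
    for i, kind in enumerate(kinds):
        ref, alt = changes[i % len(changes)]
        key = VariantKey(chrom=chrom, pos=start_pos + i * spacing, ref=ref, alt=alt)
        models.append(
            (
                key,
                SiteModel(
                    kind=kind,
                    depth_mean=depth_mean,
                    base_quality=base_quality,
                    alt_fraction=(
                        error_alt_fraction
                        if kind is SiteKind.SYSTEMATIC_ERROR
                        else None
                    ),
                ),
            )
        )
    return models


_VCF_HEADER_TEMPLATE = """\
##fileformat=VCFv4.2
##source=varbin-simulate
##INFO=<ID=QD,Number=1,Type=Float,Description="Variant confidence by depth">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled Fisher strand bias">
##INFO=<ID=HaplotypeScore,Number=1,Type=Float,Description="Haplotype consistency score">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank sum (alt vs ref reads)">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum (alt vs ref reads)">
##FILTER=<ID=QD,Description="QD below hard-filter threshold">
##FILTER=<ID=MQ,Description="MQ below hard-filter threshold">
##FILTER=<ID=FS,Description="FS above hard-filter threshold">
##FILTER=<ID=HaplotypeScore,Description="HaplotypeScore above hard-filter threshold">
##FILTER=<ID=MQRankSum,Description="MQRankSum below hard-filter threshold">
##FILTER=<ID=ReadPosRankSum,Description="ReadPosRankSum below hard-filter threshold">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Called genotype (argmin PL)">
##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled genotype likelihoods">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


@dataclass
class _SampleRecord:
    gl: GenotypeLikelihoods
    dp: int
    info: InfoAnnotations
    true_genotype: str


def _draw_record(
    rng: np.random.Generator,
    model: SiteModel,
    alt_fraction: float,
    true_genotype: str,
    biased: bool,
) -> _SampleRecord:
    dp = int(rng.poisson(model.depth_mean))
    n_alt = int(rng.binomial(dp, alt_fraction)) if dp > 0 else 0
    n_ref = dp - n_alt
    gl = (
        genotype_likelihoods_from_reads(n_ref, n_alt, model.error_rate)
        if dp > 0
        else GenotypeLikelihoods(0.0, 0.0, 0.0)
    )
    # QD emulates QUAL/DP for the emitted record: zero for confident
    # wild type, roughly the PLRD for variant-supporting records.
    from .likelihood import compute_plr

    plr = compute_plr(gl)
    qd = max(plr, 0.0) / dp if dp > 0 else 0.0
    mq = 60.0 + float(rng.normal(0.0, 0.5))
    if biased:
        fs = float(rng.uniform(65.0, 140.0))
        read_pos = float(rng.uniform(-14.0, -9.0))
    else:
        fs = abs(float(rng.normal(0.0, 2.0)))
        read_pos = float(rng.normal(0.0, 1.0))
    info = InfoAnnotations(
        qd=round(qd, 2),
        mq=round(mq, 2),
        fs=round(fs, 2),
        haplotype_score=round(abs(float(rng.normal(0.0, 1.5))), 2),
        mq_rank_sum=round(float(rng.normal(0.0, 1.0)), 2),
        read_pos_rank_sum=round(read_pos, 2),
    )
    return _SampleRecord(gl=gl, dp=dp, info=info, true_genotype=true_genotype)


def _called_gt(gl: GenotypeLikelihoods) -> str:
    pls = (gl.pl_aa, gl.pl_ab, gl.pl_bb)
    return ("0/0", "0/1", "1/1")[int(np.argmin(pls))]


def _format_record(key: VariantKey, rec: _SampleRecord) -> str:
    pl = tuple(int(round(v)) for v in (rec.gl.pl_aa, rec.gl.pl_ab, rec.gl.pl_bb))
    info = rec.info
    info_str = ";".join(
        f"{tag}={val:.2f}"
        for tag, val in (
            ("QD", info.qd),
            ("MQ", info.mq),
            ("FS", info.fs),
            ("HaplotypeScore", info.haplotype_score),
            ("MQRankSum", info.mq_rank_sum),
            ("ReadPosRankSum", info.read_pos_rank_sum),
        )
    )
    # FILTER holds the recomputed hard-filter verdict, like the upstream
    # VariantFiltration step would have written it.
    obs = SiteObservation(
        sample_id="tmp", key=key, pl=rec.gl, dp=rec.dp, info=info
    )
    verdict = classify_observation(obs, DEFAULT_THRESHOLDS)
    filter_str = ";".join(verdict.failed_rules) if verdict.failed_rules else "PASS"
    from .likelihood import compute_plr

    qual = max(compute_plr(rec.gl), 0.0)
    return "\t".join(
        (
            key.chrom,
            str(key.pos),
            ".",
            key.ref,
            key.alt,
            f"{qual:.2f}",
            filter_str,
            info_str,
            "GT:PL:DP",
            f"{_called_gt(rec.gl)}:{pl[0]},{pl[1]},{pl[2]}:{rec.dp}",
        )
    )


def simulate_cohort(spec: CohortSpec, out_dir: str) -> SimulatedCohort:
    """Generate per-sample forced-call VCFs and a truth table.

    Randomness comes from a single ``numpy`` generator seeded with
    ``spec.seed``; sites are drawn in list order and samples in a fixed
    order (proband, family, backgrounds) within each site, so output is
    byte-identical across runs.
    """
    rng = np.random.default_rng(spec.seed)
    os.makedirs(out_dir, exist_ok=True)
    pad = max(2, len(str(max(spec.n_background, spec.n_family))))
    sample_ids = (
        ["proband"]
        + [f"family{str(i + 1).zfill(pad)}" for i in range(spec.n_family)]
        + [f"background{str(i + 1).zfill(pad)}" for i in range(spec.n_background)]
    )
    records: dict[str, list[str]] = {sid: [] for sid in sample_ids}
    truth_rows: list[str] = []

    for key, model in spec.site_models:
        if model.kind is SiteKind.SYSTEMATIC_ERROR and model.shared_error:
            site_af = float(
                np.clip(
                    rng.normal(model.effective_alt_fraction, 0.05), 0.005, 0.6
                )
            )
        else:
            site_af = model.effective_alt_fraction
        for sid in sample_ids:
            if model.kind is SiteKind.TRUE_HET:
                is_carrier = sid == "proband"
                af = model.effective_alt_fraction if is_carrier else 0.0
                true_gt = "0/1" if is_carrier else "0/0"
                biased = False
            elif model.kind is SiteKind.WILD_TYPE:
                af, true_gt, biased = 0.0, "0/0", False
            else:  # SYSTEMATIC_ERROR: shared latent error in every sample
                af = float(np.clip(site_af + rng.normal(0.0, 0.03), 0.0, 1.0))
                true_gt = "0/0"
                biased = bool(rng.random() < model.bias_probability)
            rec = _draw_record(rng, model, af, true_gt, biased)
            records[sid].append(_format_record(key, rec))
            truth_rows.append(
                "\t".join(
                    (
                        key.chrom,
                        str(key.pos),
                        key.ref,
                        key.alt,
                        model.kind.value,
                        sid,
                        rec.true_genotype,
                    )
                )
            )

    contig_ids = sorted({key.chrom for key, _ in spec.site_models})
    contigs = "".join(f"##contig=<ID={c}>\n" for c in contig_ids)
    paths: dict[str, str] = {}
    for sid in sample_ids:
        path = os.path.join(out_dir, f"{sid}.vcf")
        with open(path, "w") as fh:
            fh.write(_VCF_HEADER_TEMPLATE.format(contigs=contigs, sample=sid))
            fh.write("\n".join(records[sid]))
            fh.write("\n")
        paths[sid] = path

    truth_path = os.path.join(out_dir, "truth.tsv")
    with open(truth_path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tsite_kind\tsample\ttrue_genotype\n")
        fh.write("\n".join(truth_rows))
        fh.write("\n")

    return SimulatedCohort(
        proband_path=paths["proband"],
        family_paths=tuple(paths[s] for s in sample_ids if s.startswith("family")),
        background_paths=tuple(
            paths[s] for s in sample_ids if s.startswith("background")
        ),
        truth_path=truth_path,
        sample_ids=tuple(sample_ids),
    )
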