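"""Phred-scaled genotype likelihood ratios and their depth normalization.

A forced-genotyping caller emits, for every candidate site in every sample,
the Phred-scaled likelihoods of the three diploid genotypes: PL(AA)
(homozygous reference), PL(AB) (heterozygous), PL(BB) (homozygous variant).
Smaller PL means more likely; the caller normalizes so the most likely
genotype has PL 0, but nothing here depends on that normalization.

The core statistic is the likelihood ratio of "no variant" against "some
variant"::

    PLR  = -10 * log10( L(AA) / (L(AB) + L(BB)) )
    PLRD = PLR / DP

where ``L(g) = 10**(-PL(g)/10)`` and DP is the raw read depth.  PLR is
strongly linear in depth (each informative read contributes a roughly
constant Phred increment), so dividing by DP yields a per-read evidence
score that is comparable across samples and sites: clean reference calls
sit near -3 PLRD, confident heterozygous calls above about +10.

All ratio arithmetic is carried out on the Phred (log) scale so that PL
values in the thousands -- routine in whole-genome data -- cannot underflow
to zero in linear space and produce infinite ratios.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "GenotypeLikelihoods",
    "PlrdResult",
    "Zygosity",
    "phred_to_linear",
    "compute_plr",
    "compute_plrd",
    "zygosity_call",
    "plrd_result",
]

_TEN_LOG10_2 = 10.0 * math.log10(2.0)


class Zygosity(enum.Enum):
    """Zygosity class of a forced-call record.

    Only two states matter downstream: confidently homozygous-variant
    records are excluded from binning (they are rarely false positives,
    having many variant-supporting reads), everything else stays in.
    """

    HET_OR_WT = "het_or_wt"
    HOM_VAR = "hom_var"


@dataclass(frozen=True)
class GenotypeLikelihoods:
    """One sample's Phred-scaled diploid genotype likelihood triple.

    Attributes
    ----------
    pl_aa : float
        PL of the homozygous-reference genotype.
    pl_ab : float
        PL of the heterozygous genotype.
    pl_bb : float
        PL of the homozygous-variant genotype.
    """

    pl_aa: float
    pl_ab: float
    pl_bb: float

    def __post_init__(self) -> None:
        for name in ("pl_aa", "pl_ab", "pl_bb"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v!r}")


@dataclass(frozen=True)
class PlrdResult:
    """PLR, PLRD and zygosity for one observation.

    ``plrd`` is ``None`` when depth is zero (the ratio is undefined; the
    site is unclassifiable, never NaN).  ``display_plrd`` equals ``plrd``
    except for homozygous-variant records, which are conventionally plotted
    at zero after being excluded from analysis.
    """

    plr: float
    plrd: Optional[float]
    dp: int
    zygosity: Zygosity

    @property
    def display_plrd(self) -> Optional[float]:
        if self.zygosity is Zygosity.HOM_VAR:
            return 0.0
        return self.plrd


def phred_to_linear(pl: float) -> float:
    """Convert a Phred-scaled value to a linear-scale likelihood.

    Returns ``10**(-pl/10)``.  Strictly positive for any PL up to ~3080;
    ratio computations elsewhere stay on the log scale and never rely on
    this staying above the double-precision underflow threshold.
    """
    if not math.isfinite(pl):
        raise ValueError(f"pl must be finite, got {pl!r}")
    return 10.0 ** (-pl / 10.0)


def compute_plr(gl: GenotypeLikelihoods) -> float:
    """Phred-scaled genotype likelihood ratio of wild type vs. any variant.

    Evaluates ``-10*log10( L(AA) / (L(AB) + L(BB)) )`` entirely on the
    Phred scale: the denominator is combined with a two-term log-sum-exp,
    so arbitrarily large PL values cannot underflow.  Negative values favor
    the homozygous-reference genotype, positive values favor a variant.

    Invariant under adding a common constant to all three PL fields, hence
    insensitive to the caller's normalization convention.
    """
    lo = min(gl.pl_ab, gl.pl_bb)
    hi = max(gl.pl_ab, gl.pl_bb)
    # -10*log10(10^(-ab/10) + 10^(-bb/10)) == lo - 10*log10(1 + 10^(-(hi-lo)/10))
    return gl.pl_aa - lo + 10.0 * math.log10(1.0 + 10.0 ** (-(hi - lo) / 10.0))


def compute_plrd(plr: float, dp: int) -> Optional[float]:
    """Divide PLR by raw read depth; ``None`` when depth is zero.

    Raises
    ------
    ValueError
        If ``dp`` is negative.
    """
    if dp < 0:
        raise ValueError(f"depth must be >= 0, got {dp}")
    if dp == 0:
        return None
    return plr / dp


def zygosity_call(gl: GenotypeLikelihoods) -> Zygosity:
    """Classify a record as homozygous-variant or not.

    A record is HOM_VAR only when the BB genotype is strictly the most
    likely of the three (strictly smallest PL).  Ties are kept as
    HET_OR_WT so borderline records remain in the analysis rather than
    being silently excluded.
    """
    if gl.pl_bb < gl.pl_aa and gl.pl_bb < gl.pl_ab:
        return Zygosity.HOM_VAR
    return Zygosity.HET_OR_WT


def plrd_result(gl: GenotypeLikelihoods, dp: int) -> PlrdResult:
    """Compute the full PLR/PLRD/zygosity summary for one record."""
    plr = compute_plr(gl)
    return PlrdResult(
        plr=plr,
        plrd=compute_plrd(plr, dp),
        dp=dp,
        zygosity=zygosity_call(gl),
    )
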