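"""End-to-end orchestration: cohort table in, classified report rows out."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .annotate import (
    DEFAULT_SCREEN,
    CrossSampleAnnotation,
    FalseNegativeCandidate,
    ScreenConfig,
    annotate_site,
    flag_false_negative_candidates,
)
from .binning import (
    DEFAULT_BINNING,
    BinningConfig,
    SiteResult,
    varbin_site,
)
from .hard_filters import DEFAULT_THRESHOLDS, FilterThresholds
from .vcf_interop import CohortTable, ReportRow, SiteObservation, VariantKey

__all__ = ["CohortClassification", "classify_cohort"]


@dataclass
class CohortClassification:
    """Per-site results, annotations and report rows for one cohort run."""

    site_results: dict[VariantKey, SiteResult]
    annotations: dict[VariantKey, CrossSampleAnnotation]
    report_rows: list[ReportRow]
    false_negative_candidates: list[FalseNegativeCandidate]

    @property
    def bin_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for result in self.site_results.values():
            label = result.assignment.bin.value
            counts[label] = counts.get(label, 0) + 1
        return counts


def classify_cohort(
    cohort: CohortTable,
    bin_cfg: BinningConfig = DEFAULT_BINNING,
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
    screen_cfg: ScreenConfig = DEFAULT_SCREEN,
    families: Optional[Mapping[str, str]] = None,
    trust_filter_field: bool = False,
) -> CohortClassification:
    """Classify every proband site against the cohort's backgrounds.

    ``families`` maps background sample ids to family ids for the
    unrelated-family count; by default every background sample counts as
    its own family.
    """
    families = dict(families or {})
    proband_id = cohort.proband_id
    background_ids = cohort.samples_with_role("background")
    family_ids = cohort.samples_with_role("family")

    site_results: dict[VariantKey, SiteResult] = {}
    annotations: dict[VariantKey, CrossSampleAnnotation] = {}
    rows: list[ReportRow] = []

    for key in cohort.site_list:
        proband_obs = cohort.get(proband_id, key)
        assert proband_obs is not None  # site list derives from the proband
        bg_obs_by_sample: dict[str, Optional[SiteObservation]] = {
            sid: cohort.get(sid, key) for sid in background_ids
        }
        bg_list = [o for o in bg_obs_by_sample.values() if o is not None]
        result = varbin_site(
            proband_obs,
            bg_list,
            cfg=bin_cfg,
            thresholds=thresholds,
            trust_filter_field=trust_filter_field,
        )
        ann = annotate_site(
            proband_obs, bg_obs_by_sample, families, screen_cfg, thresholds
        )
        site_results[key] = result
        annotations[key] = ann
        rows.append(
            ReportRow(
                key=key,
                proband_plrd=(
                    result.proband.display_plrd if result.proband else None
                ),
                bg_median=result.distribution.median,
                bg_iqd=result.distribution.iqd,
                bg_n_wildtype=result.distribution.n,
                bg_n_variant=result.n_background_variant,
                bin_label=result.assignment.bin.value,
                flags=tuple(sorted(ann.flags)),
            )
        )

    family_obs: dict[str, dict[VariantKey, SiteObservation]] = {}
    for sid in family_ids:
        family_obs[sid] = {
            key: obs
            for key in cohort.site_list
            if (obs := cohort.get(sid, key)) is not None
        }
    fn_candidates = flag_false_negative_candidates(
        site_results, family_obs, bin_cfg, thresholds
    )

    return CohortClassification(
        site_results=site_results,
        annotations=annotations,
        report_rows=rows,
        false_negative_candidates=fn_candidates,
    )
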