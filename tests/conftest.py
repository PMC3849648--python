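"""Shared fixtures: observation builders and a seeded simulated cohort."""

from __future__ import annotations

import collections

import pytest

from varbin import (
    GenotypeLikelihoods,
    InfoAnnotations,
    SiteObservation,
    VariantKey,
    assemble_cohort,
    read_forced_calls,
)
from varbin.pipeline import classify_cohort
from varbin.simulate import CohortSpec, make_site_models, simulate_cohort

SNV_KEY = VariantKey(chrom="1", pos=100, ref="A", alt="G")
INDEL_KEY = VariantKey(chrom="1", pos=200, ref="A", alt="AG")


def make_obs(
    sample_id="s1",
    key=SNV_KEY,
    pl=(120.0, 0.0, 200.0),
    dp=40,
    vcf_filter=".",
    **info,
):
    """Compact SiteObservation builder; pl=None / dp=None mark unusable."""
    return SiteObservation(
        sample_id=sample_id,
        key=key,
        pl=GenotypeLikelihoods(*pl) if pl is not None else None,
        dp=dp,
        vcf_filter=vcf_filter,
        info=InfoAnnotations(**info),
    )


# Study-scale synthetic cohort: 200 sites (80 true het, 60 wild type,
# 60 systematic-error), depth 30, Q30 reads, 20 backgrounds, 3 family
# members; shared session-wide because simulation + classification of the
# whole table is the expensive part of the suite.
@pytest.fixture(scope="session")
def sim_cohort(tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    models = make_site_models(80, 60, 60, depth_mean=30.0, base_quality=30.0)
    spec = CohortSpec(n_background=20, n_family=3, site_models=models, seed=0)
    return simulate_cohort(spec, str(out))


@pytest.fixture(scope="session")
def sim_truth(sim_cohort):
    truth = {}
    with open(sim_cohort.truth_path) as fh:
        next(fh)
        for line in fh:
            chrom, pos, ref, alt, kind, sample, gt = line.rstrip("\n").split("\t")
            truth[VariantKey(chrom, int(pos), ref, alt), sample] = (kind, gt)
    return truth


@pytest.fixture(scope="session")
def sim_classification(sim_cohort):
    proband = read_forced_calls(sim_cohort.proband_path)
    fams = [read_forced_calls(p) for p in sim_cohort.family_paths]
    bgs = [read_forced_calls(p) for p in sim_cohort.background_paths]
    cohort = assemble_cohort(proband, fams, bgs)
    return cohort, classify_cohort(cohort)


@pytest.fixture(scope="session")
def bins_by_kind(sim_classification, sim_truth):
    cohort, classification = sim_classification
    table = collections.defaultdict(collections.Counter)
    for key, result in classification.site_results.items():
        kind, _ = sim_truth[key, "proband"]
        table[kind][result.assignment.bin] += 1
    return table
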