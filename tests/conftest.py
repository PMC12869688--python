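"""Shared fixtures: small synthetic cohorts and reusable time-series subjects.

Expensive simulations are session-scoped so the whole suite pays for them
once; everything is seeded for reproducibility.
"""
from __future__ import annotations

import numpy as np
import pytest

from ssmap import (CohortSpec, build_bipolar_montage, simulate_map_cohort,
                   simulate_timeseries_subject)


@pytest.fixture(scope="session")
def null_cohort_20():
    """20 exchangeable subjects, pure pixel noise (no template, no structure)."""
    spec = CohortSpec(n_subjects=20, peaks=[], hotspots=[], n_clusters=1,
                      noise_sd=1.0, seed=81)
    stack, clin, gt = simulate_map_cohort(spec)
    return stack, clin, gt


@pytest.fixture(scope="session")
def pd_cohort_30():
    """30 subjects around the canonical cortical template, default noise."""
    spec = CohortSpec(n_subjects=30, noise_sd=0.15, seed=82)
    stack, clin, gt = simulate_map_cohort(spec)
    return stack, clin, gt


@pytest.fixture(scope="session")
def background_recording():
    """300-s background-only recording (b=0, k=10, chi=1.5), bipolar ECoG."""
    spec = CohortSpec(n_subjects=1, aperiodic=(0.0, 10.0, 1.5), peaks=[],
                      noise_sd=0.0, seed=83)
    ecog, dbs, gt = simulate_timeseries_subject(spec, 0, duration_s=300.0, rate_hz=1375.0)
    return build_bipolar_montage(ecog, "ecog_adjacent_7")


@pytest.fixture(scope="session")
def coupled_subject():
    """180-s subject with one strongly coupled cortico-subcortical pair."""
    spec = CohortSpec(n_subjects=1, seed=84, coupling_pairs=[(3, 2, 1.0)])
    ecog, dbs, gt = simulate_timeseries_subject(spec, 0, duration_s=180.0, rate_hz=1375.0)
    return (build_bipolar_montage(ecog, "ecog_adjacent_7"),
            build_bipolar_montage(dbs, "dbs_adjacent"), gt)
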