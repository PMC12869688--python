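#!/usr/bin/env python
"""Simulate the study cohorts: a PD-like cohort of 75 subjects with hotspot
deviations coupled to clinical scores, an ET-like control cohort of 17 with
attenuated beta, and one time-series subject for the signal-level pipeline.

Writes the cohort stacks, clinical table and ground truth under results/.
"""
import json
from pathlib import Path

import numpy as np

from ssmap import CohortSpec, Hotspot, simulate_map_cohort, simulate_timeseries_subject
from ssmap.io import save_stack, write_clinical_table, write_ground_truth, write_recording

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 7

PD_SPEC = CohortSpec(
    n_subjects=75, disease="pd_like", noise_sd=0.15, seed=SEED,
    hotspots=[Hotspot(4, 6, 15, 30, sd=0.45, latent_index=0),
              Hotspot(0, 1, 8, 12, sd=0.30, latent_index=1)],
    n_clusters=3, cluster_signature_sd=0.25,
    # beta-coherent cortico-subcortical pairs (ecog bipolar, dbs bipolar, weight)
    coupling_pairs=[(4, 2, 1.2), (5, 3, 0.9)],
)
ET_SPEC = CohortSpec(n_subjects=17, disease="et_like", noise_sd=0.15, seed=SEED + 1)


def main() -> None:
    OUT.mkdir(exist_ok=True)
    pd_stack, clin, gt = simulate_map_cohort(PD_SPEC)
    et_stack, _, _ = simulate_map_cohort(ET_SPEC)
    save_stack(pd_stack, OUT / "pd_cohort.npz")
    save_stack(et_stack, OUT / "et_cohort.npz")
    write_clinical_table(clin, OUT / "pd_clinical.csv")
    write_ground_truth(gt, OUT / "pd_ground_truth.json")

    ecog, dbs, _ = simulate_timeseries_subject(PD_SPEC, 0, duration_s=180.0,
                                               rate_hz=2400.0)
    (OUT / "recordings").mkdir(exist_ok=True)
    write_recording(ecog, OUT / "recordings" / "sub000_ecog")
    write_recording(dbs, OUT / "recordings" / "sub000_dbs")

    summary = {
        "pd_subjects": pd_stack.n_subjects, "et_subjects": et_stack.n_subjects,
        "map_shape": list(pd_stack.data.shape[1:]),
        "planted_hotspots": len(PD_SPEC.hotspots),
        "planted_clusters": PD_SPEC.n_clusters,
        "updrs_total_mean": float(clin["updrs_total"].mean()),
        "coupling_pairs": [list(p) for p in PD_SPEC.coupling_pairs],
    }
    (OUT / "01_summary.json").write_text(json.dumps(summary, indent=1))
    print("simulated cohorts:", summary)


if __name__ == "__main__":
    main()
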