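#!/usr/bin/env python
"""Run the EEG cleaning chain on one simulated subject.

Band-pass filter, iterative loud-channel rejection, ICA cardiac
recovery, neighbour-correlation interpolation, common-average reference.
Writes the cleaned EDF, the ICA-ECG trace and a preprocessing report to
results/preproc/.  Requires 01_simulate_cohort.py to have run.
"""

import json
from pathlib import Path

import numpy as np

from herpipeline.core_io import Group, build_neighbor_graph, load_recording, save_json, write_edf
from herpipeline.preprocess import (
    bandpass_filter,
    extract_ica_ecg,
    interpolate_low_correlation_channels,
    reject_channels_zscore,
    rereference_and_subset,
)

COHORT = Path("results/cohort")
OUT = Path("results/preproc")


def main() -> None:
    manifest = json.loads((COHORT / "manifest.json").read_text())
    entry = manifest["subjects"][0]
    rec = load_recording(entry["eeg"], entry["events"], entry["layout"],
                         subject_id=entry["subject_id"], group=Group(entry["group"]))
    print(f"loaded {rec.subject_id}: {rec.n_channels} ch x {rec.n_samples / rec.fs:.0f} s")

    rec = bandpass_filter(rec)
    rec, rej = reject_channels_zscore(rec)
    print(f"rejected {len(rej.rejected_channels_zscore)} loud channels")
    rec, ecg, ica_rep = extract_ica_ecg(rec, seed=manifest["seed"])
    print(f"cardiac component {ica_rep.cardiac_component_index} "
          f"(kurtosis {ica_rep.parameters['kurtosis']:.1f})")
    graph = build_neighbor_graph(rec.layout)
    rec, interp = interpolate_low_correlation_channels(rec, graph)
    print(f"interpolated {len(interp.interpolated_channels)} channels")
    rec = rereference_and_subset(rec)

    OUT.mkdir(parents=True, exist_ok=True)
    write_edf(OUT / f"{rec.subject_id}_clean.edf", rec.eeg, rec.fs, rec.layout.names)
    write_edf(OUT / f"{rec.subject_id}_ica_ecg.edf", ecg[None, :], rec.fs, ["ICA-ECG"])
    save_json(
        {
            "subject_id": rec.subject_id,
            "rejected_channels": rej.rejected_channels_zscore,
            "interpolated_channels": interp.interpolated_channels,
            "cardiac_component": ica_rep.cardiac_component_index,
            "cardiac_score": ica_rep.cardiac_component_score,
            "steps": rec.preproc_log,
        },
        OUT / f"{rec.subject_id}_report.json",
    )
    print(f"wrote cleaned EDF, ICA-ECG and report under {OUT}/")


if __name__ == "__main__":
    main()
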