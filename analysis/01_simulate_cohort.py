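#!/usr/bin/env python
"""Simulate a small patient cohort and write it in interchange formats.

Produces EDF + events/layout TSV + ground-truth JSON per subject under
results/cohort/, the input for the file-based stages (02, 03).
"""

from pathlib import Path

from herpipeline.sim import SimConfig, simulate_cohort

OUT = Path("results/cohort")


def main() -> None:
    cfg = SimConfig(n_mcs=2, n_uws=2, n_control=1, n_channels=32,
                    trials_per_block=30, seed=2026)
    manifest = simulate_cohort(cfg, out_dir=OUT)
    import json

    with open(OUT / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    print(f"simulated {len(manifest['subjects'])} subjects "
          f"({cfg.n_mcs} MCS-like, {cfg.n_uws} UWS-like, {cfg.n_control} control)")
    for s in manifest["subjects"]:
        print(f"  {s['subject_id']}: {s['eeg']}")
    print(f"manifest: {OUT / 'manifest.json'}")


if __name__ == "__main__":
    main()
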