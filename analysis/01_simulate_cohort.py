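"""Simulate the synthetic SEEG cohort and export its ground truth.

Writes results/contact_table.tsv (one row per bipolar site: identity,
array geometry, Talairach position, labels) and
results/ground_truth.tsv (injected amplitudes, HF gain depth, decay and
onset latency per contact). One example recording is saved to scratch/
as HDF5 for inspection; the cohort itself is regenerated on demand by
the later drivers, so no bulk waveforms are persisted.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

from common import (COHORT_CONFIG, CONTACTS_PER_PARTICIPANT,
                    N_PARTICIPANTS, RESULTS)
from fpvs.data_model import save_recording_h5, write_contact_table
from fpvs.synth import simulate_cohort


def main():
    table, recordings, truth = simulate_cohort(
        COHORT_CONFIG, N_PARTICIPANTS, CONTACTS_PER_PARTICIPANT)
    RESULTS.mkdir(exist_ok=True)
    write_contact_table(table, RESULTS / "contact_table.tsv")
    truth_cols = ["contact_id", "participant_id", "array_id", "tal_y",
                  "region", "hemisphere", "contact_gain", "lf_face_amp",
                  "lf_base_amp", "hf_gain_depth", "spatial_decay_d",
                  "onset_latency", "ap_multiplier"]
    truth[truth_cols].to_csv(RESULTS / "ground_truth.tsv", sep="\t",
                             index=False)

    scratch = RESULTS.parent / "scratch"
    scratch.mkdir(exist_ok=True)
    example_id = table["contact_id"].iloc[0]
    save_recording_h5(recordings[example_id][0],
                      scratch / "example_recording.h5")

    n = len(table)
    print(f"cohort: {N_PARTICIPANTS} participants, {n} contacts, "
          f"{COHORT_CONFIG.n_sequences} sequences each at "
          f"{COHORT_CONFIG.fs:g} Hz")
    print(f"Talairach y range: {table.tal_y.min():.1f} to "
          f"{table.tal_y.max():.1f} mm; regions: "
          f"{table.region.value_counts().to_dict()}")
    print(f"injected face amplitude (peak contacts): "
          f"{truth.lf_face_amp.max():.2f} uV; decay "
          f"{truth.spatial_decay_d.iloc[0]:.2f}/mm; onset "
          f"{truth.onset_latency.iloc[0] * 1000:.0f} ms")
    print(f"wrote {RESULTS / 'contact_table.tsv'} and ground_truth.tsv")


if __name__ == "__main__":
    main()
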