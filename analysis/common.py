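"""Shared configuration for the analysis drivers.

One frozen synthetic cohort stands in for the patient recordings: 8
participants, 16 bipolar VOTC contacts each (two 8-contact arrays), two
48 s stimulation sequences per contact at 512 Hz. Every driver
regenerates what it needs deterministically from these seeds, so the
scripts can run independently and all outputs under results/ are
reproducible byte-for-byte.
"""

from pathlib import Path

from fpvs.data_model import StimulusProtocol
from fpvs.synth import SimulationConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"

COHORT_SEED = 7
N_PARTICIPANTS = 8
CONTACTS_PER_PARTICIPANT = 16

PROTOCOL = StimulusProtocol(sequence_duration=48.0)

COHORT_CONFIG = SimulationConfig(
    protocol=PROTOCOL,
    n_sequences=2,
    seed=COHORT_SEED,
)

QUANTIFIED_TSV = RESULTS / "quantified_contacts.tsv"


def quantified_contacts():
    """Load the per-contact quantification table, building it if the
    quantification driver has not been run yet."""
    import pandas as pd

    if QUANTIFIED_TSV.exists():
        return pd.read_csv(QUANTIFIED_TSV, sep="\t")
    from fpvs.cohort import quantify_cohort
    from fpvs.synth import simulate_cohort

    table, recordings, _ = simulate_cohort(
        COHORT_CONFIG, N_PARTICIPANTS, CONTACTS_PER_PARTICIPANT)
    df = quantify_cohort(recordings, table)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(QUANTIFIED_TSV, sep="\t", index=False)
    return df
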