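"""Core domain types for SEEG frequency-tagging analysis.

Covers the stimulation protocol, sequence recordings, depth-electrode
contact geometry, bipolar montage construction, and the anatomical
labelling rules used to assign a ventral occipito-temporal (VOTC) region
to each bipolar recording site.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

#: Center-to-center spacing between adjacent contacts on one array (mm).
CONTACT_SPACING_MM = 3.5

#: The 14 individually-defined VOTC region labels and their main-region
#: grouping (OCC / PTL / ATL / MTL).
REGION_TO_MAIN = {
    "VMO": "OCC",
    "IOG": "OCC",
    "PHG": "PTL",
    "medFG": "PTL",
    "latFG": "PTL",
    "MTG/ITG": "PTL",
    "antPHG": "ATL",
    "antCoS": "ATL",
    "antFG": "ATL",
    "antOTS": "ATL",
    "antMTG/ITG": "ATL",
    "TP": "ATL",
    "AMG": "MTL",
    "HIP": "MTL",
}

REGIONS = tuple(REGION_TO_MAIN)
MAIN_REGIONS = ("OCC", "PTL", "ATL", "MTL")
TISSUES = ("gray", "white", "MTL")
HEMISPHERES = ("L", "R")

CONTACT_TABLE_COLUMNS = [
    "contact_id", "participant_id", "array_id", "index_along_array",
    "tal_x", "tal_y", "tal_z", "tissue", "region", "hemisphere",
]


class InvalidMontageError(ValueError):
    """Raised when a bipolar montage cannot be constructed."""


@dataclass(frozen=True)
class StimulusProtocol:
    """Fast periodic visual stimulation protocol.

    Stimuli appear at ``base_rate`` Hz; every ``oddball_period``-th
    stimulus is a face, so face-selective activity is tagged at
    ``face_rate = base_rate / oddball_period`` Hz (6 / 5 = 1.2 Hz by
    default).
    """

    base_rate: float = 6.0
    oddball_period: int = 5
    sequence_duration: float = 70.0
    fade_in: float = 2.0
    fade_out: float = 2.0
    analysis_start: float = 2.0

    def __post_init__(self) -> None:
        if self.base_rate <= 0 or self.oddball_period < 1:
            raise ValueError("base_rate must be > 0 and oddball_period >= 1")
        if self.fade_in + self.fade_out >= self.sequence_duration:
            raise ValueError("fade_in + fade_out must be < sequence_duration")

    @property
    def face_rate(self) -> float:
        """Oddball (face) stimulation frequency in Hz."""
        return self.base_rate / self.oddball_period

    @property
    def usable_duration(self) -> float:
        """Seconds available for analysis (post fade-in, pre fade-out)."""
        return self.sequence_duration - self.analysis_start - self.fade_out


@dataclass
class SequenceRecording:
    """One stimulation sequence: ``data`` is channels x samples in uV.

    ``onset_sample`` marks sequence (stimulation) onset within ``data``;
    samples before it are the pre-stimulus interval used to baseline the
    high-frequency envelope.
    """

    data: np.ndarray
    fs: float
    protocol: StimulusProtocol
    channel_ids: list[str]
    onset_sample: int = 0
    montage: str = "monopolar"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.channel_ids):
            raise ValueError("channel_ids must match data rows")
        if self.fs <= 2 * 160:
            raise ValueError("sampling rate must exceed twice the highest "
                             "analysis frequency (160 Hz)")
        n_stim = self.data.shape[1] - self.onset_sample
        expected = self.protocol.sequence_duration * self.fs
        if n_stim < expected - 1:
            raise ValueError(
                f"recording holds {n_stim} post-onset samples; protocol "
                f"requires ~{expected:.0f}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to sequence onset."""
        return (np.arange(self.data.shape[1]) - self.onset_sample) / self.fs


@dataclass(frozen=True)
class ContactRecord:
    """One recording site on a depth-electrode array."""

    contact_id: str
    participant_id: str
    array_id: str
    index_along_array: int
    tal_xyz: tuple[float, float, float]
    tissue: str
    region: str
    hemisphere: str

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if self.region not in REGIONS and self.region != "excluded":
            raise ValueError(f"unknown region {self.region!r}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {self.hemisphere!r}")

    @property
    def position_mm(self) -> float:
        """Distance along the array from the medial/deep end (mm)."""
        return self.index_along_array * CONTACT_SPACING_MM


@dataclass
class ElectrodeArray:
    """An ordered depth-electrode array; index 0 is the medial/deep end."""

    array_id: str
    contacts: list[ContactRecord]
    medial_to_lateral: bool = True

    def __post_init__(self) -> None:
        if not 2 <= len(self.contacts):
            raise InvalidMontageError(
                f"array {self.array_id}: need >= 2 contacts for a bipolar "
                "montage")

    @property
    def n_bipolar(self) -> int:
        return len(self.contacts) - 1

    @property
    def positions_mm(self) -> np.ndarray:
        return np.array([c.position_mm for c in self.contacts])


def bipolar_rereference(recording: SequenceRecording,
                        array: ElectrodeArray) -> SequenceRecording:
    """Re-reference an array recording to a bipolar montage.

    Bipolar channel ``i`` is contact ``i+1`` (more lateral, "active")
    minus contact ``i`` (its directly adjacent, more medial neighbour);
    one channel fewer than the monopolar recording. Pairs spanning a gap
    in ``index_along_array`` (missing/rejected contacts) are skipped.
    The bipolar site inherits the identity of the active contact.
    """
    if recording.montage != "monopolar":
        raise InvalidMontageError("recording is already re-referenced")
    if recording.n_channels != len(array.contacts):
        raise InvalidMontageError(
            f"recording has {recording.n_channels} channels but array "
            f"{array.array_id} has {len(array.contacts)} contacts")
    if len(array.contacts) < 2:
        raise InvalidMontageError("need at least 2 contacts")

    rows, ids, skipped = [], [], []
    for i in range(len(array.contacts) - 1):
        lo, hi = array.contacts[i], array.contacts[i + 1]
        if hi.index_along_array != lo.index_along_array + 1:
            skipped.append((lo.contact_id, hi.contact_id))
            continue
        rows.append(recording.data[i + 1] - recording.data[i])
        ids.append(hi.contact_id)
    if not rows:
        raise InvalidMontageError(
            f"array {array.array_id}: no adjacent contact pairs")
    out = SequenceRecording(
        data=np.vstack(rows), fs=recording.fs, protocol=recording.protocol,
        channel_ids=ids, onset_sample=recording.onset_sample,
        montage="bipolar")
    out.skipped_pairs = skipped
    return out


def assign_contact_label(active_tissue: str, active_region: str,
                         reference_tissue: str,
                         reference_region: str) -> str:
    """Anatomical label of a bipolar site.

    A gray-matter (or medial-temporal) active contact keeps its own
    region; a white-matter active contact borrows the label of its
    gray-matter reference contact; white/white pairs are excluded.
    """
    for t in (active_tissue, reference_tissue):
        if t not in TISSUES:
            raise ValueError(f"unknown tissue {t!r}")
    # MTL structures (amygdala/hippocampus) count as gray for inclusion.
    active_gray = active_tissue in ("gray", "MTL")
    reference_gray = reference_tissue in ("gray", "MTL")
    if active_gray:
        return active_region
    if reference_gray:
        return reference_region
    return "excluded"


def region_of(region_label: str) -> str:
    """Main VOTC region (OCC/PTL/ATL/MTL) of an individual region label."""
    try:
        return REGION_TO_MAIN[region_label]
    except KeyError:
        raise ValueError(f"unknown region label {region_label!r}") from None


def contacts_to_frame(contacts: Sequence[ContactRecord]) -> pd.DataFrame:
    """Tabulate ContactRecords into the standard contact-table layout."""
    return pd.DataFrame(
        [{
            "contact_id": c.contact_id,
            "participant_id": c.participant_id,
            "array_id": c.array_id,
            "index_along_array": c.index_along_array,
            "tal_x": c.tal_xyz[0],
            "tal_y": c.tal_xyz[1],
            "tal_z": c.tal_xyz[2],
            "tissue": c.tissue,
            "region": c.region,
            "hemisphere": c.hemisphere,
        } for c in contacts],
        columns=CONTACT_TABLE_COLUMNS,
    )


def save_recording_h5(recording: SequenceRecording, path) -> None:
    """Persist a recording to HDF5 (/data, /fs, /channel_ids + attrs)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data.astype(np.float32))
        f.create_dataset("fs", data=float(recording.fs))
        f.create_dataset(
            "channel_ids",
            data=np.array(recording.channel_ids, dtype=h5py.string_dtype()))
        f.attrs["onset_sample"] = recording.onset_sample
        f.attrs["montage"] = recording.montage
        for k, v in dataclasses.asdict(recording.protocol).items():
            f.attrs[f"protocol_{k}"] = v


def load_recording_h5(path) -> SequenceRecording:
    import h5py

    with h5py.File(path, "r") as f:
        proto = StimulusProtocol(**{
            k[len("protocol_"):]: v for k, v in f.attrs.items()
            if k.startswith("protocol_")})
        return SequenceRecording(
            data=f["data"][()].astype(float),
            fs=float(f["fs"][()]),
            protocol=proto,
            channel_ids=[s.decode() if isinstance(s, bytes) else str(s)
                         for s in f["channel_ids"][()]],
            onset_sample=int(f.attrs["onset_sample"]),
            montage=str(f.attrs["montage"]),
        )


def load_recording_edf(path, protocol: StimulusProtocol | None = None,
                       onset_sample: int = 0) -> SequenceRecording:
    """Load a raw EDF export as a monopolar SequenceRecording.

    Thin convenience wrapper (requires the optional ``mne`` dependency);
    channel selection and sequence segmentation are the caller's job.
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return SequenceRecording(
        data=raw.get_data() * 1e6,  # volts -> microvolts
        fs=float(raw.info["sfreq"]),
        protocol=protocol or StimulusProtocol(),
        channel_ids=list(raw.ch_names),
        onset_sample=onset_sample,
    )


def read_contact_table(path) -> pd.DataFrame:
    """Read a cohort contact table (TSV, one row per bipolar site)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(CONTACT_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"contact table missing columns: {sorted(missing)}")
    return df


def write_contact_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
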