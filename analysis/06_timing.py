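"""Onset-latency analysis of the face-selective response.

Builds synthetic broadband-envelope series with a known 90 ms response
onset per face (rectangular 1/3 s gain bursts, transparent to the
base-rate notch), runs the timing pipeline (notch, face-locked 1.17 s
epoching with the 41 ms contrast shift, baseline correction, 2.58-SD /
30 ms onset detection) per contact and at the group level with the
nested bootstrap, and reports recovery of the injected latency.
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))

from common import RESULTS
from fpvs.data_model import StimulusProtocol
from fpvs.timing import (contact_onset, face_epoch_average, fft_notch,
                         group_latency)

FS_ENV = 512.0 / 6
ONSET_TRUE = 0.090
SHIFT = 0.041


def burst_envelope(rng=None, noise_sd=0.0):
    proto = StimulusProtocol()
    n = int(round(74.0 * FS_ENV))
    t = np.arange(n) / FS_ENV - 2.0
    env = np.zeros(n)
    for t_f in np.arange(0.0, proto.sequence_duration, 1 / proto.face_rate):
        on = t_f + ONSET_TRUE
        env[(t >= on) & (t < on + 1.0 / 3.0)] = 1.0
    if noise_sd:
        env = env + rng.normal(0, noise_sd, n)
    return fft_notch(env, FS_ENV), proto


def main():
    RESULTS.mkdir(exist_ok=True)
    # noise-free per-contact recovery
    env, proto = burst_envelope()
    ep = face_epoch_average(env, FS_ENV, proto,
                            onset_sample=int(round(2.0 * FS_ENV)),
                            signal_class="HF")
    onset = contact_onset(ep)
    clean_ms = (onset + SHIFT) * 1000
    print(f"noise-free contact onset: {clean_ms:.1f} ms "
          f"(injected {ONSET_TRUE * 1000:.0f} ms, envelope sample "
          f"{1000 / FS_ENV:.1f} ms)")

    # noisy group latency with nested bootstrap
    rng = np.random.default_rng(17)
    eps = []
    onsets = []
    for _ in range(12):
        env, proto = burst_envelope(rng, noise_sd=0.5)
        e = face_epoch_average(env, FS_ENV, proto,
                               onset_sample=int(round(2.0 * FS_ENV)),
                               signal_class="HF")
        eps.append(e)
        o = contact_onset(e)
        if o is not None:
            onsets.append((o + SHIFT) * 1000)
    group = group_latency(eps, signal_class="HF", B_outer=500,
                          B_inner=200, seed=3)
    g_on = (group.onset + SHIFT) * 1000
    g_off = (group.offset + SHIFT) * 1000
    ci = [(v + SHIFT) * 1000 for v in group.onset_ci]
    print(f"per-contact onsets (noisy): median "
          f"{np.median(onsets):.1f} ms over {len(onsets)} contacts")
    print(f"group onset {g_on:.1f} ms, 95% CI [{ci[0]:.1f}, "
          f"{ci[1]:.1f}] ms; offset {g_off:.1f} ms")

    out = {
        "injected_onset_ms": ONSET_TRUE * 1000,
        "noise_free_contact_onset_ms": round(clean_ms, 1),
        "group_onset_ms": round(g_on, 1),
        "group_onset_ci95_ms": [round(c, 1) for c in ci],
        "group_offset_ms": round(g_off, 1),
        "n_contacts": len(eps),
    }
    (RESULTS / "timing.json").write_text(json.dumps(out, indent=2) + "\n")


if __name__ == "__main__":
    main()
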