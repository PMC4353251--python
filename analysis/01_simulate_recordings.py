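"""Generate one synthetic subject's dual-session recordings and summarize.

Produces two annotated sessions (the second with a fresh electrode
perturbation, i.e. a "replaced" subject), writes a 1 s excerpt of the raw
traces and the annotation tables under results/, and prints per-channel RMS
so the workload manipulation is visible in the raw signals.
"""

from pathlib import Path

import numpy as np

from pbci import synthgen

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

SEED = 7
TRIAL_S = 120

low, high = synthgen.default_workload_profiles()
pert1 = synthgen.replacement_perturbation(0.5, seed=SEED)
pert2 = synthgen.replacement_perturbation(0.5, seed=SEED + 1)

s1 = synthgen.generate_session(low, high, ("low", "high"), TRIAL_S, SEED, pert1, "S1")
s2 = synthgen.generate_session(low, high, ("high", "low"), TRIAL_S, SEED + 2, pert2, "S2")

excerpt = synthgen.Recording(
    sample_rate=s1.sample_rate,
    channels=s1.channels,
    samples=np.round(s1.samples[:, : 1 * 200], 3),
)
synthgen.write_recording_csv(excerpt, OUT / "example_recording_excerpt.csv")
synthgen.write_recording_csv(s1, "/dev/null", OUT / "example_s1_annotations.csv")
synthgen.write_recording_csv(s2, "/dev/null", OUT / "example_s2_annotations.csv")

print(f"sessions generated: 2 x {TRIAL_S} s trials at 200 Hz, 8 channels")
for rec, name in ((s1, "S1"), (s2, "S2")):
    for (sl, workload, _) in rec.trial_slices():
        rms = {ch: float(np.sqrt(np.mean(sl[i] ** 2))) for i, ch in enumerate(rec.channels)}
        line = ", ".join(f"{ch}={v:.1f}" for ch, v in rms.items())
        print(f"{name} {workload:>4} trial RMS (uV): {line}")
print(f"excerpt + annotations written under {OUT}")
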