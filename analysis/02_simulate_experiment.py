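"""Simulate the multi-day two-protocol imaging experiment to disk.

Generates 5 daily sessions of one synthetic focal plane (40 neurons,
16 stimuli x 10 trials, 3 frames/s) in which pure tones remap twice as
often as complex sounds (probability 0.2 vs 0.1 per day) — the drift
asymmetry the downstream analysis should recover — and writes the HDF5
sessions, WAV stimuli, and ground-truth JSON under scratch/experiment/.
"""

import json
from pathlib import Path

from caldrift import SynthConfig, make_experiment, make_stimulus_set
from caldrift.session_io import write_session, write_stimuli_wav
from caldrift.synth import CXS, PT

SCRATCH = Path(__file__).resolve().parents[1] / "scratch" / "experiment"
SEED = 1


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    cfg = SynthConfig(
        n_neurons=40, n_days=5, tuning_drift_prob={PT: 0.2, CXS: 0.1}, seed=SEED
    )
    stimuli = make_stimulus_set(seed=SEED)
    sessions, truth = make_experiment(cfg, stimuli)

    write_stimuli_wav(SCRATCH / "stimuli", stimuli)
    for s in sessions:
        write_session(SCRATCH / f"session_day{s.day_index}.h5", s)
    (SCRATCH / "ground_truth.json").write_text(truth.to_json())
    (SCRATCH / "stimulus_classes.json").write_text(json.dumps(stimuli.sound_class))
    (SCRATCH / "synth_config.json").write_text(cfg.to_json())

    n_resp = int(truth.responsive_mask[0].sum())
    print(f"wrote {len(sessions)} sessions to {SCRATCH}")
    print(f"{cfg.n_neurons} neurons; {n_resp} responsive (neuron, stimulus) pairs on day 1")
    print(f"remap probability per day: PT {cfg._drift_probs()[PT]}, CxS {cfg._drift_probs()[CXS]}")


if __name__ == "__main__":
    main()
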