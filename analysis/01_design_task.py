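"""Build the task: chord set, sequence pool, configuration, session design.

Enumerates the 13 usable chords, exhaustively generates the valid 5-chord
sequences (distinct chords, Hamming distance 3 per transition), partitions
them into 3 trained + 6 untrained sequences with no shared transition, and
schedules one 160-trial scanner session. Writes:

    results/design/configuration.json
    results/design/session0_events.tsv
"""

from pathlib import Path

import numpy as np

from chordlearn import task_design as td

OUT = Path(__file__).resolve().parents[1] / "results" / "design"
OUT.mkdir(parents=True, exist_ok=True)

chords = td.enumerate_chords()
print(f"usable chords: {len(chords)}")

pool = td.generate_sequences(chords)
dists = {td.hamming_distance(a, b) for s in pool for a, b in s.transitions}
print(f"valid sequences: {len(pool)} (transition distances: {sorted(dists)})")

config = td.partition_configurations(pool, seed=20)
shared_chords, finger_l1 = td.partition_objective(
    config.trained, config.untrained
)
print(
    f"configuration A: {len(config.trained)} trained / "
    f"{len(config.untrained)} untrained, "
    f"{shared_chords} shared chords, finger-frequency L1 {finger_l1:.3f}"
)
(OUT / "configuration.json").write_text(
    '{\n "trained": [%s],\n "untrained": [%s]\n}\n'
    % (
        ", ".join(f'"{s}"' for s in config.trained),
        ", ".join(f'"{s}"' for s in config.untrained),
    )
)

design = td.build_session_design(config, seed=20, session=0)
ev = design.to_events_frame()
ev.to_csv(OUT / "session0_events.tsv", sep="\t", index=False)
itis = np.array([t.iti for t in design.trials])
print(
    f"session design: {design.n_trials} trials over {design.runs} runs, "
    f"prescribed MT {design.prescribed_mt:.1f} s, "
    f"ITI mean {itis.mean():.2f} s in [{itis.min():.2f}, {itis.max():.2f}]"
)
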