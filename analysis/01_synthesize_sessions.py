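#!/usr/bin/env python
"""Generate the synthetic before/after sessions used by the later analyses.

Builds a matched pair of sessions per "animal": a pre-treatment session and
a post-treatment session in which every unit's nonlinearity slope is scaled
down (emulating a response-gain reduction), saves them as HDF5, and prints a
summary table.  Outputs: results/sessions/*.h5, results/session_manifest.csv.
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), ".."))

from lnkit.session import save_session
from lnkit.synth import make_session

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
GAIN_SCALE_POST = 0.6  # 40% gain reduction after "treatment"


def main() -> None:
    os.makedirs(os.path.join(OUT, "sessions"), exist_ok=True)
    rows = []
    for animal_seed in (1, 2):
        for phase, gain_scale in (("pre", 1.0), ("post", GAIN_SCALE_POST)):
            session = make_session(
                seed=animal_seed,
                noise_duration_s=300.0,
                treatment="ciproxifan",
                phase=phase,
                gain_scale=gain_scale,
            )
            path = os.path.join(
                OUT, "sessions", f"animal{animal_seed}_{phase}.h5"
            )
            save_session(session, path)
            rows.append(
                {
                    "animal": session.animal_id,
                    "phase": phase,
                    "gain_scale": gain_scale,
                    "n_units": len(session.units),
                    "n_stimuli": len(session.stimuli),
                    "total_spikes": sum(u.n_spikes for u in session.units),
                    "path": os.path.relpath(path, OUT),
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(OUT, "session_manifest.csv"), index=False)
    print(manifest.to_string(index=False))
    print(
        f"\nWrote {len(rows)} sessions; post-treatment sessions have all "
        f"unit gains scaled by {GAIN_SCALE_POST}."
    )


if __name__ == "__main__":
    main()
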