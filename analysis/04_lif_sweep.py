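#!/usr/bin/env python
"""Run the 49-cell (baseline, gain) sweep of the integrate-and-fire model.

Simulates the model neuron over a one-million-frame Gaussian noise stimulus
for every combination of baseline B in {-0.45..0.45, step 0.15} and gain
G = 1.2**g, g in {-3..3}, re-estimates the LN cascade from each cell's
spikes, and summarizes how spike count, peak latency, peak frequency and
nonlinearity slope depend on the two intrinsic parameters.
Outputs: results/lif_sweep.csv, results/lif_sweep_trends.csv.
"""

import os
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), ".."))

from lnkit.lif import ModelParams, run_sweep

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    df = run_sweep(ModelParams(seed=7, stim_len=1_000_000))
    df.to_csv(os.path.join(OUT, "lif_sweep.csv"), index=False)

    counts = df.pivot(index="B", columns="g", values="spike_count")
    lat = df.pivot(index="B", columns="g", values="latency_bins")
    freq = df.pivot(index="B", columns="g", values="freq_hz")
    slope = df.pivot(index="B", columns="g", values="nl_slope")

    print("Spike counts (rows: baseline B, cols: gain exponent g):")
    print(counts.to_string())
    print("\nEstimated peak latency (bins):")
    print(lat.round(2).to_string())
    print("\nEstimated peak frequency (Hz):")
    print(freq.round(3).to_string())
    print("\nHalf-wave nonlinearity slope:")
    print(slope.round(1).to_string())

    trends = pd.DataFrame(
        [
            {
                "trend": "spike_count_rows_monotone_in_gain",
                "value": int(np.sum(np.all(np.diff(counts.values, 1) >= 0, 1))),
            },
            {
                "trend": "latency_shortening_bins_B0_gmax_vs_gmin",
                "value": float(lat.loc[0.0].iloc[0] - lat.loc[0.0].iloc[-1]),
            },
            {
                "trend": "freq_range_across_B_at_median_G_hz",
                "value": float(freq[0].max() - freq[0].min()),
            },
            {
                "trend": "freq_range_across_G_at_B0_hz",
                "value": float(freq.loc[0.0].max() - freq.loc[0.0].min()),
            },
            {
                "trend": "nl_slope_ratio_B0_gmax_vs_gmin",
                "value": float(slope.loc[0.0].iloc[-1] / slope.loc[0.0].iloc[0]),
            },
        ]
    )
    trends.to_csv(os.path.join(OUT, "lif_sweep_trends.csv"), index=False)
    print("\n" + trends.to_string(index=False))
    print(
        "\nHigher gain or baseline -> more spikes and slightly shorter "
        "apparent latency; the apparent peak frequency moves more with the "
        "resting baseline than with the gain, and the estimated nonlinearity "
        "slope tracks the intrinsic gain."
    )


if __name__ == "__main__":
    main()
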