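"""Time below pH thresholds for a film midway to dysbiosis (50 % aciduric).

Sweeps the clearance half-time and reports, for each pH threshold between the
enamel (5.5) and dentin (6.2) critical values, how long one pulse keeps the
tooth surface below it.  The durations run roughly 5-10x the clearance
half-time, growing sub-linearly with t1/2 because slower clearance also means
a lower pulse peak at fixed dose.
"""

import plaquesim as pq

params = pq.default_params()
df = pq.threshold_sweep(
    params, t_half_list=(2.0, 3.0, 4.0, 5.0, 6.0), thresholds=(5.5, 5.8, 6.0, 6.2)
)
print(df.round(2).to_string(index=False))
ratios = df["time_below_6.2"] / df["t_half"]
print(
    f"\ntime below 6.2 is {ratios.min():.1f}-{ratios.max():.1f}x the clearance"
    " half-time across this range"
)
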