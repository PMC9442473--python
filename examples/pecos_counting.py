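"""Peak-counting spectroscopy for a protein too dim for FCS.

A long point recording of a sub-nanomolar emitter is split into 60-s
intervals; fluorescence bursts above a robust data-derived threshold are
counted as a concentration proxy.  A simulated bright-object transit
shows the rejection rule.
"""

from centrikit.pecos import count_peaks, reject_transit, split_intervals
from centrikit.synth import EmitterSpecies, TraceSimConfig, TransitEvent, simulate_trace
from centrikit.volume import DEFAULT_VOLUME

species = EmitterSpecies(d_coef=2.5, conc=0.1, epsilon=1e5)  # ~0.1 nM: FCS-dark regime
cfg = TraceSimConfig(
    duration=180.0, species=[species], volume=DEFAULT_VOLUME, box_factor=8.0,
    dt_sim=1e-3, bin_width=1e-3, background_rate=5e3, seed=7,
    transit_events=[TransitEvent(start=130.0, duration=2.0, brightness=5e5)],
)
trace = simulate_trace(cfg)
print(f"simulated {trace.duration:.0f}-s recording at 0.1 nM "
      f"(mean rate {trace.mean_rate:,.0f} counts/s)\n")

for i, interval in enumerate(split_intervals(trace, 60.0)):
    if reject_transit(interval):
        print(f"interval {i}: REJECTED (sustained intensity rise: object in the spot)")
        continue
    res = count_peaks(interval, smoothing=2e-3, k_sigma=4.0, interval_index=i)
    print(f"interval {i}: {res.peak_count} bursts (threshold {res.threshold:.1f} counts/bin)")

print("\nburst counts scale ~linearly with emitter concentration, so they serve as")
print("a relative concentration readout where the correlation amplitude is noise.")
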