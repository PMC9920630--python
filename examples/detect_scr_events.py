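"""Detect skin-conductance responses in one synthetic trace.

Builds a 2-minute high-arousal segment, conditions it (ohms → µS, 2 Hz,
median filter), splits tonic from phasic, and lists the detected events:
sustained phasic slopes of at least 0.01 µS/s lasting at least 3 s,
rising ones reported as peaks and falling ones as offsets.
"""

import edaffect as ea

profile = ea.default_profiles()[ea.QuadrantLabel.HAPPY]
session, truth = ea.generate_segment(profile, duration=120.0, rate=8.0, seed=42)

eda = ea.preprocess(session)  # 2 Hz, microsiemens, median-filtered
decomposition = ea.decompose(eda, tonic_window=10.0)
events = ea.detect_events(decomposition, ea.DetectionParams(slope_threshold=0.01, min_duration=3.0))

print(f"injected SCR onsets (ground truth): {[f'{e.onset_s:.1f}s' for e in truth]}")
print(f"detected events: {len(events)}")
for e in events:
    print(
        f"  {e.kind.value:<6} {e.start_s(eda.rate):6.1f}-{e.end_s(eda.rate):6.1f} s"
        f"  duration {e.duration:4.1f} s  amplitude {e.amplitude:.3f} µS"
    )
print("Each injected response appears as a PEAK (its rise) usually followed by an OFFSET (its decay).")
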