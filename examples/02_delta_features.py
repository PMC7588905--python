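"""Compute bounding-box delta features and classify each second.

Reads the stream written by 01_simulate_stream.py, applies the default
filter policy (overall score >= 0.5, gaps > 2 s not bridged) and prints
the per-second change metrics around the stand->walk boundary.
"""

from collections import Counter
from pathlib import Path

from posedelta import FilterPolicy, compute_deltas, label_dominant, read_stream

frames = read_stream(Path("example_output") / "stream.ndjson")
records = compute_deltas(frames, FilterPolicy())

print(f"{len(frames)} frames -> {len(records)} delta records\n")
print("t    dHeight dWidth dDistance dominant")
for rec in records:
    if 118 <= rec.timestamp <= 124:
        label = label_dominant(rec)
        print(
            f"{rec.timestamp:<5}{rec.d_height:7.2f}{rec.d_width:7.2f}"
            f"{rec.d_distance:10.2f} {label.value if label else '-'}"
        )

counts = Counter(
    label_dominant(r).value if label_dominant(r) else "none" for r in records
)
print("\ndominant-channel counts over the whole run:", dict(counts))
# Around t=120 the walk starts: dDistance jumps to ~30 px/s (the walking
# speed) and the dominant parameter flips to positional_change, while the
# noisy standing seconds before it show only small jitter deltas.
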