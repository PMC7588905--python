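"""Simulate a 10-minute monitored scene and store it as NDJSON.

A scripted person stands, walks and sits in a 320x240 px room; one pose
frame per second is emitted with 2 px coordinate noise, plus a minute of
absence that produces no frames at all.
"""

from pathlib import Path

from posedelta import ActivitySegment, SimConfig, simulate, write_stream
from posedelta.simulator import write_labels_csv

out_dir = Path("example_output")
out_dir.mkdir(exist_ok=True)

config = SimConfig(
    schedule=(
        ActivitySegment(start=0, end=120, activity="stand"),
        ActivitySegment(start=120, end=300, activity="walk", params={"speed": 30}),
        ActivitySegment(start=300, end=360, activity="absent"),
        ActivitySegment(start=360, end=600, activity="sit"),
    ),
    noise_sd=2.0,
    seed=1,
)
result = simulate(config)
write_stream(result.frames, out_dir / "stream.ndjson")
write_labels_csv(result.labels, out_dir / "labels.csv")

print(f"scheduled seconds : {len(result.labels)}")
print(f"emitted frames    : {len(result.frames)}")
print(f"first frame score : {result.frames[0].score:.3f}")
# 600 seconds were scheduled but only 540 frames exist: the absent minute
# stores nothing, exactly as a deployment that never uploads empty data.
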