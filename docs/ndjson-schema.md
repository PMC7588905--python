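# Pose-stream NDJSON schema

A pose stream is a UTF-8 text file with one JSON object per line, one line
per captured second, in strictly increasing timestamp order.

```json
{
  "timestamp": 1598832000,
  "score": 0.93,
  "persons": 1,
  "keypoints": [
    {"part": "nose", "position": {"x": 161.2, "y": 104.7}, "score": 0.98},
    ...
  ]
}
```

Fields:

| field | type | constraints |
|---|---|---|
| `timestamp` | integer | seconds; strictly increasing across lines; sub-second values are rejected, not rounded (capture runs on a 1 s grid) |
| `score` | number | overall pose confidence in [0, 1] |
| `persons` | integer | count of detected people, >= 0; the frame always carries the single estimated pose, so `persons: 2` marks a visitor while keypoints stay the subject's |
| `keypoints` | array | exactly 17 entries when `persons >= 1`, empty when `persons = 0`; no duplicate parts |
| `keypoints[].part` | string | one of the 17 names below |
| `keypoints[].position.x/.y` | number | pixels, image convention: origin top-left, x rightward, y downward, 0-based continuous |
| `keypoints[].score` | number | per-keypoint confidence in [0, 1] |

Keypoint vocabulary (order is conventional, not required):

```
nose leftEye rightEye leftEar rightEar
leftShoulder rightShoulder leftElbow rightElbow leftWrist rightWrist
leftHip rightHip leftKnee rightKnee leftAnkle rightAnkle
```

Frames with `persons = 0` are valid in memory but a monitoring deployment
never stores them (seconds with nobody visible produce no line at all);
`posedelta.write_stream` will serialize whatever frames it is given, and
`read_stream` validates every line with positional error context.

## Reference extent CSV

The evaluation harness reads reference (and predicted) box extents as CSV
with the header

```
image_id,x_min,x_max,y_min,y_max
```

or as a JSON list of `{"image_id": ..., "keypoints": [{"x": ..., "y": ...}, ...]}`
records, whose extents are computed as the min/max over the keypoints.

## Ground-truth labels CSV

`posedelta simulate --labels` writes one row per scheduled second:

```
second,activity,persons
```

with `activity` one of `stand sit walk lie hand_activity absent visitor`
(absent seconds have `persons = 0` and no corresponding stream line).
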