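{
  "description": "Built-in 30 s target-path waypoints (time_s, percent of calibrated aROM). Spans the centered 90% band [5, 95], reaching below 10 and above 90 at least once. Stand-in shape for the game's fixed star path; replace with the deployed game's coordinates when available.",
  "waypoints": [
    [0.0, 50.0],
    [2.0, 72.0],
    [4.0, 92.0],
    [6.5, 65.0],
    [8.5, 35.0],
    [10.5, 8.0],
    [13.0, 30.0],
    [15.5, 60.0],
    [18.0, 92.0],
    [20.5, 70.0],
    [22.5, 40.0],
    [24.5, 12.0],
    [26.5, 8.0],
    [28.0, 30.0],
    [30.0, 50.0]
  ]
}
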