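{
  "extremity": "LE",
  "description": "Lower-extremity channel table: per-channel proximal/distal sensor pair, measurement plane ('xy' sagittal inclination, 'zy' frontal/rotational inclination), and steering sign (+1 = movement that steers the avatar upward is positive). Joint-unit grouping drives involuntary-score aggregation.",
  "sensors": [
    "trunk",
    "thigh_upper_L", "thigh_lower_L", "shank_upper_L", "shank_lower_L", "foot_L",
    "thigh_upper_R", "thigh_lower_R", "shank_upper_R", "shank_lower_R", "foot_R"
  ],
  "channels": {
    "trunk_ventral":  {"proximal": null,            "distal": "trunk",         "plane": "xy", "sign": 1.0},
    "trunk_lateral":  {"proximal": null,            "distal": "trunk",         "plane": "zy", "sign": 1.0},
    "hip_flexion_L":  {"proximal": "trunk",         "distal": "thigh_upper_L", "plane": "xy", "sign": 1.0},
    "hip_rotation_L": {"proximal": "thigh_upper_L", "distal": "thigh_lower_L", "plane": "zy", "sign": 1.0},
    "knee_L":         {"proximal": "thigh_lower_L", "distal": "shank_upper_L", "plane": "xy", "sign": 1.0},
    "ankle_L":        {"proximal": "shank_lower_L", "distal": "foot_L",        "plane": "xy", "sign": 1.0},
    "hip_flexion_R":  {"proximal": "trunk",         "distal": "thigh_upper_R", "plane": "xy", "sign": 1.0},
    "hip_rotation_R": {"proximal": "thigh_upper_R", "distal": "thigh_lower_R", "plane": "zy", "sign": 1.0},
    "knee_R":         {"proximal": "thigh_lower_R", "distal": "shank_upper_R", "plane": "xy", "sign": 1.0},
    "ankle_R":        {"proximal": "shank_lower_R", "distal": "foot_R",        "plane": "xy", "sign": 1.0}
  },
  "units": {
    "trunk":   ["trunk_lateral", "trunk_ventral"],
    "hip_L":   ["hip_flexion_L", "hip_rotation_L"],
    "hip_R":   ["hip_flexion_R", "hip_rotation_R"],
    "knee_L":  ["knee_L"],
    "knee_R":  ["knee_R"],
    "ankle_L": ["ankle_L"],
    "ankle_R": ["ankle_R"]
  },
  "targets": ["hip_flexion_L", "hip_flexion_R", "knee_L", "knee_R", "ankle_L", "ankle_R"],
  "caps_deg": {"hip_flexion": 45.0, "hip_rotation": null, "knee": 90.0, "ankle": 90.0},
  "orientation_chain": {
    "trunk":         {"xy": ["trunk_ventral"], "zy": ["trunk_lateral"]},
    "thigh_upper_L": {"xy": ["trunk_ventral", "hip_flexion_L"], "zy": ["trunk_lateral"]},
    "thigh_lower_L": {"xy": ["trunk_ventral", "hip_flexion_L"], "zy": ["trunk_lateral", "hip_rotation_L"]},
    "shank_upper_L": {"xy": ["trunk_ventral", "hip_flexion_L", "knee_L"], "zy": ["trunk_lateral", "hip_rotation_L"]},
    "shank_lower_L": {"xy": ["trunk_ventral", "hip_flexion_L", "knee_L"], "zy": ["trunk_lateral", "hip_rotation_L"]},
    "foot_L":        {"xy": ["trunk_ventral", "hip_flexion_L", "knee_L", "ankle_L"], "zy": ["trunk_lateral", "hip_rotation_L"]},
    "thigh_upper_R": {"xy": ["trunk_ventral", "hip_flexion_R"], "zy": ["trunk_lateral"]},
    "thigh_lower_R": {"xy": ["trunk_ventral", "hip_flexion_R"], "zy": ["trunk_lateral", "hip_rotation_R"]},
    "shank_upper_R": {"xy": ["trunk_ventral", "hip_flexion_R", "knee_R"], "zy": ["trunk_lateral", "hip_rotation_R"]},
    "shank_lower_R": {"xy": ["trunk_ventral", "hip_flexion_R", "knee_R"], "zy": ["trunk_lateral", "hip_rotation_R"]},
    "foot_R":        {"xy": ["trunk_ventral", "hip_flexion_R", "knee_R", "ankle_R"], "zy": ["trunk_lateral", "hip_rotation_R"]}
  }
}
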