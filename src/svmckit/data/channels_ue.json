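{
  "extremity": "UE",
  "description": "Upper-extremity channel table. Shoulder abduction/adduction and forearm pro/supination are measured in the 'zy' plane, elbow/wrist/finger flexion-extension in the sagittal 'xy' plane. Default upward-steering directions: abduction, elbow flexion, supination, wrist extension, finger extension (sign +1); edit per deployment if the game maps differently.",
  "sensors": [
    "trunk",
    "upperarm_L", "forearm_upper_L", "forearm_lower_L", "hand_L", "fingers_L",
    "upperarm_R", "forearm_upper_R", "forearm_lower_R", "hand_R", "fingers_R"
  ],
  "channels": {
    "trunk_ventral":     {"proximal": null,              "distal": "trunk",           "plane": "xy", "sign": 1.0},
    "trunk_lateral":     {"proximal": null,              "distal": "trunk",           "plane": "zy", "sign": 1.0},
    "shoulder_abd_L":    {"proximal": "trunk",           "distal": "upperarm_L",      "plane": "zy", "sign": 1.0},
    "elbow_L":           {"proximal": "upperarm_L",      "distal": "forearm_upper_L", "plane": "xy", "sign": 1.0},
    "forearm_prosup_L":  {"proximal": "forearm_upper_L", "distal": "forearm_lower_L", "plane": "zy", "sign": 1.0},
    "wrist_L":           {"proximal": "forearm_lower_L", "distal": "hand_L",          "plane": "xy", "sign": 1.0},
    "fingers_L":         {"proximal": "hand_L",          "distal": "fingers_L",       "plane": "xy", "sign": 1.0},
    "shoulder_abd_R":    {"proximal": "trunk",           "distal": "upperarm_R",      "plane": "zy", "sign": 1.0},
    "elbow_R":           {"proximal": "upperarm_R",      "distal": "forearm_upper_R", "plane": "xy", "sign": 1.0},
    "forearm_prosup_R":  {"proximal": "forearm_upper_R", "distal": "forearm_lower_R", "plane": "zy", "sign": 1.0},
    "wrist_R":           {"proximal": "forearm_lower_R", "distal": "hand_R",          "plane": "xy", "sign": 1.0},
    "fingers_R":         {"proximal": "hand_R",          "distal": "fingers_R",       "plane": "xy", "sign": 1.0}
  },
  "units": {
    "trunk":      ["trunk_lateral", "trunk_ventral"],
    "shoulder_L": ["shoulder_abd_L"],
    "shoulder_R": ["shoulder_abd_R"],
    "elbow_L":    ["elbow_L"],
    "elbow_R":    ["elbow_R"],
    "forearm_L":  ["forearm_prosup_L"],
    "forearm_R":  ["forearm_prosup_R"],
    "wrist_L":    ["wrist_L"],
    "wrist_R":    ["wrist_R"],
    "fingers_L":  ["fingers_L"],
    "fingers_R":  ["fingers_R"]
  },
  "targets": [
    "shoulder_abd_L", "shoulder_abd_R", "elbow_L", "elbow_R",
    "forearm_prosup_L", "forearm_prosup_R", "wrist_L", "wrist_R",
    "fingers_L", "fingers_R"
  ],
  "caps_deg": {"shoulder_abd": 70.0, "elbow": 110.0, "forearm_prosup": 135.0, "wrist": 135.0, "fingers": null},
  "orientation_chain": {
    "trunk":           {"xy": ["trunk_ventral"], "zy": ["trunk_lateral"]},
    "upperarm_L":      {"xy": ["trunk_ventral"], "zy": ["trunk_lateral", "shoulder_abd_L"]},
    "forearm_upper_L": {"xy": ["trunk_ventral", "elbow_L"], "zy": ["trunk_lateral", "shoulder_abd_L"]},
    "forearm_lower_L": {"xy": ["trunk_ventral", "elbow_L"], "zy": ["trunk_lateral", "shoulder_abd_L", "forearm_prosup_L"]},
    "hand_L":          {"xy": ["trunk_ventral", "elbow_L", "wrist_L"], "zy": ["trunk_lateral", "shoulder_abd_L", "forearm_prosup_L"]},
    "fingers_L":       {"xy": ["trunk_ventral", "elbow_L", "wrist_L", "fingers_L"], "zy": ["trunk_lateral", "shoulder_abd_L", "forearm_prosup_L"]},
    "upperarm_R":      {"xy": ["trunk_ventral"], "zy": ["trunk_lateral", "shoulder_abd_R"]},
    "forearm_upper_R": {"xy": ["trunk_ventral", "elbow_R"], "zy": ["trunk_lateral", "shoulder_abd_R"]},
    "forearm_lower_R": {"xy": ["trunk_ventral", "elbow_R"], "zy": ["trunk_lateral", "shoulder_abd_R", "forearm_prosup_R"]},
    "hand_R":          {"xy": ["trunk_ventral", "elbow_R", "wrist_R"], "zy": ["trunk_lateral", "shoulder_abd_R", "forearm_prosup_R"]},
    "fingers_R":       {"xy": ["trunk_ventral", "elbow_R", "wrist_R", "fingers_R"], "zy": ["trunk_lateral", "shoulder_abd_R", "forearm_prosup_R"]}
  }
}
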