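{
  "name": "target",
  "description": "Minimum recruitment design: 36 children in each of twelve 6-month age blocks (total 432).",
  "min_child_age": 1.5,
  "blocks": [
    {"lo": 0, "hi": 6, "count": 36},
    {"lo": 6, "hi": 12, "count": 36},
    {"lo": 12, "hi": 18, "count": 36},
    {"lo": 18, "hi": 24, "count": 36},
    {"lo": 24, "hi": 30, "count": 36},
    {"lo": 30, "hi": 36, "count": 36},
    {"lo": 36, "hi": 42, "count": 36},
    {"lo": 42, "hi": 48, "count": 36},
    {"lo": 48, "hi": 54, "count": 36},
    {"lo": 54, "hi": 60, "count": 36},
    {"lo": 60, "hi": 66, "count": 36},
    {"lo": 66, "hi": 72, "count": 36}
  ]
}
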