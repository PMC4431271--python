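# Context knowledge JSON schema

A UTF-8 JSON object with exactly three top-level keys. The key names are
this package's declared dialect (the original publication shows the three
concepts — objects, sensors, error models — but not the literal keys).

```json
{
  "objects": [
    {"name": "fridge", "location": "kitchen", "attached_sensor": "fridgeSens"}
  ],
  "sensors": [
    {"name": "fridgeSens", "type": "contact"}
  ],
  "error_models": {
    "contact": 0.0208
  }
}
```

* `objects` — each entry needs `name`, `location`, `attached_sensor`.
  Locations are free-form identifiers, carried through but not interpreted
  by the simulator. `attached_sensor` must name an entry of `sensors`.
* `sensors` — each entry needs `name` (unique) and `type`. Every `type`
  must have an entry in `error_models`.
* `error_models` — maps sensor type to its missing-noise probability
  `p ∈ [0, 1]`: the chance that a real interaction produces no activation.
  Calibrate from deployment accuracy with
  `estimate_missing_prob(captured, total) = 1 - captured/total`.

Violating any of these rules is a parse error (`ContextError`), as is a
sensor used in an ADL script that this file does not declare (reported by
`validate_script`).
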