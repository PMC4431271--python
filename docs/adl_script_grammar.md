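# ADL script grammar

The ADL script is a UTF-8 plain-text file with four ordered sections.
`#` starts a comment that runs to the end of the line; blank lines are
ignored everywhere. This grammar is one consistent, deterministic reading
of the original tool's dialect (the published fragments fix the `Name@lapse`
tokens, the `S` sequence lines, the `Prob` headers and the section
contents, but not every separator); it is the dialect this package parses
and emits.

```
script        := days-section activities-section behaviours-section noise-section
days-section  := "DAYS" NEWLINE integer          ; number of days to simulate, >= 1

activities-section := "ACTIVITIES" NEWLINE activity*
activity      := name integer NEWLINE pattern{integer}
pattern       := probability step+ NEWLINE
step          := name "@" integer                ; seconds after the PREVIOUS step;
                                                 ; the first step must be name@0

behaviours-section := "BEHAVIOURS" NEWLINE behaviour*
behaviour     := "Prob" probability NEWLINE element*
element       := sequence | alteration
sequence      := "S" slot item+ NEWLINE          ; always performed
item          := name "@" integer                ; seconds after the previous
                                                 ; activity's END; first item name@0
alteration    := "A" probability slot name NEWLINE   ; performed with that probability

noise-section := "NOISE" NEWLINE noise-line*
noise-line    := name probability NEWLINE        ; per-hour spurious-activation prob.

slot          := clock ("-" | "–") clock         ; dash may be a separate token
clock         := H":"MM [":"SS]                  ; 24:00 allowed as a slot end
probability   := real in [0, 1]
name          := [A-Za-z_][A-Za-z0-9_]*
```

Constraints enforced at parse time: day count >= 1, lapses >= 0, first
lapse of every pattern and sequence is 0, slot start < end, probabilities
in [0, 1]. Constraints checked by `validate_script` (against a context
knowledge file): every sensor and activity reference resolves, and each
probability group — the patterns of one activity, and the behaviour models
of the script — sums to 1 within 1e-6.

The activity name `None` is reserved: it labels noise events in the
output dataset.
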