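# Default parameter catalog for the digital-first GP workload model.
# Rates are percentages, durations are minutes.  Each pathway variable
# carries a base estimate plus plausible lower/upper bounds from outlier
# studies or authors' judgement.  N/A cells (telephone follow-up split for
# the telephone-first and video-first pathways) are structurally absent.
version: 1
conventional:
  f2f_pct: 86
  phone_pct: 14
  f2f_minutes: 9
  phone_minutes: 5
phone_cascade:
  completion_pct: 52
  minutes: 5
pathways:
  econsult:
    access_rate:
      units: percent
      base: 90
      lower: 0.01
      upper: 100
      source_note: "base/upper: authors' estimate; lower: published study"
    completion_rate:
      units: percent
      base: 30
      lower: 28
      upper: 70
      source_note: "published studies (upper bound includes vendor claims)"
    phone_followup_fraction:
      units: percent
      base: 46
      lower: 20
      upper: 90
      source_note: "base: published study; bounds: authors' estimate"
    digital_duration:
      units: minutes
      base: 4
      lower: 3
      upper: 5
      source_note: "base/lower: authors' estimate; upper: published study"
    demand_fraction:
      units: percent
      base: 10
      lower: -10
      upper: 30
      source_note: "authors' estimate"
  telephone:
    access_rate:
      units: percent
      base: 93
      lower: 10
      upper: 100
      source_note: "base/lower: published studies; upper: authors' estimate"
    completion_rate:
      units: percent
      base: 52
      lower: 40
      upper: 90
      source_note: "base (two studies pooled, stored verbatim) and upper: published studies; lower: authors' estimate"
    digital_duration:
      units: minutes
      base: 5
      lower: 4
      upper: 6
      source_note: "published studies"
    demand_fraction:
      units: percent
      base: 0
      lower: -10
      upper: 30
      source_note: "base: published study; bounds: authors' estimate"
  video:
    access_rate:
      units: percent
      base: 90
      lower: 50
      upper: 100
      source_note: "authors' estimate"
    completion_rate:
      units: percent
      base: 65
      lower: 50
      upper: 83
      source_note: "base/lower: authors' estimate (vendor claims); upper: published study"
    digital_duration:
      units: minutes
      base: 9
      lower: 6
      upper: 15
      source_note: "base: assumed similar to conventional f2f; bounds: published studies"
    demand_fraction:
      units: percent
      base: 0
      lower: -10
      upper: 30
      source_note: "authors' estimate"
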