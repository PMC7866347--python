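# Default (modified) obstetric early warning score chart.
#
# Best-effort reconstruction of a standard obstetric EWS vital-sign banding
# (weights 0-3 per parameter); the scoring engine is chart-agnostic and this
# file can be replaced by any chart following the same schema.
#
# Schema: bands.<parameter> is an ordered list of {low, high, weight} with
# low inclusive, high exclusive; bands must be contiguous and cover the
# physiologic range ("-inf"/"inf" allowed at the extremes).
# avpu_weights maps each consciousness level to a weight.

bands:
  respiratory_rate:
    - {low: "-inf", high: 10, weight: 3}
    - {low: 10, high: 21, weight: 0}
    - {low: 21, high: 25, weight: 1}
    - {low: 25, high: 30, weight: 2}
    - {low: 30, high: "inf", weight: 3}
  spo2:
    - {low: "-inf", high: 92, weight: 3}
    - {low: 92, high: 96, weight: 2}
    - {low: 96, high: 98, weight: 1}
    - {low: 98, high: "inf", weight: 0}
  temperature:
    - {low: "-inf", high: 35, weight: 2}
    - {low: 35, high: 36, weight: 1}
    - {low: 36, high: 38, weight: 0}
    - {low: 38, high: 39, weight: 1}
    - {low: 39, high: "inf", weight: 2}
  systolic_bp:
    - {low: "-inf", high: 80, weight: 3}
    - {low: 80, high: 90, weight: 2}
    - {low: 90, high: 140, weight: 0}
    - {low: 140, high: 150, weight: 1}
    - {low: 150, high: 160, weight: 2}
    - {low: 160, high: "inf", weight: 3}
  diastolic_bp:
    - {low: "-inf", high: 90, weight: 0}
    - {low: 90, high: 100, weight: 1}
    - {low: 100, high: 110, weight: 2}
    - {low: 110, high: "inf", weight: 3}
  heart_rate:
    - {low: "-inf", high: 50, weight: 2}
    - {low: 50, high: 60, weight: 1}
    - {low: 60, high: 100, weight: 0}
    - {low: 100, high: 120, weight: 1}
    - {low: 120, high: 130, weight: 2}
    - {low: 130, high: "inf", weight: 3}

avpu_weights:
  alert: 0
  voice: 1
  pain: 2
  unresponsive: 3
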