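# Sequential Organ Failure Assessment (SOFA) component thresholds.
# Six organ systems, each scored 0-4 from a raw measurement.  Bands are
# evaluated top-down: the first band whose condition holds gives the score.
#
# direction: "low" = lower raw value is worse; "high" = higher is worse.
# Each band is [threshold, score]; for "low" the condition is value < threshold,
# for "high" it is value >= threshold.  A measurement failing every band
# scores 0.  Units are annotated and must match the raw event streams.
#
# Simplifications relative to bedside scoring (documented in docs/methods.md):
#  - respiration ignores ventilation status (PaO2/FiO2 thresholds only)
#  - cardiovascular collapses vasopressor dose tiers to a presence flag
#  - renal omits the urine-output criterion
version: 1
respiration:
  measurement: pao2_fio2
  units: mmHg
  direction: low
  bands:
    - [100, 4]
    - [200, 3]
    - [300, 2]
    - [400, 1]
coagulation:
  measurement: platelets
  units: 10^3/uL
  direction: low
  bands:
    - [20, 4]
    - [50, 3]
    - [100, 2]
    - [150, 1]
liver:
  measurement: bilirubin
  units: mg/dL
  direction: high
  bands:
    - [12.0, 4]
    - [6.0, 3]
    - [2.0, 2]
    - [1.2, 1]
cardiovascular:
  measurement: map
  units: mmHg
  direction: low
  bands:
    - [70, 1]
  vasopressor_score: 2   # any vasopressor use scores at least this
cns:
  measurement: gcs
  units: points
  direction: low
  bands:
    - [6, 4]
    - [10, 3]
    - [13, 2]
    - [15, 1]
renal:
  measurement: creatinine
  units: mg/dL
  direction: high
  bands:
    - [5.0, 4]
    - [3.5, 3]
    - [2.0, 2]
    - [1.2, 1]
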