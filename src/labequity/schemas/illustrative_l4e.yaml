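# ILLUSTRATIVE workload tariff.
#
# The point values below are invented for demonstration and testing; they do
# NOT reproduce the CAP-ACP L4E tariff, the Ontario Schedule of Benefits, or
# any other published fee/point schedule.  Replace this file with your own
# tariff before analyzing real data.
version: illustrative-0.1
metrics: [L4E, fees, cases, blocks]
unmatched_policy: zero
rules:
  - name: cytology
    match: {case_class: cytology}
    contributions:
      L4E: {base: 0.6, per_specimen: 0.2}
      fees: {base: 12.0}
      cases: {base: 1.0}
      blocks: {per_block: 1.0}
  - name: surgical-small
    match: {case_class: surgical, specimen_max: 2}
    contributions:
      L4E: {base: 1.0, per_block: 0.5}
      fees: {base: 20.0, per_specimen: 12.0}
      cases: {base: 1.0}
      blocks: {per_block: 1.0}
  - name: surgical-large
    match: {case_class: surgical, specimen_min: 3}
    contributions:
      L4E: {base: 2.0, per_block: 0.5, per_ancillary: {ihc: 0.4}}
      fees: {base: 28.0, per_specimen: 12.0}
      cases: {base: 1.0}
      blocks: {per_block: 1.0}
  - name: review
    match: {case_class: review}
    contributions:
      L4E: {base: 1.5}
      cases: {base: 1.0}
      blocks: {per_block: 1.0}
  - name: external-referral
    match: {case_class: external_referral}
    contributions:
      L4E: {base: 1.0, per_block: 0.25}
      cases: {base: 1.0}
      blocks: {per_block: 1.0}
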