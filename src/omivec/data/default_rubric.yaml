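# Clinical disease-activity rubric: percent body-weight loss bands mapped
# to integer grades 0-4, following the standard DSS disease-activity-index
# convention.  A band applies when loss < upper (loss = max(0, -weight_change)).
# Stool-consistency and rectal-bleeding grades are observed directly on the
# same 0-4 scale and pass through unchanged.
weight_loss_bands:
  - {upper: 1, grade: 0}
  - {upper: 5, grade: 1}
  - {upper: 10, grade: 2}
  - {upper: 15, grade: 3}
  - {upper: .inf, grade: 4}
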