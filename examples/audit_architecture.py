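"""Print the network's layer table and audit its parameter arithmetic.

Builds the declarative graph for the default 256x256x1 configuration,
prints every row (block, filters, dimensions, parameter count), and checks
the audited rows against the reference counts. No weights are instantiated;
this is pure shape/parameter arithmetic.
"""

import ultraseg as us
from ultraseg.graph import AUDITED_LABELS, REFERENCE_PARAMS

graph = us.assemble_model(us.ModelConfig())
print(graph.format_table("table_audit"))

matches = sum(
    us.count_params(graph.block(label), "table_audit")
    == REFERENCE_PARAMS[label]
    for label in AUDITED_LABELS)
print(f"\n{matches}/{len(AUDITED_LABELS)} audited rows reproduce the "
      f"reference parameter counts.")
print("Attention-gate counts are in_channels x 32 (bias-free 1x1 "
      "projection); multi-res rows follow (9*in + 1) * out, a single 3x3 "
      "convolution with bias.")
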