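"""Trace the network's feature-map shapes symbolically.

The shape trace walks the layer graph without allocating any weights:
five encoder stages (each a two-branch "graft" block followed by a
stride-2 max-pool), a bottleneck convolution, five decoder stages
(2x upsample, skip concatenation, convolution), and a 1-channel
sigmoid head. For the default 512x512x3 input the trace reproduces
the published 81-row layer table exactly.

Run from the repository root:
    python examples/03_architecture_trace.py
"""

from graftunet import ArchConfig, trace_network, verify_against_table2
from graftunet.arch import parameter_count_formula

cfg = ArchConfig()  # 512x512x3, filter depths (8, 16, 32, 48, 64)
trace = trace_network(cfg)

print(f"{len(trace.tabular())} tabulated layers")
print("concatenation channel counts:", trace.cnc_channels())
print("final output shape:", trace.final_shape())
print("trainable parameters:", parameter_count_formula(cfg))

mismatches = verify_against_table2(trace)
print("conformance with the published layer table:", "OK" if not mismatches else mismatches)

print()
print("first encoder stage and last decoder stage:")
rows = trace.tabular()
for entry in rows[:8] + rows[-7:]:
    print(f"  {entry.name:>6}  {entry.kind:>3}  {entry.shape}")
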