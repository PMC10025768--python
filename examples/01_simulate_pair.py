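"""Simulate a labeled source / unlabeled target pair with novel cell types.

The open-partial setting is the hardest case: the source has a private type
the target lacks, and the target has a novel type the source never saw.
"""

import sfanno as sf

cfg = sf.make_config("open_partial", seed=7)
source, target, desc = sf.simulate_pair(cfg)

print(f"setting          : {desc.setting}")
print(f"shared types     : {sorted(desc.shared)}")
print(f"source-private   : {sorted(desc.source_private)} (partialness {desc.partialness:.2f})")
print(f"target-private   : {sorted(desc.target_private)} (openness {desc.openness:.2f})")
print(f"privateness      : {desc.privateness:.2f}")
print(f"source counts    : {source.counts.shape}, target counts: {target.counts.shape}")
print(f"target zero frac : {(target.counts == 0).mean():.2f}")
# The indices quantify label-space overlap: higher means less shared
# vocabulary between the annotated atlas and the data to annotate.
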