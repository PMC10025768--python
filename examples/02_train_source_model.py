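"""Train the source model and package the privacy-safe artifact.

The artifact holds weights, class names, the gene list and preprocessing
statistics - never a single source cell - so it can be shared freely.
"""

from pathlib import Path

import numpy as np

import sfanno as sf
from sfanno.io import ExpressionMatrix

cfg = sf.make_config("closed", seed=3)
source, _, _ = sf.simulate_pair(cfg)
pre = sf.preprocess(ExpressionMatrix(source.counts, source.gene_names, source.cell_ids))

train_cfg = sf.TrainConfig(
    warmup_epochs=4, joint_epochs=50, batch_size=128, learning_rate=1.5e-3,
    latent_dim=12, encoder_hidden=(48,), decoder_hidden=(48,), seed=3,
)
model = sf.train_source(pre, source.labels, train_cfg)

_, p, _, _ = model.predict(pre.x_input)
pred = [model.class_names[i] for i in p.argmax(1)]
acc = np.mean([a == b for a, b in zip(pred, source.labels)])
first, last = model.train_log[0], model.train_log[-1]
print(f"classes                 : {model.class_names}")
print(f"training accuracy       : {acc:.3f}   (fraction of source cells recovered)")
print(f"reconstruction NLL      : {first['recon']:.3f} -> {last['recon']:.3f} per entry")
out = Path("scratch_model.sfanno")
model.save(out)
print(f"artifact size           : {out.stat().st_size / 1024:.0f} KiB (independent of cell count)")
out.unlink()
Path(str(out) + ".json").unlink()
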