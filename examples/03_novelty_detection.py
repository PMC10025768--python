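"""Detect the presence of novel cell types in unlabeled target data.

The per-cell E-score combines entropy, confidence, and the agreement of two
frozen auxiliary classifiers; novel types make its distribution bimodal.
"""

import numpy as np

import sfanno as sf
from sfanno.io import ExpressionMatrix

cfg = sf.make_config("open", seed=11)  # one target-private cell type
source, target, desc = sf.simulate_pair(cfg)
pre_s = sf.preprocess(ExpressionMatrix(source.counts, source.gene_names, source.cell_ids))
model = sf.train_source(
    pre_s, source.labels,
    sf.TrainConfig(warmup_epochs=4, joint_epochs=50, batch_size=128, learning_rate=1.5e-3,
                   latent_dim=12, encoder_hidden=(48,), decoder_hidden=(48,), seed=11),
)
pre_t = sf.preprocess(
    ExpressionMatrix(target.counts, target.gene_names, target.cell_ids),
    stats=model.scaling_stats,
)

banks = sf.init_banks(model, pre_t)
bim = sf.detect_novelty(banks.e_scores, seed=0)
print(f"bimodality coefficient : {bim.bc_value:.3f}  (threshold {bim.bc_threshold:.3f})")
print(f"dip statistic / p      : {bim.dip_statistic:.4f} / {bim.dip_pvalue:.4f}")
print(f"novel types detected   : {bim.novel_detected}")

delta = sf.mixup_threshold(banks.R, lambda z: model.net.predict_probs(z), seed=0)
part = sf.partition(banks.e_scores, delta, bim.novel_detected)
truth_novel = np.array([l in desc.target_private for l in target.labels])
flagged = np.zeros(len(target.labels), dtype=bool)
flagged[part.unknown_idx] = True
print(f"mixup threshold delta  : {delta:.3f}")
print(f"cells flagged unknown  : {flagged.sum()} of {len(flagged)} "
      f"(truly novel: {truth_novel.sum()}; overlap {(flagged & truth_novel).sum()})")
# A high overlap means the adaptive threshold separated the novel
# population without any user-chosen cutoff.
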