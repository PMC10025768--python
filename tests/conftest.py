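import numpy as np
import pytest

import sfanno as sf
from sfanno.io import ExpressionMatrix


def small_train_config(seed=0, joint=80, warmup=10):
    """CPU-sized network used throughout the tests."""
    return sf.TrainConfig(
        warmup_epochs=warmup,
        joint_epochs=joint,
        batch_size=128,
        latent_dim=8,
        encoder_hidden=(32,),
        decoder_hidden=(32,),
        seed=seed,
    )


def simulate_preprocessed(setting="closed", seed=0, **overrides):
    """Simulated pair preprocessed for training/annotation."""
    cfg = sf.make_config(setting, seed=seed, **overrides)
    src, tgt, desc = sf.simulate_pair(cfg)
    pre_s = sf.preprocess(ExpressionMatrix(src.counts, src.gene_names, src.cell_ids))
    pre_t = sf.preprocess(
        ExpressionMatrix(tgt.counts, tgt.gene_names, tgt.cell_ids), stats=pre_s.scaling_stats
    )
    return src, tgt, desc, pre_s, pre_t


@pytest.fixture(scope="session")
def trained_small_model():
    """One small source model + target pair shared across tests (open setting)."""
    cfg = sf.make_config("open", seed=1, n_source_cells=300, n_target_cells=200, n_genes=100)
    src, tgt, desc = sf.simulate_pair(cfg)
    pre_s = sf.preprocess(ExpressionMatrix(src.counts, src.gene_names, src.cell_ids))
    model = sf.train_source(pre_s, src.labels, small_train_config(seed=1, joint=60, warmup=5))
    pre_t = sf.preprocess(
        ExpressionMatrix(tgt.counts, tgt.gene_names, tgt.cell_ids), stats=model.scaling_stats
    )
    return {"src": src, "tgt": tgt, "desc": desc, "pre_s": pre_s, "pre_t": pre_t, "model": model}
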