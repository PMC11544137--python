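"""Binding-affinity-style regression on a planted synthetic dataset.

Labels are a noiseless affine function of the cross-part contact count, so
a model that reads the interface geometry can recover them; tenfold CV
should report a held-out Pearson correlation near 1.  Takes a few minutes
on one CPU (n = 60 here; the acceptance run uses n = 200).
"""

import logging

logging.disable(logging.WARNING)

from cgppi.pipeline import (samples_from_synthetic, synthetic_benchmark_config,
                            train_eval_cv)
from cgppi.synthetic import make_labelled_dataset

dataset = make_labelled_dataset(n=60, task="regression", seed=1, sigma=0.0)
samples = samples_from_synthetic(dataset)
report = train_eval_cv(samples, "regression",
                       synthetic_benchmark_config("regression"), k=10)

print(f"fold-mean Pearson R_P: {report.aggregate['pearson']:.3f}")
print(f"fold-mean RMSE:        {report.aggregate['rmse']:.3f} kcal/mol")
print(f"fold-mean MAE:         {report.aggregate['mae']:.3f} kcal/mol")
print(f"config hash:           {report.config_hash}")
print("R_P close to 1 means the encoder recovered the planted geometric "
      "rule (labels are affine in the interface contact count); RMSE/MAE "
      "are on the kcal/mol scale of the synthetic binding energies.")
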