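"""Fit PGLS with maximum-likelihood Pagel's λ on simulated Brownian data.

λ measures phylogenetic signal in the regression residuals: 0 means species
are effectively independent, 1 means residuals covary in full proportion to
shared ancestry.  Here we simulate a trait with λ = 0.5 and recover it.
"""

import numpy as np

from fadesat import fit_lambda_ml
from fadesat.models import build_design_matrix
from fadesat.simulate import SimulationConfig, simulate_traits, simulate_tree

cfg = SimulationConfig(seed=42, n_tips=120, true_lambda=0.5, sigma2=0.3)
tree = simulate_tree(cfg)
records, truth = simulate_traits(tree, cfg)

X, names = build_design_matrix(records, cfg.model)
fit = fit_lambda_ml(
    records["delta9_di"].to_numpy(), X, tree,
    taxa=list(records["species"]), coef_names=names,
)

print(f"true lambda   : {truth['lambda']:.2f}")
print(f"estimated     : {fit.lambda_hat:.3f}")
print(f"log-likelihood: {fit.lnl:.2f}   AICc: {fit.aicc:.2f}")
print()
print(fit.summary().to_string(index=False))
print()
print("λ̂ near 0.5 shows the optimiser separating phylogenetic from independent")
print("residual variance; coefficients whose CI excludes 0 are 'significant'.")
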