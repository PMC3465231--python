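"""End-to-end benchmark: simulate, build priors, infer, assess.

Generates a 60-gene lag-linear network over 25 samples and five time points,
fits the supervised prior from synthetic external evidence, runs the
informative-prior and no-prior engine variants and scores both against the
generating network. The TPR here is precision-style: the fraction of
inferred edges that are present in the generating network.
"""

import numpy as np

import ibmanet as ib
from ibmanet.assess import all_pairs_universe, contingency_assess
from ibmanet.ibma import IbmaConfig

cfg = ib.SimulationConfig(
    n_genes=60, n_samples=25, n_timepoints=5, n_pos=100, n_neg=80, seed=11
)
truth = ib.sample_true_network(cfg)
observed, _ = ib.generate_timeseries(truth, cfg)
print(f"simulated {cfg.n_genes} genes, {len(truth.edges)} true edges")

train, table = ib.generate_external_evidence(truth, cfg)
adj = ib.compute_sampling_rates(
    cfg.n_pos, cfg.n_neg, cfg.n_genes, ib.mean_in_degree(cfg.in_degree_decay)
)
imputed = ib.impute_missing_chip(train, n_imputations=10, seed=1)
table = ib.truncate_extremes(table, train)
model = ib.fit_regulatory_model(imputed, adj)
priors = ib.predict_regulatory_potential(model, table, seed=2)
print(
    f"supervised prior: mean expected regulators per gene "
    f"{priors.expected_regulators.mean():.2f}"
)

universe = all_pairs_universe(observed.gene_ids, include_self=True)
for variant in ("prior", "noprior"):
    icfg = IbmaConfig(
        variant=variant, p=40, w=20, max_size=5,
        tau=ib.mean_in_degree(cfg.in_degree_decay) / cfg.n_genes, seed=0,
    )
    net = ib.build_network(
        observed, priors if variant == "prior" else None, icfg
    )
    res = contingency_assess(net, truth.edges, universe)
    print(
        f"variant {variant:8s}: {net.n_edges:3d} edges, "
        f"TPR {res.tpr * 100:5.1f}%, O/E {res.oe_ratio:6.1f}, "
        f"misclassified {res.misclassified}"
    )
print(
    "\nThe informative prior concentrates the same evidence budget on "
    "fewer, more accurate edges."
)
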