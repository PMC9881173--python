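"""Full product-analysis chain on simulated amplicon reads.

Simulates three sequencing replicates of resolved deletion products
(5,000 molecules each, 0.5% per-base error), runs the retention
pipeline (collapse -> 0.1% abundance filter -> global alignment -> site
calls -> percent retention), aggregates replicates, compares site
pairs, and fits the resolution-model parameters back from the profile.
"""

import numpy as np

from rmdkit import (
    ResolutionParams,
    aggregate_replicates,
    compare_sites,
    default_repeat_pair,
    fit_resolution_model,
    generate_reads,
    polarity_index,
    run_pipeline,
    simulate_heteroduplex,
)

pair = default_repeat_pair("3%")
truth = ResolutionParams(pi_b=0.6, pi_t=0.6, theta_b=0.99, theta_t=0.99)

profiles = []
for rep in range(3):
    molecules = simulate_heteroduplex(pair, truth, 5000, seed=10 + rep)
    reads = generate_reads(molecules, error_rate=0.005, seed=20 + rep)
    profiles.append(run_pipeline(reads, pair, min_fraction=0.001, sample_id=f"rep{rep+1}"))

summary = aggregate_replicates(profiles)
print(summary.to_frame().round(2).to_string(index=False))
print(f"\npolarity index (rank 1 - rank 8): {polarity_index(summary):.1f} points")

pvals = compare_sites(profiles)
extremes = pvals[(pvals.site_a == 1) & (pvals.site_b == 8)].iloc[0]
print(f"site 1 vs site 8: p_raw={extremes.p_raw:.2e} p_adj={extremes.p_adjusted:.2e}")

fit = fit_resolution_model(summary, pair, seed=0)
print(
    f"fitted: pi_b={fit.params.pi_b:.3f} pi_t={fit.params.pi_t:.3f} "
    f"theta_b={fit.params.theta_b:.4f} theta_t={fit.params.theta_t:.4f} "
    f"(truth 0.6 / 0.6 / 0.99 / 0.99)"
)

# Mean retention falls from ~73% at rank 1 to ~27% at rank 8 under
# these parameters; the fit recovers the simulator's excision
# probabilities from the profile alone.
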