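"""Reporter-screen arithmetic: normalization, triage, ratios, qPCR.

Simulates a small siRNA screen with planted fold effects, normalizes
each well to its parallel transfection and to the siCTRL mean, flags
genes with a >= 1.5-fold effect in any assay (either direction),
computes the divergent/identical frequency ratio per distance, and
quantifies a knockdown with 2^-ddCt.
"""

import numpy as np

from rmdkit import (
    delta_delta_ct,
    divergent_identical_ratio,
    fold_effects_and_triage,
    normalize_batch,
    simulate_qpcr,
    simulate_screen,
)
from rmdkit.reporter_stats import fold_effects_frame

effects = {"Mlh1": {"1%:16bp": 2.2, "1%:9.1kb": 2.5, "identical:16bp": 1.1, "identical:9.1kb": 1.0},
           "Blm": 1.7, "Null": 1.0}
measurements = simulate_screen(effects, n_replicates=4, noise_cv=0.1, seed=42)
normalized = normalize_batch(measurements)

controls = [n.control_scaled_value for n in normalized if n.is_control]
print(f"control mean after scaling: {np.mean(controls):.12f}")

table = fold_effects_frame(fold_effects_and_triage(normalized))
print(table.sort_values(["gene", "assay"]).round(2).to_string(index=False))
print("flagged:", sorted(table[table.flagged].gene.unique()))

ratios = divergent_identical_ratio(normalized)
print(ratios.round(2).to_string(index=False))

qpcr = delta_delta_ct(simulate_qpcr({"siMlh1": 0.2}, noise_sd=0.1, seed=7))
print(qpcr.round(3).to_string(index=False))

# The divergent/identical ratio isolates effects specific to mismatched
# repeats (Mlh1-like genes ratio >> 1); 2^-ddCt near 0.2 confirms the
# planted 80% knockdown.
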