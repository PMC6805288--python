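"""Correlation-based feature subset selection on a labeled table.

CFS scores a subset S of k features by Hall's merit
    merit(S) = k r̄_cf / sqrt(k + k(k-1) r̄_ff),
rewarding features that correlate with the class (r̄_cf) but not with
each other (r̄_ff), and searches subsets best-first.
"""

import numpy as np
import pandas as pd

from ssmirna import select_features_cfs

rng = np.random.default_rng(0)
n = 300
y = rng.integers(0, 2, n)

signal_a = y + rng.normal(0, 0.6, n)
frame = pd.DataFrame(
    {
        "signal_a": signal_a,                          # informative
        "signal_a_copy": signal_a.copy(),              # exact duplicate
        "signal_b": -y + rng.normal(0, 0.6, n),        # equally informative
        "noise_1": rng.standard_normal(n),
        "noise_2": rng.standard_normal(n),
    }
)

result = select_features_cfs(frame, y)
print("selected:", result.selected)
print(f"merit:    {result.merit:.4f}")
print(f"subsets evaluated: {len(result.trace)}")

# Expect both signals in the subset but only ONE of the duplicate
# pair: the duplicate adds as much inter-feature redundancy (r̄_ff) as
# predictive mass (r̄_cf), so the merit does not improve and the tie
# resolves to the smaller subset.
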