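"""Sample-size calculation and Holm-Sidak multiple-comparison control.

The design question: how many animals per group are needed to detect a
25 min difference in total sleep (sd 14.6 min) at alpha 0.05 with 80%
power? The normal-approximation answer is 6 per group; the exact
noncentral-t iteration is one animal more conservative.
"""

import somnostress as ss

n = ss.sample_size(sd=14.6, diff=25, alpha=0.05, power=0.8)
n_exact = ss.sample_size(sd=14.6, diff=25, method="exact-t")
print(f"n per group (normal approximation) : {n}")
print(f"n per group (exact noncentral t)   : {n_exact}")

pvals = [0.001, 0.02, 0.04]
out = ss.holm_sidak(pvals, alpha=0.05)
print("\nHolm-Sidak step-down over a 3-comparison family:")
print(out.assign(adjusted_alpha=out["adjusted_alpha"].round(5)).to_string(index=False))
# The smallest p is tested against 1-(1-.05)^(1/3) ~ 0.01695, the next
# against ~0.02532, the last against 0.05; all three are rejected here
# while the family-wise error rate stays at 5%.
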