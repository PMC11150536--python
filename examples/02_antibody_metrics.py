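"""Antibody breadth and specificity for a single serum profile.

Breadth is the percentage of beads above the 1,500 MFI positivity cutoff;
specificity is the normalized Shannon entropy of the relative MFI
distribution (0 = one dominant antibody, 1 = uniform reactivity).
"""

import numpy as np

from hlahom import normalized_entropy, pct_above_cutoff

uniform_high = np.full(30, 6000.0)  # broad responder
spiky = np.concatenate([[9000.0, 7000.0], np.full(28, 120.0)])  # two spikes
silent = np.full(30, 90.0)  # unimmunized serum

for name, profile in [
    ("broad responder ", uniform_high),
    ("spiky responder ", spiky),
    ("silent serum    ", silent),
]:
    print(
        f"{name}: %MFI>1500 = {pct_above_cutoff(profile):5.1f}%, "
        f"H_norm = {normalized_entropy(profile):.3f}"
    )

print(
    "\nBroad responders are high on both axes (the high-risk HH corner of the"
    "\nbiplot); spiky profiles have low entropy; silent sera have high entropy"
    "\nbut near-zero breadth (uniformly low background reactivity)."
)
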