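"""Zero/tertile discretization of transcript abundance.

Transcripts with nTPM = 0 are Not detected; the positive values are cut
at their empirical 1/3 and 2/3 quantiles into Low / Medium / High, the
same four-level scale IHC protein calls use.
"""

import numpy as np

from hpaconcord.classify import categorize_transcript, compute_tertiles

rng = np.random.default_rng(0)
ntpm = np.concatenate([np.zeros(4), np.round(np.exp(rng.normal(1.8, 1.7, 14)), 2)])

thresholds = compute_tertiles(ntpm)
print(f"positive transcripts: {thresholds.n_positive}")
print(f"Low/Medium boundary (t1): {thresholds.t1:.2f} nTPM")
print(f"Medium/High boundary (t2): {thresholds.t2:.2f} nTPM")
print()
for value in [0.0, 0.8, float(thresholds.t1), 7.5, 436.6]:
    category = categorize_transcript(value, thresholds)
    print(f"nTPM {value:8.2f} -> {category.label}")

# A value sitting exactly on a boundary lands in the lower category
# (intervals are upper-closed), and only an exact zero is Not detected.
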