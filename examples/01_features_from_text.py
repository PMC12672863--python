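"""Turn one raw transcript into its stationary character fingerprint.

Normalizes a snippet of picture-description speech, fits a Laplace-smoothed
transition chain, and prints the five most-occupied character states. The
probabilities are the chain's long-run occupancy of each symbol — the space
entry is the word-boundary (pause-proxy) rate the screening stage targets.
"""

import numpy as np

import charmark as cm

text = (
    "Well the mother is... she's drying the dishes and the water is "
    "running over the sink. The little boy, he's up on the stool reaching "
    "for the cookie jar, and the stool is tipping. The girl is reaching up."
)

seq = cm.encode(cm.normalize_text(text), transcript_id="demo")
model = cm.fit_model(seq, alpha=0.01)
pi = cm.steady_state(model).pi

names = cm.ALPHABET.display_names()
order = np.argsort(pi)[::-1]
print(f"transcript length after normalization: {len(seq)} symbols")
print("top stationary probabilities:")
for i in order[:5]:
    print(f"  {names[i]:>5s}  {pi[i]:.4f}")
print(
    f"\nspace probability {pi[26]:.3f}: roughly one word boundary every "
    f"{1 / pi[26]:.1f} characters in the long run."
)
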