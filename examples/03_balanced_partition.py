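"""Balanced sub-datasets and the branch-indexed cross-entropy.

Shows how a 7:1 imbalanced dataset is split so each of the 7 output branches
sees roughly one normal sample per AF sample, and how the loss routes each
sample to its branch(es).
"""

import numpy as np

from afwave.mbtrain import LabeledDataset, make_partition, mb_loss

# The printed class counts of a public AF corpus: 5050 normal, 738 AF.
labels = np.r_[np.zeros(5050, int), np.ones(738, int)]
data = LabeledDataset(labels=labels)
part = make_partition(data, seed=0)

print(f"imbalance ratio |D-|/|D+| = {len(data.d_minus) / len(data.d_plus):.2f}")
print(f"default branch count N_b  = {part.n_branches}")
print(f"subset sizes              = {[len(s) for s in part.subsets]}")
print(f"minority class size       = {len(data.d_plus)} (paired with every subset)")

# Loss arithmetic: one AF sample predicted 0.5 by both of two branches
# contributes -log(0.5) twice.
loss = mb_loss(np.array([[0.5, 0.5]]), np.array([1]), np.array([-1]))
print(f"two-branch AF example loss = {loss:.4f} (= 2 ln 2 = {2 * np.log(2):.4f})")
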