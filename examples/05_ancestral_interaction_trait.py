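"""Ancestral tracing of the heterodimerization trait.

The interaction between the two families is scored 1 (present) or 0 (absent)
per organism; Fitch parsimony and a two-state Mk likelihood model then ask
what the ancestor most likely did.
"""

import dendropy

from coevokit.ancstate import fitch_trace, mk2_marginal

newick = "((human:2,mouse:2):3,((rice:1,maize:1):2,(arabidopsis:1,tomato:1):2):2);"
tree = dendropy.Tree.get(data=newick, schema="newick")

# interaction observed in every assayed organism
tips = {t: 1 for t in ("human", "mouse", "rice", "maize", "arabidopsis", "tomato")}
fitch = fitch_trace(tree, tips)
mk = mk2_marginal(tree, tips)
root = next(iter(mk.posteriors))
print(f"parsimony: root state set {set(fitch.root_states)}, "
      f"{fitch.n_changes} changes")
print(f"likelihood: P(interaction at root) = {mk.posteriors[root]:.4f} "
      f"(rate {mk.rate:.2g})")

# one secondary loss flips nothing at the root; the rate is fixed at a low
# value here because a single binary character cannot estimate it reliably
tips["maize"] = 0
fitch = fitch_trace(tree, tips)
mk = mk2_marginal(tree, tips, rate=0.05)
print(f"with one loss: root set {set(fitch.root_states)}, "
      f"{fitch.n_changes} change(s); "
      f"P(root interaction) = {mk.posteriors[root]:.4f}")
print("# A trait present across the whole tree is reconstructed as ancestral")
print("# (plesiomorphic) by both methods.")
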