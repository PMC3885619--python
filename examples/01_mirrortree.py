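"""Tol-MirrorTree: do two protein families share more evolutionary history
than speciation alone explains?

Simulates two families whose per-branch rates are correlated (rho = 0.9) on
one species tree, plus a clock-like neutral marker and an independent decoy
family, then correlates their Poisson-corrected distance matrices before and
after removing the speciation signal estimated from the marker.
"""

from coevokit.io import PairingRow, PairingTable
from coevokit.mirrortree import tol_mirrortree
from coevokit.synthetic import SimConfig, simulate_bundle

cfg = SimConfig(n_organisms=30, rate_correlation=0.9, marker_length=600, seed=1)
bundle = simulate_bundle(cfg)

res = tol_mirrortree(bundle.fam_a, bundle.fam_b, bundle.pairing,
                     marker=bundle.marker, n_perm=9999, seed=1)
decoy_pairing = PairingTable(
    [PairingRow(r.organism_id, r.member_a, f"{r.organism_id}_D1")
     for r in bundle.pairing.rows])
decoy = tol_mirrortree(bundle.fam_a, bundle.decoy, decoy_pairing,
                       marker=bundle.marker, n_perm=9999, seed=1)

print(f"co-evolving pair : R = {res.corrected.r:.3f} "
      f"(uncorrected {res.uncorrected.r:.3f}), Mantel p = {res.corrected.p:.4f}")
print(f"decoy control    : R = {decoy.corrected.r:.3f}, "
      f"Mantel p = {decoy.corrected.p:.4f}")
print("# Both raw R values are inflated by the shared species tree; after the")
print("# marker correction only the genuinely co-evolving pair keeps a high R.")
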