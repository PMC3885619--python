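"""Correlated-mutation detection: find site pairs that substitute together.

Plants five compensatory site pairs (a change at the family-A site forces a
change at its family-B partner on the same branch), runs the BLOSUM-based
site-profile correlation, filters against a shuffled-site-label null and
groups significant pairs by connectivity.
"""

from scipy import stats

from coevokit import caps
from coevokit.synthetic import SimConfig, simulate_bundle

planted = [(10, 15), (50, 60), (90, 100), (130, 140), (170, 180)]
cfg = SimConfig(n_organisms=30, coupled_pairs=planted, compensation_prob=1.0,
                marker_length=300, seed=2)
bundle = simulate_bundle(cfg)

matrix = caps.load_substitution_matrix("BLOSUM62")
prof_a = caps.site_profiles(bundle.fam_a,
                            caps.matched_sequence_pairs(bundle.pairing, "A"), matrix)
prof_b = caps.site_profiles(bundle.fam_b,
                            caps.matched_sequence_pairs(bundle.pairing, "B"), matrix)
pairs = caps.intermolecular_correlations(prof_a, prof_b)
sig = caps.significance_filter(pairs, prof_a, prof_b, alpha=0.05,
                               n_resample=1000, seed=2)
groups = caps.build_groups(sig, prof_a, prof_b)

sig_set = {(p.site_a, p.site_b) for p in sig}
hits = len(sig_set & set(planted))
p_enrich = stats.hypergeom.sf(hits - 1, len(pairs), len(sig), len(planted))

print(f"{len(pairs)} site pairs tested, {len(sig)} significant at alpha=0.05, "
      f"{len(groups)} connectivity groups")
print(f"planted pairs recovered in the significant set: {hits}/5 "
      f"(enrichment p = {p_enrich:.2g})")
print("# The planted compensatory pairs should be strongly over-represented")
print("# among the significant correlations relative to the 5% background.")
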