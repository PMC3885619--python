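"""Synthetic co-evolving protein families with known ground truth.

The generator emulates the statistical structure the detectors assume: two
protein families evolving on one shared species tree whose per-branch rates
are lognormally distributed and correlated between the families
(co-evolution of rates, the MirrorTree signal); planted compensatory site
pairs where a substitution at a family-A site triggers, with a configurable
probability, a substitution at its partnered family-B site on the same
branch (the CAPS signal); a strictly clock-like neutral nucleotide marker
(the 18S rRNA analog used for speciation correction); an uncorrelated decoy
family (the LFY analog); and optional within-organism paralog duplications.

Residues substitute under a uniform-exchange process (a substitution event
replaces the residue with any of the other 19, uniformly), which keeps every
downstream expectation analyzable; the marker uses the analogous 4-state
process.  Everything is deterministic under the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np

from .io import (
    AlignedFamily,
    FamilyRecord,
    PairingRow,
    PairingTable,
    SpeciesTree,
    write_alignment,
    write_pairing,
    write_tree,
)

AA = "ACDEFGHIKLMNPQRSTVWY"
NT = "ACGT"

SENSE_CODONS = [
    a + b + c
    for a in NT
    for b in NT
    for c in NT
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Rates are substitutions per site per unit branch length on a tree scaled
    to root-to-tip depth ``tree_depth``.  ``rate_correlation`` couples the
    per-branch lognormal rate multipliers of families A and B;
    ``coupled_pairs`` lists 1-based (site_A, site_B) compensatory pairs with
    per-trigger probability ``compensation_prob``.
    """

    n_organisms: int = 30
    birth_rate: float = 1.0
    tree_depth: float = 1.0
    len_a: int = 200
    len_b: int = 200
    rate_a: float = 0.25
    rate_b: float = 0.25
    rate_sigma: float = 0.6
    rate_correlation: float = 0.0
    coupled_pairs: list = field(default_factory=list)
    compensation_prob: float = 0.0
    compensation_mode: str = "favorable"  # or "random"
    duplications: list = field(default_factory=list)  # (organism_id, "A"|"B")
    marker_length: int = 1500
    marker_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.compensation_prob <= 1.0):
            raise ValueError("compensation_prob must be in [0, 1]")
        if not (-1.0 <= self.rate_correlation <= 1.0):
            raise ValueError("rate_correlation must be in [-1, 1]")
        if min(self.len_a, self.len_b, self.marker_length) <= 0:
            raise ValueError("lengths must be positive")
        for sa, sb in self.coupled_pairs:
            if not (1 <= sa <= self.len_a and 1 <= sb <= self.len_b):
                raise ValueError(f"coupled pair ({sa}, {sb}) out of range")


@dataclass
class CoevolTruth:
    """Ground truth emitted with each bundle for recovery tests."""

    coupled_pairs: list  # [(site_a, site_b), ...] 1-based
    branch_multipliers: dict  # edge (child node name) -> {"A":, "B":, "decoy":}
    duplications: list


@dataclass
class SimBundle:
    tree: SpeciesTree
    fam_a: AlignedFamily
    fam_b: AlignedFamily
    marker: AlignedFamily
    decoy: AlignedFamily
    pairing: PairingTable
    clades: dict
    truth: CoevolTruth
    config: SimConfig


# ---------------------------------------------------------------------------
# tree simulation


def simulate_tree(
    n: int, birth_rate: float = 1.0, seed: int = 0, depth: float | None = None
) -> SpeciesTree:
    """Pure-birth (Yule) ultrametric tree with ``n`` tips.

    Tips are labeled org01..orgNN; internal nodes n0, n1, ... in preorder.
    ``depth`` rescales all branch lengths to the given root-to-tip height.
    """
    if n < 3:
        raise ValueError("need n >= 3 organisms")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    birth = {root: 0.0}
    active = [root]
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        node = active.pop(int(rng.integers(len(active))))
        c1, c2 = dendropy.Node(), dendropy.Node()
        for c in (c1, c2):
            node.add_child(c)
            birth[c] = t
        # close out the split node's pendant time
        node._split_time = t
        active.extend([c1, c2])
    t_end = t + rng.exponential(1.0 / (birth_rate * n))
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        end = getattr(node, "_split_time", t_end)
        node.edge.length = end - birth[node]
    width = len(str(n))
    for k, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxa.new_taxon(f"org{k:0{width}d}")
    for k, node in enumerate(tree.preorder_internal_node_iter()):
        node.label = f"n{k}"
    if depth is not None:
        height = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
        scale = depth / height
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= scale
    return tree


# ---------------------------------------------------------------------------
# sequence evolution


def _evolve_protein(seq: np.ndarray, n_events_per_site: np.ndarray, rng) -> np.ndarray:
    """Apply uniform-exchange substitutions; returns the new sequence."""
    out = seq.copy()
    hit = np.nonzero(n_events_per_site)[0]
    for i in hit:
        for _ in range(int(n_events_per_site[i])):
            out[i] = (out[i] + 1 + rng.integers(19)) % 20
    return out


def _favorable_partner(old: int, blosum) -> np.ndarray:
    """Candidate residue indices most drastic (lowest BLOSUM score) vs old."""
    scores = np.array([blosum[AA[old], AA[j]] for j in range(20)])
    scores[old] = np.inf
    return np.nonzero(scores == scores.min())[0]


def simulate_families(tree: SpeciesTree, config: SimConfig) -> SimBundle:
    """Evolve families A, B, decoy and the neutral marker along ``tree``.

    Family A and B share lineage-correlated lognormal rate multipliers; when
    a substitution lands on a coupled A site along a branch, the partnered B
    site substitutes on the same branch with probability
    ``compensation_prob`` (target residue: most drastic BLOSUM change in
    'favorable' mode, uniform in 'random' mode).  The decoy draws independent
    multipliers; the marker is strictly clock-like.  Paralog duplications
    split at the start of the terminal branch and evolve independently
    (without coupling) thereafter.
    """
    from Bio.Align import substitution_matrices

    rng = np.random.default_rng(config.seed)
    blosum = substitution_matrices.load("BLOSUM62")
    sigma = config.rate_sigma
    rho = config.rate_correlation

    coupled_a = {sa - 1: sb - 1 for sa, sb in config.coupled_pairs}
    dup_set = {(org, fam) for org, fam in config.duplications}

    # per-edge rate multipliers, drawn in preorder for determinism
    mult: dict = {}
    edges = [n for n in tree.preorder_node_iter() if n.parent_node is not None]
    for node in edges:
        za = rng.standard_normal()
        zb = rho * za + np.sqrt(max(0.0, 1.0 - rho * rho)) * rng.standard_normal()
        zd = rng.standard_normal()
        mult[node] = (
            float(np.exp(sigma * za - sigma * sigma / 2)),
            float(np.exp(sigma * zb - sigma * sigma / 2)),
            float(np.exp(sigma * zd - sigma * sigma / 2)),
        )

    root_a = rng.integers(20, size=config.len_a)
    root_b = rng.integers(20, size=config.len_b)
    root_d = rng.integers(20, size=config.len_b)
    root_m = rng.integers(4, size=config.marker_length)

    state = {tree.seed_node: (root_a, root_b, root_d, root_m)}
    records_a, records_b, records_d, records_m = [], [], [], []

    def _evolve_edge(a, b, d, m, node, length, with_coupling=True):
        ga, gb, gd = mult[node]
        ev_a = rng.poisson(config.rate_a * ga * length, size=config.len_a)
        a2 = _evolve_protein(a, ev_a, rng)
        ev_b = rng.poisson(config.rate_b * gb * length, size=config.len_b)
        b2 = _evolve_protein(b, ev_b, rng)
        if with_coupling and config.coupled_pairs:
            for sa, sb in coupled_a.items():
                if ev_a[sa] > 0 and rng.random() < config.compensation_prob:
                    old = int(b2[sb])
                    if config.compensation_mode == "favorable":
                        cands = _favorable_partner(old, blosum)
                        b2[sb] = int(rng.choice(cands))
                    else:
                        b2[sb] = (old + 1 + int(rng.integers(19))) % 20
        ev_d = rng.poisson(config.rate_b * gd * length, size=config.len_b)
        d2 = _evolve_protein(d, ev_d, rng)
        ev_m = rng.poisson(config.marker_rate * length, size=config.marker_length)
        m2 = m.copy()
        for i in np.nonzero(ev_m)[0]:
            for _ in range(int(ev_m[i])):
                m2[i] = (m2[i] + 1 + rng.integers(3)) % 4
        return a2, b2, d2, m2

    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        a, b, d, m = state[node.parent_node]
        length = node.edge.length or 0.0
        state[node] = _evolve_edge(a, b, d, m, node, length)

    pairing_rows = []
    clades: dict = {}
    for leaf in tree.leaf_node_iter():
        org = leaf.taxon.label
        a, b, d, m = state[leaf]
        members_a = [(f"{org}_A1", a)]
        members_b = [(f"{org}_B1", b)]
        if (org, "A") in dup_set:
            # paralog re-evolves the terminal branch from the parent sequence
            pa = state[leaf.parent_node][0]
            ev = rng.poisson(
                config.rate_a * mult[leaf][0] * (leaf.edge.length or 0.0),
                size=config.len_a,
            )
            members_a.append((f"{org}_A2", _evolve_protein(pa, ev, rng)))
        if (org, "B") in dup_set:
            pb = state[leaf.parent_node][1]
            ev = rng.poisson(
                config.rate_b * mult[leaf][1] * (leaf.edge.length or 0.0),
                size=config.len_b,
            )
            members_b.append((f"{org}_B2", _evolve_protein(pb, ev, rng)))
        for sid, seq in members_a:
            records_a.append(FamilyRecord(sid, org, "".join(AA[i] for i in seq)))
        for sid, seq in members_b:
            records_b.append(FamilyRecord(sid, org, "".join(AA[i] for i in seq)))
        records_d.append(FamilyRecord(f"{org}_D1", org, "".join(AA[i] for i in d)))
        records_m.append(FamilyRecord(org, org, "".join(NT[i] for i in m)))
        for (sa, _), (sb, _) in [(x, y) for x in members_a for y in members_b]:
            pairing_rows.append(PairingRow(org, sa, sb))

    # clades: a dicot/monocot-style contrast from the most balanced clade in
    # the tree (the raw root split of a pure-birth tree is often a singleton)
    all_tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    best_clade: set | None = None
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        tips = {l.taxon.label for l in node.leaf_iter()}
        if best_clade is None or abs(len(tips) - len(all_tips) / 2) < abs(
            len(best_clade) - len(all_tips) / 2
        ):
            best_clade = tips
    if best_clade is None:  # star-like fallback
        best_clade = {next(iter(all_tips))}
    for org in all_tips:
        clades[org] = "cladeL" if org in best_clade else "cladeR"

    truth = CoevolTruth(
        coupled_pairs=list(config.coupled_pairs),
        branch_multipliers={
            (n.label or n.taxon.label): {"A": g[0], "B": g[1], "decoy": g[2]}
            for n, g in mult.items()
        },
        duplications=list(config.duplications),
    )
    return SimBundle(
        tree=tree,
        fam_a=AlignedFamily("famA", records_a),
        fam_b=AlignedFamily("famB", records_b),
        marker=AlignedFamily("marker", records_m),
        decoy=AlignedFamily("decoy", records_d),
        pairing=PairingTable(pairing_rows),
        clades=clades,
        truth=truth,
        config=config,
    )


def simulate_bundle(config: SimConfig) -> SimBundle:
    """Convenience: tree plus families from one config/seed."""
    tree = simulate_tree(
        config.n_organisms, config.birth_rate, seed=config.seed, depth=config.tree_depth
    )
    return simulate_families(tree, config)


# ---------------------------------------------------------------------------
# neutral codon fixtures for the dN/dS estimator


def simulate_neutral_codon_pairs(
    n_pairs: int,
    n_codons: int,
    divergence: float = 0.4,
    kappa: float = 2.0,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Codon-aligned pairs evolved without selection (true omega = 1).

    Each pair descends from a random sense-codon ancestor; both copies accrue
    ``divergence``/2 expected substitutions per nucleotide site under a
    kappa-biased mutation process.  Events creating a stop codon are rejected
    (unobservable in coding data), the only departure from strict neutrality.
    """
    rng = np.random.default_rng(seed)
    ts_partner = {"A": "G", "G": "A", "C": "T", "T": "C"}
    pairs = []
    for _ in range(n_pairs):
        anc = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=n_codons)]

        def _evolve(codons):
            out = list(codons)
            n_sites = 3 * len(out)
            n_events = rng.poisson(divergence / 2.0 * n_sites)
            for _ in range(n_events):
                pos = int(rng.integers(n_sites))
                ci, off = divmod(pos, 3)
                codon = out[ci]
                old = codon[off]
                # kappa-weighted target choice
                w = []
                for nt in NT:
                    if nt == old:
                        continue
                    w.append((nt, kappa if nt == ts_partner[old] else 1.0))
                probs = np.array([x[1] for x in w])
                probs /= probs.sum()
                new = w[int(rng.choice(len(w), p=probs))][0]
                cand = codon[:off] + new + codon[off + 1:]
                if cand in ("TAA", "TAG", "TGA"):
                    continue
                out[ci] = cand
            return "".join(out)

        pairs.append((_evolve(anc), _evolve(anc)))
    return pairs


# ---------------------------------------------------------------------------
# fixture bundle IO


def write_fixture_bundle(bundle: SimBundle, outdir: str | Path) -> dict:
    """Write the bundle as plain-text files re-readable by the io module."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fam_a": outdir / "famA.fasta",
        "fam_b": outdir / "famB.fasta",
        "marker": outdir / "marker.fasta",
        "decoy": outdir / "decoy.fasta",
        "tree": outdir / "tree.nwk",
        "pairing": outdir / "pairing.tsv",
        "clades": outdir / "clades.tsv",
        "organisms_a": outdir / "organisms_famA.tsv",
        "organisms_b": outdir / "organisms_famB.tsv",
        "organisms_decoy": outdir / "organisms_decoy.tsv",
        "truth": outdir / "truth.json",
    }
    write_alignment(bundle.fam_a, paths["fam_a"])
    write_alignment(bundle.fam_b, paths["fam_b"])
    write_alignment(bundle.marker, paths["marker"])
    write_alignment(bundle.decoy, paths["decoy"])
    write_tree(bundle.tree, paths["tree"])
    write_pairing(bundle.pairing, paths["pairing"])
    with open(paths["clades"], "w") as fh:
        for org in sorted(bundle.clades):
            fh.write(f"{org}\t{bundle.clades[org]}\n")
    for key, fam in (
        ("organisms_a", bundle.fam_a),
        ("organisms_b", bundle.fam_b),
        ("organisms_decoy", bundle.decoy),
    ):
        with open(paths[key], "w") as fh:
            for r in fam.records:
                fh.write(f"{r.seq_id}\t{r.organism_id}\n")
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "coupled_pairs": bundle.truth.coupled_pairs,
                "branch_multipliers": bundle.truth.branch_multipliers,
                "duplications": bundle.truth.duplications,
                "config": asdict(bundle.config),
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    return {k: str(v) for k, v in paths.items()}
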