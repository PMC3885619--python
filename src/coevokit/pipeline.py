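"""End-to-end pipeline: simulate/load -> distances -> mirrortree -> caps ->
cladespec -> ancstate, with a consolidated JSON + TSV report.

The config is a flat mapping (YAML-free by design; JSON or keyword dict).
All randomness flows from one master seed; stage seeds are derived from it
so stages stay reproducible independently.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ancstate, caps, cladespec, distances, mirrortree, synthetic
from .io import (
    AlignedFamily,
    PairingTable,
    RegionSet,
    read_alignment,
    read_clades,
    read_pairing,
    read_regions,
    read_tip_states,
    read_tree,
)

DEFAULTS = {
    "seed": 0,
    "n_perm": 999,
    "n_resample": 1000,
    "alpha": 0.05,
    "subst_matrix": "BLOSUM62",
    "correction": "residual",
    "clade_rule": "strict",
    "min_clade_size": 2,
}


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def _stage_seed(master: int, k: int) -> int:
    return int(np.random.SeedSequence([master, k]).generate_state(1)[0] % (2**31))


@dataclass
class RunReport:
    config: dict
    stages: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"config": self.config, "stages": self.stages},
                          indent=1, sort_keys=True, default=str)


def _atomic_write(text: str, path: Path) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name)
    with os.fdopen(fd, "w") as fh:
        fh.write(text)
    os.replace(tmp, path)


def run_pipeline(config: dict, outdir: str | Path | None = None) -> RunReport:
    """Execute all stages in order and return (and optionally write) a report.

    ``config`` either contains a ``simulate`` block (keywords for
    :class:`synthetic.SimConfig`) or input paths ``fam_a``/``fam_b``/
    ``pairing`` (+ optional ``marker``, ``tree``, ``clades``, ``regions``,
    ``tip_states``, ``organism_map_*``).  Any stage failure raises
    :class:`StageError` naming the stage.
    """
    cfg = {**DEFAULTS, **config}
    seed = int(cfg["seed"])
    report = RunReport(config=dict(cfg))
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    def _save(df: pd.DataFrame, name: str) -> None:
        if outdir is not None:
            df.to_csv(outdir / name, sep="\t", index=False)

    # ---- inputs -----------------------------------------------------------
    try:
        if "simulate" in cfg:
            sim_cfg = synthetic.SimConfig(**{**cfg["simulate"], "seed": seed})
            bundle = synthetic.simulate_bundle(sim_cfg)
            fam_a, fam_b = bundle.fam_a, bundle.fam_b
            marker, decoy = bundle.marker, bundle.decoy
            pairing, clades, tree = bundle.pairing, bundle.clades, bundle.tree
            tip_states = {org: 1 for org in clades}  # interaction present everywhere
            regions = None
            if outdir is not None:
                synthetic.write_fixture_bundle(bundle, outdir / "fixtures")
            report.stages["simulate"] = {
                "n_organisms": sim_cfg.n_organisms,
                "coupled_pairs": sim_cfg.coupled_pairs,
                "seed": seed,
            }
        else:
            fam_a = read_alignment(cfg["fam_a"], cfg.get("organism_map_a"))
            fam_b = read_alignment(cfg["fam_b"], cfg.get("organism_map_b"))
            pairing = read_pairing(cfg["pairing"])
            marker = read_alignment(cfg["marker"]) if cfg.get("marker") else None
            decoy = read_alignment(cfg["decoy"], cfg.get("organism_map_decoy")) if cfg.get("decoy") else None
            tree = read_tree(cfg["tree"]) if cfg.get("tree") else None
            clades = read_clades(cfg["clades"]) if cfg.get("clades") else None
            regions = read_regions(cfg["regions"]) if cfg.get("regions") else None
            tip_states = read_tip_states(cfg["tip_states"]) if cfg.get("tip_states") else None
        pairing.validate(fam_a, fam_b)
    except Exception as e:  # noqa: BLE001
        raise StageError("inputs", e) from e

    # ---- distances --------------------------------------------------------
    try:
        ident_a = distances.mean_pairwise_identity(fam_a)
        ident_b = distances.mean_pairwise_identity(fam_b)
        da = distances.poisson_distance(fam_a)
        db = distances.poisson_distance(fam_b)
        iu_a = np.triu_indices(len(da.ids), k=1)
        z, zp = distances.z_compare(da.values[iu_a],
                                    db.values[np.triu_indices(len(db.ids), k=1)])
        report.stages["distances"] = {
            "identity_pct_a": round(ident_a, 1),
            "identity_pct_b": round(ident_b, 1),
            "mean_distance_a": float(np.nanmean(da.values[iu_a])),
            "mean_distance_b": float(np.nanmean(db.values[np.triu_indices(len(db.ids), k=1)])),
            "z_distance_a_vs_b": round(z, 2),
            "z_p_approx": zp,
        }
        pair_rows = []
        for i, j in zip(*iu_a):
            pair_rows.append((da.ids[i], da.ids[j], da.values[i, j]))
        _save(pd.DataFrame(pair_rows, columns=["id_a", "id_b", "poisson_distance"]),
              "distances_famA.tsv")
    except Exception as e:  # noqa: BLE001
        raise StageError("distances", e) from e

    # ---- dN/dS (optional codon stage) -------------------------------------
    if cfg.get("codon_a") or cfg.get("neutral_codon_check"):
        try:
            if cfg.get("neutral_codon_check"):
                pairs = synthetic.simulate_neutral_codon_pairs(
                    n_pairs=20, n_codons=300, seed=_stage_seed(seed, 1)
                )
                omegas = [distances.dnds_pair(a, b).omega for a, b in pairs]
                omegas = [w for w in omegas if w is not None]
                report.stages["dnds"] = {
                    "mode": "neutral-simulation",
                    "mean_omega": float(np.mean(omegas)),
                    "n_pairs": len(omegas),
                }
            else:
                from .io import read_codon_alignment

                cod = read_codon_alignment(cfg["codon_a"])
                table = distances.dnds_family(cod)
                summ = distances.summarize_rates(table)
                report.stages["dnds"] = {
                    "mean_dn": summ.mean_dn,
                    "mean_ds": summ.mean_ds,
                    "mean_omega": summ.mean_omega,
                    "n_omega_undefined": summ.n_omega_undefined,
                }
                _save(table, "dnds_pairs.tsv")
        except Exception as e:  # noqa: BLE001
            raise StageError("dnds", e) from e
    else:
        report.stages["dnds"] = {"skipped": True}

    # ---- mirrortree -------------------------------------------------------
    try:
        mt = mirrortree.tol_mirrortree(
            fam_a, fam_b, pairing, marker=marker,
            n_perm=int(cfg["n_perm"]), seed=_stage_seed(seed, 2),
            correction=cfg["correction"],
        )
        report.stages["mirrortree"] = {
            "r_corrected": round(mt.corrected.r, 4),
            "r_uncorrected": round(mt.uncorrected.r, 4),
            "p": mt.corrected.p,
            "n_perm": mt.corrected.n_perm,
            "correction": mt.correction,
        }
        if decoy is not None:
            decoy_pairing = PairingTable([
                type(r)(r.organism_id, r.member_a,
                        decoy.organisms()[r.organism_id][0])
                for r in pairing.rows
            ])
            mt_decoy = mirrortree.tol_mirrortree(
                fam_a, decoy, decoy_pairing, marker=marker,
                n_perm=int(cfg["n_perm"]), seed=_stage_seed(seed, 3),
                correction=cfg["correction"],
            )
            report.stages["mirrortree"]["decoy_r_corrected"] = round(mt_decoy.corrected.r, 4)
            report.stages["mirrortree"]["decoy_p"] = mt_decoy.corrected.p
    except Exception as e:  # noqa: BLE001
        raise StageError("mirrortree", e) from e

    # ---- caps -------------------------------------------------------------
    try:
        mat = caps.load_substitution_matrix(cfg["subst_matrix"])
        mp_a = caps.matched_sequence_pairs(pairing, "A")
        mp_b = caps.matched_sequence_pairs(pairing, "B")
        prof_a = caps.site_profiles(fam_a, mp_a, mat)
        prof_b = caps.site_profiles(fam_b, mp_b, mat)
        corr = caps.intermolecular_correlations(prof_a, prof_b)
        sig = caps.significance_filter(
            corr, prof_a, prof_b, alpha=float(cfg["alpha"]),
            n_resample=int(cfg["n_resample"]), seed=_stage_seed(seed, 4),
        )
        groups = caps.build_groups(sig, prof_a, prof_b)
        res_a = sorted({s for g in groups for s in g.members_a})
        res_b = sorted({s for g in groups for s in g.members_b})
        report.stages["caps"] = {
            "n_site_pairs_tested": len(corr),
            "n_significant_pairs": len(sig),
            "n_groups": len(groups),
            "n_residues_a": len(res_a),
            "n_residues_b": len(res_b),
            "n_unique_residues": len(res_a) + len(res_b),
        }
        _save(pd.DataFrame(
            [(p.site_a, p.site_b, p.rho) for p in sig],
            columns=["site_a", "site_b", "rho"]), "caps_pairs.tsv")
        _save(pd.DataFrame(
            [(g.group_id, ";".join(map(str, g.members_a)),
              ";".join(map(str, g.members_b)), g.mean_rho, g.mean_dc)
             for g in groups],
            columns=["group_id", "members_a", "members_b", "mean_rho", "mean_dc"]),
            "caps_groups.tsv")
        if regions is not None:
            ref_a = cfg.get("reference_a", fam_a.seq_ids[0])
            ref_b = cfg.get("reference_b", fam_b.seq_ids[0])
            rr = caps.residue_region_report(groups, regions, fam_a, fam_b, ref_a, ref_b)
            report.stages["caps"]["region_report"] = rr.per_family.to_dict("records")
            _save(rr.per_family, "caps_regions.tsv")
    except Exception as e:  # noqa: BLE001
        raise StageError("caps", e) from e

    # ---- cladespec --------------------------------------------------------
    if clades:
        try:
            calls_a = cladespec.detect_clade_specific(
                fam_a, clades, rule=cfg["clade_rule"],
                min_clade_size=int(cfg["min_clade_size"]))
            calls_b = cladespec.detect_clade_specific(
                fam_b, clades, rule=cfg["clade_rule"],
                min_clade_size=int(cfg["min_clade_size"]))
            ov_a = cladespec.overlap_with_caps(calls_a, res_a, groups, family="A")
            ov_b = cladespec.overlap_with_caps(calls_b, res_b, groups, family="B")
            covered = sorted(set(ov_a.covered_groups) | set(ov_b.covered_groups))
            n_caps = len(res_a) + len(res_b)
            n_over = ov_a.n_overlap + ov_b.n_overlap
            report.stages["cladespec"] = {
                "n_calls_a": len(calls_a),
                "n_calls_b": len(calls_b),
                "n_overlap_a": ov_a.n_overlap,
                "n_overlap_b": ov_b.n_overlap,
                "pct_of_caps_residues": round(100.0 * n_over / n_caps, 2) if n_caps else 0.0,
                "covered_groups": covered,
                "pct_of_groups": round(100.0 * len(covered) / len(groups), 2) if groups else 0.0,
            }
            _save(cladespec.calls_to_frame(calls_a), "cladespec_famA.tsv")
            _save(cladespec.calls_to_frame(calls_b), "cladespec_famB.tsv")
        except Exception as e:  # noqa: BLE001
            raise StageError("cladespec", e) from e
    else:
        report.stages["cladespec"] = {"skipped": True}

    # ---- ancstate ---------------------------------------------------------
    if tree is not None and tip_states is not None:
        try:
            fr = ancstate.fitch_trace(tree, tip_states)
            mk = ancstate.mk2_marginal(tree, tip_states)
            root_name = next(iter(fr.node_states))
            report.stages["ancstate"] = {
                "fitch_root_states": sorted(fr.root_states),
                "fitch_changes": fr.n_changes,
                "mk2_root_posterior_state1": round(mk.posteriors[root_name], 4),
                "mk2_rate": mk.rate,
            }
        except Exception as e:  # noqa: BLE001
            raise StageError("ancstate", e) from e
    else:
        report.stages["ancstate"] = {"skipped": True}

    if outdir is not None:
        _atomic_write(report.to_json(), outdir / "report.json")
    return report
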