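"""Correlated-mutation detection between two interacting families (CAPS-style).

For each usable alignment column a transition profile is built over sequence
pairs: theta_k = B(a_i, a_j) / t_ij, the BLOSUM score of the residue pair in
sequences i and j normalized by their Poisson-corrected divergence.  Slowly
diverged pairs are thereby up-weighted: a drastic change between close
sequences carries more signal than the same change between distant ones.
Inter-family co-evolution of two sites is the Pearson correlation of their
mean-centered profiles over sequence pairs matched through the organism
pairing; significance comes from a shuffled-profile null, and significant
pairs are grouped by connectivity.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .distances import poisson_distance
from .io import (
    GAP_CHARS,
    UNKNOWN_CHARS,
    AlignedFamily,
    PairingTable,
    Region,
    RegionSet,
    column_to_reference,
)


def load_substitution_matrix(name: str = "BLOSUM62"):
    return substitution_matrices.load(name)


@dataclass
class SiteProfileSet:
    """Normalized transition profiles for one family.

    ``theta`` is (n_sites, n_seq_pairs) with NaN where a site is unusable for
    a pair (gap/unknown in either sequence).  ``columns`` are 1-based
    alignment columns; ``seq_pairs`` the (id_i, id_j) pairs in order.
    """

    family_name: str
    columns: list[int]
    seq_pairs: list[tuple[str, str]]
    theta: np.ndarray
    _resid: np.ndarray | None = None

    def site_variance(self) -> np.ndarray:
        """Per-site variance of theta (the Dc ingredient)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanvar(self.theta, axis=1)

    def residual_theta(self) -> np.ndarray:
        """Profiles with the family's shared divergence background removed.

        Every site's raw profile contains a large common component — roughly
        (diagonal substitution score)/t_ij — that correlates any two sites at
        ~0.6 regardless of co-evolution.  Each site's profile is therefore
        regressed on the family's mean profile (the mean variability per
        sequence pair) and replaced by its residuals, so correlations measure
        site-specific co-variation only.  With fewer than 3 sites the
        background is not estimable and raw profiles are returned.
        """
        if self._resid is not None:
            return self._resid
        theta = self.theta
        if theta.shape[0] < 3:
            self._resid = theta
            return theta
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = np.nanmean(theta, axis=0)
        out = np.full_like(theta, np.nan)
        for i in range(theta.shape[0]):
            x = theta[i]
            mask = ~np.isnan(x) & ~np.isnan(m)
            if mask.sum() < 3:
                continue
            mm, xx = m[mask], x[mask]
            mc = mm - mm.mean()
            denom = mc @ mc
            beta = ((xx - xx.mean()) @ mc) / denom if denom > 0 else 0.0
            out[i, mask] = xx - beta * mm
        self._resid = out
        return out


def site_profiles(
    fam: AlignedFamily,
    matched_pairs: list[tuple[str, str]],
    subst_matrix=None,
    max_gap_fraction: float = 0.5,
) -> SiteProfileSet:
    """Build theta profiles for every usable, non-constant column.

    Columns constant across all sequences carry no variance and are excluded,
    as are columns whose gap/unknown fraction exceeds ``max_gap_fraction``.
    Sequence pairs with zero divergence (identical sequences, or differing
    sequences at zero Poisson distance, which draws a warning) keep their
    position in the pair index but contribute NaN, so profiles of the two
    families built from the same pairing combinations stay index-aligned.
    """
    if subst_matrix is None:
        subst_matrix = load_substitution_matrix()
    dist = poisson_distance(fam)
    idx = {s: k for k, s in enumerate(fam.seq_ids)}
    seqs = [r.residues.upper() for r in fam.records]

    usable_pairs = []
    for (a, b) in matched_pairs:
        t = dist.values[idx[a], idx[b]]
        if t == 0:
            if seqs[idx[a]] != seqs[idx[b]]:
                warnings.warn(f"pair ({a}, {b}): zero divergence, excluded")
            t = np.nan  # keeps index alignment; theta stays NaN for this pair
        usable_pairs.append((a, b, t))

    skip = GAP_CHARS | UNKNOWN_CHARS
    n_seq = len(seqs)
    columns, profiles = [], []
    for col in range(fam.n_cols):
        chars = [s[col] for s in seqs]
        present = [c for c in chars if c not in skip]
        if len(present) < n_seq * (1.0 - max_gap_fraction):
            continue
        if len(set(present)) <= 1:
            continue  # constant column: no variance to correlate
        theta = np.full(len(usable_pairs), np.nan)
        for k, (a, b, t) in enumerate(usable_pairs):
            if not np.isfinite(t):
                continue
            ca, cb = seqs[idx[a]][col], seqs[idx[b]][col]
            if ca in skip or cb in skip:
                continue
            theta[k] = float(subst_matrix[ca, cb]) / t
        columns.append(col + 1)
        profiles.append(theta)
    theta_mat = np.array(profiles) if profiles else np.empty((0, len(usable_pairs)))
    return SiteProfileSet(
        fam.family_name, columns, [(a, b) for a, b, _ in usable_pairs], theta_mat
    )


def matched_sequence_pairs(pairing: PairingTable, family: str) -> list[tuple[str, str]]:
    """Sequence pairs for one family induced by pairing-row combinations.

    Pair k for family A corresponds to pair k for family B: both come from the
    same unordered combination of pairing rows.  Combinations whose two rows
    share the member for this family are kept (the partner family may still
    differ there); such zero-divergence pairs yield NaN profile entries and
    drop out of the correlations pairwise.
    """
    members = [getattr(r, "member_a" if family == "A" else "member_b") for r in pairing.rows]
    return [
        (members[i], members[j])
        for i, j in itertools.combinations(range(len(members)), 2)
    ]


def _row_corr_nan(A: np.ndarray, B: np.ndarray, min_shared: int = 3):
    """Pearson correlation of every row of A with every row of B.

    Handles NaNs pairwise; entries with fewer than ``min_shared`` shared
    usable values, or zero variance, are NaN.  Fast dense path when neither
    matrix has NaNs.
    """
    if not (np.isnan(A).any() or np.isnan(B).any()):
        Ac = A - A.mean(axis=1, keepdims=True)
        Bc = B - B.mean(axis=1, keepdims=True)
        na = np.linalg.norm(Ac, axis=1)
        nb = np.linalg.norm(Bc, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            R = (Ac @ Bc.T) / np.outer(na, nb)
        R[:, nb == 0] = np.nan
        R[na == 0, :] = np.nan
        if A.shape[1] < min_shared:
            R[:] = np.nan
        return R
    R = np.full((A.shape[0], B.shape[0]), np.nan)
    for i in range(A.shape[0]):
        for j in range(B.shape[0]):
            mask = ~np.isnan(A[i]) & ~np.isnan(B[j])
            if mask.sum() < min_shared:
                continue
            x, y = A[i, mask], B[j, mask]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            R[i, j] = np.corrcoef(x, y)[0, 1]
    return R


@dataclass
class CorrelatedPair:
    site_a: int  # 1-based alignment column in family A
    site_b: int
    rho: float
    significant: bool = False


def intermolecular_correlations(
    prof_a: SiteProfileSet,
    prof_b: SiteProfileSet,
    min_shared: int = 3,
) -> list[CorrelatedPair]:
    """Correlate every family-A site profile with every family-B profile.

    Profiles must be built over the same ordered sequence-pair index (both
    from :func:`matched_sequence_pairs` of one pairing table).  Correlations
    use the background-residualized profiles (see
    :meth:`SiteProfileSet.residual_theta`).  Degenerate pairs (too few shared
    entries or zero variance) are skipped.
    """
    if len(prof_a.seq_pairs) != len(prof_b.seq_pairs):
        raise ValueError("profiles built over different sequence-pair indices")
    R = _row_corr_nan(prof_a.residual_theta(), prof_b.residual_theta(), min_shared)
    out = []
    for i, ca in enumerate(prof_a.columns):
        for j, cb in enumerate(prof_b.columns):
            if np.isfinite(R[i, j]):
                out.append(CorrelatedPair(ca, cb, float(R[i, j])))
    return out


def significance_filter(
    pairs: list[CorrelatedPair],
    prof_a: SiteProfileSet,
    prof_b: SiteProfileSet,
    alpha: float = 0.05,
    n_resample: int = 1000,
    seed: int | None = None,
) -> list[CorrelatedPair]:
    """Mark pairs whose rho exceeds the (1 - alpha) quantile of a null.

    The null shuffles one family's site labels: it draws random (site_A,
    site_B) re-pairings and correlates their profiles, which preserves the
    strong background correlation all profiles share through the common
    divergence times while destroying any site-specific coupling.  A pair is
    significant only when its rho exceeds what random site pairings reach.
    """
    if not pairs:
        raise ValueError("no correlation pairs supplied")
    if n_resample < 100:
        raise ValueError("n_resample must be >= 100")
    rng = np.random.default_rng(seed)
    ra, rb = prof_a.residual_theta(), prof_b.residual_theta()
    na, nb = ra.shape[0], rb.shape[0]
    null = np.full(n_resample, np.nan)
    k = 0
    attempts = 0
    while k < n_resample and attempts < 20 * n_resample:
        attempts += 1
        i = rng.integers(na)
        j = rng.integers(nb)
        x = ra[i]
        y = rb[j]
        mask = ~np.isnan(x) & ~np.isnan(y)
        if mask.sum() < 3:
            continue
        xv, yv = x[mask], y[mask]
        if np.ptp(xv) == 0 or np.ptp(yv) == 0:
            continue
        null[k] = np.corrcoef(xv, yv)[0, 1]
        k += 1
    null = null[:k]
    if k < 100:
        raise ValueError("could not build null distribution (degenerate profiles)")
    threshold = float(np.quantile(null, 1.0 - alpha))
    out = []
    for p in pairs:
        out.append(CorrelatedPair(p.site_a, p.site_b, p.rho, p.rho > threshold))
    return [p for p in out if p.significant]


@dataclass
class CoevolutionGroup:
    group_id: str
    members_a: list[int]  # family-A sites (alignment columns)
    members_b: list[int]
    pairs: list[CorrelatedPair]
    mean_rho: float
    mean_dc: float


def build_groups(
    pairs: list[CorrelatedPair],
    prof_a: SiteProfileSet | None = None,
    prof_b: SiteProfileSet | None = None,
) -> list[CoevolutionGroup]:
    """Connected components of the bipartite significant-site graph.

    Groups are numbered G1..Gn deterministically by smallest family-A member
    site (then family-B).  mean_dc is the mean per-site variance of theta over
    member sites when profiles are supplied, else NaN.
    """
    parent: dict = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent.setdefault(x, x)
        parent.setdefault(y, y)
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for p in pairs:
        union(("A", p.site_a), ("B", p.site_b))
    comps: dict = {}
    for p in pairs:
        comps.setdefault(find(("A", p.site_a)), []).append(p)

    var_a = dict(zip(prof_a.columns, prof_a.site_variance())) if prof_a else {}
    var_b = dict(zip(prof_b.columns, prof_b.site_variance())) if prof_b else {}

    groups = []
    for plist in comps.values():
        ma = sorted({p.site_a for p in plist})
        mb = sorted({p.site_b for p in plist})
        dcs = [var_a[s] for s in ma if s in var_a] + [var_b[s] for s in mb if s in var_b]
        groups.append(
            CoevolutionGroup(
                "",
                ma,
                mb,
                sorted(plist, key=lambda p: (p.site_a, p.site_b)),
                float(np.mean([p.rho for p in plist])),
                float(np.mean(dcs)) if dcs else float("nan"),
            )
        )
    groups.sort(key=lambda g: (g.members_a[0], g.members_b[0]))
    for k, g in enumerate(groups, start=1):
        g.group_id = f"G{k}"
    return groups


# ---------------------------------------------------------------------------
# region overlap reporting


@dataclass
class RegionReport:
    per_family: pd.DataFrame  # family, n_residues, region, n_in_region, pct
    group_classes: pd.DataFrame  # group_id, class (both-domain/one-domain/neither)
    residues: pd.DataFrame  # family, residue, in_region flags, conserved flag


def _to_reference(fam: AlignedFamily, ref_id: str, cols: list[int]) -> dict[int, int]:
    """alignment column -> reference residue (gap columns dropped)."""
    out = {}
    for c in cols:
        r = column_to_reference(fam, ref_id, c)
        if r != -1:
            out[c] = r
    return out


def _is_conserved(fam: AlignedFamily, col: int) -> bool:
    skip = GAP_CHARS | UNKNOWN_CHARS
    chars = {s.residues.upper()[col - 1] for s in fam.records}
    return len(chars - skip) <= 1


def residue_region_report(
    groups: list[CoevolutionGroup],
    regions: RegionSet,
    fam_a: AlignedFamily,
    fam_b: AlignedFamily,
    ref_a: str,
    ref_b: str,
) -> RegionReport:
    """Overlap of correlated residues with named regions (core/RBD/MID).

    Residue numbering follows each family's reference sequence.  A group is
    'both-domain' when it has at least one member inside a region of each
    family, 'one-domain' when only one family's members hit a region, else
    'neither'.  A residue is 'conserved' when its alignment column is constant.
    """
    sites_a = sorted({s for g in groups for s in g.members_a})
    sites_b = sorted({s for g in groups for s in g.members_b})
    map_a = _to_reference(fam_a, ref_a, sites_a)
    map_b = _to_reference(fam_b, ref_b, sites_b)
    regions_a = [r for r in regions.entries if r.reference_seq_id == ref_a]
    regions_b = [r for r in regions.entries if r.reference_seq_id == ref_b]

    res_rows = []
    for fam, ref_map, regs, label in (
        (fam_a, map_a, regions_a, "A"),
        (fam_b, map_b, regions_b, "B"),
    ):
        for col, res in ref_map.items():
            row = {
                "family": label,
                "column": col,
                "residue": res,
                "conserved": _is_conserved(fam, col),
            }
            for reg in regs:
                row[f"in_{reg.region_name}"] = reg.contains(res)
            res_rows.append(row)
    residues = pd.DataFrame(res_rows)

    fam_rows = []
    for label, ref_map, regs in (("A", map_a, regions_a), ("B", map_b, regions_b)):
        vals = list(ref_map.values())
        for reg in regs:
            n_in = sum(reg.contains(v) for v in vals)
            fam_rows.append(
                {
                    "family": label,
                    "n_residues": len(vals),
                    "region": reg.region_name,
                    "n_in_region": n_in,
                    "pct_in_region": round(100.0 * n_in / len(vals), 1) if vals else 0.0,
                }
            )
    per_family = pd.DataFrame(fam_rows)

    grp_rows = []
    for g in groups:
        hit_a = any(
            reg.contains(map_a[s]) for s in g.members_a if s in map_a for reg in regions_a
        ) if regions_a else False
        hit_b = any(
            reg.contains(map_b[s]) for s in g.members_b if s in map_b for reg in regions_b
        ) if regions_b else False
        cls = "both-domain" if hit_a and hit_b else ("one-domain" if hit_a or hit_b else "neither")
        grp_rows.append({"group_id": g.group_id, "class": cls})
    group_classes = pd.DataFrame(grp_rows)
    return RegionReport(per_family, group_classes, residues)


def region_overlap_counts(residues: list[int], region: Region) -> tuple[int, int, float]:
    """(n_in_region, n_total, percent) for a plain residue list.

    Percent is rounded to one decimal, matching the reporting convention
    36/46 = 78.3.
    """
    n_in = sum(region.contains(r) for r in residues)
    n = len(residues)
    pct = round(100.0 * n_in / n, 1) if n else 0.0
    return n_in, n, pct
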