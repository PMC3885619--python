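"""Pairwise evolutionary distances and rate/selection summaries.

Implements the amino-acid p-distance with pairwise or complete deletion,
Poisson correction d = -ln(1 - p), percent identity, the Kimura two-parameter
(K2P) nucleotide distance, a modified Nei-Gojobori dN/dS estimator with
K2P-style correction applied separately to the synonymous and nonsynonymous
difference proportions, and a two-sample Z comparison of family means.

Gap and unknown symbols are removed pairwise by default; a pair with no
comparable column is flagged missing rather than reported as zero.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import AA20, GAP_CHARS, UNKNOWN_CHARS, AlignedFamily, CodonFamily, STOP_CODONS

PURINES = set("AG")
PYRIMIDINES = set("CT")

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


class SaturationError(ValueError):
    """A distance correction's log argument was non-positive."""


def is_transition(a: str, b: str) -> bool:
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with missing-pair flags."""

    ids: list[str]
    values: np.ndarray
    method: str = "p-distance"
    deletion: str = "pairwise"
    missing: np.ndarray | None = None  # boolean mask of incomparable pairs

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix not symmetric")
        if self.missing is None:
            self.missing = np.zeros((n, n), dtype=bool)

    def get(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def _comparable_mask(arrs: np.ndarray) -> np.ndarray:
    """Boolean (n_seq, n_col) mask of residues that are neither gap nor unknown."""
    drop = GAP_CHARS | UNKNOWN_CHARS
    bad = np.isin(arrs, sorted(drop))
    return ~bad


def _seq_array(fam: AlignedFamily) -> np.ndarray:
    return np.array([list(r.residues.upper()) for r in fam.records])


def p_distance(fam: AlignedFamily, mode: str = "pairwise") -> DistanceMatrix:
    """Proportion of differing residues over mutually comparable columns.

    ``mode``: 'pairwise' (drop gap/unknown per pair) or 'complete' (drop any
    column with a gap/unknown in any sequence before comparing).
    """
    if len(fam.records) < 2:
        raise ValueError("need at least 2 sequences")
    arr = _seq_array(fam)
    ok = _comparable_mask(arr)
    if mode == "complete":
        keep = ok.all(axis=0)
        arr, ok = arr[:, keep], ok[:, keep]
    elif mode != "pairwise":
        raise ValueError(f"unknown deletion mode {mode!r}")
    n = arr.shape[0]
    vals = np.zeros((n, n))
    missing = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            m = int(both.sum())
            if m == 0:
                missing[i, j] = missing[j, i] = True
                vals[i, j] = vals[j, i] = np.nan
                continue
            diff = int((arr[i, both] != arr[j, both]).sum())
            vals[i, j] = vals[j, i] = diff / m
    return DistanceMatrix(fam.seq_ids, vals, "p-distance", mode, missing)


def poisson_correct(p):
    """Poisson-corrected amino-acid distance, d = -ln(1 - p)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) & ~np.isnan(p)):
        raise ValueError("p must be non-negative")
    if np.any(p >= 1):
        raise SaturationError("p >= 1: Poisson correction saturated")
    d = -np.log1p(-p)
    return float(d) if d.ndim == 0 else d


def poisson_distance(fam: AlignedFamily, mode: str = "pairwise") -> DistanceMatrix:
    pd_ = p_distance(fam, mode)
    vals = pd_.values.copy()
    off = ~np.eye(len(pd_.ids), dtype=bool)
    with np.errstate(invalid="ignore"):
        sat = (vals >= 1) & off
    if sat.any():
        raise SaturationError("saturated pair(s) in Poisson correction")
    vals[off & ~pd_.missing] = -np.log1p(-vals[off & ~pd_.missing])
    return DistanceMatrix(pd_.ids, vals, "poisson", mode, pd_.missing)


def mean_pairwise_identity(fam: AlignedFamily, mode: str = "pairwise") -> float:
    """Mean percent identity over all unordered sequence pairs."""
    dm = p_distance(fam, mode)
    iu = np.triu_indices(len(dm.ids), k=1)
    vals = dm.values[iu]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no comparable pairs")
    return float((1.0 - vals).mean() * 100.0)


# ---------------------------------------------------------------------------
# nucleotide distances


def count_transitions_transversions(a: str, b: str) -> tuple[int, int, int]:
    """(n_compared, transitions, transversions) over pairwise-deletion sites."""
    drop = GAP_CHARS | {"N", "?"}
    n = ts = tv = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in drop or y in drop:
            continue
        n += 1
        if x != y:
            if is_transition(x, y):
                ts += 1
            else:
                tv += 1
    return n, ts, tv


def kimura2p_from_pq(P: float, Q: float) -> float:
    """K2P distance d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"K2P saturated (P={P:.4f}, Q={Q:.4f})")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def kimura2p_pair(a: str, b: str) -> float:
    n, ts, tv = count_transitions_transversions(a, b)
    if n == 0:
        raise ValueError("no comparable sites")
    return kimura2p_from_pq(ts / n, tv / n)


def kimura2p_matrix(fam: AlignedFamily) -> DistanceMatrix:
    n = len(fam.records)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = kimura2p_pair(fam.records[i].residues, fam.records[j].residues)
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(fam.seq_ids, vals, "kimura2p", "pairwise")


# ---------------------------------------------------------------------------
# modified Nei-Gojobori dN/dS with K2P correction


def _codon_sites(codon: str, kappa: float) -> tuple[float, float]:
    """Weighted (synonymous, nonsynonymous) site counts for one codon.

    Each possible single-nucleotide change is weighted kappa if it is a
    transition, 1 if a transversion; changes to stop codons are excluded from
    the weighting (mutations to stops are not observable in the data).
    """
    aa = _CODON_TABLE[codon]
    s = nsites = 0.0
    for pos in range(3):
        wsum = syn = 0.0
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1:]
            if _CODON_TABLE[mut] == "*":
                continue
            w = kappa if is_transition(codon[pos], alt) else 1.0
            wsum += w
            if _CODON_TABLE[mut] == aa:
                syn += w
        if wsum > 0:
            s += syn / wsum
            nsites += 1.0 - syn / wsum
    return s, nsites


def _path_differences(c1: str, c2: str) -> tuple[float, float, float, float]:
    """Average (syn_ts, syn_tv, nonsyn_ts, nonsyn_tv) difference counts.

    All shortest mutational paths between the codons are enumerated and
    averaged with equal weights; paths passing through a stop codon are
    discarded unless every path does.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0, 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        steps = []
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            syn = _CODON_TABLE[cur] == _CODON_TABLE[nxt]
            ts = is_transition(cur[pos], c2[pos])
            if _CODON_TABLE[nxt] == "*":
                through_stop = True
            steps.append((syn, ts))
            cur = nxt
        paths.append((through_stop, steps))
    usable = [p for stop, p in paths if not stop] or [p for _, p in paths]
    sts = stv = nts = ntv = 0.0
    for steps in usable:
        for syn, ts in steps:
            if syn and ts:
                sts += 1
            elif syn:
                stv += 1
            elif ts:
                nts += 1
            else:
                ntv += 1
    k = len(usable)
    return sts / k, stv / k, nts / k, ntv / k


def _estimate_kappa(a: str, b: str) -> float:
    """Transition/transversion rate ratio R = alpha/(2*beta) from K2P."""
    n, ts, tv = count_transitions_transversions(a, b)
    if n == 0 or tv == 0:
        return 1.0
    P, Q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return 1.0
    alpha = -0.5 * math.log(w1) + 0.25 * math.log(w2)
    beta = -0.25 * math.log(w2)
    if beta <= 0 or alpha <= 0:
        return 1.0
    return alpha / (2.0 * beta)


@dataclass
class PairRates:
    dn: float
    ds: float
    omega: float | None  # None when dS == 0 or saturated
    s_sites: float
    n_sites: float
    ds_saturated: bool = False


def dnds_pair(
    a: str,
    b: str,
    kappa: float | None = None,
    correction: str = "k2p",
) -> PairRates:
    """Modified Nei-Gojobori dN/dS for one codon-aligned pair.

    Site counts weight transitions by ``kappa`` (estimated from the pair via
    K2P when None); differences are averaged over equally weighted shortest
    substitution paths.  ``correction`` is 'k2p' (K2P-style correction applied
    separately to the synonymous and nonsynonymous transition/transversion
    proportions), 'jc' (Jukes-Cantor on the pooled proportions, the plain
    NG86 correction) or 'none'.
    """
    a, b = a.upper(), b.upper()
    if len(a) != len(b) or len(a) % 3:
        raise ValueError("sequences must be codon-aligned with equal length")
    if kappa is None:
        kappa = _estimate_kappa(a, b) if correction == "k2p" else 1.0
    S = N = 0.0
    sts = stv = nts = ntv = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if any(c in GAP_CHARS or c == "N" for c in ca + cb):
            continue
        if _CODON_TABLE[ca] == "*" or _CODON_TABLE[cb] == "*":
            continue
        s1, n1 = _codon_sites(ca, kappa)
        s2, n2 = _codon_sites(cb, kappa)
        S += (s1 + s2) / 2.0
        N += (n1 + n2) / 2.0
        d = _path_differences(ca, cb)
        sts += d[0]
        stv += d[1]
        nts += d[2]
        ntv += d[3]
    if S == 0 or N == 0:
        raise ValueError("no countable codons")

    def _correct(ts_d: float, tv_d: float, sites: float) -> float:
        P, Q = ts_d / sites, tv_d / sites
        if correction == "none":
            return P + Q
        if correction == "jc":
            p = P + Q
            if p >= 0.75:
                raise SaturationError("JC correction saturated")
            return -0.75 * math.log(1.0 - 4.0 * p / 3.0)
        return kimura2p_from_pq(P, Q)

    dn = _correct(nts, ntv, N)
    try:
        ds = _correct(sts, stv, S)
    except SaturationError:
        return PairRates(dn, float("nan"), None, S, N, ds_saturated=True)
    omega = dn / ds if ds > 0 else None
    return PairRates(dn, ds, omega, S, N)


def dnds_family(
    fam: CodonFamily, kappa: float | None = None, correction: str = "k2p"
) -> pd.DataFrame:
    """All-pairs dN/dS table with columns id_a, id_b, dn, ds, omega."""
    rows = []
    for (ra, rb) in itertools.combinations(fam.records, 2):
        r = dnds_pair(ra.residues, rb.residues, kappa=kappa, correction=correction)
        rows.append((ra.seq_id, rb.seq_id, r.dn, r.ds, r.omega))
    return pd.DataFrame(rows, columns=["id_a", "id_b", "dn", "ds", "omega"])


@dataclass
class RateSummary:
    pairs: pd.DataFrame
    mean_dn: float
    mean_ds: float
    mean_omega: float | None
    n_omega_undefined: int


def summarize_rates(pairs: pd.DataFrame) -> RateSummary:
    """Family means; pairs with undefined omega are excluded and counted."""
    omega = pairs["omega"].dropna()
    return RateSummary(
        pairs=pairs,
        mean_dn=float(pairs["dn"].mean()),
        mean_ds=float(pairs["ds"].mean()),
        mean_omega=float(omega.mean()) if len(omega) else None,
        n_omega_undefined=int(pairs["omega"].isna().sum()),
    )


# ---------------------------------------------------------------------------
# two-sample comparison


def z_compare(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample Z on means with per-sample standard errors.

    Pairwise distances are not independent, so the returned normal-tail
    p-value is approximate and should be read as descriptive.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 values")
    se2 = a.var(ddof=1) / a.size + b.var(ddof=1) / b.size
    if se2 == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    z = (a.mean() - b.mean()) / math.sqrt(se2)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)
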