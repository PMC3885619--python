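"""Tol-MirrorTree: distance-matrix correlation between two interacting
protein families, with the shared speciation signal removed using a neutral
marker (an 18S rRNA analog) and significance from a Mantel permutation test.

Paralogs are handled by expanding the pairing table: an organism with m
members of family A and n of family B contributes m*n index rows, so each
family's matrix may contain the same sequence more than once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distances import DistanceMatrix, poisson_distance
from .io import AlignedFamily, CrossReferenceError, PairingTable


@dataclass
class PairedDistanceMatrices:
    """Index-aligned distance matrices for the two families (and marker)."""

    pair_index: list  # list of PairingRow
    X: np.ndarray  # family A distances, one row/col per pairing row
    Y: np.ndarray  # family B distances
    S: np.ndarray | None = None  # neutral-marker distances, keyed by organism

    @property
    def n(self) -> int:
        return len(self.pair_index)


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int | None
    alternative: str = "greater"


def build_paired_matrices(
    dist_a: DistanceMatrix,
    dist_b: DistanceMatrix,
    pairing: PairingTable,
    marker: DistanceMatrix | None = None,
) -> PairedDistanceMatrices:
    """Expand two family distance matrices over the pairing rows.

    Row order follows the pairing table.  ``marker`` is keyed by organism id;
    its same-organism entries are zero by construction.
    """
    ia = {s: k for k, s in enumerate(dist_a.ids)}
    ib = {s: k for k, s in enumerate(dist_b.ids)}
    for row in pairing.rows:
        if row.member_a not in ia:
            raise CrossReferenceError(f"{row.member_a} not in family-A matrix")
        if row.member_b not in ib:
            raise CrossReferenceError(f"{row.member_b} not in family-B matrix")
    rows = pairing.rows
    ka = [ia[r.member_a] for r in rows]
    kb = [ib[r.member_b] for r in rows]
    X = dist_a.values[np.ix_(ka, ka)]
    Y = dist_b.values[np.ix_(kb, kb)]
    S = None
    if marker is not None:
        im = {s: k for k, s in enumerate(marker.ids)}
        for row in rows:
            if row.organism_id not in im:
                raise CrossReferenceError(f"{row.organism_id} not in marker matrix")
        km = [im[r.organism_id] for r in rows]
        S = marker.values[np.ix_(km, km)]
    return PairedDistanceMatrices(list(rows), X.copy(), Y.copy(), S)


def _offdiag(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def speciation_correct(
    pdm: PairedDistanceMatrices, method: str = "residual"
) -> tuple[np.ndarray, np.ndarray]:
    """Remove the speciation signal estimated from the neutral marker.

    'residual' (default) subtracts beta*S where beta is the least-squares
    slope of the family distances on the marker distances over off-diagonal
    cells; 'subtract' removes S element-wise.  Cells with S = 0 (same-organism
    paralog pairs) pass through unchanged in both modes.
    """
    if pdm.S is None:
        raise ValueError("no marker matrix present")
    s = _offdiag(pdm.S)
    if np.ptp(s) == 0:
        import warnings

        warnings.warn("marker distances constant; speciation correction skipped")
        return pdm.X.copy(), pdm.Y.copy()

    def _correct(M: np.ndarray) -> np.ndarray:
        if method == "subtract":
            return M - pdm.S
        m = _offdiag(M)
        sc = s - s.mean()
        beta = ((m - m.mean()) @ sc) / (sc @ sc)
        out = M - beta * pdm.S
        np.fill_diagonal(out, 0.0)
        return out

    return _correct(pdm.X), _correct(pdm.Y)


def mantel_test(
    X: np.ndarray,
    Y: np.ndarray,
    n_perm: int = 9999,
    seed: int | None = None,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel permutation test on two index-aligned symmetric matrices.

    R is the Pearson correlation of the off-diagonal upper-triangle cells;
    the null is built by jointly permuting the row/column labels of Y.
    p = (1 + #{perm >= observed}) / (1 + n_perm), one-sided for positive
    association by default ('two-sided' compares |R|).
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape != Y.shape or X.shape[0] != X.shape[1]:
        raise ValueError("matrices must be square and of identical shape")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    n = X.shape[0]
    iu = np.triu_indices(n, k=1)
    x, y = X[iu], Y[iu]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a matrix; R undefined")
    xc = x - x.mean()
    xn = xc / np.linalg.norm(xc)
    yc = y - y.mean()
    r_obs = float(xn @ (yc / np.linalg.norm(yc)))
    rng = np.random.default_rng(seed)
    # vectorized null: all label permutations applied to Y at once
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    yp = Y[perms[:, :, None], perms[:, None, :]][:, iu[0], iu[1]]
    yp = yp - yp.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(yp, axis=1)
    r_null = (yp @ xn) / norms
    if alternative == "two-sided":
        count = int(np.sum(np.abs(r_null) >= abs(r_obs)))
    else:
        count = int(np.sum(r_null >= r_obs))
    p = (1 + count) / (1 + n_perm)
    return MantelResult(r_obs, p, n_perm, seed, alternative)


@dataclass
class TolMirrorTreeResult:
    corrected: MantelResult
    uncorrected: MantelResult
    pdm: PairedDistanceMatrices
    correction: str


def tol_mirrortree(
    fam_a: AlignedFamily,
    fam_b: AlignedFamily,
    pairing: PairingTable,
    marker: AlignedFamily | None = None,
    marker_distances: DistanceMatrix | None = None,
    n_perm: int = 9999,
    seed: int | None = None,
    correction: str = "residual",
    alternative: str = "greater",
) -> TolMirrorTreeResult:
    """End-to-end Tol-MirrorTree for two families and an optional marker.

    Family distances are Poisson-corrected p-distances (pairwise deletion);
    marker distances are K2P (computed here from ``marker`` unless
    ``marker_distances`` is supplied pre-keyed by organism id).
    """
    pairing.validate(fam_a, fam_b)
    da = poisson_distance(fam_a)
    db = poisson_distance(fam_b)
    dm = marker_distances
    if dm is None and marker is not None:
        from .distances import kimura2p_matrix

        km = kimura2p_matrix(marker)
        # marker sequences are one per organism; key by organism label
        org_ids = [r.organism_id for r in marker.records]
        dm = DistanceMatrix(org_ids, km.values, km.method, km.deletion)
    pdm = build_paired_matrices(da, db, pairing, dm)
    uncorrected = mantel_test(pdm.X, pdm.Y, n_perm, seed, alternative)
    if pdm.S is not None:
        Xc, Yc = speciation_correct(pdm, method=correction)
        corrected = mantel_test(Xc, Yc, n_perm, seed, alternative)
    else:
        corrected = uncorrected
    return TolMirrorTreeResult(corrected, uncorrected, pdm, correction)
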