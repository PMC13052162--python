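"""Interspecific community statistics: richness, Jaccard, PCoA, ANOSIM, Mantel.

All dissimilarities are computed on basin-level presence/absence. Permutation
tests are seeded and use the (1 + exceedances) / (1 + permutations) p-value
convention; the observed configuration is never drawn as a permutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .asv_filtering import ASVRecord, CommunityMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# dissimilarity and ordination
# ---------------------------------------------------------------------------

def highest_assigned_taxon(record: ASVRecord) -> str | None:
    """Deepest non-empty rank; None unless assigned at family level or deeper."""
    for name in reversed(record.taxon_path):
        if name.strip():
            break
    else:
        return None
    if not record.has_family_or_deeper:
        return None
    return name.strip()


def taxon_presence(community: CommunityMatrix, records: list[ASVRecord]) -> pd.DataFrame:
    """Collapse the ASV presence matrix to highest-assigned-taxon presence
    (taxa below family level are dropped)."""
    taxon_of = {
        r.asv_id: highest_assigned_taxon(r)
        for r in records
        if r.asv_id in community.presence.columns
    }
    cols = {a: t for a, t in taxon_of.items() if t is not None}
    sub = community.presence[list(cols)]
    return sub.T.groupby(pd.Series(cols)).any().T


def jaccard(presence: pd.DataFrame | CommunityMatrix) -> pd.DataFrame:
    """Jaccard dissimilarity 1 - |A∩B| / |A∪B| between basin presence sets.

    A pair of empty basins has dissimilarity 0 (with a warning).
    """
    P = (presence.presence if isinstance(presence, CommunityMatrix) else presence)
    labels = list(P.index)
    M = P.to_numpy(dtype=float)
    inter = M @ M.T
    sizes = M.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    if (sizes == 0).any():
        logger.warning("empty basins present: their Jaccard entries default to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(union > 0, 1.0 - inter / union, 0.0)
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=labels, columns=labels)


@dataclass
class OrdinationResult:
    labels: list[str]
    coordinates: pd.DataFrame   # labels x axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray     # positive eigenvalues, descending
    negative_eigenvalues: np.ndarray


def pcoa(D: pd.DataFrame) -> OrdinationResult:
    """Classical metric multidimensional scaling (principal coordinates).

    -D²/2 is double-centred and eigendecomposed; only positive-eigenvalue axes
    are returned, scaled by the square root of their eigenvalue. Axis signs are
    fixed by making each axis's largest-magnitude loading positive. Negative
    eigenvalues are dropped but reported for inspection.
    """
    labels = list(D.index)
    A = D.to_numpy(dtype=float)
    n = len(labels)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (A ** 2) @ J
    B = (B + B.T) / 2.0
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(1e-12, np.abs(vals).max() * 1e-9) if n else 0.0
    pos = vals > tol
    neg = vals[vals < -tol]
    if not pos.any():
        logger.warning("no positive eigenvalues: zero-dimensional ordination")
        coords = pd.DataFrame(np.zeros((n, 0)), index=labels)
        return OrdinationResult(labels, coords, np.array([]), neg)
    vals_p, vecs_p = vals[pos], vecs[:, pos]
    coords = vecs_p * np.sqrt(vals_p)
    for k in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, k]))
        if coords[i, k] < 0:
            coords[:, k] = -coords[:, k]
    frame = pd.DataFrame(
        coords, index=labels, columns=[f"PCo{k + 1}" for k in range(coords.shape[1])]
    )
    return OrdinationResult(labels, frame, vals_p, neg)


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

@dataclass
class PermutationTestResult:
    statistic: float
    n_permutations: int
    p_value: float
    null_mean: float
    null_sd: float
    method: str


def _condensed_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def anosim(
    D: pd.DataFrame,
    groups: pd.Series | dict | list,
    n_permutations: int = 999,
    seed: int | None = 0,
) -> PermutationTestResult:
    """Analysis of similarities on a distance matrix.

    All off-diagonal pairs are midranked; R = (mean between-group rank - mean
    within-group rank) / (M/2) with M = n(n-1)/2. The null is generated by
    shuffling group labels.
    """
    labels = list(D.index)
    if isinstance(groups, (dict, pd.Series)):
        g = np.array([groups[l] for l in labels])
    else:
        g = np.asarray(groups)
    uniq, counts = np.unique(g, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise ValueError("ANOSIM needs >= 2 groups with >= 2 members each")
    n = len(labels)
    iu, ju = _condensed_indices(n)
    dvec = D.to_numpy()[iu, ju]
    ranks = stats.rankdata(dvec)  # midranks
    M = len(ranks)

    def r_stat(within: np.ndarray) -> np.ndarray:
        w = within.astype(float)
        mean_w = (ranks * w).sum(axis=-1) / w.sum(axis=-1)
        mean_b = (ranks * (1 - w)).sum(axis=-1) / (1 - w).sum(axis=-1)
        return (mean_b - mean_w) / (M / 2.0)

    observed = float(r_stat(g[iu] == g[ju]))
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(g) for _ in range(n_permutations)])
    within_perm = perms[:, iu] == perms[:, ju]
    null = r_stat(within_perm)
    p = (1 + int(np.sum(null >= observed))) / (1 + n_permutations)
    return PermutationTestResult(observed, n_permutations, p,
                                 float(null.mean()), float(null.std()), "anosim")


def mantel(
    D1: pd.DataFrame,
    D2: pd.DataFrame,
    n_permutations: int = 999,
    seed: int | None = 0,
) -> PermutationTestResult:
    """Mantel test: Pearson correlation of the upper triangles of two distance
    matrices, one-sided (greater) p by simultaneous row/column permutation of D2."""
    if list(D1.index) != list(D2.index):
        D2 = D2.loc[D1.index, D1.index]
    n = len(D1)
    if n < 4:
        raise ValueError("Mantel test needs at least 4 labels")
    iu, ju = _condensed_indices(n)
    v1 = D1.to_numpy()[iu, ju].astype(float)
    M2 = D2.to_numpy().astype(float)
    v2 = M2[iu, ju]
    if v1.std() == 0 or v2.std() == 0:
        raise ValueError("zero variance in a distance triangle: r undefined")
    z1 = (v1 - v1.mean()) / v1.std()
    observed = float((z1 * (v2 - v2.mean()) / v2.std()).mean())
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for k in range(n_permutations):
        p = rng.permutation(n)
        vp = M2[np.ix_(p, p)][iu, ju]
        s = vp.std()
        null[k] = (z1 * (vp - vp.mean()) / s).mean() if s > 0 else 0.0
    pval = (1 + int(np.sum(null >= observed))) / (1 + n_permutations)
    return PermutationTestResult(observed, n_permutations, pval,
                                 float(null.mean()), float(null.std()), "mantel")


# ---------------------------------------------------------------------------
# richness comparison between sides of the divide
# ---------------------------------------------------------------------------

@dataclass
class RichnessResult:
    per_basin: pd.Series
    side_summary: pd.DataFrame   # mean, sd, total distinct per side
    statistic: float             # Mann-Whitney U (rank-sum form)
    p_value: float               # two-sided


def richness_by_side(
    presence: pd.DataFrame | CommunityMatrix,
    side_of_divide: pd.Series | None = None,
) -> RichnessResult:
    """Per-basin richness, per-side mean ± SD and distinct totals, and a
    two-sided Wilcoxon rank-sum comparison of the two sides (exact for small
    untied samples, normal approximation with tie/continuity correction else)."""
    if isinstance(presence, CommunityMatrix):
        side_of_divide = presence.side_of_divide
        presence = presence.presence
    if side_of_divide is None:
        raise ValueError("side_of_divide labels are required")
    rich = presence.sum(axis=1)
    sides = side_of_divide.loc[rich.index]
    uniq = sides.unique()
    if len(uniq) != 2 or any((sides == s).sum() == 0 for s in uniq):
        raise ValueError("richness comparison needs exactly two non-empty sides")
    rows = {}
    for s in sorted(uniq):
        sub = presence.loc[sides == s]
        rows[s] = {
            "mean": float(rich[sides == s].mean()),
            "sd": float(rich[sides == s].std(ddof=1)),
            "total_distinct": int(sub.any(axis=0).sum()),
            "n_basins": int((sides == s).sum()),
        }
    a, b = sorted(uniq)
    res = stats.mannwhitneyu(rich[sides == a], rich[sides == b],
                             alternative="two-sided", method="auto")
    return RichnessResult(
        per_basin=rich,
        side_summary=pd.DataFrame(rows).T,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )
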