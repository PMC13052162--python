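"""Intraspecific diversity: alignment, mismatch distances, betaMPD, haplotype networks.

ASVs of one species are aligned, pairwise base-pair mismatches counted with
pairwise deletion of gaps/ambiguities, and basin-to-basin genetic dissimilarity
summarised as betaMPD — the mean pairwise genetic distance over all cross pairs
of variants drawn one from each basin (presence/absence weighted). A minimum
spanning tree over haplotype mismatch distances gives the haplotype network.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .asv_filtering import ASVRecord, CommunityMatrix

logger = logging.getLogger(__name__)

_UNAMBIGUOUS = frozenset(b"ACGT")


# ---------------------------------------------------------------------------
# species selection
# ---------------------------------------------------------------------------

def select_species(community: CommunityMatrix, records: list[ASVRecord]) -> list[str]:
    """Species usable for intraspecific analysis: those whose species-level
    ASVs occur in at least two basins (pairwise comparison requires >= 2)."""
    by_species: dict[str, set[str]] = {}
    present = set(community.asv_ids)
    for rec in records:
        sp = rec.rank("species").strip()
        if sp and rec.asv_id in present:
            by_species.setdefault(sp, set()).update(
                community.presence.index[community.presence[rec.asv_id]]
            )
    return sorted(sp for sp, basins in by_species.items() if len(basins) >= 2)


# ---------------------------------------------------------------------------
# progressive multiple alignment
# ---------------------------------------------------------------------------

@dataclass
class SpeciesAlignment:
    species_name: str
    asv_ids: list[str]
    aligned_sequences: list[str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.aligned_sequences}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def length(self) -> int:
        return len(self.aligned_sequences[0]) if self.aligned_sequences else 0


def _pair_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


def _merge_profiles(rows_a: list[str], rows_b: list[str],
                    aligner: Align.PairwiseAligner) -> tuple[list[str], list[str]]:
    """Align two profiles via their consensus sequences and propagate gaps."""

    def consensus(rows: list[str]) -> str:
        arr = np.frombuffer("".join(rows).encode(), dtype="S1").reshape(len(rows), -1)
        out = []
        for col in arr.T:
            vals, counts = np.unique(col[col != b"-"], return_counts=True)
            out.append(vals[np.argmax(counts)].decode() if len(vals) else "A")
        return "".join(out)

    ca, cb = consensus(rows_a), consensus(rows_b)
    aln = aligner.align(ca, cb)[0]
    a_gapped, b_gapped = str(aln[0]), str(aln[1])

    def expand(rows: list[str], gapped: str) -> list[str]:
        out = []
        for row in rows:
            chars, i = [], 0
            for ch in gapped:
                if ch == "-":
                    chars.append("-")
                else:
                    chars.append(row[i])
                    i += 1
            out.append("".join(chars))
        return out

    return expand(rows_a, a_gapped), expand(rows_b, b_gapped)


def align_species(
    sequences: dict[str, str], species_name: str = ""
) -> SpeciesAlignment:
    """Progressive multiple alignment (UPGMA guide tree over quick pairwise
    mismatch distances; match +1, mismatch -1, gap open -5, extend -1).

    Equal-length inputs differing only by substitutions return the gap-free
    identity alignment.
    """
    ids = list(sequences)
    seqs = [sequences[i].upper() for i in ids]
    if len(ids) == 0:
        raise ValueError("no sequences to align")
    if len(ids) == 1:
        logger.warning("single sequence for %s: identity alignment", species_name)
        return SpeciesAlignment(species_name, ids, seqs)

    aligner = _pair_aligner()
    # guide distances: Hamming for equal lengths, alignment mismatches otherwise
    n = len(ids)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = seqs[i], seqs[j]
        if len(a) == len(b):
            d[i, j] = d[j, i] = sum(x != y for x, y in zip(a, b))
        else:
            aln = aligner.align(a, b)[0]
            ra, rb = str(aln[0]), str(aln[1])
            d[i, j] = d[j, i] = sum(
                1 for x, y in zip(ra, rb) if x != "-" and y != "-" and x != y
            ) + abs(len(a) - len(b))

    tree = to_tree(linkage(squareform(d, checks=False), method="average"))
    profiles: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seqs[i]]) for i in range(n)
    }

    def build(node) -> tuple[list[int], list[str]]:
        if node.is_leaf():
            return profiles[node.id]
        la, ra = build(node.left), build(node.right)
        rows_a, rows_b = _merge_profiles(la[1], ra[1], aligner)
        return la[0] + ra[0], rows_a + rows_b

    order, rows = build(tree)
    out_ids = [ids[i] for i in order]
    # restore the input order of rows
    perm = {aid: row for aid, row in zip(out_ids, rows)}
    return SpeciesAlignment(species_name, ids, [perm[i] for i in ids])


# ---------------------------------------------------------------------------
# pairwise genetic distances
# ---------------------------------------------------------------------------

@dataclass
class GeneticDistanceMatrix:
    """Pairwise base-pair mismatches with pairwise deletion of gaps/ambiguities."""

    asv_ids: list[str]
    D: np.ndarray                 # integer mismatch counts
    comparable_sites: np.ndarray  # per-pair count of columns compared
    proportion: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        with np.errstate(invalid="ignore", divide="ignore"):
            self.proportion = np.where(
                self.comparable_sites > 0, self.D / self.comparable_sites, np.nan
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.asv_ids, columns=self.asv_ids)


def pairwise_distances(alignment: SpeciesAlignment) -> GeneticDistanceMatrix:
    """Count mismatches per pair over columns where both rows carry unambiguous
    bases (gaps and IUPAC ambiguity codes are deleted pairwise)."""
    rows = alignment.aligned_sequences
    n = len(rows)
    arr = np.frombuffer("".join(rows).encode(), dtype=np.uint8).reshape(n, -1)
    ok = np.isin(arr, list(_UNAMBIGUOUS))
    D = np.zeros((n, n), dtype=int)
    comp = np.zeros((n, n), dtype=int)
    for i in range(n):
        both = ok[i] & ok[i + 1:]
        comp[i, i + 1:] = both.sum(axis=1)
        D[i, i + 1:] = ((arr[i] != arr[i + 1:]) & both).sum(axis=1)
    D += D.T
    comp += comp.T
    np.fill_diagonal(comp, arr.shape[1])
    if np.any((comp == 0) & ~np.eye(n, dtype=bool)):
        logger.warning("pairs with zero comparable sites: distance undefined")
    return GeneticDistanceMatrix(list(alignment.asv_ids), D, comp)


# ---------------------------------------------------------------------------
# betaMPD
# ---------------------------------------------------------------------------

def beta_mpd(
    community: CommunityMatrix,
    species_asvs: list[str],
    distances: GeneticDistanceMatrix | pd.DataFrame,
    use_proportion: bool = False,
) -> pd.DataFrame:
    """Between-basin mean pairwise genetic distance (betaMPD).

    betaMPD(b1, b2) is the mean of D[i, j] over all cross pairs i in ASVs(b1),
    j in ASVs(b2) with presence/absence weighting. Basin pairs where either
    basin holds no ASV of the species are NaN.
    """
    if isinstance(distances, GeneticDistanceMatrix):
        Dfull = pd.DataFrame(
            distances.proportion if use_proportion else distances.D,
            index=distances.asv_ids, columns=distances.asv_ids, dtype=float,
        )
    else:
        Dfull = distances.astype(float)
    asvs = [a for a in species_asvs if a in community.presence.columns]
    missing = [a for a in asvs if a not in Dfull.index]
    if missing:
        raise ValueError(f"distance matrix does not cover ASVs: {missing}")
    P = community.presence[asvs].to_numpy(dtype=float)
    D = Dfull.loc[asvs, asvs].to_numpy()
    counts = P.sum(axis=1)
    num = P @ D @ P.T
    denom = np.outer(counts, counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        B = np.where(denom > 0, num / denom, np.nan)
    empty = counts == 0
    if empty.any():
        logger.warning("basins without ASVs of this species: %s",
                       list(np.array(community.basin_ids)[empty]))
    B[empty, :] = np.nan
    B[:, empty] = np.nan
    B = (B + B.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(B, np.where(empty, np.nan, 0.0))
    out = pd.DataFrame(B, index=community.basin_ids, columns=community.basin_ids)
    return out


def community_beta_mpd(
    community: CommunityMatrix,
    species_of_asv: dict[str, str],
    per_species_distances: dict[str, GeneticDistanceMatrix],
    cross_species: str = "cap",
) -> pd.DataFrame:
    """Whole-community betaMPD over the union of species-level ASVs.

    Genetic distances are defined within species only; cross-species ASV pairs
    receive the global maximum observed intraspecific distance (``cap``, the
    default, bounding their influence) or are excluded (``exclude``).
    """
    asvs = [a for a in community.asv_ids if a in species_of_asv]
    caps = [
        g.D.max() for g in per_species_distances.values() if g.D.size
    ]
    cap_value = float(max(caps)) if caps else 0.0
    n = len(asvs)
    if cross_species == "cap":
        D = np.full((n, n), cap_value)
    elif cross_species == "exclude":
        D = np.full((n, n), np.nan)
    else:
        raise ValueError(f"unknown cross_species policy {cross_species!r}")
    idx = {a: i for i, a in enumerate(asvs)}
    for sp, g in per_species_distances.items():
        ii = [idx[a] for a in g.asv_ids if a in idx]
        aa = [a for a in g.asv_ids if a in idx]
        sub = pd.DataFrame(g.D, index=g.asv_ids, columns=g.asv_ids).loc[aa, aa].to_numpy()
        D[np.ix_(ii, ii)] = sub
    np.fill_diagonal(D, 0.0)
    Dframe = pd.DataFrame(D, index=asvs, columns=asvs)
    if cross_species == "exclude":
        # mean over defined (within-species) cross pairs only
        P = community.presence[asvs].to_numpy(dtype=float)
        M = Dframe.to_numpy()
        defined = ~np.isnan(M)
        num = P @ np.where(defined, M, 0.0) @ P.T
        den = P @ defined.astype(float) @ P.T
        with np.errstate(invalid="ignore", divide="ignore"):
            B = np.where(den > 0, num / den, np.nan)
        B = (B + B.T) / 2.0
        np.fill_diagonal(B, 0.0)
        return pd.DataFrame(B, index=community.basin_ids, columns=community.basin_ids)
    return beta_mpd(community, asvs, Dframe)


# ---------------------------------------------------------------------------
# haplotype network
# ---------------------------------------------------------------------------

@dataclass
class Haplotype:
    haplotype_id: str
    sequence: str
    frequency: int
    side_counts: dict[str, int]


@dataclass
class NetworkEdge:
    a: str
    b: str
    steps: int
    is_alternative: bool


@dataclass
class HaplotypeNetwork:
    haplotypes: list[Haplotype]
    edges: list[NetworkEdge]

    @property
    def spanning_edges(self) -> list[NetworkEdge]:
        return [e for e in self.edges if not e.is_alternative]


def _trim_to_overlap(rows: list[str]) -> list[str]:
    cols = [
        j for j in range(len(rows[0]))
        if all(r[j] != "-" and r[j] in "ACGTacgt" for r in rows)
    ]
    if not cols:
        raise ValueError("zero-length overlap between sequences")
    return ["".join(r[j] for j in cols) for r in rows]


def build_haplotype_network(
    aligned_sequences: list[str],
    side_labels: list[str],
    external_reference_haplotypes: list[str] | None = None,
    trim_to_overlap: bool = False,
) -> HaplotypeNetwork:
    """Collapse aligned sequences into haplotypes and connect them by a minimum
    spanning tree over pairwise mismatch counts (infinite-sites reading: one
    mismatch = one mutational step).

    External reference haplotypes (e.g. published sequences of the same marker)
    may be appended; they then require ``trim_to_overlap`` so all sequences are
    compared on their common gap-free region. Kruskal with lexicographic
    tie-breaks keeps the tree deterministic; non-tree edges whose length equals
    the bottleneck of the tree path they would shortcut are reported as
    alternative connections.
    """
    rows = [s.upper() for s in aligned_sequences]
    sides = list(side_labels)
    if external_reference_haplotypes:
        if not trim_to_overlap:
            raise ValueError("external haplotypes require trim_to_overlap=True")
        rows += [s.upper() for s in external_reference_haplotypes]
        sides += ["reference"] * len(external_reference_haplotypes)
    if len({len(r) for r in rows}) > 1:
        raise ValueError("sequences must be aligned (equal length)")
    if trim_to_overlap:
        rows = _trim_to_overlap(rows)

    haplo_of: dict[str, list[int]] = {}
    for i, r in enumerate(rows):
        haplo_of.setdefault(r, []).append(i)
    uniq = sorted(haplo_of)  # deterministic
    ids = [f"H{k + 1:02d}" for k in range(len(uniq))]
    haplotypes = []
    for hid, seq in zip(ids, uniq):
        members = haplo_of[seq]
        side_counts: dict[str, int] = {}
        for m in members:
            side_counts[sides[m]] = side_counts.get(sides[m], 0) + 1
        haplotypes.append(Haplotype(hid, seq, len(members), side_counts))

    k = len(uniq)
    steps = np.zeros((k, k), dtype=int)
    for i, j in itertools.combinations(range(k), 2):
        steps[i, j] = steps[j, i] = sum(a != b for a, b in zip(uniq[i], uniq[j]))

    # Kruskal, ties broken lexicographically by haplotype id pair
    all_edges = sorted(
        ((int(steps[i, j]), ids[i], ids[j], i, j)
         for i, j in itertools.combinations(range(k), 2))
    )
    parent = list(range(k))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree_pairs: set[tuple[int, int]] = set()
    edges: list[NetworkEdge] = []
    T = nx.Graph()
    for w, a, b, i, j in all_edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            tree_pairs.add((i, j))
            edges.append(NetworkEdge(a, b, w, is_alternative=False))
            T.add_edge(i, j, weight=w)
    for w, a, b, i, j in all_edges:
        if (i, j) in tree_pairs:
            continue
        path = nx.shortest_path(T, i, j)
        bottleneck = max(
            T.edges[u, v]["weight"] for u, v in zip(path, path[1:])
        )
        if w == bottleneck:
            edges.append(NetworkEdge(a, b, w, is_alternative=True))
    return HaplotypeNetwork(haplotypes=haplotypes, edges=edges)
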