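"""Alignment, mismatch distances, betaMPD and haplotype networks."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.sparse.csgraph import minimum_spanning_tree

from edna_divide import intraspecific as intra
from edna_divide import synthetic_data as sd
from edna_divide.asv_filtering import ASVRecord, CommunityMatrix

from conftest import random_distance_frame


def community_of(presence: np.ndarray, basins=None, asvs=None) -> CommunityMatrix:
    basins = basins or [f"b{i}" for i in range(presence.shape[0])]
    asvs = asvs or [f"a{j}" for j in range(presence.shape[1])]
    return CommunityMatrix(
        presence=pd.DataFrame(presence.astype(bool), index=basins, columns=asvs),
        side_of_divide=pd.Series("w", index=basins),
    )


class TestSelectSpecies:
    def rec(self, aid, species):
        return ASVRecord(aid, "ACGT",
                         taxon_path=("Actinopterygii", "o", "f", "g", species))

    def test_two_basin_rule(self):
        comm = community_of(np.array([[1, 1], [0, 1]]))
        recs = [self.rec("a0", "one basin sp"), self.rec("a1", "two basin sp")]
        assert intra.select_species(comm, recs) == ["two basin sp"]

    def test_default_scenario_selects_all_but_single_basin_species(self, filtered):
        species = intra.select_species(filtered.community, filtered.records)
        assert len(species) == 5  # 6 species, one confined to a single basin


class TestAlignment:
    def test_identical_pair_gap_free(self):
        aln = intra.align_species({"a": "ACGTACGT", "b": "ACGTACGT"})
        assert aln.aligned_sequences == ["ACGTACGT", "ACGTACGT"]

    def test_single_substitution_gap_free(self):
        aln = intra.align_species({"a": "ACGT", "b": "ACGA"})
        assert "-" not in "".join(aln.aligned_sequences)
        d = intra.pairwise_distances(aln)
        assert d.D[0, 1] == 1

    def test_substitution_only_sets_align_without_gaps(self):
        rng = np.random.default_rng(0)
        for seed in range(10):
            anc = sd.random_coding_sequence(120, rng)
            seqs = {
                f"s{i}": sd.mutate_sequence(anc, int(rng.integers(0, 15)), rng)
                for i in range(10)
            }
            aln = intra.align_species(seqs)
            assert "-" not in "".join(aln.aligned_sequences)
            # rows reproduce inputs
            assert [aln.aligned_sequences[aln.asv_ids.index(k)] for k in seqs] == \
                [seqs[k] for k in seqs]

    def test_indel_produces_gap_and_ungapped_rows_reproduce_inputs(self):
        seqs = {"a": "ACGTTTACGTACGT", "b": "ACGTACGTACGT"}  # 2-base deletion
        aln = intra.align_species(seqs)
        joined = dict(zip(aln.asv_ids, aln.aligned_sequences))
        assert joined["b"].count("-") == 2
        for k, row in joined.items():
            assert row.replace("-", "") == seqs[k]


class TestPairwiseDistances:
    def test_identical_rows_zero(self):
        aln = intra.SpeciesAlignment("", ["a", "b"], ["ACGT", "ACGT"])
        assert intra.pairwise_distances(aln).D[0, 1] == 0

    def test_pairwise_deletion_of_gap_columns(self):
        aln = intra.SpeciesAlignment("", ["a", "b"], ["AC-T", "ACGT"])
        d = intra.pairwise_distances(aln)
        assert d.D[0, 1] == 0
        assert d.comparable_sites[0, 1] == 3

    def test_matches_per_column_brute_force(self):
        rng = np.random.default_rng(4)
        chars = np.array(list("ACGT-N"))
        for _ in range(20):
            rows = ["".join(rng.choice(chars, size=60)) for _ in range(2)]
            aln = intra.SpeciesAlignment("", ["a", "b"], rows)
            d = intra.pairwise_distances(aln)
            mm = comp = 0
            for x, y in zip(*rows):
                if x in "ACGT" and y in "ACGT":
                    comp += 1
                    mm += x != y
            assert d.D[0, 1] == mm and d.comparable_sites[0, 1] == comp


class TestBetaMpd:
    def test_shared_single_haplotype_is_zero(self):
        comm = community_of(np.array([[1], [1]]))
        D = pd.DataFrame([[0.0]], index=["a0"], columns=["a0"])
        out = intra.beta_mpd(comm, ["a0"], D)
        assert out.loc["b0", "b1"] == 0.0

    def test_worked_four_cross_pair_example(self):
        # b1={h1,h2}, b2={h2,h3}: (D12 + D13 + D22 + D23)/4 = (2+4+0+1)/4
        comm = community_of(np.array([[1, 1, 0], [0, 1, 1]]),
                            asvs=["h1", "h2", "h3"])
        D = pd.DataFrame(
            [[0, 2, 4], [2, 0, 1], [4, 1, 0]],
            index=["h1", "h2", "h3"], columns=["h1", "h2", "h3"], dtype=float)
        out = intra.beta_mpd(comm, ["h1", "h2", "h3"], D)
        assert out.loc["b0", "b1"] == pytest.approx(1.75, abs=1e-12)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            P = rng.random((8, 20)) < 0.5
            P[P.sum(axis=1) == 0, 0] = True
            comm = community_of(P)
            D = random_distance_frame(rng, 20, scale=30,
                                      labels=[f"a{j}" for j in range(20)])
            out = intra.beta_mpd(comm, list(D.index), D)
            for i in range(8):
                for j in range(i + 1, 8):
                    ii, jj = np.where(P[i])[0], np.where(P[j])[0]
                    expect = np.mean([D.iloc[a, b] for a in ii for b in jj])
                    assert out.iloc[i, j] == pytest.approx(expect, abs=1e-12)

    def test_invariant_to_relabelling_and_duplicate_columns(self):
        rng = np.random.default_rng(8)
        P = rng.random((4, 6)) < 0.6
        P[P.sum(axis=1) == 0, 0] = True
        comm = community_of(P)
        D = random_distance_frame(rng, 6, labels=[f"a{j}" for j in range(6)])
        base = intra.beta_mpd(comm, list(D.index), D)
        perm = rng.permutation(6)
        asvs = [f"a{j}" for j in perm]
        comm2 = CommunityMatrix(presence=comm.presence[asvs],
                                side_of_divide=comm.side_of_divide)
        again = intra.beta_mpd(comm2, asvs, D)
        assert np.allclose(base.to_numpy(), again.to_numpy())

    def test_zero_distances_give_zero_matrix(self):
        comm = community_of(np.ones((3, 4)))
        D = pd.DataFrame(np.zeros((4, 4)),
                         index=[f"a{j}" for j in range(4)],
                         columns=[f"a{j}" for j in range(4)])
        out = intra.beta_mpd(comm, list(D.index), D)
        assert (out.to_numpy() == 0).all()

    def test_empty_basin_yields_missing_value(self):
        comm = community_of(np.array([[1], [0]]))
        D = pd.DataFrame([[0.0]], index=["a0"], columns=["a0"])
        out = intra.beta_mpd(comm, ["a0"], D)
        assert np.isnan(out.loc["b0", "b1"])

    def test_agrees_with_picante_comdist(self, tmp_path):
        """Independent oracle: R picante's comdist on the same instance."""
        rng = np.random.default_rng(3)
        P = rng.random((5, 8)) < 0.6
        P[P.sum(axis=1) == 0, 0] = True
        comm = community_of(P)
        D = random_distance_frame(rng, 8, scale=20,
                                  labels=[f"a{j}" for j in range(8)])
        mine = intra.beta_mpd(comm, list(D.index), D)
        comm.presence.astype(int).to_csv(tmp_path / "comm.csv")
        D.to_csv(tmp_path / "dist.csv")
        script = f'''
suppressMessages(library(picante))
comm <- as.matrix(read.csv("{tmp_path}/comm.csv", row.names=1))
d <- as.dist(as.matrix(read.csv("{tmp_path}/dist.csv", row.names=1)))
write.csv(as.matrix(comdist(comm, d, abundance.weighted=FALSE)),
          "{tmp_path}/out.csv")
'''
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        oracle = pd.read_csv(tmp_path / "out.csv", index_col=0)
        a = mine.loc[oracle.index, oracle.columns].to_numpy()
        b = oracle.to_numpy()
        off = ~np.eye(len(oracle), dtype=bool)
        assert np.allclose(a[off], b[off], atol=1e-9)


class TestCommunityBetaMpd:
    def test_single_species_equals_per_species(self):
        rng = np.random.default_rng(9)
        P = rng.random((4, 5)) < 0.7
        P[P.sum(axis=1) == 0, 0] = True
        comm = community_of(P)
        rows = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(5)]
        aln = intra.SpeciesAlignment("sp", [f"a{j}" for j in range(5)], rows)
        g = intra.pairwise_distances(aln)
        species_of = {f"a{j}": "sp" for j in range(5)}
        combined = intra.community_beta_mpd(comm, species_of, {"sp": g})
        single = intra.beta_mpd(comm, list(species_of), g)
        assert np.allclose(combined.to_numpy(), single.to_numpy(), equal_nan=True)

    def test_capped_cross_species_pairs_match_hand_computation(self):
        # species X: x1 in b0, x2 in b1 with D=2 (cap); species Y: y1 in both
        comm = community_of(np.array([[1, 0, 1], [0, 1, 1]]),
                            asvs=["x1", "x2", "y1"])
        gx = intra.GeneticDistanceMatrix(
            ["x1", "x2"], np.array([[0, 2], [2, 0]]), np.full((2, 2), 30))
        gy = intra.GeneticDistanceMatrix(["y1"], np.zeros((1, 1), int),
                                         np.full((1, 1), 30))
        out = intra.community_beta_mpd(
            comm, {"x1": "X", "x2": "X", "y1": "Y"}, {"X": gx, "Y": gy})
        # cross pairs b0->b1: (x1,x2)=2, (x1,y1)=cap=2, (y1,x2)=2, (y1,y1)=0
        assert out.loc["b0", "b1"] == pytest.approx(6 / 4)

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(10)
        P = rng.random((5, 6)) < 0.6
        P[P.sum(axis=1) == 0, 0] = True
        comm = community_of(P)
        rows = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(6)]
        ids = [f"a{j}" for j in range(6)]
        g = intra.pairwise_distances(intra.SpeciesAlignment("s", ids[:3], rows[:3]))
        g.asv_ids = ids[:3]
        g2 = intra.pairwise_distances(intra.SpeciesAlignment("t", ids[3:], rows[3:]))
        g2.asv_ids = ids[3:]
        species_of = {a: ("s" if j < 3 else "t") for j, a in enumerate(ids)}
        out = intra.community_beta_mpd(comm, species_of, {"s": g, "t": g2})
        M = out.to_numpy()
        assert np.allclose(M, M.T, equal_nan=True)
        assert np.allclose(np.diag(M), 0)


class TestHaplotypeNetwork:
    def test_star_topology(self):
        centre = "A" * 20
        sats = [centre[:i] + "C" + centre[i + 1:] for i in range(4)]
        net = intra.build_haplotype_network([centre] * 3 + sats,
                                            ["w"] * 3 + ["e"] * 4)
        tree = net.spanning_edges
        assert len(tree) == 4
        assert all(e.steps == 1 for e in tree)
        centre_id = next(h.haplotype_id for h in net.haplotypes
                         if h.sequence == centre)
        assert all(centre_id in (e.a, e.b) for e in tree)

    def test_frequencies_conserve_input_count(self):
        rng = np.random.default_rng(11)
        seqs = ["".join(rng.choice(list("ACGT"), size=25)) for _ in range(8)]
        seqs += seqs[:3]
        net = intra.build_haplotype_network(seqs, ["w"] * len(seqs))
        assert sum(h.frequency for h in net.haplotypes) == len(seqs)

    def test_mst_weight_matches_scipy_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            anc = sd.random_coding_sequence(60, rng)
            seqs = [sd.mutate_sequence(anc, int(rng.integers(0, 8)), rng)
                    for _ in range(30)]
            net = intra.build_haplotype_network(seqs, ["w"] * 30)
            uniq = sorted({s for s in seqs})
            k = len(uniq)
            M = np.zeros((k, k))
            for i in range(k):
                for j in range(i + 1, k):
                    M[i, j] = sum(a != b for a, b in zip(uniq[i], uniq[j]))
            oracle = minimum_spanning_tree(M).sum()
            assert sum(e.steps for e in net.spanning_edges) == pytest.approx(oracle)

    def test_equal_cost_triangle_reports_alternative_edge(self):
        seqs = ["AAA", "AAC", "ACA"]  # mutual distance 1-1-2? -> use symmetric trio
        seqs = ["AAT", "ATA", "TAA"]  # all pairwise distance 2
        net = intra.build_haplotype_network(seqs, ["w"] * 3)
        assert len(net.spanning_edges) == 2
        alts = [e for e in net.edges if e.is_alternative]
        assert len(alts) == 1 and alts[0].steps == 2

    def test_external_haplotypes_trimmed_to_overlap(self):
        core = "ACGT" * 10
        ext = "-" * 4 + core[4:36] + "-" * 4
        net = intra.build_haplotype_network(
            [core, core], ["w", "e"],
            external_reference_haplotypes=[ext], trim_to_overlap=True)
        assert all(len(h.sequence) == 32 for h in net.haplotypes)

    def test_external_without_trim_rejected(self):
        with pytest.raises(ValueError, match="trim_to_overlap"):
            intra.build_haplotype_network(["AAAA"], ["w"],
                                          external_reference_haplotypes=["AAAA"])
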