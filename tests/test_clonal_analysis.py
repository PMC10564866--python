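"""Dereplication, clonal families and mutation networks against
brute-force oracles and simulator truth."""

import random

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from oracles import derep_greedy_oracle, hamming1_edges_bruteforce
from repgut.clonal_analysis import (
    build_clone_network,
    clone_size_tail_exponent,
    dereplicate_99,
    expansion_summary,
    infer_clonal_families,
)
from repgut.repertoire_io import Rearrangement


def _rec(seq_id, sequence, dup=1, v="TVH1-1*01", j="TVJ1*01", cdr3=None, **meta):
    return Rearrangement(
        sequence_id=seq_id,
        sequence=sequence,
        v_call=v,
        j_call=j,
        cdr3_aa=cdr3,
        cdr3_nt=None if cdr3 is None else "NNN" * len(cdr3),
        duplicate_count=dup,
        metadata=meta,
    )


def _random_seq(rng, n=300):
    return "".join(rng.choice("ACGT") for _ in range(n))


def _mutate(rng, seq, k):
    seq = list(seq)
    for pos in rng.sample(range(len(seq)), k):
        seq[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
    return "".join(seq)


class TestDereplication:
    def test_identical_sequences_collapse(self):
        rng = random.Random(0)
        seq = _random_seq(rng)
        reps = dereplicate_99([_rec("a", seq), _rec("b", seq)])
        assert len(reps) == 1
        assert reps[0].duplicate_count == 2

    def test_two_mismatches_in_300nt_cluster_together(self):
        rng = random.Random(1)
        seq = _random_seq(rng, 300)
        reps = dereplicate_99([_rec("a", seq, dup=5), _rec("b", _mutate(rng, seq, 2))])
        assert len(reps) == 1  # identity 298/300 = 99.33%

    def test_four_mismatches_in_300nt_stay_apart(self):
        rng = random.Random(2)
        seq = _random_seq(rng, 300)
        reps = dereplicate_99([_rec("a", seq, dup=5), _rec("b", _mutate(rng, seq, 4))])
        assert len(reps) == 2  # identity 296/300 < 99%

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_greedy_first_seed_oracle(self, seed):
        rng = random.Random(seed)
        records = []
        for base_idx in range(rng.randint(2, 5)):
            base = _random_seq(rng, rng.choice([280, 300]))
            for member_idx in range(rng.randint(1, 6)):
                k = rng.choice([0, 0, 1, 2, 3, 5])
                records.append(
                    _rec(f"s{base_idx}.{member_idx}", _mutate(rng, base, k),
                         dup=rng.randint(1, 20))
                )
        records = records[:30]
        oracle = derep_greedy_oracle(records)
        reps = dereplicate_99(records)
        assert {r.sequence_id for r in reps} == set(oracle.values())
        # duplicate totals per cluster agree
        totals = {}
        by_id = {r.sequence_id: r for r in records}
        for member, seed_id in oracle.items():
            totals[seed_id] = totals.get(seed_id, 0) + by_id[member].duplicate_count
        assert {r.sequence_id: r.duplicate_count for r in reps} == totals

    def test_idempotent(self):
        rng = random.Random(3)
        base = _random_seq(rng)
        records = [_rec(f"s{i}", _mutate(rng, base, k), dup=i + 1)
                   for i, k in enumerate([0, 1, 2, 8, 9])]
        once = dereplicate_99(records)
        twice = dereplicate_99(once)
        assert {r.sequence_id for r in once} == {r.sequence_id for r in twice}
        assert sum(r.duplicate_count for r in once) == sum(r.duplicate_count for r in twice)


class TestClonalFamilies:
    def test_identical_cdr3_one_family(self):
        records = [
            _rec("a", "A" * 60, cdr3="ARDYYGMDV"),
            _rec("b", "C" * 60, cdr3="ARDYYGMDV"),
        ]
        families = infer_clonal_families(records)
        assert len(families) == 1
        assert families[0].member_ids == ["a", "b"]

    def test_identity_below_cutoff_splits(self):
        records = [
            _rec("a", "A" * 60, cdr3="ARDYYGMDVW"),
            _rec("b", "C" * 60, cdr3="ARDYYGMQLC"),  # 3 of 10 differ -> 0.7
        ]
        assert len(infer_clonal_families(records)) == 2

    def test_identity_at_cutoff_joins(self):
        records = [
            _rec("a", "A" * 60, cdr3="ARDYYGMDVW"),
            _rec("b", "C" * 60, cdr3="ARDYYGMDLC"),  # 8 of 10 match -> 0.8
        ]
        assert len(infer_clonal_families(records)) == 1

    def test_allele_suffix_stripped_for_grouping(self):
        records = [
            _rec("a", "A" * 60, v="TVH3-1*01", cdr3="ARDYYGMDV"),
            _rec("b", "C" * 60, v="TVH3-1*02", cdr3="ARDYYGMDV"),
        ]
        families = infer_clonal_families(records)
        assert len(families) == 1
        assert families[0].v_call == "TVH3-1"

    def test_different_vj_or_length_split(self):
        records = [
            _rec("a", "A" * 60, v="TVH1-1*01", cdr3="ARDYYGMDV"),
            _rec("b", "C" * 60, v="TVH2-1*01", cdr3="ARDYYGMDV"),
            _rec("c", "G" * 60, v="TVH1-1*01", cdr3="ARDYYGMD"),
        ]
        assert len(infer_clonal_families(records)) == 3

    def test_order_invariance(self):
        rng = random.Random(4)
        records = []
        for i in range(30):
            cdr3 = "".join(rng.choice("ARNDCQEGHILKMFPSTWYV") for _ in range(9))
            records.append(_rec(f"s{i}", _random_seq(rng, 30), cdr3=cdr3,
                                v=rng.choice(["TVH1-1*01", "TVH2-1*01"])))
        forward = infer_clonal_families(records)
        backward = infer_clonal_families(records[::-1])
        assert [f.family_id for f in forward] == [f.family_id for f in backward]

    def test_partition_property(self):
        rng = random.Random(5)
        records = [
            _rec(f"s{i}", _random_seq(rng, 30),
                 cdr3="".join(rng.choice("ARDYG") for _ in range(8)))
            for i in range(40)
        ]
        families = infer_clonal_families(records)
        all_ids = sorted(i for f in families for i in f.member_ids)
        assert all_ids == sorted(r.sequence_id for r in records)

    def test_simulator_truth_partition_recovered(self, small_clean_sim):
        truth = small_clean_sim.truth.set_index("sequence_id")
        records = [
            _rec(sid, row["junction"] * 2, v=row["v_call"], j=row["j_call"],
                 cdr3=row["junction_aa"])
            for sid, row in truth.iterrows()
        ]
        families = infer_clonal_families(records)
        pred = {}
        for fam in families:
            for member in fam.member_ids:
                pred[member] = fam.family_id
        ids = list(truth.index)
        ari = adjusted_rand_score(
            [truth.loc[i, "clone_id"] for i in ids], [pred[i] for i in ids]
        )
        assert ari == 1.0


class TestCloneNetwork:
    def test_enumerated_hamming_chain(self):
        records = [_rec("a", "AAA"), _rec("b", "AAT"), _rec("c", "ATT")]
        graph = build_clone_network(records)
        assert set(map(frozenset, graph.edges())) == {
            frozenset(("a", "b")),
            frozenset(("b", "c")),
        }
        assert nx.number_connected_components(graph) == 1

    def test_no_edges_between_lengths(self):
        records = [_rec("a", "AAAA"), _rec("b", "AAA")]
        assert build_clone_network(records).number_of_edges() == 0

    def test_matches_bruteforce_oracle_on_200_sequences(self):
        rng = random.Random(6)
        sequences = {}
        base = _random_seq(rng, 40)
        i = 0
        while len(sequences) < 200:
            seq = _mutate(rng, base, rng.choice([1, 1, 2, 3]))
            if seq not in sequences.values():
                sequences[f"s{i}"] = seq
                i += 1
        records = [_rec(k, v) for k, v in sequences.items()]
        graph = build_clone_network(records)
        assert set(map(frozenset, graph.edges())) == hamming1_edges_bruteforce(sequences)

    def test_vertex_sizes_exported(self, tmp_path):
        records = [_rec("a", "AAA", dup=7), _rec("b", "AAT", dup=2)]
        graph = build_clone_network(records)
        p = tmp_path / "net.graphml"
        from repgut.clonal_analysis import export_network

        export_network(graph, graphml_path=p, edgelist_path=tmp_path / "edges.tsv")
        back = nx.read_graphml(p)
        assert {d["size"] for _, d in back.nodes(data=True)} == {7, 2}


class TestExpansion:
    def _families(self, sizes, group="eART", isotype="IGA"):
        families = []
        counter = 0
        for fam_idx, size in enumerate(sizes):
            members = []
            for _ in range(size):
                counter += 1
                rec = _rec(f"m{counter}", "A" * 30, cdr3="ARDYY", group=group)
                rec.isotype = isotype
                rec.vh_mutation_count = 5
                members.append(rec)
            fam = infer_clonal_families(members)
            families.append(
                type(fam[0])(
                    family_id=f"f{fam_idx}", v_call="TVH1-1", j_call="TVJ1",
                    cdr3_length_aa=5, member_ids=[m.sequence_id for m in members],
                    representative_id=members[0].sequence_id,
                    total_duplicates=size, members=members,
                )
            )
        return families

    def test_all_singletons(self):
        table = expansion_summary(self._families([1, 1, 1]))
        assert table["fraction_in_expanded"].iloc[0] == 0.0

    def test_single_dominant_clone(self):
        table = expansion_summary(self._families([10]))
        assert table["fraction_in_expanded"].iloc[0] == 1.0

    def test_power_law_exponent_recovered(self):
        rng = np.random.default_rng(12)
        sizes = np.minimum(rng.zipf(2.5, size=4000), 10_000)
        estimate = clone_size_tail_exponent(sizes)
        assert abs(estimate - 2.5) / 2.5 < 0.2
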