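"""Dereplication, clonal-family inference and mutation networks.

Clonal families follow the three-condition rule: same V gene, same J
gene (allele suffixes stripped), same CDR_H3 amino-acid length, and
CDR_H3 amino-acid identity >= 0.8 — read as normalized similarity with
single-linkage closure within each (V, J, length) bucket. Dereplication
is greedy incremental clustering at 99% global identity, CD-HIT style:
records are processed in decreasing (duplicate_count, length) order and
join the first cluster whose seed they match, otherwise seed their own.
Networks connect unique sequences differing by exactly one non-indel
nucleotide.
"""

from __future__ import annotations

import hashlib
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

import edlib
import networkx as nx
import numpy as np
import pandas as pd

from .repertoire_io import Rearrangement, gene_from_name

# ---------------------------------------------------------------------------
# 99% dereplication
# ---------------------------------------------------------------------------

_KMER = 24
_STRIDE = 12


def _signature(seq: str) -> frozenset:
    if len(seq) < _KMER:
        return frozenset((seq,))
    return frozenset(seq[i : i + _KMER] for i in range(0, len(seq) - _KMER + 1, _STRIDE))


def global_identity(a: str, b: str, min_identity: float = 0.0) -> float:
    """matches / alignment-length of a global (NW) alignment.

    When ``min_identity`` > 0 the computation may early-exit with 0.0 as
    soon as the pair provably falls below it.
    """
    k = -1
    if min_identity > 0.0:
        k = int((1.0 - min_identity) * (len(a) + len(b))) + 1
    res = edlib.align(a, b, mode="NW", task="path", k=k)
    if res["editDistance"] < 0:
        return 0.0
    cigar = res["cigar"]
    n_cols = n_match = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            n_cols += n
            if ch == "=":
                n_match += n
    return n_match / n_cols if n_cols else 0.0


def dereplicate_99(
    records: Iterable[Rearrangement], threshold: float = 0.99
) -> list[Rearrangement]:
    """Collapse records at >= ``threshold`` global identity.

    Returns one representative per cluster (the cluster seed) with
    ``duplicate_count`` summed over members. Identical inputs collapse
    exactly; the operation is idempotent.
    """
    ordered = sorted(
        records, key=lambda r: (-r.duplicate_count, -len(r.sequence), r.sequence_id)
    )
    seeds: list[Rearrangement] = []
    seed_sigs: list[frozenset] = []
    totals: list[int] = []
    max_len_delta = 0
    for rec in ordered:
        sig = _signature(rec.sequence)
        placed = False
        for i, seed in enumerate(seeds):
            if abs(len(seed.sequence) - len(rec.sequence)) > (1 - threshold) * (
                len(seed.sequence) + len(rec.sequence)
            ) + 1:
                continue
            common = len(sig & seed_sigs[i])
            if common < max(1, len(seed_sigs[i]) // 3):
                continue
            if global_identity(rec.sequence, seed.sequence, threshold) >= threshold:
                totals[i] += rec.duplicate_count
                placed = True
                break
        if not placed:
            seeds.append(rec)
            seed_sigs.append(sig)
            totals.append(rec.duplicate_count)
    out = []
    for seed, total in zip(seeds, totals):
        rep = Rearrangement(**{**seed.__dict__})
        rep.duplicate_count = total
        out.append(rep)
    return out


# ---------------------------------------------------------------------------
# Clonal families
# ---------------------------------------------------------------------------


@dataclass
class ClonalFamily:
    family_id: str
    v_call: str  # gene level
    j_call: str  # gene level
    cdr3_length_aa: int
    member_ids: list
    representative_id: str
    total_duplicates: int
    members: list = field(default_factory=list, repr=False)


def _aa_identity_matrix(cdr3s: list[str]) -> np.ndarray:
    arr = np.frombuffer("".join(cdr3s).encode(), dtype=np.uint8).reshape(
        len(cdr3s), len(cdr3s[0])
    )
    eq = (arr[:, None, :] == arr[None, :, :]).mean(axis=2)
    return eq


def infer_clonal_families(
    records: Iterable[Rearrangement], threshold: float = 0.8
) -> list[ClonalFamily]:
    """Single-linkage clonal grouping by the three-condition rule.

    Output is a partition of the input records, invariant to input order;
    ``family_id`` is a content hash of the sorted member ids.
    """
    buckets: dict[tuple, list[Rearrangement]] = defaultdict(list)
    for rec in records:
        if rec.v_call is None or rec.j_call is None or rec.cdr3_aa is None:
            continue
        key = (gene_from_name(rec.v_call), gene_from_name(rec.j_call), len(rec.cdr3_aa))
        buckets[key].append(rec)
    families: list[ClonalFamily] = []
    for (v_gene, j_gene, length), members in buckets.items():
        members = sorted(members, key=lambda r: r.sequence_id)
        n = len(members)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        if n > 1 and length > 0:
            identity = _aa_identity_matrix([m.cdr3_aa for m in members])
            ii, jj = np.nonzero(identity >= threshold)
            for i, j in zip(ii, jj):
                if i < j:
                    ri, rj = find(int(i)), find(int(j))
                    if ri != rj:
                        parent[rj] = ri
        groups: dict[int, list[Rearrangement]] = defaultdict(list)
        for i, rec in enumerate(members):
            groups[find(i)].append(rec)
        for group in groups.values():
            ids = sorted(r.sequence_id for r in group)
            fam_id = hashlib.sha1("\x1f".join(ids).encode()).hexdigest()[:12]
            rep = sorted(group, key=lambda r: (-r.duplicate_count, r.sequence_id))[0]
            families.append(
                ClonalFamily(
                    family_id=fam_id,
                    v_call=v_gene,
                    j_call=j_gene,
                    cdr3_length_aa=length,
                    member_ids=ids,
                    representative_id=rep.sequence_id,
                    total_duplicates=sum(r.duplicate_count for r in group),
                    members=group,
                )
            )
    families.sort(key=lambda f: f.family_id)
    return families


def families_table(families: list[ClonalFamily]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "family_id": [f.family_id for f in families],
            "v_call": [f.v_call for f in families],
            "j_call": [f.j_call for f in families],
            "cdr3_length_aa": [f.cdr3_length_aa for f in families],
            "n_members": [len(f.member_ids) for f in families],
            "total_duplicates": [f.total_duplicates for f in families],
            "representative_id": [f.representative_id for f in families],
            "member_ids": [",".join(f.member_ids) for f in families],
        }
    )


# ---------------------------------------------------------------------------
# Single-nucleotide clone networks
# ---------------------------------------------------------------------------


def build_clone_network(records: Iterable[Rearrangement]) -> nx.Graph:
    """Graph over unique sequences with edges at Hamming distance exactly 1.

    Vertices carry ``size`` (duplicate_count) and ``mutations``
    (vh_mutation_count); edges connect equal-length sequences differing by
    a single non-indel nucleotide. Uses a one-position-wildcard index for
    expected O(n·L) construction.
    """
    records = list(records)
    graph = nx.Graph()
    for rec in records:
        graph.add_node(
            rec.sequence_id,
            size=rec.duplicate_count,
            mutations=rec.vh_mutation_count,
            sequence=rec.sequence,
        )
    index: dict[tuple, list] = defaultdict(list)
    for rec in records:
        seq = rec.sequence
        for pos in range(len(seq)):
            index[(len(seq), pos, seq[:pos], seq[pos + 1 :])].append(rec)
    for bucket in index.values():
        if len(bucket) < 2:
            continue
        for i in range(len(bucket)):
            for j in range(i + 1, len(bucket)):
                a, b = bucket[i], bucket[j]
                if a.sequence != b.sequence:
                    graph.add_edge(a.sequence_id, b.sequence_id)
    return graph


def network_components(graph: nx.Graph) -> pd.DataFrame:
    rows = []
    for comp in nx.connected_components(graph):
        sizes = [graph.nodes[n]["size"] for n in comp]
        muts = [graph.nodes[n].get("mutations") for n in comp]
        muts = [m for m in muts if m is not None]
        rows.append(
            {
                "n_vertices": len(comp),
                "total_duplicates": sum(sizes),
                "max_vertex_size": max(sizes),
                "mean_mutations": float(np.mean(muts)) if muts else np.nan,
            }
        )
    return pd.DataFrame(rows).sort_values(
        ["n_vertices", "total_duplicates"], ascending=False, ignore_index=True
    )


def export_network(graph: nx.Graph, graphml_path=None, edgelist_path=None) -> None:
    if graphml_path is not None:
        export = nx.Graph()
        for n, data in graph.nodes(data=True):
            export.add_node(n, size=int(data.get("size", 1)))
        export.add_edges_from(graph.edges())
        nx.write_graphml(export, graphml_path)
    if edgelist_path is not None:
        with open(edgelist_path, "w") as out:
            out.write("source\ttarget\n")
            for a, b in sorted(map(sorted, graph.edges())):
                out.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Clonal expansion summaries
# ---------------------------------------------------------------------------

_SIZE_STRATA = ((1, 1), (2, 4), (5, 9), (10, None))


def expansion_summary(
    families: list[ClonalFamily], min_expanded_size: int = 2
) -> pd.DataFrame:
    """Per (group, isotype) clonal-expansion statistics.

    Clone size is the member count; the table reports clone counts, size
    quantiles, the fraction of sequences lying in clones of size >=
    ``min_expanded_size``, and the mean mutation load per size stratum.
    """
    rows = []
    keyed: dict[tuple, list[ClonalFamily]] = defaultdict(list)
    for fam in families:
        groups = {m.metadata.get("group", "all") for m in fam.members}
        isotypes = {m.isotype for m in fam.members}
        for g in groups:
            for iso in isotypes:
                keyed[(g, iso)].append(fam)
    for (group, isotype), fams in sorted(keyed.items()):
        sizes = np.array([len(f.member_ids) for f in fams])
        n_seqs = sizes.sum()
        expanded = sizes[sizes >= min_expanded_size].sum()
        row = {
            "group": group,
            "isotype": isotype,
            "n_clones": len(fams),
            "n_sequences": int(n_seqs),
            "clone_size_q50": float(np.quantile(sizes, 0.5)),
            "clone_size_q90": float(np.quantile(sizes, 0.9)),
            "clone_size_max": int(sizes.max()),
            "fraction_in_expanded": float(expanded / n_seqs) if n_seqs else 0.0,
        }
        for lo, hi in _SIZE_STRATA:
            label = f"mean_mutations_size_{lo}" + (f"_{hi}" if hi else "_plus")
            muts = [
                m.vh_mutation_count
                for f in fams
                if lo <= len(f.member_ids) <= (hi or np.inf)
                for m in f.members
                if m.vh_mutation_count is not None
            ]
            row[label] = float(np.mean(muts)) if muts else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def clone_size_tail_exponent(sizes: Iterable[int]) -> float:
    """Discrete power-law (zeta) MLE for the clone-size exponent at xmin=1."""
    from scipy.optimize import minimize_scalar
    from scipy.special import zeta

    sizes = np.asarray(list(sizes), dtype=float)
    sizes = sizes[sizes >= 1]
    mean_log = np.mean(np.log(sizes))

    def negative_loglik(alpha):
        return alpha * mean_log + np.log(zeta(alpha, 1))

    result = minimize_scalar(negative_loglik, bounds=(1.01, 10.0), method="bounded")
    return float(result.x)
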