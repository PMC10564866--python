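"""Blood–gut clone sharing: find mucosal monoclonal antibody sequences
inside bulk repertoires.

A monoclonal antibody (mAb) matches a bulk NGS record iff both carry the
identical V gene and J gene (allele suffixes stripped), their CDR_H3s
have equal amino-acid length, and the CDR_H3 amino-acid identity is at
least 90%. Isotype is deliberately not part of the rule: shared clones
may appear under both IgA and IgG. Homology between different-length
junctions is undefined without an indel model, so length equality is
required before identity is computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .repertoire_io import Rearrangement, gene_from_name
from .repertoire_features import fisher_exact_2x2


@dataclass
class SharingRecord:
    mab_id: str
    v_gene: str
    j_gene: str
    cdr3_aa: str
    isotype: str
    polyreactive: Optional[bool]
    match_ids: list = field(default_factory=list)
    match_compartments: list = field(default_factory=list)
    best_identity: float = 0.0


def _aa_identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


def find_shared(
    mab_table: pd.DataFrame,
    ngs_records: Iterable[Rearrangement],
    min_identity: float = 0.90,
) -> list[SharingRecord]:
    """Match each mAb against the bulk repertoire under the sharing rule.

    ``mab_table`` needs columns mab_id, v_call, j_call, cdr3_aa and
    optionally isotype / polyreactive. Returns one SharingRecord per mAb
    with at least one match; mAbs lacking a CDR_H3 are skipped with a
    warning.
    """
    index: dict[tuple, list[Rearrangement]] = {}
    for rec in ngs_records:
        if rec.v_call is None or rec.j_call is None or not rec.cdr3_aa:
            continue
        key = (gene_from_name(rec.v_call), gene_from_name(rec.j_call), len(rec.cdr3_aa))
        index.setdefault(key, []).append(rec)
    shared: list[SharingRecord] = []
    for row in mab_table.to_dict("records"):
        cdr3 = row.get("cdr3_aa")
        if not isinstance(cdr3, str) or not cdr3:
            warnings.warn(f"mAb {row.get('mab_id')} lacks a CDR_H3; skipped", stacklevel=2)
            continue
        v_gene = gene_from_name(str(row["v_call"]))
        j_gene = gene_from_name(str(row["j_call"]))
        record = SharingRecord(
            mab_id=str(row["mab_id"]),
            v_gene=v_gene,
            j_gene=j_gene,
            cdr3_aa=cdr3,
            isotype=str(row.get("isotype", "unknown")),
            polyreactive=(None if "polyreactive" not in row else bool(row["polyreactive"])),
        )
        for rec in index.get((v_gene, j_gene, len(cdr3)), []):
            identity = _aa_identity(cdr3, rec.cdr3_aa)
            if identity >= min_identity:
                record.match_ids.append(rec.sequence_id)
                record.match_compartments.append(rec.metadata.get("compartment", ""))
                record.best_identity = max(record.best_identity, identity)
        if record.match_ids:
            shared.append(record)
    return shared


def sharing_frequency_test(
    shared_a: int, n_a: int, shared_b: int, n_b: int
) -> dict:
    """Per-group sharing percentages with the two-sided Fisher exact p."""
    if n_a == 0 or n_b == 0:
        raise ValueError("group size must be > 0")
    return {
        "percent_a": 100.0 * shared_a / n_a,
        "percent_b": 100.0 * shared_b / n_b,
        "p_value": fisher_exact_2x2(shared_a, n_a - shared_a, shared_b, n_b - shared_b),
    }


def export_sharing_links(records: list[SharingRecord], path) -> int:
    """Circos-style link table: one row per (mAb, matching NGS sequence),
    sorted by mab_id then target id."""
    rows = []
    for rec in sorted(records, key=lambda r: r.mab_id):
        for ngs_id, compartment in sorted(zip(rec.match_ids, rec.match_compartments)):
            rows.append(
                {
                    "source_compartment": "gut",
                    "mab_id": rec.mab_id,
                    "target_compartment": compartment,
                    "ngs_id": ngs_id,
                    "identity": rec.best_identity,
                }
            )
    pd.DataFrame(
        rows,
        columns=["source_compartment", "mab_id", "target_compartment", "ngs_id", "identity"],
    ).to_csv(path, sep="\t", index=False)
    return len(rows)
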