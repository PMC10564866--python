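"""Sequence I/O and the germline segment reference.

This module owns the on-disk formats used throughout the pipeline —
FASTA, FASTQ (Phred+33) and an AIRR-style rearrangement TSV — and the
in-memory model of the V/J/C germline reference every other stage
aligns against.

Coordinates are 0-based half-open internally; serialized alignment
positions (``v_subject_start``) are 1-based, mirroring the BLAST
convention used by the subject-alignment-start quality filter.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

IUPAC_NT = set("ACGTRYSWKMBDHVN")
STOP_CODONS = {"TAA", "TAG", "TGA"}
CYS_CODONS = {"TGT", "TGC"}
GLY_CODONS = {"GGT", "GGC", "GGA", "GGG"}


class ParseError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Domain invariant violated by an input object."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


def family_from_name(name: str) -> str:
    """Gene-family label from an allele name, e.g. ``TVH3-1*01`` -> ``VH3``.

    The leading letter is a provenance prefix; the family is the token up
    to the gene number (before ``-``) with the allele suffix stripped.
    """
    core = name.split("*")[0]
    core = core.split("-")[0]
    return core[1:] if core[:1].isalpha() and len(core) > 1 else core


def gene_from_name(name: str) -> str:
    """Gene-level call: the allele suffix ``*NN`` stripped."""
    return name.split("*")[0]


@dataclass(frozen=True)
class GermlineSegment:
    """One reference V, J or constant-region segment.

    V segments carry ``cys104_offset``, the 0-based offset of the
    conserved cysteine codon that opens CDR_H3; J segments carry
    ``fr4_motif_offset``, the offset of the codon beginning the
    W-G-x-G framework-4 motif that closes it.
    """

    name: str
    segment_type: str  # V, J or C
    sequence: str
    cys104_offset: Optional[int] = None
    fr4_motif_offset: Optional[int] = None
    isotype_label: Optional[str] = None  # IGA / IGG for C segments

    @property
    def family(self) -> str:
        return family_from_name(self.name)

    @property
    def gene(self) -> str:
        return gene_from_name(self.name)

    def validate(self) -> None:
        if self.segment_type not in {"V", "J", "C"}:
            raise ValidationError(f"{self.name}: segment_type must be V/J/C")
        if len(self.sequence) < 3:
            raise ValidationError(f"{self.name}: sequence shorter than one codon")
        if set(self.sequence) - set("ACGT"):
            raise ValidationError(f"{self.name}: germline contains non-ACGT characters")
        if self.segment_type == "V":
            if self.cys104_offset is None:
                raise ValidationError(f"{self.name}: V segment lacks cys104_offset")
            codon = self.sequence[self.cys104_offset : self.cys104_offset + 3]
            if codon not in CYS_CODONS:
                raise ValidationError(
                    f"{self.name}: codon at cys104_offset is {codon!r}, not a Cys codon"
                )
            aa = str(Seq(self.sequence[: self.cys104_offset + 3]).translate())
            if "*" in aa:
                raise ValidationError(f"{self.name}: stop codon upstream of Cys104")
        elif self.cys104_offset is not None:
            raise ValidationError(f"{self.name}: cys104_offset only valid on V segments")
        if self.segment_type == "J":
            off = self.fr4_motif_offset
            if off is None:
                raise ValidationError(f"{self.name}: J segment lacks fr4_motif_offset")
            codons = [self.sequence[off + 3 * i : off + 3 * i + 3] for i in range(4)]
            if len(codons[3]) < 3:
                raise ValidationError(f"{self.name}: W-G-x-G motif runs past sequence end")
            if codons[0] != "TGG" or codons[1] not in GLY_CODONS or codons[3] not in GLY_CODONS:
                raise ValidationError(f"{self.name}: no W-G-x-G motif at fr4_motif_offset")
        elif self.fr4_motif_offset is not None:
            raise ValidationError(f"{self.name}: fr4_motif_offset only valid on J segments")
        if self.segment_type == "C":
            if self.isotype_label not in {"IGA", "IGG"}:
                raise ValidationError(f"{self.name}: C segment needs isotype_label IGA/IGG")
        elif self.isotype_label is not None:
            raise ValidationError(f"{self.name}: isotype_label only valid on C segments")


class GermlineReference:
    """A validated set of germline segments with unique names."""

    def __init__(self, segments: Iterable[GermlineSegment]):
        self.segments = list(segments)
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate germline names: {dupes}")
        for seg in self.segments:
            seg.validate()
        self.by_name = {s.name: s for s in self.segments}
        self.v_segments = [s for s in self.segments if s.segment_type == "V"]
        self.j_segments = [s for s in self.segments if s.segment_type == "J"]
        self.c_segments = [s for s in self.segments if s.segment_type == "C"]

    def __len__(self) -> int:
        return len(self.segments)

    def __getitem__(self, name: str) -> GermlineSegment:
        return self.by_name[name]


@dataclass
class SequenceRecord:
    """One raw or merged read with optional qualities and sample metadata."""

    id: str
    sequence: str
    qualities: Optional[list[int]] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValidationError(
                f"record {self.id}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )


@dataclass
class Rearrangement:
    """One annotated heavy-chain sequence (AIRR-style record)."""

    sequence_id: str
    sequence: str
    v_call: Optional[str] = None
    j_call: Optional[str] = None
    v_family: Optional[str] = None
    j_family: Optional[str] = None
    v_score: Optional[float] = None
    v_evalue: Optional[float] = None
    v_subject_start: Optional[int] = None  # 1-based, BLAST convention
    cdr3_nt: Optional[str] = None
    cdr3_aa: Optional[str] = None
    isotype: str = "unknown"
    vh_mutation_count: Optional[int] = None
    vh_mutation_freq: Optional[float] = None
    productive: Optional[bool] = None
    duplicate_count: int = 1
    qc_flags: frozenset = frozenset()
    metadata: dict = field(default_factory=dict)

    @property
    def cdr3_length_aa(self) -> Optional[int]:
        return None if self.cdr3_aa is None else len(self.cdr3_aa)

    @property
    def passes_qc(self) -> bool:
        return len(self.qc_flags) == 0


# ---------------------------------------------------------------------------
# FASTQ / FASTA
# ---------------------------------------------------------------------------


def read_fastq(path) -> Iterator[SequenceRecord]:
    """Stream Phred+33 FASTQ records in file order.

    Raises :class:`ParseError` naming the (1-based) record index on a
    truncated block or a sequence/quality length mismatch.
    """
    with open(path) as handle:
        index = 0
        while True:
            header = handle.readline()
            if not header:
                return
            if not header.strip() and handle.readline() == "":
                return  # trailing blank line
            index += 1
            seq = handle.readline()
            plus = handle.readline()
            qual = handle.readline()
            if not qual:
                raise ParseError(f"record {index}: truncated FASTQ block")
            if not header.startswith("@") or not plus.startswith("+"):
                raise ParseError(f"record {index}: malformed FASTQ block")
            seq = seq.strip().upper()
            qual = qual.strip()
            if len(seq) != len(qual):
                raise ParseError(
                    f"record {index}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            yield SequenceRecord(
                id=header[1:].strip().split()[0],
                sequence=seq,
                qualities=[ord(c) - 33 for c in qual],
            )


def read_fasta(path) -> Iterator[SequenceRecord]:
    """Stream FASTA records; bases uppercased, non-IUPAC characters rejected,
    duplicate ids rejected."""
    seen: set[str] = set()
    dupes: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - IUPAC_NT
        if bad:
            raise ParseError(f"record {rec.id}: non-IUPAC characters {sorted(bad)}")
        if rec.id in seen:
            dupes.append(rec.id)
            continue
        seen.add(rec.id)
        meta = _parse_kv_description(rec.description)
        yield SequenceRecord(id=rec.id, sequence=seq, metadata=meta)
    if dupes:
        raise ParseError(f"duplicate sequence ids: {sorted(set(dupes))}")


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 80) -> int:
    """Write records as FASTA; metadata serialized as key=value tokens."""
    n = 0
    with open(path, "w") as out:
        for rec in records:
            desc = " ".join(f"{k}={v}" for k, v in sorted(rec.metadata.items()))
            header = f">{rec.id} {desc}".rstrip()
            out.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i : i + width] + "\n")
            n += 1
    return n


def _parse_kv_description(description: str) -> dict:
    meta = {}
    for token in description.split()[1:]:
        if "=" in token:
            k, v = token.split("=", 1)
            meta[k] = v
    return meta


# ---------------------------------------------------------------------------
# AIRR-style rearrangement TSV
# ---------------------------------------------------------------------------

# AIRR Rearrangement field names are used where the schema has a matching
# field; pipeline-specific columns keep their internal names.
_AIRR_COLUMNS = [
    "sequence_id",
    "sequence",
    "v_call",
    "j_call",
    "v_family",
    "j_family",
    "v_score",
    "v_evalue",
    "v_subject_start",
    "junction",
    "junction_aa",
    "isotype",
    "vh_mutation_count",
    "vh_mutation_freq",
    "productive",
    "duplicate_count",
    "qc_flags",
]
_METADATA_COLUMNS = ["donor_id", "group", "compartment", "clone_id"]


def write_rearrangements(records: Iterable[Rearrangement], path) -> int:
    """Serialize annotated records as a tab-separated AIRR-style table."""
    rows = []
    for r in records:
        row = {
            "sequence_id": r.sequence_id,
            "sequence": r.sequence,
            "v_call": r.v_call,
            "j_call": r.j_call,
            "v_family": r.v_family,
            "j_family": r.j_family,
            "v_score": r.v_score,
            "v_evalue": r.v_evalue,
            "v_subject_start": r.v_subject_start,
            "junction": r.cdr3_nt,
            "junction_aa": r.cdr3_aa,
            "isotype": "" if r.isotype == "unknown" else r.isotype,
            "vh_mutation_count": r.vh_mutation_count,
            "vh_mutation_freq": r.vh_mutation_freq,
            "productive": "" if r.productive is None else ("T" if r.productive else "F"),
            "duplicate_count": r.duplicate_count,
            "qc_flags": ",".join(sorted(r.qc_flags)),
        }
        for col in _METADATA_COLUMNS:
            row[col] = r.metadata.get(col, "")
        rows.append(row)
    df = pd.DataFrame(rows, columns=_AIRR_COLUMNS + _METADATA_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return len(rows)


def read_rearrangements(path) -> list[Rearrangement]:
    """Read back a rearrangement TSV written by :func:`write_rearrangements`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        meta = {c: d[c] for c in _METADATA_COLUMNS if d.get(c, "") != ""}
        records.append(
            Rearrangement(
                sequence_id=d["sequence_id"],
                sequence=d["sequence"],
                v_call=d["v_call"] or None,
                j_call=d["j_call"] or None,
                v_family=d["v_family"] or None,
                j_family=d["j_family"] or None,
                v_score=float(d["v_score"]) if d["v_score"] else None,
                v_evalue=float(d["v_evalue"]) if d["v_evalue"] else None,
                v_subject_start=int(d["v_subject_start"]) if d["v_subject_start"] else None,
                cdr3_nt=d["junction"] or None,
                cdr3_aa=d["junction_aa"] or None,
                isotype=d["isotype"] or "unknown",
                vh_mutation_count=int(d["vh_mutation_count"]) if d["vh_mutation_count"] else None,
                vh_mutation_freq=float(d["vh_mutation_freq"]) if d["vh_mutation_freq"] else None,
                productive=None if d["productive"] == "" else d["productive"] == "T",
                duplicate_count=int(d["duplicate_count"]),
                qc_flags=frozenset(f for f in d["qc_flags"].split(",") if f),
                metadata=meta,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Germline reference loading
# ---------------------------------------------------------------------------

_NONSTOP_CODONS = sorted(
    {a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"} - STOP_CODONS
)


def _builtin_reference() -> GermlineReference:
    """Deterministically construct the packaged toy germline set.

    Nine V alleles over four families (two genes per family plus a second
    allele of TVH3-1), four J alleles and two constant segments. The set is
    synthetic — generated from a fixed seed, not copied from IMGT — with
    families ~75% divergent so assignment is unambiguous even under heavy
    hypermutation, and sibling genes differing at 9 codons.
    """
    rng = np.random.default_rng(20240817)

    def codons(n):
        return [_NONSTOP_CODONS[i] for i in rng.integers(0, len(_NONSTOP_CODONS), n)]

    segments: list[GermlineSegment] = []
    n_codons = 97  # plus the terminal Cys codon -> 294 nt
    for fam in (1, 2, 3, 4):
        backbone = codons(n_codons)
        variant = list(backbone)
        for pos in rng.choice(n_codons, size=9, replace=False):
            alternatives = [c for c in _NONSTOP_CODONS if c != variant[pos]]
            variant[pos] = alternatives[rng.integers(0, len(alternatives))]
        for gene_num, cod in ((1, backbone), (2, variant)):
            seq = "".join(cod) + "TGT"
            segments.append(
                GermlineSegment(
                    name=f"TVH{fam}-{gene_num}*01",
                    segment_type="V",
                    sequence=seq,
                    cys104_offset=len(seq) - 3,
                )
            )
    # second allele of TVH3-1, as distinguishable as sibling genes so
    # hypermutation cannot plausibly flip allele calls
    base = segments[4]
    cod = [base.sequence[i : i + 3] for i in range(0, n_codons * 3, 3)]
    for pos in rng.choice(n_codons, size=9, replace=False):
        alternatives = [c for c in _NONSTOP_CODONS if c != cod[pos]]
        cod[pos] = alternatives[rng.integers(0, len(alternatives))]
    segments.append(
        GermlineSegment(
            name="TVH3-1*02",
            segment_type="V",
            sequence="".join(cod) + "TGT",
            cys104_offset=n_codons * 3,
        )
    )
    gly = list(GLY_CODONS)
    for j in (1, 2, 3, 4):
        tail = "".join(codons(2))  # 6 nt of CDR3 contributed by J
        motif = "TGG" + gly[int(rng.integers(0, 4))] + codons(1)[0] + gly[int(rng.integers(0, 4))]
        fr4 = "".join(codons(7))
        segments.append(
            GermlineSegment(
                name=f"TVJ{j}*01",
                segment_type="J",
                sequence=tail + motif + fr4,
                fr4_motif_offset=6,
            )
        )
    for isotype in ("IGA", "IGG"):
        segments.append(
            GermlineSegment(
                name=f"T{isotype}*01",
                segment_type="C",
                sequence="".join(str(b) for b in rng.choice(list("ACGT"), 60)),
                isotype_label=isotype,
            )
        )
    return GermlineReference(segments)


_BUILTIN_CACHE: Optional[GermlineReference] = None


def load_germline_reference(source="builtin") -> GermlineReference:
    """Load a germline reference from a FASTA with key=value anchor
    annotations in the description line, or the packaged toy set."""
    global _BUILTIN_CACHE
    if source == "builtin":
        if _BUILTIN_CACHE is None:
            _BUILTIN_CACHE = _builtin_reference()
        return _BUILTIN_CACHE
    segments = []
    for rec in SeqIO.parse(str(source), "fasta"):
        meta = _parse_kv_description(rec.description)
        if "segment_type" not in meta:
            raise ValidationError(f"{rec.id}: description lacks segment_type=")
        segments.append(
            GermlineSegment(
                name=rec.id,
                segment_type=meta["segment_type"],
                sequence=str(rec.seq).upper(),
                cys104_offset=int(meta["cys104_offset"]) if "cys104_offset" in meta else None,
                fr4_motif_offset=(
                    int(meta["fr4_motif_offset"]) if "fr4_motif_offset" in meta else None
                ),
                isotype_label=meta.get("isotype_label"),
            )
        )
    return GermlineReference(segments)


def write_germline_reference(reference: GermlineReference, path) -> None:
    """Serialize a reference as annotated FASTA (round-trips through
    :func:`load_germline_reference`)."""
    with open(path, "w") as out:
        for seg in reference.segments:
            parts = [f"segment_type={seg.segment_type}"]
            if seg.cys104_offset is not None:
                parts.append(f"cys104_offset={seg.cys104_offset}")
            if seg.fr4_motif_offset is not None:
                parts.append(f"fr4_motif_offset={seg.fr4_motif_offset}")
            if seg.isotype_label is not None:
                parts.append(f"isotype_label={seg.isotype_label}")
            out.write(f">{seg.name} {' '.join(parts)}\n{seg.sequence}\n")
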