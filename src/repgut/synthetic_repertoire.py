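"""Synthetic gut/blood immunoglobulin repertoire generator.

Emulates the statistical structure of paired mucosal (gut) and
peripheral-blood (blood) heavy-chain repertoires from two donor groups
(eART / lART): clonally expanded lineages built from toy germline V/J
segments, group- and compartment-dependent somatic hypermutation (SHM)
loads, an IgA-dominated isotype mix, a group-dependent fraction of gut
clones re-appearing in blood, and per-clone polyreactivity labels.
Every emitted sequence is tracked in a truth table so downstream stages
can be scored exactly.

The SHM model is substitution-only (mutation networks downstream assume
non-indel differences); substitutions that would create an in-frame stop
codon are resampled, modelling selection for productive receptors.
Mutations avoid the CDR3 anchor codons so junction extraction stays
well-defined in the clean limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .repertoire_io import (
    GermlineReference,
    STOP_CODONS,
    SequenceRecord,
    load_germline_reference,
)

GROUPS = ("eART", "lART")
COMPARTMENTS = ("gut", "blood")
ISOTYPES = ("IGA", "IGG")

# Mean V_H mutation counts per (group, compartment, isotype): the study
# conditions the generator reproduces.
DEFAULT_SHM_MEANS = {
    ("eART", "gut", "IGA"): 20.5,
    ("lART", "gut", "IGA"): 21.4,
    ("eART", "gut", "IGG"): 22.0,
    ("lART", "gut", "IGG"): 21.9,
    ("eART", "blood", "IGA"): 18.4,
    ("lART", "blood", "IGA"): 19.8,
    ("eART", "blood", "IGG"): 19.8,
    ("lART", "blood", "IGG"): 18.9,
}

# Gut memory B cells are ~36% IgA+ vs 22% IgG+ -> P(IgA)=36/58 renormalized.
DEFAULT_ISOTYPE_MIX = {"gut": 36.0 / 58.0, "blood": 0.55}

DEFAULT_SHARED_CLONE_FRACTION = {"eART": 0.049, "lART": 0.333}
DEFAULT_POLYREACTIVE_FRACTION = {"eART": 0.188, "lART": 0.313}


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Parameters of the synthetic repertoire.

    ``n_clones`` is the number of independent clonal lineages seeded per
    (group, compartment); shared gut clones additionally emit members in
    blood. ``clone_size_law`` is the exponent of the discrete power law
    for per-member duplicate counts.
    """

    seed: int = 0
    n_clones: int = 200
    clone_size_law: float = 2.5
    mean_members_per_clone: float = 5.0
    shm_mean: dict = field(default_factory=lambda: dict(DEFAULT_SHM_MEANS))
    isotype_mix: dict = field(default_factory=lambda: dict(DEFAULT_ISOTYPE_MIX))
    shared_clone_fraction: dict = field(
        default_factory=lambda: dict(DEFAULT_SHARED_CLONE_FRACTION)
    )
    polyreactive_fraction: dict = field(
        default_factory=lambda: dict(DEFAULT_POLYREACTIVE_FRACTION)
    )
    clone_shared_mutation_fraction: float = 0.6
    junction_length_range: tuple = (9, 60)  # nt, multiples of 3
    donors_per_group: int = 3
    read_error_rate: float = 0.001
    read_length: int = 300
    fragment_overlap: int = 150

    def validate(self) -> None:
        errors = []
        for name, mapping in (
            ("isotype_mix", self.isotype_mix),
            ("shared_clone_fraction", self.shared_clone_fraction),
            ("polyreactive_fraction", self.polyreactive_fraction),
        ):
            for k, v in mapping.items():
                if not 0.0 <= v <= 1.0:
                    errors.append(f"{name}[{k}]={v} outside [0,1]")
        for k, v in self.shm_mean.items():
            if v < 0:
                errors.append(f"shm_mean[{k}]={v} negative")
        lo, hi = self.junction_length_range
        if lo % 3 or hi % 3 or lo < 3 or hi < lo:
            errors.append(
                f"junction_length_range {self.junction_length_range} must be "
                "in-frame (multiples of 3) with 3 <= lo <= hi"
            )
        if not 0.0 <= self.read_error_rate <= 1.0:
            errors.append("read_error_rate outside [0,1]")
        if not 0.0 <= self.clone_shared_mutation_fraction <= 1.0:
            errors.append("clone_shared_mutation_fraction outside [0,1]")
        if self.n_clones < 1:
            errors.append("n_clones must be >= 1")
        if errors:
            raise ConfigError("; ".join(errors))


@dataclass
class TrueMember:
    member_id: str
    compartment: str
    sequence: str
    mutation_positions: tuple  # 0-based positions within the V region
    vh_mutation_count: int
    duplicate_count: int


@dataclass
class TrueClone:
    """Ground-truth clonal lineage: one V(D)J recombination event."""

    clone_id: str
    group: str
    donor_id: str
    v_name: str
    j_name: str
    junction_nt: str  # CDR_H3 nucleotides (post-Cys through pre-Trp)
    junction_aa: str
    isotype: str
    polyreactive: bool
    compartments: tuple
    members: list = field(default_factory=list)


@dataclass
class SimulatedRepertoire:
    config: SimulationConfig
    reference: GermlineReference
    clones: list
    truth: pd.DataFrame  # one row per emitted member sequence

    def sequences(self, compartment: Optional[str] = None) -> list[SequenceRecord]:
        out = []
        for clone in self.clones:
            for m in clone.members:
                if compartment is not None and m.compartment != compartment:
                    continue
                out.append(
                    SequenceRecord(
                        id=m.member_id,
                        sequence=m.sequence,
                        metadata={
                            "donor_id": clone.donor_id,
                            "group": clone.group,
                            "compartment": m.compartment,
                            "clone_id": clone.clone_id,
                            "duplicate_count": m.duplicate_count,
                        },
                    )
                )
        return out


_CODON_TABLE = None


def _translate(nt: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(nt[: len(nt) - len(nt) % 3]).translate())


def _random_junction(rng, lo, hi) -> str:
    """In-frame stop-free junction insert of random length in [lo, hi] nt."""
    n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
    codons = []
    bases = "ACGT"
    while len(codons) < n_codons:
        codon = "".join(bases[i] for i in rng.integers(0, 4, 3))
        if codon not in STOP_CODONS:
            codons.append(codon)
    return "".join(codons)


def _apply_mutations(sequence: str, v_len: int, positions, rng) -> str:
    """Substitute the V-region positions, avoiding in-frame stop codons.

    The reading frame starts at 0 (germline V is in frame by construction).
    """
    seq = list(sequence)
    for pos in positions:
        codon_start = pos - pos % 3
        old = seq[pos]
        choices = []
        for base in "ACGT":
            if base == old:
                continue
            codon = "".join(seq[codon_start : codon_start + 3])
            idx = pos - codon_start
            codon = codon[:idx] + base + codon[idx + 1 :]
            if codon not in STOP_CODONS:
                choices.append(base)
        seq[pos] = choices[int(rng.integers(0, len(choices)))]
    return "".join(seq)


def _draw_positions(rng, allowed: np.ndarray, k: int, exclude: set) -> list[int]:
    pool = [p for p in allowed if p not in exclude]
    k = min(k, len(pool))
    if k == 0:
        return []
    return [int(p) for p in rng.choice(pool, size=k, replace=False)]


def simulate_repertoire(
    config: SimulationConfig, reference: Optional[GermlineReference] = None
) -> SimulatedRepertoire:
    """Generate the full two-group, two-compartment synthetic repertoire.

    For every clone a V and J allele are drawn, a random in-frame junction
    inserted, clone-level shared mutations applied, then per-member private
    substitutions; shared gut clones also emit members in blood with the
    identical junction. Output is deterministic given ``config.seed``.
    """
    config.validate()
    if reference is None:
        reference = load_germline_reference("builtin")
    rng = np.random.default_rng(config.seed)
    lo, hi = config.junction_length_range

    c_by_isotype = {c.isotype_label: c for c in reference.c_segments}
    clones: list[TrueClone] = []
    truth_rows: list[dict] = []
    clone_counter = 0

    for group in GROUPS:
        donors = [f"{group[0].upper()}{i+1}" for i in range(config.donors_per_group)]
        for compartment in COMPARTMENTS:
            for _ in range(config.n_clones):
                clone_counter += 1
                clone_id = f"clone{clone_counter:06d}"
                v = reference.v_segments[int(rng.integers(0, len(reference.v_segments)))]
                j = reference.j_segments[int(rng.integers(0, len(reference.j_segments)))]
                isotype = "IGA" if rng.random() < config.isotype_mix[compartment] else "IGG"
                insert = _random_junction(rng, lo, hi)
                junction_nt = insert + j.sequence[: j.fr4_motif_offset]
                donor = donors[int(rng.integers(0, len(donors)))]
                polyreactive = bool(rng.random() < config.polyreactive_fraction[group])

                shared_to_blood = (
                    compartment == "gut"
                    and rng.random() < config.shared_clone_fraction[group]
                )
                compartments = ("gut", "blood") if shared_to_blood else (compartment,)

                clone = TrueClone(
                    clone_id=clone_id,
                    group=group,
                    donor_id=donor,
                    v_name=v.name,
                    j_name=j.name,
                    junction_nt=junction_nt,
                    junction_aa=_translate(junction_nt),
                    isotype=isotype,
                    polyreactive=polyreactive,
                    compartments=compartments,
                )

                v_len = len(v.sequence)
                # mutable V positions: everything before the anchor Cys codon
                allowed = np.arange(0, v.cys104_offset)
                mu_home = config.shm_mean[(group, compartment, isotype)]
                n_shared = int(rng.poisson(config.clone_shared_mutation_fraction * mu_home))
                shared_positions = _draw_positions(rng, allowed, n_shared, set())
                template = v.sequence + insert + j.sequence + c_by_isotype[isotype].sequence
                clone_base = _apply_mutations(template, v_len, shared_positions, rng)

                member_counter = 0
                for member_compartment in compartments:
                    mu_local = config.shm_mean[(group, member_compartment, isotype)]
                    private_mu = max(
                        0.0, mu_local - config.clone_shared_mutation_fraction * mu_home
                    )
                    n_members = 1 + int(rng.poisson(config.mean_members_per_clone - 1.0))
                    for _ in range(n_members):
                        member_counter += 1
                        n_private = int(rng.poisson(private_mu))
                        private_positions = _draw_positions(
                            rng, allowed, n_private, set(shared_positions)
                        )
                        seq = _apply_mutations(clone_base, v_len, private_positions, rng)
                        positions = tuple(sorted(shared_positions + private_positions))
                        dup = int(min(rng.zipf(config.clone_size_law), 10_000))
                        member = TrueMember(
                            member_id=f"{clone_id}.{member_compartment}.{member_counter}",
                            compartment=member_compartment,
                            sequence=seq,
                            mutation_positions=positions,
                            vh_mutation_count=len(positions),
                            duplicate_count=dup,
                        )
                        clone.members.append(member)
                        truth_rows.append(
                            {
                                "sequence_id": member.member_id,
                                "clone_id": clone_id,
                                "group": group,
                                "compartment": member_compartment,
                                "donor_id": donor,
                                "isotype": isotype,
                                "v_call": v.name,
                                "j_call": j.name,
                                "junction": junction_nt,
                                "junction_aa": clone.junction_aa,
                                "vh_mutation_count": member.vh_mutation_count,
                                "duplicate_count": dup,
                                "polyreactive": polyreactive,
                            }
                        )
                clones.append(clone)

    truth = pd.DataFrame(truth_rows)
    return SimulatedRepertoire(config=config, reference=reference, clones=clones, truth=truth)


# ---------------------------------------------------------------------------
# Paired-end read emission
# ---------------------------------------------------------------------------


def emit_paired_reads(
    repertoire: SimulatedRepertoire,
    config: Optional[SimulationConfig] = None,
    compartment: Optional[str] = None,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Split each template into an overlapping 5' (R1) / 3' (R2) read pair.

    R2 is reverse-complemented, as sequenced. Per-base substitution errors
    are applied at ``read_error_rate``; erroneous bases are assigned lower
    Phred qualities than correct ones so quality-aware merging can vote.
    """
    config = config or repertoire.config
    if config.fragment_overlap < 10:
        warnings.warn(
            "fragment_overlap < 10: the merger's minimum-overlap rule will drop all pairs",
            stacklevel=2,
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x9E3779B9]))
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    r1_out, r2_out = [], []
    for rec in repertoire.sequences(compartment):
        template = rec.sequence
        L = len(template)
        r1_len = min(config.read_length, (L + config.fragment_overlap + 1) // 2, L)
        r2_len = min(config.read_length, L + config.fragment_overlap - r1_len, L)
        for mate, raw in (("1", template[:r1_len]), ("2", template[L - r2_len :])):
            bases = list(raw)
            quals = np.clip(
                np.rint(rng.normal(38.0, 1.5, len(bases))), 30, 40
            ).astype(int)
            err = rng.random(len(bases)) < config.read_error_rate
            for i in np.flatnonzero(err):
                alternatives = [b for b in "ACGT" if b != bases[i]]
                bases[i] = alternatives[int(rng.integers(0, 3))]
                quals[i] = int(np.clip(np.rint(rng.normal(18.0, 3.0)), 2, 25))
            read = "".join(bases)
            if mate == "2":
                read = "".join(comp[b] for b in reversed(read))
                quals = quals[::-1]
            (r1_out if mate == "1" else r2_out).append(
                SequenceRecord(
                    id=f"{rec.id}/{mate}",
                    sequence=read,
                    qualities=[int(q) for q in quals],
                    metadata=dict(rec.metadata),
                )
            )
    return r1_out, r2_out


def write_fastq(records, path) -> int:
    n = 0
    with open(path, "w") as out:
        for rec in records:
            qual = "".join(chr(q + 33) for q in rec.qualities)
            out.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")
            n += 1
    return n


def write_truth_table(repertoire: SimulatedRepertoire, path) -> None:
    repertoire.truth.to_csv(path, sep="\t", index=False)
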