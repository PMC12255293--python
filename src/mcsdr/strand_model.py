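"""Sequence/domain data model for mismatch-closure strand-displacement probes.

A probe system couples four functional strands:

* ``target_pm`` -- the probe-matched (mutant) target, written 5'->3' as
  ``[toehold][branch-migration][spacer][association]``; the interrogated base
  sits at the last position of the toehold, abutting the branch-migration
  domain.
* ``target_mm`` -- the same strand carrying the other allele at that position.
* ``helper`` -- an auxiliary strand whose 5' block anchors on the association
  domain and whose 3' end "closes" ``n_close`` bases ending at the mutation
  site.  The helper is complementary to the *mismatched* target there, so on
  the matched target the closure carries a destabilising mismatch and falls
  off, leaving the normal displacement pathway open.
* ``f_strand`` / ``q_strand`` -- the fluorophore/quencher reporter duplex.
  ``q_strand`` exposes a single-stranded toehold complementary to the target's
  toehold; displacement of ``f_strand`` restores fluorescence.

Coordinates are 0-based, half-open, on the 5'->3' strand string.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

__all__ = [
    "AlphabetError",
    "DesignError",
    "MutationConsistencyError",
    "NucleotideStrand",
    "DomainAnnotation",
    "MutationSpec",
    "ProbeSystem",
    "reverse_complement",
    "apply_mutation",
    "enumerate_mutation_types",
    "build_probe_system",
    "read_fasta",
    "write_fasta",
    "load_design",
    "save_design",
    "build_from_design",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = "ACGT"

DomainKind = Literal["toehold", "branch_migration", "spacer", "association", "reverse_toehold"]
SpacerPos = Literal["bottom", "helper", "target"]

# Fixed sequence used for the retained reverse toehold in the toehold-exchange
# variant; alternating C/A avoids self-structure and accidental target pairing.
_REV_TOEHOLD_POOL = "CACACACACACACACA"
# Spacers are unpaired flexibility bases; poly-T is the conventional choice.
_SPACER_BASE = "T"


class AlphabetError(ValueError):
    """A sequence contains characters outside {A, C, G, T}."""


class DesignError(ValueError):
    """Design parameters are inconsistent with the supplied sequences."""


class MutationConsistencyError(ValueError):
    """A mutation's reference base does not match the target sequence."""


def _check_alphabet(seq: str) -> str:
    bad = set(seq) - set(_BASES)
    if bad:
        raise AlphabetError(f"non-ACGT characters in sequence: {sorted(bad)}")
    return seq


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement, 5'->3' in and out."""
    _check_alphabet(seq)
    return seq.translate(str.maketrans(_COMPLEMENT))[::-1]


@dataclass(frozen=True)
class NucleotideStrand:
    """A named DNA strand, sequence 5'->3', optionally dye/quencher labelled."""

    name: str
    seq: str
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise DesignError(f"strand {self.name!r} has an empty sequence")
        _check_alphabet(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class DomainAnnotation:
    """Half-open [start, end) interval of a functional domain on a named strand."""

    kind: DomainKind
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise DesignError(f"invalid domain interval [{self.start}, {self.end})")


@dataclass(frozen=True)
class MutationSpec:
    """Single-base substitution: ``ref_base`` at ``position`` becomes ``alt_base``."""

    position: int
    ref_base: str
    alt_base: str

    def __post_init__(self) -> None:
        for b in (self.ref_base, self.alt_base):
            if b not in _BASES:
                raise AlphabetError(f"invalid base {b!r}")
        if self.ref_base == self.alt_base:
            raise DesignError("ref_base and alt_base must differ")
        if self.position < 0:
            raise DesignError("mutation position must be non-negative")


def apply_mutation(seq: str, spec: MutationSpec) -> str:
    """Return ``seq`` with the single-base substitution of ``spec`` applied."""
    _check_alphabet(seq)
    if spec.position >= len(seq):
        raise IndexError(f"mutation position {spec.position} outside sequence of length {len(seq)}")
    if seq[spec.position] != spec.ref_base:
        raise MutationConsistencyError(
            f"ref base {spec.ref_base!r} does not match sequence base "
            f"{seq[spec.position]!r} at position {spec.position}"
        )
    return seq[: spec.position] + spec.alt_base + seq[spec.position + 1 :]


def enumerate_mutation_types(position: int = 0) -> list[MutationSpec]:
    """All 12 ordered ref->alt single-base substitution templates."""
    return [
        MutationSpec(position=position, ref_base=r, alt_base=a)
        for r, a in itertools.product(_BASES, _BASES)
        if r != a
    ]


@dataclass(frozen=True)
class ProbeSystem:
    """A fully assembled probe system plus its design bookkeeping.

    ``toehold_len``/``bm_len``/``spacer_len`` describe the matched (PM) target;
    the mismatched target's *effective* domains follow from the closure: its
    free toehold is shorter by ``n_close`` bases, its branch-migration domain
    is shorter by one base and its spacer longer by one base (the closed bases
    are sequestered by the helper and the junction base is reassigned to the
    spacer).
    """

    target_pm: NucleotideStrand
    target_mm: NucleotideStrand
    helper: NucleotideStrand
    f_strand: NucleotideStrand
    q_strand: NucleotideStrand
    mutation: MutationSpec
    domains: tuple[DomainAnnotation, ...]
    n_close: int
    toehold_len: int
    bm_len: int
    spacer_len: int
    spacer_pos: SpacerPos
    rev_toehold_len: int

    # -- derived sequence views -------------------------------------------------
    @property
    def mut_index(self) -> int:
        return self.mutation.position

    @property
    def toehold_seq(self) -> str:
        return self.target_pm.seq[: self.toehold_len]

    @property
    def bm_seq(self) -> str:
        return self.target_pm.seq[self.toehold_len : self.toehold_len + self.bm_len]

    @property
    def displacement_seq(self) -> str:
        """Toehold + branch-migration region of the matched target."""
        return self.target_pm.seq[: self.toehold_len + self.bm_len]

    @property
    def association_seq(self) -> str:
        start = self.toehold_len + self.bm_len
        if self.spacer_pos == "target":
            start += self.spacer_len
        return self.target_pm.seq[start:]

    @property
    def rev_toehold_seq(self) -> str:
        return self.f_strand.seq[self.bm_len :]

    @property
    def mm_free_toehold_len(self) -> int:
        """Toehold bases the mismatched target can still nucleate with."""
        return self.toehold_len - self.n_close

    @property
    def mm_bm_len(self) -> int:
        return self.bm_len - 1

    def domain(self, kind: DomainKind, strand: str) -> DomainAnnotation:
        for d in self.domains:
            if d.kind == kind and d.strand == strand:
                return d
        raise KeyError(f"no {kind} domain on strand {strand}")


def build_probe_system(
    target: str,
    mut: MutationSpec,
    toehold_len: int,
    bm_len: int,
    spacer_len: int = 2,
    spacer_pos: SpacerPos = "bottom",
    n_close: int = 1,
    rev_toehold_len: int = 0,
) -> ProbeSystem:
    """Assemble a probe system around a matched target string.

    ``target`` is the probe-matched strand 5'->3' with the interrogated base at
    the toehold/branch-migration junction, i.e. ``mut.position`` must equal
    ``toehold_len - 1``.  ``apply_mutation`` produces the mismatched variant.
    Everything downstream (helper, reporter duplex, domain annotations) is
    derived from this one string by exact complementarity.
    """
    _check_alphabet(target)
    if toehold_len < 1:
        raise DesignError("toehold_len must be >= 1")
    if bm_len < 2:
        raise DesignError("bm_len must be >= 2 (one base is lost to the closure)")
    if n_close < 1:
        raise DesignError("n_close must be >= 1")
    if n_close > toehold_len:
        raise DesignError(f"n_close={n_close} exceeds the coverable toehold ({toehold_len} nt)")
    if rev_toehold_len < 0:
        raise DesignError("rev_toehold_len must be >= 0")
    if rev_toehold_len > len(_REV_TOEHOLD_POOL):
        raise DesignError(f"rev_toehold_len must be <= {len(_REV_TOEHOLD_POOL)}")
    if mut.position != toehold_len - 1:
        raise DesignError(
            "mutation must sit at the last base of the toehold "
            f"(expected position {toehold_len - 1}, got {mut.position})"
        )
    core = toehold_len + bm_len
    spacer_on_target = spacer_len if spacer_pos == "target" else 0
    if core + spacer_on_target >= len(target):
        raise DesignError(
            f"domains (toehold {toehold_len} + bm {bm_len} + spacer {spacer_on_target}) "
            f"leave no association domain on a {len(target)} nt target"
        )

    target_mm_seq = apply_mutation(target, mut)

    assoc_start = core + spacer_on_target
    assoc_seq = target[assoc_start:]

    # Helper: 5' anchor on the association domain, 3' closure over n_close
    # bases ending at the mutation, complementary to the MISMATCHED allele.
    closure_mm = target_mm_seq[toehold_len - n_close : toehold_len]
    helper_spacer = _SPACER_BASE * spacer_len if spacer_pos == "helper" else ""
    helper_seq = reverse_complement(assoc_seq) + helper_spacer + reverse_complement(closure_mm)

    # Reporter duplex: Q spans (reverse toehold)* + bm* + toehold*; F carries
    # the bm sequence plus the retained reverse toehold.
    rev_seq = _REV_TOEHOLD_POOL[:rev_toehold_len]
    bm_seq = target[toehold_len:core]
    toehold_seq = target[:toehold_len]
    q_spacer = _SPACER_BASE * spacer_len if spacer_pos == "bottom" else ""
    q_seq = reverse_complement(toehold_seq + bm_seq + rev_seq)
    f_seq = bm_seq + rev_seq

    domains = [
        DomainAnnotation("toehold", "target_pm", 0, toehold_len),
        DomainAnnotation("branch_migration", "target_pm", toehold_len, core),
        DomainAnnotation("association", "target_pm", assoc_start, len(target)),
        DomainAnnotation("toehold", "q_strand", len(q_seq) - toehold_len, len(q_seq)),
        DomainAnnotation("branch_migration", "f_strand", 0, bm_len),
    ]
    if spacer_len > 0:
        if spacer_pos == "target":
            domains.append(DomainAnnotation("spacer", "target_pm", core, core + spacer_len))
        elif spacer_pos == "helper":
            a = len(assoc_seq)
            domains.append(DomainAnnotation("spacer", "helper", a, a + spacer_len))
        else:  # bottom: annotated on the Q strand 5' of the duplex region
            q_seq = q_spacer + q_seq
            for i, d in enumerate(domains):
                if d.strand == "q_strand":
                    domains[i] = replace(d, start=d.start + spacer_len, end=d.end + spacer_len)
            domains.append(DomainAnnotation("spacer", "q_strand", 0, spacer_len))
    if rev_toehold_len > 0:
        domains.append(
            DomainAnnotation("reverse_toehold", "f_strand", bm_len, bm_len + rev_toehold_len)
        )

    return ProbeSystem(
        target_pm=NucleotideStrand("target_pm", target),
        target_mm=NucleotideStrand("target_mm", target_mm_seq),
        helper=NucleotideStrand("helper", helper_seq),
        f_strand=NucleotideStrand("F", f_seq, label="fluorophore"),
        q_strand=NucleotideStrand("Q", q_seq, label="quencher"),
        mutation=mut,
        domains=tuple(domains),
        n_close=n_close,
        toehold_len=toehold_len,
        bm_len=bm_len,
        spacer_len=spacer_len,
        spacer_pos=spacer_pos,
        rev_toehold_len=rev_toehold_len,
    )


# -- external interfaces --------------------------------------------------------

_ROLES = {"target_pm": "target", "target_mm": "variant", "helper": "helper", "F": "F", "Q": "Q"}


def write_fasta(system: ProbeSystem, path: str | Path) -> None:
    """One record per strand; description carries a ``role=`` tag."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = []
    for strand in (system.target_pm, system.target_mm, system.helper, system.f_strand, system.q_strand):
        role = _ROLES.get(strand.name, strand.name)
        records.append(SeqRecord(Seq(strand.seq), id=strand.name, description=f"role={role}"))
    seqio_write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[NucleotideStrand]:
    from Bio.SeqIO import parse

    strands = []
    for rec in parse(str(path), "fasta"):
        strands.append(NucleotideStrand(rec.id, str(rec.seq).upper()))
    return strands


def save_design(system: ProbeSystem, path: str | Path) -> None:
    spec = {
        "target": system.target_pm.seq,
        "mutation": {
            "pos": system.mutation.position,
            "ref": system.mutation.ref_base,
            "alt": system.mutation.alt_base,
        },
        "toehold_len": system.toehold_len,
        "bm_len": system.bm_len,
        "spacer_len": system.spacer_len,
        "spacer_pos": system.spacer_pos,
        "n_close": system.n_close,
        "rev_toehold_len": system.rev_toehold_len,
    }
    Path(path).write_text(json.dumps(spec, indent=2) + "\n")


def load_design(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def build_from_design(spec: dict) -> ProbeSystem:
    m = spec["mutation"]
    return build_probe_system(
        spec["target"],
        MutationSpec(m["pos"], m["ref"], m["alt"]),
        toehold_len=spec["toehold_len"],
        bm_len=spec["bm_len"],
        spacer_len=spec.get("spacer_len", 2),
        spacer_pos=spec.get("spacer_pos", "bottom"),
        n_close=spec.get("n_close", 1),
        rev_toehold_len=spec.get("rev_toehold_len", 0),
    )
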