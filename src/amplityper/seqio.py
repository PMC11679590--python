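"""Sequence and primer I/O plus the alphabet primitives everything else builds on.

The package works on the IUPAC nucleotide alphabet throughout.  Sequences are
normalised on ingest (uppercase, U→T) so downstream modules can compare raw
characters; degenerate codes are interpreted as base *sets* wherever matching
or composition is computed.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"

#: IUPAC nucleotide codes mapped to the set of unambiguous bases they denote.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Watson–Crick complement extended to degenerate codes (R↔Y, K↔M, B↔V, D↔H; S, W, N fixed).
COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
    GAP: GAP,
}

_SPECIES_RE = re.compile(r"species=(\S+)")


class SequenceError(ValueError):
    """Malformed sequence or sequence file."""


def _normalize(residues: str) -> str:
    return residues.upper().replace("U", "T")


def _validate_residues(residues: str, *, allow_gaps: bool, context: str = "") -> None:
    if not residues:
        raise SequenceError(f"empty sequence{' for ' + context if context else ''}")
    allowed = set(IUPAC_SETS)
    if allow_gaps:
        allowed.add(GAP)
    for pos, ch in enumerate(residues, start=1):
        if ch not in allowed:
            where = f" in {context}" if context else ""
            if ch == GAP:
                raise SequenceError(
                    f"gap character at position {pos}{where}; pass aligned=True to read aligned FASTA"
                )
            raise SequenceError(f"non-IUPAC character {ch!r} at position {pos}{where}")


@dataclass
class NucleotideSequence:
    """An identified DNA string over the IUPAC alphabet, optionally species-labelled.

    Residues are case-folded to upper case and U is normalised to T at
    construction.  Gap characters ('-') are only legal when ``allow_gaps`` is
    set, i.e. for rows of an alignment.
    """

    id: str
    residues: str
    species: str | None = None
    description: str | None = None
    allow_gaps: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("sequence id must be non-empty")
        self.residues = _normalize(self.residues)
        _validate_residues(self.residues, allow_gaps=self.allow_gaps, context=self.id)

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> "NucleotideSequence":
        """Copy of this sequence with gap characters removed."""
        return NucleotideSequence(
            self.id, self.residues.replace(GAP, ""), self.species, self.description
        )


class PrimerRole(str, enum.Enum):
    BARCODING = "barcoding"
    COMMON_REVERSE = "common_reverse"
    SPECIES_FORWARD = "species_forward"


@dataclass
class PrimerRecord:
    """A named oligo (5'→3') with its role in the assay.

    Species-specific forward primers must name their target species; the
    common reverse and generic barcoding primers must not require one.
    """

    name: str
    sequence: NucleotideSequence
    role: PrimerRole
    target_species: str | None = None

    MIN_LENGTH = 10
    MAX_LENGTH = 40

    def __post_init__(self) -> None:
        if isinstance(self.sequence, str):
            self.sequence = NucleotideSequence(self.name, self.sequence)
        self.role = PrimerRole(self.role)
        n = len(self.sequence)
        if not self.MIN_LENGTH <= n <= self.MAX_LENGTH:
            raise SequenceError(
                f"primer {self.name}: length {n} outside [{self.MIN_LENGTH}, {self.MAX_LENGTH}]"
            )
        if self.role is PrimerRole.SPECIES_FORWARD and not self.target_species:
            raise SequenceError(f"primer {self.name}: species_forward requires target_species")

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, *, aligned: bool = False) -> list[NucleotideSequence]:
    """Read a FASTA file into a list of :class:`NucleotideSequence`.

    Order is preserved.  A ``species=<label>`` key in the description line is
    parsed into the species field.  Gap characters are only accepted when
    ``aligned`` is set.  Empty files, duplicate ids and non-IUPAC characters
    raise :class:`SequenceError`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    out: list[NucleotideSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise SequenceError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        m = _SPECIES_RE.search(desc)
        species = m.group(1) if m else None
        out.append(
            NucleotideSequence(rec.id, str(rec.seq), species, desc or None, allow_gaps=aligned)
        )
    return out


def write_fasta(seqs: Iterable[NucleotideSequence], path: str | Path, *, wrap: int = 70) -> None:
    """Write sequences to FASTA; the species label is serialised as ``species=<name>``."""
    records = []
    for s in seqs:
        parts = []
        if s.species and (s.description is None or f"species={s.species}" not in s.description):
            parts.append(f"species={s.species}")
        if s.description:
            parts.append(s.description)
        records.append(SeqRecord(Seq(s.residues), id=s.id, description=" ".join(parts)))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Primer tables (TSV: name, sequence, role, target_species)
# ---------------------------------------------------------------------------

def read_primer_tsv(path: str | Path) -> list[PrimerRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    required = {"name", "sequence", "role", "target_species"}
    missing = required - set(df.columns)
    if missing:
        raise SequenceError(f"primer table {path} missing columns: {sorted(missing)}")
    return [
        PrimerRecord(
            name=row["name"],
            sequence=NucleotideSequence(row["name"], row["sequence"]),
            role=PrimerRole(row["role"]),
            target_species=row["target_species"] or None,
        )
        for _, row in df.iterrows()
    ]


def write_primer_tsv(primers: Iterable[PrimerRecord], path: str | Path,
                     header_lines: Sequence[str] = ()) -> None:
    df = pd.DataFrame(
        {
            "name": [p.name for p in primers],
            "sequence": [p.sequence.residues for p in primers],
            "role": [p.role.value for p in primers],
            "target_species": [p.target_species or "" for p in primers],
        }
    )
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Alphabet operations
# ---------------------------------------------------------------------------

def revcomp(residues: str) -> str:
    """Reverse complement of a raw IUPAC string (degeneracy-aware)."""
    return "".join(COMPLEMENT[c] for c in reversed(residues))


def reverse_complement(seq: NucleotideSequence) -> NucleotideSequence:
    """Reverse complement; an involution on every IUPAC string."""
    return NucleotideSequence(
        seq.id, revcomp(seq.residues), seq.species, seq.description, allow_gaps=seq.allow_gaps
    )


def gc_content(seq: NucleotideSequence | str) -> float:
    """G+C percentage; degenerate codes contribute their mean G+C probability.

    E.g. S counts 1, W counts 0, N counts 0.5.
    """
    residues = seq if isinstance(seq, str) else seq.residues
    if not residues:
        raise SequenceError("gc_content of empty sequence")
    weight = 0.0
    for c in residues:
        bases = IUPAC_SETS[c]
        weight += len(bases & {"G", "C"}) / len(bases)
    return 100.0 * weight / len(residues)


def wallace_tm(seq: NucleotideSequence | str, resolve: str | None = None) -> float:
    """Wallace-rule melting temperature: 2 °C per A/T plus 4 °C per G/C.

    Degenerate codes have no single Wallace value; they raise unless a
    ``resolve`` policy is given: "mean" (average over the base set), "min" or
    "max" (extremes over the base set).
    """
    residues = seq if isinstance(seq, str) else seq.residues
    if not residues:
        raise SequenceError("wallace_tm of empty sequence")
    tm = 0.0
    for pos, c in enumerate(residues, start=1):
        bases = IUPAC_SETS[c]
        contribs = [4.0 if b in "GC" else 2.0 for b in sorted(bases)]
        if len(bases) == 1:
            tm += contribs[0]
        elif resolve == "mean":
            tm += sum(contribs) / len(contribs)
        elif resolve == "min":
            tm += min(contribs)
        elif resolve == "max":
            tm += max(contribs)
        else:
            raise SequenceError(
                f"degenerate base {c!r} at position {pos}: pass resolve='mean'|'min'|'max'"
            )
    return tm


def max_homopolymer_run(residues: str) -> int:
    """Length of the longest run of one identical character."""
    best = run = 1
    for prev, cur in zip(residues, residues[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best
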