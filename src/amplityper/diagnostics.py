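"""Alignment, identity and diagnostic-site discovery on barcode panels.

This module automates what a taxonomist does by eye on a barcode alignment:
quantify between-species identity, confirm the absence of within-species
variation, list the columns where one species differs from every other
(candidate species-specific primer sites), and list the fully conserved
windows (candidate common-primer sites).

All coordinates are 1-based inclusive alignment columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqio import GAP, IUPAC_SETS, NucleotideSequence, SequenceError


@dataclass(frozen=True)
class AlignmentRow:
    id: str
    species: str | None
    residues: str


@dataclass
class Alignment:
    """A rectangular multiple alignment of species-labelled rows."""

    rows: tuple[AlignmentRow, ...]
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.rows = tuple(self.rows)
        if len(self.rows) < 2:
            raise SequenceError("alignment needs at least 2 rows")
        lengths = {len(r.residues) for r in self.rows}
        if len(lengths) != 1:
            raise SequenceError(f"alignment rows have unequal lengths: {sorted(lengths)}")
        ids = [r.id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise SequenceError("alignment row ids must be unique")

    @classmethod
    def from_sequences(cls, seqs: Iterable[NucleotideSequence],
                       score: float | None = None) -> "Alignment":
        return cls(tuple(AlignmentRow(s.id, s.species, s.residues) for s in seqs), score)

    @property
    def length(self) -> int:
        return len(self.rows[0].residues)

    def row(self, row_id: str) -> AlignmentRow:
        for r in self.rows:
            if r.id == row_id:
                return r
        raise SequenceError(f"no alignment row with id {row_id!r}")

    def species_rows(self, species: str) -> list[AlignmentRow]:
        return [r for r in self.rows if r.species == species]

    def species(self) -> list[str]:
        """Distinct species labels in row order."""
        seen: list[str] = []
        for r in self.rows:
            if r.species is not None and r.species not in seen:
                seen.append(r.species)
        return seen

    def column(self, col: int) -> str:
        """Characters of 1-based column ``col``, in row order."""
        if not 1 <= col <= self.length:
            raise SequenceError(f"column {col} outside alignment of length {self.length}")
        return "".join(r.residues[col - 1] for r in self.rows)

    def to_sequences(self) -> list[NucleotideSequence]:
        return [
            NucleotideSequence(r.id, r.residues, r.species, allow_gaps=True) for r in self.rows
        ]


@dataclass(frozen=True)
class DiagnosticSite:
    """A column where the target species' base differs from every other species'."""

    column: int
    target_species: str
    target_base: str
    contrast_bases: tuple[tuple[str, str], ...]  # (species, base or base1/base2)


@dataclass(frozen=True)
class ConservedWindow:
    """A maximal gap-free run of columns identical across all covered rows."""

    start: int
    end: int
    species: tuple[str, ...]

    def __len__(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# Pairwise global alignment (Needleman–Wunsch, linear gaps)
# ---------------------------------------------------------------------------

def global_align_pair(a: NucleotideSequence, b: NucleotideSequence,
                      match_score: float = 1.0, mismatch_penalty: float = -1.0,
                      gap_penalty: float = -2.0) -> Alignment:
    """Optimal global alignment of two ungapped sequences under linear gap costs.

    Ties during traceback are broken deterministically: diagonal (match or
    mismatch) is preferred over a gap in ``b`` (up), which is preferred over a
    gap in ``a`` (left).  Returns a two-row :class:`Alignment` whose ``score``
    attribute carries the optimal score.
    """
    if not a.residues or not b.residues:
        raise SequenceError("cannot align empty sequences")
    if GAP in a.residues or GAP in b.residues:
        raise SequenceError("global_align_pair expects ungapped inputs")
    ra, rb = a.residues, b.residues
    m, n = len(ra), len(rb)
    g = float(gap_penalty)
    bvec = np.frombuffer(rb.encode(), dtype="S1")
    F = np.empty((m + 1, n + 1), dtype=float)
    F[0, :] = g * np.arange(n + 1)
    js = np.arange(n + 1, dtype=float)
    for i in range(1, m + 1):
        s = np.where(bvec == ra[i - 1].encode(), match_score, mismatch_penalty)
        cand = np.empty(n + 1)
        cand[0] = g * i
        # best of diagonal and up moves into each cell of this row
        cand[1:] = np.maximum(F[i - 1, :-1] + s, F[i - 1, 1:] + g)
        # left moves are a running max: F[i,j] = max_{k<=j} cand[k] + g*(j-k)
        F[i, :] = np.maximum.accumulate(cand - g * js) + g * js

    # traceback, diagonal > up > left on ties
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = m, n
    while i > 0 or j > 0:
        here = F[i, j]
        if i > 0 and j > 0:
            s = match_score if ra[i - 1] == rb[j - 1] else mismatch_penalty
            if np.isclose(here, F[i - 1, j - 1] + s):
                out_a.append(ra[i - 1]); out_b.append(rb[j - 1])
                i -= 1; j -= 1
                continue
        if i > 0 and np.isclose(here, F[i - 1, j] + g):
            out_a.append(ra[i - 1]); out_b.append(GAP)
            i -= 1
            continue
        out_a.append(GAP); out_b.append(rb[j - 1])
        j -= 1

    rows = (
        AlignmentRow(a.id, a.species, "".join(reversed(out_a))),
        AlignmentRow(b.id, b.species, "".join(reversed(out_b))),
    )
    return Alignment(rows, score=float(F[m, n]))


# ---------------------------------------------------------------------------
# Identity and variation
# ---------------------------------------------------------------------------

def percent_identity(alignment: Alignment, pair: tuple[str, str]) -> float:
    """Percent identity between two rows over columns where neither is gapped.

    Returns the exact (unrounded) value; round only for presentation.
    """
    ra = alignment.row(pair[0]).residues
    rb = alignment.row(pair[1]).residues
    comparable = identical = 0
    for x, y in zip(ra, rb):
        if x == GAP or y == GAP:
            continue
        comparable += 1
        if x == y:
            identical += 1
    if comparable == 0:
        raise SequenceError(f"rows {pair} share no gap-free columns")
    return 100.0 * identical / comparable


def within_species_variation(seqs: Sequence[NucleotideSequence]) -> int:
    """Number of variable columns among equal-length sequences of one species."""
    if len(seqs) < 2:
        raise SequenceError("within_species_variation needs at least 2 sequences")
    labels = {s.species for s in seqs}
    if len(labels) != 1:
        raise SequenceError(f"mixed species labels: {sorted(str(x) for x in labels)}")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise SequenceError("sequences must be aligned (equal length)")
    return sum(
        1 for col in zip(*(s.residues for s in seqs)) if len(set(col)) > 1
    )


# ---------------------------------------------------------------------------
# Diagnostic sites and conserved windows
# ---------------------------------------------------------------------------

def _strictly_different(a: str, b: str) -> bool:
    """True iff the IUPAC base sets of a and b cannot denote a common base."""
    if a == GAP or b == GAP:
        return False
    return not (IUPAC_SETS[a] & IUPAC_SETS[b])


def find_diagnostic_sites(alignment: Alignment, target_species: str) -> list[DiagnosticSite]:
    """Columns where all target rows share one base that strictly differs from
    every non-target row's base.

    Degenerate codes whose base sets overlap are treated as non-diagnostic
    (conservative).  Columns with gaps in any row are never diagnostic.
    """
    targets = alignment.species_rows(target_species)
    if not targets:
        raise SequenceError(f"target species {target_species!r} absent from alignment")
    others = [r for r in alignment.rows if r.species != target_species]
    if not others:
        raise SequenceError("alignment has no non-target rows to contrast against")
    sites: list[DiagnosticSite] = []
    for col in range(1, alignment.length + 1):
        tbases = {r.residues[col - 1] for r in targets}
        if len(tbases) != 1:
            continue
        tbase = next(iter(tbases))
        if tbase == GAP:
            continue
        if all(_strictly_different(tbase, r.residues[col - 1]) for r in others):
            contrast: dict[str, set[str]] = {}
            for r in others:
                contrast.setdefault(r.species or r.id, set()).add(r.residues[col - 1])
            sites.append(
                DiagnosticSite(
                    column=col,
                    target_species=target_species,
                    target_base=tbase,
                    contrast_bases=tuple(
                        (sp, "/".join(sorted(bs))) for sp, bs in sorted(contrast.items())
                    ),
                )
            )
    return sites


def find_conserved_windows(alignment: Alignment, min_length: int = 1) -> list[ConservedWindow]:
    """Maximal runs of fully conserved, gap-free columns of length >= min_length."""
    if min_length < 1:
        raise SequenceError("min_length must be >= 1")
    species = tuple(
        dict.fromkeys(r.species if r.species is not None else r.id for r in alignment.rows)
    )
    windows: list[ConservedWindow] = []
    start: int | None = None
    for col in range(1, alignment.length + 2):
        conserved = False
        if col <= alignment.length:
            chars = set(alignment.column(col))
            conserved = len(chars) == 1 and GAP not in chars
        if conserved and start is None:
            start = col
        elif not conserved and start is not None:
            if col - start >= min_length:
                windows.append(ConservedWindow(start, col - 1, species))
            start = None
    return windows


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def sites_to_frame(sites: Sequence[DiagnosticSite], *, bed: bool = False) -> pd.DataFrame:
    """Tabulate diagnostic sites; with ``bed`` coordinates become 0-based half-open."""
    rows = []
    for s in sites:
        contrast = ";".join(f"{sp}:{b}" for sp, b in s.contrast_bases)
        if bed:
            rows.append({"start": s.column - 1, "end": s.column,
                         "species": s.target_species, "base": s.target_base,
                         "contrast": contrast})
        else:
            rows.append({"column": s.column, "species": s.target_species,
                         "base": s.target_base, "contrast": contrast})
    return pd.DataFrame(rows)


def windows_to_frame(windows: Sequence[ConservedWindow], *, bed: bool = False) -> pd.DataFrame:
    rows = []
    for w in windows:
        if bed:
            rows.append({"start": w.start - 1, "end": w.end, "length": len(w)})
        else:
            rows.append({"start": w.start, "end": w.end, "length": len(w)})
    return pd.DataFrame(rows)


def write_tsv(frame: pd.DataFrame, path: str | Path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)
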