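"""In-silico PCR: primer binding-site search and amplicon prediction.

The binding model abstracts wet-lab annealing stringency into two knobs: a
total mismatch budget over the primer, and a 3'-terminal window that must
match exactly (polymerase extension is blocked by 3' mismatches, which is the
mechanism species-specific primers exploit).  Degenerate IUPAC codes match
wherever their base sets intersect; gaps are not allowed in binding.

Primers bind the plus strand directly (forward orientation, + strand) or via
their reverse complement (reverse orientation, reported as - strand).  A pair
of a forward + site and a reverse - site downstream of it yields one amplicon
whose length spans both primer footprints: end - start + 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqio import (
    GAP,
    IUPAC_SETS,
    NucleotideSequence,
    PrimerRecord,
    SequenceError,
    revcomp,
)

_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
_CODE2MASK = {code: sum(_BITS[b] for b in bases) for code, bases in IUPAC_SETS.items()}


@dataclass(frozen=True)
class BindingModel:
    """Stringency of primer annealing in the simulation.

    max_mismatches: mismatch budget over the whole primer (default 2).
    three_prime_exact: 3'-terminal window length that must match with zero
        mismatches (default 5 nt); must not exceed the primer length.
    min_product/max_product: amplicon length bounds reported by simulate_pcr.
    """

    max_mismatches: int = 2
    three_prime_exact: int = 5
    min_product: int = 1
    max_product: int = 10_000

    def __post_init__(self) -> None:
        if self.max_mismatches < 0 or self.three_prime_exact < 0:
            raise SequenceError("binding model parameters must be non-negative")
        if self.min_product < 1 or self.max_product < self.min_product:
            raise SequenceError("invalid amplicon length bounds")


@dataclass(frozen=True)
class BindingSite:
    """Placement of a primer on a template's plus-strand coordinates (1-based inclusive)."""

    primer_name: str
    template_id: str
    strand: str  # '+' or '-'
    start: int
    end: int
    mismatch_positions: tuple[int, ...]  # 1-based template positions

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatch_positions)


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product delimited by a forward + site and a reverse - site."""

    template_id: str
    forward: BindingSite
    reverse: BindingSite
    sequence: str = field(repr=False)

    @property
    def start(self) -> int:
        return self.forward.start

    @property
    def end(self) -> int:
        return self.reverse.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _as_residues(primer: PrimerRecord | NucleotideSequence | str) -> tuple[str, str]:
    if isinstance(primer, PrimerRecord):
        return primer.name, primer.sequence.residues
    if isinstance(primer, NucleotideSequence):
        return primer.id, primer.residues
    return primer, primer


def _encode(residues: str) -> np.ndarray:
    try:
        return np.array([_CODE2MASK[c] for c in residues], dtype=np.uint8)
    except KeyError as exc:
        raise SequenceError(f"cannot encode character {exc.args[0]!r} for binding search") from exc


def _scan(template_mask: np.ndarray, primer_mask: np.ndarray,
          exact_zone: slice, max_mismatches: int) -> list[tuple[int, np.ndarray]]:
    """All 0-based offsets where the primer binds, with per-window mismatch flags."""
    n, m = len(template_mask), len(primer_mask)
    if m > n:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(template_mask, m)
    mism = (windows & primer_mask) == 0  # (n-m+1, m) True where sets disjoint
    ok = (mism.sum(axis=1) <= max_mismatches) & ~mism[:, exact_zone].any(axis=1)
    return [(int(off), mism[off]) for off in np.nonzero(ok)[0]]


def find_binding_sites(primer: PrimerRecord | NucleotideSequence | str,
                       template: NucleotideSequence,
                       model: BindingModel = BindingModel()) -> list[BindingSite]:
    """All binding sites of a primer on an ungapped template, both orientations.

    Forward-orientation matches of the primer itself are reported on the +
    strand; matches of its reverse complement on the - strand.  Sites are
    sorted by start (then + before -).  The 3'-exact window sits at the end
    of the primer, which is the right edge of a + site and the left edge of
    a - site on plus-strand coordinates.
    """
    if GAP in template.residues:
        raise SequenceError("find_binding_sites expects an ungapped template")
    name, residues = _as_residues(primer)
    m = len(residues)
    if model.three_prime_exact > m:
        raise SequenceError(
            f"3'-exact window ({model.three_prime_exact}) exceeds primer length ({m})"
        )
    tmask = _encode(template.residues)
    e = model.three_prime_exact
    sites: list[BindingSite] = []
    plus = _scan(tmask, _encode(residues), slice(m - e, m) if e else slice(0, 0),
                 model.max_mismatches)
    for off, mism in plus:
        positions = tuple(int(off + k + 1) for k in np.nonzero(mism)[0])
        sites.append(BindingSite(name, template.id, "+", off + 1, off + m, positions))
    minus = _scan(tmask, _encode(revcomp(residues)), slice(0, e), model.max_mismatches)
    for off, mism in minus:
        positions = tuple(int(off + k + 1) for k in np.nonzero(mism)[0])
        sites.append(BindingSite(name, template.id, "-", off + 1, off + m, positions))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def simulate_pcr(forward_primers: PrimerRecord | Sequence[PrimerRecord],
                 reverse_primer: PrimerRecord | NucleotideSequence | str,
                 template: NucleotideSequence,
                 model: BindingModel = BindingModel()) -> list[Amplicon]:
    """Predicted amplicons from pairing forward + sites with reverse - sites.

    Every non-overlapping (forward, reverse) site pair whose product length
    falls within the model's bounds yields one amplicon; an empty list is the
    in-silico negative control.  Amplicons are sorted by (start, length).
    """
    if isinstance(forward_primers, (PrimerRecord, NucleotideSequence, str)):
        forward_primers = [forward_primers]
    rev_sites = [s for s in find_binding_sites(reverse_primer, template, model)
                 if s.strand == "-"]
    amplicons: list[Amplicon] = []
    for fwd in forward_primers:
        fwd_sites = [s for s in find_binding_sites(fwd, template, model) if s.strand == "+"]
        for fs in fwd_sites:
            for rs in rev_sites:
                if fs.end >= rs.start:
                    continue
                length = rs.end - fs.start + 1
                if not model.min_product <= length <= model.max_product:
                    continue
                product = template.residues[fs.start - 1: rs.end]
                amplicons.append(Amplicon(template.id, fs, rs, product))
    amplicons.sort(key=lambda a: (a.start, a.length))
    return amplicons


def specificity_matrix(panel, templates: Sequence[NucleotideSequence],
                       model: BindingModel = BindingModel()) -> pd.DataFrame:
    """Species x assay-lane matrix of predicted amplicon lengths.

    Rows are template species, columns the panel's per-species forward lanes;
    each cell holds the sorted tuple of product lengths from pairing that
    forward with the panel's common reverse on that species' templates.  The
    panel is specific iff every diagonal cell is non-empty and every
    off-diagonal cell is empty (see :func:`is_specific`).
    """
    by_species: dict[str, list[NucleotideSequence]] = {}
    for t in templates:
        if t.species is None:
            raise SequenceError(f"template {t.id} lacks a species label")
        by_species.setdefault(t.species, []).append(t)
    lanes = list(panel.forwards)
    data = {}
    for lane in lanes:
        fwd = panel.forwards[lane].primer
        col = {}
        for sp, seqs in by_species.items():
            lengths: list[int] = []
            for t in seqs:
                lengths.extend(a.length for a in simulate_pcr(fwd, panel.common_reverse.primer,
                                                              t, model))
            col[sp] = tuple(sorted(lengths))
        data[lane] = col
    return pd.DataFrame(data, index=list(by_species)).rename_axis("template_species")


def is_specific(matrix: pd.DataFrame) -> bool:
    """True iff diagonal cells are all non-empty and off-diagonal all empty."""
    for sp in matrix.index:
        for lane in matrix.columns:
            cell = matrix.at[sp, lane]
            if sp == lane and not cell:
                return False
            if sp != lane and cell:
                return False
    return True


def amplicons_to_frame(amplicons: Iterable[Amplicon]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "template": a.template_id,
                "forward": a.forward.primer_name,
                "reverse": a.reverse.primer_name,
                "start": a.start,
                "end": a.end,
                "length": a.length,
                "forward_mismatches": a.forward.n_mismatches,
                "reverse_mismatches": a.reverse.n_mismatches,
            }
            for a in amplicons
        ],
        columns=["template", "forward", "reverse", "start", "end", "length",
                 "forward_mismatches", "reverse_mismatches"],
    )
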