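"""Synthetic COI-barcode panels with known ground truth.

Real looper barcodes cannot ship with the package, so this module generates
panels that reproduce the published assay's structure: 657-bp gap-free
barcode alignments for five Plusiinae species in which the published primer
binding sites sit verbatim at their published alignment coordinates, the two
focal species differ by exactly 56 substitutions (91.48% identity), and every
off-target barcode carries a 3'-terminal mismatch under each species-specific
forward primer.  Generators record the ground truth they seed (diagnostic
columns, substitution columns, batch composition) so tests can use the
bookkeeping as an oracle.  All generators are bit-reproducible per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classify import LaneRecord
from .diagnostics import Alignment
from .primer_design import AssayPanel, PrimerCandidate
from .seqio import (
    NucleotideSequence,
    PrimerRecord,
    PrimerRole,
    SequenceError,
    gc_content,
    max_homopolymer_run,
    revcomp,
    wallace_tm,
)

BARCODE_LENGTH = 657

CI = "C_includens"
RN = "R_nu"
TNI = "T_ni"
AG = "A_gamma"
AE = "A_egena"
PANEL_SPECIES = (CI, RN, TNI, AG, AE)

#: Published primer set: the Folmer barcoding pair plus the diagnostic assay
#: (one common reverse, two species-specific forwards).
TABLE1 = (
    ("LCO 1490", "GGTCAACAAATCATAAAGATATTGG", PrimerRole.BARCODING, None),
    ("HCO 2198", "TAAACTTCAGGGTGACCAAAAAATCA", PrimerRole.BARCODING, None),
    ("MMRC_1955", "CAGATCTACCACCATGAGCAATA", PrimerRole.COMMON_REVERSE, None),
    ("MMRC_1964", "GGATTTGGTAATTGACTTGTACCTCTT", PrimerRole.SPECIES_FORWARD, CI),
    ("MMRC_1988", "TCCTGGATCTTTAATTGGAGAT", PrimerRole.SPECIES_FORWARD, RN),
)

#: Published binding spans, 1-based inclusive alignment columns.
COMMON_REVERSE_SPAN = (357, 379)
CI_FORWARD_SPAN = (181, 207)
RN_FORWARD_SPAN = (81, 102)

#: Number of substitutions separating the two focal barcodes: 657 columns at
#: 91.48% identity leaves 56 differing columns (601/657 = 91.476...%).
CI_RN_SUBSTITUTIONS = 56

_BASES = np.array(list("ACGT"))
# insect mtDNA is A/T-rich
_BASE_PROBS = (0.33, 0.16, 0.17, 0.34)


def paper_primers() -> dict[str, PrimerRecord]:
    """The published primer set keyed by primer name."""
    return {
        name: PrimerRecord(name, NucleotideSequence(name, seq), role, target)
        for name, seq, role, target in TABLE1
    }


def _candidate(primer: PrimerRecord, span: tuple[int, int], strand: str,
               diagnostic_columns: tuple[int, ...] = ()) -> PrimerCandidate:
    seq = primer.sequence.residues
    return PrimerCandidate(
        primer=primer, start=span[0], end=span[1], strand=strand,
        gc=gc_content(seq), tm=wallace_tm(seq, resolve="mean"),
        homopolymer=max_homopolymer_run(seq), diagnostic_columns=diagnostic_columns,
    )


def paper_assay(size_tolerance: float = 10.0,
                diagnostic_columns: dict[str, tuple[int, ...]] | None = None) -> AssayPanel:
    """The published assay as an :class:`AssayPanel` at its published coordinates.

    Expected sizes follow from the span arithmetic alone: 379-181+1 = 199 and
    379-81+1 = 299.
    """
    primers = paper_primers()
    diag = diagnostic_columns or {}
    forwards = {
        CI: _candidate(primers["MMRC_1964"], CI_FORWARD_SPAN, "forward",
                       tuple(diag.get(CI, ()))),
        RN: _candidate(primers["MMRC_1988"], RN_FORWARD_SPAN, "forward",
                       tuple(diag.get(RN, ()))),
    }
    rev = _candidate(primers["MMRC_1955"], COMMON_REVERSE_SPAN, "reverse")
    sizes = {sp: COMMON_REVERSE_SPAN[1] - c.start + 1 for sp, c in forwards.items()}
    return AssayPanel(common_reverse=rev, forwards=forwards, expected_sizes=sizes,
                      size_tolerance=size_tolerance)


@dataclass
class PanelFixture:
    """A generated barcode panel plus the ground truth seeded into it."""

    sequences: list[NucleotideSequence]
    diagnostic_columns: dict[str, list[int]]  # 1-based, per species
    focal_diff_columns: list[int]  # columns where the two focal rows differ
    within_species_snp_columns: dict[str, list[int]] = field(default_factory=dict)
    seed: int = 0

    def alignment(self) -> Alignment:
        return Alignment.from_sequences(self.sequences)

    def templates(self, species: str) -> list[NucleotideSequence]:
        return [s for s in self.sequences if s.species == species]


def make_paper_panel(seed: int = 0, replicates: int = 1,
                     within_species_snps: int = 0) -> PanelFixture:
    """Generate the five-species panel emulating the published alignment.

    Guarantees, for any seed:

    * 657-column gap-free alignment, one row per species (times ``replicates``);
    * the C. includens row carries MMRC_1964 verbatim at columns 181-207, the
      R. nu row carries MMRC_1988 verbatim at 81-102, and every row carries the
      reverse complement of MMRC_1955 at 357-379;
    * every off-target row mismatches each forward within the forward's
      3'-terminal 5 columns (so a strict 3'-exact binding model keeps the
      assay species-specific);
    * the two focal rows differ at exactly 56 columns (91.48% identity);
    * replicate rows of one species are identical unless
      ``within_species_snps`` > 0, in which case one replicate carries that
      many private substitutions (requires ``replicates`` >= 2).
    """
    if replicates < 1:
        raise SequenceError("replicates must be >= 1")
    if within_species_snps and replicates < 2:
        raise SequenceError("within_species_snps needs replicates >= 2")
    rng = np.random.default_rng(seed)
    bg = rng.choice(_BASES, size=BARCODE_LENGTH, p=_BASE_PROBS)

    primers = {name: seq for name, seq, _, _ in TABLE1}
    _embed(bg, primers["MMRC_1988"], RN_FORWARD_SPAN)
    _embed(bg, primers["MMRC_1964"], CI_FORWARD_SPAN)
    _embed(bg, revcomp(primers["MMRC_1955"]), COMMON_REVERSE_SPAN)

    rows: dict[str, np.ndarray] = {sp: bg.copy() for sp in PANEL_SPECIES}

    # one diagnostic-breaking column inside each forward's 3'-terminal 5 columns:
    # the target keeps the primer base, all other species share a different base
    c1 = int(rng.integers(CI_FORWARD_SPAN[1] - 4, CI_FORWARD_SPAN[1] + 1))  # 203..207
    b1 = _other_base(rng, bg[c1 - 1])
    for sp in (RN, TNI, AG, AE):
        rows[sp][c1 - 1] = b1
    c2 = int(rng.integers(RN_FORWARD_SPAN[1] - 4, RN_FORWARD_SPAN[1] + 1))  # 98..102
    b2 = _other_base(rng, bg[c2 - 1])
    for sp in (CI, TNI, AG, AE):
        rows[sp][c2 - 1] = b2

    motif_cols = set()
    for lo, hi in (RN_FORWARD_SPAN, CI_FORWARD_SPAN, COMMON_REVERSE_SPAN):
        motif_cols.update(range(lo, hi + 1))
    free = [c for c in range(1, BARCODE_LENGTH + 1) if c not in motif_cols]
    # delimit the conserved reverse-primer window by forcing divergence at its flanks
    flank_lo, flank_hi = COMMON_REVERSE_SPAN[0] - 1, COMMON_REVERSE_SPAN[1] + 1
    pool = [c for c in free if c not in (flank_lo, flank_hi)]
    rng.shuffle(pool)

    n_focal = CI_RN_SUBSTITUTIONS - 2  # c1 and c2 already separate the focal rows
    n_other = 55  # background divergence for the three outgroup-like rows
    take = iter(pool)
    rn_cols = sorted(next(take) for _ in range(n_focal))
    tni_cols = sorted([flank_lo] + [next(take) for _ in range(n_other - 1)])
    ag_cols = sorted([flank_hi] + [next(take) for _ in range(n_other - 1)])
    ae_cols = sorted(next(take) for _ in range(n_other))

    for sp, cols in ((RN, rn_cols), (TNI, tni_cols), (AG, ag_cols), (AE, ae_cols)):
        for c in cols:
            rows[sp][c - 1] = _other_base(rng, rows[sp][c - 1])

    diagnostic = {
        CI: [c1],
        RN: sorted([c2] + rn_cols),
        TNI: tni_cols,
        AG: ag_cols,
        AE: ae_cols,
    }
    focal_diff = sorted([c1, c2] + rn_cols)

    snp_cols: dict[str, list[int]] = {}
    sequences: list[NucleotideSequence] = []
    for sp in PANEL_SPECIES:
        base_row = rows[sp]
        for i in range(1, replicates + 1):
            arr = base_row.copy()
            if within_species_snps and i == replicates:
                cols = sorted(next(take) for _ in range(within_species_snps))
                for c in cols:
                    arr[c - 1] = _other_base(rng, arr[c - 1])
                snp_cols[sp] = cols
            sid = f"{sp}_{i}" if replicates > 1 else sp
            sequences.append(NucleotideSequence(sid, "".join(arr), species=sp))

    return PanelFixture(sequences=sequences, diagnostic_columns=diagnostic,
                        focal_diff_columns=focal_diff,
                        within_species_snp_columns=snp_cols, seed=seed)


def _embed(bg: np.ndarray, motif: str, span: tuple[int, int]) -> None:
    lo, hi = span
    assert hi - lo + 1 == len(motif), (span, len(motif))
    bg[lo - 1: hi] = list(motif)


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(0, 3))]


def make_random_panel(n_species: int, length: int, divergence: float,
                      seed: int = 0) -> tuple[list[NucleotideSequence], dict[str, list[int]]]:
    """Substitution-only panel from a random ancestor, with a diagnostic ledger.

    Each species receives ``round(divergence * length)`` private substitutions
    at columns disjoint from every other species', so the returned ledger
    lists exactly the diagnostic columns of each species (for two-species
    panels every differing column is diagnostic for both sides, and the
    ledger reflects that).
    """
    if not 0 <= divergence < 1:
        raise SequenceError(f"divergence must be in [0, 1), got {divergence}")
    if length < 100:
        raise SequenceError("length must be >= 100")
    if n_species < 2:
        raise SequenceError("need at least 2 species")
    n_mut = round(divergence * length)
    if n_species * n_mut > length:
        raise SequenceError(
            f"cannot place {n_species} x {n_mut} disjoint substitutions in {length} columns"
        )
    rng = np.random.default_rng(seed)
    ancestor = rng.choice(_BASES, size=length, p=_BASE_PROBS)
    cols = list(range(1, length + 1))
    rng.shuffle(cols)
    take = iter(cols)
    names = [f"sp{i}" for i in range(1, n_species + 1)]
    own: dict[str, list[int]] = {}
    seqs: list[NucleotideSequence] = []
    for name in names:
        arr = ancestor.copy()
        mine = sorted(next(take) for _ in range(n_mut))
        for c in mine:
            arr[c - 1] = _other_base(rng, arr[c - 1])
        own[name] = mine
        seqs.append(NucleotideSequence(name, "".join(arr), species=name))
    if n_species == 2:
        both = sorted(own[names[0]] + own[names[1]])
        ledger = {names[0]: both, names[1]: both}
    else:
        ledger = own
    return seqs, ledger


def make_field_batch(composition: dict[str, int], panel: AssayPanel, seed: int = 0,
                     jitter: int = 0) -> tuple[list[LaneRecord], dict[str, str]]:
    """Synthetic field collection: one gel lane per individual.

    Each individual of species ``sp`` shows one band at the panel's expected
    size for ``sp``, optionally jittered by a uniform integer in
    [-jitter, jitter] to mimic gel size-estimation error.  Lane order is
    shuffled; truth labels are returned separately.
    """
    unknown = set(composition) - set(panel.expected_sizes)
    if unknown:
        raise SequenceError(f"composition names species absent from panel: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    lanes: list[LaneRecord] = []
    truth: dict[str, str] = {}
    idx = 1
    for sp, count in composition.items():
        for _ in range(count):
            size = panel.expected_sizes[sp]
            if jitter:
                size = size + int(rng.integers(-jitter, jitter + 1))
            sid = f"sample_{idx:03d}"
            lanes.append(LaneRecord(sid, (float(size),)))
            truth[sid] = sp
            idx += 1
    rng.shuffle(lanes)
    return lanes, truth


def fig4_lanes() -> tuple[list[LaneRecord], dict[str, str]]:
    """The published field-validation gel, transcribed lane by lane.

    Nineteen larvae: lanes 7, 8 and 11 showed the 199-bp product
    (C. includens); the other sixteen lanes showed the 299-bp product (R. nu).
    """
    lanes = []
    truth = {}
    for i in range(1, 20):
        size = 199.0 if i in (7, 8, 11) else 299.0
        sid = f"lane_{i:02d}"
        lanes.append(LaneRecord(sid, (size,)))
        truth[sid] = CI if i in (7, 8, 11) else RN
    return lanes, truth
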