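"""Automated design of species-discriminating PCR panels.

The assay geometry: every species shares one reverse primer placed in a window
conserved across the whole panel, and each target species gets its own forward
primer whose 3' end sits on a species-diagnostic column.  Because all products
share the same right edge (the reverse primer), the forward primers' positions
translate directly into distinct product lengths, and a plain agarose gel
reads out the species.

The search is exhaustive over QC-passing candidates and optimises
lexicographically: first the minimum pairwise product-size separation (which
must reach the configured floor), then the worst per-primer QC margin.  Ties
are broken by coordinates, so the result is deterministic and independent of
input row order.
"""

from __future__ import annotations

import bisect
import itertools
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

from .diagnostics import Alignment, find_conserved_windows, find_diagnostic_sites
from .seqio import (
    GAP,
    NucleotideSequence,
    PrimerRecord,
    PrimerRole,
    gc_content,
    max_homopolymer_run,
    revcomp,
    wallace_tm,
)


class DesignError(ValueError):
    """Panel design failed or produced an inconsistent panel."""


class InfeasibleDesignError(DesignError):
    """No panel satisfies the constraints; ``report`` says which stage failed."""

    def __init__(self, message: str, report: dict):
        super().__init__(message)
        self.report = report


@dataclass(frozen=True)
class DesignConstraints:
    """QC and geometry constraints for panel design.

    Lengths in nt, GC in percent, Tm in °C (Wallace rule).  The defaults
    enclose typical barcoding primers (18-28 nt, 30-60% GC, Tm 50-75 °C,
    homopolymer runs of at most 4).  ``three_prime_k`` is the 3'-terminal
    span of a species forward that must cover at least one diagnostic site;
    ``min_separation`` is the smallest acceptable pairwise difference between
    expected product sizes.
    """

    length_range: tuple[int, int] = (18, 28)
    gc_range: tuple[float, float] = (30.0, 60.0)
    tm_range: tuple[float, float] = (50.0, 75.0)
    max_homopolymer: int = 4
    three_prime_k: int = 5
    amplicon_range: tuple[int, int] = (80, 1000)
    min_separation: int = 50

    def __post_init__(self) -> None:
        for lo, hi in (self.length_range, self.gc_range, self.tm_range, self.amplicon_range):
            if lo > hi:
                raise DesignError(f"range ({lo}, {hi}) has min > max")
        if self.min_separation < 1:
            raise DesignError("min_separation must be >= 1")
        if self.three_prime_k < 1 or self.max_homopolymer < 1:
            raise DesignError("three_prime_k and max_homopolymer must be >= 1")


@dataclass(frozen=True)
class PrimerCandidate:
    """A primer plus its placement on the alignment and its QC metrics."""

    primer: PrimerRecord
    start: int  # 1-based inclusive alignment columns of the footprint
    end: int
    strand: str  # 'forward' | 'reverse'
    gc: float
    tm: float
    homopolymer: int
    diagnostic_columns: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.primer):
            raise DesignError(
                f"candidate {self.primer.name}: span {self.start}-{self.end} "
                f"does not match primer length {len(self.primer)}"
            )

    def qc_margin(self, constraints: DesignConstraints) -> float:
        """Smallest slack to any GC or Tm bound (negative = violation)."""
        return min(
            self.gc - constraints.gc_range[0], constraints.gc_range[1] - self.gc,
            self.tm - constraints.tm_range[0], constraints.tm_range[1] - self.tm,
        )


@dataclass
class AssayPanel:
    """One common reverse + per-species forwards with their expected product sizes."""

    common_reverse: PrimerCandidate
    forwards: dict[str, PrimerCandidate]
    expected_sizes: dict[str, int]
    size_tolerance: float = 10.0

    def __post_init__(self) -> None:
        for sp, fwd in self.forwards.items():
            expected = self.common_reverse.end - fwd.start + 1
            if self.expected_sizes.get(sp) != expected:
                raise DesignError(
                    f"panel size for {sp}: stated {self.expected_sizes.get(sp)} "
                    f"!= reverse.end - forward.start + 1 = {expected}"
                )

    @property
    def min_pairwise_separation(self) -> int:
        sizes = list(self.expected_sizes.values())
        if len(sizes) < 2:
            return 0
        return min(abs(a - b) for a, b in itertools.combinations(sizes, 2))

    def validate(self, constraints: DesignConstraints) -> None:
        if self.min_pairwise_separation < constraints.min_separation:
            raise DesignError(
                f"pairwise size separation {self.min_pairwise_separation} < "
                f"required {constraints.min_separation}"
            )
        k = constraints.three_prime_k
        for sp, fwd in self.forwards.items():
            zone = range(fwd.end - k + 1, fwd.end + 1)
            if not any(c in zone for c in fwd.diagnostic_columns):
                raise DesignError(
                    f"forward for {sp} has no diagnostic site in its 3'-terminal {k} nt"
                )

    def all_primers(self) -> list[PrimerRecord]:
        return [self.common_reverse.primer] + [c.primer for c in self.forwards.values()]

    # -- serialisation (round-trips through the CLI) --

    def to_dict(self) -> dict:
        def cand(c: PrimerCandidate) -> dict:
            d = asdict(c)
            d["primer"]["sequence"] = c.primer.sequence.residues
            d["primer"]["role"] = c.primer.role.value
            return d

        return {
            "common_reverse": cand(self.common_reverse),
            "forwards": {sp: cand(c) for sp, c in self.forwards.items()},
            "expected_sizes": self.expected_sizes,
            "size_tolerance": self.size_tolerance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AssayPanel":
        def cand(cd: dict) -> PrimerCandidate:
            p = cd["primer"]
            rec = PrimerRecord(p["name"], NucleotideSequence(p["name"], p["sequence"]),
                               PrimerRole(p["role"]), p.get("target_species"))
            return PrimerCandidate(rec, cd["start"], cd["end"], cd["strand"], cd["gc"],
                                   cd["tm"], cd["homopolymer"],
                                   tuple(cd.get("diagnostic_columns", ())))

        return cls(
            common_reverse=cand(d["common_reverse"]),
            forwards={sp: cand(c) for sp, c in d["forwards"].items()},
            expected_sizes={sp: int(v) for sp, v in d["expected_sizes"].items()},
            size_tolerance=float(d.get("size_tolerance", 10.0)),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "AssayPanel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class DesignResult:
    panel: AssayPanel
    alternatives: list[AssayPanel] = field(default_factory=list)
    report: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Candidate enumeration
# ---------------------------------------------------------------------------

def _consensus_slice(alignment: Alignment, rows, start: int, end: int) -> str | None:
    """Residues of [start, end] if all given rows agree and carry no gap."""
    pieces = {r.residues[start - 1: end] for r in rows}
    if len(pieces) != 1:
        return None
    piece = next(iter(pieces))
    return None if GAP in piece else piece


def _make_candidate(name: str, residues: str, start: int, end: int, strand: str,
                    role: PrimerRole, target: str | None,
                    diagnostic_columns: tuple[int, ...]) -> PrimerCandidate:
    seq = residues if strand == "forward" else revcomp(residues)
    rec = PrimerRecord(name, NucleotideSequence(name, seq), role, target)
    return PrimerCandidate(
        primer=rec, start=start, end=end, strand=strand,
        gc=gc_content(seq), tm=wallace_tm(seq, resolve="mean"),
        homopolymer=max_homopolymer_run(seq), diagnostic_columns=diagnostic_columns,
    )


def _passes_qc(cand: PrimerCandidate, constraints: DesignConstraints) -> bool:
    lo, hi = constraints.gc_range
    tlo, thi = constraints.tm_range
    return (lo <= cand.gc <= hi and tlo <= cand.tm <= thi
            and cand.homopolymer <= constraints.max_homopolymer)


def enumerate_candidates(alignment: Alignment, window: tuple[int, int], strand: str,
                         constraints: DesignConstraints,
                         species: str | None = None,
                         diagnostic_columns: Sequence[int] = ()) -> list[PrimerCandidate]:
    """All QC-passing primer candidates inside an alignment window.

    Candidates are read off the rows of ``species`` (all rows when None) and
    require those rows to agree, gap-free, over the footprint.  ``strand``
    'forward' takes the slice as is; 'reverse' takes its reverse complement.
    Deterministic order: by start, then length.
    """
    lo, hi = window
    if not (1 <= lo <= hi <= alignment.length):
        raise DesignError(f"window {window} outside alignment of length {alignment.length}")
    if strand not in ("forward", "reverse"):
        raise DesignError(f"strand must be 'forward' or 'reverse', got {strand!r}")
    rows = alignment.species_rows(species) if species else list(alignment.rows)
    if not rows:
        raise DesignError(f"no rows for species {species!r}")
    diag = tuple(sorted(diagnostic_columns))
    role = PrimerRole.SPECIES_FORWARD if strand == "forward" else PrimerRole.COMMON_REVERSE
    min_len, max_len = constraints.length_range
    out: list[PrimerCandidate] = []
    for start in range(lo, hi + 1):
        for length in range(min_len, max_len + 1):
            end = start + length - 1
            if end > hi:
                break
            piece = _consensus_slice(alignment, rows, start, end)
            if piece is None:
                continue
            covered = tuple(c for c in diag if start <= c <= end)
            cand = _make_candidate(
                f"{species or 'panel'}_{strand[0]}_{start}_{end}", piece, start, end,
                strand, role, species if strand == "forward" else None, covered,
            )
            if _passes_qc(cand, constraints):
                out.append(cand)
    return out


def _forward_candidates(alignment: Alignment, species: str, diag_columns: Sequence[int],
                        constraints: DesignConstraints) -> list[PrimerCandidate]:
    """Forwards whose 3'-terminal k columns cover at least one diagnostic site."""
    k = constraints.three_prime_k
    min_len, max_len = constraints.length_range
    rows = alignment.species_rows(species)
    seen: set[tuple[int, int]] = set()
    out: list[PrimerCandidate] = []
    diag = sorted(diag_columns)
    for col in diag:
        for end in range(col, min(col + k, alignment.length + 1)):
            for length in range(min_len, max_len + 1):
                start = end - length + 1
                if start < 1 or (start, end) in seen:
                    continue
                seen.add((start, end))
                piece = _consensus_slice(alignment, rows, start, end)
                if piece is None:
                    continue
                covered = tuple(c for c in diag if start <= c <= end)
                if not any(end - k + 1 <= c <= end for c in covered):
                    continue
                cand = _make_candidate(
                    f"{species}_fwd_{start}_{end}", piece, start, end,
                    "forward", PrimerRole.SPECIES_FORWARD, species, covered,
                )
                if _passes_qc(cand, constraints):
                    out.append(cand)
    out.sort(key=lambda c: (c.start, c.end - c.start + 1))
    return out


# ---------------------------------------------------------------------------
# Panel assembly
# ---------------------------------------------------------------------------

def assemble_assay(alignment: Alignment, target_species: Sequence[str],
                   constraints: DesignConstraints = DesignConstraints(),
                   n_alternatives: int = 5) -> DesignResult:
    """Search for the best discriminating panel over the target species.

    Reverse candidates come from windows conserved across *all* rows; forward
    candidates sit upstream with a diagnostic site under their 3' end.  For
    each reverse placement the optimal forward combination is found exactly
    (see the selection helpers below); panels are then ranked by (min pairwise
    size separation, worst QC margin) with coordinate tie-breaks, and the
    runners-up across reverse placements are returned as alternatives.
    Raises :class:`InfeasibleDesignError` with a stage-by-stage report when
    no combination satisfies every constraint.
    """
    target_species = list(dict.fromkeys(target_species))
    if len(target_species) < 2:
        raise DesignError("need at least 2 target species to discriminate")
    for sp in target_species:
        if not alignment.species_rows(sp):
            raise DesignError(f"species {sp!r} has no rows in the alignment")

    report: dict = {"constraints": asdict(constraints)}

    windows = find_conserved_windows(alignment, constraints.length_range[0])
    report["conserved_windows"] = [(w.start, w.end) for w in windows]
    if not windows:
        raise InfeasibleDesignError(
            f"no conserved window of length >= {constraints.length_range[0]}", report)

    diag: dict[str, list[int]] = {}
    for sp in target_species:
        diag[sp] = [s.column for s in find_diagnostic_sites(alignment, sp)]
    report["diagnostic_sites"] = {sp: len(cols) for sp, cols in diag.items()}
    missing = [sp for sp, cols in diag.items() if not cols]
    if missing:
        raise InfeasibleDesignError(f"no diagnostic sites for species: {missing}", report)

    reverses: list[PrimerCandidate] = []
    for w in windows:
        reverses.extend(enumerate_candidates(alignment, (w.start, w.end), "reverse", constraints))
    reverses.sort(key=lambda c: (c.start, c.end - c.start + 1))
    report["reverse_candidates"] = len(reverses)
    if not reverses:
        raise InfeasibleDesignError("no reverse candidate passed QC in conserved windows", report)

    forwards: dict[str, list[PrimerCandidate]] = {}
    for sp in target_species:
        forwards[sp] = _forward_candidates(alignment, sp, diag[sp], constraints)
    report["forward_candidates"] = {sp: len(v) for sp, v in forwards.items()}
    missing = [sp for sp, v in forwards.items() if not v]
    if missing:
        raise InfeasibleDesignError(
            f"no QC-passing forward with a 3'-terminal diagnostic site for: {missing}", report)

    if len(target_species) > 12:
        raise DesignError("panel search supports at most 12 target species")

    amp_lo, amp_hi = constraints.amplicon_range
    scored: list[tuple[tuple, AssayPanel]] = []
    for rev in reverses:
        # per species, per distinct start keep the best-margin (then shortest)
        # forward: size depends only on start, so this preserves the optimum
        per_species: dict[str, dict[int, PrimerCandidate]] = {}
        feasible = True
        for sp in target_species:
            by_start: dict[int, PrimerCandidate] = {}
            for f in forwards[sp]:
                if f.end >= rev.start:
                    continue
                size = rev.end - f.start + 1
                if not amp_lo <= size <= amp_hi:
                    continue
                held = by_start.get(f.start)
                if held is None or (
                    (-f.qc_margin(constraints), len(f.primer))
                    < (-held.qc_margin(constraints), len(held.primer))
                ):
                    by_start[f.start] = f
            if not by_start:
                feasible = False
                break
            per_species[sp] = by_start
        if not feasible:
            continue
        chosen = _best_selection(per_species, target_species, constraints)
        if chosen is None:
            continue
        sizes = {sp: rev.end - c.start + 1 for sp, c in chosen.items()}
        sep = min(abs(a - b) for a, b in itertools.combinations(sizes.values(), 2))
        margin = min([rev.qc_margin(constraints)]
                     + [c.qc_margin(constraints) for c in chosen.values()])
        panel = AssayPanel(common_reverse=rev, forwards=chosen, expected_sizes=sizes)
        key = (
            -sep, -margin, rev.start, len(rev.primer),
            tuple(chosen[sp].start for sp in target_species),
            tuple(len(chosen[sp].primer) for sp in target_species),
        )
        scored.append((key, panel))

    report["reverse_placements_feasible"] = len(scored)
    if not scored:
        raise InfeasibleDesignError(
            f"no primer combination reaches pairwise size separation >= "
            f"{constraints.min_separation} within amplicon bounds {constraints.amplicon_range}",
            report,
        )
    scored.sort(key=lambda kv: kv[0])
    best = scored[0][1]
    best.validate(constraints)
    alternatives = [p for _, p in scored[1: 1 + n_alternatives]]
    report["panels_found"] = len(scored)
    return DesignResult(panel=best, alternatives=alternatives, report=report)


# ---------------------------------------------------------------------------
# Optimal start selection per reverse placement
#
# Product sizes depend only on the forward starts, so for a fixed reverse the
# search reduces to: pick one start per species maximising (1) the minimum
# pairwise gap, then (2) the worst QC margin, with lexicographic tie-breaks.
# Feasibility of "one start per species, pairwise gaps >= d" is decided by a
# subset DP over species (any valid pick sorts into an increasing sequence
# with consecutive gaps >= d); both objectives are monotone in their
# thresholds, so each is a binary search over feasibility checks.
# ---------------------------------------------------------------------------

_NEG = -(10**9)
_INF = 10**9


def _gap_feasible(groups: list[list[int]], d: int) -> bool:
    """Can we pick one value per sorted group with all pairwise gaps >= d?"""
    k = len(groups)
    f = [_INF] * (1 << k)  # f[S]: minimal possible largest value using groups in S
    f[0] = _NEG
    for S in range(1, 1 << k):
        best = _INF
        for j in range(k):
            bit = 1 << j
            if not S & bit:
                continue
            prev = f[S ^ bit]
            if prev >= _INF:
                continue
            i = bisect.bisect_left(groups[j], prev + d)
            if i < len(groups[j]) and groups[j][i] < best:
                best = groups[j][i]
        f[S] = best
    return f[(1 << k) - 1] < _INF


def _best_selection(per_species: dict[str, dict[int, PrimerCandidate]],
                    order: Sequence[str],
                    constraints: DesignConstraints) -> dict[str, PrimerCandidate] | None:
    """Optimal forward choice per species for one reverse placement, or None."""
    starts = {sp: sorted(per_species[sp]) for sp in order}
    margins = {sp: {s: per_species[sp][s].qc_margin(constraints) for s in starts[sp]}
               for sp in order}

    def groups_at(min_margin: float | None) -> list[list[int]]:
        if min_margin is None:
            return [starts[sp] for sp in order]
        return [[s for s in starts[sp] if margins[sp][s] >= min_margin] for sp in order]

    lo = constraints.min_separation
    if not _gap_feasible(groups_at(None), lo):
        return None
    hi = max(max(v) for v in starts.values()) - min(min(v) for v in starts.values())
    while lo < hi:  # largest feasible minimum pairwise gap
        mid = (lo + hi + 1) // 2
        if _gap_feasible(groups_at(None), mid):
            lo = mid
        else:
            hi = mid - 1
    d_star = lo

    # highest margin floor that stays feasible at the optimal separation
    levels = sorted({m for sp in order for m in margins[sp].values()})
    mlo, mhi = 0, len(levels) - 1
    while mlo < mhi:
        mid = (mlo + mhi + 1) // 2
        if _gap_feasible(groups_at(levels[mid]), d_star):
            mlo = mid
        else:
            mhi = mid - 1
    floor = levels[mlo]

    # lexicographically smallest start assignment among the optima
    filtered = {sp: [s for s in starts[sp] if margins[sp][s] >= floor] for sp in order}
    fixed: dict[str, int] = {}
    for sp in order:
        for s in filtered[sp]:
            trial = [[fixed[q]] if q in fixed else filtered[q] for q in order if q != sp]
            if _gap_feasible(trial + [[s]], d_star):
                fixed[sp] = s
                break
        else:  # pragma: no cover - guarded by the feasibility checks above
            return None
    return {sp: per_species[sp][fixed[sp]] for sp in order}


# ---------------------------------------------------------------------------
# Cross-dimer QC
# ---------------------------------------------------------------------------

def cross_dimer_3prime_check(a: PrimerRecord, b: PrimerRecord,
                             max_3prime_complementarity: int = 4) -> tuple[bool, int]:
    """Longest perfect complementary run anchored at either primer's 3' end.

    The score is the longest antiparallel Watson-Crick run that includes the
    terminal 3' base of ``a`` against any stretch of ``b``, or vice versa;
    the check fails when it exceeds the threshold.  Degenerate positions pair
    whenever their base sets can pair.
    """
    score = max(_anchored_run(a.sequence.residues, b.sequence.residues),
                _anchored_run(b.sequence.residues, a.sequence.residues))
    return score <= max_3prime_complementarity, score


def _pairs(x: str, y: str) -> bool:
    from .seqio import IUPAC_SETS, COMPLEMENT
    comp = {COMPLEMENT[b] for b in IUPAC_SETS[x]}
    return bool(comp & IUPAC_SETS[y])


def _anchored_run(anchored: str, other: str) -> int:
    """Longest run of consecutive pairings ending at ``anchored``'s 3' end."""
    best = 0
    n = len(anchored)
    # antiparallel: anchored 3'-terminal base pairs some other[j]; walk outward
    for j in range(len(other)):
        run = 0
        while run < n and j + run < len(other) and _pairs(anchored[n - 1 - run], other[j + run]):
            run += 1
        best = max(best, run)
    return best
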