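"""Amplicon-size genotyping: turn observed gel band sizes into species calls.

Each sample is one virtual gel lane: a list of observed band sizes in nt
(empty = no amplification).  A band matches a panel species when it lies
within the size tolerance of that species' expected product.  Lanes whose
bands match exactly one species are called; lanes with no matching band are
``no_call``; lanes compatible with two or more species are ``ambiguous``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .primer_design import AssayPanel

NO_CALL = "no_call"
AMBIGUOUS = "ambiguous"


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class LaneRecord:
    """One sample's observed band sizes (nt); an empty list is a blank lane."""

    sample_id: str
    sizes: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sizes", tuple(self.sizes))
        if any(s <= 0 for s in self.sizes):
            raise ClassificationError(f"lane {self.sample_id}: band sizes must be positive")


@dataclass(frozen=True)
class SpeciesCall:
    sample_id: str
    call: str  # species name, NO_CALL or AMBIGUOUS
    matched_size: float | None = None  # expected size matched, if any
    deviation: float | None = None  # |observed - expected| of the best band


@dataclass
class ClassificationReport:
    """Batch composition: per-species counts with exact fractions retained."""

    counts: dict[str, int]
    n: int
    no_call: int = 0
    ambiguous: int = 0
    calls: list[SpeciesCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = sum(self.counts.values()) + self.no_call + self.ambiguous
        if total != self.n:
            raise ClassificationError(f"counts sum to {total}, not n={self.n}")

    def fraction(self, species: str) -> float:
        return self.counts.get(species, 0) / self.n if self.n else 0.0

    def percent(self, species: str) -> int:
        """Display percentage, rounded half-away-from-zero to an integer."""
        return round_half_away(100.0 * self.fraction(species))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"species": sp, "count": c,
             "fraction": c / self.n if self.n else 0.0,
             "percent": self.percent(sp)}
            for sp, c in self.counts.items()
        ]
        rows.append({"species": NO_CALL, "count": self.no_call,
                     "fraction": self.no_call / self.n if self.n else 0.0,
                     "percent": round_half_away(100.0 * self.no_call / self.n) if self.n else 0})
        rows.append({"species": AMBIGUOUS, "count": self.ambiguous,
                     "fraction": self.ambiguous / self.n if self.n else 0.0,
                     "percent": round_half_away(100.0 * self.ambiguous / self.n) if self.n else 0})
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n": self.n,
            "counts": self.counts,
            "no_call": self.no_call,
            "ambiguous": self.ambiguous,
            "percent": {sp: self.percent(sp) for sp in self.counts},
            "calls": [
                {"sample_id": c.sample_id, "call": c.call,
                 "matched_size": c.matched_size, "deviation": c.deviation}
                for c in self.calls
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def round_half_away(x: float) -> int:
    """Round to nearest integer with ties going away from zero (16% from 15.79 is
    plain rounding; the tie rule matters for exact .5 fractions)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _check_tolerance(panel: AssayPanel, tolerance: float) -> None:
    if tolerance <= 0:
        raise ClassificationError("tolerance must be positive")
    sep = panel.min_pairwise_separation
    if len(panel.expected_sizes) > 1 and tolerance >= sep / 2:
        raise ClassificationError(
            f"tolerance {tolerance} >= half the minimum expected-size separation "
            f"({sep}/2); calls would overlap"
        )


def call_species(lane: LaneRecord, panel: AssayPanel,
                 tolerance: float | None = None, percent_mode: bool = False) -> SpeciesCall:
    """Call one lane against the panel's expected sizes.

    ``tolerance`` defaults to the panel's size tolerance; in ``percent_mode``
    it is interpreted as a percentage of each expected size instead of nt.
    """
    tol = panel.size_tolerance if tolerance is None else tolerance
    if not percent_mode:
        _check_tolerance(panel, tol)
    matches: dict[str, float] = {}
    for band in lane.sizes:
        for sp, expected in panel.expected_sizes.items():
            limit = expected * tol / 100.0 if percent_mode else tol
            dev = abs(band - expected)
            if dev <= limit:
                if sp not in matches or dev < matches[sp]:
                    matches[sp] = dev
    if not matches:
        return SpeciesCall(lane.sample_id, NO_CALL)
    if len(matches) > 1:
        return SpeciesCall(lane.sample_id, AMBIGUOUS)
    sp, dev = next(iter(matches.items()))
    return SpeciesCall(lane.sample_id, sp, matched_size=float(panel.expected_sizes[sp]),
                       deviation=dev)


def classify_batch(lanes: Sequence[LaneRecord], panel: AssayPanel,
                   tolerance: float | None = None,
                   percent_mode: bool = False) -> ClassificationReport:
    """Aggregate per-lane calls into a composition report."""
    if not lanes:
        raise ClassificationError("classify_batch needs at least one lane")
    calls = [call_species(lane, panel, tolerance, percent_mode) for lane in lanes]
    counts = {sp: 0 for sp in panel.expected_sizes}
    no_call = ambiguous = 0
    for c in calls:
        if c.call == NO_CALL:
            no_call += 1
        elif c.call == AMBIGUOUS:
            ambiguous += 1
        else:
            counts[c.call] += 1
    return ClassificationReport(counts=counts, n=len(lanes), no_call=no_call,
                                ambiguous=ambiguous, calls=calls)


# ---------------------------------------------------------------------------
# Lane TSV I/O (sample_id <tab> comma-separated sizes; empty field = blank lane)
# ---------------------------------------------------------------------------

def read_lane_tsv(path: str | Path) -> list[LaneRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    if "sample_id" not in df.columns or "sizes" not in df.columns:
        raise ClassificationError(f"lane table {path} needs columns sample_id, sizes")
    lanes = []
    for _, row in df.iterrows():
        raw = row["sizes"].strip()
        sizes = tuple(float(x) for x in raw.split(",") if x.strip()) if raw else ()
        lanes.append(LaneRecord(row["sample_id"], sizes))
    return lanes


def write_lane_tsv(lanes: Sequence[LaneRecord], path: str | Path,
                   header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("sample_id\tsizes\n")
        for lane in lanes:
            fh.write(f"{lane.sample_id}\t{','.join(str(int(s)) if float(s).is_integer() else str(s) for s in lane.sizes)}\n")
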