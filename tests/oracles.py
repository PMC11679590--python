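"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (character-by-character, all-offsets,
all-substrings) and shares no code with the package's scan/search paths.
"""

from __future__ import annotations

from amplityper.seqio import COMPLEMENT, GAP, IUPAC_SETS, revcomp


def bases_match(a: str, b: str) -> bool:
    return bool(IUPAC_SETS[a] & IUPAC_SETS[b])


def brute_force_binding_sites(primer: str, template: str, max_mismatches: int,
                              three_prime_exact: int) -> list[tuple[str, int, int, tuple[int, ...]]]:
    """All (strand, start, end, mismatch_positions) by trying every offset."""
    out = []
    m = len(primer)
    for strand, probe in (("+", primer), ("-", revcomp(primer))):
        # 3'-exact zone on plus-strand coordinates: right edge for +, left for -
        zone = range(m - three_prime_exact, m) if strand == "+" else range(three_prime_exact)
        for off in range(len(template) - m + 1):
            mism = [k for k in range(m) if not bases_match(probe[k], template[off + k])]
            if len(mism) > max_mismatches:
                continue
            if any(k in zone for k in mism):
                continue
            out.append((strand, off + 1, off + m, tuple(off + k + 1 for k in mism)))
    out.sort(key=lambda s: (s[1], s[0]))
    return out


def brute_force_diagnostic_columns(rows: list[tuple[str, str]], target: str) -> list[int]:
    """Columns diagnostic for ``target`` by direct recount.  rows = (species, residues)."""
    targets = [r for sp, r in rows if sp == target]
    others = [r for sp, r in rows if sp != target]
    length = len(rows[0][1])
    cols = []
    for i in range(length):
        tb = {r[i] for r in targets}
        if len(tb) != 1 or GAP in tb:
            continue
        t = next(iter(tb))
        if all(o[i] != GAP and not bases_match(t, o[i]) for o in others):
            cols.append(i + 1)
    return cols


def brute_force_conserved_windows(rows: list[str], min_length: int) -> list[tuple[int, int]]:
    length = len(rows[0])
    conserved = [len({r[i] for r in rows}) == 1 and rows[0][i] != GAP for i in range(length)]
    out = []
    i = 0
    while i < length:
        if conserved[i]:
            j = i
            while j < length and conserved[j]:
                j += 1
            if j - i >= min_length:
                out.append((i + 1, j))
            i = j
        else:
            i += 1
    return out


def brute_force_dimer_score(a: str, b: str) -> int:
    """Longest complementary run containing either primer's 3'-terminal base,
    by checking every run length against every substring of the partner."""
    def anchored(p: str, q: str) -> int:
        best = 0
        for r in range(1, len(p) + 1):
            tail = p[-r:]
            # antiparallel: tail read 3'->5' pairs q read 5'->3'
            probe = "".join(COMPLEMENT[c] for c in reversed(tail))
            for j in range(len(q) - r + 1):
                if all(bases_match(probe[t], q[j + t]) for t in range(r)):
                    best = max(best, r)
                    break
        return best

    return max(anchored(a, b), anchored(b, a))
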