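"""Independent brute-force oracles for the sequence-feature operations.

These deliberately avoid the implementations they check: counters are
naive positional scans, pairing maxima come from explicit enumeration of
pair sets rather than dynamic programming.
"""

from __future__ import annotations

PYRIMIDINES = {"C", "T"}
BONDS = {frozenset("GC"): 3, frozenset("AT"): 2, frozenset("GT"): 2}


def bond(x: str, y: str) -> int:
    return BONDS.get(frozenset((x, y)), 0) if x != y else 0


def tna_scan(seq: str) -> int:
    seq = seq.upper()
    count = 0
    for i in range(len(seq)):
        if i + 2 < len(seq):
            if seq[i] == "T" and seq[i + 1] in "ACGT" and seq[i + 2] == "A":
                count += 1
    return count


def t_rich_scan(seq: str, window: int = 4, min_t: int = 3) -> int:
    seq = seq.upper()
    count = 0
    for i in range(len(seq) - window + 1):
        if sum(1 for c in seq[i : i + window] if c == "T") >= min_t:
            count += 1
    return count


def branch_point_scan(seq: str, min_score: float = 1.0) -> list[tuple[int, int]]:
    """(offset, score) for every retained BP adenine, naive re-derivation."""
    seq = seq.upper()
    out = []
    for i in range(len(seq)):
        if seq[i] != "A" or i < 3 or i + 1 >= len(seq):
            continue
        matches = 1  # the A itself
        if seq[i - 3] in PYRIMIDINES:
            matches += 1
        if seq[i - 2] == "T":
            matches += 1
        if seq[i + 1] in PYRIMIDINES:
            matches += 1
        score = matches - 2
        if score > min_score:
            out.append((i - len(seq), score))
    return out


def duplex_enumerate(target: str, probe: str) -> int:
    """Maximum bond sum over antiparallel non-crossing pairings, by
    explicit recursive enumeration of every monotone match set."""
    t = target.upper().replace("U", "T")
    p = probe.upper().replace("U", "T")[::-1]

    def best_from(i: int, j: int) -> int:
        if i >= len(t) or j >= len(p):
            return 0
        options = [best_from(i + 1, j)]  # leave t[i] unpaired
        for jj in range(j, len(p)):
            w = bond(t[i], p[jj])
            if w:
                options.append(w + best_from(i + 1, jj + 1))
        return max(options)

    return best_from(0, 0)


def fold_enumerate(seq: str, min_loop: int = 3) -> int:
    """Maximum bond sum over non-crossing secondary structures, by
    exhaustive enumeration of pair sets (exponential; use on short
    sequences only)."""
    s = seq.upper().replace("U", "T")

    def best(indices: tuple[int, ...]) -> int:
        if not indices:
            return 0
        i, rest = indices[0], indices[1:]
        options = [best(rest)]
        for pos, k in enumerate(rest):
            w = bond(s[i], s[k])
            if w and k - i > min_loop:
                inside = tuple(x for x in rest[:pos] if i < x < k)
                outside = tuple(x for x in rest[pos + 1 :])
                options.append(w + best(inside) + best(outside))
        return max(options)

    return best(tuple(range(len(s))))


def window_profile_scan(seqs: list[str], base_set: str, window: int = 20) -> list[float]:
    """Per-window mean base-set percent across sequences, naive version."""
    n_windows = len(seqs[0]) - window + 1
    out = []
    for w in range(n_windows):
        vals = []
        for seq in seqs:
            chunk = seq[w : w + window].upper()
            denom = sum(1 for c in chunk if c in "ACGT")
            if denom:
                vals.append(100.0 * sum(1 for c in chunk if c in base_set) / denom)
        out.append(sum(vals) / len(vals) if vals else float("nan"))
    return out
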