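"""Independent test oracles (brute force / enumeration / closed forms).

These deliberately avoid the package's own algorithms: the alignment oracle
enumerates every alignment path explicitly and scores it from scratch; the
demux oracle is a plain Hamming scan; the clone-outcome oracle enumerates
the full draw space with exact probabilities.
"""

from __future__ import annotations

from itertools import product


def oracle_semi_global_score(query: str, reference: str, match: int, mismatch: int,
                             gap_open: int, gap_extend: int) -> int:
    """Best semi-global score by exhaustive enumeration of alignment paths.

    An alignment is a sequence of columns (M = pair bases, I = consume query
    only, D = consume reference only) that consumes the whole query and some
    window of the reference; reference overhangs are free.  A gap run of
    length g costs gap_open + g * gap_extend; adjacent runs of different gap
    types are charged separately.
    """
    L, R = len(query), len(reference)
    best = [-(10 ** 9)]

    def rec(i: int, j: int, last: str | None, acc: int) -> None:
        if i == L:
            if acc > best[0]:
                best[0] = acc
            return
        # consume query base against reference base
        if j < R:
            s = match if query[i] == reference[j] else -mismatch
            rec(i + 1, j + 1, "M", acc + s)
            # gap in query (reference base skipped inside the alignment)
            cost = gap_extend if last == "D" else gap_open + gap_extend
            rec(i, j + 1, "D", acc - cost)
        # gap in reference (query base opposite nothing)
        cost = gap_extend if last == "I" else gap_open + gap_extend
        rec(i + 1, j, "I", acc - cost)

    for start in range(R + 1):
        rec(0, start, None, 0)
    return best[0]


def oracle_demux_assignment(prefix: str, barcodes: dict[str, str], max_mismatch: int) -> str | None:
    """Sample id if exactly one barcode is within max_mismatch, else None."""
    hits = [
        sample
        for sample, bc in barcodes.items()
        if sum(a != b for a, b in zip(prefix[: len(bc)], bc)) <= max_mismatch
    ]
    return hits[0] if len(hits) == 1 else None


def oracle_p_more_than_two_distinct(outcomes: dict[str, float], n_draws: int = 4) -> float:
    """P(> 2 distinct outcomes among n iid draws), by full enumeration."""
    total = 0.0
    keys = list(outcomes)
    for combo in product(keys, repeat=n_draws):
        if len(set(combo)) > 2:
            p = 1.0
            for k in combo:
                p *= outcomes[k]
            total += p
    return total


def oracle_binom_tail(n: int, p: float, k: int) -> float:
    """P(X >= k) for X ~ Binomial(n, p) by direct summation."""
    from math import comb

    return sum(comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1))
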