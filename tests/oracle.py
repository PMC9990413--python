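"""Independent brute-force reimplementation of the score formulas.

Deliberately written with plain Python loops, dicts and ``math`` — no
numpy, no imports from the scoring module — so agreement with the
package is a genuine two-route check.
"""

import math


def brute_counts(rows: list[str], alphabet: str) -> list[dict[str, int]]:
    length = len(rows[0])
    out = []
    for p in range(length):
        col: dict[str, int] = {l: 0 for l in alphabet}
        for row in rows:
            ch = row[p]
            if ch in col:
                col[ch] += 1
        out.append(col)
    return out


def brute_f_prime(counts, background: dict[str, float], c: float):
    out = []
    for col in counts:
        total = sum(col.values())
        out.append(
            {l: (col[l] + c * background[l]) / (total + c) for l in col}
        )
    return out


def brute_f_second(f_prime, background):
    return [{l: fp[l] / background[l] for l in fp} for fp in f_prime]


def brute_m(f_second):
    return [{l: math.log(fs[l]) for l in fs} for fs in f_second]


def brute_scores(rows, alphabet, background, c):
    """All four matrices from raw rows in one call."""
    counts = brute_counts(rows, alphabet)
    f_prime = brute_f_prime(counts, background, c)
    f_second = brute_f_second(f_prime, background)
    m = brute_m(f_second)
    return counts, f_prime, f_second, m


def brute_delta(m, p: int, wt: str, mut: str) -> float:
    """Δ = M(p, mut) − M(p, wt), 0-based p."""
    return m[p][mut] - m[p][wt]
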