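"""Shared exact-enumeration oracle for two-sided Fisher tests.

Integer arithmetic throughout: with margins fixed, every table's
hypergeometric probability shares the denominator C(n, c1), so tables can
be classified by comparing integer numerators exactly.
"""

import math


def fisher_enumeration(a: int, b: int, c: int, d: int) -> float:
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if min(r1, r2, c1, b + d) == 0:
        return 1.0
    num_obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = 0
    acc = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        num = math.comb(r1, x) * math.comb(r2, c1 - x)
        total += num
        if num <= num_obs:
            acc += num
    return acc / total
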