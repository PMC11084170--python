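"""Brute-force reference implementations of the five heterogeneity scores.

Deliberately naive: explicit enumeration of reads, substrings, epiallele
patterns and read pairs, with no shortcuts shared with the package kernels.
"""

from __future__ import annotations

import itertools
from typing import Optional, Sequence


def pdr_oracle(reads, min_cpgs: int = 4, min_depth: int = 10) -> Optional[float]:
    eligible = [r for r in reads if len(r.positions) >= min_cpgs]
    if len(eligible) < min_depth:
        return None
    discordant = 0
    for r in eligible:
        states = set(r.states)
        if states == {"M", "U"}:
            discordant += 1
    return discordant / len(eligible)


def pm_oracle(reads, quartet: Sequence[int], min_depth: int = 10) -> Optional[float]:
    quartet = tuple(quartet)
    counts = {"".join(p): 0 for p in itertools.product("MU", repeat=4)}
    n = 0
    for r in reads:
        call_map = {p: s for p, s in zip(r.positions, r.states)}
        if all(p in call_map for p in quartet):
            counts["".join(call_map[p] for p in quartet)] += 1
            n += 1
    if n < min_depth:
        return None
    return 1.0 - sum((c / n) ** 2 for c in counts.values())


def mhl_oracle(reads, min_depth: int = 10) -> Optional[float]:
    if len(reads) < min_depth:
        return None
    total: dict[int, int] = {}
    meth: dict[int, int] = {}
    for r in reads:
        s = r.states
        for i in range(len(s)):
            for j in range(i, len(s)):
                sub = s[i : j + 1]
                l = len(sub)
                total[l] = total.get(l, 0) + 1
                if set(sub) == {"M"}:
                    meth[l] = meth.get(l, 0) + 1
    num = sum(l * meth.get(l, 0) / total[l] for l in total)
    den = sum(total)
    return num / den


def _pair_values(reads, anchor: int, window: Optional[int], min_depth: int):
    if len(reads) < min_depth:
        return None
    values = []
    for a, b in itertools.combinations(reads, 2):
        ca = {p: s for p, s in zip(a.positions, a.states)
              if window is None or abs(p - anchor) <= window}
        cb = {p: s for p, s in zip(b.positions, b.states)
              if window is None or abs(p - anchor) <= window}
        shared = sorted(set(ca) & set(cb))
        if not shared:
            continue
        diff = sum(1 for p in shared if ca[p] != cb[p])
        values.append(diff / len(shared))
    return values or None


def fdrp_oracle(reads, anchor: int, window: Optional[int] = 50,
                min_depth: int = 10) -> Optional[float]:
    values = _pair_values(reads, anchor, window, min_depth)
    if values is None:
        return None
    return sum(1 for v in values if v > 0) / len(values)


def qfdrp_oracle(reads, anchor: int, window: Optional[int] = 50,
                 min_depth: int = 10) -> Optional[float]:
    values = _pair_values(reads, anchor, window, min_depth)
    if values is None:
        return None
    return sum(values) / len(values)
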