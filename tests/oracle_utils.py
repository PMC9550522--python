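"""Independent brute-force oracles used by the test-suite.

These deliberately re-derive the definitions from first principles
(language generation, exhaustive enumeration) rather than reusing the
package's code paths, so each test compares two independent routes.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations
from math import comb

from polyxy.detect import ProteinRecord


# --- direpeat / joined membership by language generation -------------------

@lru_cache(maxsize=None)
def _direpeat_language(x: str, y: str, n: int) -> frozenset:
    """All direpeat strings of length n over letters {x, y}: every placement
    of (XY)+ or (YX)+ with at most one lone-residue insertion."""
    out = set()
    for u in (x + y, y + x):
        if n % 2 == 0:
            out.add(u * (n // 2))
        else:
            base = u * ((n - 1) // 2)
            for c in (x, y):
                for i in range(len(base) + 1):
                    out.add(base[:i] + c + base[i:])
    return frozenset(out)


def brute_is_direpeat(seq: str) -> bool:
    letters = sorted(set(seq))
    if len(letters) != 2:
        return False
    return seq in _direpeat_language(letters[0], letters[1], len(seq))


def brute_is_joined(seq: str) -> bool:
    letters = set(seq)
    if len(letters) != 2:
        return False
    for a in letters:
        b = (letters - {a}).pop()
        for i in range(2, len(seq) - 1):
            if seq == a * i + b * (len(seq) - i):
                return True
    return False


# --- exhaustive embedded-pattern enumeration -------------------------------

def brute_embedded(seq: str, window: int) -> tuple[bool, bool]:
    fj = fd = False
    n = len(seq)
    for length in range(window, n + 1):
        for i in range(n - length + 1):
            sub = seq[i : i + length]
            fj = fj or brute_is_joined(sub)
            fd = fd or brute_is_direpeat(sub)
    return fj, fd


# --- exact Mann-Whitney U enumeration (no ties) ----------------------------

def exact_mwu(a, b) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney U by enumerating all rank assignments.

    Valid for tie-free pooled samples.  U is reported for the first
    sample; the two-sided p uses the symmetry of the null distribution:
    p = 2 * P(U >= max(u, n1*n2 - u)).
    """
    n1, n2 = len(a), len(b)
    pooled = sorted(list(a) + list(b))
    assert len(set(pooled)) == n1 + n2, "exact enumeration assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in a) - n1 * (n1 + 1) / 2

    total = comb(n1 + n2, n1)
    u_big = max(u_obs, n1 * n2 - u_obs)
    count = 0
    for combo in combinations(range(1, n1 + n2 + 1), n1):
        u = sum(combo) - n1 * (n1 + 1) / 2
        if u >= u_big:
            count += 1
    p = min(1.0, 2 * count / total)
    return u_obs, p


def protein(seq: str, pid: str = "P") -> ProteinRecord:
    return ProteinRecord(id=pid, sequence=seq)
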