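"""ISub string similarity, the metric of choice for ontology label matching.

ISub scores two strings by balancing their commonality against their
difference, with a Jaro-Winkler-style reward for a shared prefix:

    sim(s1, s2) = comm(s1, s2) - diff(s1, s2) + winkler(s1, s2)

* ``comm`` is twice the total length of the greedily-removed maximal common
  substrings over the summed string lengths,
* ``diff`` combines the unmatched fractions of the two strings through a
  Hamacher product parameterised by p = 0.6, and
* ``winkler`` adds up to 0.4 of the remaining headroom for a shared prefix
  of up to four characters.

The raw value lies in [-1, 1]; this module clamps it to [0, 1] because all
downstream similarity contracts require that range.
"""

from __future__ import annotations

_HAMACHER_P = 0.6
_MIN_SUBSTRING = 1
_WINKLER_PREFIX = 4
_WINKLER_SCALE = 0.1

#: Unequal strings whose characters fully cover each other (block
#: anagrams, e.g. transposed words) can reach a raw score of 1.0; the
#: exact score 1.0 is reserved for string equality, so such pairs are
#: capped just below it.
_UNEQUAL_CAP = 0.999


def _longest_common_substring(s1: str, s2: str) -> tuple[int, int, int]:
    """(length, start1, start2) of the longest common substring."""
    best_len = 0
    best1 = best2 = 0
    # classic O(len1*len2) DP over suffix match lengths, one row at a time
    prev = [0] * (len(s2) + 1)
    for i in range(1, len(s1) + 1):
        cur = [0] * (len(s2) + 1)
        c1 = s1[i - 1]
        for j in range(1, len(s2) + 1):
            if c1 == s2[j - 1]:
                length = prev[j - 1] + 1
                cur[j] = length
                if length > best_len:
                    best_len = length
                    best1 = i - length
                    best2 = j - length
        prev = cur
    return best_len, best1, best2


def isub(a: str, b: str) -> float:
    """ISub similarity between two non-empty strings, clamped to [0, 1].

    Symmetric, and exactly 1.0 iff the strings are equal.
    """
    if not a or not b:
        raise ValueError("isub requires non-empty strings")
    if a == b:
        return 1.0

    l1, l2 = len(a), len(b)

    # shared prefix measured on the original strings
    prefix = 0
    for ca, cb in zip(a, b):
        if ca != cb:
            break
        prefix += 1
    prefix = min(prefix, _WINKLER_PREFIX)

    # greedily remove maximal common substrings
    s1, s2 = a, b
    common = 0
    while True:
        length, p1, p2 = _longest_common_substring(s1, s2)
        if length < _MIN_SUBSTRING:
            break
        common += length
        s1 = s1[:p1] + s1[p1 + length:]
        s2 = s2[:p2] + s2[p2 + length:]

    comm = 2.0 * common / (l1 + l2)
    u1 = (l1 - common) / l1
    u2 = (l2 - common) / l2
    denom = _HAMACHER_P + (1.0 - _HAMACHER_P) * (u1 + u2 - u1 * u2)
    diff = (u1 * u2) / denom if denom else 0.0
    winkler = prefix * _WINKLER_SCALE * (1.0 - comm)

    raw = comm - diff + winkler
    return min(_UNEQUAL_CAP, max(0.0, raw))
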