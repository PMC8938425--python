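"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results with the most naive possible logic
(explicit loops, hand-written pairing rules) so they stay independent of
the implementation paths they check.
"""

import itertools

STRONG = {"AU", "UA", "GC", "CG", "GU", "UG"}
WEAK = {"GG", "UU", "GA", "AG"}


def naive_type1_es(stem, mm5):
    """Hand-derived excited-state pairing for a +1 register shift.

    ``stem`` is a list of pair strings ordered loop -> terminal; each 3'
    base re-pairs with the 5' base one position below, the loop-adjacent
    5' base joins the loop, and the mismatch 5' base joins the bottom.
    """
    fives = [p[0] for p in stem] + [mm5]
    threes = [p[1] for p in stem]
    return [fives[i + 1] + threes[i] for i in range(len(stem))]


def naive_enumerate(stem_len, loop_tok, mm, constraints=("strong", "triplet", "es")):
    """Exhaustive triple-loop stem enumeration under the design rules."""
    out = []
    for combo in itertools.product(sorted(STRONG), repeat=stem_len):
        if "triplet" in constraints:
            sigs = []
            for i in range(stem_len):
                above = combo[i - 1] if i > 0 else loop_tok
                below = combo[i + 1] if i < stem_len - 1 else "mm:" + mm[0] + mm[1]
                sigs.append((above, combo[i], below))
            if len(set(sigs)) != len(sigs):
                continue
        if "es" in constraints:
            es = naive_type1_es(list(combo), mm[0])
            if any(p not in STRONG and p not in WEAK for p in es):
                continue
            if sum(p in WEAK for p in es) > 1:
                continue
        out.append(combo)
    return out
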