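"""Simplified nearest-neighbor free-energy parameters for hairpin stems.

Stacking free energies dG37 (kcal/mol) for consecutive base pairs.  A
stack key is ``(upper, lower)`` where each pair is written
five-prime-base + three-prime-base and ``upper`` is the pair closer to
the hairpin loop.  The table stores one orientation per stack; lookups
try the symmetry-equivalent reading (reverse both pairs and swap) as
well.

The ten canonical Watson-Crick stacks carry the standard Turner-style
dG37 values.  G.U-wobble-containing stacks and the hairpin-loop
initiation penalties are round-number approximations: this backend is a
deliberately simplified, fully deterministic stand-in for a structure
prediction program, good enough to rank register-shift candidates, and
is labelled approximate wherever it is exposed.
"""

from __future__ import annotations

from .constants import R_KCAL_MOL_K

#: Watson-Crick / wobble stack free energies, kcal/mol at 37 C.
#: Key (upper_pair, lower_pair); pair string = 5' base + 3' base.
STACK_DG37 = {
    # canonical Watson-Crick stacks (Turner-style)
    ("AU", "AU"): -0.93,
    ("AU", "UA"): -1.10,
    ("UA", "AU"): -1.33,
    ("CG", "AU"): -2.11,
    ("CG", "UA"): -2.08,
    ("GC", "AU"): -2.35,
    ("GC", "UA"): -2.24,
    ("CG", "GC"): -2.36,
    ("GC", "CG"): -3.42,
    ("GC", "GC"): -3.26,
    # G.U wobble stacks (approximate)
    ("AU", "GU"): -1.30,
    ("AU", "UG"): -1.40,
    ("UA", "GU"): -1.00,
    ("UA", "UG"): -0.60,
    ("CG", "GU"): -2.10,
    ("CG", "UG"): -1.40,
    ("GC", "GU"): -2.50,
    ("GC", "UG"): -1.50,
    ("GU", "AU"): -0.80,
    ("GU", "UA"): -1.00,
    ("UG", "AU"): -1.20,
    ("UG", "UA"): -0.90,
    ("GU", "CG"): -1.50,
    ("GU", "GC"): -2.20,
    ("UG", "CG"): -1.20,
    ("UG", "GC"): -1.90,
    # wobble-wobble stacks (approximate)
    ("GU", "GU"): -0.50,
    ("GU", "UG"): 0.50,
    ("UG", "GU"): -0.60,
    ("UG", "UG"): -0.50,
}

#: Hairpin-loop initiation penalty by loop size (kcal/mol, approximate).
HAIRPIN_LOOP_DG = {
    3: 5.4,
    4: 5.6,
    5: 5.7,
    6: 5.4,
    7: 6.0,
    8: 6.1,
    9: 6.3,
}

#: Destabilisation assigned to a weak (G.G / U.U / G.A / A.G) pair; its
#: flanking stacks are not scored.
WEAK_PAIR_PENALTY = 1.0


def hairpin_loop_dg(size: int, T: float = 310.15) -> float:
    """Loop initiation penalty; sizes beyond the table extrapolate with
    the Jacobson-Stockmayer 1.75 RT ln(n/9) term."""
    if size < 3:
        raise ValueError("hairpin loops need at least 3 nucleotides")
    if size in HAIRPIN_LOOP_DG:
        return HAIRPIN_LOOP_DG[size]
    import math

    return HAIRPIN_LOOP_DG[9] + 1.75 * R_KCAL_MOL_K * T * math.log(size / 9.0)


def stack_dg(upper: str, lower: str) -> float:
    """Stack free energy with symmetry-aware lookup.

    Reading the same stack from the other strand maps (upper, lower) to
    (lower[::-1], upper[::-1]).  Raises KeyError naming the stack when no
    parameter exists.
    """
    key = (upper, lower)
    if key in STACK_DG37:
        return STACK_DG37[key]
    alt = (lower[::-1], upper[::-1])
    if alt in STACK_DG37:
        return STACK_DG37[alt]
    raise KeyError(f"no stacking parameter for stack 5'{upper[0]}{lower[0]}3'/3'{upper[1]}{lower[1]}5' ({upper}/{lower})")
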