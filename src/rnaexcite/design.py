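"""Combinatorial design of hairpin stems with a predefined excited state.

A hairpin is built from an invariant tetraloop, a variable stem and a
non-canonical cap (mismatch) below the stem.  The designed excited state
(ES) is the structure reached by sliding one strand of the stem by one
or two nucleotides in register.  Design constraints:

1. every ground-state (GS) pair is *strong* -- a Watson-Crick pair or a
   G.U wobble;
2. every stem nucleotide sits at the centre of a unique base-pair
   triplet, so imino resonances stay resolved;
3. the ES formed by the register shift contains at most one *weak* pair
   (G.G, U.U, G.A or A.G), all others strong.

Candidates passing the constraints are scored by a pluggable energy
backend (ddG = E(ES) - E(GS)); the design filter keeps candidates whose
designed ES lies within a ddG threshold (default 3 kcal/mol, an ES
population of roughly 0.5% at 10 C -- the practical dispersion-detection
floor) and scores below every alternative structure in a bounded scan.

Stem coordinates: pairs are ordered from loop-proximal (index 0) to
terminal, each stored as (5' base, 3' base).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .nn_params import WEAK_PAIR_PENALTY, hairpin_loop_dg, stack_dg

__all__ = [
    "BasePair",
    "HairpinSpec",
    "StemCandidate",
    "EnergyBackend",
    "NearestNeighborBackend",
    "STRONG_PAIRS",
    "WEAK_PAIRS",
    "SHIFT_MODES",
    "classify_pair",
    "register_shift",
    "enumerate_stems",
    "score_candidate",
    "design_filter",
]

BASES = ("A", "C", "G", "U")

#: Watson-Crick pairs and G.U wobbles, written 5' base + 3' base.
STRONG_PAIRS = ("AU", "CG", "GC", "GU", "UA", "UG")

#: Tolerated non-canonical ES pairs.
WEAK_PAIRS = ("AG", "GA", "GG", "UU")

#: Register-shift modes: signed offset of the 5' strand relative to the
#: 3' strand.  type1: +1 (5'->3' slide, loop grows by one); type2: -1
#: (opposite direction); type3: +2; type4: +1 applied to a lower stem
#: next to a single bulge (same pair arithmetic, different context).
SHIFT_MODES = {"type1": 1, "type2": -1, "type3": 2, "type4": 1}


@dataclass(frozen=True)
class BasePair:
    """One stem base pair, (5' base, 3' base)."""

    five_prime_base: str
    three_prime_base: str

    def __post_init__(self) -> None:
        for b in (self.five_prime_base, self.three_prime_base):
            if b not in BASES:
                raise ValueError(f"invalid base {b!r}; expected one of {BASES}")

    @property
    def as_str(self) -> str:
        return self.five_prime_base + self.three_prime_base

    @property
    def klass(self) -> str:
        return classify_pair(self)

    @classmethod
    def from_str(cls, s: str) -> "BasePair":
        if len(s) != 2:
            raise ValueError("pair string must have two bases")
        return cls(s[0], s[1])


def classify_pair(pair) -> str:
    """strong (WC or G.U wobble), weak (G.G/U.U/G.A/A.G) or other."""
    s = pair.as_str if isinstance(pair, BasePair) else str(pair)
    if len(s) != 2 or any(b not in BASES for b in s):
        raise ValueError(f"invalid pair {s!r}")
    if s in STRONG_PAIRS:
        return "strong"
    if s in WEAK_PAIRS:
        return "weak"
    return "other"


@dataclass(frozen=True)
class HairpinSpec:
    """Design brief for one hairpin family.

    closing_mismatch is the non-canonical cap below the stem,
    (5' base, 3' base); its 5' base is the nucleotide recruited into the
    bottom pair on a type1 shift.  dangling_5prime is the optional
    transcription-optimising 5' G, the second recruitable context base
    for two-nucleotide shifts.
    """

    loop_seq: str = "GCAA"
    stem_len: int = 5
    closing_mismatch: tuple = ("G", "A")
    shift_mode: str = "type1"
    dangling_5prime: str | None = "G"

    def __post_init__(self) -> None:
        if self.stem_len < 1:
            raise ValueError("stem_len must be >= 1")
        if self.shift_mode not in SHIFT_MODES:
            raise ValueError(f"shift_mode must be one of {sorted(SHIFT_MODES)}")
        if abs(SHIFT_MODES[self.shift_mode]) > self.stem_len:
            raise ValueError("shift magnitude exceeds stem length")
        if any(b not in BASES for b in self.loop_seq):
            raise ValueError("loop_seq must be ACGU")

    @property
    def shift(self) -> int:
        return SHIFT_MODES[self.shift_mode]

    @property
    def five_prime_context(self) -> tuple:
        ctx = [self.closing_mismatch[0]]
        if self.dangling_5prime:
            ctx.append(self.dangling_5prime)
        return tuple(ctx)

    @property
    def three_prime_context(self) -> tuple:
        return (self.closing_mismatch[1],)


@dataclass
class StemCandidate:
    """A stem with its GS pairing, shift-derived ES pairing and score."""

    spec: HairpinSpec
    gs_pairs: tuple
    es_pairs: tuple
    displaced: tuple
    triplet_signatures: tuple
    ddG: float | None = None
    rank_ok: bool | None = None

    @property
    def inverted(self) -> bool:
        """GS/ES inversion: the designed excited state scores as the more
        stable structure (ddG < 0), so the intended ground state is not
        the ground state at all."""
        return self.ddG is not None and self.ddG < 0.0

    @property
    def gs_str(self) -> str:
        return "-".join(p.as_str for p in self.gs_pairs)

    def sequence(self) -> str:
        """Full 5'->3' construct sequence: dangling G, mismatch 5' base,
        5' strand (terminal to loop), loop, 3' strand, mismatch 3' base."""
        s = self.spec
        fives = "".join(p.five_prime_base for p in reversed(self.gs_pairs))
        threes = "".join(p.three_prime_base for p in self.gs_pairs)
        return (
            (s.dangling_5prime or "")
            + s.closing_mismatch[0]
            + fives
            + s.loop_seq
            + threes
            + s.closing_mismatch[1]
        )


# --------------------------------------------------------------------------
# register shift
# --------------------------------------------------------------------------


def register_shift(
    gs_pairs,
    shift,
    five_prime_context=(),
    three_prime_context=(),
):
    """Re-pair a stem after sliding one strand by ``shift`` nucleotides.

    ``shift`` may be a mode name from :data:`SHIFT_MODES` or a signed
    integer: positive shifts re-pair each 3'-strand base with the
    5'-strand partner ``shift`` positions closer to the terminus
    (recruiting context bases below the stem and displacing 5' bases into
    the loop); negative shifts mirror this on the 3' strand.  shift 0 is
    the identity.

    Context tuples list recruitable bases below the stem, innermost
    first.  Returns ``(es_pairs, displaced)`` where ``displaced`` records
    each unpaired nucleotide as (base, strand, 'loop'|'terminal').
    Deterministic, and invertible for interior pairs (a +s shift followed
    by -s restores their pairing).
    """
    if isinstance(shift, str):
        shift = SHIFT_MODES[shift]
    gs_pairs = tuple(
        p if isinstance(p, BasePair) else BasePair.from_str(p) for p in gs_pairs
    )
    n = len(gs_pairs)
    if abs(shift) > n:
        raise ValueError(f"shift {shift} exceeds stem length {n}")
    if shift == 0:
        return gs_pairs, ()

    fives = [p.five_prime_base for p in gs_pairs]
    threes = [p.three_prime_base for p in gs_pairs]
    displaced = []
    es = []
    if shift > 0:
        ext = fives + list(five_prime_context[: shift])
        for b in fives[:shift]:
            displaced.append((b, "5p", "loop"))
        for i in range(n):
            j = i + shift
            if j < len(ext):
                es.append(BasePair(ext[j], threes[i]))
            else:
                displaced.append((threes[i], "3p", "terminal"))
        for b in three_prime_context:
            displaced.append((b, "3p", "terminal"))
    else:
        s = -shift
        ext = threes + list(three_prime_context[:s])
        for b in threes[:s]:
            displaced.append((b, "3p", "loop"))
        for i in range(n):
            j = i + s
            if j < len(ext):
                es.append(BasePair(fives[i], ext[j]))
            else:
                displaced.append((fives[i], "5p", "terminal"))
        for b in five_prime_context:
            displaced.append((b, "5p", "terminal"))
    return tuple(es), tuple(displaced)


def _triplet_signatures(spec: HairpinSpec, gs_pairs) -> tuple:
    """Per-nucleotide (strand, pair-above, pair, pair-below) signatures
    with loop / closing-mismatch context tokens at the termini."""
    n = len(gs_pairs)
    loop_tok = f"loop:{spec.loop_seq}"
    mm_tok = f"mm:{spec.closing_mismatch[0]}{spec.closing_mismatch[1]}"
    sigs = []
    for i, p in enumerate(gs_pairs):
        above = gs_pairs[i - 1].as_str if i > 0 else loop_tok
        below = gs_pairs[i + 1].as_str if i < n - 1 else mm_tok
        for strand in ("5p", "3p"):
            sigs.append((strand, above, p.as_str, below))
    return tuple(sigs)


def _stem_base(strand: str, pair: BasePair) -> str:
    return pair.five_prime_base if strand == "5p" else pair.three_prime_base


# --------------------------------------------------------------------------
# enumeration
# --------------------------------------------------------------------------

ALL_CONSTRAINTS = ("strong", "triplet", "es")


def enumerate_stems(
    spec: HairpinSpec,
    constraints=ALL_CONSTRAINTS,
    gu_only_triplets: bool = False,
):
    """Exhaustively enumerate stem candidates in lexicographic order.

    ``constraints`` selects which of the three design rules apply:
    "strong" (GS pairs all strong -- always effectively on, since only
    strong pairs are enumerated), "triplet" (base-pair-triplet
    uniqueness; with ``gu_only_triplets`` only imino-bearing G/U
    nucleotides are checked) and "es" (register-shifted ES has at most
    one weak pair, the rest strong).
    """
    constraints = set(constraints)
    unknown = constraints - set(ALL_CONSTRAINTS)
    if unknown:
        raise ValueError(f"unknown constraints {sorted(unknown)}")
    out = []
    for combo in itertools.product(STRONG_PAIRS, repeat=spec.stem_len):
        gs = tuple(BasePair.from_str(s) for s in combo)
        sigs = _triplet_signatures(spec, gs)
        if "triplet" in constraints:
            checked = sigs
            if gu_only_triplets:
                doubled = [p for pair in gs for p in (pair, pair)]
                checked = tuple(
                    s
                    for s, p in zip(sigs, doubled)
                    if _stem_base(s[0], p) in ("G", "U")
                )
            if len(set(checked)) != len(checked):
                continue
        es, displaced = register_shift(
            gs, spec.shift, spec.five_prime_context, spec.three_prime_context
        )
        if "es" in constraints:
            klasses = [p.klass for p in es]
            if any(k == "other" for k in klasses):
                continue
            if sum(k == "weak" for k in klasses) > 1:
                continue
        out.append(
            StemCandidate(
                spec=spec,
                gs_pairs=gs,
                es_pairs=es,
                displaced=displaced,
                triplet_signatures=sigs,
            )
        )
    return out


# --------------------------------------------------------------------------
# energy backends and filtering
# --------------------------------------------------------------------------


class EnergyBackend:
    """Deterministic secondary-structure free-energy scorer.

    Implementations provide ``score_structure(pairs, loop_size)`` in
    kcal/mol; lower is more stable.  The bundled backend is additive over
    stacking units; external programs can be adapted behind the same
    surface.
    """

    name = "abstract"

    def score_structure(self, pairs, loop_size: int) -> float:  # pragma: no cover
        raise NotImplementedError


class NearestNeighborBackend(EnergyBackend):
    """Simplified nearest-neighbor backend (approximate parameters).

    E = loop initiation + sum of stacks between consecutive strong pairs
    + a fixed penalty per weak pair (whose flanking stacks are skipped).
    A pair outside the strong/weak sets raises; a missing stack parameter
    raises naming the stack.
    """

    name = "nearest-neighbor (simplified)"

    def score_structure(self, pairs, loop_size: int) -> float:
        pairs = [p if isinstance(p, BasePair) else BasePair.from_str(p) for p in pairs]
        e = hairpin_loop_dg(loop_size)
        klasses = [p.klass for p in pairs]
        for p, k in zip(pairs, klasses):
            if k == "other":
                raise ValueError(f"pair {p.as_str} is neither strong nor weak")
            if k == "weak":
                e += WEAK_PAIR_PENALTY
        for (pu, ku), (pl, kl) in zip(
            zip(pairs, klasses), zip(pairs[1:], klasses[1:])
        ):
            if ku == "strong" and kl == "strong":
                e += stack_dg(pu.as_str, pl.as_str)
        return e


DEFAULT_BACKEND = NearestNeighborBackend()


def _structure_energy(backend, pairs, loop_size):
    try:
        return backend.score_structure(pairs, loop_size)
    except ValueError:
        return float("inf")  # structures with disallowed pairs never compete


def score_candidate(
    cand: StemCandidate,
    backend: EnergyBackend = DEFAULT_BACKEND,
) -> float:
    """ddG = E(designed ES) - E(GS), including the loop-size change from
    displaced nucleotides.  A negative value means the nominal ES is the
    more stable structure (a GS/ES inversion)."""
    gs_loop = len(cand.spec.loop_seq)
    es_loop = gs_loop + sum(1 for _, _, where in cand.displaced if where == "loop")
    e_gs = backend.score_structure(cand.gs_pairs, gs_loop)
    e_es = backend.score_structure(cand.es_pairs, es_loop)
    cand.ddG = float(e_es - e_gs)
    return cand.ddG


def alternative_ddGs(
    cand: StemCandidate,
    backend: EnergyBackend = DEFAULT_BACKEND,
    max_shift: int = 2,
):
    """Bounded alternative-structure scan: every register shift of
    magnitude <= ``max_shift`` other than the designed one, plus the
    terminal- and loop-side pair-melted variants of the GS.  Returns the
    list of ddG values relative to the GS (alternatives containing
    disallowed pairs are skipped)."""
    spec = cand.spec
    gs_loop = len(spec.loop_seq)
    e_gs = backend.score_structure(cand.gs_pairs, gs_loop)
    alts = []
    for s in range(-max_shift, max_shift + 1):
        if s == 0 or s == spec.shift:
            continue
        if abs(s) > spec.stem_len:
            continue
        pairs, displaced = register_shift(
            cand.gs_pairs, s, spec.five_prime_context, spec.three_prime_context
        )
        loop = gs_loop + sum(1 for _, _, w in displaced if w == "loop")
        e = _structure_energy(backend, pairs, loop)
        if np.isfinite(e):
            alts.append(e - e_gs)
    # melt the loop-proximal pair (loop grows by 2)
    if len(cand.gs_pairs) > 1:
        e = _structure_energy(backend, cand.gs_pairs[1:], gs_loop + 2)
        if np.isfinite(e):
            alts.append(e - e_gs)
        # melt the terminal pair (frays into dangling ends)
        e = _structure_energy(backend, cand.gs_pairs[:-1], gs_loop)
        if np.isfinite(e):
            alts.append(e - e_gs)
    return alts


def design_filter(
    cands,
    threshold: float = 3.0,
    backend: EnergyBackend = DEFAULT_BACKEND,
    external_alternatives=None,
    include_scan: bool = True,
):
    """Accept candidates whose designed ES is reachable and best-ranked.

    A candidate passes iff 0 <= ddG(designed ES) <= ``threshold``
    (inclusive) and no scanned alternative structure has a lower ddG;
    inverted candidates (ddG < 0, the intended GS is not the most stable
    structure) are design failures and never accepted.
    ``external_alternatives`` optionally supplies, per candidate, extra
    alternative ddG values computed by an external structure-prediction
    program; they are merged with the bundled scan (or replace it with
    ``include_scan=False``).  Returns accepted candidates sorted by ddG
    ascending, each with ``rank_ok`` set.
    """
    accepted = []
    for i, cand in enumerate(cands):
        if cand.ddG is None:
            score_candidate(cand, backend)
        alts = alternative_ddGs(cand, backend) if include_scan else []
        if external_alternatives is not None:
            alts = list(alts) + list(external_alternatives[i])
        cand.rank_ok = not alts or cand.ddG <= min(alts)
        if 0.0 <= cand.ddG <= threshold and cand.rank_ok:
            accepted.append(cand)
    accepted.sort(key=lambda c: c.ddG)
    return accepted
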