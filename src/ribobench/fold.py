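"""Thermodynamic folding engine.

Predicts secondary-structure ensembles for short RNA windows under a
simplified nearest-neighbour energy model: per-pair energies for the six
canonical/wobble pairs plus optional stacking bonuses for directly adjacent
(coaxial) pairs.  Three quantities are exposed:

* the partition function ``Z = sum over structures of exp(-E/kT)``,
* the base-pairing probability matrix (BPPM) ``p_ij`` via an
  inside--outside dynamic programme in the style of McCaskill,
* a minimum-free-energy (MFE) structure via a Zuker-style recursion.

A brute-force enumerator over all pseudoknot-free structures serves as an
internal oracle for small sequences; the dynamic programmes are validated
against it in the test suite.

Positions are 1-based in every public interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterator, List, Mapping, Optional, Tuple

import numpy as np

__all__ = [
    "RnaSequence",
    "EnergyModel",
    "SecondaryStructure",
    "BPPM",
    "PairingProfile",
    "enumerate_structures",
    "partition_function",
    "pair_probabilities",
    "mfe_structure",
    "pairing_profile",
    "DEFAULT_PAIR_ENERGIES",
    "DEFAULT_KT",
]

# Defaults: AU/UA -2, GC/CG -3, GU/UG -1 kcal/mol; kT at 37 degrees C.
DEFAULT_PAIR_ENERGIES: Dict[str, float] = {
    "AU": -2.0, "UA": -2.0, "GC": -3.0, "CG": -3.0, "GU": -1.0, "UG": -1.0,
}
DEFAULT_KT = 0.6156

_ALPHABET = frozenset("ACGU")

# Probabilities below this are dropped from sparse BPPM storage.
DEFAULT_SPARSITY_EPS = 1e-12


class RnaSequence:
    """An RNA sequence with an identifier.

    Input is normalised: uppercased, T converted to U.  Only A/C/G/U are
    accepted after normalisation.  Positions are 1-based.
    """

    __slots__ = ("id", "bases")

    def __init__(self, id: str, bases: str):
        norm = bases.upper().replace("T", "U")
        if len(norm) < 1:
            raise ValueError(f"sequence {id!r} is empty")
        bad = set(norm) - _ALPHABET
        if bad:
            raise ValueError(
                f"sequence {id!r} contains non-RNA characters: {sorted(bad)}"
            )
        self.id = id
        self.bases = norm

    def __len__(self) -> int:
        return len(self.bases)

    def base(self, i: int) -> str:
        """Base at 1-based position *i*."""
        if not 1 <= i <= len(self.bases):
            raise IndexError(f"position {i} outside 1..{len(self.bases)}")
        return self.bases[i - 1]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, RnaSequence)
            and self.id == other.id
            and self.bases == other.bases
        )

    def __hash__(self) -> int:
        return hash((self.id, self.bases))

    def __repr__(self) -> str:
        return f"RnaSequence({self.id!r}, {self.bases!r})"


def _normalise_stack_key(key) -> Tuple[str, str]:
    # accept ("GC", "AU") tuples or "GC/AU" strings (outer pair / inner pair)
    if isinstance(key, str):
        outer, inner = key.split("/")
    else:
        outer, inner = key
    return outer.upper().replace("T", "U"), inner.upper().replace("T", "U")


@dataclass(frozen=True)
class EnergyModel:
    """Pair + optional stacking energy model.

    ``pair_energies`` maps the six legal pair types to kcal/mol; any pair
    type absent from the map is forbidden.  ``stack_energies`` maps
    (outer pair, inner pair) type combinations -- the pair (i, j) directly
    enclosing (i+1, j-1) -- to a stacking energy added on top of the two
    pair energies.  A hairpin loop must contain at least
    ``min_hairpin_loop`` unpaired bases, i.e. a pair (i, j) requires
    ``j - i - 1 >= min_hairpin_loop``.
    """

    pair_energies: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PAIR_ENERGIES)
    )
    stack_energies: Optional[Mapping] = None
    min_hairpin_loop: int = 3
    temperature_kT: float = DEFAULT_KT

    def __post_init__(self):
        pe = {}
        for k, v in self.pair_energies.items():
            k = k.upper().replace("T", "U")
            if k not in DEFAULT_PAIR_ENERGIES:
                raise ValueError(f"{k!r} is not a canonical or wobble pair")
            pe[k] = float(v)
        object.__setattr__(self, "pair_energies", pe)
        if self.stack_energies is not None:
            se = {}
            for k, v in self.stack_energies.items():
                outer, inner = _normalise_stack_key(k)
                for p in (outer, inner):
                    if p not in DEFAULT_PAIR_ENERGIES:
                        raise ValueError(f"{p!r} is not a legal pair type")
                se[(outer, inner)] = float(v)
            object.__setattr__(self, "stack_energies", se)
        if self.min_hairpin_loop < 0:
            raise ValueError("min_hairpin_loop must be >= 0")
        if self.temperature_kT <= 0:
            raise ValueError("temperature_kT must be positive")

    def pair_energy(self, b1: str, b2: str) -> Optional[float]:
        """Energy of the pair (b1, b2), or None if forbidden."""
        return self.pair_energies.get(b1 + b2)

    def stack_energy(self, outer: str, inner: str) -> float:
        """Stacking energy for pair type *outer* enclosing *inner* (0 if unset)."""
        if self.stack_energies is None:
            return 0.0
        return self.stack_energies.get((outer, inner), 0.0)


class SecondaryStructure:
    """A pseudoknot-free set of base pairs with an energy.

    ``pairs`` are 1-based (i, j) tuples with i < j; each base participates
    in at most one pair and no two pairs cross.
    """

    __slots__ = ("pairs", "energy", "dot_bracket")

    def __init__(self, pairs, length: int, energy: float = 0.0):
        pairs = frozenset((int(i), int(j)) for i, j in pairs)
        partners: Dict[int, int] = {}
        for i, j in pairs:
            if not (1 <= i < j <= length):
                raise ValueError(f"pair ({i},{j}) outside 1..{length} or i >= j")
            for x in (i, j):
                if x in partners:
                    raise ValueError(f"base {x} appears in more than one pair")
            partners[i] = j
            partners[j] = i
        ordered = sorted(pairs)
        for a in range(len(ordered)):
            i, j = ordered[a]
            for k, l in ordered[a + 1:]:
                if k >= j:
                    break
                if i < k < j < l:
                    raise ValueError(
                        f"pseudoknot: pairs ({i},{j}) and ({k},{l}) cross"
                    )
        db = ["."] * length
        for i, j in pairs:
            db[i - 1] = "("
            db[j - 1] = ")"
        self.pairs: FrozenSet[Tuple[int, int]] = pairs
        self.energy = float(energy)
        self.dot_bracket = "".join(db)

    @classmethod
    def from_dot_bracket(cls, db: str, energy: float = 0.0) -> "SecondaryStructure":
        stack: List[int] = []
        pairs = []
        for pos, c in enumerate(db, start=1):
            if c == "(":
                stack.append(pos)
            elif c == ")":
                if not stack:
                    raise ValueError(f"unbalanced ')' at position {pos}")
                pairs.append((stack.pop(), pos))
            elif c != ".":
                raise ValueError(f"invalid dot-bracket character {c!r}")
        if stack:
            raise ValueError(f"unbalanced '(' at position {stack[-1]}")
        return cls(pairs, length=len(db), energy=energy)

    def __len__(self) -> int:
        return len(self.dot_bracket)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SecondaryStructure)
            and self.pairs == other.pairs
            and len(self) == len(other)
        )

    def __hash__(self) -> int:
        return hash((self.pairs, len(self.dot_bracket)))

    def __repr__(self) -> str:
        return f"SecondaryStructure({self.dot_bracket!r}, energy={self.energy:g})"


class BPPM:
    """Sparse base-pairing probability matrix.

    ``probs`` maps 1-based (i, j), i < j, to the ensemble probability that
    bases i and j pair.  Entries below ``eps`` are dropped.
    """

    __slots__ = ("length", "probs")

    def __init__(self, length: int, probs: Mapping[Tuple[int, int], float],
                 eps: float = DEFAULT_SPARSITY_EPS):
        self.length = int(length)
        clean: Dict[Tuple[int, int], float] = {}
        for (i, j), p in probs.items():
            if not (1 <= i < j <= self.length):
                raise ValueError(f"BPPM entry ({i},{j}) outside 1..{self.length}")
            if p < -1e-9 or p > 1 + 1e-9:
                raise ValueError(f"probability {p} for ({i},{j}) outside [0,1]")
            p = min(max(float(p), 0.0), 1.0)
            if p >= eps:
                clean[(int(i), int(j))] = p
        self.probs = clean

    def to_matrix(self) -> np.ndarray:
        """Dense symmetric (length x length) matrix, 0-based indexing."""
        m = np.zeros((self.length, self.length))
        for (i, j), p in self.probs.items():
            m[i - 1, j - 1] = p
            m[j - 1, i - 1] = p
        return m

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BPPM)
            and self.length == other.length
            and self.probs == other.probs
        )


class PairingProfile:
    """Per-base (upstream-paired, downstream-paired, unpaired) probabilities.

    ``up[i]`` is the probability that base i pairs with a partner j > i
    (an opening bracket), ``down[i]`` with a partner j < i (a closing
    bracket), and ``unpaired[i] = 1 - up[i] - down[i]``.  Arrays are
    0-based internally; entry k corresponds to base k+1.
    """

    __slots__ = ("length", "up", "down", "unpaired")

    def __init__(self, up, down, unpaired=None):
        up = np.asarray(up, dtype=float)
        down = np.asarray(down, dtype=float)
        if unpaired is None:
            unpaired = 1.0 - up - down
        unpaired = np.asarray(unpaired, dtype=float)
        if not (up.shape == down.shape == unpaired.shape):
            raise ValueError("profile vectors must have equal length")
        for name, v in (("up", up), ("down", down), ("unpaired", unpaired)):
            if np.any(v < -1e-9) or np.any(v > 1 + 1e-9):
                raise ValueError(f"{name} entries outside [0,1]")
        total = up + down + unpaired
        if np.any(np.abs(total - 1.0) > 1e-9):
            raise ValueError("up + down + unpaired must sum to 1 per base")
        self.length = len(up)
        self.up = np.clip(up, 0.0, 1.0)
        self.down = np.clip(down, 0.0, 1.0)
        self.unpaired = np.clip(unpaired, 0.0, 1.0)

    def total_pairing(self) -> np.ndarray:
        """Per-base probability of being paired at all (1 - unpaired)."""
        return 1.0 - self.unpaired


# ---------------------------------------------------------------------------
# Brute-force enumeration oracle
# ---------------------------------------------------------------------------

def structure_energy(pairs, seq: RnaSequence, model: EnergyModel) -> float:
    """Energy of an explicit pair set: pair terms plus stacking bonuses."""
    e = 0.0
    pset = set(map(tuple, pairs))
    for i, j in pset:
        pe = model.pair_energy(seq.base(i), seq.base(j))
        if pe is None:
            raise ValueError(f"illegal pair ({i},{j}) for {seq.bases!r}")
        e += pe
        if (i + 1, j - 1) in pset:
            e += model.stack_energy(
                seq.base(i) + seq.base(j), seq.base(i + 1) + seq.base(j - 1)
            )
    return e


def enumerate_structures(
    seq: RnaSequence, model: EnergyModel, max_len: int = 20
) -> List[SecondaryStructure]:
    """Every pseudoknot-free structure legal under the model, with energies.

    Intended as a testing oracle; refuses sequences longer than *max_len*
    to guard against combinatorial explosion.
    """
    n = len(seq)
    if n > max_len:
        raise ValueError(
            f"enumerate_structures refuses length {n} > max_len {max_len}"
        )
    mh = model.min_hairpin_loop
    legal = {}
    for i in range(1, n + 1):
        for j in range(i + mh + 1, n + 1):
            if model.pair_energy(seq.base(i), seq.base(j)) is not None:
                legal[(i, j)] = True

    def enum(lo: int, hi: int) -> List[FrozenSet[Tuple[int, int]]]:
        if lo >= hi:
            return [frozenset()]
        out = list(enum(lo + 1, hi))  # lo unpaired
        for k in range(lo + mh + 1, hi + 1):
            if (lo, k) in legal:
                inner = enum(lo + 1, k - 1)
                outer = enum(k + 1, hi)
                for a in inner:
                    for b in outer:
                        out.append(a | b | {(lo, k)})
        return out

    return [
        SecondaryStructure(p, length=n, energy=structure_energy(p, seq, model))
        for p in enum(1, n)
    ]


# ---------------------------------------------------------------------------
# Dynamic programmes
# ---------------------------------------------------------------------------

def _model_arrays(seq: RnaSequence, model: EnergyModel):
    """Boltzmann pair weights B, stack factors S, and pair energies E.

    All arrays are (n+2) x (n+2), 1-based; index 0 and n+1 are padding.
    ``B[i, j] = exp(-e_pair(i,j)/kT)`` for legal pairs else 0.
    ``S[i, j] = exp(-e_stack((i,j) over (i+1,j-1))/kT)`` where both pairs
    are legal, else 1 (no correction).
    """
    n = len(seq)
    kt = model.temperature_kT
    mh = model.min_hairpin_loop
    B = np.zeros((n + 2, n + 2))
    E = np.full((n + 2, n + 2), np.inf)
    S = np.ones((n + 2, n + 2))
    for i in range(1, n + 1):
        for j in range(i + mh + 1, n + 1):
            pe = model.pair_energy(seq.base(i), seq.base(j))
            if pe is None:
                continue
            B[i, j] = math.exp(-pe / kt)
            E[i, j] = pe
    if model.stack_energies:
        for i in range(1, n + 1):
            for j in range(i + mh + 3, n + 1):
                if B[i, j] > 0 and B[i + 1, j - 1] > 0:
                    st = model.stack_energy(
                        seq.base(i) + seq.base(j),
                        seq.base(i + 1) + seq.base(j - 1),
                    )
                    S[i, j] = math.exp(-st / kt)
    return B, S, E


def _inside(seq: RnaSequence, model: EnergyModel):
    """Inside partition arrays Q (segment sums) and Qb (closed by a pair).

    Q[i, j] sums Boltzmann weights over all structures of segment [i, j];
    Q[i, j] = 1 whenever j < i (empty segment).  Qb[i, j] restricts to
    structures where (i, j) itself pairs, including the stacking bonus to
    an adjacent inner pair.
    """
    n = len(seq)
    B, S, _ = _model_arrays(seq, model)
    mh = model.min_hairpin_loop
    Q = np.ones((n + 2, n + 2))
    Qb = np.zeros((n + 2, n + 2))
    for d in range(mh + 1, n):
        for i in range(1, n - d + 1):
            j = i + d
            if B[i, j] > 0:
                inner = Q[i + 1, j - 1] + (S[i, j] - 1.0) * Qb[i + 1, j - 1]
                Qb[i, j] = B[i, j] * inner
            k0 = i + mh + 1
            acc = Q[i + 1, j]
            if k0 <= j:
                # sum_k Qb[i,k] * Q[k+1,j]
                acc += float(np.dot(Qb[i, k0:j + 1], Q[k0 + 1:j + 2, j]))
            Q[i, j] = acc
    return Q, Qb, B, S


def partition_function(seq: RnaSequence, model: EnergyModel) -> float:
    """Partition function Z = sum over legal structures of exp(-E/kT)."""
    n = len(seq)
    if n <= model.min_hairpin_loop:
        return 1.0
    Q, _, _, _ = _inside(seq, model)
    return float(Q[1, n])


def pair_probabilities(
    seq: RnaSequence, model: EnergyModel, eps: float = DEFAULT_SPARSITY_EPS
) -> BPPM:
    """Base-pairing probability matrix via inside--outside recursion.

    ``p_ij`` is the Boltzmann mass of structures containing the pair (i, j)
    divided by the partition function.  The outside pass decomposes over
    the innermost enclosing pair, with an explicit correction for a
    stacking bonus donated by a directly adjacent enclosing pair.
    """
    n = len(seq)
    if n <= model.min_hairpin_loop:
        return BPPM(n, {}, eps=eps)
    Q, Qb, B, S = _inside(seq, model)
    Z = Q[1, n]
    mh = model.min_hairpin_loop

    Qhat = np.zeros((n + 2, n + 2))   # exterior weight for each legal pair
    # A[h, jp] = sum_{l > jp} Qhat[h, l] * B[h, l] * Q[jp+1, l-1]
    A = np.zeros((n + 2, n + 2))

    probs: Dict[Tuple[int, int], float] = {}
    for d in range(n - 1, mh, -1):
        level: List[Tuple[int, int]] = []
        for i in range(1, n - d + 1):
            j = i + d
            if B[i, j] == 0:
                continue
            val = Q[1, i - 1] * Q[j + 1, n]
            if i > 1:
                # innermost enclosing pair (h, l), h < i, l > j
                val += float(np.dot(A[1:i, j], Q[2:i + 1, i - 1]))
            if i > 1 and j < n and B[i - 1, j + 1] > 0:
                # stacking correction when the enclosing pair is adjacent
                val += Qhat[i - 1, j + 1] * B[i - 1, j + 1] * (S[i - 1, j + 1] - 1.0)
            Qhat[i, j] = val
            level.append((i, j))
        for i, j in level:
            w = Qhat[i, j] * B[i, j]
            if w != 0.0 and j - i >= 2:
                # contributions of (i, j) as enclosing pair to A[i, jp], jp<j
                A[i, i + 1:j] += w * Q[i + 2:j + 1, j - 1]
        for i, j in level:
            p = Qb[i, j] * Qhat[i, j] / Z
            if p >= eps:
                probs[(i, j)] = min(p, 1.0)
    return BPPM(n, probs, eps=eps)


def pairing_profile(bppm: BPPM) -> PairingProfile:
    """Collapse a BPPM to per-base (up, down, unpaired) probabilities."""
    n = bppm.length
    up = np.zeros(n)
    down = np.zeros(n)
    for (i, j), p in bppm.probs.items():
        up[i - 1] += p
        down[j - 1] += p
    return PairingProfile(up, down)


_TIE_TOL = 1e-9


def mfe_structure(seq: RnaSequence, model: EnergyModel) -> SecondaryStructure:
    """A minimum-free-energy structure under the model.

    Zuker-style O(n^3) recursion over the pair + stacking terms.  Among
    co-minimal structures the traceback prefers pairing over leaving a
    base unpaired and, at a paired base i, the smallest partner j; ties
    are therefore resolved deterministically toward pairs at the smallest
    (i, then j).
    """
    n = len(seq)
    mh = model.min_hairpin_loop
    if n <= mh:
        return SecondaryStructure([], length=n, energy=0.0)
    B, S, E = _model_arrays(seq, model)
    kt = model.temperature_kT
    # stacking energies back on the kcal/mol scale
    ST = -kt * np.log(S)

    F = np.zeros((n + 2, n + 2))   # min energy over segment [i, j]
    G = np.zeros((n + 2, n + 2))   # same, excluding structures pairing (i, j)
    Eb = np.full((n + 2, n + 2), np.inf)  # min energy with (i, j) paired

    for d in range(mh + 1, n):
        for i in range(1, n - d + 1):
            j = i + d
            if np.isfinite(E[i, j]):
                inner = G[i + 1, j - 1]
                if np.isfinite(Eb[i + 1, j - 1]):
                    inner = min(inner, ST[i, j] + Eb[i + 1, j - 1])
                Eb[i, j] = E[i, j] + inner
            best_g = F[i + 1, j]
            best_f = best_g
            k0 = i + mh + 1
            if k0 <= j:
                with np.errstate(invalid="ignore"):
                    cand = Eb[i, k0:j + 1] + F[k0 + 1:j + 2, j]
                if cand.size > 1:
                    best_g = min(best_g, float(np.min(cand[:-1])))
                best_f = min(best_f, float(np.min(cand)))
            G[i, j] = best_g
            F[i, j] = best_f

    pairs: List[Tuple[int, int]] = []

    def trace_pair(i: int, j: int) -> None:
        pairs.append((i, j))
        if j - 1 < i + 1:
            return
        inner_target = Eb[i, j] - E[i, j]
        if (
            np.isfinite(Eb[i + 1, j - 1])
            and ST[i, j] + Eb[i + 1, j - 1] <= inner_target + _TIE_TOL
        ):
            trace_pair(i + 1, j - 1)
        else:
            trace_segment(i + 1, j - 1, full_pair_allowed=False)

    def trace_segment(i: int, j: int, full_pair_allowed: bool = True) -> None:
        while i < j:
            target = F[i, j] if full_pair_allowed else G[i, j]
            kmax = j if full_pair_allowed else j - 1
            paired = False
            for k in range(i + mh + 1, kmax + 1):
                if np.isfinite(Eb[i, k]) and Eb[i, k] + F[k + 1, j] <= target + _TIE_TOL:
                    trace_pair(i, k)
                    i = k + 1
                    full_pair_allowed = True
                    paired = True
                    break
            if not paired:
                i += 1
                full_pair_allowed = True

    trace_segment(1, n)
    return SecondaryStructure(pairs, length=n, energy=float(F[1, n]))
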