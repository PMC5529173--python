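"""Partition functions and Boltzmann stochastic sampling of RNA ensembles.

Two engines share one interface:

* :class:`ReferenceEngine` — a self-contained McCaskill-style dynamic
  program over a simple stacking/pair energy model (Watson-Crick + GU
  wobble pairs, minimum hairpin loop of 3, 37 degC).  It computes exact
  equilibrium base-pairing probabilities by an inside/outside pass and
  draws structures by exact stochastic traceback.  It is meant for short
  RNAs where its behaviour can be verified against exhaustive enumeration.
* ``ViennaEngine`` (:mod:`ensemblemap.vienna`) — an adapter over the
  ViennaRNA nearest-neighbor implementation, for realistic sequences.

SHAPE reactivities enter as the standard log-linear pseudo-energy
``dG(r) = m*ln(r+1) + b`` added per paired nucleotide; high reactivity
(flexible backbone) penalizes pairing.

Energies are in kcal/mol throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .sequences import SequenceRecord
from .structures import (
    BasePairProbabilityMatrix,
    SecondaryStructure,
    ShapeProfile,
)

#: Gas constant times temperature at 310.15 K (37 degC), kcal/mol.
RT = 0.616

#: Canonical pairs: Watson-Crick plus GU wobble.
ALLOWED_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)


class EngineError(RuntimeError):
    """A folding engine failed; carries the engine diagnostic."""


@dataclass(frozen=True)
class EnergyModel:
    """Parameters of the reference stacking/pair energy model.

    A structure's energy is the sum of one term per base pair (graded by
    pair identity: GC strongest, GU weakest) plus a bonus for every pair of
    contiguously stacked base pairs, plus SHAPE pseudo-energies for paired
    nucleotides.  Magnitudes are deliberately modest so that short toy
    sequences populate genuinely mixed ensembles at 37 degC.
    """

    pair_energies: Tuple[Tuple[str, float], ...] = (
        ("GC", -2.0), ("CG", -2.0),
        ("AU", -1.1), ("UA", -1.1),
        ("GU", -0.7), ("UG", -0.7),
    )
    stack_energy: float = -0.9
    #: entropic initiation cost charged once per hairpin loop; internal and
    #: multibranch loops are left free in this simplified model
    hairpin_penalty: float = 3.0
    min_hairpin: int = 3
    #: minimum pairs per helix; 2 forbids isolated (lonely) base pairs,
    #: which are thermodynamic artifacts and break the stem abstraction
    min_helix_length: int = 2
    shape_slope: float = 1.8    # m, kcal/mol
    shape_intercept: float = -0.6  # b, kcal/mol

    def pair_energy(self, a: str, b: str) -> float:
        return dict(self.pair_energies)[a + b]

    def can_pair(self, a: str, b: str) -> bool:
        return (a, b) in ALLOWED_PAIRS


DEFAULT_MODEL = EnergyModel()


def shape_pseudo_energy(reactivity: float, m: float = 1.8, b: float = -0.6) -> float:
    """Log-linear SHAPE pseudo-energy ``m*ln(r+1) + b`` in kcal/mol.

    Defined for reactivities > -1; callers must exclude the -999
    missing-data sentinel before calling (missing positions contribute no
    pseudo-energy).
    """
    if reactivity <= -1.0:
        raise ValueError(
            f"SHAPE reactivity {reactivity} <= -1 has no defined pseudo-energy"
        )
    return m * math.log(reactivity + 1.0) + b


def _per_nucleotide_pseudo_energies(n: int, shape: Optional[ShapeProfile],
                                    model: EnergyModel) -> np.ndarray:
    g = np.zeros(n)
    if shape is None:
        return g
    if len(shape) != n:
        raise ValueError(
            f"SHAPE profile length {len(shape)} does not match sequence length {n}"
        )
    missing = shape.missing_mask()
    for i in range(n):
        if not missing[i]:
            g[i] = shape_pseudo_energy(
                float(shape.reactivity[i]), model.shape_slope, model.shape_intercept
            )
    return g


# --------------------------------------------------------------------------
# Reference engine: inside/outside partition function + stochastic traceback
# --------------------------------------------------------------------------

class _InsideTables:
    """Inside partition-function tables for one sequence (0-based).

    The recursion is written over whole helices so a minimum helix length
    (no lonely pairs) is exact.  ``Zh[i, j]`` sums Boltzmann weights of
    structures on [i..j] in which (i, j) is the *outermost pair of a
    helix*; the helix runs inward over L >= min_helix_length contiguous
    pairs (each contributing its pair weight, with L-1 stacking bonuses)
    and its interior must not extend the helix:

        Zh(i,j) = sum_L W(i,j,L) * s^(L-1)
                  * [h + (Z(i+L,j-L) - Zh(i+L,j-L) - 1)]
        Z(i,j)  = Z(i+1,j) + sum_k Zh(i,k) * Z(k+1,j)

    where W(i,j,L) is the product of the L pair weights (pair energy plus
    SHAPE pseudo-energies), ``s`` the stacking-bonus weight, and ``h`` the
    hairpin-loop initiation weight: a pair-free interior (Boltzmann weight
    1) closes a hairpin loop and is charged the initiation penalty, while
    interiors holding further helices are not.
    """

    def __init__(self, seq: str, shape: Optional[ShapeProfile],
                 model: EnergyModel) -> None:
        n = len(seq)
        self.n = n
        self.model = model
        self.s = math.exp(-model.stack_energy / RT)
        self.h = math.exp(-model.hairpin_penalty / RT)
        g = _per_nucleotide_pseudo_energies(n, shape, model)
        w = np.zeros((n, n))
        for i in range(n):
            for j in range(i + model.min_hairpin + 1, n):
                if model.can_pair(seq[i], seq[j]):
                    e = model.pair_energy(seq[i], seq[j]) + g[i] + g[j]
                    w[i, j] = math.exp(-e / RT)
        self.w = w
        Lmin = model.min_helix_length
        Z = np.ones((n, n))
        Zh = np.zeros((n, n))
        for span in range(1, n):
            for i in range(0, n - span):
                j = i + span
                if w[i, j] > 0:
                    acc = 0.0
                    for L, wgt in self._helix_weights(i, j):
                        inner = self.__z(Z, i + L, j - L)
                        innerh = Zh[i + L, j - L] if i + L < j - L else 0.0
                        acc += wgt * (self.h + inner - innerh - 1.0)
                    Zh[i, j] = acc
                total = self.__z(Z, i + 1, j)
                for k in range(i + model.min_hairpin + 1, j + 1):
                    if Zh[i, k] > 0:
                        total += Zh[i, k] * self.__z(Z, k + 1, j)
                Z[i, j] = total
        if not np.all(np.isfinite(Z)):
            raise EngineError(
                "partition function overflow; the reference engine is "
                "intended for short RNAs"
            )
        self.Z, self.Zh = Z, Zh
        self.total = Z[0, n - 1] if n else 1.0

    def _helix_weights(self, i: int, j: int):
        """Yield (L, W(i,j,L)*s^(L-1)) for every legal helix at (i, j)."""
        wgt = 1.0
        L = 0
        while True:
            a, b = i + L, j - L
            if b - a <= self.model.min_hairpin or self.w[a, b] == 0.0:
                break
            wgt *= self.w[a, b] * (self.s if L > 0 else 1.0)
            L += 1
            if L >= self.model.min_helix_length:
                yield L, wgt

    def __z(self, Z: np.ndarray, i: int, j: int) -> float:
        return 1.0 if i > j else Z[i, j]

    def z(self, i: int, j: int) -> float:
        """Z on [i..j]; 1 for an empty interval."""
        return 1.0 if i > j else self.Z[i, j]

    def pair_probabilities(self) -> np.ndarray:
        """Exact P(i pairs j) by an outside pass over direct parent helices.

        Every structure in which (i, j) starts a helix is attributed to the
        innermost pair enclosing that helix (the closing pair of its parent
        helix) or to the exterior.  Flanking segments between parent and
        child cannot pair across the child, so their weights factorize.
        ``U(i,j)`` accumulates the exterior weight of all such contexts;
        ``K(a,b)`` is the enclosure coefficient of a parent helix whose
        innermost pair is (a, b).
        """
        n = self.n
        P = np.zeros((n, n))
        U = np.zeros((n, n))
        K = np.zeros((n, n))
        pairs = [(i, j) for i in range(n) for j in range(n) if self.Zh[i, j] > 0]
        pairs.sort(key=lambda ij: ij[1] - ij[0], reverse=True)
        for i, j in pairs:
            val = self.z(0, i - 1) * self.z(j + 1, n - 1) / self.total
            if i >= 1 and j <= n - 2:
                zl = np.array([self.z(p + 1, i - 1) for p in range(i)])
                zr = np.array([self.z(j + 1, q - 1) for q in range(j + 1, n)])
                val += zl @ K[:i, j + 1:] @ zr
                # an (i-1, j+1) parent closing pair would extend this helix;
                # the inside recursion excludes that configuration
                val -= K[i - 1, j + 1]
            U[i, j] = val
            for L, wgt in self._helix_weights(i, j):
                a, b = i + L - 1, j - L + 1
                K[a, b] += val * wgt
                inner = self.z(i + L, j - L)
                innerh = self.Zh[i + L, j - L] if i + L < j - L else 0.0
                prob = val * wgt * (self.h + inner - innerh - 1.0)
                for t in range(L):
                    P[i + t, j - t] += prob
        return P + P.T

    def sample_one(self, rng: np.random.Generator) -> Tuple[int, ...]:
        """Exact stochastic traceback of one structure (1-based pair table)."""
        n = self.n
        pt = [0] * n
        # pending intervals: (i, j, exclude_end, nonempty).  exclude_end
        # forbids the single outcome "i starts a helix whose outer pair is
        # (i, j)" (the helix below would extend); nonempty requires at
        # least one pair in the interval (the hairpin outcome was already
        # weighed separately).
        tasks: List[Tuple[int, int, bool, bool]] = [(0, n - 1, False, False)]
        while tasks:
            i, j, exclude_end, nonempty = tasks.pop()
            while i <= j:
                if j - i < self.model.min_hairpin + 1:
                    break  # too short to hold a pair: all unpaired
                unpaired_wt = self.z(i + 1, j) - (1.0 if nonempty else 0.0)
                options: List[Tuple[float, int]] = [(unpaired_wt, -1)]
                for k in range(i + self.model.min_hairpin + 1, j + 1):
                    if exclude_end and k == j:
                        continue
                    if self.Zh[i, k] > 0:
                        options.append((self.Zh[i, k] * self.z(k + 1, j), k))
                u = rng.random() * sum(wt for wt, _ in options)
                acc, choice = 0.0, -1
                for wt, k in options:
                    acc += wt
                    if u < acc:
                        choice = k
                        break
                if choice == -1:
                    i += 1
                    exclude_end = False  # constraints bound to the old (i, j)
                    continue
                k = choice
                helix_opts = []
                for L, wgt in self._helix_weights(i, k):
                    inner = self.z(i + L, k - L)
                    innerh = self.Zh[i + L, k - L] if i + L < k - L else 0.0
                    helix_opts.append(
                        (wgt * (self.h + inner - innerh - 1.0), L, innerh, inner)
                    )
                u = rng.random() * sum(o[0] for o in helix_opts)
                acc = 0.0
                length, innerh, inner = helix_opts[-1][1:]
                for wt, L, ih, iz in helix_opts:
                    acc += wt
                    if u < acc:
                        length, innerh, inner = L, ih, iz
                        break
                for t in range(length):
                    pt[i + t], pt[k - t] = k - t + 1, i + t + 1
                # interior: hairpin loop (weight h) vs at least one further
                # helix, not extending this one (weight inner - innerh - 1)
                if rng.random() * (self.h + inner - innerh - 1.0) >= self.h:
                    tasks.append((i + length, k - length, True, True))
                i = k + 1
                exclude_end = False
                nonempty = False
        return tuple(pt)


class ReferenceEngine:
    """Self-contained folding engine over the reference energy model."""

    name = "reference"

    def __init__(self, model: EnergyModel = DEFAULT_MODEL) -> None:
        self.model = model
        self._cache: Dict[Tuple, _InsideTables] = {}

    def _tables(self, seq: SequenceRecord,
                shape: Optional[ShapeProfile]) -> _InsideTables:
        key = (seq.sequence, None if shape is None else tuple(shape.reactivity))
        if key not in self._cache:
            self._cache[key] = _InsideTables(seq.sequence, shape, self.model)
        return self._cache[key]

    def compute_partition(self, seq: SequenceRecord,
                          shape: Optional[ShapeProfile] = None
                          ) -> BasePairProbabilityMatrix:
        tables = self._tables(seq, shape)
        P = tables.pair_probabilities()
        P[np.abs(P) < 1e-300] = 0.0
        return BasePairProbabilityMatrix(sequence_id=seq.id, P=np.clip(P, 0.0, 1.0))

    def sample_boltzmann(self, seq: SequenceRecord, n: int,
                         shape: Optional[ShapeProfile] = None,
                         seed: int = 0) -> List[SecondaryStructure]:
        if n < 0:
            raise ValueError("sample count must be >= 0")
        tables = self._tables(seq, shape)
        rng = np.random.default_rng(seed)
        return [
            SecondaryStructure(sequence_id=seq.id, pair_table=tables.sample_one(rng))
            for _ in range(n)
        ]


# --------------------------------------------------------------------------
# Exhaustive enumeration oracle for short sequences
# --------------------------------------------------------------------------

ENUMERATION_GUARD = 25


def structure_energy(seq: str, structure: SecondaryStructure,
                     shape: Optional[ShapeProfile] = None,
                     model: EnergyModel = DEFAULT_MODEL) -> float:
    """Reference-model energy of one structure: pair terms, stacking
    bonuses, one hairpin-loop initiation penalty per leaf helix, and SHAPE
    pseudo-energies for paired nucleotides."""
    from .nestedness import decompose_helices

    g = _per_nucleotide_pseudo_energies(len(seq), shape, model)
    e = 0.0
    pt = structure.pair_table
    for i, j in structure.pairs():
        e += model.pair_energy(seq[i - 1], seq[j - 1]) + g[i - 1] + g[j - 1]
        if i + 1 < j - 1 and pt[i] == j - 1 and j - 1 > i + 1:
            e += model.stack_energy  # (i+1, j-1) continues the helix
    if pt and any(pt):
        helices = decompose_helices(structure, min_helix=1)
        e += model.hairpin_penalty * sum(
            1 for h in helices if not h.children
        )
    return e


def enumerate_all_structures(seq: SequenceRecord,
                             min_hairpin: int = 3,
                             shape: Optional[ShapeProfile] = None,
                             model: Optional[EnergyModel] = None
                             ) -> List[Tuple[SecondaryStructure, float]]:
    """Every nested structure over legal pairs, with reference-model energy.

    Exhaustive enumeration is exponential; refuses sequences longer than
    25 nt.  Serves as the independent oracle for partition-function and
    sampling correctness on short fixtures.  All nested structures over
    legal pairs are generated, then those violating the model's minimum
    helix length (by default: containing a lonely pair) are dropped.
    """
    if model is None:
        model = EnergyModel(
            pair_energies=DEFAULT_MODEL.pair_energies,
            stack_energy=DEFAULT_MODEL.stack_energy,
            min_hairpin=min_hairpin,
        )
    s = seq.sequence
    n = len(s)
    if n > ENUMERATION_GUARD:
        raise ValueError(
            f"refusing exhaustive enumeration for N={n} > {ENUMERATION_GUARD}"
        )

    memo: Dict[Tuple[int, int], List[Tuple[Tuple[int, int], ...]]] = {}

    def enum(i: int, j: int) -> List[Tuple[Tuple[int, int], ...]]:
        if j - i < min_hairpin + 1:
            return [()]
        if (i, j) in memo:
            return memo[(i, j)]
        out = list(enum(i + 1, j))
        for k in range(i + min_hairpin + 1, j + 1):
            if model.can_pair(s[i], s[k]):
                for inner in enum(i + 1, k - 1):
                    for rest in enum(k + 1, j):
                        out.append(((i, k),) + inner + rest)
        memo[(i, j)] = out
        return out

    from .nestedness import decompose_helices

    results = []
    for pairset in enum(0, n - 1):
        pt = [0] * n
        for i, k in pairset:
            pt[i], pt[k] = k + 1, i + 1
        st = SecondaryStructure(sequence_id=seq.id, pair_table=tuple(pt))
        if model.min_helix_length > 1 and pairset:
            shortest = min(
                h.length for h in decompose_helices(st, min_helix=1)
            )
            if shortest < model.min_helix_length:
                continue
        results.append((st, structure_energy(s, st, shape, model)))
    return results


def exact_boltzmann_probabilities(
    seq: SequenceRecord, min_hairpin: int = 3,
    shape: Optional[ShapeProfile] = None,
    model: Optional[EnergyModel] = None,
) -> Dict[Tuple[int, ...], float]:
    """Exact Boltzmann probability of every structure, by enumeration."""
    structs = enumerate_all_structures(seq, min_hairpin, shape, model)
    energies = np.array([e for _, e in structs])
    wts = np.exp(-(energies - energies.min()) / RT)
    probs = wts / wts.sum()
    return {st.pair_table: float(p) for (st, _), p in zip(structs, probs)}


# --------------------------------------------------------------------------
# Engine selection
# --------------------------------------------------------------------------

def get_engine(name: str, **kwargs):
    """Return a folding engine by name: 'reference' or 'vienna'/'external'."""
    if name == "reference":
        return ReferenceEngine(**kwargs)
    if name in ("vienna", "external"):
        from .vienna import ViennaEngine
        return ViennaEngine(**kwargs)
    raise ValueError(f"unknown engine {name!r}; choose 'reference' or 'vienna'")
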