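"""Secondary structures, SHAPE reactivity profiles, and pairing matrices.

All user-facing indices are 1-based (CT / SHAPE convention).  Structures are
strictly nested (pseudoknot-free): the nestedness abstraction downstream
presumes a tree of helices.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Tuple, Union

import numpy as np

#: Missing-data sentinel in SHAPE reactivity files.
SHAPE_MISSING = -999.0


class StructureError(ValueError):
    """Raised for invalid pair tables, dot-brackets, or pseudoknots."""


@dataclass(frozen=True)
class SecondaryStructure:
    """One nested secondary structure as a 1-based pair table.

    ``pair_table[i-1]`` is the partner of nucleotide ``i``, or 0 if unpaired.
    Construction validates the involution (partner-of-partner) property and
    rejects crossing (pseudoknotted) pairs.
    """

    sequence_id: str
    pair_table: Tuple[int, ...]

    def __post_init__(self) -> None:
        pt = tuple(int(x) for x in self.pair_table)
        object.__setattr__(self, "pair_table", pt)
        n = len(pt)
        for i1, j1 in enumerate(pt, start=1):
            if j1 < 0 or j1 > n:
                raise StructureError(f"partner index {j1} out of range 1..{n}")
            if j1 == i1:
                raise StructureError(f"nucleotide {i1} paired with itself")
            if j1 and pt[j1 - 1] != i1:
                raise StructureError(
                    f"pair table is not an involution at ({i1},{j1})"
                )
        pairs = self.pairs()
        for a, (i, j) in enumerate(pairs):
            for k, l in pairs[a + 1:]:
                if i < k < j < l:
                    raise StructureError(
                        f"crossing pairs ({i},{j}) and ({k},{l}): pseudoknots "
                        "are not supported"
                    )

    def __len__(self) -> int:
        return len(self.pair_table)

    def pairs(self) -> List[Tuple[int, int]]:
        """Sorted list of pairs (i, j) with i < j, 1-based."""
        return [
            (i, j) for i, j in enumerate(self.pair_table, start=1) if j > i
        ]

    def paired_mask(self) -> np.ndarray:
        """Binary per-nucleotide paired(1)/unpaired(0) vector."""
        return np.fromiter(
            (1 if p else 0 for p in self.pair_table), dtype=np.int8,
            count=len(self.pair_table),
        )

    def to_dotbracket(self) -> str:
        out = []
        for i, j in enumerate(self.pair_table, start=1):
            out.append("." if j == 0 else ("(" if j > i else ")"))
        return "".join(out)

    @classmethod
    def from_dotbracket(cls, db: str, sequence_id: str = "") -> "SecondaryStructure":
        pt = [0] * len(db)
        stack: List[int] = []
        for i, c in enumerate(db, start=1):
            if c == "(":
                stack.append(i)
            elif c == ")":
                if not stack:
                    raise StructureError(f"unbalanced ')' at position {i}")
                j = stack.pop()
                pt[j - 1], pt[i - 1] = i, j
            elif c not in ".":
                raise StructureError(
                    f"unsupported dot-bracket character {c!r} at position {i}"
                )
        if stack:
            raise StructureError(f"unbalanced '(' at position {stack[-1]}")
        return cls(sequence_id=sequence_id, pair_table=tuple(pt))


def jaccard_similarity(a: SecondaryStructure, b: SecondaryStructure) -> float:
    """Jaccard similarity of the binary paired/unpaired representations.

    Two all-unpaired structures are identical and score 1.
    """
    ma, mb = a.paired_mask().astype(bool), b.paired_mask().astype(bool)
    union = np.logical_or(ma, mb).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(ma, mb).sum() / union)


# --- CT format ---------------------------------------------------------------

def write_ct(structure: SecondaryStructure, sequence: str,
             path: Union[str, Path], energy: float = 0.0) -> None:
    """Write a single-structure CT (connectivity table) file."""
    n = len(structure)
    lines = [f"{n}\tdG = {energy:.2f}\t{structure.sequence_id}"]
    for i in range(1, n + 1):
        lines.append(
            f"{i}\t{sequence[i - 1]}\t{i - 1}\t{(i + 1) % (n + 1)}\t"
            f"{structure.pair_table[i - 1]}\t{i}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_ct(path: Union[str, Path]) -> Tuple[SecondaryStructure, str]:
    """Read the first structure from a CT file -> (structure, sequence)."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    header = lines[0].split()
    try:
        n = int(header[0])
    except (IndexError, ValueError) as exc:
        raise StructureError(f"{path}: malformed CT header {lines[0]!r}") from exc
    seq_id = header[-1] if len(header) > 1 else ""
    pt, seq = [0] * n, []
    for ln in lines[1:n + 1]:
        cols = ln.split()
        i, base, partner = int(cols[0]), cols[1], int(cols[4])
        seq.append(base)
        pt[i - 1] = partner
    return SecondaryStructure(sequence_id=seq_id, pair_table=tuple(pt)), "".join(seq)


# --- SHAPE profiles ----------------------------------------------------------

@dataclass(frozen=True)
class ShapeProfile:
    """Per-nucleotide SHAPE reactivities; ``SHAPE_MISSING`` marks no-data.

    Missing entries are excluded from all arithmetic (pseudo-energies,
    correlations, median tracks).
    """

    sequence_id: str
    reactivity: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.reactivity, dtype=float)
        object.__setattr__(self, "reactivity", arr)

    def __len__(self) -> int:
        return len(self.reactivity)

    def missing_mask(self) -> np.ndarray:
        """True where the reactivity is the missing-data sentinel."""
        return np.isclose(self.reactivity, SHAPE_MISSING)

    def values_masked(self) -> np.ma.MaskedArray:
        return np.ma.masked_array(self.reactivity, mask=self.missing_mask())


def read_shape(path: Union[str, Path], sequence_id: str = "") -> ShapeProfile:
    """Read a two-column whitespace-separated 'position reactivity' file.

    Positions are 1-based; unlisted positions become missing.
    """
    entries = {}
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        if not ln.strip() or ln.lstrip().startswith("#"):
            continue
        cols = ln.split()
        try:
            pos, val = int(cols[0]), float(cols[1])
        except (IndexError, ValueError) as exc:
            raise StructureError(
                f"{path}: line {lineno}: expected 'position reactivity'"
            ) from exc
        entries[pos] = val
    n = max(entries) if entries else 0
    arr = np.full(n, SHAPE_MISSING)
    for pos, val in entries.items():
        arr[pos - 1] = val
    return ShapeProfile(sequence_id=sequence_id or str(path), reactivity=arr)


def write_shape(profile: ShapeProfile, path: Union[str, Path]) -> None:
    lines = [
        f"{i}\t{v:.6g}" for i, v in enumerate(profile.reactivity, start=1)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# --- base-pair probability matrices ------------------------------------------

@dataclass(frozen=True)
class BasePairProbabilityMatrix:
    """Symmetric N x N equilibrium pairing probabilities P(x_ij).

    Row sums are at most 1; the residual ``1 - sum_j P(x_ij)`` is the
    probability that nucleotide i is unpaired.
    """

    sequence_id: str
    P: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise StructureError("probability matrix must be square")
        if not np.allclose(P, P.T, atol=1e-10):
            raise StructureError("probability matrix must be symmetric")
        if np.any(np.diag(P) != 0):
            raise StructureError("probability matrix diagonal must be zero")
        if P.min() < -1e-12 or P.max() > 1 + 1e-9:
            raise StructureError("probabilities must lie in [0, 1]")
        if np.any(P.sum(axis=1) > 1 + 1e-6):
            raise StructureError("row mass exceeds 1")
        object.__setattr__(self, "P", P)

    @property
    def N(self) -> int:
        return self.P.shape[0]

    def pairing_probabilities(self) -> np.ndarray:
        """P(x_i) = sum_j P(x_ij): probability each nucleotide is paired."""
        return self.P.sum(axis=1)


def write_bppm_triples(bppm: BasePairProbabilityMatrix, path: Union[str, Path],
                       threshold: float = 0.0) -> None:
    """Serialize as tab-separated 'i j P' triples (1-based, upper triangle)."""
    lines = [f"# {bppm.sequence_id}\t{bppm.N}"]
    idx = np.triu_indices(bppm.N, k=1)
    for i, j in zip(*idx):
        p = bppm.P[i, j]
        if p > threshold:
            lines.append(f"{i + 1}\t{j + 1}\t{p!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_bppm_triples(path: Union[str, Path]) -> BasePairProbabilityMatrix:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise StructureError(f"{path}: missing '# id\\tN' header")
    seq_id, n = lines[0].lstrip("# ").split("\t")
    P = np.zeros((int(n), int(n)))
    for ln in lines[1:]:
        if not ln.strip():
            continue
        i, j, p = ln.split("\t")
        P[int(i) - 1, int(j) - 1] = P[int(j) - 1, int(i) - 1] = float(p)
    return BasePairProbabilityMatrix(sequence_id=seq_id, P=P)
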