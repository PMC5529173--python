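"""Toy inputs with enumerable structure spaces, for tests and examples.

Every sequence fixture is at most 25 nt so the exhaustive enumeration
oracle applies; structure spaces stay below ~200 structures.  The
``shape_pair`` fixture builds two synthetic SHAPE profiles that agree up
to noise except over a designated divergent block, emulating an in vitro
versus in vivo comparison with a localized structural rearrangement.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Tuple, Union

import numpy as np

from .sequences import SequenceRecord, write_fasta
from .structures import SHAPE_MISSING, ShapeProfile, write_shape

FIXTURE_KINDS = ("hairpin", "two_hairpin", "riboswitch_like", "shape_pair")

#: 12-nt stem-loop: one dominant 4-bp helix plus enumerable alternatives.
HAIRPIN_SEQ = "GGGGAAAACCCC"

#: Two independent stem-loops separated by a linker (23 nt).
TWO_HAIRPIN_SEQ = "GGGAAAACCCAAAGGGAAAACCC"

#: Toggle sequence: the central segment can pair 5' or 3', two mutually
#: exclusive helices emulating a riboswitch on/off pair (20 nt).
RIBOSWITCH_LIKE_SEQ = "CCCCAAAAGGGGAAAACCCC"


def fixture_sequence(kind: str) -> SequenceRecord:
    seqs = {
        "hairpin": HAIRPIN_SEQ,
        "two_hairpin": TWO_HAIRPIN_SEQ,
        "riboswitch_like": RIBOSWITCH_LIKE_SEQ,
    }
    if kind not in seqs:
        raise ValueError(f"no sequence fixture of kind {kind!r}")
    return SequenceRecord(id=kind, sequence=seqs[kind])


def make_shape_pair(seed: int = 0, length: int = 200,
                    divergent_block: Tuple[int, int] = (20, 30),
                    n_missing: int = 6,
                    noise: float = 0.05) -> Tuple[ShapeProfile, ShapeProfile]:
    """Two correlated synthetic SHAPE profiles with one divergent block.

    Reactivities are exponential-like (most nucleotides weakly reactive, a
    tail of highly reactive ones, the standard shape of normalized SHAPE
    data).  Profile 2 equals profile 1 plus small noise except on the
    0-based half-open ``divergent_block``, where it is drawn independently;
    ``n_missing`` positions per profile carry the -999 sentinel.
    """
    rng = np.random.default_rng(seed)
    base = rng.exponential(scale=0.5, size=length)
    p2 = np.clip(base + rng.normal(scale=noise, size=length), 0.0, None)
    lo, hi = divergent_block
    p2[lo:hi] = rng.exponential(scale=0.5, size=hi - lo)
    p1 = base.copy()
    miss1 = rng.choice(length, size=n_missing, replace=False)
    miss2 = rng.choice(length, size=n_missing, replace=False)
    p1[miss1] = SHAPE_MISSING
    p2[miss2] = SHAPE_MISSING
    return (
        ShapeProfile(sequence_id="shape_a", reactivity=p1),
        ShapeProfile(sequence_id="shape_b", reactivity=p2),
    )


def make_fixture(kind: str, seed: int = 0,
                 outdir: Union[str, Path] = ".") -> List[Path]:
    """Write fixture files; returns the paths written.

    Sequence kinds write ``<kind>.fasta``; ``shape_pair`` writes two
    ``.shape`` files.  Output is byte-identical for a fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if kind in ("hairpin", "two_hairpin", "riboswitch_like"):
        path = outdir / f"{kind}.fasta"
        write_fasta([fixture_sequence(kind)], path)
        return [path]
    if kind == "shape_pair":
        a, b = make_shape_pair(seed=seed)
        pa, pb = outdir / "shape_a.shape", outdir / "shape_b.shape"
        write_shape(a, pa)
        write_shape(b, pb)
        return [pa, pb]
    raise ValueError(
        f"unknown fixture kind {kind!r}; choose one of {FIXTURE_KINDS}"
    )
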