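"""Locality-sensitive h-mer hashing of nucleotide windows.

An *h-mer* is a hashed, modified k-mer designed to tolerate the two most
common classes of neutral sequence change between related genomes:

* every third base of the window (the codon wobble position when the window
  is in-frame coding sequence) is dropped outright;
* the remaining bases are collapsed to a 1-bit purine/pyrimidine alphabet
  ({A,G} -> 0, {C,T} -> 1), so transition substitutions never change the key.

The packed bit string is mixed through a fixed 64-bit finalizer and truncated
to the key width; the canonical key of a window is the lesser of the forward
and reverse-complement hashes ("minword"), which makes keys strand-invariant.

Two window geometries are used: 56-bp windows giving 38-bit keys for the
reference database, and 30-bp windows giving 20-bit keys for the on-the-fly
query index built during alignment refinement.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "DB_HMER",
    "QUERY_HMER",
    "HmerKey",
    "HmerSpec",
    "canonical_hmer",
    "encode_sequence",
    "reverse_complement",
    "splitmix64",
    "window_keys",
]

# 2-bit nucleotide codes.  The low bit is the purine/pyrimidine bit, so the
# 1-bit alphabet is simply ``code & 1`` and complementation flips it.
_CODE_A, _CODE_C, _CODE_G, _CODE_T = 0, 1, 2, 3
_BASES = "ACGT"

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

# splitmix64 finalizer constants (multiply-xorshift).  Pinned: determinism of
# databases and screens across platforms depends on these exact values.
_MIX_C1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX_C2 = np.uint64(0x94D049BB133111EB)


def splitmix64(x: np.ndarray | int) -> np.ndarray:
    """Mix 64-bit values through the splitmix64 finalizer (vectorized)."""
    z = np.asarray(x, dtype=np.uint64).copy()
    z ^= z >> np.uint64(30)
    z *= _MIX_C1
    z ^= z >> np.uint64(27)
    z *= _MIX_C2
    z ^= z >> np.uint64(31)
    return z


@dataclass(frozen=True)
class HmerSpec:
    """Geometry of an h-mer: window size and retained-bit width.

    ``offsets`` are the 0-based window indices kept after dropping every
    position ``i`` with ``i % 3 == 2`` (the wobble frame of that strand's own
    5'->3' reading).
    """

    window: int = 56
    hash_bits: int = 38
    offsets: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        offs = tuple(i for i in range(self.window) if i % 3 != 2)
        if len(offs) != self.hash_bits:
            raise ValueError(
                f"window {self.window} retains {len(offs)} bases, "
                f"but hash_bits is {self.hash_bits}"
            )
        object.__setattr__(self, "offsets", offs)

    @property
    def mask(self) -> np.uint64:
        return np.uint64((1 << self.hash_bits) - 1)


DB_HMER = HmerSpec(window=56, hash_bits=38)
QUERY_HMER = HmerSpec(window=30, hash_bits=20)


class HmerKey(NamedTuple):
    """A canonical h-mer key split into 30-bit upper / 8-bit lower subkeys."""

    value: int
    upper_subkey: int
    lower_subkey: int

    @classmethod
    def from_value(cls, value: int) -> "HmerKey":
        return cls(value, value >> 8, value & 0xFF)


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


def _sequence_fill_seed(seq_id: str) -> int:
    digest = hashlib.blake2b(seq_id.encode(), digest_size=8).digest()
    return int.from_bytes(digest, "little")


def encode_sequence(seq: str, seq_id: str = "") -> tuple[np.ndarray, np.ndarray]:
    """Encode a nucleotide string to 2-bit codes, filling non-ACGT bases.

    Non-ACGT positions (IUPAC ambiguity codes, hard-masked bases, remnant Ns)
    are filled with pseudorandom bases derived deterministically from
    ``(seq_id, position)``, so a rebuild from the same input reproduces
    identical codes.  Filled positions are flagged; downstream scoring never
    counts them toward 100%-identity segments.

    Returns ``(codes, filled)`` where ``codes`` is uint8 in {0..3} and
    ``filled`` is a boolean mask of pseudorandom positions.
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE[raw]
    filled = codes == 255
    if filled.any():
        pos = np.nonzero(filled)[0].astype(np.uint64)
        seed = np.uint64(_sequence_fill_seed(seq_id))
        codes = codes.copy()
        codes[filled] = (splitmix64(seed ^ (pos + np.uint64(1)) * _MIX_C1) & np.uint64(3)).astype(
            np.uint8
        )
    else:
        codes = codes.copy()
    return codes, filled


def window_keys(
    codes: np.ndarray, starts: np.ndarray, spec: HmerSpec = DB_HMER
) -> tuple[np.ndarray, np.ndarray]:
    """Canonical keys and orientations for windows starting at ``starts``.

    Both strands are packed independently in their own 5'->3' reading frame
    and hashed; the canonical key is the elementwise minimum.  Orientation is
    +1 where the forward strand minimizes the hash (ties included) and -1
    where the reverse complement does.

    Returns ``(keys, orient)`` with ``keys`` uint64 (< 2**hash_bits) and
    ``orient`` int8 in {+1, -1}.
    """
    starts = np.asarray(starts, dtype=np.int64)
    bits = (codes & 1).astype(np.uint64)
    fwd = np.zeros(len(starts), dtype=np.uint64)
    rev = np.zeros(len(starts), dtype=np.uint64)
    one = np.uint64(1)
    w = spec.window
    for off in spec.offsets:
        fwd = (fwd << one) | bits[starts + off]
        # complementation flips the purine/pyrimidine bit
        rev = (rev << one) | (one ^ bits[starts + (w - 1 - off)])
    hf = splitmix64(fwd) & spec.mask
    hr = splitmix64(rev) & spec.mask
    keys = np.minimum(hf, hr)
    orient = np.where(hf <= hr, 1, -1).astype(np.int8)
    return keys, orient


def canonical_hmer(window: str, spec: HmerSpec = DB_HMER) -> HmerKey | None:
    """Canonical key of a single window, or ``None`` if it is too short.

    The window must contain only A/C/G/T (ambiguity codes are filled by the
    caller before hashing); a window longer than the spec width is rejected.
    """
    if len(window) < spec.window:
        return None
    if len(window) > spec.window:
        raise ValueError(f"window must be exactly {spec.window} bp, got {len(window)}")
    raw = np.frombuffer(window.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE[raw]
    if (codes == 255).any():
        raise ValueError("window contains non-ACGT bases; fill them first")
    keys, _ = window_keys(codes, np.array([0]), spec)
    return HmerKey.from_value(int(keys[0]))
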