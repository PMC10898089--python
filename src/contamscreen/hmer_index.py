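"""Reference database: packed sequences, sorted h-mer node index, metadata.

The index is conceptually a sorted array of nodes ``(h-mer key,
subject-ordinal, signed subject position)``.  The 38-bit key splits into a
30-bit upper and an 8-bit lower subkey; only the lower subkey is stored in
the node (9 bytes total: 1-byte lower subkey, 4-byte subject ordinal, 4-byte
signed position).  A precomputed offsets array locates the node bucket for
an upper subkey, and a binary search on the lower subkey finds the matching
sub-span in time logarithmic in the bucket size.

At desk scale the offsets array is kept configurable: with ``upper_bits``
below 30, buckets are keyed on the low ``upper_bits`` bits of the upper
subkey, so the index discriminates on ``upper_bits + 8`` key bits (collision
probability is negligible for databases far below a billion h-mers).  The
node layout is unchanged at any setting.

The signed position encodes the strand on which the hash was minimized:
``position = orient * (start + 1)`` where ``start`` is the 0-based window
start; the +1 bias keeps the sign meaningful at start 0.  Palindromic ties
(forward and reverse-complement hashes equal) are stored once with positive
sign.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hashing import DB_HMER, HmerKey, HmerSpec, encode_sequence, window_keys
from .taxonomy import EUKARYOTE_KINGDOMS, TaxonomyTable

__all__ = [
    "NODE_DTYPE",
    "GxDatabase",
    "PackedSequence",
    "build_database",
    "extract_hmers",
    "lookup",
]

#: on-disk / in-memory node record: exactly 9 bytes, little-endian
NODE_DTYPE = np.dtype([("lower", "u1"), ("ordinal", "<u4"), ("pos", "<i4")])
assert NODE_DTYPE.itemsize == 9

_GXI_MAGIC = b"CSGXI1\x00\x00"
_GXS_MAGIC = b"CSGXS1\x00\x00"
_FORMAT_VERSION = 1

DEFAULT_UPPER_BITS = 20
PROKARYOTE_STRIDE = 10
EUKARYOTE_STRIDE = 20


@dataclass
class PackedSequence:
    """A reference (or query) sequence as 2-bit codes plus fill flags."""

    ordinal: int
    seq_id: str
    codes: np.ndarray  # uint8 in {0..3}
    filled: np.ndarray  # bool; pseudorandom-filled positions
    taxid: int = 0

    @property
    def length(self) -> int:
        return len(self.codes)

    def decode(self) -> str:
        return "".join("ACGT"[c] for c in self.codes)

    @classmethod
    def from_string(
        cls, ordinal: int, seq_id: str, sequence: str, taxid: int = 0
    ) -> "PackedSequence":
        codes, filled = encode_sequence(sequence, seq_id)
        return cls(ordinal=ordinal, seq_id=seq_id, codes=codes, filled=filled, taxid=taxid)


def _pack_2bit(codes: np.ndarray) -> bytes:
    pad = (-len(codes)) % 4
    c = np.concatenate([codes, np.zeros(pad, dtype=np.uint8)])
    c = c.reshape(-1, 4)
    return (c[:, 0] << 6 | c[:, 1] << 4 | c[:, 2] << 2 | c[:, 3]).astype(np.uint8).tobytes()


def _unpack_2bit(data: bytes, length: int) -> np.ndarray:
    b = np.frombuffer(data, dtype=np.uint8)
    out = np.empty((len(b), 4), dtype=np.uint8)
    out[:, 0] = b >> 6
    out[:, 1] = (b >> 4) & 3
    out[:, 2] = (b >> 2) & 3
    out[:, 3] = b & 3
    return out.reshape(-1)[:length].copy()


def hmer_positions(
    codes: np.ndarray, stride: int, spec: HmerSpec = DB_HMER
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Window starts, canonical keys and orientations at the given stride."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    n = len(codes) - spec.window
    if n < 0:
        empty = np.array([], dtype=np.int64)
        return empty, empty.astype(np.uint64), empty.astype(np.int8)
    starts = np.arange(0, n + 1, stride, dtype=np.int64)
    keys, orient = window_keys(codes, starts, spec)
    return starts, keys, orient


def extract_hmers(
    seq: PackedSequence, stride: int, spec: HmerSpec = DB_HMER
) -> list[tuple[int, HmerKey]]:
    """All (position, key) pairs for windows at 0, stride, 2*stride, ...

    A sequence shorter than the window yields an empty list.
    """
    starts, keys, _ = hmer_positions(seq.codes, stride, spec)
    return [(int(p), HmerKey.from_value(int(k))) for p, k in zip(starts, keys)]


@dataclass
class GxDatabase:
    """Packed reference sequences + sorted h-mer node index + metadata."""

    sequences: list[PackedSequence]
    nodes: np.ndarray  # NODE_DTYPE, sorted by (effective key, ordinal, pos)
    bucket_offsets: np.ndarray  # int64, length 2**upper_bits + 1
    upper_bits: int
    taxonomy: TaxonomyTable
    strides: dict[int, int]  # ordinal -> stride used at build
    spec: HmerSpec = field(default_factory=lambda: DB_HMER)
    _ekeys: np.ndarray | None = field(default=None, repr=False)

    # -- derived ---------------------------------------------------------
    @property
    def effective_key_bits(self) -> int:
        return self.upper_bits + 8

    @property
    def effective_mask(self) -> int:
        return (1 << self.effective_key_bits) - 1

    @property
    def ekeys(self) -> np.ndarray:
        """Effective (bucketed) keys per node, reconstructed on demand."""
        if self._ekeys is None:
            counts = np.diff(self.bucket_offsets)
            buckets = np.repeat(
                np.arange(len(counts), dtype=np.uint64), counts.astype(np.int64)
            )
            self._ekeys = (buckets << np.uint64(8)) | self.nodes["lower"].astype(np.uint64)
        return self._ekeys

    @property
    def seq_taxids(self) -> np.ndarray:
        return np.array([s.taxid for s in self.sequences], dtype=np.int64)

    def total_bp(self) -> int:
        return sum(s.length for s in self.sequences)

    def division_stats(self) -> pd.DataFrame:
        """Per-division sequence count and total bp in the database."""
        rows = []
        for s in self.sequences:
            lin = self.taxonomy.resolve(s.taxid)
            rows.append((lin.division, lin.kingdom, s.length))
        if not rows:
            return pd.DataFrame(columns=["division", "kingdom", "n_sequences", "total_bp"])
        df = pd.DataFrame(rows, columns=["division", "kingdom", "bp"])
        return (
            df.groupby(["division", "kingdom"], as_index=False)
            .agg(n_sequences=("bp", "size"), total_bp=("bp", "sum"))
        )

    # -- lookup ----------------------------------------------------------
    def lookup_batch(self, keys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Node span [lo, hi) per query key (vectorized over all keys)."""
        ek = np.asarray(keys, dtype=np.uint64) & np.uint64(self.effective_mask)
        lo = np.searchsorted(self.ekeys, ek, side="left")
        hi = np.searchsorted(self.ekeys, ek, side="right")
        return lo, hi

    def lookup(self, key: HmerKey | int) -> np.ndarray:
        """All nodes whose (effective) key equals the query key.

        Locates the bucket via the upper-subkey offsets array, then binary
        searches the lower subkey within the bucket.  An absent key returns
        an empty span.
        """
        value = key.value if isinstance(key, HmerKey) else int(key)
        ek = value & self.effective_mask
        bucket = ek >> 8
        lo, hi = int(self.bucket_offsets[bucket]), int(self.bucket_offsets[bucket + 1])
        lower = np.uint8(ek & 0xFF)
        sub = self.nodes["lower"][lo:hi]
        a = lo + int(np.searchsorted(sub, lower, side="left"))
        b = lo + int(np.searchsorted(sub, lower, side="right"))
        return self.nodes[a:b]

    # -- persistence -----------------------------------------------------
    def save(self, prefix: str | Path) -> None:
        """Write the index (.gxi), sequences (.gxs) and metadata sidecars."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)

        with open(prefix.with_suffix(".gxi"), "wb") as f:
            f.write(_GXI_MAGIC)
            f.write(struct.pack("<IIQ", _FORMAT_VERSION, self.upper_bits, len(self.nodes)))
            f.write(self.bucket_offsets.astype("<i8").tobytes())
            f.write(self.nodes.tobytes())

        with open(prefix.with_suffix(".gxs"), "wb") as f:
            f.write(_GXS_MAGIC)
            f.write(struct.pack("<I", len(self.sequences)))
            for s in self.sequences:
                sid = s.seq_id.encode()
                f.write(struct.pack("<H", len(sid)))
                f.write(sid)
                fill_pos = np.nonzero(s.filled)[0].astype("<u4")
                f.write(struct.pack("<QQ", s.length, len(fill_pos)))
                f.write(fill_pos.tobytes())
                f.write(_pack_2bit(s.codes))

        meta = pd.DataFrame(
            {
                "ordinal": [s.ordinal for s in self.sequences],
                "seq_id": [s.seq_id for s in self.sequences],
                "length": [s.length for s in self.sequences],
                "taxid": [s.taxid for s in self.sequences],
                "stride": [self.strides[s.ordinal] for s in self.sequences],
            }
        )
        meta.to_csv(prefix.with_suffix(".meta.tsv"), sep="\t", index=False)
        self.taxonomy.to_tsv(prefix.with_suffix(".taxa.tsv"))
        params = {
            "version": _FORMAT_VERSION,
            "k": self.spec.window,
            "hash_bits": self.spec.hash_bits,
            "upper_bits": self.upper_bits,
        }
        prefix.with_suffix(".params.json").write_text(json.dumps(params, indent=2) + "\n")

    @classmethod
    def load(cls, prefix: str | Path) -> "GxDatabase":
        prefix = Path(prefix)
        params = json.loads(prefix.with_suffix(".params.json").read_text())
        spec = HmerSpec(window=params["k"], hash_bits=params["hash_bits"])
        upper_bits = params["upper_bits"]

        with open(prefix.with_suffix(".gxi"), "rb") as f:
            magic = f.read(8)
            if magic != _GXI_MAGIC:
                raise ValueError(f"{prefix}.gxi: not an h-mer index file")
            version, ub, n_nodes = struct.unpack("<IIQ", f.read(16))
            if ub != upper_bits:
                raise ValueError("index header disagrees with params sidecar")
            offsets = np.frombuffer(f.read(8 * ((1 << ub) + 1)), dtype="<i8").copy()
            nodes = np.frombuffer(f.read(9 * n_nodes), dtype=NODE_DTYPE).copy()

        meta = pd.read_csv(prefix.with_suffix(".meta.tsv"), sep="\t")
        sequences: list[PackedSequence] = []
        strides: dict[int, int] = {}
        with open(prefix.with_suffix(".gxs"), "rb") as f:
            if f.read(8) != _GXS_MAGIC:
                raise ValueError(f"{prefix}.gxs: not a packed-sequence file")
            (n_seqs,) = struct.unpack("<I", f.read(4))
            for i in range(n_seqs):
                (id_len,) = struct.unpack("<H", f.read(2))
                seq_id = f.read(id_len).decode()
                length, n_fill = struct.unpack("<QQ", f.read(16))
                fill_pos = np.frombuffer(f.read(4 * n_fill), dtype="<u4")
                packed = f.read((length + 3) // 4)
                codes = _unpack_2bit(packed, length)
                filled = np.zeros(length, dtype=bool)
                filled[fill_pos.astype(np.int64)] = True
                row = meta.iloc[i]
                sequences.append(
                    PackedSequence(
                        ordinal=int(row["ordinal"]),
                        seq_id=seq_id,
                        codes=codes,
                        filled=filled,
                        taxid=int(row["taxid"]),
                    )
                )
                strides[int(row["ordinal"])] = int(row["stride"])

        taxonomy = TaxonomyTable.from_tsv(prefix.with_suffix(".taxa.tsv"))
        return cls(
            sequences=sequences,
            nodes=nodes,
            bucket_offsets=offsets,
            upper_bits=upper_bits,
            taxonomy=taxonomy,
            strides=strides,
            spec=spec,
        )


def stride_for_kingdom(kingdom: str) -> int:
    """10-bp stride for prokaryotes (and viruses/synthetic), 20 for eukaryotes."""
    return EUKARYOTE_STRIDE if kingdom in EUKARYOTE_KINGDOMS else PROKARYOTE_STRIDE


def build_database(
    records: list[tuple[str, int, str]],
    taxonomy: TaxonomyTable,
    stride: int | None = None,
    upper_bits: int = DEFAULT_UPPER_BITS,
    spec: HmerSpec = DB_HMER,
) -> GxDatabase:
    """Build a database from ``(seq_id, taxid, sequence)`` records.

    ``stride`` overrides the per-kingdom default (10 bp prokaryote / 20 bp
    eukaryote).  Every record's taxid must resolve through ``taxonomy``;
    a missing taxid is a hard error naming the sequence.
    """
    sequences: list[PackedSequence] = []
    strides: dict[int, int] = {}
    key_parts: list[np.ndarray] = []
    ord_parts: list[np.ndarray] = []
    pos_parts: list[np.ndarray] = []

    for ordinal, (seq_id, taxid, sequence) in enumerate(records):
        try:
            lineage = taxonomy.resolve(taxid)
        except KeyError as err:
            raise KeyError(f"sequence {seq_id!r}: {err.args[0]}") from None
        s = PackedSequence.from_string(ordinal, seq_id, sequence, taxid)
        sequences.append(s)
        st = stride if stride is not None else stride_for_kingdom(lineage.kingdom)
        strides[ordinal] = st
        starts, keys, orient = hmer_positions(s.codes, st, spec)
        key_parts.append(keys)
        ord_parts.append(np.full(len(starts), ordinal, dtype=np.uint32))
        pos_parts.append((orient.astype(np.int64) * (starts + 1)).astype(np.int32))

    if key_parts:
        keys = np.concatenate(key_parts)
        ordinals = np.concatenate(ord_parts)
        positions = np.concatenate(pos_parts)
    else:
        keys = np.array([], dtype=np.uint64)
        ordinals = np.array([], dtype=np.uint32)
        positions = np.array([], dtype=np.int32)

    emask = np.uint64((1 << (upper_bits + 8)) - 1)
    ekeys = keys & emask
    order = np.lexsort((positions, ordinals, ekeys))
    ekeys = ekeys[order]

    nodes = np.empty(len(ekeys), dtype=NODE_DTYPE)
    nodes["lower"] = (ekeys & np.uint64(0xFF)).astype(np.uint8)
    nodes["ordinal"] = ordinals[order]
    nodes["pos"] = positions[order]

    buckets = (ekeys >> np.uint64(8)).astype(np.int64)
    counts = np.bincount(buckets, minlength=1 << upper_bits)
    offsets = np.zeros((1 << upper_bits) + 1, dtype=np.int64)
    np.cumsum(counts, out=offsets[1:])

    return GxDatabase(
        sequences=sequences,
        nodes=nodes,
        bucket_offsets=offsets,
        upper_bits=upper_bits,
        taxonomy=taxonomy,
        strides=strides,
        spec=spec,
        _ekeys=ekeys,
    )


def lookup(db: GxDatabase, key: HmerKey | int) -> np.ndarray:
    """Module-level convenience wrapper for :meth:`GxDatabase.lookup`."""
    return db.lookup(key)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly wrapped) FASTA file into (id, sequence) pairs.

    The id is the defline up to the first whitespace.
    """
    from Bio.SeqIO.FastaIO import SimpleFastaParser

    with open(path) as handle:
        return [(title.split()[0], seq) for title, seq in SimpleFastaParser(handle)]


def write_fasta(path: str | Path, records: list[tuple[str, str]], width: int = 80) -> None:
    with open(path, "w") as f:
        for seq_id, seq in records:
            f.write(f">{seq_id}\n")
            for i in range(0, len(seq), width):
                f.write(seq[i : i + width] + "\n")
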