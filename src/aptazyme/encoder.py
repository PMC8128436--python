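"""Binary structure-aware feature tensors for stem-loop pairs.

Each parsed stem-loop becomes a 2-D grid: rows run from the stem base (row 0,
closest to the catalytic core) toward the loop apex, with two columns for the
5' and 3' strand sides.  Every occupied cell is one-hot across 8 channels —
the four nucleotides crossed with paired/unpaired.  The two grids (stem-loop I
and II) are stacked on a third axis so that a small 3-D convolution window can
see spatially adjacent nucleotides of *both* loops at once, mimicking the
loop-loop tertiary interaction geometry of the cleaving ribozyme.

Array layout: ``(row, side, stemloop, channel)`` = ``(L_max, 2, 2, 8)``.
Channel order: A,C,G,U unpaired then A,C,G,U paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyBatch, EncodingOverflow
from .scaffold import ParsedConstruct, StemLoop

#: rows; must hold the longest stem + half-loop walk.  Training loops reach
#: 13 nt on stems extending to 11 bp, and grafted aptamer loops reach 26 nt on
#: the 6-bp stem (6 + ceil(26/2) = 19 rows), so 20 leaves one row of headroom.
DEFAULT_L_MAX = 20

CHANNELS = ("A_unpaired", "C_unpaired", "G_unpaired", "U_unpaired",
            "A_paired", "C_paired", "G_paired", "U_paired")
_NUC_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}


@dataclass(frozen=True)
class EncoderConfig:
    """Encoder settings; stored in model metadata so that a trained model can
    refuse tensors produced under different conventions."""

    l_max: int = DEFAULT_L_MAX
    channel_order: tuple[str, ...] = CHANNELS

    def as_dict(self) -> dict:
        return {"l_max": self.l_max, "channel_order": list(self.channel_order)}


@dataclass(frozen=True)
class EncodedTensor:
    array: np.ndarray   # (l_max, 2, 2, 8) float32, binary
    mask: np.ndarray    # (l_max, 2, 2) uint8 occupancy
    config: EncoderConfig = field(default_factory=EncoderConfig)


def _cells_of(sl: StemLoop, full_seq: str, l_max: int):
    """Yield (row, side, nucleotide, paired) cells for one stem-loop walk.

    Stem base pairs occupy both sides at the same row with paired channels;
    the loop then walks up the 5' side to the apex (ceil(n/2) positions, apex
    on the 5' side for odd n) and back down the 3' side.  Branch-stem
    nucleotides keep their walk position but carry paired channels.
    """
    ls, le = sl.loop_positions
    n = le - ls
    cells = []
    for r in range(sl.stem_len):
        # row 0 is the junction-proximal (core-side) pair; rows walk inward
        p5 = ls - sl.stem_len + r
        p3 = le + sl.stem_len - 1 - r
        cells.append((r, 0, full_seq[p5], True))
        cells.append((r, 1, full_seq[p3], True))
    up = (n + 1) // 2
    for k in range(n):
        paired = sl.paired_flags[k]
        nt = full_seq[ls + k]
        if k < up:
            row, side = sl.stem_len + k, 0
        else:
            row, side = sl.stem_len + (n - 1 - k), 1
        cells.append((row, side, nt, paired))
    max_row = max(r for r, *_ in cells)
    if max_row >= l_max:
        raise EncodingOverflow(
            f"stem-loop {sl.which} walk needs {max_row + 1} rows > L_max={l_max}")
    return cells


def encode_stemloop(sl: StemLoop, full_seq: str,
                    l_max: int = DEFAULT_L_MAX) -> np.ndarray:
    """One stem-loop as a (l_max, 2 sides, 8 channels) binary grid."""
    grid = np.zeros((l_max, 2, 8), dtype=np.float32)
    for row, side, nt, paired in _cells_of(sl, full_seq, l_max):
        grid[row, side, _NUC_INDEX[nt] + (4 if paired else 0)] = 1.0
    return grid


def encode_pair(sl1: StemLoop, sl2: StemLoop, full_seq: str,
                l_max: int = DEFAULT_L_MAX) -> EncodedTensor:
    """Both stem-loops stacked into the (l_max, 2, 2, 8) tensor."""
    g1 = encode_stemloop(sl1, full_seq, l_max)
    g2 = encode_stemloop(sl2, full_seq, l_max)
    arr = np.stack([g1, g2], axis=2)
    mask = (arr.sum(axis=-1) > 0).astype(np.uint8)
    return EncodedTensor(arr, mask, EncoderConfig(l_max=l_max))


def encode_parsed(p: ParsedConstruct, l_max: int = DEFAULT_L_MAX) -> EncodedTensor:
    if p.misfolded:
        raise ValueError("cannot encode a misfolded construct")
    return encode_pair(p.sl1, p.sl2, p.structure.sequence, l_max)


def batch_encode(records: list[ParsedConstruct], l_max: int = DEFAULT_L_MAX,
                 on_overflow: str = "skip"):
    """Encode a list of parsed constructs into one stacked array.

    Misfolded records must be pre-filtered.  Overflowing records are skipped
    and reported (``on_overflow="skip"``) or raise (``"raise"``).

    Returns ``(stacked array (N, l_max, 2, 2, 8), mask (N, l_max, 2, 2),
    kept_indices, skipped_indices)``.
    """
    if not records:
        raise EmptyBatch("no records to encode")
    arrays, masks, kept, skipped = [], [], [], []
    for i, p in enumerate(records):
        try:
            t = encode_parsed(p, l_max)
        except EncodingOverflow:
            if on_overflow == "raise":
                raise
            skipped.append(i)
            continue
        arrays.append(t.array)
        masks.append(t.mask)
        kept.append(i)
    if not arrays:
        raise EmptyBatch("every record overflowed the encoder")
    return (np.stack(arrays), np.stack(masks), kept, skipped)


def save_tensor(path, stacked: np.ndarray, config: EncoderConfig,
                extra_meta: dict | None = None) -> None:
    """Portable export: .npy array plus a JSON sidecar with the layout."""
    import json
    from pathlib import Path
    path = Path(path)
    np.save(path.with_suffix(".npy"), stacked)
    meta = {"shape": list(stacked.shape), **config.as_dict()}
    if extra_meta:
        meta.update(extra_meta)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
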