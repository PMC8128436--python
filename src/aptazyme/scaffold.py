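"""Ribozyme construct assembly, secondary-structure prediction and stem-loop parsing.

The hammerhead ribozyme scaffold is fixed sequence; only the two loops (I and
II) vary.  A construct is assembled by inserting loop sequences into the
scaffold, folded with a pluggable minimum-free-energy backend, and the
predicted dot-bracket is parsed back into the two stem-loops.  Which
nucleotides actually form a loop is only known after folding: loop-flanking
bases that extend the closing stem are credited to the stem, and long loops
may contain branch stems (hairpins inside the loop), both of which are
recorded per nucleotide.

Coordinates are 0-based, half-open.  T is silently mapped to U and lowercase
is uppercased on input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import NamedTuple

import numpy as np

from .errors import BackendError, InputTooLong, InvalidAlphabet, InvalidLoop

RNA_ALPHABET = frozenset("ACGU")
_COMPLEMENT = str.maketrans("ACGU", "UGCA")

#: Watson-Crick + wobble pair weights used by the Nussinov test folder.
_PAIR_WEIGHT = {("G", "C"): 3, ("C", "G"): 3,
                ("A", "U"): 2, ("U", "A"): 2,
                ("G", "U"): 1, ("U", "G"): 1}

DEFAULT_MAX_FOLD_LEN = 300
MIN_HAIRPIN = 3


def clean_rna(seq: str, what: str = "sequence") -> str:
    """Uppercase, map T to U, and validate the alphabet."""
    s = seq.upper().replace("T", "U")
    if not set(s) <= RNA_ALPHABET:
        bad = sorted(set(s) - RNA_ALPHABET)
        raise InvalidAlphabet(f"{what} contains non-nucleotide characters: {bad}")
    return s


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIR_WEIGHT


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scaffold:
    """Fixed ribozyme sequence blocks with two loop-insertion slots.

    ``order`` lists block names 5'→3'; the literals ``"LOOP1"`` and ``"LOOP2"``
    mark the insertion slots.  Stem arms must be exact reverse complements.
    """

    name: str
    order: tuple[str, ...]
    segments: dict[str, str]
    default_stem1_len: int
    default_stem2_len: int
    native_loop1: str = ""
    native_loop2: str = ""
    native_full_sequence: str = ""

    def __post_init__(self):
        for key in ("stem1_5arm", "stem1_3arm", "stem2_5arm", "stem2_3arm"):
            if key not in self.segments:
                raise ValueError(f"scaffold missing segment {key!r}")
        if reverse_complement(self.segments["stem1_5arm"]) != self.segments["stem1_3arm"]:
            raise ValueError("stem I arms are not reverse complements")
        if reverse_complement(self.segments["stem2_5arm"]) != self.segments["stem2_3arm"]:
            raise ValueError("stem II arms are not reverse complements")

    @classmethod
    def from_json(cls, path_or_dict) -> "Scaffold":
        if isinstance(path_or_dict, dict):
            d = path_or_dict
        else:
            with open(path_or_dict) as fh:
                d = json.load(fh)
        return cls(
            name=d["name"],
            order=tuple(d["order"]),
            segments={k: clean_rna(v, k) if v else "" for k, v in d["segments"].items()},
            default_stem1_len=int(d["default_stem1_len"]),
            default_stem2_len=int(d["default_stem2_len"]),
            native_loop1=d.get("native_loop1", ""),
            native_loop2=d.get("native_loop2", ""),
            native_full_sequence=d.get("native_full_sequence", ""),
        )

    @classmethod
    def load_default(cls) -> "Scaffold":
        """The bundled literature-derived sTRSV scaffold fixture."""
        ref = resources.files("aptazyme.data") / "strsv_scaffold.json"
        return cls.from_json(json.loads(ref.read_text()))

    @property
    def fixed_length(self) -> int:
        return sum(len(self.segments[b]) for b in self.order if b not in ("LOOP1", "LOOP2"))

    def block_coords(self, loop1_len: int, loop2_len: int) -> dict[str, tuple[int, int]]:
        """Half-open coordinates of every block for given insert lengths."""
        coords, pos = {}, 0
        for b in self.order:
            n = loop1_len if b == "LOOP1" else loop2_len if b == "LOOP2" else len(self.segments[b])
            coords[b] = (pos, pos + n)
            pos += n
        return coords


@dataclass(frozen=True)
class RibozymeConstruct:
    loop1_insert: str
    loop2_insert: str
    full_sequence: str
    scaffold_name: str


@dataclass(frozen=True)
class SecondaryStructure:
    sequence: str
    dot_bracket: str
    backend: str = ""

    def __post_init__(self):
        if len(self.sequence) != len(self.dot_bracket):
            raise ValueError("sequence / dot-bracket length mismatch")
        if self.dot_bracket.count("(") != self.dot_bracket.count(")"):
            raise ValueError("unbalanced dot-bracket")


@dataclass(frozen=True)
class StemLoop:
    which: str                       # "I" or "II"
    stem_len: int                    # scaffold stem plus any loop-derived extension
    loop_positions: tuple[int, int]  # half-open range into full_sequence
    loop_sequence: str
    paired_flags: tuple[bool, ...]   # per loop position: inside a branch stem
    branch_stems: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]

    @property
    def loop_len(self) -> int:
        return self.loop_positions[1] - self.loop_positions[0]

    @property
    def has_branch(self) -> bool:
        return len(self.branch_stems) > 0


class StructureKey(NamedTuple):
    stem1_len: int
    stem2_len: int
    loop1_len: int
    loop2_len: int
    branch1: bool
    branch2: bool


@dataclass(frozen=True)
class ParsedConstruct:
    """A construct together with its fold and parsed stem-loops.

    ``misfolded`` constructs (scaffold stems broken in the MFE structure, or a
    loop base pairing outside its own loop) carry ``sl1 is None``.
    """

    construct: RibozymeConstruct
    structure: SecondaryStructure
    sl1: StemLoop | None
    sl2: StemLoop | None
    misfolded: bool
    misfold_reason: str = ""

    @property
    def key(self) -> StructureKey | None:
        if self.misfolded:
            return None
        return structure_key(self.sl1, self.sl2)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def assemble(loop1_insert: str, loop2_insert: str, scaffold: Scaffold) -> RibozymeConstruct:
    """Insert the two loop sequences into the scaffold's loop slots."""
    if not loop1_insert or not loop2_insert:
        raise InvalidLoop("loop inserts must be nonempty")
    l1 = clean_rna(loop1_insert, "loop1")
    l2 = clean_rna(loop2_insert, "loop2")
    parts = []
    for b in scaffold.order:
        if b == "LOOP1":
            parts.append(l1)
        elif b == "LOOP2":
            parts.append(l2)
        else:
            parts.append(scaffold.segments[b])
    return RibozymeConstruct(l1, l2, "".join(parts), scaffold.name)


def recover_inserts(construct: RibozymeConstruct, scaffold: Scaffold) -> tuple[str, str]:
    """Slice the full sequence at the scaffold sites to recover both inserts."""
    coords = scaffold.block_coords(len(construct.loop1_insert), len(construct.loop2_insert))
    s = construct.full_sequence
    return s[slice(*coords["LOOP1"])], s[slice(*coords["LOOP2"])]


# ---------------------------------------------------------------------------
# Folding backends
# ---------------------------------------------------------------------------

_NUC_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
_W8 = np.zeros((4, 4), dtype=np.int64)
for (a, b), w in _PAIR_WEIGHT.items():
    _W8[_NUC_CODE[a], _NUC_CODE[b]] = w


def _nussinov_py(codes: np.ndarray) -> str:
    """Maximum-weight pairing (GC=3, AU=2, GU=1), min hairpin 3, no lonely
    pairs (every helix >= 2 bp), deterministic traceback.

    Three-matrix DP: W = best unconstrained score, V1 = best with (i, j)
    paired, V2 = best with (i, j) paired *and* stacked on an inner pair.
    Closed substructures enter W only through V2, which forbids isolated
    pairs — without this, a maximum-pairing folder shatters the designed
    scaffold stems into scattered single pairs.
    """
    n = len(codes)
    tw, tv1 = _nussinov_kernel(codes, _W8, MIN_HAIRPIN)
    pairs = []
    stack = [(0, n - 1, 0)]   # state 0 = W, 1 = V1, 2 = V2
    while stack:
        i, j, state = stack.pop()
        if i >= j or j - i < MIN_HAIRPIN + 1:
            continue
        if state == 0:
            k = tw[i, j]
            if k == -1:
                stack.append((i, j - 1, 0))
            else:
                if k > i:
                    stack.append((i, k - 1, 0))
                stack.append((k, j, 2))
        elif state == 2:
            pairs.append((i, j))
            stack.append((i + 1, j - 1, 1))
        else:  # V1
            pairs.append((i, j))
            stack.append((i + 1, j - 1, 1 if tv1[i, j] == 0 else 0))
    db = ["."] * n
    for a, b in pairs:
        db[a], db[b] = "(", ")"
    return "".join(db)


def _nussinov_kernel_py(codes, wmat, min_hairpin):
    NEG = np.int64(-(10 ** 9))
    n = codes.shape[0]
    W = np.zeros((n + 1, n + 1), dtype=np.int64)
    V1 = np.full((n + 1, n + 1), NEG, dtype=np.int64)
    V2 = np.full((n + 1, n + 1), NEG, dtype=np.int64)
    tw = -np.ones((n, n), dtype=np.int64)
    tv1 = np.zeros((n, n), dtype=np.int64)
    for span in range(min_hairpin + 1, n):
        for i in range(0, n - span):
            j = i + span
            w = wmat[codes[i], codes[j]]
            if w > 0:
                inner_v1 = V1[i + 1, j - 1]
                inner_w = W[i + 1, j - 1]
                if inner_v1 >= inner_w:
                    V1[i, j] = w + inner_v1
                    tv1[i, j] = 0
                else:
                    V1[i, j] = w + inner_w
                    tv1[i, j] = 1
                if inner_v1 > NEG:
                    V2[i, j] = w + inner_v1
            best = W[i, j - 1]
            argk = -1
            for k in range(i, j - min_hairpin):
                v = V2[k, j]
                if v > NEG:
                    left = W[i, k - 1] if k > i else 0
                    s = left + v
                    if s > best:
                        best = s
                        argk = k
            W[i, j] = best
            tw[i, j] = argk
    return tw, tv1


try:
    from numba import njit
    _nussinov_kernel = njit(cache=True)(_nussinov_kernel_py)
except ImportError:  # pragma: no cover - numba is installed in practice
    _nussinov_kernel = _nussinov_kernel_py


def _fold_vienna(seq: str) -> str:
    try:
        import RNA
    except ImportError as exc:  # pragma: no cover
        raise BackendError("ViennaRNA python bindings unavailable") from exc
    db, _mfe = RNA.fold(seq)
    return db


def fold(sequence: str, backend: str = "vienna",
         max_len: int = DEFAULT_MAX_FOLD_LEN) -> SecondaryStructure:
    """Predict a single MFE secondary structure for an RNA sequence.

    Backends: ``"vienna"`` (thermodynamic MFE, default) and ``"nussinov"``
    (deterministic maximum-weight pairing for dependency-free testing).
    """
    if not sequence:
        raise InvalidLoop("cannot fold an empty sequence")
    seq = clean_rna(sequence)
    if len(seq) > max_len:
        raise InputTooLong(f"sequence length {len(seq)} exceeds max {max_len}")
    if backend == "vienna":
        db = _fold_vienna(seq)
    elif backend == "nussinov":
        codes = np.array([_NUC_CODE[c] for c in seq], dtype=np.int64)
        db = _nussinov_py(codes)
    else:
        raise BackendError(f"unknown folding backend {backend!r}")
    return SecondaryStructure(seq, db, backend)


def pair_table(dot_bracket: str) -> np.ndarray:
    """Partner index per position, -1 if unpaired."""
    pt = np.full(len(dot_bracket), -1, dtype=np.int64)
    stack = []
    for i, c in enumerate(dot_bracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket")
            j = stack.pop()
            pt[i], pt[j] = j, i
    if stack:
        raise ValueError("unbalanced dot-bracket")
    return pt


# ---------------------------------------------------------------------------
# Stem-loop parsing
# ---------------------------------------------------------------------------

def _parse_one(pt: np.ndarray, arm5: tuple[int, int], arm3: tuple[int, int],
               which: str, seq: str) -> tuple[StemLoop | None, str]:
    a5s, a5e = arm5
    a3s, a3e = arm3
    stem = a5e - a5s
    for i in range(stem):
        if pt[a5s + i] != a3e - 1 - i:
            return None, f"stem {which} broken"
    loop_s, loop_e = a5e, a3s
    # stem extension: contiguous pairs stacking inward on the scaffold stem
    ext = 0
    while loop_s + ext < loop_e - 1 - ext and pt[loop_s + ext] == loop_e - 1 - ext:
        ext += 1
    ls, le = loop_s + ext, loop_e - ext
    flags, opens = [], []
    branch_pairs = []
    for p in range(ls, le):
        q = pt[p]
        if q == -1:
            flags.append(False)
        elif ls <= q < le:
            flags.append(True)
            if p < q:
                branch_pairs.append((p, q))
        else:
            return None, f"loop {which} pairs outside its loop"
    # group branch pairs into helices (stacked runs)
    branch_stems = []
    cur_open, cur_close = [], []
    for p, q in branch_pairs:
        if cur_open and p == cur_open[-1] + 1 and q == cur_close[-1] - 1:
            cur_open.append(p)
            cur_close.append(q)
        else:
            if cur_open:
                branch_stems.append((tuple(cur_open), tuple(cur_close)))
            cur_open, cur_close = [p], [q]
    if cur_open:
        branch_stems.append((tuple(cur_open), tuple(cur_close)))
    sl = StemLoop(
        which=which,
        stem_len=stem + ext,
        loop_positions=(ls, le),
        loop_sequence=seq[ls:le],
        paired_flags=tuple(flags),
        branch_stems=tuple(branch_stems),
    )
    return sl, ""


def parse_stemloops(structure: SecondaryStructure, scaffold: Scaffold,
                    loop1_len: int, loop2_len: int
                    ) -> tuple[StemLoop | None, StemLoop | None, str]:
    """Parse the two stem-loops out of a predicted structure.

    Returns ``(sl1, sl2, misfold_reason)``; a nonempty reason marks the
    construct as non-parseable (misfolded) rather than raising.
    """
    coords = scaffold.block_coords(loop1_len, loop2_len)
    pt = pair_table(structure.dot_bracket)
    sl1, r1 = _parse_one(pt, coords["stem1_5arm"], coords["stem1_3arm"], "I",
                         structure.sequence)
    if r1:
        return None, None, r1
    sl2, r2 = _parse_one(pt, coords["stem2_5arm"], coords["stem2_3arm"], "II",
                         structure.sequence)
    if r2:
        return None, None, r2
    return sl1, sl2, ""


def structure_key(sl1: StemLoop, sl2: StemLoop) -> StructureKey:
    """The structural-segment identity of a parsed construct (Fig 4E-style
    grouping: stem lengths, loop lengths, branch flags)."""
    return StructureKey(sl1.stem_len, sl2.stem_len, sl1.loop_len, sl2.loop_len,
                        sl1.has_branch, sl2.has_branch)


def analyze(loop1_insert: str, loop2_insert: str, scaffold: Scaffold,
            backend: str = "vienna") -> ParsedConstruct:
    """Assemble, fold and parse one construct."""
    c = assemble(loop1_insert, loop2_insert, scaffold)
    st = fold(c.full_sequence, backend=backend)
    sl1, sl2, reason = parse_stemloops(st, scaffold, len(c.loop1_insert),
                                       len(c.loop2_insert))
    return ParsedConstruct(c, st, sl1, sl2, misfolded=bool(reason),
                           misfold_reason=reason)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def constructs_to_fasta(constructs, path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord
    recs = [SeqRecord(Seq(c.full_sequence),
                      id=f"{c.scaffold_name}|{c.loop1_insert}|{c.loop2_insert}",
                      description="") for c in constructs]
    seqio_write(recs, str(path), "fasta")


def constructs_from_fasta(path, scaffold: Scaffold):
    """Read constructs written by :func:`constructs_to_fasta`."""
    from Bio.SeqIO import parse as seqio_parse
    out = []
    for rec in seqio_parse(str(path), "fasta"):
        _, l1, l2 = rec.id.split("|")
        out.append(RibozymeConstruct(l1, l2, clean_rna(str(rec.seq)), scaffold.name))
    return out


def parsed_to_table(parsed: list[ParsedConstruct]):
    """Per-construct table (sequence, loops, dot-bracket, key, misfold flag)."""
    import pandas as pd
    rows = []
    for p in parsed:
        rows.append({
            "sequence": p.construct.full_sequence,
            "loop1": p.construct.loop1_insert,
            "loop2": p.construct.loop2_insert,
            "dot_bracket": p.structure.dot_bracket,
            "backend": p.structure.backend,
            "structure_key": "" if p.misfolded else "|".join(map(str, p.key)),
            "misfolded": p.misfolded,
            "misfold_reason": p.misfold_reason,
        })
    return pd.DataFrame(rows)
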