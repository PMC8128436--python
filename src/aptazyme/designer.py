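"""Forward design: aptamer grafting, variable-loop enumeration and ranking.

An aptamer is grafted onto loop I or II by removing the terminal helix leading
up to its ligand-binding bulge and attaching the remaining nucleotides to the
ribozyme stem, completing that loop.  The opposite (variable) loop is
enumerated exhaustively over N5-N8, every candidate is folded, parsed, encoded
and scored with a trained activity model, and the k candidates with the lowest
predicted basal activity form the designed library.
"""

from __future__ import annotations

import heapq
import itertools
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .encoder import DEFAULT_L_MAX, EncoderConfig, encode_parsed
from .errors import (AnnotationError, ConfigError, EncodingOverflow, NoBulge,
                     SelectionError)
from .models import TrainedRegressor, predict
from .scaffold import Scaffold, analyze, clean_rna, pair_table

DESIGN_LENGTHS = (5, 6, 7, 8)
DEFAULT_LIBRARY_SIZE = 200
DEFAULT_TOP_N = 15
NUCS = "ACGU"


@dataclass(frozen=True)
class Aptamer:
    name: str
    full_sequence: str
    full_structure: str
    binding_bulge: tuple[int, int] | None = None   # 0-based half-open
    allowed_positions: tuple[str, ...] = ("I", "II")
    ligand: str = ""
    provenance: str = ""

    def __post_init__(self):
        if len(self.full_sequence) != len(self.full_structure):
            raise AnnotationError("sequence / structure length mismatch")


def load_aptamers() -> dict[str, Aptamer]:
    """The bundled aptamer fixtures (literature-derived + synthetic placeholders)."""
    out: dict[str, Aptamer] = {}
    for fname in ("aptamers_literature.json", "aptamers_synthetic.json"):
        ref = resources.files("aptazyme.data") / fname
        d = json.loads(ref.read_text())
        for a in d["aptamers"]:
            out[a["name"]] = Aptamer(
                name=a["name"],
                full_sequence=clean_rna(a["full_sequence"], a["name"]),
                full_structure=a["full_structure"],
                binding_bulge=tuple(a["binding_bulge"]) if a.get("binding_bulge") else None,
                allowed_positions=tuple(a.get("allowed_positions", ("I", "II"))),
                ligand=a.get("ligand", ""),
                provenance=a.get("provenance", ""),
            )
    return out


def _terminal_helix(pt: np.ndarray) -> tuple[int, int]:
    """(first open position, helix length) of the outermost stacked helix."""
    n = len(pt)
    f = next((i for i in range(n) if pt[i] > i), None)
    if f is None:
        raise NoBulge("aptamer structure contains no helix")
    k = 1
    while f + k < n and pt[f + k] == pt[f] - k:
        k += 1
    return f, k


def _find_bulge(pt: np.ndarray, f: int, k: int) -> tuple[int, int]:
    """Unpaired run immediately inside the terminal helix (bulge closest to the
    terminal stem); requires a further helix inside, i.e. an internal loop."""
    inner_start, inner_end = f + k, pt[f] - k + 1
    p = inner_start
    while p < inner_end and pt[p] == -1:
        p += 1
    if p == inner_start or p >= inner_end:
        raise NoBulge("no internal loop adjacent to the terminal stem")
    return inner_start, p


def derive_loop_insert(aptamer: Aptamer, retained_pairs: int = 0) -> str:
    """Remove the closing helix on the terminal side of the binding bulge and
    return the remaining aptamer nucleotides 5'→3'."""
    pt = pair_table(aptamer.full_structure)
    n = len(pt)
    f, k = _terminal_helix(pt)
    if aptamer.binding_bulge is not None:
        s, e = aptamer.binding_bulge
        if not (0 <= s < e <= n):
            raise AnnotationError(f"binding bulge {aptamer.binding_bulge} outside "
                                  f"sequence of length {n}")
        if not (f + k <= s and e <= pt[f] - k + 1):
            raise AnnotationError("binding bulge is not enclosed by the terminal helix")
    else:
        _find_bulge(pt, f, k)
    cut = k - retained_pairs
    if cut < 0:
        raise ConfigError("retained_pairs exceeds the terminal helix length")
    return aptamer.full_sequence[f + cut: pt[f] - cut + 1]


@dataclass(frozen=True)
class DesignCandidate:
    aptamer_name: str
    aptamer_loop: str          # loop holding the aptamer: "I" or "II"
    variable_loop: str
    loop1: str
    loop2: str
    full_sequence: str = ""
    predicted_activity: float = float("nan")
    rank: int = 0


def enumerate_library(aptamer: Aptamer, lengths=DESIGN_LENGTHS,
                      positions: tuple[str, ...] = ("I", "II"),
                      retained_pairs: int = 0):
    """Lazily stream every (aptamer position) x (variable loop N_l) candidate.

    Count = |positions| x sum(4^l).  Duplicate-free by construction.
    """
    lengths = tuple(sorted(set(int(x) for x in lengths)))
    if not lengths:
        raise ConfigError("empty variable-loop length set")
    positions = tuple(p for p in positions if p in aptamer.allowed_positions)
    if not positions:
        raise ConfigError("no allowed aptamer positions")
    insert = derive_loop_insert(aptamer, retained_pairs)
    for pos in positions:
        for L in lengths:
            for tup in itertools.product(NUCS, repeat=L):
                var = "".join(tup)
                l1, l2 = (insert, var) if pos == "I" else (var, insert)
                yield DesignCandidate(aptamer.name, pos, var, l1, l2)


def library_size(lengths=DESIGN_LENGTHS, n_positions: int = 2) -> int:
    """Closed form |positions| x sum over lengths of 4^l."""
    return n_positions * sum(4 ** int(l) for l in set(lengths))


class _RevKey:
    """Inverts comparison so heapq's min-heap behaves as a max-heap on
    (predicted activity, full sequence); the lexicographically smaller
    sequence wins score ties."""

    __slots__ = ("key", "cand")

    def __init__(self, key, cand):
        self.key, self.cand = key, cand

    def __lt__(self, other):
        return self.key > other.key


def rank_and_select(candidates, model: TrainedRegressor, k: int,
                    scaffold: Scaffold, backend: str = "vienna",
                    l_max: int = DEFAULT_L_MAX, batch_size: int = 4096,
                    ) -> tuple[list[DesignCandidate], dict]:
    """Score a candidate stream and keep the k lowest-predicted candidates.

    Misfolded and encoder-overflowing candidates are excluded from ranking but
    counted.  Returns the ascending ranked list (ties broken lexicographically
    by full sequence) and a stats dict.
    """
    heap: list[_RevKey] = []
    stats = {"scored": 0, "misfolded": 0, "overflow": 0}
    enc_cfg = EncoderConfig(l_max=l_max)

    def flush(batch):
        if not batch:
            return
        arrays, kept = [], []
        for cand in batch:
            parsed = analyze(cand.loop1, cand.loop2, scaffold, backend=backend)
            if parsed.misfolded:
                stats["misfolded"] += 1
                continue
            try:
                t = encode_parsed(parsed, l_max)
            except EncodingOverflow:
                stats["overflow"] += 1
                continue
            arrays.append(t.array)
            kept.append((cand, parsed.construct.full_sequence))
        if not kept:
            return
        preds = predict(model, np.stack(arrays), enc_cfg)
        stats["scored"] += len(kept)
        for (cand, full), score in zip(kept, preds):
            item = _RevKey((float(score), full),
                           DesignCandidate(cand.aptamer_name, cand.aptamer_loop,
                                           cand.variable_loop, cand.loop1,
                                           cand.loop2, full, float(score)))
            if len(heap) < k:
                heapq.heappush(heap, item)
            elif item.key < heap[0].key:
                heapq.heapreplace(heap, item)

    batch = []
    for cand in candidates:
        batch.append(cand)
        if len(batch) >= batch_size:
            flush(batch)
            batch = []
    flush(batch)

    if stats["scored"] < k:
        raise SelectionError(
            f"requested k={k} but only {stats['scored']} scoreable candidates",
            scoreable=stats["scored"])
    ranked = sorted(heap, key=lambda it: it.key)
    out = [DesignCandidate(c.cand.aptamer_name, c.cand.aptamer_loop,
                           c.cand.variable_loop, c.cand.loop1, c.cand.loop2,
                           c.cand.full_sequence, c.cand.predicted_activity,
                           rank=i + 1)
           for i, c in enumerate(ranked)]
    return out, stats


def design_library(aptamer: Aptamer, model: TrainedRegressor, scaffold: Scaffold,
                   k: int = DEFAULT_LIBRARY_SIZE, lengths=DESIGN_LENGTHS,
                   positions: tuple[str, ...] = ("I", "II"),
                   backend: str = "vienna", l_max: int = DEFAULT_L_MAX,
                   batch_size: int = 4096) -> tuple[list[DesignCandidate], dict]:
    """Enumerate, score and select one aptamer's designed library."""
    stream = enumerate_library(aptamer, lengths=lengths, positions=positions)
    return rank_and_select(stream, model, k, scaffold, backend=backend,
                           l_max=l_max, batch_size=batch_size)


def top_n(designed: list[DesignCandidate], n: int = DEFAULT_TOP_N) -> list[DesignCandidate]:
    """First n of a ranked designed library (the 'predicted best')."""
    if n > len(designed):
        raise SelectionError(f"n={n} exceeds library size {len(designed)}",
                             scoreable=len(designed))
    return designed[:n]


def designed_to_frame(designed: list[DesignCandidate]):
    import pandas as pd
    return pd.DataFrame([{
        "rank": c.rank, "aptamer": c.aptamer_name, "aptamer_loop": c.aptamer_loop,
        "variable_loop": c.variable_loop, "loop1": c.loop1, "loop2": c.loop2,
        "full_sequence": c.full_sequence, "predicted_activity": c.predicted_activity,
    } for c in designed])
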