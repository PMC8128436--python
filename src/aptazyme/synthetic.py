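"""Synthetic training and sort-seq data with the statistical structure the
pipeline assumes.

The surrogate activity function is a deliberate caricature of loop-loop
tertiary interaction: activity (log10(GFP/mCherry)) drops by a fixed weight
per nucleotide of the longest antiparallel complementary run between loop I
and loop II, with additive motif effects, a mild length penalty, and optional
Gaussian noise.  The complementarity term is non-additive in any flattened
one-hot feature basis, which is exactly why the spatially paired convolutional
encoding should beat a linear model on this signal.  It makes no claim of
biophysical fidelity.

The read simulator draws, per sequence, ``depth`` reads multinomially over the
8 sort bins with probabilities given by a Normal(activity, sigma) integrated
over the bin intervals — the idealized sort of a clonal cell population whose
cell-to-cell log-expression spread is sigma.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidAlphabet
from .facs_seq import BIN_COLUMNS, BinScheme
from .scaffold import RNA_ALPHABET, can_pair

NUCS = "ACGU"

#: loop-length presets mirroring the two training library designs:
#: "uniform" = both loops N5-N10; "asymmetric" = one long (N9-N13) one short (N5-N7)
LENGTH_PRESETS = {
    "uniform": tuple(range(5, 11)),
    "long": tuple(range(9, 14)),
    "short": tuple(range(5, 8)),
}


#: default motif shifts: the UGGAG/loop-II motif with its ~-0.3 activity
#: effect plus short composition motifs, so the surrogate carries both a
#: convolution-friendly local-motif signal and the non-additive loop-pair
#: interaction term
DEFAULT_MOTIF_EFFECTS = {
    "UGGAG@II": -0.30,
    "GGA@II": -0.12,
    "UU@I": +0.10,
}


@dataclass(frozen=True)
class SurrogateSpec:
    base_activity: float = 0.0
    pair_interaction_weight: float = -0.05   # per nt of complementary run
    motif_effects: dict = field(default_factory=lambda: dict(DEFAULT_MOTIF_EFFECTS))
    length_penalty: float = 0.06             # per loop nt beyond 8 total
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def max_complementary_run(loop1: str, loop2: str) -> int:
    """Longest contiguous Watson-Crick/GU-complementary run between loop1 and
    reversed loop2 (i.e. the longest antiparallel duplex the loops could form),
    over all alignments.  Brute force; loops are short."""
    r2 = loop2[::-1]
    n1, n2 = len(loop1), len(r2)
    best = 0
    for i in range(n1):
        for j in range(n2):
            t = 0
            while i + t < n1 and j + t < n2 and can_pair(loop1[i + t], r2[j + t]):
                t += 1
            if t > best:
                best = t
    return best


def _motif_shift(loop1: str, loop2: str, effects: dict) -> float:
    shift = 0.0
    for key, eff in effects.items():
        motif, _, where = key.partition("@")
        where = where or "any"
        if where in ("I", "any") and motif in loop1:
            shift += eff
        if where in ("II", "any") and motif in loop2:
            shift += eff
    return shift


def surrogate_activity(loop1: str, loop2: str, spec: SurrogateSpec = SurrogateSpec()) -> float:
    """Deterministic (given spec.seed) surrogate basal activity for a loop pair."""
    l1, l2 = loop1.upper().replace("T", "U"), loop2.upper().replace("T", "U")
    if not (set(l1) <= RNA_ALPHABET and set(l2) <= RNA_ALPHABET):
        raise InvalidAlphabet("loops must be RNA over {A,C,G,U}")
    value = (spec.base_activity
             + spec.pair_interaction_weight * max_complementary_run(l1, l2)
             + _motif_shift(l1, l2, spec.motif_effects)
             + spec.length_penalty * (len(l1) + len(l2) - 8))
    if spec.noise_sd > 0:
        h = zlib.crc32(f"{spec.seed}|{l1}|{l2}".encode())
        value += np.random.default_rng(h).normal(0.0, spec.noise_sd)
    return float(value)


def random_loops(n: int, lengths, rng: np.random.Generator,
                 probs=None) -> list[str]:
    lengths = np.asarray(list(lengths))
    ls = rng.choice(lengths, size=n, p=probs)
    return ["".join(rng.choice(list(NUCS), size=k)) for k in ls]


def generate_training_set(n: int, spec: SurrogateSpec = SurrogateSpec(),
                          lengths1="uniform", lengths2="uniform",
                          seed: int = 0) -> pd.DataFrame:
    """Seeded table of (loop1, loop2, activity) with surrogate labels.

    ``lengths1``/``lengths2`` are iterables of loop lengths or preset names
    ("uniform", "long", "short").
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    l1s = LENGTH_PRESETS.get(lengths1, lengths1)
    l2s = LENGTH_PRESETS.get(lengths2, lengths2)
    loop1 = random_loops(n, l1s, rng)
    loop2 = random_loops(n, l2s, rng)
    acts = [surrogate_activity(a, b, spec) for a, b in zip(loop1, loop2)]
    return pd.DataFrame({"loop1": loop1, "loop2": loop2, "activity": acts})


def simulate_facs_reads(activities, scheme: BinScheme, depth: int = 100,
                        sigma: float = 0.4, seed: int = 0,
                        sequences=None) -> pd.DataFrame:
    """Multinomial bin counts per sequence from Normal(activity, sigma) masses."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    acts = np.asarray(activities, dtype=float)
    rng = np.random.default_rng(seed)
    P = scheme.bin_probabilities(acts, np.full_like(acts, sigma))
    P = np.atleast_2d(P)
    P = P / P.sum(axis=1, keepdims=True)
    counts = rng.multinomial(depth, P)
    df = pd.DataFrame(counts, columns=BIN_COLUMNS)
    df.insert(0, "sequence",
              sequences if sequences is not None else
              [f"seq{i}" for i in range(len(acts))])
    return df
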