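"""Cross-library motif analysis: shared variable loops, positional consensus
matrices, and motif-conditioned activity contrasts.

Membership identity includes the loop position: a loop-I sequence and an
identical loop-II sequence are distinct designs.  Variable-length consensus
uses 5'-anchoring with explicit gap mass.  Motif queries accept IUPAC
degenerate codes (so both UGGAG and UGGAR are expressible).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from scipy.stats import ranksums

from .errors import EmptyLibrary, NoMatch

IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U", "T": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}

ALPHABET = ("A", "C", "G", "U", "-")   # '-' is gap mass past a sequence's 3' end


def iupac_regex(motif: str) -> re.Pattern:
    try:
        return re.compile("".join(f"[{IUPAC[c]}]" for c in motif.upper()))
    except KeyError as exc:
        raise ValueError(f"not an IUPAC nucleotide code: {exc}") from exc


@dataclass(frozen=True)
class ConsensusMatrix:
    length: int
    frequencies: np.ndarray   # (length, 5) over A,C,G,U,gap; rows sum to 1

    def purine_fraction(self) -> float:
        """A+G fraction of the non-gap mass."""
        non_gap = self.frequencies[:, :4].sum()
        return float((self.frequencies[:, 0].sum() + self.frequencies[:, 2].sum())
                     / non_gap)


def shared_membership(libraries: dict[str, set]) -> dict:
    """For each design, in how many of the libraries it appears.

    Library elements are designs — either plain variable-loop strings or
    (loop position, sequence) tuples; exact set-intersection counting.
    """
    if len(libraries) < 2:
        raise EmptyLibrary("need at least 2 libraries")
    for name, lib in libraries.items():
        if not lib:
            raise EmptyLibrary(f"library {name!r} is empty")
    counts: dict = {}
    for lib in libraries.values():
        for elem in set(lib):
            counts[elem] = counts.get(elem, 0) + 1
    return counts


def consensus(seqs) -> ConsensusMatrix:
    """5'-anchored per-position frequencies; shorter sequences contribute gap
    mass at tail positions."""
    seqs = [s.upper().replace("T", "U") for s in seqs]
    if not seqs:
        raise EmptyLibrary("no sequences for consensus")
    L = max(len(s) for s in seqs)
    idx = {c: i for i, c in enumerate(ALPHABET)}
    freq = np.zeros((L, 5))
    for s in seqs:
        for p in range(L):
            freq[p, idx[s[p]] if p < len(s) else idx["-"]] += 1
    freq /= len(seqs)
    return ConsensusMatrix(L, freq)


def motif_activity_contrast(table, motif: str, loop: str = "II"
                            ) -> tuple[float, float, float]:
    """Mean activity of motif-matched records vs the whole background set.

    ``table`` needs columns loop1, loop2 and activity.  The motif (IUPAC) is
    substring-matched on the designated loop.  Returns (matched mean,
    background mean over all records, two-sided rank-sum p of matched vs
    unmatched); p = 1 when every record matches.
    """
    col = "loop1" if loop.upper() == "I" else "loop2"
    pat = iupac_regex(motif)
    hit = table[col].map(lambda s: pat.search(s) is not None).to_numpy()
    if not hit.any():
        raise NoMatch(f"motif {motif} matched no records on loop {loop}")
    acts = table["activity"].to_numpy(dtype=float)
    matched_mean = float(acts[hit].mean())
    background_mean = float(acts.mean())
    if hit.all():
        return matched_mean, background_mean, 1.0
    p = float(ranksums(acts[hit], acts[~hit]).pvalue)
    return matched_mean, background_mean, p


def consensus_to_frame(cm: ConsensusMatrix):
    import pandas as pd
    return pd.DataFrame(cm.frequencies, columns=list(ALPHABET),
                        index=pd.RangeIndex(1, cm.length + 1, name="position"))
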