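"""Matching statistics of a pivot sequence against one target text.

``MS[j]`` (1-based in the usual notation; stored 0-based here as
``values[j-1]``) is the length of the longest suffix of the pattern prefix
``P[1..j]`` that occurs as a substring of the target text.  Matching
statistics are computed left-to-right and obey the sawtooth property:
consecutive values increase by at most one.

The production engine is a suffix automaton of the target text: the
automaton is built once in linear time, after which a single streaming scan
of the pattern yields the longest-match length at every position.  Any
engine producing all matching statistics would serve; the automaton is
simply a good fit at the scale of genomes held in memory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seq_io import TargetText, pattern_tokens

__all__ = ["MSVector", "SuffixAutomaton", "compute_ms", "ms_oracle"]


@dataclass(frozen=True)
class MSVector:
    """Matching-statistics array for one pivot sequence.

    ``values[j]`` is the length of the longest suffix of ``pattern[: j + 1]``
    occurring in the target.  Validates the sawtooth property and the bound
    ``0 <= values[j] <= j + 1`` on construction.
    """

    pivot_sequence_name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.int64)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("MS vector must be a non-empty 1-D array")
        if (vals < 0).any():
            raise ValueError("MS values must be non-negative")
        if (vals > np.arange(1, vals.size + 1)).any():
            raise ValueError("MS[j] cannot exceed the prefix length j+1")
        if vals.size > 1 and (np.diff(vals) > 1).any():
            raise ValueError("sawtooth property violated: MS[j] - MS[j-1] > 1")

    def __len__(self) -> int:
        return int(self.values.size)


class SuffixAutomaton:
    """Suffix automaton over a token sequence (ints; dict transitions).

    States are indices into parallel arrays; ``link`` is the suffix link and
    ``length`` the longest string reaching the state.  Accepts arbitrary
    integer alphabets, which is how separator and ambiguous-residue tokens
    (unique negatives) stay unmatchable for free: they occur once in the
    text and never in a normal pattern.
    """

    __slots__ = ("trans", "link", "length", "_last")

    def __init__(self, tokens) -> None:
        self.trans: list[dict[int, int]] = [{}]
        self.link: list[int] = [-1]
        self.length: list[int] = [0]
        self._last = 0
        for tok in tokens:
            self._extend(tok)

    def _extend(self, c: int) -> None:
        trans, link, length = self.trans, self.link, self.length
        cur = len(trans)
        trans.append({})
        length.append(length[self._last] + 1)
        link.append(-1)
        p = self._last
        while p != -1 and c not in trans[p]:
            trans[p][c] = cur
            p = link[p]
        if p == -1:
            link[cur] = 0
        else:
            q = trans[p][c]
            if length[p] + 1 == length[q]:
                link[cur] = q
            else:
                clone = len(trans)
                trans.append(dict(trans[q]))
                length.append(length[p] + 1)
                link.append(link[q])
                while p != -1 and trans[p].get(c) == q:
                    trans[p][c] = clone
                    p = link[p]
                link[q] = clone
                link[cur] = clone
        self._last = cur

    def longest_match_per_position(self, pattern_toks) -> np.ndarray:
        """Length of the longest suffix of each pattern prefix found in the
        indexed text — i.e. the matching-statistics vector."""
        trans, link, length = self.trans, self.link, self.length
        out = np.empty(len(pattern_toks), dtype=np.int64)
        state, ln = 0, 0
        for i, c in enumerate(pattern_toks):
            while state != 0 and c not in trans[state]:
                state = link[state]
                ln = length[state]
            nxt = trans[state].get(c)
            if nxt is None:
                state, ln = 0, 0
            else:
                state, ln = nxt, ln + 1
            out[i] = ln
        return out


def compute_ms(
    pattern: str, target: TargetText, pivot_sequence_name: str = ""
) -> MSVector:
    """Matching statistics of ``pattern`` against ``target``.

    Non-ACGT residues in the pattern are unmatchable, so the MS value drops
    to zero at such a position — the same behaviour as a mismatch.
    """
    if len(pattern) == 0:
        raise ValueError("pattern must be non-empty")
    automaton = SuffixAutomaton(target.tokens)
    values = automaton.longest_match_per_position(pattern_tokens(pattern))
    return MSVector(pivot_sequence_name, values)


def compute_ms_automaton(
    pattern: str, automaton: SuffixAutomaton, pivot_sequence_name: str = ""
) -> MSVector:
    """As :func:`compute_ms` but reusing a prebuilt automaton (one target
    text is typically queried with several pivot sequences)."""
    if len(pattern) == 0:
        raise ValueError("pattern must be non-empty")
    values = automaton.longest_match_per_position(pattern_tokens(pattern))
    return MSVector(pivot_sequence_name, values)


def ms_oracle(
    pattern: str, target: TargetText, pivot_sequence_name: str = ""
) -> MSVector:
    """Quadratic brute-force matching statistics, used only as a test
    reference: for every position try suffix lengths from longest to
    shortest and substring-search each candidate in the token text."""
    if len(pattern) == 0:
        raise ValueError("pattern must be non-empty")
    ptoks = pattern_tokens(pattern)
    # remap the joint token alphabet to codepoints so candidate suffixes can
    # be substring-searched as strings; unmatchable tokens stay unique
    alphabet = {tok: chr(0x100 + idx) for idx, tok in enumerate(dict.fromkeys([*target.tokens, *ptoks]))}
    text = "".join(alphabet[t] for t in target.tokens)
    pat = "".join(alphabet[t] for t in ptoks)
    m = len(pat)
    values = np.zeros(m, dtype=np.int64)
    for j in range(m):
        for ell in range(j + 1, 0, -1):
            if pat[j + 1 - ell : j + 1] in text:
                values[j] = ell
                break
    return MSVector(pivot_sequence_name, values)
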