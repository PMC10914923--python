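"""Mapping basecall ordinals onto reference amplicon coordinates.

Global (Needleman–Wunsch/Gotoh) alignment with affine gaps and
IUPAC-aware scoring: an ambiguity call such as R matches a reference A
or G, so mixed-signal positions — exactly the ones carrying editing —
do not count as mismatches.  Reference coordinates are 1-based
throughout; basecall ordinals are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trace_io import IUPAC_SETS

__all__ = [
    "SiteMap",
    "CandidateSites",
    "MappingFailure",
    "align_basecalls",
    "enumerate_candidates",
    "SUBSTRATE_BASE",
    "PRODUCT_BASE",
]

MATCH_SCORE = 2.0
MISMATCH_SCORE = -2.0
GAP_OPEN = 5.0      # cost of the first gapped column
GAP_EXTEND = 1.0    # cost of each further gapped column

#: substrate (reference) base and product base per editing chemistry, as
#: read on the sequenced strand: adenosine deamination reads A -> G,
#: cytidine deamination reads C -> T in the cDNA.
SUBSTRATE_BASE = {"A_to_G": "A", "C_to_T": "C"}
PRODUCT_BASE = {"A_to_G": "G", "C_to_T": "T"}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class MappingFailure(ValueError):
    """Alignment identity fell below the acceptance floor."""


@dataclass
class SiteMap:
    """Aligned (call_index, ref_position) pairs plus unaligned leftovers.

    ``call_to_ref`` maps 0-based basecall ordinals to 1-based reference
    positions for every aligned column; ``unaligned_calls`` are call
    ordinals opposite a reference gap, ``uncovered_ref`` reference
    positions opposite a basecall gap.
    """

    call_to_ref: dict
    unaligned_calls: list = field(default_factory=list)
    uncovered_ref: list = field(default_factory=list)
    identity: float = 1.0
    score: float = 0.0

    def __post_init__(self):
        refs = list(self.call_to_ref.values())
        if refs != sorted(refs) or len(set(refs)) != len(refs):
            raise ValueError("reference positions must be strictly increasing")

    @property
    def ref_to_call(self) -> dict:
        return {r: c for c, r in self.call_to_ref.items()}


@dataclass
class CandidateSites:
    """All reference positions whose base is the editing substrate."""

    edit_mode: str
    positions: list
    ref_bases: list

    def __post_init__(self):
        sub = SUBSTRATE_BASE[self.edit_mode]
        if any(b != sub for b in self.ref_bases):
            raise ValueError(f"candidate with base other than {sub}")

    def __len__(self) -> int:
        return len(self.positions)


def _score_matrix(basecalls: str, reference: str) -> np.ndarray:
    """(n_calls, n_ref) substitution scores under IUPAC set-containment."""
    scores = np.full((len(basecalls), len(reference)), MISMATCH_SCORE)
    for i, b in enumerate(basecalls):
        members = IUPAC_SETS.get(b, frozenset())
        for j, r in enumerate(reference):
            if r in members:
                scores[i, j] = MATCH_SCORE
    return scores


def align_basecalls(basecalls: str, reference: str,
                    identity_floor: float = 0.70) -> SiteMap:
    """Globally align basecalls to the reference and build a SiteMap.

    Affine gap scoring (first gapped column -5, each further -1); a gap
    of length L costs 5 + (L - 1).  Traceback ties prefer the diagonal,
    then a gap in the basecalls, then a gap in the reference, so the
    alignment is deterministic.

    Raises :class:`MappingFailure` when the fraction of IUPAC-matching
    aligned columns falls below ``identity_floor``.
    """
    basecalls = basecalls.upper()
    reference = reference.upper()
    if not basecalls or not reference:
        raise ValueError("both sequences must be non-empty")
    n, m = len(basecalls), len(reference)
    sub = _score_matrix(basecalls, reference)

    NEG = -1e30
    # M: call i aligned to ref j; Ix: gap in reference (call consumed);
    # Iy: gap in basecalls (ref consumed).  Indices are 1-based into seqs.
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -GAP_OPEN - GAP_EXTEND * (i - 1)
    for j in range(1, m + 1):
        Iy[0, j] = -GAP_OPEN - GAP_EXTEND * (j - 1)

    js = np.arange(1, m + 1)
    for i in range(1, n + 1):
        best_prev = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = best_prev[:-1] + sub[i - 1]
        Ix[i, 1:] = np.maximum(M[i - 1, 1:] - GAP_OPEN, Ix[i - 1, 1:] - GAP_EXTEND)
        Ix[i, 0] = -GAP_OPEN - GAP_EXTEND * (i - 1)
        # Iy[i, j] = max(M[i, j-1] - OPEN, Iy[i, j-1] - EXTEND) = the best
        # gap opened after any M[i, k] (k < j) minus its extensions; one
        # cumulative-maximum pass resolves the left-to-right dependency.
        cand = M[i, :-1] - GAP_OPEN + GAP_EXTEND * np.arange(m)
        running = np.maximum.accumulate(cand)
        Iy[i, 1:] = running - GAP_EXTEND * np.arange(m)

    # end-state tie preference mirrors the traceback preference:
    # diagonal, then gap-in-basecalls, then gap-in-reference.
    finals = {0: M[n, m], 2: Iy[n, m], 1: Ix[n, m]}
    score = max(finals.values())
    end_state = next(s for s in (0, 2, 1) if finals[s] == score)
    score = float(score)

    # Traceback with the documented tie preference.
    call_to_ref = {}
    unaligned_calls = []
    uncovered_ref = []
    matches = 0
    columns = 0
    i, j, state = n, m, end_state
    tol = 1e-9
    while i > 0 or j > 0:
        if state == 0:  # M
            if i == 0 or j == 0:
                raise RuntimeError("invalid traceback state")
            call_to_ref[i - 1] = j
            columns += 1
            if sub[i - 1, j - 1] == MATCH_SCORE:
                matches += 1
            target = M[i, j] - sub[i - 1, j - 1]
            i, j = i - 1, j - 1
            for cand_state, val in ((0, M[i, j]), (2, Iy[i, j]), (1, Ix[i, j])):
                if abs(val - target) <= tol:
                    state = cand_state
                    break
        elif state == 1:  # gap in reference: basecall i unaligned
            unaligned_calls.append(i - 1)
            columns += 1
            if i > 1 or j > 0:
                if abs(Ix[i, j] - (M[i - 1, j] - GAP_OPEN)) <= tol:
                    state = 0
                else:
                    state = 1
            i -= 1
        else:  # gap in basecalls: reference j uncovered
            uncovered_ref.append(j)
            columns += 1
            if j > 1 or i > 0:
                if abs(Iy[i, j] - (M[i, j - 1] - GAP_OPEN)) <= tol:
                    state = 0
                else:
                    state = 2
            j -= 1

    aligned = len(call_to_ref)
    identity = matches / aligned if aligned else 0.0
    if identity < identity_floor:
        raise MappingFailure(
            f"alignment identity {identity:.2%} below floor {identity_floor:.0%}")

    return SiteMap(
        call_to_ref=dict(sorted(call_to_ref.items())),
        unaligned_calls=sorted(unaligned_calls),
        uncovered_ref=sorted(uncovered_ref),
        identity=identity,
        score=score,
    )


def enumerate_candidates(reference: str, edit_mode: str) -> CandidateSites:
    """All 1-based reference positions carrying the substrate base."""
    if edit_mode not in SUBSTRATE_BASE:
        raise ValueError(f"unknown edit mode {edit_mode!r}")
    sub = SUBSTRATE_BASE[edit_mode]
    reference = reference.upper()
    positions = [i + 1 for i, b in enumerate(reference) if b == sub]
    return CandidateSites(
        edit_mode=edit_mode,
        positions=positions,
        ref_bases=[sub] * len(positions),
    )


def reverse_complement(seq: str) -> str:
    """Reverse complement with IUPAC ambiguity support (for reverse-primer reads)."""
    return seq.translate(_COMPLEMENT)[::-1]
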