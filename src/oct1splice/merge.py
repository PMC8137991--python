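"""Overlap-based merging of paired-end amplicon reads.

Amplicon fragments are shorter than twice the read length, so R1 and the
reverse complement of R2 overlap near-fully. The merger scans every overlap
length of at least ``min_overlap``, scores each candidate as
``matches - mismatches``, keeps the maximal score (ties broken toward the
longer overlap), and accepts the merge if the mismatch fraction inside the
overlap does not exceed ``max_mismatch_frac``. Disagreements are resolved
toward the higher-quality base, ties toward R1. Pairs without an acceptable
overlap are reported as unmerged, not raised.

Staggered overlaps (fragment shorter than a single read) are not modelled —
the simulator never emits them for amplicon geometries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .defaults import DEFAULT_MAX_MISMATCH_FRAC, DEFAULT_MIN_OVERLAP
from .refmodel import revcomp

MERGED = "merged"
UNMERGED = "unmerged"


@dataclass
class MergedRead:
    seq: str | None
    quals: str | None
    overlap_len: int
    n_overlap_mismatch: int
    status: str


def _to_mat(seqs: list[str]) -> np.ndarray:
    return np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(
        len(seqs), -1)


def _merge_uniform(r1: list[str], r2: list[str], q1: list[str],
                   q2: list[str], min_overlap: int,
                   max_mismatch_frac: float) -> list[MergedRead]:
    """Vectorised merge of pairs sharing read lengths (L1, L2)."""
    n = len(r1)
    a1 = _to_mat(r1)
    a2 = _to_mat([revcomp(s) for s in r2])         # fragment orientation
    qa1 = _to_mat(q1)
    qa2 = _to_mat([q[::-1] for q in q2])
    L1, L2 = a1.shape[1], a2.shape[1]

    vmax = min(L1, L2)
    if min_overlap > vmax:
        return [MergedRead(None, None, 0, 0, UNMERGED)] * n

    best_score = np.full(n, -np.inf)
    best_v = np.zeros(n, dtype=int)
    best_match = np.zeros(n, dtype=int)
    for v in range(min_overlap, vmax + 1):
        matches = (a1[:, L1 - v:] == a2[:, :v]).sum(axis=1)
        score = 2 * matches - v
        upd = score >= best_score          # >= prefers the longer overlap
        best_score[upd] = score[upd]
        best_v[upd] = v
        best_match[upd] = matches[upd]

    mism = best_v - best_match
    ok = mism <= max_mismatch_frac * best_v

    out: list[MergedRead] = []
    for i in range(n):
        v = int(best_v[i])
        if not ok[i]:
            out.append(MergedRead(None, None, v, int(mism[i]), UNMERGED))
            continue
        head = a1[i]
        tail = a2[i]
        take1 = qa1[i, L1 - v:] >= qa2[i, :v]      # tie -> R1
        cons = np.where(take1, head[L1 - v:], tail[:v])
        consq = np.maximum(qa1[i, L1 - v:], qa2[i, :v])
        seq = (head[: L1 - v].tobytes() + cons.tobytes()
               + tail[v:].tobytes()).decode()
        quals = (qa1[i, : L1 - v].tobytes() + consq.tobytes()
                 + qa2[i, v:].tobytes()).decode()
        out.append(MergedRead(seq, quals, v, int(mism[i]), MERGED))
    return out


def merge_pairs(r1: list[str], r2: list[str], q1: list[str] | None = None,
                q2: list[str] | None = None,
                min_overlap: int = DEFAULT_MIN_OVERLAP,
                max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
                ) -> list[MergedRead]:
    """Merge many pairs; groups by read-length combination internally."""
    if len(r1) != len(r2):
        raise ValueError("r1 and r2 must have equal length")
    if q1 is None:
        q1 = ["I" * len(s) for s in r1]
    if q2 is None:
        q2 = ["I" * len(s) for s in r2]
    groups: dict[tuple[int, int], list[int]] = {}
    for i, (a, b) in enumerate(zip(r1, r2)):
        if not a or not b:
            raise ValueError("reads must be non-empty")
        groups.setdefault((len(a), len(b)), []).append(i)
    out: list[MergedRead | None] = [None] * len(r1)
    for idx in groups.values():
        sub = _merge_uniform([r1[i] for i in idx], [r2[i] for i in idx],
                             [q1[i] for i in idx], [q2[i] for i in idx],
                             min_overlap, max_mismatch_frac)
        for i, m in zip(idx, sub):
            out[i] = m
    return out  # type: ignore[return-value]


def merge_pair(r1: str, r2: str, q1: str | None = None, q2: str | None = None,
               min_overlap: int = DEFAULT_MIN_OVERLAP,
               max_mismatch_frac: float = DEFAULT_MAX_MISMATCH_FRAC,
               ) -> MergedRead:
    """Merge a single pair (R2 given in sequencer orientation)."""
    return merge_pairs([r1], [r2], None if q1 is None else [q1],
                       None if q2 is None else [q2], min_overlap,
                       max_mismatch_frac)[0]
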