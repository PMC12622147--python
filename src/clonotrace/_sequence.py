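"""Small sequence primitives shared across modules.

Only substitution-aware comparisons are needed by the callers (simulated and
targeted reads carry no indels); Levenshtein is used for barcode merging.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = "ACGT"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Substitution distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def levenshtein(a: str, b: str, limit: int | None = None) -> int:
    """Edit distance with optional early-exit band.

    With ``limit`` set, any true distance > limit is reported as limit + 1,
    which is all the barcode merger needs.
    """
    if a == b:
        return 0
    la, lb = len(a), len(b)
    if limit is not None and abs(la - lb) > limit:
        return limit + 1
    prev = list(range(lb + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i] + [0] * lb
        best = i
        for j, cb in enumerate(b, start=1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            best = min(best, cur[j])
        if limit is not None and best > limit:
            return limit + 1
        prev = cur
    return prev[lb]


def encode(seq: str) -> np.ndarray:
    """Byte-encode a DNA string for vectorized window comparisons."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def best_window_distance(query: str, target: str) -> tuple[int, int]:
    """Minimal substitution distance of ``query`` over all full-length
    windows of ``target`` (query slides inside target).

    Returns (distance, offset). If the query is longer than the target the
    roles are swapped so the shorter string slides inside the longer one.
    """
    if len(query) > len(target):
        query, target = target, query
    q = encode(query)
    t = encode(target)
    n_win = len(t) - len(q) + 1
    windows = np.lib.stride_tricks.sliding_window_view(t, len(q))
    dists = (windows != q).sum(axis=1)
    off = int(dists.argmin())
    return int(dists[off]), off
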