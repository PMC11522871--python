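"""Independent brute-force reference implementations used only by tests.

These are written directly from the definitions (string comparisons,
explicit window enumeration, per-minimizer scoring loops) and share no
code with the package's array-based implementation.
"""

from __future__ import annotations

import math

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_VAL = {"A": 0, "C": 1, "G": 2, "T": 3}


def rc(seq: str) -> str:
    return "".join(_COMP.get(c, c) for c in reversed(seq))


def kmer_hash(kmer: str) -> int:
    h = 0
    for c in kmer:
        h = h * 4 + _VAL[c]
    return h


def brute_force_minimizers(seq: str, k: int) -> set[int]:
    """Enumerate every window, list its canonical k-mers, take the minimum."""
    seq = seq.upper()
    n_pos = len(seq) - k + 1
    if n_pos <= 0:
        return set()
    canon: list[str | None] = []
    for j in range(n_pos):
        km = seq[j : j + k]
        if any(c not in "ACGT" for c in km):
            canon.append(None)
        else:
            canon.append(min(km, rc(km)))
    windows = []
    for j in range(n_pos - k + 1):  # interior: k consecutive k-mers
        windows.append(canon[j : j + k])
    for size in range(1, min(k - 1, n_pos) + 1):  # anchored end windows
        windows.append(canon[:size])
        windows.append(canon[n_pos - size :])
    out: set[int] = set()
    for win in windows:
        valid = [c for c in win if c is not None]
        if valid:
            out.add(kmer_hash(min(valid)))
    return out


def naive_classify(
    read_seq: str,
    genomes: dict[str, tuple[set[int], int]],
    k: int,
    mu: float,
    phi: float,
    theta: float,
) -> tuple[list[str], dict[str, float]]:
    """Naive scoring pipeline straight from the definitions.

    ``genomes`` maps genome_id -> (minimizer hash set, total k-mer count).
    Returns (candidate genome ids, scores of genomes passing mu).
    """
    read_mins = brute_force_minimizers(read_seq, k)
    if not read_mins:
        return [], {}
    scores: dict[str, float] = {}
    for gid, (mins, count) in genomes.items():
        shared = read_mins & mins
        if len(shared) == 0:
            continue
        if len(shared) / len(read_mins) < mu:
            continue
        score = 0.0
        for z in read_mins:
            score += math.log(1.0 / count) if z in mins else phi
        scores[gid] = score
    if not scores:
        return [], {}
    distinct = sorted(set(scores.values()), reverse=True)
    kept_values = [distinct[0]]
    for prev, nxt in zip(distinct, distinct[1:]):
        if prev - nxt > theta:
            break
        kept_values.append(nxt)
    candidates = [g for g, s in scores.items() if s in kept_values]
    return sorted(candidates), scores
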