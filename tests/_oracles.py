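"""Small independent oracles used to check the implementations.

Everything here is deliberately naive — exhaustive enumeration or direct
transcription of the defining formula — and shares no code with the
package internals it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def naive_fasta_parse(text: str) -> list[tuple[str, str]]:
    """Two-pass FASTA parser: (id, seq) per header, multi-line concatenated."""
    records = []
    header = None
    chunks: list[str] = []
    for line in text.splitlines():
        if line.startswith(">"):
            if header is not None:
                records.append((header, "".join(chunks)))
            header = line[1:].split()[0]
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    if header is not None:
        records.append((header, "".join(chunks)))
    return records


def brute_force_global_score(a: str, b: str, gap_open: float = 11.0,
                             gap_extend: float = 1.0) -> float:
    """Best global affine-gap alignment score by exhaustive enumeration.

    A gap run of length L costs gap_open + gap_extend * L; terminal gaps
    are penalized. Only practical for len(a), len(b) <= ~6.
    """

    def substitution(x: str, y: str) -> float:
        return float(_BLOSUM62[x][y])

    best = -math.inf

    def score_alignment(cols: list[tuple[str, str]]) -> float:
        total = 0.0
        for row in (0, 1):
            run = 0
            for col in cols:
                if col[row] == "-":
                    run += 1
                else:
                    if run:
                        total -= gap_open + gap_extend * run
                    run = 0
            if run:
                total -= gap_open + gap_extend * run
        total += sum(substitution(x, y) for x, y in cols
                     if x != "-" and y != "-")
        return total

    def rec(i: int, j: int, cols: list[tuple[str, str]]) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score_alignment(cols))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, cols + [(a[i], b[j])])
        if i < len(a):
            rec(i + 1, j, cols + [(a[i], "-")])
        if j < len(b):
            rec(i, j + 1, cols + [("-", b[j])])

    rec(0, 0, [])
    return best


def brute_force_viterbi(profile, seq: str) -> float:
    """Best log2-odds state path by exhaustive recursion over M/I/D paths."""
    from mermine.profile import AA_INDEX, _STATES

    n = profile.n_columns
    with np.errstate(divide="ignore"):
        lt = {s: np.log2(profile.trans[s]) for s in _STATES}
    lo = profile.match_logodds
    L = len(seq)
    best = [-np.inf]

    def rec(state: str, i: int, j: int, sc: float) -> None:
        if j == n and i == L:
            best[0] = max(best[0], sc + lt[state][n, 0])
        if j < n and i < L:
            emit = 0.0 if seq[i] not in AA_INDEX else lo[j, AA_INDEX[seq[i]]]
            rec("M", i + 1, j + 1, sc + lt[state][j, 0] + emit)
        if i < L:
            rec("I", i + 1, j, sc + lt[state][j, 1])
        if j < n:
            rec("D", i, j + 1, sc + lt[state][j, 2])

    rec("M", 0, 0, 0.0)
    return float(best[0])


def exhaustive_mantel_p(d1: np.ndarray, d2: np.ndarray,
                        alternative: str = "greater") -> tuple[float, float]:
    """Mantel r and exact p over all n! simultaneous permutations of d2."""
    n = d1.shape[0]
    iu = np.triu_indices(n, k=1)
    x = d1[iu]

    def corr(perm) -> float:
        p = np.asarray(perm)
        return float(np.corrcoef(x, d2[np.ix_(p, p)][iu])[0, 1])

    r_obs = corr(range(n))
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = corr(perm)
        total += 1
        if alternative == "greater":
            count += r >= r_obs
        else:
            count += abs(r) >= abs(r_obs)
    return r_obs, count / total


def anderson_pseudo_f(d: np.ndarray, labels) -> float:
    """Pseudo-F computed directly from the defining sums of squares."""
    labels = np.asarray(labels)
    n = len(labels)
    d2 = d ** 2
    ss_total = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        ss_within += sum(d2[i, j] for i in idx for j in idx if i < j) / len(idx)
    a = len(np.unique(labels))
    return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))


def exhaustive_permanova_p(d: np.ndarray, labels) -> tuple[float, float]:
    """Pseudo-F and exact p over all distinct label arrangements."""
    labels = list(labels)
    f_obs = anderson_pseudo_f(d, labels)
    seen = set()
    count = 0
    for perm in itertools.permutations(labels):
        if perm in seen:
            continue
        seen.add(perm)
        count += anderson_pseudo_f(d, perm) >= f_obs
    return f_obs, count / len(seen)


def naive_greedy_catalog(genes, t_id: float, t_cov: float):
    """Reference greedy clustering: length-descending order, first-fit
    representative assignment, using the package's pairwise measure only."""
    from mermine.catalog import pairwise_identity

    ordered = sorted(genes, key=lambda g: (-len(g.seq), g.id))
    reps: list = []
    members: dict[str, list[str]] = {}
    for g in ordered:
        for r in reps:
            ident, cov = pairwise_identity(r, g)
            if ident >= t_id and cov >= t_cov:
                members[r.id].append(g.id)
                break
        else:
            reps.append(g)
            members[g.id] = [g.id]
    return members
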