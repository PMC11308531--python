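"""Profile hidden Markov models for mer-family search.

A profile is built from a star alignment of seed proteins against the
family reference: reference residues define the match columns, seed
insertions relative to the reference are projected into insert states,
and seed gaps into delete states. Scoring is plain Viterbi in log2 space
("Plan7-lite"): begin -> (M/I/D)^n -> end, no local-alignment flanking
states, because candidates are full-length predicted genes. Match
emissions are scored as log-odds against a background distribution
(uniform by default), insert emissions score zero, and transition
probabilities are estimated from the seed alignment with pseudocounts.

This is deliberately not HMMER-compatible: no E-values, no glocal/local
modes, and a simpler transition topology in which all nine M/I/D
transitions are permitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import AMINO_ACIDS, SequenceRecord
from .verifier import global_align

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
_STATES = ("M", "I", "D")
_NEG_INF = -np.inf

DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class StarAlignment:
    """Seeds aligned to reference columns.

    ``rows[r][j]`` is the residue of seed r at reference column j+1 (or
    '-' for a deletion); ``insertions[r][j]`` holds residues of seed r
    inserted between reference columns j and j+1 (j=0 means before the
    first column).
    """

    reference: SequenceRecord
    seed_ids: list[str]
    rows: list[str]
    insertions: list[dict[int, str]]

    @property
    def n_columns(self) -> int:
        return len(self.reference)


def build_seed_alignment(
    seeds: list[SequenceRecord], reference: SequenceRecord
) -> StarAlignment:
    """Star-align every seed globally against the reference.

    Columns are defined by reference positions; the reference is ungapped
    in its own coordinate system, so the column count always equals the
    reference length.
    """
    if len(seeds) < 2:
        raise ValueError("need at least 2 seed sequences")
    for s in seeds:
        if s.alphabet != reference.alphabet:
            raise ValueError(f"seed {s.id!r} alphabet differs from reference")
    rows: list[str] = []
    insertions: list[dict[int, str]] = []
    for seed in seeds:
        aln = global_align(reference, seed)
        row = []
        ins: dict[int, str] = {}
        col = 0  # last reference column consumed
        for r, c in zip(aln.ref_aln, aln.cand_aln):
            if r != "-":
                col += 1
                row.append(c)
            else:  # seed residue inserted after reference column `col`
                ins[col] = ins.get(col, "") + c
        rows.append("".join(row))
        insertions.append(ins)
    return StarAlignment(reference=reference, seed_ids=[s.id for s in seeds],
                         rows=rows, insertions=insertions)


@dataclass
class ProfileHMM:
    """Position-specific match/insert/delete model over 20 amino acids.

    ``match_probs[j]`` is the emission distribution of match state j+1;
    ``trans[s][j, d]`` the probability of moving from state s at boundary
    j (between columns j and j+1; boundary 0 leaves the begin state,
    boundary n enters the end state) to destination d in (M, I, D).
    """

    name: str
    match_probs: np.ndarray      # (n_columns, 20)
    trans: dict[str, np.ndarray]  # each (n_columns + 1, 3)
    background: np.ndarray       # (20,)
    threshold_bits: float = 0.0

    @property
    def n_columns(self) -> int:
        return self.match_probs.shape[0]

    @property
    def match_logodds(self) -> np.ndarray:
        return np.log2(self.match_probs) - np.log2(self.background)

    def consensus(self) -> SequenceRecord:
        seq = "".join(AA_ORDER[i] for i in self.match_probs.argmax(axis=1))
        return SequenceRecord(id=f"{self.name}_consensus", seq=seq)


@dataclass(frozen=True)
class ProfileHit:
    seq_id: str
    bit_score: float
    viterbi_path: str
    passed: bool


def build_profile(
    msa: StarAlignment,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: np.ndarray | None = None,
    name: str | None = None,
) -> ProfileHMM:
    """Estimate a ProfileHMM from a star alignment.

    Match emissions per column are ``(count + pseudocount) /
    (column total + 20 * pseudocount)``; transition probabilities get the
    same pseudocount per permitted transition. ``X`` residues are skipped
    when counting emissions.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if not msa.rows:
        raise ValueError("empty alignment")
    n = msa.n_columns
    if background is None:
        background = np.full(20, 1.0 / 20)
    background = np.asarray(background, dtype=float)

    counts = np.zeros((n, 20))
    for row in msa.rows:
        for j, c in enumerate(row):
            if c in AA_INDEX:
                counts[j, AA_INDEX[c]] += 1
    match_probs = (counts + pseudocount) / (
        counts.sum(axis=1, keepdims=True) + 20 * pseudocount
    )

    # transition counts per boundary; destinations ordered (M, I, D)
    tcounts = {s: np.zeros((n + 1, 3)) for s in _STATES}
    for row, ins in zip(msa.rows, msa.insertions):
        states = ["M"] + ["M" if c != "-" else "D" for c in row] + ["M"]
        for j in range(n + 1):
            k = len(ins.get(j, ""))
            src, dst = states[j], states[j + 1]
            if k == 0:
                tcounts[src][j, _STATES.index(dst)] += 1
            else:
                tcounts[src][j, 1] += 1           # src -> I
                tcounts["I"][j, 1] += k - 1       # I -> I
                tcounts["I"][j, _STATES.index(dst)] += 1

    trans = {}
    for s in _STATES:
        c = tcounts[s] + pseudocount
        c[n, 2] = 0.0  # no delete state beyond the last column
        trans[s] = c / c.sum(axis=1, keepdims=True)

    return ProfileHMM(name=name or f"{msa.reference.id}_profile",
                      match_probs=match_probs, trans=trans,
                      background=background)


def viterbi_score(profile: ProfileHMM, seq: SequenceRecord) -> ProfileHit:
    """Best-path log2-odds score of a protein sequence under the profile.

    The score sums log2 transition probabilities along the path plus
    per-residue match log-odds against the background (insert emissions
    and ``X`` residues contribute zero). Deterministic; ties in the
    dynamic program are resolved in fixed M > I > D order.
    """
    if seq.alphabet != "protein":
        raise ValueError("profile scoring requires a protein sequence")
    L, n = len(seq), profile.n_columns
    if L < 1:
        raise ValueError("empty sequence")
    with np.errstate(divide="ignore"):
        lt = {s: np.log2(profile.trans[s]) for s in _STATES}
        lo = profile.match_logodds
    res_idx = np.array([AA_INDEX.get(c, -1) for c in seq.seq])

    # V[s][i, j]: best score of a path ending in state s at column j having
    # emitted i residues. Columns j=0..n (M at j=0 is the begin state; the
    # end state is entered via the "to M" transition at boundary n).
    M = np.full((L + 1, n + 1), _NEG_INF)
    I = np.full((L + 1, n + 1), _NEG_INF)
    D = np.full((L + 1, n + 1), _NEG_INF)
    # traceback: 0=M, 1=I, 2=D, -1=none
    bM = np.full((L + 1, n + 1), -1, dtype=np.int8)
    bI = np.full((L + 1, n + 1), -1, dtype=np.int8)
    bD = np.full((L + 1, n + 1), -1, dtype=np.int8)

    M[0, 0] = 0.0
    tMM, tMI, tMD = (lt["M"][:, 0], lt["M"][:, 1], lt["M"][:, 2])
    tIM, tII, tID = (lt["I"][:, 0], lt["I"][:, 1], lt["I"][:, 2])
    tDM, tDI, tDD = (lt["D"][:, 0], lt["D"][:, 1], lt["D"][:, 2])
    tMD_l, tID_l, tDD_l = tMD.tolist(), tID.tolist(), tDD.tolist()

    def d_scan(i: int) -> None:
        """Within-row delete scan: D[i, j] depends on D[i, j-1]."""
        Mi, Ii = M[i].tolist(), I[i].tolist()
        Di = [_NEG_INF] * (n + 1)
        bDi = bD[i]
        prev = _NEG_INF
        for j in range(1, n + 1):
            c0 = Mi[j - 1] + tMD_l[j - 1]
            c1 = Ii[j - 1] + tID_l[j - 1]
            c2 = prev + tDD_l[j - 1]
            if c0 >= c1 and c0 >= c2:
                prev, bDi[j] = c0, 0
            elif c1 >= c2:
                prev, bDi[j] = c1, 1
            else:
                prev, bDi[j] = c2, 2
            Di[j] = prev
        D[i] = Di

    d_scan(0)
    for i in range(1, L + 1):
        ri = res_idx[i - 1]
        emit = np.zeros(n) if ri < 0 else lo[:, ri]
        cand = np.stack((M[i - 1, :n] + tMM[:n], I[i - 1, :n] + tIM[:n],
                         D[i - 1, :n] + tDM[:n]))
        bM[i, 1:] = cand.argmax(axis=0)
        M[i, 1:] = cand.max(axis=0) + emit
        cand = np.stack((M[i - 1] + tMI, I[i - 1] + tII, D[i - 1] + tDI))
        bI[i] = cand.argmax(axis=0)
        I[i] = cand.max(axis=0)
        d_scan(i)

    final = (M[L, n] + lt["M"][n, 0], I[L, n] + lt["I"][n, 0],
             D[L, n] + lt["D"][n, 0])
    k = int(np.argmax(final))
    score = float(final[k])

    # traceback
    path = []
    state, i, j = k, L, n
    while not (state == 0 and i == 0 and j == 0):
        path.append(_STATES[state])
        if state == 0:
            prev = bM[i, j]
            i, j = i - 1, j - 1
        elif state == 1:
            prev = bI[i, j]
            i = i - 1
        else:
            prev = bD[i, j]
            j = j - 1
        state = int(prev)
    path.reverse()
    return ProfileHit(seq_id=seq.id, bit_score=score,
                      viterbi_path="".join(path),
                      passed=score >= profile.threshold_bits)


def calibrate_threshold(family_scores, decoy_scores) -> float:
    """Midpoint between the lowest true-family score and the highest decoy
    score; used when no curated gathering threshold exists."""
    return 0.5 * (min(family_scores) + max(decoy_scores))


def search(
    profile: ProfileHMM,
    candidates: list[SequenceRecord],
    threshold_bits: float | None = None,
) -> list[ProfileHit]:
    """Score candidates against the profile, best first.

    Hits are sorted by bit score descending with lexicographic seq-id
    tie-break; ``passed`` marks scores at or above the threshold.
    """
    thr = profile.threshold_bits if threshold_bits is None else threshold_bits
    if not np.isfinite(thr):
        raise ValueError("threshold must be finite")
    hits = []
    for c in candidates:
        h = viterbi_score(profile, c)
        hits.append(ProfileHit(seq_id=h.seq_id, bit_score=h.bit_score,
                               viterbi_path=h.viterbi_path,
                               passed=h.bit_score >= thr))
    return sorted(hits, key=lambda h: (-h.bit_score, h.seq_id))


# ---------------------------------------------------------------------------
# TSV serialization (long format: section, state, boundary/column, key, value)
# ---------------------------------------------------------------------------


def save_profile(profile: ProfileHMM, path) -> None:
    rows = [("meta", "", -1, "name", profile.name),
            ("meta", "", -1, "threshold_bits", profile.threshold_bits)]
    for a, b in zip(AA_ORDER, profile.background):
        rows.append(("background", "", -1, a, b))
    for j in range(profile.n_columns):
        for a in AA_ORDER:
            rows.append(("emission", "M", j + 1, a, profile.match_probs[j, AA_INDEX[a]]))
    for s in _STATES:
        for j in range(profile.n_columns + 1):
            for d_i, d in enumerate(_STATES):
                rows.append(("transition", s, j, d, profile.trans[s][j, d_i]))
    pd.DataFrame(rows, columns=["section", "state", "index", "key", "value"]).to_csv(
        path, sep="\t", index=False)


def load_profile(path) -> ProfileHMM:
    df = pd.read_csv(path, sep="\t", dtype={"key": str})
    meta = df[df.section == "meta"].set_index("key")["value"]
    em = df[df.section == "emission"]
    n = int(em["index"].max())
    match_probs = np.zeros((n, 20))
    for _, r in em.iterrows():
        match_probs[int(r["index"]) - 1, AA_INDEX[r["key"]]] = float(r["value"])
    trans = {s: np.zeros((n + 1, 3)) for s in _STATES}
    for _, r in df[df.section == "transition"].iterrows():
        trans[r["state"]][int(r["index"]), _STATES.index(r["key"])] = float(r["value"])
    bg = df[df.section == "background"].sort_values("key")
    background = np.array([float(bg[bg.key == a]["value"].iloc[0]) for a in AA_ORDER])
    return ProfileHMM(name=str(meta["name"]), match_probs=match_probs, trans=trans,
                      background=background,
                      threshold_bits=float(meta["threshold_bits"]))
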