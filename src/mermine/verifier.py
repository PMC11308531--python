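"""Reference-anchored verification of essential catalytic residues.

The verifier aligns each candidate protein globally against the family
reference (mercuric reductase or organomercurial lyase), maps each
reference-numbered rule position through the alignment onto the candidate,
and checks the observed candidate residue against the rule's allowed set.
A candidate is accepted only if every applicable rule passes; a rule whose
reference column aligns to a gap in the candidate fails.

Alignment is true global by default (terminal gaps penalized), so fragment
candidates that do not span a rule position are rejected rather than
silently passed; ``semiglobal=True`` waives terminal gap penalties for
users screening known fragments.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import ResidueRule, ResidueRuleTable, SequenceRecord

#: standard protein alignment parameters (BLOSUM62, affine gaps)
PROTEIN_GAP_OPEN = 11.0
PROTEIN_GAP_EXTEND = 1.0
#: nucleotide alignment parameters (match/mismatch +1/-1, affine gaps)
DNA_MATCH = 1.0
DNA_MISMATCH = -1.0
DNA_GAP_OPEN = 5.0
DNA_GAP_EXTEND = 1.0


@dataclass(frozen=True)
class Alignment:
    """A pairwise global alignment as two equal-length gapped strings.

    A gap of length L costs ``gap_open + gap_extend * L``.
    """

    ref_aln: str
    cand_aln: str
    score: float
    identity: float

    def __post_init__(self) -> None:
        if len(self.ref_aln) != len(self.cand_aln):
            raise ValueError("aligned rows differ in length")
        if any(a == "-" and b == "-" for a, b in zip(self.ref_aln, self.cand_aln)):
            raise ValueError("alignment has a column gapped in both rows")


@dataclass(frozen=True)
class RuleCheck:
    """Outcome of one residue rule on one candidate."""

    rule: ResidueRule
    mapped_cand_pos: int | None
    observed: str  # residue letter, or "-" for a gap
    passed: bool


@dataclass(frozen=True)
class VerificationReport:
    """Per-candidate verdict with one check per applicable rule."""

    seq_id: str
    family: str
    taxon_flag: str
    checks: tuple[RuleCheck, ...]
    verdict: bool

    @property
    def failed_positions(self) -> list[int]:
        return [c.rule.ref_pos for c in self.checks if not c.passed]


@lru_cache(maxsize=8)
def _make_aligner(alphabet: str, gap_open: float, gap_extend: float,
                  semiglobal: bool) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if alphabet == "protein":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    else:
        aligner.match_score = DNA_MATCH
        aligner.mismatch_score = DNA_MISMATCH
    # Biopython charges open_gap_score for the first gapped position and
    # extend_gap_score thereafter; shift so a length-L gap costs open + L*extend.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    if semiglobal:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    return aligner


def _identity_and_coverage(ref_aln: str, cand_aln: str) -> tuple[float, float]:
    """Identity over the core (non-terminal-gap) columns, and coverage of
    the shorter sequence by that core region."""
    both = [i for i, (a, b) in enumerate(zip(ref_aln, cand_aln))
            if a != "-" and b != "-"]
    if not both:  # no column with residues in both rows
        return 0.0, 0.0
    first, last = both[0], both[-1]
    core_ref = ref_aln[first:last + 1]
    core_cand = cand_aln[first:last + 1]
    matches = sum(a == b and a != "-" for a, b in zip(core_ref, core_cand))
    identity = matches / len(core_ref)
    len_ref = len(ref_aln.replace("-", ""))
    len_cand = len(cand_aln.replace("-", ""))
    shorter_row = core_ref if len_ref <= len_cand else core_cand
    span = len(shorter_row.replace("-", ""))
    coverage = span / min(len_ref, len_cand)
    return identity, coverage


def global_align(
    a: SequenceRecord,
    b: SequenceRecord,
    gap_open: float | None = None,
    gap_extend: float | None = None,
    semiglobal: bool = False,
) -> Alignment:
    """Optimal global (Needleman-Wunsch, affine-gap) alignment of ``a`` vs ``b``.

    Proteins are scored with BLOSUM62 (gap open 11, extend 1 by default),
    nucleotides with +1/-1 match/mismatch (gap open 5, extend 1).
    Deterministic: ties between co-optimal alignments are broken by the
    aligner's fixed traceback order.
    """
    if a.alphabet != b.alphabet:
        raise ValueError(f"alphabet mismatch: {a.alphabet} vs {b.alphabet}")
    if gap_open is None:
        gap_open = PROTEIN_GAP_OPEN if a.alphabet == "protein" else DNA_GAP_OPEN
    if gap_extend is None:
        gap_extend = PROTEIN_GAP_EXTEND if a.alphabet == "protein" else DNA_GAP_EXTEND
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap penalties must be positive")
    aligner = _make_aligner(a.alphabet, gap_open, gap_extend, semiglobal)
    aln = aligner.align(a.seq, b.seq)[0]
    ref_aln, cand_aln = str(aln[0]), str(aln[1])
    identity, _ = _identity_and_coverage(ref_aln, cand_aln)
    return Alignment(ref_aln=ref_aln, cand_aln=cand_aln, score=float(aln.score),
                     identity=identity)


def map_reference_position(aln: Alignment, ref_pos: int) -> int | None:
    """Map a 1-based reference position through the alignment.

    Returns the 1-based candidate coordinate aligned to reference position
    ``ref_pos``, or ``None`` when that column is a gap in the candidate.
    """
    ref_len = len(aln.ref_aln.replace("-", ""))
    if not 1 <= ref_pos <= ref_len:
        raise ValueError(f"reference position {ref_pos} outside 1..{ref_len}")
    ref_count = 0
    cand_count = 0
    for r, c in zip(aln.ref_aln, aln.cand_aln):
        if c != "-":
            cand_count += 1
        if r != "-":
            ref_count += 1
            if ref_count == ref_pos:
                return cand_count if c != "-" else None
    raise AssertionError("unreachable: ref_pos within ungapped length")


def verify_candidate(
    candidate: SequenceRecord,
    reference: SequenceRecord,
    rules: ResidueRuleTable,
    taxon_flag: str = "bacteria",
    semiglobal: bool = False,
) -> VerificationReport:
    """Check a candidate against the family's essential-residue rules.

    The candidate is globally aligned to the reference once; each rule
    applicable under ``taxon_flag`` is then evaluated at its mapped
    position. ``X`` (ambiguous residue) never satisfies a rule, and a rule
    position aligned to a candidate gap fails.
    """
    rules.validate_against_reference(reference)
    aln = global_align(reference, candidate, semiglobal=semiglobal)
    checks = []
    for rule in rules.applicable(taxon_flag):
        pos = map_reference_position(aln, rule.ref_pos)
        if pos is None:
            checks.append(RuleCheck(rule=rule, mapped_cand_pos=None,
                                    observed="-", passed=False))
        else:
            observed = candidate.seq[pos - 1]
            checks.append(RuleCheck(rule=rule, mapped_cand_pos=pos,
                                    observed=observed,
                                    passed=observed in rule.allowed))
    verdict = all(c.passed for c in checks)
    return VerificationReport(seq_id=candidate.id, family=rules.family,
                              taxon_flag=taxon_flag, checks=tuple(checks),
                              verdict=verdict)
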