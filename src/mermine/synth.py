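"""Seedable generators for every input the pipeline consumes.

Everything the real pipeline reads from sequencing projects — diverged
mer-family proteins (with or without intact catalytic residues), decoy
paralogs, nucleotide genes, short reads, count matrices with varying
library sizes and single-copy-gene signal, and environmental gradients
coupled to community composition — can be produced here from a seed, so
the whole package is testable without downloads. Every generator returns
its ground truth alongside the data (planted rule violations, true
per-cell copy numbers, the latent gradient).

A synthetic reference pair ships as packaged fixtures: a mercuric-
reductase-like protein of realistic length (631 aa) and an
organomercurial-lyase-like protein (212 aa), each carrying the canonical
catalytic residues at the canonical positions. They are stand-ins
generated from a random background, not the deposited reference
sequences; users analysing real data should supply the real references.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .seqio import (
    AMINO_ACIDS,
    CountMatrix,
    ResidueRuleTable,
    SampleMetadata,
    SequenceRecord,
    load_rule_table,
    read_fasta,
)

AA = sorted(AMINO_ACIDS)
DNA = list("ACGT")

#: residues on each side of a rule position kept free of indels
INDEL_RULE_MARGIN = 8


def load_synthetic_reference(family: str) -> SequenceRecord:
    """Load the packaged synthetic reference protein for merA or merB."""
    if family not in ("merA", "merB"):
        raise ValueError(f"no synthetic reference for family {family!r}")
    path = resources.files("mermine.data.references") / f"synthetic_{family}.faa"
    return read_fasta(str(path))[0]


# ---------------------------------------------------------------------------
# Family simulation
# ---------------------------------------------------------------------------


@dataclass
class FamilySimSpec:
    """Parameters for simulating a diverged gene family.

    With ``preserve_rules=True`` no mutation or indel ever touches a rule
    position, so every variant keeps the catalytic residues. With
    ``preserve_rules=False`` each variant carries exactly one planted
    rule-site violation (cycled over the applicable rules); all other rule
    positions stay intact, giving clean single-violation decoys.
    """

    reference: SequenceRecord
    n_variants: int = 20
    sub_rate: float = 0.1
    indel_rate: float = 0.01
    preserve_rules: bool = True
    rule_table: ResidueRuleTable | None = None
    taxon_flag: str = "bacteria"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.sub_rate < 1.0 or self.indel_rate < 0:
            raise ValueError("mutation rates out of range")
        if self.sub_rate > 0.7:
            raise ValueError(
                f"sub_rate={self.sub_rate} gives expected identity < 0.3; "
                "variants would be unalignable"
            )
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")


def simulate_family(spec: FamilySimSpec) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Generate diverged variants of the reference.

    Returns ``(records, truth)`` where ``truth`` has one row per variant
    with the planted violation position and the disallowed residue used
    (both null when ``preserve_rules`` is set).
    """
    rng = np.random.default_rng(spec.seed)
    alphabet = spec.reference.alphabet
    letters = AA if alphabet == "protein" else DNA
    ref = spec.reference.seq
    rules = (spec.rule_table.applicable(spec.taxon_flag)
             if spec.rule_table is not None else [])
    protected = ({r.ref_pos - 1 for r in spec.rule_table.rules}
                 if spec.rule_table is not None else set())
    # indels keep a margin around rule sites: a gap placed next to a rule
    # position makes the alignment-mapped residue there ambiguous, which
    # would corrupt the planted ground truth in either direction
    indel_excluded = {i + d for i in protected
                      for d in range(-INDEL_RULE_MARGIN, INDEL_RULE_MARGIN + 1)}

    records: list[SequenceRecord] = []
    truth_rows = []
    for v in range(spec.n_variants):
        seq = list(ref)
        planted_pos: int | None = None
        planted_res: str | None = None
        if not spec.preserve_rules:
            if not rules:
                raise ValueError("decoy simulation needs a rule table")
            rule = rules[v % len(rules)]
            bad = [a for a in letters if a not in rule.allowed]
            planted_res = bad[rng.integers(len(bad))]
            planted_pos = rule.ref_pos
            seq[rule.ref_pos - 1] = planted_res
        # substitutions everywhere except rule sites
        for i in range(len(seq)):
            if i in protected or (planted_pos is not None and i == planted_pos - 1):
                continue
            if rng.random() < spec.sub_rate:
                choices = [a for a in letters if a != seq[i]]
                seq[i] = choices[rng.integers(len(choices))]
        # indels (geometric length, p = 0.5), never overlapping rule sites
        if spec.indel_rate > 0:
            ops = []
            for i in range(len(seq)):
                if rng.random() < spec.indel_rate:
                    length = int(rng.geometric(0.5))
                    kind = "ins" if rng.random() < 0.5 else "del"
                    if kind == "del":
                        span = set(range(i, min(i + length, len(seq))))
                        if span & indel_excluded:
                            continue
                    elif i in indel_excluded:
                        continue
                    ops.append((i, kind, length))
            for i, kind, length in reversed(ops):
                if kind == "ins":
                    insert = [letters[rng.integers(len(letters))]
                              for _ in range(length)]
                    seq[i:i] = insert
                elif len(seq) - len(seq[i:i + length]) >= 1:
                    del seq[i:i + length]
        rec_id = (f"{spec.reference.id}_var{v:03d}" if spec.preserve_rules
                  else f"{spec.reference.id}_decoy{v:03d}")
        records.append(SequenceRecord(id=rec_id, seq="".join(seq),
                                      alphabet=alphabet))
        truth_rows.append((rec_id, planted_pos, planted_res))
    truth = pd.DataFrame(truth_rows,
                         columns=["seq_id", "violated_pos", "planted_residue"])
    return records, truth


def simulate_mer_family(
    family: str = "merA",
    n_variants: int = 20,
    sub_rate: float = 0.1,
    indel_rate: float = 0.01,
    preserve_rules: bool = True,
    seed: int | None = None,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Convenience wrapper using the packaged synthetic reference and the
    built-in rule table of the family."""
    spec = FamilySimSpec(reference=load_synthetic_reference(family),
                         n_variants=n_variants, sub_rate=sub_rate,
                         indel_rate=indel_rate, preserve_rules=preserve_rules,
                         rule_table=load_rule_table(family), seed=seed)
    return simulate_family(spec)


# ---------------------------------------------------------------------------
# Nucleotide genes and reads
# ---------------------------------------------------------------------------


def simulate_dna_genes(
    n_genes: int,
    length: int = 900,
    seed: int | None = None,
    gene_prefix: str = "gene",
) -> list[SequenceRecord]:
    """Independent random nucleotide genes (mutually ~75% divergent)."""
    rng = np.random.default_rng(seed)
    return [
        SequenceRecord(
            id=f"{gene_prefix}{i:03d}",
            seq="".join(rng.choice(DNA, size=length)),
            alphabet="dna",
        )
        for i in range(n_genes)
    ]


def simulate_reads(
    gene: SequenceRecord,
    n_reads: int,
    read_len: int = 100,
    error_rate: float = 0.0,
    seed: int | None = None,
) -> list[SequenceRecord]:
    """Short reads from uniform start positions with per-base substitutions."""
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if read_len > len(gene):
        raise ValueError(f"read_len {read_len} exceeds gene length {len(gene)}")
    rng = np.random.default_rng(seed)
    letters = DNA if gene.alphabet == "dna" else AA
    reads = []
    for r in range(n_reads):
        start = int(rng.integers(0, len(gene) - read_len + 1))
        seq = list(gene.seq[start:start + read_len])
        if error_rate > 0:
            for i in range(read_len):
                if rng.random() < error_rate:
                    choices = [a for a in letters if a != seq[i]]
                    seq[i] = choices[rng.integers(len(choices))]
        reads.append(SequenceRecord(id=f"{gene.id}_read{r:05d}",
                                    seq="".join(seq), alphabet=gene.alphabet))
    return reads


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------


@dataclass
class CommunitySimSpec:
    """Parameters for simulating effective-count tables.

    Library sizes are log-normal; the three SCG counts track library size
    (each cell carries one copy), and each mer gene's counts are negative
    binomial with mean rho * SCG-mean, rho being the per-cell copy number
    to recover. Background genes receive sample-varying means along a
    latent gradient of strength ``env_gradient_strength`` so the
    community composition has structure for the ordination and the
    permutation tests to find.
    """

    n_samples: int = 20
    mer_rho: dict[str, float] = field(default_factory=lambda: {"merA": 0.25,
                                                               "merB": 0.05})
    n_background_genes: int = 30
    library_log_mean: float = np.log(1e5)
    library_log_sigma: float = 0.5
    scg_fraction: float = 0.01
    nb_size: float = 10.0
    env_gradient_strength: float = 0.0
    assay: str = "metaG"
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.mer_rho.values()):
            raise ValueError("per-cell copy numbers must be >= 0")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")


def _nbinom(rng: np.random.Generator, mean: np.ndarray, size: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=float)
    pos = mean > 0
    p = size / (size + mean[pos])
    out[pos] = rng.negative_binomial(size, p)
    return out


def simulate_counts(spec: CommunitySimSpec) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate an effective-count table plus its ground-truth table.

    Returns ``(counts, truth)``; ``truth`` holds per-sample library size,
    SCG mean, the latent gradient value, and the true rho of each mer gene.
    """
    rng = np.random.default_rng(spec.seed)
    samples = [f"S{i:02d}" for i in range(spec.n_samples)]
    lib = rng.lognormal(spec.library_log_mean, spec.library_log_sigma,
                        size=spec.n_samples)
    scg_mean = lib * spec.scg_fraction
    gradient = np.linspace(-1.0, 1.0, spec.n_samples)

    rows = {}
    for scg in ("recA", "rpoB", "gyrB"):
        rows[scg] = _nbinom(rng, scg_mean, spec.nb_size)
    for gene, rho in spec.mer_rho.items():
        rows[gene] = _nbinom(rng, rho * scg_mean, spec.nb_size)
    beta = rng.standard_normal(spec.n_background_genes)
    base = rng.lognormal(np.log(0.1), 1.0, size=spec.n_background_genes)
    for g in range(spec.n_background_genes):
        mean = base[g] * scg_mean * np.exp(
            spec.env_gradient_strength * beta[g] * gradient)
        rows[f"bg{g:03d}"] = _nbinom(rng, mean, spec.nb_size)

    counts = CountMatrix(data=pd.DataFrame(rows, index=samples).T,
                         assay=spec.assay)
    truth = pd.DataFrame({"sample_id": samples, "library_size": lib,
                          "scg_mean": scg_mean, "gradient": gradient})
    for gene, rho in spec.mer_rho.items():
        truth[f"rho_{gene}"] = rho
    return counts, truth.set_index("sample_id")


# ---------------------------------------------------------------------------
# Environmental covariates
# ---------------------------------------------------------------------------


def simulate_env(
    community: CountMatrix,
    strength: float,
    seed: int | None = None,
    covariate_names: tuple[str, ...] = ("AOU", "salinity", "C1"),
) -> SampleMetadata:
    """Environmental covariates correlated with community composition.

    Each covariate is ``strength * PC1 + (1 - strength) * noise`` where
    PC1 is the leading principal axis of the log-transformed community
    matrix, standardized; ``strength=0`` gives pure noise (a true null for
    the Mantel test), ``strength=1`` a deterministic function of the
    community. Size-fraction and basin factors are assigned round-robin.
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    x = np.log1p(community.counts.T)  # samples x genes
    x = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    pc1 = x @ vt[0]
    sd = pc1.std()
    if sd > 0:
        pc1 = pc1 / sd
    n = len(community.sample_ids)
    data = {"size_fraction": [("FL", "PA")[i % 2] for i in range(n)],
            "basin": [("Atlantic", "Pacific", "Indian")[i % 3] for i in range(n)]}
    for name in covariate_names:
        noise = rng.standard_normal(n)
        data[name] = strength * pc1 + (1.0 - strength) * noise
    df = pd.DataFrame(data, index=community.sample_ids)
    return SampleMetadata(data=df)
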