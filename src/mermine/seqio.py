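"""Core record types and readers/writers shared by the whole pipeline.

Sequences travel as :class:`SequenceRecord` (FASTA in/out via Biopython),
count tables and sample metadata as thin wrappers around pandas DataFrames,
and the essential-residue constraints of the mer enzymes as
:class:`ResidueRuleTable` objects loaded from YAML (built-in tables for
merA and merB ship with the package).

All residue positions are 1-based in the numbering of the family reference
sequence, with position 1 = first residue of the deposited sequence
(initiator methionine included).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
PROTEIN_ALPHABET = AMINO_ACIDS | {"X"}
DNA_ALPHABET = set("ACGT") | {"N"}

#: metadata columns that are categorical, not environmental covariates
METADATA_FACTORS = ("size_fraction", "basin")


class SeqioError(ValueError):
    """Raised for malformed sequence, count-table or rule-table input."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named residue string with an alphabet tag.

    Parameters
    ----------
    id : str
        Unique identifier; must not contain whitespace.
    seq : str
        Residue string; uppercase letters of the declared alphabet plus
        the ambiguity code (``X`` for protein, ``N`` for DNA).
    alphabet : {"protein", "dna"}
    """

    id: str
    seq: str
    alphabet: str = "protein"

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise SeqioError(f"sequence id {self.id!r} is empty or contains whitespace")
        if not self.seq:
            raise SeqioError(f"sequence {self.id!r} is empty")
        if self.alphabet not in ("protein", "dna"):
            raise SeqioError(f"unknown alphabet {self.alphabet!r}")
        allowed = PROTEIN_ALPHABET if self.alphabet == "protein" else DNA_ALPHABET
        bad = set(self.seq) - allowed
        if bad:
            raise SeqioError(
                f"sequence {self.id!r} contains characters {sorted(bad)} "
                f"outside the {self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path: str | Path, alphabet: str = "protein") -> list[SequenceRecord]:
    """Read a FASTA file into a list of records, order preserved.

    Multi-line sequences are concatenated; duplicate identifiers and empty
    sequences are errors.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqioError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise SeqioError(f"empty sequence under header {rec.id!r} in {path}")
        records.append(SequenceRecord(id=rec.id, seq=seq, alphabet=alphabet))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA."""
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Residue rule tables
# ---------------------------------------------------------------------------

TAXON_CONDITIONS = ("any", "bacteria", "archaea")


@dataclass(frozen=True)
class ResidueRule:
    """One essential-residue constraint in reference numbering.

    ``taxon_condition`` restricts the rule to candidates flagged as coming
    from that domain; ``"any"`` applies to all candidates.
    """

    ref_pos: int
    allowed: frozenset[str]
    taxon_condition: str = "any"
    label: str = ""

    def __post_init__(self) -> None:
        if self.ref_pos < 1:
            raise SeqioError(f"rule position {self.ref_pos} must be >= 1")
        if not self.allowed:
            raise SeqioError(f"rule at position {self.ref_pos} has an empty allowed set")
        bad = set(self.allowed) - AMINO_ACIDS
        if bad:
            raise SeqioError(
                f"rule at position {self.ref_pos}: residues {sorted(bad)} are not "
                "amino-acid letters"
            )
        if self.taxon_condition not in TAXON_CONDITIONS:
            raise SeqioError(f"unknown taxon condition {self.taxon_condition!r}")

    def applies_to(self, taxon_flag: str) -> bool:
        return self.taxon_condition == "any" or self.taxon_condition == taxon_flag


@dataclass(frozen=True)
class ResidueRuleTable:
    """Ordered essential-residue rules for one gene family.

    Positions are non-decreasing; two rules may share a position only when
    their taxon conditions differ (e.g. merA position 605: tyrosine for
    bacteria, phenylalanine for archaea), so that the rules applicable to
    any single candidate sit at strictly increasing positions.
    """

    family: str
    reference_id: str
    rules: tuple[ResidueRule, ...]

    def __post_init__(self) -> None:
        if not self.rules:
            raise SeqioError(f"rule table for {self.family!r} has no rules")
        for prev, cur in zip(self.rules, self.rules[1:]):
            if cur.ref_pos < prev.ref_pos:
                raise SeqioError(
                    f"rule positions must be non-decreasing; got {prev.ref_pos} "
                    f"then {cur.ref_pos} in family {self.family!r}"
                )
        for taxon in ("bacteria", "archaea"):
            pos = [r.ref_pos for r in self.applicable(taxon)]
            if len(pos) != len(set(pos)):
                raise SeqioError(
                    f"duplicate rule position for taxon {taxon!r} in family "
                    f"{self.family!r}"
                )

    @property
    def positions(self) -> list[int]:
        """Sorted distinct reference positions covered by the table."""
        return sorted({r.ref_pos for r in self.rules})

    def applicable(self, taxon_flag: str) -> list[ResidueRule]:
        return [r for r in self.rules if r.applies_to(taxon_flag)]

    def validate_against_reference(self, reference: SequenceRecord) -> None:
        """Check every rule position falls within the reference sequence."""
        if self.rules[-1].ref_pos > len(reference):
            raise SeqioError(
                f"rule position {self.rules[-1].ref_pos} exceeds reference "
                f"{reference.id!r} length {len(reference)}"
            )


BUILTIN_RULE_TABLES = ("merA", "merB")


def load_rule_table(path_or_builtin: str | Path) -> ResidueRuleTable:
    """Load a residue rule table from YAML, or a built-in table by name.

    Built-in ``"merA"`` encodes the catalytic cysteine pair C207/C212, the
    tyrosine Y264, the domain-dependent position 605 (Y in bacteria, F in
    archaea) and the C-terminal vicinal cysteine pair C628/C629 of mercuric
    reductase; built-in ``"merB"`` encodes Y93 and C159 of organomercurial
    lyase.
    """
    name = str(path_or_builtin)
    if name in BUILTIN_RULE_TABLES:
        with resources.files("mermine.data.rules").joinpath(f"{name}.yaml").open() as fh:
            doc = yaml.safe_load(fh)
    else:
        with open(path_or_builtin) as fh:
            doc = yaml.safe_load(fh)
    try:
        family = doc["family"]
        reference_id = doc["reference_id"]
        raw_rules = doc["rules"]
    except (TypeError, KeyError) as exc:
        raise SeqioError(f"rule-table config {name!r} missing key {exc}") from exc
    if not raw_rules:
        raise SeqioError(f"rule-table config {name!r} declares no rules")
    rules = tuple(
        ResidueRule(
            ref_pos=int(r["ref_pos"]),
            allowed=frozenset(str(a).upper() for a in r["allowed"]),
            taxon_condition=r.get("taxon", "any"),
            label=r.get("label", ""),
        )
        for r in raw_rules
    )
    return ResidueRuleTable(family=family, reference_id=reference_id, rules=rules)


# ---------------------------------------------------------------------------
# Count matrices and sample metadata
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Genes x samples non-negative counts for one assay (metaG or metaT)."""

    data: pd.DataFrame  # index = gene ids, columns = sample ids
    assay: str = "metaG"

    def __post_init__(self) -> None:
        if self.assay not in ("metaG", "metaT"):
            raise SeqioError(f"unknown assay {self.assay!r}")
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise SeqioError("duplicate gene or sample ids in count matrix")
        values = self.data.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise SeqioError("count matrix contains missing values")
        if (values < 0).any():
            raise SeqioError("count matrix contains negative entries")
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def read_counts(path: str | Path, assay: str = "metaG") -> CountMatrix:
    """Read a genes x samples TSV count table (first column = gene id)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise SeqioError(f"count table {path} has no sample columns")
    if df.isna().any().any():
        raise SeqioError(f"count table {path} has missing or ragged entries")
    try:
        return CountMatrix(data=df, assay=assay)
    except SeqioError as exc:
        raise SeqioError(f"count table {path}: {exc}") from exc


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class SampleMetadata:
    """Per-sample factors (size fraction, basin) and environmental covariates.

    Covariates may contain missing values (``NaN``); they stay missing and
    are handled by pairwise-complete deletion downstream, never zero-filled.
    """

    data: pd.DataFrame  # index = sample ids

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise SeqioError("duplicate sample ids in metadata")
        if len(self.data) == 0:
            raise SeqioError("metadata table has no samples")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def covariate_names(self) -> list[str]:
        return [
            c
            for c in self.data.columns
            if c not in METADATA_FACTORS and pd.api.types.is_numeric_dtype(self.data[c])
        ]

    def covariates(self) -> pd.DataFrame:
        """Numeric covariate block (missing values preserved as NaN)."""
        return self.data[self.covariate_names].astype(float)


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read a sample metadata TSV (first column = sample id, 'NA' = missing)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", "NaN", ""])
    if len(df) == 0:
        raise SeqioError(f"metadata table {path} has no samples")
    try:
        return SampleMetadata(data=df)
    except SeqioError as exc:
        raise SeqioError(f"metadata table {path}: {exc}") from exc


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.data.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")
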