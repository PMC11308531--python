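"""Nonredundant gene catalog construction by greedy identity/coverage clustering.

Emulates cd-hit-style incremental clustering at desk scale: genes are
sorted by length (longest first, ties broken by id), the first gene seeds
the first cluster, and each subsequent gene joins the first existing
representative it matches at >= ``t_id`` identity and >= ``t_cov``
coverage, otherwise it opens a new cluster. Defaults are 95% identity and
90% coverage. Coverage is measured against the shorter sequence of the
pair. No k-mer prefiltering is used: every gene is aligned against the
open representatives, which is fine for catalogs up to ~10^4 genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .seqio import SequenceRecord
from .verifier import _identity_and_coverage, global_align

DEFAULT_T_ID = 0.95
DEFAULT_T_COV = 0.90


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> tuple[float, float]:
    """Global-alignment identity and coverage of a sequence pair.

    Identity = matches / alignment columns between the first and last
    column where both sequences carry residues (terminal gaps excluded);
    coverage = residues of the shorter sequence inside that region /
    length of the shorter sequence.
    """
    aln = global_align(a, b)
    return _identity_and_coverage(aln.ref_aln, aln.cand_aln)


@dataclass
class Cluster:
    representative: SequenceRecord
    members: list[SequenceRecord] = field(default_factory=list)
    identity_to_rep: list[float] = field(default_factory=list)
    coverage_to_rep: list[float] = field(default_factory=list)

    @property
    def member_ids(self) -> list[str]:
        return [m.id for m in self.members]

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class Catalog:
    clusters: list[Cluster]
    t_id: float
    t_cov: float

    @property
    def representatives(self) -> list[SequenceRecord]:
        return [c.representative for c in self.clusters]

    def membership(self) -> dict[str, str]:
        """Map every gene id to its representative id."""
        return {m: c.representative.id for c in self.clusters for m in c.member_ids}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (m.id, c.representative.id, ident, cov)
            for c in self.clusters
            for m, ident, cov in zip(c.members, c.identity_to_rep, c.coverage_to_rep)
        ]
        return pd.DataFrame(rows, columns=["member_id", "representative_id",
                                           "identity", "coverage"])


def build_catalog(
    genes: list[SequenceRecord],
    t_id: float = DEFAULT_T_ID,
    t_cov: float = DEFAULT_T_COV,
) -> Catalog:
    """Cluster genes greedily into a nonredundant catalog.

    Deterministic given the input set: processing order is length
    descending with lexicographic id tie-break, and each gene joins the
    first (earliest-opened) matching representative.
    """
    if not genes:
        raise ValueError("cannot build a catalog from zero genes")
    for t, name in ((t_id, "t_id"), (t_cov, "t_cov")):
        if not 0.0 < t <= 1.0:
            raise ValueError(f"{name}={t} outside (0, 1]")
    ordered = sorted(genes, key=lambda g: (-len(g), g.id))
    clusters: list[Cluster] = []
    for gene in ordered:
        placed = False
        for cluster in clusters:
            ident, cov = pairwise_identity(cluster.representative, gene)
            if ident >= t_id and cov >= t_cov:
                cluster.members.append(gene)
                cluster.identity_to_rep.append(ident)
                cluster.coverage_to_rep.append(cov)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(representative=gene, members=[gene],
                                    identity_to_rep=[1.0], coverage_to_rep=[1.0]))
    return Catalog(clusters=clusters, t_id=t_id, t_cov=t_cov)
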