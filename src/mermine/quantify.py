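"""Single-copy-gene normalization of effective counts, plus a toy read assigner.

Effective counts (reads assigned per catalog gene per sample) are divided,
sample by sample, by the arithmetic mean of the counts of three essential
single-copy genes (recA, rpoB, gyrB). Because virtually every bacterial or
archaeal cell carries one copy of each SCG, the ratio reads as a per-cell
average copy number (or, for metatranscriptomes, per-cell expression),
making samples with different library sizes directly comparable.

Count tables normally arrive from an external read mapper; the k-mer
``assign_reads`` here is a deliberately small exact-seed assigner so the
whole pipeline can be exercised end to end on simulated reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import CountMatrix, SeqioError, SequenceRecord

logger = logging.getLogger(__name__)

DEFAULT_SCG_IDS = ("recA", "rpoB", "gyrB")


@dataclass
class NormalizedMatrix:
    """Genes x samples per-cell abundances with the per-sample SCG means.

    Samples whose SCG mean is zero carry missing values (NaN), never
    infinities: downstream dissimilarities must drop them, not zero-fill.
    """

    data: pd.DataFrame
    scg_means: pd.Series
    assay: str = "metaG"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def scg_normalize(
    counts: CountMatrix, scg_ids: tuple[str, ...] = DEFAULT_SCG_IDS
) -> NormalizedMatrix:
    """Divide every gene's counts by the per-sample mean SCG count.

    ``scg_means[s]`` is the arithmetic mean of the SCG rows in sample s;
    every row of the matrix (SCG rows included, which therefore normalize
    to ~1) is divided by it.
    """
    for g in scg_ids:
        if g not in counts.data.index:
            raise SeqioError(f"single-copy gene {g!r} missing from count matrix")
    scg_means = counts.data.loc[list(scg_ids)].mean(axis=0)
    zero = scg_means[scg_means == 0].index
    if len(zero):
        logger.warning(
            "samples %s have zero mean SCG counts; normalized values set missing",
            list(zero),
        )
    denom = scg_means.replace(0, np.nan)
    return NormalizedMatrix(data=counts.data.div(denom, axis=1),
                            scg_means=scg_means, assay=counts.assay)


def write_normalized(norm: NormalizedMatrix, path) -> None:
    norm.data.to_csv(path, sep="\t", index_label="gene_id", na_rep="NA")


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def assign_reads(
    reads_by_sample: dict[str, list[SequenceRecord]],
    catalog_genes: list[SequenceRecord],
    k: int = 15,
    min_matches: int = 1,
    assay: str = "metaG",
) -> CountMatrix:
    """Assign each read to the catalog gene sharing the most exact k-mers.

    A read counts toward a gene only if it is the unique best match with at
    least ``min_matches`` shared k-mers; ties are discarded (unique-best
    counting, so multi-mapping reads are dropped rather than fractionally
    split). ``k`` below 8 is rejected because such short words match
    spuriously.
    """
    if k < 8:
        raise ValueError(f"k={k} is too short for reliable exact seeding (need >= 8)")
    index: dict[str, set[int]] = {}
    for gi, gene in enumerate(catalog_genes):
        for km in _kmers(gene.seq, k):
            index.setdefault(km, set()).add(gi)
    gene_ids = [g.id for g in catalog_genes]
    samples = list(reads_by_sample)
    table = pd.DataFrame(0.0, index=gene_ids, columns=samples)
    for sample, reads in reads_by_sample.items():
        for read in reads:
            hits = np.zeros(len(catalog_genes), dtype=int)
            for km in _kmers(read.seq, k):
                for gi in index.get(km, ()):
                    hits[gi] += 1
            best = hits.max(initial=0)
            if best < min_matches:
                continue
            winners = np.flatnonzero(hits == best)
            if len(winners) != 1:
                continue  # ambiguous read: discard
            table.iloc[winners[0], table.columns.get_loc(sample)] += 1
    return CountMatrix(data=table, assay=assay)
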