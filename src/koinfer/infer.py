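"""Inference of ortholog abundances from an OTU table and nearest-neighbor hits.

Given per-sample OTU abundances A_t and each OTU's m tied nearest-neighbor
genomes, the inferred abundance of ortholog K in a sample is

    A_K = sum_t A_t * [ sum_{g=1..m} Kcopy_g / Rcopy_g ] / m

where Kcopy_g is the copy number of K in genome g and Rcopy_g the genome's
16S rRNA gene copy number.  Dividing by Rcopy converts 16S-derived
abundance into genome abundance; multiplying by Kcopy converts genome
abundance into gene abundance; ties split the OTU's count equally among
the m genomes.  OTUs without a hit contribute nothing.

The computation runs per sample directly from the OTU table; the
intermediate genome table (:func:`assign_otus`) is exposed separately and
is mathematically equivalent, but the direct path avoids double rounding.
Accumulation order is fixed (OTUs in table order, genomes in sorted
order), so results are bit-reproducible.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .nnsearch import HitSet
from .refdb import ReferenceDatabase
from .tables import GenomeTable, KoAbundanceTable, OtuTable

__all__ = [
    "assign_otus",
    "infer_ko_abundance",
    "floor_counts",
    "passed_fraction",
]

logger = logging.getLogger("koinfer.infer")


def _check_hits(otus: OtuTable, hits: Mapping[str, HitSet]) -> None:
    unknown = set(hits) - set(otus.feature_ids)
    if unknown:
        raise ValueError(
            f"hits reference OTUs absent from the table: {sorted(unknown)[:5]}"
        )


def assign_otus(otus: OtuTable, hits: Mapping[str, HitSet]) -> GenomeTable:
    """Convert the OTU table into a genome abundance table.

    Each passing OTU's per-sample abundance is divided by its tie count m
    and added to each tied genome; OTUs without hits contribute nothing.
    Column sums therefore equal the per-sample summed abundance of passing
    OTUs (conservation under 1/m splitting).
    """
    _check_hits(otus, hits)
    genome_ids = sorted({g for h in hits.values() for g in h.genome_ids})
    gindex = {g: i for i, g in enumerate(genome_ids)}
    mat = np.zeros((len(genome_ids), len(otus.sample_ids)))
    values = otus.df.to_numpy(dtype=float)
    for i, otu in enumerate(otus.feature_ids):
        hit = hits.get(otu)
        if hit is None:
            continue
        share = values[i] / hit.m
        for g in sorted(hit.genome_ids):
            mat[gindex[g]] += share
    return GenomeTable(pd.DataFrame(mat, index=genome_ids, columns=otus.sample_ids))


def infer_ko_abundance(
    otus: OtuTable,
    hits: Mapping[str, HitSet],
    db: ReferenceDatabase,
    full_universe: bool = False,
) -> KoAbundanceTable:
    """Compute the inferred ortholog abundance table A_K.

    Parameters
    ----------
    otus
        OTU x sample abundance table.
    hits
        Per-OTU nearest-neighbor assignments (missing OTUs were dropped).
    db
        Reference database supplying Kcopy and Rcopy per genome.
    full_universe
        When True, the output carries every ortholog in the reference
        universe including all-zero rows; by default only orthologs with
        A_K > 0 in at least one sample are kept.

    Returns
    -------
    KoAbundanceTable
        Orthologs in lexicographic order, samples in input order;
        fractional values are kept (flooring is a separate explicit step).

    Raises
    ------
    KeyError
        If a hit references a genome absent from the database.
    """
    _check_hits(otus, hits)
    ko_ids = sorted(db.ortholog_universe)
    ko_index = {k: i for i, k in enumerate(ko_ids)}
    n_kos, n_samples = len(ko_ids), len(otus.sample_ids)

    missing = {g for h in hits.values() for g in h.genome_ids} - set(db.genomes)
    if missing:
        raise KeyError(
            f"hit genomes absent from the reference database: {sorted(missing)[:5]}"
        )

    # per-genome ratio vector Kcopy/Rcopy over the sorted ortholog universe
    ratio_cache: dict[str, np.ndarray] = {}

    def ratios(gid: str) -> np.ndarray:
        vec = ratio_cache.get(gid)
        if vec is None:
            rec = db.genomes[gid]
            vec = np.zeros(n_kos)
            for ko, copies in rec.ko_copies.items():
                if ko in ko_index:
                    vec[ko_index[ko]] = copies / rec.rrna_copy_number
            ratio_cache[gid] = vec
        return vec

    acc = np.zeros((n_kos, n_samples))
    values = otus.df.to_numpy(dtype=float)
    for i, otu in enumerate(otus.feature_ids):
        hit = hits.get(otu)
        if hit is None:
            continue
        w = np.zeros(n_kos)
        for gid in sorted(hit.genome_ids):
            w += ratios(gid)
        w = w / hit.m
        acc += np.outer(w, values[i])

    df = pd.DataFrame(acc, index=ko_ids, columns=otus.sample_ids)
    if not full_universe:
        df = df.loc[(df.to_numpy() > 0).any(axis=1)]
    return KoAbundanceTable(df)


def floor_counts(table: KoAbundanceTable) -> KoAbundanceTable:
    """Floor each fractional abundance to an integer.

    Count-based downstream statistics (e.g. negative-binomial tests)
    require integer counts; flooring is kept explicit so the fractional
    table remains available.  Features that become all-zero are retained.
    """
    floored = pd.DataFrame(
        np.floor(table.matrix).astype(np.int64),
        index=table.df.index,
        columns=table.df.columns,
    )
    return KoAbundanceTable(floored)


def passed_fraction(otus: OtuTable, hits: Mapping[str, HitSet]) -> pd.Series:
    """Abundance-weighted fraction of each sample assigned to any genome.

    Per sample: (summed abundance of OTUs with hits) / (total summed
    abundance).  A sample with zero total abundance yields 0.0 with a
    warning.
    """
    _check_hits(otus, hits)
    values = otus.df.to_numpy(dtype=float)
    total = values.sum(axis=0)
    mask = np.array([otu in hits for otu in otus.feature_ids])
    passed = values[mask].sum(axis=0) if mask.any() else np.zeros(len(total))
    out = np.zeros(len(total))
    nonzero = total > 0
    out[nonzero] = passed[nonzero] / total[nonzero]
    for sample, tot in zip(otus.sample_ids, total):
        if tot == 0:
            logger.warning(
                "event=empty_sample sample_id=%s passed_fraction=0", sample
            )
    return pd.Series(out, index=otus.sample_ids, name="passed_fraction")
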