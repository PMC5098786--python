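"""Synthetic references and communities with analytically known ground truth.

The generator stands in for an annotated-genome reference (per-genome 16S
genes plus ortholog copy numbers) and for amplicon survey data (a sparse
OTU count table plus representative sequences), so the whole pipeline is
testable without downloads.

Design choices that make expectations provable rather than statistical:

* Genome 16S sequences are i.i.d. random, which keeps cross-genome
  identities far below 0.90 (verified at build time), so nearest-neighbor
  assignment is unambiguous at high cutoffs.
* A genome's 16S copies are identical, so a multi-copy genome exercises
  the "several tied copies count once" rule.
* Mutations are substitutions only, placed at exactly ``round(d * L)``
  positions, so a mutated representative has identity exactly
  ``(L - k) / L`` to its source and cutoff behavior is exact arithmetic.
* Representatives are windows of the source 16S (default 250 nt,
  emulating a V4 amplicon) so the semi-global alignment path real data
  requires is exercised; set ``rep_len=None`` for full-length reps.

Draw order for a fixed seed (documented so determinism is a contract):
reference — per genome: length, sequence, 16S copy count, then the KO
copy vector; community — per OTU: source genome, window start, mutation
positions, substituted bases; then the abundance matrix row-major.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .nnsearch import HitSet, pairwise_identity
from .refdb import GenomeRecord, ReferenceDatabase
from .tables import KoAbundanceTable, OtuTable

__all__ = [
    "SyntheticSpec",
    "ReferenceTruth",
    "Community",
    "SeparationError",
    "generate_reference",
    "mutate_sequence",
    "generate_community",
    "naive_ko_abundance",
]

_BASES = np.array(list("ACGT"))

#: Cross-genome 16S identities must stay below this for unambiguous
#: nearest-neighbor assignment at high cutoffs.
SEPARATION_LIMIT = 0.90


class SeparationError(ValueError):
    """Requested genomes cannot be kept below the cross-identity limit."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study.

    ``divergence`` is the per-site substitution rate applied to each OTU
    representative relative to its source 16S; ``rep_len`` is the amplicon
    window length (None = full-length representatives).
    """

    n_genomes: int = 10
    n_kos: int = 50
    n_otus: int = 20
    n_samples: int = 6
    divergence: float = 0.0
    rrna_len: int = 1500
    rep_len: int | None = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_otus < 1 or self.n_genomes < 1 or self.n_samples < 1:
            raise ValueError("n_otus, n_genomes and n_samples must be >= 1")
        if not 0.0 <= self.divergence < 1.0:
            raise ValueError(f"divergence {self.divergence} outside [0, 1)")
        if self.n_kos < 0:
            raise ValueError("n_kos must be >= 0")


@dataclass(frozen=True)
class ReferenceTruth:
    """Generator bookkeeping for a synthetic reference."""

    ko_ids: tuple[str, ...]          # every KO id the generator drew over
    ko_universe: frozenset[str]      # KOs with copy > 0 in at least one genome


@dataclass
class Community:
    """A synthetic amplicon study plus its analytically known ground truth."""

    otu_table: OtuTable
    rep_seqs: dict[str, str]
    source_genomes: dict[str, str]   # OTU -> the genome its rep was taken from
    truth_hits: dict[str, HitSet]    # the correct assignment (m = 1 each)
    ko_truth: KoAbundanceTable       # formula applied to the true assignment


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_reference(
    spec: SyntheticSpec,
    max_check_pairs: int = 300,
) -> tuple[ReferenceDatabase, ReferenceTruth]:
    """Generate a reference database of well-separated synthetic genomes.

    Each genome gets a 16S copy number drawn uniformly from {1..7} (the
    copies identical), a 16S length within +-min(50, L/10) of
    ``spec.rrna_len``, and KO copy numbers drawn uniformly from {0..5}
    over ``spec.n_kos`` ortholog IDs (zeros stored implicitly).  All
    cross-genome 16S identities are verified to be below 0.90 (all pairs,
    or a seeded subsample when the pair count exceeds ``max_check_pairs``);
    a genome that cannot be separated after repeated redraws raises
    :class:`SeparationError`.
    """
    rng = np.random.default_rng(spec.seed)
    half = min(50, spec.rrna_len // 10)
    lo, hi = max(1, spec.rrna_len - half), spec.rrna_len + half

    ko_ids = tuple(f"K{i + 1:05d}" for i in range(spec.n_kos))
    genomes: dict[str, GenomeRecord] = {}
    accepted_seqs: list[str] = []

    for g in range(spec.n_genomes):
        gid = f"G{g + 1:03d}"
        seq = None
        for _attempt in range(30):
            length = int(rng.integers(lo, hi + 1))
            cand = "".join(rng.choice(_BASES, size=length))
            if _separated(cand, accepted_seqs, max_check_pairs, rng):
                seq = cand
                break
        if seq is None:
            raise SeparationError(
                f"could not separate genome {gid} from earlier genomes below "
                f"identity {SEPARATION_LIMIT}; increase rrna_len"
            )
        accepted_seqs.append(seq)
        n_copies = int(rng.integers(1, 8))
        ko_draws = rng.integers(0, 6, size=spec.n_kos)
        ko_copies = {k: int(c) for k, c in zip(ko_ids, ko_draws) if c > 0}
        genomes[gid] = GenomeRecord(
            genome_id=gid,
            rrna_seqs=(seq,) * n_copies,
            ko_copies=ko_copies,
        )

    db = ReferenceDatabase(genomes=genomes, min_len=lo, max_len=hi)
    truth = ReferenceTruth(ko_ids=ko_ids, ko_universe=db.ortholog_universe)
    return db, truth


def _separated(
    cand: str,
    accepted: list[str],
    max_check_pairs: int,
    rng: np.random.Generator,
) -> bool:
    others = accepted
    if len(accepted) > max_check_pairs:
        idx = rng.choice(len(accepted), size=max_check_pairs, replace=False)
        others = [accepted[i] for i in idx]
    return all(
        pairwise_identity(cand, other).identity < SEPARATION_LIMIT
        for other in others
    )


def mutate_sequence(seq: str, divergence: float, seed) -> str:
    """Substitute exactly ``round(divergence * L)`` positions of ``seq``.

    Positions are drawn without replacement and each base is replaced by a
    different base, so the mutant's semi-global identity to the source is
    exactly ``(L - k) / L``.  No indels are introduced.
    """
    if not 0.0 <= divergence < 1.0:
        raise ValueError(f"divergence {divergence} outside [0, 1)")
    rng = _rng(seed)
    L = len(seq)
    k = round(divergence * L)
    if k == 0:
        return seq
    positions = rng.choice(L, size=k, replace=False)
    out = list(seq)
    for p in positions:
        alternatives = [b for b in "ACGT" if b != out[p]]
        out[p] = alternatives[int(rng.integers(0, len(alternatives)))]
    return "".join(out)


def generate_community(
    db: ReferenceDatabase,
    spec: SyntheticSpec,
) -> Community:
    """Generate an OTU table, representative sequences, and ground truth.

    Each OTU representative is a (possibly mutated) window of one genome's
    16S gene; per-sample abundances are drawn log-uniform over [1, 10^4]
    and rounded to integers.  Ground truth is computed by the independent
    naive formula implementation (:func:`naive_ko_abundance`) from the
    true source genomes.
    """
    rng = np.random.default_rng([spec.seed, 1])
    genome_ids = sorted(db.genomes)
    otu_ids = [f"OTU{i + 1:04d}" for i in range(spec.n_otus)]

    rep_seqs: dict[str, str] = {}
    source: dict[str, str] = {}
    truth_hits: dict[str, HitSet] = {}
    for otu in otu_ids:
        gid = genome_ids[int(rng.integers(0, len(genome_ids)))]
        full = db.genomes[gid].rrna_seqs[0]
        if spec.rep_len is not None and len(full) > spec.rep_len:
            start = int(rng.integers(0, len(full) - spec.rep_len + 1))
            rep = full[start:start + spec.rep_len]
        else:
            rep = full
        k = round(spec.divergence * len(rep))
        rep = mutate_sequence(rep, spec.divergence, rng)
        rep_seqs[otu] = rep
        source[otu] = gid
        truth_hits[otu] = HitSet(
            otu_id=otu,
            best_identity=(len(rep) - k) / len(rep),
            genome_ids=frozenset({gid}),
        )

    raw = 10.0 ** rng.uniform(0.0, 4.0, size=(spec.n_otus, spec.n_samples))
    counts = np.rint(raw).astype(np.int64)
    sample_ids = [f"S{j + 1:02d}" for j in range(spec.n_samples)]
    otu_table = OtuTable(pd.DataFrame(counts, index=otu_ids, columns=sample_ids))

    ko_truth = naive_ko_abundance(otu_table, truth_hits, db)
    return Community(
        otu_table=otu_table,
        rep_seqs=rep_seqs,
        source_genomes=source,
        truth_hits=truth_hits,
        ko_truth=ko_truth,
    )


def naive_ko_abundance(
    otus: OtuTable,
    hits: Mapping[str, HitSet],
    db: ReferenceDatabase,
    full_universe: bool = False,
) -> KoAbundanceTable:
    """Reference implementation of the inference formula as explicit loops.

    Computes A_K = sum_t A_t * (sum_g Kcopy_g / Rcopy_g) / m one scalar at
    a time, with the same accumulation order as the production path (OTUs
    in table order, genomes sorted).  Serves as the independent oracle for
    the vectorized implementation and supplies ground-truth tables for
    synthetic communities.
    """
    ko_ids = sorted(db.ortholog_universe)
    sample_ids = otus.sample_ids
    acc = {ko: [0.0] * len(sample_ids) for ko in ko_ids}
    for otu in otus.feature_ids:
        hit = hits.get(otu)
        if hit is None:
            continue
        row = [float(v) for v in otus.df.loc[otu]]
        for ko in ko_ids:
            w = 0.0
            for gid in sorted(hit.genome_ids):
                rec = db.genomes[gid]
                w += rec.ko_copy(ko) / rec.rrna_copy_number
            w = w / hit.m
            for j in range(len(sample_ids)):
                acc[ko][j] += w * row[j]
    df = pd.DataFrame.from_dict(acc, orient="index", columns=sample_ids)
    df = df.reindex(ko_ids)
    if not full_universe:
        df = df.loc[(df.to_numpy() > 0).any(axis=1)]
    return KoAbundanceTable(df)
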