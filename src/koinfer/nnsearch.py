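"""Nearest-neighbor genome assignment by semi-global percent identity.

Each OTU representative sequence (typically a ~250 nt V4 amplicon) is
aligned against every 16S rRNA gene sequence in the reference database.
The alignment is semi-global: the query must align end-to-end, while the
reference's overhanging ends are gap-free, so a short amplicon can sit
inside a full-length (~1.5 kb) 16S gene without terminal-gap penalty.

Percent identity is defined as matching columns divided by all alignment
columns spanning the aligned query (internal gaps count as columns; the
free terminal reference gaps do not).  Scoring: match +1, mismatch -1,
gap open -2, gap extend -1 (a gap of length k costs 2 + k).  Ambiguous
IUPAC codes are compared literally, i.e. they count as mismatches unless
identical.

The genome owning the highest-identity 16S at or above the identity
cutoff is the OTU's nearest neighbor; genomes tied at the best identity
(within 1e-9) share the assignment, each counted once no matter how many
of its 16S copies tie.  Queries whose best identity falls below the
cutoff get no hit and are dropped from downstream inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from skbio.alignment import pair_align

from .refdb import InvalidSequenceError, ReferenceDatabase, _validate_dna

__all__ = [
    "AlignmentResult",
    "HitSet",
    "IDENTITY_TIE_TOL",
    "pairwise_identity",
    "nearest_neighbors",
    "search_all",
    "reverse_complement",
]

logger = logging.getLogger("koinfer.nnsearch")

#: Absolute tolerance used both for tie detection among reference genomes
#: and for the cutoff comparison on the identity fraction.
IDENTITY_TIE_TOL = 1e-9

_MATCH = 1.0
_MISMATCH = -1.0
_GAP_OPEN = 2.0
_GAP_EXTEND = 1.0

_RC = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string."""
    return seq.upper().translate(_RC)[::-1]


@dataclass(frozen=True)
class AlignmentResult:
    """Identity summary of one semi-global alignment.

    ``columns`` counts the alignment columns spanning the aligned query
    (internal gaps included, free terminal reference gaps excluded);
    ``matches`` counts the columns whose two residues are identical.
    """

    matches: int
    columns: int

    def __post_init__(self) -> None:
        if not (0 <= self.matches <= self.columns):
            raise ValueError(
                f"invalid alignment counts: matches={self.matches} "
                f"columns={self.columns}"
            )

    @property
    def identity(self) -> float:
        return self.matches / self.columns


@dataclass(frozen=True)
class HitSet:
    """Per-OTU nearest-neighbor result.

    ``genome_ids`` holds the m distinct genomes tied at ``best_identity``;
    downstream the OTU's abundance is split equally among them.
    """

    otu_id: str
    best_identity: float
    genome_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genome_ids:
            raise ValueError(f"HitSet for {self.otu_id!r} has no genomes")
        if not (0.0 <= self.best_identity <= 1.0):
            raise ValueError(f"identity {self.best_identity} outside [0, 1]")

    @property
    def m(self) -> int:
        """Number of tied nearest-neighbor genomes."""
        return len(self.genome_ids)


def pairwise_identity(query: str, reference: str) -> AlignmentResult:
    """Align ``query`` semi-globally inside ``reference`` and count identity.

    The query is aligned end-to-end; terminal gaps on the reference are
    free and excluded from the identity denominator.

    Parameters
    ----------
    query, reference
        Non-empty IUPAC DNA strings.

    Returns
    -------
    AlignmentResult
        Matches and columns over the aligned query span.
    """
    q = _validate_dna(query, "query")
    r = _validate_dna(reference, "reference")
    res = pair_align(
        q,
        r,
        mode="global",
        sub_score=(_MATCH, _MISMATCH),
        gap_cost=(_GAP_OPEN, _GAP_EXTEND),
        free_ends=(True, False),  # free terminal gaps in the query row = reference overhang
        trim_ends=True,
        max_paths=1,
    )
    aln_q, aln_r = res.paths[0].to_aligned((q, r))
    a = np.frombuffer(aln_q.encode(), dtype="S1")
    b = np.frombuffer(aln_r.encode(), dtype="S1")
    matches = int(np.count_nonzero((a == b) & (a != b"-")))
    return AlignmentResult(matches=matches, columns=len(aln_q))


def _best_identity_vs_genome(
    query: str, seqs: tuple[str, ...], search_rc: bool
) -> float:
    best = 0.0
    queries = [query] if not search_rc else [query, reverse_complement(query)]
    # identical gene copies score identically; align each distinct sequence once
    for seq in dict.fromkeys(seqs):
        for q in queries:
            ident = pairwise_identity(q, seq).identity
            if ident > best:
                best = ident
    return best


def nearest_neighbors(
    query: str,
    db: ReferenceDatabase,
    cutoff: float = 0.97,
    otu_id: str = "query",
    search_rc: bool = False,
) -> HitSet | None:
    """Find the nearest-neighbor genome(s) of one query at the given cutoff.

    Evaluates the semi-global identity of the query against every indexed
    16S sequence.  Returns ``None`` (no hit) when the maximum identity is
    below ``cutoff``; otherwise a :class:`HitSet` with every distinct
    genome whose best 16S identity ties the maximum within 1e-9.  A genome
    contributing several tied 16S copies appears once.

    Parameters
    ----------
    query
        OTU representative sequence.
    db
        Reference database (must be non-empty).
    cutoff
        Identity cutoff in (0, 1].
    search_rc
        Also score the reverse complement of the query and keep the better
        orientation (off by default; amplicon pipelines normally orient
        reads).
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError(f"cutoff {cutoff} outside (0, 1]")
    if not db.genomes:
        raise ValueError("reference database is empty")
    per_genome: dict[str, float] = {
        gid: _best_identity_vs_genome(query, rec.rrna_seqs, search_rc)
        for gid, rec in db.genomes.items()
    }
    best = max(per_genome.values())
    if best < cutoff - IDENTITY_TIE_TOL:
        return None
    tied = frozenset(
        gid for gid, ident in per_genome.items()
        if ident >= best - IDENTITY_TIE_TOL
    )
    return HitSet(otu_id=otu_id, best_identity=best, genome_ids=tied)


def search_all(
    rep_seqs: Mapping[str, str],
    db: ReferenceDatabase,
    cutoff: float = 0.97,
    search_rc: bool = False,
) -> dict[str, HitSet]:
    """Assign every OTU representative to its nearest-neighbor genome(s).

    OTUs whose best identity falls below the cutoff are absent from the
    result (dropped); the count of dropped OTUs is logged.
    """
    hits: dict[str, HitSet] = {}
    for otu_id, seq in rep_seqs.items():
        hit = nearest_neighbors(seq, db, cutoff, otu_id=otu_id, search_rc=search_rc)
        if hit is not None:
            hits[otu_id] = hit
    n_dropped = len(rep_seqs) - len(hits)
    logger.info(
        "event=search_all cutoff=%g n_otus=%d n_passed=%d n_dropped=%d",
        cutoff, len(rep_seqs), len(hits), n_dropped,
    )
    return hits


def best_hits(
    rep_seqs: Mapping[str, str],
    db: ReferenceDatabase,
    search_rc: bool = False,
) -> dict[str, HitSet]:
    """Best identity and tied genomes per OTU, with no cutoff applied.

    Equivalent to :func:`search_all` at an infinitesimal cutoff; used to
    evaluate many cutoffs from a single pass over the alignments (the
    per-OTU best identity does not depend on the cutoff, only the keep/
    drop decision does).
    """
    out: dict[str, HitSet] = {}
    for otu_id, seq in rep_seqs.items():
        hit = nearest_neighbors(
            seq, db, cutoff=1e-12, otu_id=otu_id, search_rc=search_rc
        )
        if hit is not None:  # cutoff ~0 always yields a hit for non-empty db
            out[otu_id] = hit
    return out


def apply_cutoff(hits: Mapping[str, HitSet], cutoff: float) -> dict[str, HitSet]:
    """Filter a no-cutoff hit map down to the OTUs passing ``cutoff``."""
    return {
        otu: h for otu, h in hits.items()
        if h.best_identity >= cutoff - IDENTITY_TIE_TOL
    }
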