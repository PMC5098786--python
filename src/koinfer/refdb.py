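"""Reference database: 16S rRNA gene sequences and ortholog copy numbers per genome.

The reference maps each annotated genome to (a) its qualifying full-length
16S rRNA gene sequences and (b) a sparse table of ortholog (KO) copy
numbers.  The 16S copy number of a genome, ``Rcopy``, is defined as the
number of its 16S sequences that pass the length filter; it is the
denominator that converts 16S-derived abundance into genome abundance
downstream.  Genomes that lose every 16S copy to the length filter are
excluded from the database entirely, so ``Rcopy >= 1`` always holds.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "DEFAULT_MIN_LEN",
    "DEFAULT_MAX_LEN",
    "GenomeRecord",
    "ReferenceDatabase",
    "InvalidSequenceError",
    "DuplicateGenomeError",
    "CopyTableError",
    "BundleError",
    "filter_16s_by_length",
    "build_reference",
    "build_reference_from_files",
    "save_reference",
    "load_reference",
]

logger = logging.getLogger("koinfer.refdb")

#: Default length window for a qualifying full-length 16S rRNA gene (bp).
DEFAULT_MIN_LEN = 1400
DEFAULT_MAX_LEN = 1600

BUNDLE_FORMAT_VERSION = 1

_IUPAC_DNA = re.compile(r"^[ACGTRYSWKMBDHVN]+$")


class InvalidSequenceError(ValueError):
    """A sequence contains characters outside the IUPAC DNA alphabet."""


class DuplicateGenomeError(ValueError):
    """The same genome identifier was supplied more than once."""


class CopyTableError(ValueError):
    """An ortholog copy-number table row could not be parsed."""


class BundleError(RuntimeError):
    """A saved reference bundle is missing, inconsistent, or incompatible."""


def _validate_dna(seq: str, label: str) -> str:
    s = seq.upper()
    if not s or not _IUPAC_DNA.match(s):
        raise InvalidSequenceError(
            f"sequence {label!r} contains non-IUPAC DNA characters (or is empty)"
        )
    return s


def filter_16s_by_length(
    seqs: Sequence[str],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[str]:
    """Keep the sequences whose length lies inside the inclusive window.

    Parameters
    ----------
    seqs
        Nucleotide sequences (IUPAC codes allowed; case-insensitive).
    min_len, max_len
        Inclusive bounds on sequence length, in bp.

    Returns
    -------
    list of str
        Uppercased sequences with ``min_len <= len <= max_len``, in their
        original order.
    """
    if min_len > max_len:
        raise ValueError(f"min_len ({min_len}) exceeds max_len ({max_len})")
    out = []
    for i, seq in enumerate(seqs):
        s = _validate_dna(seq, f"#{i}")
        if min_len <= len(s) <= max_len:
            out.append(s)
    return out


@dataclass(frozen=True)
class GenomeRecord:
    """One reference genome: its 16S gene copies and its ortholog copy map.

    Attributes
    ----------
    genome_id
        Opaque genome identifier.
    rrna_seqs
        The qualifying 16S rRNA gene sequences, one per gene copy.
    ko_copies
        Sparse map ortholog ID -> copy number; absent orthologs read as 0.
    """

    genome_id: str
    rrna_seqs: tuple[str, ...]
    ko_copies: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rrna_seqs:
            raise ValueError(f"genome {self.genome_id!r} has no 16S sequences")
        for ko, n in self.ko_copies.items():
            if not isinstance(n, (int,)) or isinstance(n, bool) or n < 0:
                raise ValueError(
                    f"genome {self.genome_id!r}: copy number for {ko!r} "
                    f"must be a non-negative integer, got {n!r}"
                )

    @property
    def rrna_copy_number(self) -> int:
        """Rcopy: the number of qualifying 16S gene copies."""
        return len(self.rrna_seqs)

    def ko_copy(self, ko_id: str) -> int:
        """Kcopy for one ortholog; 0 when the ortholog is absent."""
        return int(self.ko_copies.get(ko_id, 0))


@dataclass
class ReferenceDatabase:
    """Indexed collection of :class:`GenomeRecord` searchable by 16S sequence.

    ``seq_index`` maps a 16S sequence identifier (``genomeID|seqN``) to its
    owning genome; every indexed sequence resolves to exactly one genome.
    """

    genomes: dict[str, GenomeRecord]
    min_len: int = DEFAULT_MIN_LEN
    max_len: int = DEFAULT_MAX_LEN
    seq_index: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.seq_index:
            self.seq_index = {
                seq_id: gid for seq_id, gid, _ in self._iter_all_seqs()
            }

    def _iter_all_seqs(self) -> Iterator[tuple[str, str, str]]:
        for gid in sorted(self.genomes):
            rec = self.genomes[gid]
            for i, seq in enumerate(rec.rrna_seqs):
                yield f"{gid}|seq{i + 1}", gid, seq

    def iter_seqs(self) -> Iterator[tuple[str, str, str]]:
        """Yield ``(seq_id, genome_id, sequence)`` for every indexed 16S copy."""
        return self._iter_all_seqs()

    @property
    def ortholog_universe(self) -> frozenset[str]:
        """All ortholog IDs appearing (with copy > 0) in any genome."""
        ids: set[str] = set()
        for rec in self.genomes.values():
            ids.update(k for k, v in rec.ko_copies.items() if v > 0)
        return frozenset(ids)

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)

    def __len__(self) -> int:
        return len(self.genomes)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferenceDatabase):
            return NotImplemented
        if set(self.genomes) != set(other.genomes):
            return False
        for gid, rec in self.genomes.items():
            orec = other.genomes[gid]
            if rec.rrna_seqs != orec.rrna_seqs:
                return False
            # sparse/dense equivalence: zero copies equal absent entries
            kos = set(rec.ko_copies) | set(orec.ko_copies)
            if any(rec.ko_copy(k) != orec.ko_copy(k) for k in kos):
                return False
        return (self.min_len, self.max_len) == (other.min_len, other.max_len)


def build_reference(
    genome_inputs: Iterable[tuple[str, Sequence[str], Mapping[str, int]]],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> ReferenceDatabase:
    """Assemble a :class:`ReferenceDatabase` from per-genome inputs.

    Each input is ``(genome_id, raw_16s_seqs, ko_copies)``.  Sequences are
    length-filtered first; a genome whose 16S list is empty after filtering
    is excluded (and logged) rather than kept with Rcopy = 0, which would
    make the downstream copy-number normalization undefined.

    Raises
    ------
    DuplicateGenomeError
        If the same genome_id appears twice.
    """
    genomes: dict[str, GenomeRecord] = {}
    excluded: list[str] = []
    for genome_id, seqs, ko_copies in genome_inputs:
        if genome_id in genomes or genome_id in excluded:
            raise DuplicateGenomeError(f"duplicate genome id {genome_id!r}")
        kept = filter_16s_by_length(seqs, min_len, max_len)
        if not kept:
            excluded.append(genome_id)
            logger.info(
                "event=genome_excluded genome_id=%s reason=no_16s_in_window "
                "window=[%d,%d]", genome_id, min_len, max_len,
            )
            continue
        genomes[genome_id] = GenomeRecord(
            genome_id=genome_id,
            rrna_seqs=tuple(kept),
            ko_copies={k: int(v) for k, v in ko_copies.items()},
        )
    logger.info(
        "event=reference_built n_genomes=%d n_excluded=%d",
        len(genomes), len(excluded),
    )
    return ReferenceDatabase(genomes=genomes, min_len=min_len, max_len=max_len)


def read_copy_table(path: Path | str) -> dict[str, int]:
    """Read a two-column ``ko_id<TAB>copies`` table (header optional)."""
    copies: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() in {"ko_id", "ko", "ortholog"}:
                continue
            if len(parts) != 2:
                raise CopyTableError(
                    f"{path}: line {lineno}: expected 2 tab-separated fields, "
                    f"got {len(parts)}"
                )
            ko, n = parts
            try:
                count = int(n)
            except ValueError:
                raise CopyTableError(
                    f"{path}: line {lineno}: copy number {n!r} is not an integer"
                ) from None
            if count < 0:
                raise CopyTableError(
                    f"{path}: line {lineno}: negative copy number {count}"
                )
            if ko in copies:
                raise CopyTableError(
                    f"{path}: line {lineno}: duplicate ortholog id {ko!r}"
                )
            copies[ko] = count
    return copies


def build_reference_from_files(
    pairs: Iterable[tuple[str, Path | str, Path | str]],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> ReferenceDatabase:
    """Build from per-genome ``(genome_id, 16S FASTA path, copy TSV path)`` triples."""

    def gen() -> Iterator[tuple[str, list[str], dict[str, int]]]:
        for genome_id, fasta, tsv in pairs:
            seqs = [str(r.seq) for r in SeqIO.parse(str(fasta), "fasta")]
            yield genome_id, seqs, read_copy_table(tsv)

    return build_reference(gen(), min_len=min_len, max_len=max_len)


def save_reference(db: ReferenceDatabase, path: Path | str) -> Path:
    """Write the database as a plain-text bundle directory.

    The bundle holds one multi-FASTA of 16S sequences (headers encode the
    genome as ``genomeID|seqN``), one sparse TSV of ortholog copy counts
    (``genome_id  ko_id  copies``), one TSV of per-genome 16S copy numbers
    (the authoritative sidecar), and a JSON manifest recording the format
    version and the length-filter bounds.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    records = [
        SeqRecord(Seq(seq), id=seq_id, description="")
        for seq_id, _gid, seq in db.iter_seqs()
    ]
    SeqIO.write(records, str(path / "sixteen_s.fasta"), "fasta")

    with open(path / "ko_copies.tsv", "w") as fh:
        fh.write("genome_id\tko_id\tcopies\n")
        for gid in sorted(db.genomes):
            rec = db.genomes[gid]
            for ko in sorted(rec.ko_copies):
                fh.write(f"{gid}\t{ko}\t{rec.ko_copies[ko]}\n")

    with open(path / "rrna_copies.tsv", "w") as fh:
        fh.write("genome_id\trrna_copy_number\n")
        for gid in sorted(db.genomes):
            fh.write(f"{gid}\t{db.genomes[gid].rrna_copy_number}\n")

    manifest = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "tool": "koinfer",
        "min_len": db.min_len,
        "max_len": db.max_len,
        "n_genomes": db.n_genomes,
    }
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def load_reference(path: Path | str) -> ReferenceDatabase:
    """Load a bundle written by :func:`save_reference`.

    Raises :class:`BundleError` on a missing file, a format-version
    mismatch, a 16S header referencing an unknown genome, or a copy-number
    sidecar that disagrees with the FASTA contents.
    """
    path = Path(path)
    for name in ("manifest.json", "sixteen_s.fasta", "ko_copies.tsv", "rrna_copies.tsv"):
        if not (path / name).exists():
            raise BundleError(f"bundle {path}: missing file {name!r}")

    with open(path / "manifest.json") as fh:
        manifest = json.load(fh)
    if manifest.get("format_version") != BUNDLE_FORMAT_VERSION:
        raise BundleError(
            f"bundle {path}: format version {manifest.get('format_version')!r} "
            f"is not supported (expected {BUNDLE_FORMAT_VERSION})"
        )

    declared: dict[str, int] = {}
    with open(path / "rrna_copies.tsv") as fh:
        header = next(fh, None)
        for line in fh:
            gid, n = line.rstrip("\n").split("\t")
            declared[gid] = int(n)

    seqs_by_genome: dict[str, list[str]] = {}
    for rec in SeqIO.parse(str(path / "sixteen_s.fasta"), "fasta"):
        if "|" not in rec.id:
            raise BundleError(
                f"bundle {path}: 16S header {rec.id!r} lacks 'genomeID|seqN' form"
            )
        gid = rec.id.rsplit("|", 1)[0]
        if gid not in declared:
            raise BundleError(
                f"bundle {path}: 16S header {rec.id!r} references unknown "
                f"genome {gid!r}"
            )
        seqs_by_genome.setdefault(gid, []).append(str(rec.seq).upper())

    for gid, n in declared.items():
        found = len(seqs_by_genome.get(gid, []))
        if found != n:
            raise BundleError(
                f"bundle {path}: genome {gid!r} declares {n} 16S copies but "
                f"FASTA holds {found}"
            )

    copies: dict[str, dict[str, int]] = {gid: {} for gid in declared}
    with open(path / "ko_copies.tsv") as fh:
        next(fh, None)
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise BundleError(
                    f"bundle {path}: ko_copies.tsv line {lineno}: expected 3 fields"
                )
            gid, ko, n = parts
            if gid not in declared:
                raise BundleError(
                    f"bundle {path}: ko_copies.tsv line {lineno}: unknown "
                    f"genome {gid!r}"
                )
            copies[gid][ko] = int(n)

    genomes = {
        gid: GenomeRecord(
            genome_id=gid,
            rrna_seqs=tuple(seqs_by_genome[gid]),
            ko_copies=copies[gid],
        )
        for gid in declared
    }
    return ReferenceDatabase(
        genomes=genomes,
        min_len=int(manifest["min_len"]),
        max_len=int(manifest["max_len"]),
    )
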