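"""Exact canonical k-mer species classification.

Each *sensu stricto* reference genome contributes the set of canonical
31-mers found in it and in no other reference (species-unique markers).  A
read set is reduced to its canonical k-mer profile (k-mers observed more
than ``min_count - 1`` times, i.e. > 4 by default), matched exactly against
every unique-marker set, and the per-species proportions of matched k-mers
reported.  Canonical form is the lexicographic minimum of a k-mer and its
reverse complement (A < C < G < T), making profiles strand-independent.
"""

from __future__ import annotations

import gzip
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

UNCLASSIFIED = "UNCLASSIFIED"

_RC = str.maketrans("ACGT", "TGCA")
_VALID_RUN = re.compile(r"[^ACGT]+")


def canonical(kmer: str) -> str:
    rc = kmer.translate(_RC)[::-1]
    return kmer if kmer <= rc else rc


def iter_canonical_kmers(seq: str, k: int) -> Iterable[str]:
    """Canonical k-mers of a sequence; runs of non-ACGT bases break windows."""
    seq = seq.upper()
    for chunk in _VALID_RUN.split(seq):
        for i in range(len(chunk) - k + 1):
            yield canonical(chunk[i : i + k])


@dataclass
class KmerDB:
    k: int
    species: list[str]
    unique_sets: dict[str, set[str]]

    def save(self, path: str | Path) -> None:
        """Sorted-text serialization: k, then one `species\\tkmer` per line."""
        with open(path, "w") as fh:
            fh.write(f"#k={self.k}\n")
            for sp in self.species:
                for kmer in sorted(self.unique_sets[sp]):
                    fh.write(f"{sp}\t{kmer}\n")

    @classmethod
    def load(cls, path: str | Path) -> "KmerDB":
        unique: dict[str, set[str]] = {}
        k = 0
        with open(path) as fh:
            for line in fh:
                if line.startswith("#k="):
                    k = int(line.strip().split("=", 1)[1])
                    continue
                sp, kmer = line.rstrip("\n").split("\t")
                unique.setdefault(sp, set()).add(kmer)
        return cls(k=k, species=sorted(unique), unique_sets=unique)


@dataclass
class SpeciesAssignment:
    sample: str
    total_matched: int
    counts: dict[str, int]
    proportions: dict[str, float] | None
    n_unmatched: int
    label: str = ""

    def __post_init__(self) -> None:
        if not self.label:
            if self.proportions is None:
                self.label = UNCLASSIFIED
            else:
                self.label = max(self.proportions, key=self.proportions.get)


def _open_maybe_gz(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def build_db(references: Mapping[str, str | Path], k: int = 31) -> KmerDB:
    """Per-species unique canonical k-mer sets from reference FASTAs.

    K-mers present in more than one species' reference are removed from
    every set.
    """
    per_species: dict[str, set[str]] = {}
    for sp, fasta in references.items():
        kmers: set[str] = set()
        with _open_maybe_gz(fasta) as fh:
            n_rec = 0
            for rec in SeqIO.parse(fh, "fasta"):
                n_rec += 1
                if len(rec.seq) < k:
                    logger.warning("%s: record %s shorter than k", sp, rec.id)
                    continue
                kmers.update(iter_canonical_kmers(str(rec.seq), k))
        if n_rec == 0:
            raise ValueError(f"empty FASTA for species {sp!r}")
        per_species[sp] = kmers
    seen: Counter[str] = Counter()
    for kmers in per_species.values():
        seen.update(kmers)
    shared = {kmer for kmer, c in seen.items() if c > 1}
    unique = {sp: kmers - shared for sp, kmers in per_species.items()}
    return KmerDB(k=k, species=sorted(per_species), unique_sets=unique)


def profile_sample(
    reads: str | Path | Sequence[str | Path],
    k: int = 31,
    min_count: int = 5,
) -> Counter:
    """Canonical k-mer multiset of one or more FASTQ files.

    Retains k-mers observed at least ``min_count`` times (default 5: the
    classifier keeps k-mers seen *more than 4* times).
    """
    if isinstance(reads, (str, Path)):
        reads = [reads]
    counts: Counter[str] = Counter()
    n_reads = 0
    for path in reads:
        with _open_maybe_gz(path) as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                n_reads += 1
                counts.update(iter_canonical_kmers(str(rec.seq), k))
    if n_reads == 0:
        logger.warning("no reads parsed from %s", reads)
    return Counter({kmer: c for kmer, c in counts.items() if c >= min_count})


def classify(
    profile: Counter,
    db: KmerDB,
    sample: str = "sample",
    count_weighted: bool = False,
) -> SpeciesAssignment:
    """Match a k-mer profile against the unique-marker database.

    Default proportions are over *distinct* matched k-mers; with
    ``count_weighted`` each k-mer contributes its observation count.
    Unmatched k-mers are excluded from the denominator and reported.
    """
    kmers = set(profile)
    counts: dict[str, int] = {}
    matched_kmers: set[str] = set()
    for sp in db.species:
        hit = kmers & db.unique_sets[sp]
        matched_kmers |= hit
        counts[sp] = (
            sum(profile[kmer] for kmer in hit) if count_weighted else len(hit)
        )
    total = sum(counts.values())
    props = {sp: c / total for sp, c in counts.items()} if total else None
    return SpeciesAssignment(
        sample=sample,
        total_matched=len(matched_kmers),
        counts=counts,
        proportions=props,
        n_unmatched=len(kmers - matched_kmers),
    )
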