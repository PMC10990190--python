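"""Genotype matrices, QC filters and genomic windowing.

Diploid genotypes are held as a dense dosage matrix (samples x sites) with
values 0/1/2 counting alternate alleles and -1 for missing.  All QC rules
operate on this representation:

* genotype-level: a call with low genotype quality or low depth is set to
  missing (``GQ <= gq_min`` or ``DP <= dp_min``, both inclusive);
* site-level: a site is dropped when *more than* ``max_missing`` of sample
  genotypes are missing;
* sample-level: a sample is kept when its mean depth is >= ``min_mean_dp``
  and *strictly more than* ``min_genotyped_fraction`` of its genotypes are
  non-missing.

Coordinates are 0-based half-open internally; VCF positions are converted on
read and converted back on write.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

MISSING = -1


class GenotypeError(ValueError):
    """Raised for malformed or empty genotype inputs."""


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNV. ``pos`` is 0-based."""

    chrom: str
    pos: int
    ref_allele: str = "A"
    alt_allele: str = "T"
    site_dp: int | None = None


@dataclass
class GenotypeMatrix:
    """Samples x sites dosage matrix with optional per-genotype GQ/DP."""

    sites: list[VariantSite]
    samples: list[str]
    dosage: np.ndarray  # int8/int16, shape (n_samples, n_sites), -1 missing
    gq: np.ndarray | None = None
    dp: np.ndarray | None = None
    contigs: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage)
        if self.dosage.shape != (len(self.samples), len(self.sites)):
            raise GenotypeError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.samples)}, {len(self.sites)})"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise GenotypeError(f"unknown sample: {sample!r}") from None

    def positions(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (chrom array, pos array) over sites."""
        chroms = np.array([s.chrom for s in self.sites])
        pos = np.array([s.pos for s in self.sites], dtype=np.int64)
        return chroms, pos

    def take_sites(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=np.intp)
        return GenotypeMatrix(
            sites=[self.sites[i] for i in idx],
            samples=list(self.samples),
            dosage=self.dosage[:, idx],
            gq=None if self.gq is None else self.gq[:, idx],
            dp=None if self.dp is None else self.dp[:, idx],
            contigs=dict(self.contigs),
        )

    def take_samples(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=np.intp)
        return GenotypeMatrix(
            sites=list(self.sites),
            samples=[self.samples[i] for i in idx],
            dosage=self.dosage[idx, :],
            gq=None if self.gq is None else self.gq[idx, :],
            dp=None if self.dp is None else self.dp[idx, :],
            contigs=dict(self.contigs),
        )


@dataclass
class RepeatMask:
    """Per-contig half-open [start, end) intervals; normalized on creation."""

    intervals: dict[str, np.ndarray]  # (n, 2) int arrays, merged & sorted

    @classmethod
    def from_intervals(cls, raw: dict[str, Iterable[tuple[int, int]]]) -> "RepeatMask":
        out: dict[str, np.ndarray] = {}
        for chrom, ivs in raw.items():
            arr = np.array(sorted((int(a), int(b)) for a, b in ivs), dtype=np.int64)
            out[chrom] = _merge_intervals(arr)
        return cls(out)

    @classmethod
    def from_bed(cls, path: str | Path) -> "RepeatMask":
        raw: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end = line.split("\t")[:3]
                raw.setdefault(chrom, []).append((int(start), int(end)))
        return cls.from_intervals(raw)

    @classmethod
    def empty(cls) -> "RepeatMask":
        return cls({})

    def covers(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Boolean mask: which of ``pos`` fall inside a masked interval."""
        pos = np.asarray(pos)
        ivs = self.intervals.get(chrom)
        if ivs is None or len(ivs) == 0:
            return np.zeros(pos.shape, dtype=bool)
        i = np.searchsorted(ivs[:, 0], pos, side="right") - 1
        ok = i >= 0
        out = np.zeros(pos.shape, dtype=bool)
        out[ok] = pos[ok] < ivs[i[ok], 1]
        return out

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.intervals):
                for a, b in self.intervals[chrom]:
                    fh.write(f"{chrom}\t{a}\t{b}\n")


def _merge_intervals(arr: np.ndarray) -> np.ndarray:
    if len(arr) == 0:
        return arr.reshape(0, 2)
    merged = [list(arr[0])]
    for a, b in arr[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return np.array(merged, dtype=np.int64)


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int
    end: int
    site_indices: tuple[int, ...]
    partial: bool = False

    @property
    def span(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class WindowSet:
    windows: list[Window]
    size: int
    step: int

    def __iter__(self):
        return iter(self.windows)

    def __len__(self) -> int:
        return len(self.windows)

    def __getitem__(self, i) -> Window:
        return self.windows[i]


def load_genotypes(
    vcf_path: str | Path, gq_min: int = 20, dp_min: int = 6
) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Genotypes with ``GQ <= gq_min`` or ``DP <= dp_min`` are set to missing.
    Non-biallelic records are dropped (count logged).  Positions are stored
    0-based.
    """
    from cyvcf2 import VCF

    path = Path(vcf_path)
    if not path.exists():
        raise IOError(f"no such VCF: {path}")
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise GenotypeError("VCF contains no samples")

    contigs: dict[str, int] = {}
    try:
        contigs = {n: l for n, l in zip(vcf.seqnames, vcf.seqlens)}
    except Exception:  # header without contig lengths
        contigs = {}

    sites: list[VariantSite] = []
    dosage_rows: list[np.ndarray] = []
    gq_rows: list[np.ndarray] = []
    dp_rows: list[np.ndarray] = []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_multi += 1
            continue
        # gts012: 0/1/2 dosage, 3 = unknown
        dos = var.gt_types.astype(np.int16)
        dos[dos == 3] = MISSING
        gq_field = var.format("GQ")
        dp_field = var.format("DP")
        gq = (
            gq_field[:, 0].astype(float)
            if gq_field is not None
            else np.full(len(dos), -1.0)
        )
        dp = (
            dp_field[:, 0].astype(float)
            if dp_field is not None
            else np.full(len(dos), -1.0)
        )
        bad = (gq <= gq_min) | (dp <= dp_min)
        dos[bad] = MISSING
        dosage_rows.append(dos)
        gq_rows.append(np.asarray(gq, dtype=np.int32))
        dp_rows.append(np.asarray(dp, dtype=np.int32))
        site_dp = var.INFO.get("DP")
        sites.append(
            VariantSite(
                chrom=var.CHROM,
                pos=var.POS - 1,
                ref_allele=var.REF,
                alt_allele=var.ALT[0],
                site_dp=int(site_dp) if site_dp is not None else None,
            )
        )
    if n_multi:
        logger.info("dropped %d non-biallelic records", n_multi)
    dosage = (
        np.stack(dosage_rows, axis=1)
        if dosage_rows
        else np.zeros((len(samples), 0), dtype=np.int16)
    )
    gq_arr = np.stack(gq_rows, axis=1) if gq_rows else None
    dp_arr = np.stack(dp_rows, axis=1) if dp_rows else None
    return GenotypeMatrix(
        sites=sites, samples=samples, dosage=dosage, gq=gq_arr, dp=dp_arr,
        contigs=contigs,
    )


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix back out as a minimal uncompressed VCF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in gm.contigs.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, site in enumerate(gm.sites):
            cells = []
            for i in range(gm.n_samples):
                gt = gt_str[int(gm.dosage[i, j])]
                gq = int(gm.gq[i, j]) if gm.gq is not None else 99
                dp = int(gm.dp[i, j]) if gm.dp is not None else 30
                cells.append(f"{gt}:{gq}:{dp}")
            fh.write(
                f"{site.chrom}\t{site.pos + 1}\t.\t{site.ref_allele}\t"
                f"{site.alt_allele}\t.\tPASS\t.\tGT:GQ:DP\t" + "\t".join(cells) + "\n"
            )


def filter_sites(gm: GenotypeMatrix, max_missing: float = 0.8) -> GenotypeMatrix:
    """Drop sites where strictly more than ``max_missing`` genotypes are missing."""
    if gm.n_sites == 0:
        return gm
    miss_frac = (gm.dosage == MISSING).mean(axis=0)
    keep = np.nonzero(miss_frac <= max_missing)[0]
    if len(keep) == 0:
        logger.warning("filter_sites removed every site")
    return gm.take_sites(keep)


def filter_samples(
    gm: GenotypeMatrix,
    min_mean_dp: float = 6,
    min_genotyped_fraction: float = 0.8,
) -> GenotypeMatrix:
    """Keep samples with mean DP >= ``min_mean_dp`` and genotyped fraction
    strictly > ``min_genotyped_fraction``."""
    if gm.dp is None:
        raise GenotypeError("per-genotype DP required for sample filtering")
    mean_dp = np.where(gm.dp >= 0, gm.dp, 0).mean(axis=1)
    geno_frac = (gm.dosage != MISSING).mean(axis=1)
    keep = np.nonzero((mean_dp >= min_mean_dp) & (geno_frac > min_genotyped_fraction))[0]
    return gm.take_samples(keep)


def build_windows(
    contigs: dict[str, int],
    size: int,
    step: int | None = None,
    mask: RepeatMask | None = None,
    sites: Sequence[VariantSite] = (),
) -> WindowSet:
    """Tile (or slide) windows across contigs, excluding masked sites.

    ``step == size`` gives tiled windows; the final short window at a contig
    end is retained and flagged ``partial``.
    """
    if step is None:
        step = size
    if size <= 0 or step <= 0:
        raise ValueError("size and step must be positive")
    if step > size:
        raise ValueError("step must be <= size")
    mask = mask or RepeatMask.empty()

    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for i, s in enumerate(sites):
        by_chrom.setdefault(s.chrom, []).append((s.pos, i))

    windows: list[Window] = []
    for chrom in contigs:
        length = contigs[chrom]
        entries = sorted(by_chrom.get(chrom, []))
        pos = np.array([p for p, _ in entries], dtype=np.int64)
        idx = np.array([i for _, i in entries], dtype=np.intp)
        if len(pos):
            unmasked = ~mask.covers(chrom, pos)
            pos, idx = pos[unmasked], idx[unmasked]
        last_start = max(length - size, 0)
        for start in range(0, last_start + step, step):
            end = min(start + size, length)
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="left")
            windows.append(
                Window(
                    chrom=chrom,
                    start=start,
                    end=end,
                    site_indices=tuple(int(i) for i in idx[lo:hi]),
                    partial=(end - start) < size,
                )
            )
    return WindowSet(windows=windows, size=size, step=step)


def heterozygosity(gm: GenotypeMatrix, sample: str) -> float:
    """Fraction of non-missing genotypes that are heterozygous."""
    row = gm.dosage[gm.sample_index(sample)]
    called = row != MISSING
    n = int(called.sum())
    if n == 0:
        raise GenotypeError(f"sample {sample!r} has no called genotypes")
    return float((row[called] == 1).sum() / n)


def windows_to_tsv(ws: WindowSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tn_sites\tpartial\n")
        for w in ws:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{len(w.site_indices)}\t{int(w.partial)}\n")


def read_metadata(path: str | Path):
    """Sample metadata TSV with columns sample, clade, lineage, category, year, location."""
    import pandas as pd

    return pd.read_csv(path, sep="\t", dtype=str)
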