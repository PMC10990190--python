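"""Windowed population-genetic statistics.

Implements Nei's nucleotide diversity (pi), absolute divergence (d_XY) and
net ancestral distance (d_a = d_XY - (pi_A + pi_B)/2) from allele
frequencies; pairwise identity-by-state on the dosage scale; a pairwise
coancestry coefficient; and the fd statistic of Martin et al. used to scan
windows for introgression.

All statistics consume a :class:`~feralgen.genotype.GenotypeMatrix` plus a
set of site indices (typically a window's ``site_indices``).  Frequencies
are computed from non-missing diploid genotypes; sites where a required
population is entirely missing are skipped and do not enter numerators or
denominators.

``pi`` and ``d_XY`` are per-site averages.  When the genotype set holds
variant sites only, the average is over variant sites and the resulting
``WindowStat`` carries ``mode="variant_sites"``; pass ``n_accessible`` to
average over all accessible sites instead (``mode="accessible"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genotype import MISSING, GenotypeMatrix


class PopulationError(ValueError):
    """Raised for invalid population specifications."""


@dataclass
class PopulationSpec:
    name: str
    members: list[str]
    role: str = "plain"  # one of P1, P2, P3, O, plain

    def indices(self, gm: GenotypeMatrix) -> np.ndarray:
        if not self.members:
            raise PopulationError(f"population {self.name!r} has no members")
        return np.array([gm.sample_index(m) for m in self.members], dtype=np.intp)


@dataclass
class WindowStat:
    window: tuple[str, int, int] | None
    value: float | None
    n_sites: int
    mode: str = "variant_sites"
    extra: dict = field(default_factory=dict)

    @property
    def defined(self) -> bool:
        return self.value is not None


def _freqs(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Alternate-allele frequency and haplotype count per site.

    ``dosage``: (members, sites).  Returns (p, n_hap) with p = nan where no
    member is genotyped.
    """
    called = dosage != MISSING
    n_hap = 2 * called.sum(axis=0)
    alt = np.where(called, dosage, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_hap > 0, alt / np.maximum(n_hap, 1), np.nan)
    return p.astype(float), n_hap


def nucleotide_diversity(
    gm: GenotypeMatrix,
    pop: PopulationSpec,
    site_indices: Sequence[int],
    window: tuple[str, int, int] | None = None,
    n_accessible: int | None = None,
) -> WindowStat:
    """Nei's pi: mean over sites of ``2 p (1-p) n/(n-1)``."""
    idx = np.asarray(site_indices, dtype=np.intp)
    if len(idx) == 0:
        return WindowStat(window, None, 0)
    sub = gm.dosage[np.ix_(pop.indices(gm), idx)]
    p, n = _freqs(sub)
    ok = n >= 2
    if not ok.any():
        return WindowStat(window, None, 0)
    per_site = 2.0 * p[ok] * (1.0 - p[ok]) * n[ok] / (n[ok] - 1.0)
    denom = n_accessible if n_accessible is not None else int(ok.sum())
    mode = "accessible" if n_accessible is not None else "variant_sites"
    return WindowStat(window, float(per_site.sum() / denom), int(ok.sum()), mode)


def dxy(
    gm: GenotypeMatrix,
    popA: PopulationSpec,
    popB: PopulationSpec,
    site_indices: Sequence[int],
    window: tuple[str, int, int] | None = None,
    n_accessible: int | None = None,
) -> WindowStat:
    """Nei's d_XY: mean over sites of ``pA (1-pB) + pB (1-pA)``."""
    idx = np.asarray(site_indices, dtype=np.intp)
    if len(idx) == 0:
        return WindowStat(window, None, 0)
    pA, nA = _freqs(gm.dosage[np.ix_(popA.indices(gm), idx)])
    pB, nB = _freqs(gm.dosage[np.ix_(popB.indices(gm), idx)])
    ok = (nA > 0) & (nB > 0)
    if not ok.any():
        return WindowStat(window, None, 0)
    per_site = pA[ok] * (1 - pB[ok]) + pB[ok] * (1 - pA[ok])
    denom = n_accessible if n_accessible is not None else int(ok.sum())
    mode = "accessible" if n_accessible is not None else "variant_sites"
    return WindowStat(window, float(per_site.sum() / denom), int(ok.sum()), mode)


def nei_da(
    gm: GenotypeMatrix,
    popA: PopulationSpec,
    popB: PopulationSpec,
    site_indices: Sequence[int],
    window: tuple[str, int, int] | None = None,
    n_accessible: int | None = None,
) -> WindowStat:
    """Nei's d_a = d_XY - (pi_A + pi_B)/2; may be negative, reported as-is.

    Singleton populations contribute pi = 0 (a lone diploid still carries two
    haplotypes, so its heterozygous sites do contribute)."""
    d = dxy(gm, popA, popB, site_indices, window, n_accessible)
    if not d.defined:
        return WindowStat(window, None, 0)
    piA = nucleotide_diversity(gm, popA, site_indices, window, n_accessible)
    piB = nucleotide_diversity(gm, popB, site_indices, window, n_accessible)
    if not (piA.defined and piB.defined):
        return WindowStat(window, None, 0)
    return WindowStat(
        window,
        d.value - (piA.value + piB.value) / 2.0,
        d.n_sites,
        d.mode,
    )


def ibs(
    gm: GenotypeMatrix,
    sampleA: str,
    sampleB: str,
    site_indices: Sequence[int],
) -> tuple[float | None, int, float]:
    """Pairwise identity-by-state on the dosage scale.

    Per co-genotyped site IBS = ``1 - |g_A - g_B| / 2``.  Returns
    (mean IBS or None, n co-genotyped sites, fraction of sites with either
    genotype missing).
    """
    idx = np.asarray(site_indices, dtype=np.intp)
    if len(idx) == 0:
        return None, 0, 1.0
    a = gm.dosage[gm.sample_index(sampleA), idx]
    b = gm.dosage[gm.sample_index(sampleB), idx]
    both = (a != MISSING) & (b != MISSING)
    n = int(both.sum())
    missing_fraction = 1.0 - n / len(idx)
    if n == 0:
        return None, 0, 1.0
    val = float(np.mean(1.0 - np.abs(a[both] - b[both]) / 2.0))
    return val, n, missing_fraction


def pairwise_ibs_matrix(
    gm: GenotypeMatrix, samples: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Genome-wide IBS for every sample pair (vectorized)."""
    names = list(samples) if samples is not None else list(gm.samples)
    idx = np.array([gm.sample_index(s) for s in names], dtype=np.intp)
    D = gm.dosage[idx].astype(np.float64)
    called = D != MISSING
    D = np.where(called, D, 0.0)
    n = len(names)
    out = np.ones((n, n))
    for i in range(n):
        both = called[i] & called[i + 1 :]
        diff = np.abs(D[i] - D[i + 1 :]) * both
        cnt = both.sum(axis=1)
        with np.errstate(invalid="ignore"):
            vals = 1.0 - (diff.sum(axis=1) / np.maximum(cnt, 1)) / 2.0
        vals = np.where(cnt > 0, vals, np.nan)
        out[i, i + 1 :] = vals
        out[i + 1 :, i] = vals
    return out, names


def coancestry(gm: GenotypeMatrix, sampleA: str, sampleB: str) -> float:
    """Method-of-moments pairwise coancestry on the allele-sharing scale.

    The observed mean allele sharing ``s_AB`` is standardized against its
    expectation ``s_0`` for two independent draws from the panel-wide allele
    frequencies: ``f = (s_AB - s_0) / (1 - s_0)``.  Duplicate samples score
    ~1 and panel-average pairs ~0.
    """
    a = gm.dosage[gm.sample_index(sampleA)]
    b = gm.dosage[gm.sample_index(sampleB)]
    p, n_hap = _freqs(gm.dosage)
    both = (a != MISSING) & (b != MISSING) & (n_hap > 0)
    if not both.any():
        raise PopulationError("no co-genotyped sites")
    pj = p[both]
    var = pj * (1 - pj)
    if not (var > 0).any():
        raise PopulationError("monomorphic matrix: coancestry undefined")
    aj, bj = a[both].astype(float), b[both].astype(float)
    s_obs = float(np.mean(1.0 - np.abs(aj - bj) / 2.0))
    # E|gA - gB|/2 for independent HWE draws at frequency p:
    # dosage difference |X - Y| with X,Y ~ Binomial(2, p) independent.
    q = 1 - pj
    # P(|X-Y|=1) and P(|X-Y|=2) in closed form
    p0, p1_, p2 = q * q, 2 * pj * q, pj * pj
    pr_diff1 = 2 * (p0 * p1_ + p1_ * p2)
    pr_diff2 = 2 * p0 * p2
    s_null = float(np.mean(1.0 - (pr_diff1 + 2 * pr_diff2) / 2.0))
    if s_null >= 1.0:
        raise PopulationError("monomorphic matrix: coancestry undefined")
    return (s_obs - s_null) / (1.0 - s_null)


def fd_window(
    gm: GenotypeMatrix,
    P1: PopulationSpec,
    P2: PopulationSpec,
    P3: PopulationSpec,
    O: PopulationSpec,
    site_indices: Sequence[int],
    window: tuple[str, int, int] | None = None,
    negative: str = "clamp",
) -> WindowStat:
    """The fd statistic for one window.

    Sites are polarized so the outgroup major allele is ancestral (outgroup
    frequency ties at 0.5 are uninformative and skipped).  With derived
    frequencies p1..p3, pO:

    ``S  = sum (1-p1) p2 p3 (1-pO) - p1 (1-p2) p3 (1-pO)``
    ``S_D`` substitutes ``pD = max(p2, p3)`` for both p2 and p3.
    ``fd = S / S_D``; ``S_D = 0`` is undefined.  Windows with ``S <= 0``:
    ``negative="clamp"`` returns 0 (fd is only interpretable for an excess
    of shared derived alleles), ``"undefined"`` returns None, ``"keep"``
    returns the raw signed ratio (useful for null-calibration, where the
    signed windowed values are symmetric about 0 while clamping censors
    one tail).
    """
    if negative not in ("clamp", "undefined", "keep"):
        raise ValueError("negative must be clamp | undefined | keep")
    pops = [P1, P2, P3, O]
    seen: set[str] = set()
    for p_ in pops:
        overlap = seen & set(p_.members)
        if overlap:
            raise PopulationError(f"populations overlap: {sorted(overlap)}")
        seen |= set(p_.members)

    idx = np.asarray(site_indices, dtype=np.intp)
    if len(idx) == 0:
        return WindowStat(window, None, 0)
    freqs = []
    for p_ in pops:
        f, n = _freqs(gm.dosage[np.ix_(p_.indices(gm), idx)])
        freqs.append((f, n))
    ok = np.ones(len(idx), dtype=bool)
    for f, n in freqs:
        ok &= n > 0
    p1, p2, p3, pO = (f[ok] for f, _ in freqs)
    # polarize: outgroup major allele = ancestral
    flip = pO > 0.5
    tie = pO == 0.5
    use = ~tie
    p1, p2, p3, pO, flip = p1[use], p2[use], p3[use], pO[use], flip[use]
    p1 = np.where(flip, 1 - p1, p1)
    p2 = np.where(flip, 1 - p2, p2)
    p3 = np.where(flip, 1 - p3, p3)
    pO = np.where(flip, 1 - pO, pO)
    if len(p1) == 0:
        return WindowStat(window, None, 0)
    S = float(np.sum((1 - p1) * p2 * p3 * (1 - pO) - p1 * (1 - p2) * p3 * (1 - pO)))
    pD = np.maximum(p2, p3)
    S_D = float(np.sum((1 - p1) * pD * pD * (1 - pO) - p1 * (1 - pD) * pD * (1 - pO)))
    n_used = int(len(p1))
    if S <= 0 and negative != "keep":
        return WindowStat(window, 0.0 if negative == "clamp" else None, n_used)
    if S_D == 0:
        return WindowStat(window, None, n_used)
    return WindowStat(window, S / S_D, n_used)


def window_stats_to_tsv(stats: Sequence[WindowStat], stat_name: str, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstat\tvalue\tn_sites\n")
        for s in stats:
            chrom, start, end = s.window if s.window else (".", -1, -1)
            val = "NA" if s.value is None else f"{s.value:.6g}"
            fh.write(f"{chrom}\t{start}\t{end}\t{stat_name}\t{val}\t{s.n_sites}\n")
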