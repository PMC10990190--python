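"""Synthetic data generators with known truth.

Everything the pipeline consumes can be generated here with a truth table,
emulating the statistical structure the analyses assume:

* a reference panel of clades with drift-structured allele frequencies
  (Balding-Nichols Beta model, per-clade drift parameter F) containing
  near-clonal lineages of homozygous isolates;
* mosaic recombinant genomes assembled window-by-window from panel lineage
  haplotypes via a Markov donor process, optionally overwritten in blocks
  by a divergent unsampled donor (introgression);
* local window trees under congruent vs introgressed topologies with an
  explicit unresolved-placement noise process;
* per-site read-depth profiles under Normal(mean=30, sd=10) noise with
  configurable whole-chromosome and segmental copy-number events
  (see :func:`feralgen.ploidy.simulate_depth_profile`, re-exported here).

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype import GenotypeMatrix, VariantSite, WindowSet
from .introgression import LocalTree
from .ploidy import simulate_depth_profile  # noqa: F401  (re-export)

DEFAULT_CONTIGS = {"chrI": 250_000, "chrII": 250_000}


@dataclass
class PanelModel:
    n_clades: int = 3
    F: float | Sequence[float] = 0.2
    lineages_per_clade: int = 3
    members_per_lineage: int = 3
    clone_mutation_rate: float = 1e-3
    n_sites: int = 5000
    contigs: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CONTIGS))

    def f_values(self) -> list[float]:
        if np.isscalar(self.F):
            return [float(self.F)] * self.n_clades
        vals = list(self.F)
        if len(vals) != self.n_clades:
            raise ValueError("per-clade F length != n_clades")
        return [float(f) for f in vals]


@dataclass
class MosaicSpec:
    n_isolates: int = 5
    switch_prob: float = 0.3
    donor_weights: Mapping[str, float] | None = None
    introgression_fraction: float = 0.0
    introgression_block: int = 3
    heterozygosity: float = 0.0
    seed: int = 0


@dataclass
class Panel:
    gm: GenotypeMatrix
    truth: pd.DataFrame  # sample, clade, lineage
    founder_haplotypes: dict[str, np.ndarray]  # lineage_id -> 0/1 haplotype
    lineage_clade: dict[str, str]
    ancestral_freq: np.ndarray


def _evenly_spaced_sites(contigs: Mapping[str, int], n_sites: int) -> list[VariantSite]:
    total = sum(contigs.values())
    sites: list[VariantSite] = []
    alloc = {c: max(1, int(round(n_sites * l / total))) for c, l in contigs.items()}
    for chrom, length in contigs.items():
        n = alloc[chrom]
        pos = np.linspace(0, length - 1, num=n, dtype=np.int64)
        pos = np.unique(pos)
        sites.extend(VariantSite(chrom=chrom, pos=int(p)) for p in pos)
    return sites


def simulate_panel(model: PanelModel, seed: int = 0) -> Panel:
    """Drift-structured reference panel with near-clonal lineages.

    Ancestral frequencies ~ Uniform(0.05, 0.95); clade frequencies follow
    the Balding-Nichols Beta(p(1-F)/F, (1-p)(1-F)/F) drift model; each
    lineage is founded by one haplotype drawn from its clade frequencies
    (members are homozygous founder clones with ``clone_mutation_rate``
    per-site flips).
    """
    if model.lineages_per_clade < 1 or model.members_per_lineage < 1:
        raise ValueError("need at least one lineage and one member per lineage")
    rng = np.random.default_rng(seed)
    sites = _evenly_spaced_sites(model.contigs, model.n_sites)
    n_sites = len(sites)
    p_anc = rng.uniform(0.05, 0.95, size=n_sites)

    samples: list[str] = []
    rows: list[np.ndarray] = []
    truth_rows = []
    founders: dict[str, np.ndarray] = {}
    lineage_clade: dict[str, str] = {}
    for ci, F in enumerate(model.f_values()):
        if not 0 < F < 1:
            raise ValueError("F must be in (0, 1)")
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        p_clade = rng.beta(a, b)
        clade = f"clade{ci}"
        for li in range(model.lineages_per_clade):
            lid = f"{clade}_lin{li}"
            hap = (rng.random(n_sites) < p_clade).astype(np.int16)
            founders[lid] = hap
            lineage_clade[lid] = clade
            for mi in range(model.members_per_lineage):
                dos = 2 * hap.copy()
                if model.clone_mutation_rate > 0:
                    flip = rng.random(n_sites) < model.clone_mutation_rate
                    dos[flip] = 2 - dos[flip]
                name = f"{lid}_m{mi}"
                samples.append(name)
                rows.append(dos)
                truth_rows.append({"sample": name, "clade": clade, "lineage": lid})

    dosage = np.stack(rows, axis=0)
    gm = GenotypeMatrix(
        sites=sites,
        samples=samples,
        dosage=dosage,
        gq=np.full(dosage.shape, 99, dtype=np.int32),
        dp=np.full(dosage.shape, 30, dtype=np.int32),
        contigs=dict(model.contigs),
    )
    return Panel(
        gm=gm,
        truth=pd.DataFrame(truth_rows),
        founder_haplotypes=founders,
        lineage_clade=lineage_clade,
        ancestral_freq=p_anc,
    )


def _mosaic_haplotype(
    panel: Panel,
    windows: WindowSet,
    spec: MosaicSpec,
    rng: np.random.Generator,
    donor_hap: np.ndarray | None,
    intro_windows: set[int],
) -> tuple[np.ndarray, list[str]]:
    lineage_ids = sorted(panel.founder_haplotypes)
    weights = None
    if spec.donor_weights:
        w = np.array([spec.donor_weights.get(l, 0.0) for l in lineage_ids])
        weights = w / w.sum()
    n_sites = panel.gm.n_sites
    hap = np.zeros(n_sites, dtype=np.int16)
    donors: list[str] = []
    current = str(rng.choice(lineage_ids, p=weights))
    for wi, w in enumerate(windows):
        if wi > 0 and rng.random() < spec.switch_prob:
            others = [l for l in lineage_ids if l != current]
            ow = None
            if weights is not None:
                ow = np.array([spec.donor_weights.get(l, 0.0) for l in others])
                ow = ow / ow.sum()
            current = str(rng.choice(others, p=ow))
        idx = np.asarray(w.site_indices, dtype=np.intp)
        if wi in intro_windows and donor_hap is not None:
            hap[idx] = donor_hap[idx]
            donors.append("DONOR")
        else:
            hap[idx] = panel.founder_haplotypes[current][idx]
            donors.append(current)
    return hap, donors


def simulate_mosaic(
    panel: Panel,
    spec: MosaicSpec,
    windows: WindowSet,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Mosaic recombinant isolates assembled from panel lineage haplotypes.

    The window donor follows a Markov chain with per-window switch
    probability; introgressed blocks (consecutive runs of
    ``introgression_block`` windows totalling ``introgression_fraction`` of
    windows) are overwritten with a divergent unsampled donor haplotype.
    With ``heterozygosity > 0`` two independent mosaic haplotypes are
    paired, otherwise isolates are homozygous.  Returns the mosaic genotype
    matrix (same sites as the panel) and a truth table
    (sample, window_index, chrom, start, end, donor, introgressed).
    """
    if not 0 <= spec.introgression_fraction <= 1:
        raise ValueError("introgression fraction must be in [0, 1]")
    if len(panel.founder_haplotypes) < 2:
        raise ValueError("panel must carry >= 2 lineages")
    rng = np.random.default_rng(spec.seed)
    n_sites = panel.gm.n_sites
    n_win = len(windows)

    donor_hap = None
    if spec.introgression_fraction > 0:
        # divergent unsampled donor: independent frequencies, strong drift
        p_div = rng.beta(
            panel.ancestral_freq * 0.25, (1 - panel.ancestral_freq) * 0.25
        )
        donor_hap = (rng.random(n_sites) < p_div).astype(np.int16)

    samples, rows, truth_rows = [], [], []
    for mi in range(spec.n_isolates):
        intro_windows: set[int] = set()
        if spec.introgression_fraction > 0:
            n_target = int(round(spec.introgression_fraction * n_win))
            while len(intro_windows) < n_target:
                start = int(rng.integers(0, max(1, n_win - spec.introgression_block)))
                intro_windows.update(
                    range(start, min(start + spec.introgression_block, n_win))
                )
        h1, donors1 = _mosaic_haplotype(panel, windows, spec, rng, donor_hap, intro_windows)
        if spec.heterozygosity > 0:
            h2, _ = _mosaic_haplotype(panel, windows, spec, rng, donor_hap, intro_windows)
            mixed = rng.random(n_sites) < 2 * spec.heterozygosity
            dos = np.where(mixed, h1 + h2, 2 * h1).astype(np.int16)
        else:
            dos = (2 * h1).astype(np.int16)
        name = f"mosaic{mi:02d}"
        samples.append(name)
        rows.append(dos)
        for wi, w in enumerate(windows):
            truth_rows.append(
                {"sample": name, "window_index": wi, "chrom": w.chrom,
                 "start": w.start, "end": w.end, "donor": donors1[wi],
                 "introgressed": wi in intro_windows}
            )

    dosage = np.stack(rows, axis=0)
    gm = GenotypeMatrix(
        sites=list(panel.gm.sites),
        samples=samples,
        dosage=dosage,
        gq=np.full(dosage.shape, 99, dtype=np.int32),
        dp=np.full(dosage.shape, 30, dtype=np.int32),
        contigs=dict(panel.gm.contigs),
    )
    return gm, pd.DataFrame(truth_rows)


def concat_samples(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Stack two matrices over the same site list."""
    if [s.pos for s in a.sites] != [s.pos for s in b.sites] or [
        s.chrom for s in a.sites
    ] != [s.chrom for s in b.sites]:
        raise ValueError("site lists differ")
    return GenotypeMatrix(
        sites=list(a.sites),
        samples=list(a.samples) + list(b.samples),
        dosage=np.concatenate([a.dosage, b.dosage], axis=0),
        gq=None
        if a.gq is None or b.gq is None
        else np.concatenate([a.gq, b.gq], axis=0),
        dp=None
        if a.dp is None or b.dp is None
        else np.concatenate([a.dp, b.dp], axis=0),
        contigs=dict(a.contigs),
    )


# ---------------------------------------------------------------------------
# local trees
# ---------------------------------------------------------------------------


@dataclass
class TreePopulations:
    test: list[str]
    source: list[str]
    mo: list[str]
    wrp: list[str]
    outgroup: list[str]

    @classmethod
    def default(cls, n_test: int = 10) -> "TreePopulations":
        return cls(
            test=[f"test{i}_h1" for i in range(n_test)],
            source=["src1", "src2", "src3", "src4"],
            mo=["mo1", "mo2"],
            wrp=["wrp1", "wrp2", "wrp3"],
            outgroup=["og1", "og2"],
        )


def _clade(leaves: Sequence[str], rng: np.random.Generator) -> str:
    parts = [f"{l}:{0.05 + 0.1 * rng.random():.4f}" for l in leaves]
    return "(" + ",".join(parts) + f"):{0.05 + 0.1 * rng.random():.4f}"


def simulate_local_trees(
    windows: WindowSet,
    introgressed_windows: Sequence[int],
    populations: TreePopulations | None = None,
    introgressed_af: float = 1.0,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[list[LocalTree], pd.DataFrame]:
    """One newick tree per window under congruent vs introgressed topology.

    Congruent windows nest every test haplotype inside the wrp clade
    (sister to mo, with the source clade outside); introgressed windows
    place each test haplotype inside the source clade with probability
    ``introgressed_af``.  With probability ``noise`` a test haplotype is
    instead attached above the source/(mo,wrp) split, a placement that is
    deliberately neither congruent nor incongruent (UNRESOLVED).
    """
    pops = populations or TreePopulations.default()
    intro = set(int(i) for i in introgressed_windows)
    rng = np.random.default_rng(seed)
    trees, truth_rows = [], []
    for wi, w in enumerate(windows):
        src_extra, wrp_extra, floating = [], [], []
        for hap in pops.test:
            if noise > 0 and rng.random() < noise:
                floating.append(hap)
            elif wi in intro and rng.random() < introgressed_af:
                src_extra.append(hap)
            else:
                wrp_extra.append(hap)
        og = _clade(pops.outgroup, rng)
        src = _clade(pops.source + src_extra, rng)
        mo = _clade(pops.mo, rng)
        wrp = _clade(pops.wrp + wrp_extra, rng)
        core = f"({src},({mo},{wrp}):{0.1 + 0.05 * rng.random():.4f})"
        if floating:
            inner = ",".join(
                [f"{h}:{0.05 + 0.1 * rng.random():.4f}" for h in floating] + [core + ":0.05"]
            )
            core = f"({inner})"
        newick = f"({og},{core}:0.05);"
        trees.append(LocalTree(window=w.span, newick=newick, rooted=False))
        truth_rows.append(
            {"window_index": wi, "chrom": w.chrom, "start": w.start,
             "end": w.end, "introgressed": wi in intro,
             "n_introgressed_haps": len(src_extra)}
        )
    return trees, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# toy references / reads and fixture emission
# ---------------------------------------------------------------------------


def random_genome(length: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def simulate_reads(
    genome: str, n_reads: int, read_len: int = 80, seed: int = 0,
    revcomp_fraction: float = 0.5,
) -> list[str]:
    """Error-free reads uniformly sampled from a genome, random strand."""
    from .kmers import _RC

    rng = np.random.default_rng(seed)
    reads = []
    for _ in range(n_reads):
        start = int(rng.integers(0, len(genome) - read_len + 1))
        seq = genome[start : start + read_len]
        if rng.random() < revcomp_fraction:
            seq = seq.translate(_RC)[::-1]
        reads.append(seq)
    return reads


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_fastq(reads: Sequence[str], path: str | Path, prefix: str = "read") -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{prefix}{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def emit_fixtures(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a complete set of plain-text pipeline inputs with truth tables."""
    from .genotype import RepeatMask, build_windows, write_vcf
    from .ploidy import default_site_counts

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    model = PanelModel()
    panel = simulate_panel(model, seed=seed)
    mask = RepeatMask.from_intervals({"chrI": [(100_000, 110_000)]})
    windows = build_windows(model.contigs, size=25_000, mask=mask,
                            sites=panel.gm.sites)
    mspec = MosaicSpec(n_isolates=4, seed=seed + 1,
                       introgression_fraction=0.2, heterozygosity=0.0)
    mosaic_gm, mosaic_truth = simulate_mosaic(panel, mspec, windows)
    combined = concat_samples(panel.gm, mosaic_gm)

    paths["vcf"] = out / "cohort.vcf"
    write_vcf(combined, paths["vcf"])
    paths["mask"] = out / "repeats.bed"
    mask.to_bed(paths["mask"])
    paths["panel_truth"] = out / "panel_truth.tsv"
    panel.truth.to_csv(paths["panel_truth"], sep="\t", index=False)
    paths["mosaic_truth"] = out / "mosaic_truth.tsv"
    mosaic_truth.to_csv(paths["mosaic_truth"], sep="\t", index=False)

    meta = panel.truth.copy()
    meta["category"] = np.where(
        meta["lineage"].str.endswith("lin0"), "starter", "non-starter"
    )
    meta["year"] = 2020
    meta["location"] = "synthetic"
    paths["metadata"] = out / "metadata.tsv"
    meta.to_csv(paths["metadata"], sep="\t", index=False)

    tree_windows = build_windows({"chrI": 200_000}, size=10_000)
    rng = np.random.default_rng(seed + 2)
    intro = sorted(rng.choice(len(tree_windows), size=6, replace=False))
    trees, tree_truth = simulate_local_trees(tree_windows, intro, seed=seed + 3)
    tree_dir = out / "trees"
    tree_dir.mkdir(exist_ok=True)
    index_rows = []
    for i, lt in enumerate(trees):
        p = tree_dir / f"window_{i:03d}.nwk"
        p.write_text(lt.newick + "\n")
        index_rows.append(
            {"chrom": lt.window[0], "start": lt.window[1], "end": lt.window[2],
             "path": f"trees/window_{i:03d}.nwk"}
        )
    paths["tree_index"] = out / "tree_index.tsv"
    pd.DataFrame(index_rows).to_csv(paths["tree_index"], sep="\t", index=False)
    paths["tree_truth"] = out / "tree_truth.tsv"
    tree_truth.to_csv(paths["tree_truth"], sep="\t", index=False)

    counts = default_site_counts(4000)
    prof = simulate_depth_profile(counts, aneuploidies=[("chrVI", 0.5)], seed=seed + 4)
    depth_rows = []
    for chrom, v in prof.depths.items():
        for pos, d in enumerate(v):
            depth_rows.append((chrom, pos, int(d)))
    paths["depth"] = out / "depth.tsv"
    with open(paths["depth"], "w") as fh:
        fh.write("chrom\tpos\tdepth\n")
        for chrom, pos, d in depth_rows:
            fh.write(f"{chrom}\t{pos}\t{d}\n")

    ref_a = random_genome(3000, seed=seed + 5)
    ref_b = random_genome(3000, seed=seed + 6)
    paths["ref_a"] = out / "species_A.fasta"
    paths["ref_b"] = out / "species_B.fasta"
    write_fasta({"A_chr1": ref_a}, paths["ref_a"])
    write_fasta({"B_chr1": ref_b}, paths["ref_b"])
    reads = simulate_reads(ref_a, n_reads=400, seed=seed + 7)
    paths["reads"] = out / "sample_A.fastq"
    write_fastq(reads * 5, paths["reads"])  # repeat so k-mer counts pass min_count
    return paths
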