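"""Local-tree incongruence scanning and fixed admixture-block selection.

For each genomic window a haplotype-labelled local tree is tested: a focal
haplotype is INCONGRUENT when, on the subtree pruned to the focal haplotype,
the putative source clade, the Mediterranean-oak-like anchor clade (mo) and
the wine reference panel (wrp), the focal haplotype forms a clade with the
source group that excludes every mo/wrp leaf while failing to form a clade
with mo+wrp.  CONGRUENT is the reverse (focal + mo + wrp form a clade
excluding the source); anything else is UNRESOLVED.

Per window, the admixture allele frequency (AF) is the fraction of resolved
population haplotypes called INCONGRUENT.  Fixed blocks are maximal runs of
AF = 1 windows of at least ``min_run`` windows with breakpoint windows
trimmed off both ends.  fd-scan and topology evidence combine by union.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy

INCONGRUENT = "INCONGRUENT"
CONGRUENT = "CONGRUENT"
UNRESOLVED = "UNRESOLVED"


class RootingError(ValueError):
    """Outgroup absent from an unrooted tree."""


@dataclass
class LocalTree:
    window: tuple[str, int, int]
    newick: str
    rooted: bool = False

    def tree(self) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.newick, schema="newick",
            rooting="force-rooted" if self.rooted else "force-unrooted",
            preserve_underscores=True,
        )


@dataclass
class SubtreeCall:
    window: tuple[str, int, int]
    haplotype: str
    call: str  # INCONGRUENT | CONGRUENT | UNRESOLVED


@dataclass
class WindowAFRecord:
    window: tuple[str, int, int]
    af: float | None  # None when every call UNRESOLVED
    n_incongruent: int
    n_resolved: int
    calls: list[SubtreeCall] = field(default_factory=list)


@dataclass
class AdmixtureBlock:
    population: str
    chrom: str
    start: int
    end: int
    windows: list[tuple[str, int, int]]
    fixed: bool = True


def _leafset(tree: dendropy.Tree) -> set[str]:
    return {lf.taxon.label for lf in tree.leaf_node_iter()}


def _mrca_leafset(tree: dendropy.Tree, labels: set[str]) -> set[str]:
    mrca = tree.mrca(taxon_labels=sorted(labels))
    return {lf.taxon.label for lf in mrca.leaf_iter()}


def classify_local_topology(
    tree: LocalTree,
    test_hap: str,
    source: Iterable[str],
    mo: Iterable[str],
    wrp: Iterable[str],
    outgroup: Iterable[str],
) -> SubtreeCall:
    """Classify one haplotype on one window tree.

    The tree is rooted on the outgroup (if unrooted), pruned to the groups
    of interest, the outgroup removed, and monophyly of
    ``{test} + source`` versus ``{test} + mo + wrp`` evaluated.
    """
    source, mo, wrp = set(source), set(mo), set(wrp)
    outgroup = set(outgroup)
    t = tree.tree()
    leaves = _leafset(t)
    if test_hap not in leaves:
        raise ValueError(f"test haplotype {test_hap!r} not in tree")

    src_in, mo_in, wrp_in = source & leaves, mo & leaves, wrp & leaves
    if not (src_in and mo_in and wrp_in):
        return SubtreeCall(tree.window, test_hap, UNRESOLVED)

    if not tree.rooted:
        og_in = outgroup & leaves
        if not og_in:
            raise RootingError("outgroup absent from unrooted tree")
        if og_in == leaves:
            return SubtreeCall(tree.window, test_hap, UNRESOLVED)
        t.is_rooted = True  # treat seed as provisional root while locating the outgroup
        mrca = t.mrca(taxon_labels=sorted(og_in))
        if mrca is t.seed_node:
            # outgroup spans the root; root on the first outgroup leaf's edge
            node = t.find_node_with_taxon_label(sorted(og_in)[0])
            t.reroot_at_edge(node.edge, update_bipartitions=False)
        else:
            t.reroot_at_edge(mrca.edge, update_bipartitions=False)

    keep = ({test_hap} | src_in | mo_in | wrp_in) & leaves
    t.retain_taxa_with_labels(sorted(keep))

    in_clade_src = _mrca_leafset(t, {test_hap} | src_in)
    test_src_monophyletic = not (in_clade_src & (mo_in | wrp_in))
    in_clade_mw = _mrca_leafset(t, {test_hap} | mo_in | wrp_in)
    test_mw_clade = in_clade_mw == ({test_hap} | mo_in | wrp_in)

    if test_src_monophyletic and not test_mw_clade:
        return SubtreeCall(tree.window, test_hap, INCONGRUENT)
    if test_mw_clade and not (in_clade_mw & src_in):
        return SubtreeCall(tree.window, test_hap, CONGRUENT)
    return SubtreeCall(tree.window, test_hap, UNRESOLVED)


def scan_windows(
    trees: Sequence[LocalTree],
    population: Iterable[str],
    source: Iterable[str],
    mo: Iterable[str],
    wrp: Iterable[str],
    outgroup: Iterable[str],
) -> list[WindowAFRecord]:
    """Run the subtree test for every population haplotype in every window.

    AF = incongruent / resolved calls; haplotypes missing from a window's
    tree (failed trees) are excluded from the denominator.
    """
    population = sorted(set(population))
    if not population:
        raise ValueError("empty population")
    records = []
    for lt in trees:
        calls = []
        tree_leaves = _leafset(lt.tree())
        for hap in population:
            if hap not in tree_leaves:
                continue
            try:
                call = classify_local_topology(lt, hap, source, mo, wrp, outgroup)
            except RootingError:
                call = SubtreeCall(lt.window, hap, UNRESOLVED)
            calls.append(call)
        n_inc = sum(c.call == INCONGRUENT for c in calls)
        n_res = sum(c.call != UNRESOLVED for c in calls)
        af = n_inc / n_res if n_res else None
        records.append(WindowAFRecord(lt.window, af, n_inc, n_res, calls))
    return records


def fixed_blocks(
    af_track: Sequence[WindowAFRecord],
    min_run: int = 3,
    trim: int = 1,
    population: str = "pop",
) -> list[AdmixtureBlock]:
    """Maximal runs of AF = 1 windows of length >= ``min_run``, with the
    first and last ``trim`` breakpoint windows discarded."""
    if min_run <= 2 * trim:
        raise ValueError("min_run must exceed 2*trim")
    blocks: list[AdmixtureBlock] = []
    run: list[WindowAFRecord] = []

    def flush() -> None:
        if len(run) >= min_run:
            core = run[trim : len(run) - trim] if trim else list(run)
            blocks.append(
                AdmixtureBlock(
                    population=population,
                    chrom=core[0].window[0],
                    start=core[0].window[1],
                    end=core[-1].window[2],
                    windows=[r.window for r in core],
                )
            )
        run.clear()

    prev_chrom = None
    for rec in af_track:
        contiguous = rec.window[0] == prev_chrom
        if rec.af == 1.0:
            if run and not contiguous:
                flush()
            run.append(rec)
        else:
            flush()
        prev_chrom = rec.window[0]
    flush()
    return blocks


def combined_evidence(
    fd_track, af_track: Sequence[WindowAFRecord], fd_threshold: float
) -> list[tuple[str, int, int]]:
    """Union of windows flagged by fd (>= threshold) and topology (AF > 0)."""
    fd_windows = [s.window for s in fd_track]
    af_windows = [r.window for r in af_track]
    if fd_windows != af_windows:
        raise ValueError("fd and topology tracks use different windowings")
    out = []
    for s, r in zip(fd_track, af_track):
        fd_hit = s.value is not None and s.value >= fd_threshold
        topo_hit = r.af is not None and r.af > 0
        if fd_hit or topo_hit:
            out.append(s.window)
    return out


def read_tree_index(index_tsv) -> list[LocalTree]:
    """TSV columns chrom, start, end, path -> LocalTree list (newick files)."""
    import csv
    from pathlib import Path

    trees = []
    base = Path(index_tsv).parent
    with open(index_tsv) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            p = Path(row["path"])
            if not p.is_absolute():
                p = base / p
            trees.append(
                LocalTree(
                    window=(row["chrom"], int(row["start"]), int(row["end"])),
                    newick=p.read_text().strip(),
                )
            )
    return trees


def blocks_to_bed(blocks: Sequence[AdmixtureBlock], path) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{b.population}\n")


def af_track_to_tsv(track: Sequence[WindowAFRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\taf\tn_incongruent\tn_resolved\n")
        for r in track:
            af = "NA" if r.af is None else f"{r.af:.6g}"
            fh.write(
                f"{r.window[0]}\t{r.window[1]}\t{r.window[2]}\t{af}\t"
                f"{r.n_incongruent}\t{r.n_resolved}\n"
            )
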