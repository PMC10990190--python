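"""Lineage collapsing and window-wise chromosome painting.

A reference panel of near-clonal isolates is collapsed into lineages by
average-linkage clustering of the pairwise IBS matrix; a merge survives only
when the between-subcluster dissimilarity is statistically indistinguishable
from within-cluster dissimilarity (permutation Z-score below ``z_cutoff``)
AND every within-cluster pair shares IBS at or above ``ibs_cutoff``.

A query genome is then painted window by window: either to the lineage whose
best-matching member exceeds a hard IBS cutoff (default 0.98), or to the
clade minimizing Nei's d_a.  Windows where no lineage reaches the cutoff
stay UNASSIGNED — on real data these are candidate introgressions from
donors absent from the panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform

from .genotype import GenotypeMatrix, Window, WindowSet
from .popgen import PopulationSpec, ibs, nei_da

UNASSIGNED = "UNASSIGNED"
TOO_MISSING = "TOO_MISSING"


@dataclass
class Lineage:
    lineage_id: str
    members: list[str]
    category: str = "non-starter"  # starter | non-starter | mixed


@dataclass
class WindowAssignment:
    window: tuple[str, int, int]
    label: str  # lineage/clade id, UNASSIGNED or TOO_MISSING
    score: float | None  # best IBS or best d_a
    n_sites: int
    tied: bool = False


@dataclass
class Painting:
    query: str
    window_size: int
    assignments: list[WindowAssignment] = field(default_factory=list)

    @property
    def assigned(self) -> list[WindowAssignment]:
        return [a for a in self.assignments if a.label not in (UNASSIGNED, TOO_MISSING)]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("query\tchrom\tstart\tend\tlabel\tscore\tn_sites\ttied\n")
            for a in self.assignments:
                score = "NA" if a.score is None else f"{a.score:.6g}"
                fh.write(
                    f"{self.query}\t{a.window[0]}\t{a.window[1]}\t{a.window[2]}\t"
                    f"{a.label}\t{score}\t{a.n_sites}\t{int(a.tied)}\n"
                )


def _merge_zscore(
    dism: np.ndarray,
    left: np.ndarray,
    right: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> float:
    """Z-score of observed between-subcluster mean dissimilarity against a
    null built by re-partitioning the merged members into random groups of
    the same sizes."""
    obs = float(dism[np.ix_(left, right)].mean())
    members = np.concatenate([left, right])
    k = len(left)
    null = np.empty(n_perm)
    for t in range(n_perm):
        perm = rng.permutation(members)
        null[t] = dism[np.ix_(perm[:k], perm[k:])].mean()
    mu, sd = float(null.mean()), float(null.std())
    if sd == 0:
        return 0.0 if obs <= mu else np.inf
    return (obs - mu) / sd


def cluster_lineages(
    ibs_matrix: np.ndarray,
    sample_ids: Sequence[str],
    z_cutoff: float = 3.0,
    ibs_cutoff: float = 0.99,
    n_perm: int = 1000,
    seed: int = 0,
    categories: Mapping[str, str] | None = None,
) -> list[Lineage]:
    """Collapse a panel into near-clonal lineages.

    Average-linkage hierarchical clustering on ``1 - IBS``; the dendrogram is
    cut top-down: a node is kept as a single lineage only when its merge
    Z-score is below ``z_cutoff`` and its minimum within IBS is at least
    ``ibs_cutoff``; otherwise the two subclusters are examined recursively.
    Singletons become unique-isolate lineages.
    """
    import warnings

    M = np.asarray(ibs_matrix, dtype=float)
    n = M.shape[0]
    if M.shape != (n, n) or not np.allclose(M, M.T, equal_nan=True):
        raise ValueError("ibs_matrix must be square and symmetric")
    if n != len(sample_ids):
        raise ValueError("sample_ids length mismatch")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives an unstable permutation null")
    rng = np.random.default_rng(seed)
    dism = 1.0 - M
    np.fill_diagonal(dism, 0.0)

    if n == 1:
        groups = [np.array([0])]
    else:
        Z = average(squareform(dism, checks=False))
        # children of each internal node
        members: list[np.ndarray] = [np.array([i]) for i in range(n)]
        kids: list[tuple[int, int]] = []
        for a, b, _, _ in Z:
            kids.append((int(a), int(b)))
            members.append(np.concatenate([members[int(a)], members[int(b)]]))

        groups = []

        def visit(node: int) -> None:
            mem = members[node]
            if node < n:
                groups.append(mem)
                return
            a, b = kids[node - n]
            sub = dism[np.ix_(mem, mem)]
            min_ibs = 1.0 - float(sub.max())
            z = _merge_zscore(dism, members[a], members[b], n_perm, rng)
            if z < z_cutoff and min_ibs >= ibs_cutoff:
                groups.append(mem)
            else:
                visit(a)
                visit(b)

        visit(2 * n - 2)

    groups.sort(key=lambda g: int(g.min()))
    lineages = []
    for gi, g in enumerate(groups):
        mem = [sample_ids[i] for i in sorted(g)]
        cat = _category_of(mem, categories)
        lineages.append(Lineage(lineage_id=f"l{gi:02d}", members=mem, category=cat))
    return lineages


def _category_of(members: Sequence[str], categories: Mapping[str, str] | None) -> str:
    if not categories:
        return "non-starter"
    cats = {categories.get(m, "non-starter") for m in members}
    return cats.pop() if len(cats) == 1 else "mixed"


def paint_ibs(
    gm: GenotypeMatrix,
    query: str,
    lineages: Sequence[Lineage],
    windows: WindowSet,
    min_ibs: float = 0.98,
    max_missing: float = 0.2,
) -> Painting:
    """Assign each window to the lineage with the best member IBS match.

    Lineage score = max over members of pairwise IBS on the window's sites;
    the window is UNASSIGNED below ``min_ibs`` and TOO_MISSING when the
    query itself is missing at more than ``max_missing`` of the window's
    sites.  Ties break to the lexicographically first lineage and are
    flagged.
    """
    if not lineages:
        raise ValueError("empty lineage list")
    qi = gm.sample_index(query)
    painting = Painting(query=query, window_size=windows.size)
    from .genotype import MISSING

    for w in windows:
        idx = np.asarray(w.site_indices, dtype=np.intp)
        n_sites = len(idx)
        if n_sites == 0:
            painting.assignments.append(
                WindowAssignment(w.span, TOO_MISSING, None, 0)
            )
            continue
        q_missing = float((gm.dosage[qi, idx] == MISSING).mean())
        if q_missing > max_missing:
            painting.assignments.append(
                WindowAssignment(w.span, TOO_MISSING, None, n_sites)
            )
            continue
        best_label, best_score, tied = UNASSIGNED, None, False
        for lin in sorted(lineages, key=lambda l: l.lineage_id):
            score = None
            for m in lin.members:
                val, _, _ = ibs(gm, query, m, idx)
                if val is not None and (score is None or val > score):
                    score = val
            if score is None:
                continue
            if best_score is None or score > best_score:
                best_label, best_score, tied = lin.lineage_id, score, False
            elif score == best_score:
                tied = True
        if best_score is None or best_score < min_ibs:
            painting.assignments.append(
                WindowAssignment(w.span, UNASSIGNED, best_score, n_sites)
            )
        else:
            painting.assignments.append(
                WindowAssignment(w.span, best_label, best_score, n_sites, tied)
            )
    return painting


def assign_clade_da(
    gm: GenotypeMatrix,
    query: str,
    clades: Sequence[PopulationSpec],
    windows: WindowSet,
) -> tuple[Painting, dict[str, float]]:
    """Per window, assign the clade minimizing Nei's d_a to the query.

    The query is treated as a singleton population and must not be a member
    of any clade.  Returns the painting and per-clade genome proportions
    over assignable windows.
    """
    for c in clades:
        if query in c.members:
            raise ValueError(f"query {query!r} is a member of clade {c.name!r}")
    qpop = PopulationSpec(name=query, members=[query])
    painting = Painting(query=query, window_size=windows.size)
    for w in windows:
        idx = w.site_indices
        best_label, best_val, tied, n_used = UNASSIGNED, None, False, 0
        for c in sorted(clades, key=lambda c: c.name):
            st = nei_da(gm, qpop, c, idx, w.span)
            if not st.defined:
                continue
            if best_val is None or st.value < best_val:
                best_label, best_val, tied, n_used = c.name, st.value, False, st.n_sites
            elif st.value == best_val:
                tied = True
        painting.assignments.append(
            WindowAssignment(w.span, best_label, best_val, n_used, tied)
        )
    assigned = painting.assigned
    props: dict[str, float] = {c.name: 0.0 for c in clades}
    if assigned:
        for a in assigned:
            props[a.label] += 1.0
        for k in props:
            props[k] /= len(assigned)
    return painting, props


def contribution_summary(
    painting: Painting, lineages: Sequence[Lineage]
) -> dict:
    """Per-lineage and per-category genome proportions over assigned windows."""
    assigned = painting.assigned
    if not assigned:
        return {
            "query": painting.query,
            "proportions": None,
            "category_proportions": None,
            "n_distinct_lineages": 0,
        }
    cat_of = {l.lineage_id: l.category for l in lineages}
    counts: dict[str, int] = {}
    for a in assigned:
        counts[a.label] = counts.get(a.label, 0) + 1
    total = len(assigned)
    props = {k: v / total for k, v in sorted(counts.items())}
    cats: dict[str, float] = {"starter": 0.0, "non-starter": 0.0, "mixed": 0.0}
    for lid, p in props.items():
        cats[cat_of.get(lid, "non-starter")] += p
    return {
        "query": painting.query,
        "proportions": props,
        "category_proportions": cats,
        "n_distinct_lineages": len(counts),
    }
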