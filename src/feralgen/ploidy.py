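"""Read-depth aneuploidy detection and genome-instability statistics.

Sequencing reads sample genomic positions approximately independently, so a
chromosome present in extra (or fewer) copies shifts its whole per-site
depth distribution relative to the rest of the genome.  Each chromosome is
therefore compared against the pooled depth of all other chromosomes with a
two-sided Mann-Whitney (Wilcoxon rank-sum) test; a chromosome is called
aneuploid when the rank-biserial effect size is large (|r_rb| >= 0.5 by
default).  Relative copy number is estimated by the Hodges-Lehmann location
shift (median of all pairwise chromosome-minus-background depth
differences) divided by the median depth of chromosomes called euploid, so
a clean single duplication (3N) sits at a normalized shift of 0.5 and each
further copy adds another 0.5.

The simulation designs probing this framework (scaling grids, segmental
duplications, co-occurring polysomes) are implemented here as well; they
draw per-site depth from Normal(mean=30, sd=10), rounded and floored at 0,
with per-chromosome site counts proportional to the 16 S. cerevisiae
chromosome lengths by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

GAIN, LOSS, NONE = "GAIN", "LOSS", "NONE"

#: S288C nuclear chromosome lengths (bp), chrI..chrXVI.
S288C_CHROM_LENGTHS: dict[str, int] = {
    "chrI": 230218, "chrII": 813184, "chrIII": 316620, "chrIV": 1531933,
    "chrV": 576874, "chrVI": 270161, "chrVII": 1090940, "chrVIII": 562643,
    "chrIX": 439888, "chrX": 745751, "chrXI": 666816, "chrXII": 1078177,
    "chrXIII": 924431, "chrXIV": 784333, "chrXV": 1091291, "chrXVI": 948066,
}


def default_site_counts(total_sites: int = 16000) -> dict[str, int]:
    """Per-chromosome site counts proportional to S288C chromosome lengths."""
    total_len = sum(S288C_CHROM_LENGTHS.values())
    counts = {
        c: max(2, int(round(total_sites * l / total_len)))
        for c, l in S288C_CHROM_LENGTHS.items()
    }
    return counts


def aneuploidy_rate_weights(
    chrom_lengths: Mapping[str, int] | None = None,
) -> dict[str, float]:
    """Chromosome-selection weights proportional to inverse length.

    Observed aneuploidy frequency in yeast falls with chromosome length
    (small chromosomes such as I, III, VI and IX are gained far more often
    than large ones), so simulated aneuploid chromosomes are drawn with
    probability proportional to 1/length by default.
    """
    lengths = chrom_lengths or S288C_CHROM_LENGTHS
    w = {c: 1.0 / l for c, l in lengths.items()}
    tot = sum(w.values())
    return {c: v / tot for c, v in w.items()}


def _resolve_weights(
    background_weights, chroms: Sequence[str]
) -> np.ndarray | None:
    """None -> uniform; "inverse_length" -> aneuploidy-rate weights; or an
    explicit chrom -> weight mapping (renormalized over ``chroms``)."""
    if background_weights is None:
        return None
    if background_weights == "inverse_length":
        background_weights = aneuploidy_rate_weights()
    w = np.array([background_weights.get(c, 0.0) for c in chroms], dtype=float)
    s = w.sum()
    if s <= 0:
        return None
    return w / s


@dataclass
class DepthProfile:
    isolate: str
    depths: dict[str, np.ndarray]  # chrom -> per-site depth (non-negative ints)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.depths) < 2:
            raise ValueError("DepthProfile requires >= 2 chromosomes")
        for c, v in self.depths.items():
            v = np.asarray(v)
            if v.size == 0:
                raise ValueError(f"chromosome {c} has no sites")
            self.depths[c] = v

    def all_depths(self) -> np.ndarray:
        return np.concatenate(list(self.depths.values()))

    def background(self, chrom: str) -> np.ndarray:
        if chrom not in self.depths:
            raise KeyError(chrom)
        return np.concatenate([v for c, v in self.depths.items() if c != chrom])


@dataclass
class AneuploidyCall:
    isolate: str
    chrom: str
    rank_biserial: float
    hl_shift_raw: float
    hl_shift_norm: float | None
    direction: str  # GAIN | LOSS | NONE
    p_value: float
    degenerate: bool = False


@dataclass
class InstabilityRecord:
    isolate: str
    chrom: str
    hl_shift_norm: float
    mean_background_shift: float | None  # None when no other polysome
    group: str = "feral"  # admixed | feral


def coverage_gate(profile: DepthProfile, min_mean: float = 20.0) -> bool:
    """Accept the isolate iff genome-wide mean depth >= ``min_mean``."""
    return bool(profile.all_depths().mean() >= min_mean)


def _kth_pairwise_diff(x: np.ndarray, y: np.ndarray, k: int) -> float:
    """k-th smallest (1-based) value of {x_i - y_j} by counting bisection.

    Exact for integer-valued inputs: binary-search the integer difference d
    and count pairs with x_i - y_j <= d via searchsorted.
    """
    ys = np.sort(y)
    xs = np.sort(x)

    def count_le(d: float) -> int:
        # pairs with x_i - y_j <= d  <=>  y_j >= x_i - d
        return int((len(ys) - np.searchsorted(ys, xs - d, side="left")).sum())

    lo = int(np.floor(xs[0] - ys[-1])) - 1
    hi = int(np.ceil(xs[-1] - ys[0]))
    while lo < hi:
        mid = (lo + hi) // 2
        if count_le(mid) >= k:
            hi = mid
        else:
            lo = mid + 1
    return float(lo)


def hodges_lehmann_shift(x: np.ndarray, y: np.ndarray) -> float:
    """Median of all pairwise differences ``x_i - y_j``.

    Computed by exact bisection on integer inputs (averaging the middle two
    order statistics when the pair count is even); falls back to the dense
    pairwise matrix for non-integer inputs of workable size.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    total = x.size * y.size
    if total == 0:
        raise ValueError("empty input")
    integral = np.all(x == np.round(x)) and np.all(y == np.round(y))
    if not integral:
        if total > 2 * 10**7:
            raise ValueError("non-integer inputs too large for exact HL")
        return float(np.median(np.subtract.outer(x, y)))
    if total % 2 == 1:
        return _kth_pairwise_diff(x, y, (total + 1) // 2)
    a = _kth_pairwise_diff(x, y, total // 2)
    b = _kth_pairwise_diff(x, y, total // 2 + 1)
    return (a + b) / 2.0


def rank_biserial(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Signed rank-biserial effect size and two-sided Mann-Whitney p-value.

    Positive values mean x (the test chromosome) is stochastically deeper
    than y (the background): ``r = 2 U_x / (n_x n_y) - 1``.
    """
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return 0.0, 1.0  # degenerate: identical constants
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    u_x = float(res.statistic)
    r = 2.0 * u_x / (len(x) * len(y)) - 1.0
    return r, float(res.pvalue)


def test_chromosome(
    profile: DepthProfile,
    chrom: str,
    max_sites_per_group: int | None = None,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Compare one chromosome's depth distribution to the rest of the genome.

    Returns (rank_biserial, hl_shift_raw, p_value).  Optional per-group site
    subsampling (seeded) caps the cost on large profiles.
    """
    x = np.asarray(profile.depths[chrom], dtype=float)
    y = np.asarray(profile.background(chrom), dtype=float)
    if max_sites_per_group is not None:
        rng = np.random.default_rng(seed)
        if len(x) > max_sites_per_group:
            x = rng.choice(x, max_sites_per_group, replace=False)
        if len(y) > max_sites_per_group:
            y = rng.choice(y, max_sites_per_group, replace=False)
    r, p = rank_biserial(x, y)
    hl = hodges_lehmann_shift(x, y)
    return r, hl, p


def call_aneuploidies(
    profile: DepthProfile,
    effect_threshold: float = 0.5,
    max_sites_per_group: int | None = None,
    seed: int = 0,
) -> list[AneuploidyCall]:
    """One aneuploidy call per chromosome.

    |rank_biserial| >= threshold gives GAIN/LOSS by sign; normalized shifts
    divide by the median depth of chromosomes called NONE (genome-wide
    median when every chromosome is called).
    """
    raw: dict[str, tuple[float, float, float]] = {}
    for chrom in profile.depths:
        raw[chrom] = test_chromosome(profile, chrom, max_sites_per_group, seed)

    none_chroms = [c for c, (r, _, _) in raw.items() if abs(r) < effect_threshold]
    if none_chroms:
        norm_med = float(np.median(np.concatenate([profile.depths[c] for c in none_chroms])))
    else:
        norm_med = float(np.median(profile.all_depths()))

    calls = []
    for chrom, (r, hl, p) in raw.items():
        if r >= effect_threshold and hl > 0:
            direction = GAIN
        elif r <= -effect_threshold and hl < 0:
            direction = LOSS
        else:
            direction = NONE
        calls.append(
            AneuploidyCall(
                isolate=profile.isolate,
                chrom=chrom,
                rank_biserial=r,
                hl_shift_raw=hl,
                hl_shift_norm=hl / norm_med if norm_med > 0 else None,
                direction=direction,
                p_value=p,
                degenerate=(r == 0.0 and p == 1.0),
            )
        )
    return calls


def instability_records(
    calls_by_isolate: Mapping[str, Sequence[AneuploidyCall]],
    groups: Mapping[str, str] | None = None,
) -> list[InstabilityRecord]:
    """Per-polysome records: normalized shift vs mean shift of the isolate's
    *other* polysomes (None for single-polysome isolates)."""
    records = []
    for isolate, calls in calls_by_isolate.items():
        poly = [c for c in calls if c.direction != NONE and c.hl_shift_norm is not None]
        for c in poly:
            others = [o.hl_shift_norm for o in poly if o.chrom != c.chrom]
            records.append(
                InstabilityRecord(
                    isolate=isolate,
                    chrom=c.chrom,
                    hl_shift_norm=c.hl_shift_norm,
                    mean_background_shift=float(np.mean(others)) if others else None,
                    group=(groups or {}).get(isolate, "feral"),
                )
            )
    return records


def instability_regression(records: Sequence[InstabilityRecord]) -> pd.DataFrame:
    """Gaussian identity-link GLM (OLS) of polysome shift on mean background
    shift, per chromosome stratum and pooled.

    Isolates with a single polysome (undefined background) are excluded;
    strata with < 3 usable records are skipped.
    """
    import statsmodels.api as sm

    usable = [r for r in records if r.mean_background_shift is not None]
    rows = []

    def fit(stratum: str, recs: Sequence[InstabilityRecord]) -> None:
        if len(recs) < 3:
            return
        x = np.array([r.mean_background_shift for r in recs])
        y = np.array([r.hl_shift_norm for r in recs])
        if np.var(x) == 0:
            rows.append(
                {"stratum": stratum, "n": len(recs), "slope": np.nan,
                 "intercept": np.nan, "r2": np.nan, "flag": "zero_variance"}
            )
            return
        model = sm.OLS(y, sm.add_constant(x)).fit()
        rows.append(
            {"stratum": stratum, "n": len(recs),
             "slope": float(model.params[1]), "intercept": float(model.params[0]),
             "r2": float(model.rsquared), "flag": ""}
        )

    for chrom in sorted({r.chrom for r in usable}):
        fit(chrom, [r for r in usable if r.chrom == chrom])
    fit("pooled", usable)
    return pd.DataFrame(rows)


def compare_groups(
    records: Sequence[InstabilityRecord],
    groupA: str = "admixed",
    groupB: str = "feral",
) -> tuple[float, str]:
    """One-sided Mann-Whitney: P(random A isolate mean shift > random B).

    The per-isolate statistic is the mean normalized polysome shift.  Exact
    when combined n <= 50, otherwise the normal approximation with
    continuity correction.  Returns (p_value, method).
    """
    means: dict[str, list[float]] = {}
    grp: dict[str, str] = {}
    for r in records:
        means.setdefault(r.isolate, []).append(r.hl_shift_norm)
        grp[r.isolate] = r.group
    a = np.array([np.mean(v) for i, v in means.items() if grp[i] == groupA])
    b = np.array([np.mean(v) for i, v in means.items() if grp[i] == groupB])
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    method = "exact" if len(a) + len(b) <= 50 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="greater", method=method)
    return float(res.pvalue), method


# ---------------------------------------------------------------------------
# simulation designs
# ---------------------------------------------------------------------------


def simulate_depth_profile(
    site_counts: Mapping[str, int],
    mean: float = 30.0,
    sd: float = 10.0,
    aneuploidies: Sequence[tuple[str, float]] = (),
    segmental: Sequence[tuple[str, float, float]] = (),
    seed: int = 0,
    isolate: str = "sim",
) -> DepthProfile:
    """Per-site depth ~ round(Normal(mean, sd) * (1 + shift)), floored at 0.

    ``aneuploidies``: (chrom, shift) with shift = scaling factor - 1 applied
    to the whole chromosome (0.5 -> 3N, -0.5 -> 1N, -1 -> 0N).
    ``segmental``: (chrom, fraction, scale) scales a contiguous |fraction|
    of the chromosome's sites by ``scale``, from the chromosome start.
    """
    rng = np.random.default_rng(seed)
    shifts = dict(aneuploidies)
    for chrom, shift in shifts.items():
        if shift < -1:
            raise ValueError("shift below -1 would give negative copy number")
    depths: dict[str, np.ndarray] = {}
    for chrom, n in site_counts.items():
        base = rng.normal(mean, sd, size=int(n))
        base = base * (1.0 + shifts.get(chrom, 0.0))
        depths[chrom] = base
    for chrom, fraction, scale in segmental:
        if abs(fraction) > 0.5 + 1e-12:
            raise ValueError("|fraction| must be <= 0.5")
        n_seg = int(round(abs(fraction) * len(depths[chrom])))
        if n_seg:
            depths[chrom][:n_seg] *= scale
    depths = {c: np.maximum(0, np.round(v)).astype(np.int64) for c, v in depths.items()}
    lengths = {
        c: S288C_CHROM_LENGTHS.get(c, len(depths[c])) for c in depths
    }
    return DepthProfile(isolate=isolate, depths=depths, chrom_lengths=lengths)


def simulate_power_grid(
    seed: int = 0,
    bg_mean: float = 30.0,
    bg_sd: float = 10.0,
    n_background_aneu: Sequence[int] = (0, 1, 2, 3, 4, 5),
    scale_grid: Sequence[float] | None = None,
    site_counts: Mapping[str, int] | None = None,
    focal_chrom: str = "chrVI",
    n_reps: int = 20,
    background_weights="inverse_length",
) -> pd.DataFrame:
    """Whole-chromosome gain/loss power grid.

    The focal chromosome is scaled by ``1 + scale`` for scale in -1..1 by
    0.1; 0-5 background chromosomes, drawn with aneuploidy-rate weights
    (see :func:`aneuploidy_rate_weights`; pass ``None`` for uniform), are
    scaled to 3N (x1.5); rank-biserial of the focal test is recorded per
    replicate.
    """
    if scale_grid is None:
        scale_grid = np.round(np.arange(-1.0, 1.0 + 1e-9, 0.1), 10)
    site_counts = dict(site_counts or default_site_counts())
    rng = np.random.default_rng(seed)
    others = [c for c in site_counts if c != focal_chrom]
    weights = _resolve_weights(background_weights, others)
    rows = []
    for n_bg in n_background_aneu:
        for scale in scale_grid:
            for rep in range(n_reps):
                bg = list(rng.choice(others, size=n_bg, replace=False, p=weights))
                events = [(c, 0.5) for c in bg] + [(focal_chrom, float(scale))]
                prof = simulate_depth_profile(
                    site_counts, bg_mean, bg_sd, aneuploidies=events,
                    seed=int(rng.integers(2**31)),
                )
                r, hl, p = test_chromosome(prof, focal_chrom)
                rows.append(
                    {"scale": float(scale), "n_background": n_bg, "rep": rep,
                     "rank_biserial": r, "hl_shift_raw": hl, "p_value": p}
                )
    return pd.DataFrame(rows)


def simulate_segmental_grid(
    seed: int = 0,
    bg_mean: float = 30.0,
    bg_sd: float = 10.0,
    fraction_grid: Sequence[float] | None = None,
    dup_scale: float = 1.5,
    loss_scale: float = 0.5,
    n_background_aneu: Sequence[int] = (0, 5),
    site_counts: Mapping[str, int] | None = None,
    focal_chrom: str = "chrVI",
    n_reps: int = 20,
    background_weights="inverse_length",
) -> pd.DataFrame:
    """Segmental duplication/loss grid.

    Negative fractions scale |fraction| of the focal chromosome to 1N
    (x0.5); positive fractions to 3N (x1.5).  Effect sizes are recorded to
    show segmental events do not trigger whole-chromosome calls.
    """
    if fraction_grid is None:
        fraction_grid = np.round(np.arange(-0.5, 0.5 + 1e-9, 0.1), 10)
    site_counts = dict(site_counts or default_site_counts())
    rng = np.random.default_rng(seed)
    others = [c for c in site_counts if c != focal_chrom]
    weights = _resolve_weights(background_weights, others)
    rows = []
    for n_bg in n_background_aneu:
        for fraction in fraction_grid:
            scale = dup_scale if fraction > 0 else loss_scale
            for rep in range(n_reps):
                bg = list(rng.choice(others, size=n_bg, replace=False, p=weights))
                seg = [(focal_chrom, float(fraction), scale)] if fraction != 0 else []
                prof = simulate_depth_profile(
                    site_counts, bg_mean, bg_sd,
                    aneuploidies=[(c, 0.5) for c in bg], segmental=seg,
                    seed=int(rng.integers(2**31)),
                )
                r, hl, p = test_chromosome(prof, focal_chrom)
                rows.append(
                    {"fraction": float(fraction), "n_background": n_bg, "rep": rep,
                     "rank_biserial": r, "hl_shift_raw": hl, "p_value": p}
                )
    return pd.DataFrame(rows)


def simulate_cooccurrence(
    seed: int = 0,
    bg_mean: float = 30.0,
    bg_sd: float = 10.0,
    n_cooccurring: Sequence[int] = (0, 1, 2, 3, 4, 5),
    background_shift: Sequence[float] = (0.0, 1.0, 2.0, 3.0),
    foreground_shift_grid: Sequence[float] | None = None,
    site_counts: Mapping[str, int] | None = None,
    n_reps: int = 20,
    effect_threshold: float = 0.5,
    background_weights="inverse_length",
) -> pd.DataFrame:
    """Co-occurring-polysome bias grid.

    Background polysomes carry a true normalized shift of 0 (2N), 1 (4N),
    2 (6N) or 3 (8N) and are drawn with aneuploidy-rate weights (pass
    ``None`` for uniform); one uniformly chosen distinct foreground
    chromosome carries a true shift of 0..5 (0.5 steps, 0-10N).  The
    foreground shift is re-estimated with the full calling pipeline
    (normalization by the median of chromosomes called euploid) and the
    relative underestimation ``(true - estimated) / true`` recorded for
    true > 0.
    """
    if foreground_shift_grid is None:
        foreground_shift_grid = np.round(np.arange(0.0, 5.0 + 1e-9, 0.5), 10)
    site_counts = dict(site_counts or default_site_counts())
    chroms = list(site_counts)
    rng = np.random.default_rng(seed)
    rows = []
    for n_co in n_cooccurring:
        for bshift in background_shift:
            for fshift in foreground_shift_grid:
                for rep in range(n_reps):
                    fg = str(rng.choice(chroms))
                    others = [c for c in chroms if c != fg]
                    ow = _resolve_weights(background_weights, others)
                    bg = list(rng.choice(others, size=n_co, replace=False, p=ow))
                    # a 2N background polysome (shift 0) is a no-op
                    events = [(c, bshift) for c in bg if bshift != 0]
                    events.append((fg, float(fshift)))
                    prof = simulate_depth_profile(
                        site_counts, bg_mean, bg_sd, aneuploidies=events,
                        seed=int(rng.integers(2**31)),
                    )
                    est = _estimate_normalized_shift(prof, fg, effect_threshold)
                    under = (fshift - est) / fshift if fshift > 0 else np.nan
                    rows.append(
                        {"n_cooccurring": n_co, "background_shift": float(bshift),
                         "foreground_shift": float(fshift), "rep": rep,
                         "estimated_shift": est, "underestimation": under}
                    )
    return pd.DataFrame(rows)


def _estimate_normalized_shift(
    profile: DepthProfile, chrom: str, effect_threshold: float = 0.5
) -> float:
    """Normalized HL shift of one chromosome, with the euploid normalization
    median determined by rank-biserial calls across all chromosomes."""
    none_chroms = []
    for c in profile.depths:
        x = np.asarray(profile.depths[c], dtype=float)
        y = np.asarray(profile.background(c), dtype=float)
        r, _ = rank_biserial(x, y)
        if abs(r) < effect_threshold:
            none_chroms.append(c)
    if none_chroms:
        norm_med = float(np.median(np.concatenate([profile.depths[c] for c in none_chroms])))
    else:
        norm_med = float(np.median(profile.all_depths()))
    hl = hodges_lehmann_shift(
        np.asarray(profile.depths[chrom], dtype=float),
        np.asarray(profile.background(chrom), dtype=float),
    )
    return hl / norm_med


def normalized_depth_track(
    profile: DepthProfile,
    calls: Sequence[AneuploidyCall] | None = None,
    window: int = 10000,
    step: int = 2000,
) -> pd.DataFrame:
    """Median depth in sliding bp windows divided by the 2N median.

    Site positions are taken as evenly spaced along each chromosome's
    length (per-variant-site profiles carry no explicit positions).  The 2N
    median comes from chromosomes called NONE; with no euploid chromosome
    the genome-wide median is used and flagged.
    """
    none_chroms = None
    if calls is not None:
        none_chroms = [c.chrom for c in calls if c.direction == NONE]
    flagged = False
    if none_chroms:
        norm = float(np.median(np.concatenate([profile.depths[c] for c in none_chroms])))
    else:
        norm = float(np.median(profile.all_depths()))
        flagged = True
    rows = []
    for chrom, v in profile.depths.items():
        length = profile.chrom_lengths.get(chrom, len(v))
        pos = np.linspace(0, length, num=len(v), endpoint=False)
        last_start = max(length - window, 0)
        for start in range(0, int(last_start) + step, step):
            end = min(start + window, length)
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="left")
            if hi <= lo:
                continue
            rows.append(
                {"chrom": chrom, "start": start, "end": int(end),
                 "norm_depth": float(np.median(v[lo:hi])) / norm,
                 "fallback_norm": flagged}
            )
    return pd.DataFrame(rows)


def plot_normalized_track(track: pd.DataFrame, path, title: str = "") -> None:
    """Normalized depth along the genome with copy-number gridlines at
    1 + 0.5k (k = copy-number change)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(12, 3))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, g) in enumerate(track.groupby("chrom", sort=False)):
        x = offset + (g["start"] + g["end"]) / 2
        ax.plot(x, g["norm_depth"], ".", ms=2,
                color="0.3" if i % 2 else "0.6")
        ticks.append(offset + g["end"].max() / 2)
        labels.append(chrom)
        offset += g["end"].max()
    for k in range(-2, 5):
        ax.axhline(1 + 0.5 * k, lw=0.5, ls="--", color="tab:blue", alpha=0.5)
    ax.set_xticks(ticks, labels, rotation=90, fontsize=7)
    ax.set_ylabel("depth / 2N median")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_shift_heatmap(
    shifts: pd.DataFrame, path, value_col: str = "hl_shift_norm"
) -> None:
    """Isolate x chromosome heatmap of normalized location shifts, rows
    ordered by Ward clustering."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster.hierarchy import leaves_list, ward
    from scipy.spatial.distance import pdist

    mat = shifts.pivot_table(index="isolate", columns="chrom",
                             values=value_col).fillna(0.0)
    if len(mat) > 2:
        order = leaves_list(ward(pdist(mat.values)))
        mat = mat.iloc[order]
    fig, ax = plt.subplots(figsize=(8, max(2, 0.25 * len(mat))))
    im = ax.imshow(mat.values, aspect="auto", cmap="RdBu_r",
                   vmin=-2, vmax=2)
    ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(mat.shape[0]), mat.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="normalized location shift")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def read_depth_tsv(path, isolate: str = "sample") -> DepthProfile:
    """Per-site depth TSV with columns chrom, pos, depth."""
    df = pd.read_csv(path, sep="\t")
    depths = {
        str(c): g.sort_values("pos")["depth"].to_numpy(dtype=np.int64)
        for c, g in df.groupby("chrom")
    }
    return DepthProfile(isolate=isolate, depths=depths)
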