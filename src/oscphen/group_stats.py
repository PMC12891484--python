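"""Hierarchical bootstrap group statistics, effect sizes, and corrections.

The bootstrap resamples subjects with replacement (level 1) and, when
epoch-level data exist, epochs within each selected subject (level 2),
forming per-replicate group means and rank-ordered confidence intervals of
the group difference.  Matched mode drives both groups' selections from the
same random index streams when the sample sizes allow, supporting
littermate-pair and pre/post comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io_preprocess import InvalidConfigError


@dataclass
class CohortDataset:
    """group → subject → stacked per-epoch items (first axis = epochs).

    Items are arrays on one shared grid: spectra (n_freq,), PA
    distributions (18,), or comodulograms (n_phase, n_amp).
    """

    groups: dict[str, dict[str, np.ndarray]]
    grid: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = None
        for g, subjects in self.groups.items():
            if not subjects:
                raise InvalidConfigError(f"group {g!r} has no subjects")
            for s, items in subjects.items():
                items = np.asarray(items, dtype=float)
                if items.shape[0] < 1:
                    raise InvalidConfigError(f"subject {s!r} has no items")
                if shape is None:
                    shape = items.shape[1:]
                elif items.shape[1:] != shape:
                    raise InvalidConfigError("item grids differ across subjects")
                subjects[s] = items

    def group(self, name: str) -> dict[str, np.ndarray]:
        return self.groups[name]

    def subject_means(self, name: str) -> np.ndarray:
        return np.stack([v.mean(axis=0) for v in self.groups[name].values()])


@dataclass(frozen=True)
class BootstrapConfig:
    n_boot: int = 1000
    ci_level: int = 99  # 99 → ranks 5/995 of 1000; 95 → 25/975
    levels: int = 2
    matched: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.ci_level not in (95, 99):
            raise InvalidConfigError("ci_level must be 95 or 99")
        if self.levels not in (1, 2):
            raise InvalidConfigError("levels must be 1 or 2")
        if self.n_boot < 10:
            raise InvalidConfigError("n_boot too small")

    @property
    def rank_indices(self) -> tuple[int, int]:
        lo = int(round(self.n_boot * (100 - self.ci_level) / 200.0))
        if lo < 1:
            raise InvalidConfigError("n_boot inconsistent with ci_level")
        return lo - 1, self.n_boot - lo  # 0-based: 5th/995th of 1000


@dataclass
class BootstrapResult:
    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    significant: np.ndarray
    n_boot: int
    ci_level: int

    def __post_init__(self) -> None:
        if np.any(self.lower > self.median + 1e-12) or np.any(self.median > self.upper + 1e-12):
            raise InvalidConfigError("CI bounds must bracket the median")


def _group_replicate_mean(
    items: list[np.ndarray],
    rng: np.random.Generator,
    levels: int,
    subj_idx: np.ndarray | None = None,
    epoch_idx: list[np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """One bootstrap replicate's group mean; returns the index draws so
    matched mode can replay them on the other group."""
    n = len(items)
    if subj_idx is None:
        subj_idx = rng.integers(0, n, size=n)
    chosen = []
    used_epochs: list[np.ndarray] = []
    for slot, s in enumerate(subj_idx):
        arr = items[s]
        if levels == 2 and arr.shape[0] > 1:
            if epoch_idx is not None:
                e = epoch_idx[slot]
            else:
                e = rng.integers(0, arr.shape[0], size=arr.shape[0])
            used_epochs.append(e)
            chosen.append(arr[e].mean(axis=0))
        else:
            used_epochs.append(np.arange(arr.shape[0]))
            chosen.append(arr.mean(axis=0))
    return np.mean(chosen, axis=0), subj_idx, used_epochs


def hier_bootstrap_diff(
    a: dict[str, np.ndarray],
    b: dict[str, np.ndarray],
    cfg: BootstrapConfig = BootstrapConfig(),
) -> BootstrapResult:
    """Bootstrapped difference (a − b) with rank-ordered CIs.

    Per replicate the random streams are drawn in a fixed order — group a
    subjects, group a epochs, group b subjects, group b epochs — so matched
    mode (equal sample sizes and epoch counts) can replay a's streams for b.
    Elements whose CI excludes 0 are flagged significant.
    """
    if not a or not b:
        raise InvalidConfigError("both groups must be non-empty")
    items_a = [np.asarray(v, dtype=float) for v in a.values()]
    items_b = [np.asarray(v, dtype=float) for v in b.values()]
    shape = items_a[0].shape[1:]
    rng = np.random.default_rng(cfg.seed)

    matched = cfg.matched and len(items_a) == len(items_b)
    if matched and cfg.levels == 2:
        matched = all(
            x.shape[0] == y.shape[0] for x, y in zip(items_a, items_b)
        )

    diffs = np.empty((cfg.n_boot,) + shape)
    for r in range(cfg.n_boot):
        mean_a, sidx, eidx = _group_replicate_mean(items_a, rng, cfg.levels)
        if matched:
            mean_b, _, _ = _group_replicate_mean(
                items_b, rng, cfg.levels, subj_idx=sidx, epoch_idx=eidx
            )
        else:
            mean_b, _, _ = _group_replicate_mean(items_b, rng, cfg.levels)
        diffs[r] = mean_a - mean_b

    return _summarize(diffs, cfg)


def _summarize(diffs: np.ndarray, cfg: BootstrapConfig) -> BootstrapResult:
    ordered = np.sort(diffs, axis=0)
    lo_i, hi_i = cfg.rank_indices
    lower = ordered[lo_i]
    upper = ordered[hi_i]
    median = np.median(diffs, axis=0)
    significant = (lower > 0) | (upper < 0)
    return BootstrapResult(median, lower, upper, significant,
                           n_boot=cfg.n_boot, ci_level=cfg.ci_level)


def _mismatched_draw(rng: np.random.Generator, n_ep: int) -> tuple[np.ndarray, np.ndarray]:
    """Two with-replacement epoch index lists where no position pairs an
    epoch with itself."""
    idx1 = rng.integers(0, n_ep, size=n_ep)
    idx2 = rng.integers(0, n_ep, size=n_ep)
    clash = idx1 == idx2
    while clash.any():
        idx2[clash] = rng.integers(0, n_ep, size=int(clash.sum()))
        clash = idx1 == idx2
    return idx1, idx2


def hier_bootstrap_comod(
    pairwise: dict[str, np.ndarray],
    cfg: BootstrapConfig = BootstrapConfig(),
) -> tuple[BootstrapResult, np.ndarray]:
    """Noise-subtracted comodulogram bootstrap for one group.

    ``pairwise[subject]`` is the (n_ep, n_ep, n_phase, n_amp) MI tensor
    whose diagonal holds matched (true) matrices and off-diagonal cells
    mismatched (noise) matrices.  Per replicate, subjects are resampled,
    then per subject two epoch lists are drawn — the second never matching
    the first position-wise — giving mean true (diagonal at list 1) and
    mean noise (cells [list1, list2]) matrices whose difference is stored.
    Returns the bootstrap summary and the masked median (cells with CI
    including 0 set to 0).
    """
    if not pairwise:
        raise InvalidConfigError("empty group")
    tensors = [np.asarray(v, dtype=float) for v in pairwise.values()]
    for t in tensors:
        if t.shape[0] < 2:
            raise InvalidConfigError(
                "subjects need ≥ 2 epochs for the mismatch constraint"
            )
    shape = tensors[0].shape[2:]
    rng = np.random.default_rng(cfg.seed)
    n_subj = len(tensors)

    diffs = np.empty((cfg.n_boot,) + shape)
    for r in range(cfg.n_boot):
        subj_idx = rng.integers(0, n_subj, size=n_subj)
        true_means, noise_means = [], []
        for s in subj_idx:
            t = tensors[s]
            n_ep = t.shape[0]
            idx1, idx2 = _mismatched_draw(rng, n_ep)
            true_means.append(t[idx1, idx1].mean(axis=0))
            noise_means.append(t[idx1, idx2].mean(axis=0))
        diffs[r] = np.mean(true_means, axis=0) - np.mean(noise_means, axis=0)

    result = _summarize(diffs, cfg)
    masked = np.where(result.significant, result.median, 0.0)
    return result, masked


# ---------------------------------------------------------------------------
# Effect sizes, corrections, correlation, rank tests
# ---------------------------------------------------------------------------

def cliffs_delta(x, y, paired: bool = False) -> float:
    """Dominance effect size in [−1, 1]; positive when x tends larger.

    Unpaired: (#{x_i > y_j} − #{x_i < y_j}) / (n_x·n_y) over all pairs.
    Paired: mean within-pair dominance sign (requires equal lengths).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise InvalidConfigError("samples must be non-empty")
    if paired:
        if len(x) != len(y):
            raise InvalidConfigError("paired samples must have equal length")
        return float(np.mean(np.sign(x - y)))
    gt = (x[:, None] > y[None, :]).sum()
    lt = (x[:, None] < y[None, :]).sum()
    return float((gt - lt) / (len(x) * len(y)))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InvalidConfigError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def pearson_r2(x, y) -> tuple[float, float]:
    """Least-squares r² = 1 − SSres/SStot and r = √r²."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InvalidConfigError("need equal-length samples of size ≥ 3")
    if np.ptp(y) == 0:
        raise InvalidConfigError("y must not be constant")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float((resid ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    return r2, float(np.sqrt(max(r2, 0.0)))


def rank_sum_test(x, y) -> dict:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) via scipy."""
    res = sps.ranksums(x, y)
    return {"statistic": float(res.statistic), "p": float(res.pvalue), "z": float(res.statistic)}


def signed_rank_test(x, y) -> dict:
    """Two-sided Wilcoxon signed-rank test for paired samples via scipy."""
    res = sps.wilcoxon(x, y)
    return {"statistic": float(res.statistic), "p": float(res.pvalue)}
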