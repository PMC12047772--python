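"""Permutation inference on the difference of tachometric-curve minima.

The observed statistic is ``min_congruent - min_incongruent``: the deeper
the below-chance dip on incongruent trials, the more positive the
difference. The null distribution is built by re-running the whole curve
analysis (pooling, LOESS smoothing, minimum extraction for both
conditions) on ``B`` random relabelings of the congruency column — each
trial keeps its rPT and correctness, only the condition labels are
shuffled across the pooled trial set (optionally within participants).

The p value uses the add-one convention p = (1 + #{null >= observed}) /
(B + 1) (two-sided on |diff|), so it is never zero; its floor is
1/(B+1). The effect size d_z is the observed difference divided by the
standard deviation of the null distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .curves import DEFAULT_DEGREE, DEFAULT_SPAN
from .smoothing import loess_fit
from .trials import TrialTable


@dataclass
class PermutationResult:
    observed_diff: float
    null_diffs: np.ndarray = field(repr=False)
    p_value: float
    d_z: float
    B: int
    seed: int
    sidedness: str
    min_congruent: float
    min_incongruent: float
    n_retries: int = 0

    def to_json(self, path: str | Path | None = None) -> dict:
        nd = np.asarray(self.null_diffs)
        rec = {
            "observed_diff": self.observed_diff,
            "min_congruent": self.min_congruent,
            "min_incongruent": self.min_incongruent,
            "p_value": self.p_value,
            "d_z": self.d_z,
            "B": self.B,
            "seed": self.seed,
            "sidedness": self.sidedness,
            "n_retries": self.n_retries,
            "null_summary": {
                "mean": float(nd.mean()),
                "sd": float(nd.std(ddof=1)),
                "q95": float(np.quantile(nd, 0.95)),
            },
        }
        if path is not None:
            Path(path).write_text(json.dumps(rec, indent=2))
        return rec


def effect_size_dz(observed_diff: float, null_diffs) -> float:
    """Observed difference divided by the SD (ddof=1) of the null diffs."""
    nd = np.asarray(null_diffs, dtype=float)
    if len(nd) < 2:
        raise ValueError("need at least 2 null values")
    sd = nd.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate null distribution (zero sd)")
    return float(observed_diff / sd)


class _MinimaEngine:
    """Precomputed pooling machinery shared by all permutation replicates.

    Total per-bin counts are fixed; a replicate only needs the congruent
    share, and the incongruent share is the complement — one pair of
    bincounts per replicate instead of two full pooling passes.
    """

    def __init__(self, rpt, correct, span, degree, bin_width, search_lo, search_hi):
        self.span, self.degree = span, degree
        self.bw = max(int(bin_width), 1)
        self.search_lo, self.search_hi = search_lo, search_hi
        if self.bw > 1:
            centers = np.floor_divide(rpt, self.bw) * self.bw + self.bw // 2
        else:
            centers = rpt
        self.lo = int(centers.min())
        self.idx = ((centers - self.lo) // self.bw).astype(np.int64)
        self.nbins = int(self.idx.max()) + 1
        self.correct = correct
        self.cnt_tot = np.bincount(self.idx, minlength=self.nbins)
        self.hit_tot = np.bincount(self.idx[correct], minlength=self.nbins)

    def _min_one(self, cnt, hit):
        sup = cnt > 0
        grid = (np.flatnonzero(sup) * self.bw + self.lo).astype(float)
        acc = hit[sup] / cnt[sup]
        fitted = loess_fit(grid, acc, span=self.span, degree=self.degree)
        sel = (grid >= self.search_lo) & (grid <= self.search_hi)
        if not sel.any():
            raise ValueError("no grid points in the search range")
        return float(fitted[sel].min())

    def minima(self, is_congruent):
        cnt_c = np.bincount(self.idx[is_congruent], minlength=self.nbins)
        hit_c = np.bincount(self.idx[is_congruent & self.correct],
                            minlength=self.nbins)
        return (
            self._min_one(cnt_c, hit_c),
            self._min_one(self.cnt_tot - cnt_c, self.hit_tot - hit_c),
        )


def permutation_test_minima(
    table: TrialTable,
    B: int = 1000,
    seed: int = 0,
    span: float = DEFAULT_SPAN,
    degree: int = DEFAULT_DEGREE,
    sidedness: str = "one_sided",
    bin_width: int = 1,
    search_lo: int = -200,
    search_hi: int = 1000,
    stratify_by_participant: bool = False,
    max_retries: int = 10,
) -> PermutationResult:
    """Permutation test of the congruent-vs-incongruent minima difference.

    Each replicate permutes the congruency labels uniformly at random over
    all analyzed trials (the label multiset is preserved exactly), then
    recomputes both curves and their minima. ``stratify_by_participant``
    restricts shuffling to within-participant label exchanges. A replicate
    whose smoothing fails (degenerate resampled support) is reshuffled, up
    to ``max_retries`` times, and counted in ``n_retries``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if sidedness not in ("one_sided", "two_sided"):
        raise ValueError(f"sidedness must be one_sided or two_sided, got {sidedness!r}")
    df = table.data
    labels = (df["congruency"] == "congruent").to_numpy()
    if labels.all() or not labels.any():
        raise ValueError("both congruency conditions must be present")
    rpt = df["rpt_ms"].to_numpy("int64")
    correct = df["correct"].to_numpy(bool)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    engine = _MinimaEngine(rpt, correct, span, degree, bin_width,
                           search_lo, search_hi)
    mc, mi = engine.minima(labels)
    observed = mc - mi

    if stratify_by_participant:
        groups = [
            np.flatnonzero((df["participant_id"] == p).to_numpy())
            for p in df["participant_id"].unique()
        ]
    null = np.empty(B)
    n_retries = 0
    for b in range(B):
        for attempt in range(max_retries + 1):
            perm = labels.copy()
            if stratify_by_participant:
                for g in groups:
                    perm[g] = perm[g[rng.permutation(len(g))]]
            else:
                perm = perm[rng.permutation(len(perm))]
            try:
                pc, pi = engine.minima(perm)
                null[b] = pc - pi
                break
            except (ValueError, np.linalg.LinAlgError):
                n_retries += 1
                if attempt == max_retries:
                    raise
    if sidedness == "one_sided":
        count = int(np.sum(null >= observed))
    else:
        count = int(np.sum(np.abs(null) >= abs(observed)))
    p = (1 + count) / (B + 1)
    return PermutationResult(
        observed_diff=observed,
        null_diffs=null,
        p_value=p,
        d_z=effect_size_dz(observed, null),
        B=B,
        seed=seed,
        sidedness=sidedness,
        min_congruent=mc,
        min_incongruent=mi,
        n_retries=n_retries,
    )
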