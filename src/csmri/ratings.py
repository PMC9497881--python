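"""Ordinal reader-study statistics.

Radiological image-quality studies score each case on a five-point scale
(1 = unacceptable ... 5 = excellent) for several criteria and compare paired
sequences with the Wilcoxon signed-rank test under a Bonferroni-style
significance threshold; a case rated 1 or 2 counts as "insufficient".
This module implements that workflow — descriptive statistics,
insufficiency rates, an exact-and-approximate Wilcoxon test that copes with
the heavy ties of ordinal data, and the three-way pairwise comparison —
plus a latent-quality ratings simulator so the pipeline is testable without
human readers.

The exact Wilcoxon null distribution is computed by dynamic-programming
convolution over (doubled, hence integer) midranks, which stays exact in
the presence of ties; the normal approximation delegates to
``scipy.stats.wilcoxon`` with continuity correction.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

SEQUENCES = ("ssfse_conv", "mtse", "ssfse_cs")
CRITERIA = (
    "artifact",
    "organ_sharpness",
    "small_structure",
    "overall",
    "liver_lesion",
    "pancreatic_lesion",
)
PAIRS = (("ssfse_conv", "mtse"), ("ssfse_conv", "ssfse_cs"), ("mtse", "ssfse_cs"))

RATING_COLUMNS = ["case_id", "sequence", "criterion", "score"]


@dataclass
class RatingTable:
    """Five-point ordinal scores, one row per (case, sequence, criterion)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = set(RATING_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"rating table missing columns {sorted(missing)}")
        if not df["score"].isin([1, 2, 3, 4, 5]).all():
            raise ValueError("scores must be integers 1-5")
        if df.duplicated(subset=["case_id", "sequence", "criterion"]).any():
            raise ValueError("duplicate (case, sequence, criterion) entries")
        bad_seq = set(df["sequence"]) - set(SEQUENCES)
        if bad_seq:
            raise ValueError(f"unknown sequences {sorted(bad_seq)}")

    @classmethod
    def from_csv(cls, path) -> "RatingTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data[RATING_COLUMNS].to_csv(path, index=False)

    def scores(self, sequence: str, criterion: str) -> pd.Series:
        df = self.data
        sel = df[(df["sequence"] == sequence) & (df["criterion"] == criterion)]
        return sel.set_index("case_id")["score"]


@dataclass
class DescriptiveStats:
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    range: tuple[float, float]


def descriptive_stats(scores: Sequence[float]) -> DescriptiveStats:
    """Mean ± sample SD (n-1), median, quartiles (linear interpolation),
    min-max range."""
    x = np.asarray(scores, dtype=float)
    if x.size == 0:
        raise ValueError("empty score list")
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return DescriptiveStats(
        mean=float(np.mean(x)),
        sd=sd,
        median=float(np.median(x)),
        q1=float(np.quantile(x, 0.25)),
        q3=float(np.quantile(x, 0.75)),
        range=(float(x.min()), float(x.max())),
    )


def insufficient_rate(scores: Sequence[int]) -> tuple[int, float]:
    """Count and percentage (one decimal) of scores rated insufficient
    (<= 2)."""
    x = np.asarray(scores)
    if x.size == 0:
        raise ValueError("empty score list")
    count = int(np.sum(x <= 2))
    return count, round(100.0 * count / x.size, 1)


@dataclass
class TestResult:
    """Wilcoxon signed-rank outcome for one paired comparison."""

    statistic: float  # W+ = sum of ranks of positive differences
    p_value: float
    method: str  # "exact" | "normal_approx" | "degenerate"
    n_effective: int  # nonzero differences
    significant: bool | None = None
    p_adjusted: float | None = None


def _signed_ranks(d: np.ndarray, zero_method: str) -> tuple[np.ndarray, np.ndarray]:
    """Midranks of |d| and the signs, after the chosen zero handling.

    pratt: zeros are ranked with everything else, then dropped from the
    sums; wilcox: zeros discarded before ranking.
    """
    if zero_method == "wilcox":
        d = d[d != 0]
        ranks = stats.rankdata(np.abs(d))
        return ranks, np.sign(d)
    if zero_method == "pratt":
        ranks = stats.rankdata(np.abs(d))
        keep = d != 0
        return ranks[keep], np.sign(d[keep])
    raise ValueError(f"unknown zero_method {zero_method!r}")


def _exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p by DP convolution over doubled midranks."""
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    n_assign = 2.0 ** len(r2)
    w2 = int(np.rint(2 * w_plus))
    cdf = counts[: w2 + 1].sum() / n_assign
    sf = counts[w2:].sum() / n_assign
    return float(min(1.0, 2.0 * min(cdf, sf)))


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    zero_method: str = "pratt",
    mode: str = "auto",
    exact_cutoff: int = 25,
) -> TestResult:
    """Two-sided paired Wilcoxon signed-rank test.

    ``mode="exact"`` enumerates the null distribution of W+ over all sign
    assignments of the nonzero ranked differences (ties handled by
    midranks); ``"approx"`` uses the tie-corrected normal approximation
    with continuity correction; ``"auto"`` picks exact when the number of
    nonzero differences is at most ``exact_cutoff``.  If every difference
    is zero the test is degenerate and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("x and y must be equal-length 1D with n >= 1")
    d = x - y
    if np.all(d == 0):
        return TestResult(0.0, 1.0, "degenerate", 0)

    ranks, signs = _signed_ranks(d, zero_method)
    w_plus = float(ranks[signs > 0].sum())
    m = len(ranks)

    if mode not in ("exact", "approx", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    use_exact = mode == "exact" or (mode == "auto" and m <= exact_cutoff)

    if use_exact:
        p = _exact_p(ranks, w_plus)
        return TestResult(w_plus, p, "exact", m)

    res = stats.wilcoxon(x, y, zero_method=zero_method, correction=True, method="approx")
    return TestResult(w_plus, float(res.pvalue), "normal_approx", m)


@dataclass
class SequenceComparison:
    """Results of the three pairwise sequence comparisons for one criterion."""

    criterion: str
    alpha: float
    results: dict[tuple[str, str], TestResult] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"Pairwise Wilcoxon signed-rank tests — criterion: {self.criterion}",
            f"significance threshold: p < {self.alpha}",
            "-" * 64,
            f"{'pair':<28}{'W+':>8}{'n_eff':>7}{'p':>10}{'p_adj':>10}  sig",
        ]
        for (a, b), r in self.results.items():
            lines.append(
                f"{a + ' vs ' + b:<28}{r.statistic:>8.1f}{r.n_effective:>7}"
                f"{r.p_value:>10.4g}{r.p_adjusted:>10.4g}  {'*' if r.significant else ''}"
            )
        return "\n".join(lines)


def compare_sequences(
    table: RatingTable,
    criterion: str,
    alpha_family: float = 0.025,
    correction: str = "bonferroni",
    zero_method: str = "pratt",
    mode: str = "auto",
) -> SequenceComparison:
    """Three pairwise Wilcoxon tests (conv-mtse, conv-cs, mtse-cs) on cases
    rated under both members of each pair.

    Significance is declared at ``alpha_family`` per pair (0.025 by
    convention in this study design); Bonferroni-adjusted p-values
    (times the number of pairs, capped at 1) are reported alongside.
    """
    if correction != "bonferroni":
        raise ValueError("only bonferroni correction is supported")
    out = SequenceComparison(criterion, alpha_family)
    for a, b in PAIRS:
        sa = table.scores(a, criterion)
        sb = table.scores(b, criterion)
        common = sa.index.intersection(sb.index)
        if len(common) < 2:
            raise ValueError(f"fewer than 2 complete pairs for {a} vs {b}")
        r = wilcoxon_signed_rank(
            sa.loc[common].to_numpy(), sb.loc[common].to_numpy(),
            zero_method=zero_method, mode=mode,
        )
        r.p_adjusted = min(1.0, len(PAIRS) * r.p_value)
        r.significant = r.p_value < alpha_family
        out.results[(a, b)] = r
    return out


def simulate_ratings(
    n_cases: int,
    latent_quality: Mapping[str, float],
    reader_sd: float,
    seed: int = 0,
    criterion: str = "overall",
) -> RatingTable:
    """Synthetic consensus ratings: per case and sequence,
    ``score = clip(round(latent + N(0, reader_sd)), 1, 5)``."""
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    if reader_sd < 0:
        raise ValueError("reader_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for seq, latent in latent_quality.items():
        noise = rng.normal(0.0, reader_sd, size=n_cases) if reader_sd > 0 else np.zeros(n_cases)
        scores = np.clip(np.rint(latent + noise), 1, 5).astype(int)
        for case, s in enumerate(scores):
            rows.append((case, seq, criterion, int(s)))
    return RatingTable(pd.DataFrame(rows, columns=RATING_COLUMNS))
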