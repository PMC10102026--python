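"""Stochastic frequency matching for incompletely penetrant phenotypes.

Ten-cell outgrowth transcriptomes are screened for genes whose expression
occupies distinct states across outgrowths, and the per-gene frequency of
extreme-expression events is compared with the binomial distribution implied
by the phenotype penetrance.  With 20 sampled outgrowths and a 35% penetrant
phenotype, a matched gene should show ~0.35 × 20 = 7 events: genes inside the
interquartile range of B(20, 0.35) are scored high-priority and genes inside
its 90% confidence interval are candidates.

Event thresholds come from per-gene empirical 10th/90th percentiles of the
untreated (minus-AP) condition, mirroring the ~10% background rate of the
phenotype; counting uses strict inequalities so threshold ties are not
events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "BinomialBand",
    "binomial_band",
    "control_thresholds",
    "count_events",
    "classify_count",
    "heterogeneity_screen",
    "frequency_matching",
    "penetrance_stats",
]

LN2 = np.log(2.0)


@dataclass
class ExpressionMatrix:
    """log₂-scale expression values with per-sample condition metadata.

    values: genes × samples DataFrame; samples: DataFrame indexed by sample
    id with columns ``condition`` ∈ {minusAP, plusAP} and ``sample_type`` ∈
    {biological, poolsplit}; detected: optional boolean DataFrame aligned
    with values.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    detected: pd.DataFrame | None = None

    def __post_init__(self):
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene identifiers")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample identifiers")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
        for col in ("condition", "sample_type"):
            if col not in self.samples.columns:
                raise ValueError(f"sample sheet lacks column {col!r}")
        if self.detected is not None and self.detected.shape != self.values.shape:
            raise ValueError("detection flags must align with values")

    def select(self, condition: str, sample_type: str) -> pd.DataFrame:
        keep = self.samples.index[
            (self.samples["condition"] == condition)
            & (self.samples["sample_type"] == sample_type)
        ]
        return self.values.loc[:, [c for c in self.values.columns if c in set(keep)]]


@dataclass(frozen=True)
class BinomialBand:
    """Inverse-binomial count intervals for frequency matching."""

    n: int
    p: float
    expected: float
    iqr: tuple[int, int]
    ci90: tuple[int, int]

    def classify(self, matched_count: int) -> str:
        if self.iqr[0] <= matched_count <= self.iqr[1]:
            return "high_priority"
        if self.ci90[0] <= matched_count <= self.ci90[1]:
            return "candidate"
        return "unmatched"


def binomial_band(n: int, p: float, iqr_levels=(0.25, 0.75),
                  ci_levels=(0.05, 0.95)) -> BinomialBand:
    """Exact binomial count band: endpoints are min{k : CDF(k) ≥ level}.

    Computed by exact CDF summation (scipy's binom is exact for these n; no
    normal approximation is involved).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    b = stats.binom(n, p)
    q = lambda level: int(b.ppf(level))
    return BinomialBand(
        n=n, p=p, expected=n * p,
        iqr=(q(iqr_levels[0]), q(iqr_levels[1])),
        ci90=(q(ci_levels[0]), q(ci_levels[1])),
    )


def control_thresholds(minus_ap_values) -> tuple[float, float]:
    """Empirical 10th/90th percentiles of the control condition for one gene.

    Linear interpolation between closest order statistics (the numpy
    default convention).
    """
    v = np.asarray(minus_ap_values, float)
    v = v[np.isfinite(v)]
    if v.size < 5:
        raise ValueError("need >= 5 finite control values")
    p10, p90 = np.percentile(v, [10.0, 90.0])
    return float(p10), float(p90)


def count_events(plus_ap_values, thresholds: tuple[float, float]) -> tuple[int, int]:
    """Count outgrowths strictly above p90 / strictly below p10."""
    p10, p90 = thresholds
    v = np.asarray(plus_ap_values, float)
    v = v[np.isfinite(v)]
    return int((v > p90).sum()), int((v < p10).sum())


def classify_count(n_above: int, n_below: int, band: BinomialBand,
                   n_samples: int, mode: str = "max"):
    """Tier a gene by its matched event count against the binomial band.

    ``mode="max"`` (default) scores the dominant direction only, avoiding
    double counting of bidirectional genes; ``mode="sum"`` pools both
    directions.
    """
    if band.n != n_samples:
        raise ValueError(
            f"band is for n={band.n} trials but {n_samples} samples were scored"
        )
    if mode == "max":
        matched = max(n_above, n_below)
    elif mode == "sum":
        matched = n_above + n_below
    else:
        raise ValueError(f"unknown mode {mode!r}")
    direction = "up" if n_above >= n_below else "down"
    tied = n_above == n_below
    return matched, direction, tied, band.classify(matched)


@dataclass
class HeterogeneityParams:
    detection_p: float = 0.1
    max_fc_reproducible: float = 5.0
    fdr_sampling: float = 0.05
    ref_cv: float = 0.2
    fdr_het: float = 0.1


def heterogeneity_screen(matrix: ExpressionMatrix, condition: str = "plusAP",
                         params: HeterogeneityParams | None = None) -> pd.DataFrame:
    """Flag genes more variable across outgrowths than technical replicates.

    A simplified variance-ratio surrogate for the full stochastic-profiling
    filter: per retained gene, a one-sided F test of the biological
    log-variance against the larger of the pool-and-split variance and a
    floor implied by the reference CV, followed by Benjamini-Hochberg
    adjustment at ``fdr_het``.

    Genes undetected in more than half of the condition's samples, and genes
    whose pool-and-split replicates span more than ``max_fc_reproducible``
    fold, are excluded before testing.
    """
    params = params or HeterogeneityParams()
    bio = matrix.select(condition, "biological")
    tech = matrix.select(condition, "poolsplit")
    if tech.shape[1] < 3:
        raise ValueError("technical reference requires >= 3 pool-and-split samples")
    if bio.shape[1] < 3:
        raise ValueError("need >= 3 biological samples")

    genes = matrix.values.index
    keep = pd.Series(True, index=genes)
    if matrix.detected is not None:
        det = matrix.detected[list(bio.columns)]
        keep &= det.sum(axis=1) >= det.shape[1] / 2.0
    # pool-split fold-range reproducibility gate (log2 scale)
    fc_span = tech.max(axis=1) - tech.min(axis=1)
    keep &= fc_span <= np.log2(params.max_fc_reproducible)

    var_bio = bio.var(axis=1, ddof=1)
    var_tech = tech.var(axis=1, ddof=1)
    # CV floor mapped to the log2 scale (lognormal small-CV approximation)
    floor = (params.ref_cv / LN2) ** 2
    denom = np.maximum(var_tech, floor)
    f_stat = var_bio / denom
    df1, df2 = bio.shape[1] - 1, tech.shape[1] - 1
    pvals = stats.f.sf(f_stat, df1, df2)

    out = pd.DataFrame({
        "variance_ratio": f_stat,
        "p": pvals,
        "tested": keep,
        "q": np.nan,
        "flagged": False,
    }, index=genes)
    out.loc[~keep, ["variance_ratio", "p"]] = np.nan
    tested = out.index[keep]
    if len(tested):
        rej, qvals, _, _ = multipletests(out.loc[tested, "p"], alpha=params.fdr_het,
                                         method="fdr_bh")
        out.loc[tested, "q"] = qvals
        out.loc[tested, "flagged"] = rej
    return out


def frequency_matching(matrix: ExpressionMatrix, n: int | None = None,
                       p: float = 0.35, mode: str = "max",
                       het: pd.DataFrame | None = None,
                       params: HeterogeneityParams | None = None) -> pd.DataFrame:
    """Run the full screen: heterogeneity filter, thresholds, counts, tiers.

    Only genes flagged as heterogeneous in the treated condition are scored
    (pass ``het`` to reuse a precomputed screen).  ``n`` defaults to the
    number of plus-AP biological samples.
    """
    if het is None:
        het = heterogeneity_screen(matrix, "plusAP", params)
    plus = matrix.select("plusAP", "biological")
    minus = matrix.select("minusAP", "biological")
    if n is None:
        n = plus.shape[1]
    band = binomial_band(n, p)
    rows = []
    for gene in matrix.values.index[het["flagged"]]:
        p10, p90 = control_thresholds(minus.loc[gene])
        n_above, n_below = count_events(plus.loc[gene], (p10, p90))
        matched, direction, tied, tier = classify_count(
            n_above, n_below, band, plus.shape[1], mode=mode)
        rows.append({
            "gene": gene, "p10": p10, "p90": p90, "n_above": n_above,
            "n_below": n_below, "matched_count": matched,
            "direction": direction, "direction_tied": tied, "tier": tier,
        })
    cols = ["gene", "p10", "p90", "n_above", "n_below", "matched_count",
            "direction", "direction_tied", "tier"]
    return pd.DataFrame(rows, columns=cols).set_index("gene")


def penetrance_stats(successes, totals, other: tuple | None = None):
    """Arcsine-transformed phenotype penetrance summary (and group test).

    Each replicate proportion s/t is transformed as arcsin(√(s/t)); returns
    the transformed mean ± s.e. and the back-transformed proportion.  If
    ``other=(successes, totals)`` is given, a two-sided t test on the
    transformed scale compares the groups.  Zero-total replicates are
    excluded with a note.
    """
    s = np.asarray(successes, float)
    t = np.asarray(totals, float)
    if np.any(s > t) or np.any(s < 0):
        raise ValueError("need 0 <= successes <= totals")
    notes = []
    ok = t > 0
    if not ok.all():
        notes.append(f"excluded {int((~ok).sum())} zero-total replicate(s)")
    x = np.arcsin(np.sqrt(s[ok] / t[ok]))
    mean = float(x.mean())
    se = float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan
    out = {
        "transformed_mean": mean,
        "transformed_se": se,
        "proportion": float(np.sin(mean) ** 2),
        "n": int(ok.sum()),
        "notes": notes,
    }
    if other is not None:
        s2 = np.asarray(other[0], float)
        t2 = np.asarray(other[1], float)
        ok2 = t2 > 0
        x2 = np.arcsin(np.sqrt(s2[ok2] / t2[ok2]))
        tt = stats.ttest_ind(x, x2)
        out["t_statistic"] = float(tt.statistic)
        out["p_two_sided"] = float(tt.pvalue)
    return out
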