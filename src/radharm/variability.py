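"""Cross-centre feature-distribution variability: sequential correlation
filtering, pairwise-centre Jensen–Shannon divergence (JSD), threshold-based
similarity proportions and per-family summaries.

JSD here is base-2 (bounded in [0, 1]); the similarity threshold ``tau``
(default 0.01) counts a feature's centre-pair comparison as "similar" when
its JSD is strictly below ``tau``.  Divergences are estimated from
histograms built on a shared support (pooled range, equal-width bins, bin
count growing as the square root of the smaller sample) with additive
smoothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import FeatureTable


# ---------------------------------------------------------------------------
# sequential correlation filter
# ---------------------------------------------------------------------------

def correlation_filter(table: FeatureTable, r2_threshold: float = 0.9
                       ) -> tuple[FeatureTable, list[str]]:
    """Greedy sequential de-correlation in canonical column order.

    Scanning columns left to right, a feature is removed iff its squared
    Pearson correlation with any previously *retained* feature is at least
    ``r2_threshold``.  Zero-variance columns are undefined under R² and are
    removed with a warning.
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ValueError("r2_threshold must be in (0, 1]")
    x = table.data.to_numpy(dtype=float)
    cols = list(table.data.columns)
    spread = np.ptp(x, axis=0) if x.shape[0] else np.zeros(x.shape[1])
    retained: list[int] = []
    removed: list[str] = []
    for j in range(x.shape[1]):
        if spread[j] == 0:
            warnings.warn(f"zero-variance feature {cols[j]!r} removed",
                          stacklevel=2)
            removed.append(cols[j])
            continue
        drop = False
        for k in retained:
            r = np.corrcoef(x[:, j], x[:, k])[0, 1]
            if r * r >= r2_threshold:
                drop = True
                break
        if drop:
            removed.append(cols[j])
        else:
            retained.append(j)
    keep = [cols[j] for j in retained]
    filtered = FeatureTable(
        data=table.data[keep].copy(),
        row_meta=table.row_meta.copy(),
        col_meta=table.col_meta.loc[keep].copy(),
    )
    return filtered, removed


# ---------------------------------------------------------------------------
# Jensen-Shannon divergence between samples
# ---------------------------------------------------------------------------

def _shared_histograms(p_samples, q_samples, n_bins=None):
    pooled = np.concatenate([p_samples, q_samples])
    lo, hi = pooled.min(), pooled.max()
    if hi == lo:
        return None, None
    if n_bins is None:
        # Bin count scales as sqrt(n)/4 of the smaller sample (floor 2).
        # The same-distribution sampling-noise floor of the divergence is
        # ~(B-1)/(5.5 n): with this rule it sits at the similarity
        # threshold's scale (~0.01) for cohort-sized samples (n ~ 20-30)
        # and vanishes for large n, so identical distributions register as
        # similar while real shifts do not.
        n_min = min(p_samples.size, q_samples.size)
        n_bins = max(2, int(np.sqrt(n_min) / 4))
        n_bins = min(n_bins, 512)
    edges = np.linspace(lo, hi, n_bins + 1)
    hp, _ = np.histogram(p_samples, bins=edges)
    hq, _ = np.histogram(q_samples, bins=edges)
    return hp.astype(float), hq.astype(float)


def jsd(p_samples: np.ndarray, q_samples: np.ndarray, n_bins: int | None = None,
        eps: float = 1e-10) -> float:
    """Base-2 Jensen–Shannon divergence between two samples.

    ``JSD = 0.5 KL(p || m) + 0.5 KL(q || m)`` with ``m = (p + q) / 2`` on
    histograms over a shared support; 0 for identical distributions, 1 for
    fully disjoint supports.  A degenerate pooled support (single point)
    returns 0 with a warning.
    """
    p_samples = np.asarray(p_samples, dtype=float).ravel()
    q_samples = np.asarray(q_samples, dtype=float).ravel()
    if p_samples.size == 0 or q_samples.size == 0:
        raise ValueError("jsd requires non-empty samples")
    hp, hq = _shared_histograms(p_samples, q_samples, n_bins)
    if hp is None:
        warnings.warn("degenerate shared support in jsd; returning 0",
                      stacklevel=2)
        return 0.0
    return jsd_hist(hp, hq, eps=eps)


def jsd_hist(hp: np.ndarray, hq: np.ndarray, eps: float = 1e-10) -> float:
    """Base-2 JSD of two (unnormalised) histograms on common bins."""
    p = np.asarray(hp, dtype=float) + eps
    q = np.asarray(hq, dtype=float) + eps
    p = p / p.sum()
    q = q / q.sum()
    m = 0.5 * (p + q)
    with np.errstate(divide="ignore", invalid="ignore"):
        kl_pm = np.sum(np.where(p > 0, p * np.log2(p / m), 0.0))
        kl_qm = np.sum(np.where(q > 0, q * np.log2(q / m), 0.0))
    return float(np.clip(0.5 * kl_pm + 0.5 * kl_qm, 0.0, 1.0))


# ---------------------------------------------------------------------------
# per-feature, per-centre-pair records
# ---------------------------------------------------------------------------

@dataclass
class JSDRecord:
    feature: str
    family: str
    roi: str
    order: str
    phase: str
    centre_a: str
    centre_b: str
    jsd: float


def centre_pair_jsd(table: FeatureTable, pathology: str | None = "healthy",
                    r2_threshold: float | None = 0.9,
                    min_subjects: int = 2) -> list[JSDRecord]:
    """JSD between every unordered centre pair for every retained feature.

    By default only healthy subjects are compared (disease subgroups would
    confound the centre comparison) and the sequential correlation filter at
    R² >= ``r2_threshold`` is applied per (ROI, order, phase) group before
    computing divergences.  Centres with fewer than ``min_subjects`` rows
    are skipped with a warning.
    """
    sub = table.select(pathology=pathology) if pathology else table
    centres = sorted(sub.row_meta["centre"].unique())
    if len(centres) < 2:
        raise ValueError("need at least 2 centres")
    records: list[JSDRecord] = []
    for phase in sorted(sub.row_meta["phase"].unique()):
        for roi in sorted(sub.col_meta["roi"].unique()):
            for order in ("first", "second"):
                grp = sub.select(phase=phase, roi=roi, order=order)
                if grp.data.shape[1] == 0 or grp.n_subjects == 0:
                    continue
                if r2_threshold is not None:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        grp, _ = correlation_filter(grp, r2_threshold)
                cmeta = grp.col_meta
                for ca, cb in combinations(centres, 2):
                    a = grp.data[(grp.row_meta["centre"] == ca).values]
                    b = grp.data[(grp.row_meta["centre"] == cb).values]
                    if len(a) < min_subjects or len(b) < min_subjects:
                        warnings.warn(
                            f"skipping pair ({ca}, {cb}) for {roi}/{order}: "
                            "too few subjects", stacklevel=2)
                        continue
                    for feat in grp.data.columns:
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            val = jsd(a[feat].to_numpy(), b[feat].to_numpy())
                        records.append(JSDRecord(
                            feature=feat, family=cmeta.at[feat, "family"],
                            roi=roi, order=order, phase=phase,
                            centre_a=ca, centre_b=cb, jsd=val))
    return records


def records_frame(records: list[JSDRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


@dataclass
class VariabilityReport:
    """Similarity proportions and per-family JSD summaries."""

    threshold: float
    #: % of (feature x ROI x centre-pair) comparisons with JSD < tau, by
    #: (order, phase): mean and sd over centre pairs x ROI
    proportions: pd.DataFrame
    #: per (family, phase): mean and sd of JSD over features/pairs/ROIs
    family_summary: pd.DataFrame
    #: features whose JSD sd across comparisons exceeds the threshold
    most_dissimilar: pd.DataFrame
    records: pd.DataFrame = field(repr=False, default=None)


def summarise(records: list[JSDRecord], tau: float = 0.01) -> VariabilityReport:
    """Aggregate JSD records into threshold proportions and family tables.

    The proportion for an (order, phase) cell is the percentage of retained
    features with JSD strictly below ``tau``, computed per (centre pair,
    ROI) stratum and then averaged (mean and sd) over strata.
    """
    if not records:
        raise ValueError("no JSD records to summarise")
    df = records_frame(records)
    df["below"] = df["jsd"] < tau
    df["pair"] = df["centre_a"] + "|" + df["centre_b"]

    strata = (
        df.groupby(["order", "phase", "pair", "roi"])["below"]
        .mean()
        .mul(100.0)
        .reset_index(name="pct")
    )
    proportions = (
        strata.groupby(["order", "phase"])["pct"]
        .agg(mean="mean", sd="std")
        .reset_index()
    )

    family_summary = (
        df.groupby(["family", "phase"])["jsd"]
        .agg(mean="mean", sd="std")
        .reset_index()
    )

    per_feature_sd = (
        df.groupby(["feature", "roi", "phase"])["jsd"].std().reset_index(name="sd")
    )
    most_dissimilar = per_feature_sd[per_feature_sd["sd"] > tau].reset_index(
        drop=True)

    return VariabilityReport(threshold=tau, proportions=proportions,
                             family_summary=family_summary,
                             most_dissimilar=most_dissimilar, records=df)


# ---------------------------------------------------------------------------
# distribution comparisons between methods
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    test: str
    statistic: float
    p_value: float
    alpha_adjusted: float
    significant: bool


def compare_methods(*groups, alpha: float = 0.01,
                    n_comparisons: int = 1) -> ComparisonResult:
    """Two-sided Mann–Whitney U for two groups, Kruskal–Wallis for three or
    more, with Bonferroni-adjusted significance level
    ``alpha / n_comparisons``."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    adj = alpha / n_comparisons
    if len(arrays) == 2:
        res = stats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
        return ComparisonResult("mannwhitneyu", float(res.statistic),
                                float(res.pvalue), adj, res.pvalue < adj)
    res = stats.kruskal(*arrays)
    return ComparisonResult("kruskal", float(res.statistic),
                            float(res.pvalue), adj, res.pvalue < adj)


def bonferroni(alpha: float, n_comparisons: int) -> float:
    """Bonferroni-adjusted per-comparison significance level."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return alpha / n_comparisons
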