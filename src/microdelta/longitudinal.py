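"""Paired baseline-to-end analyses.

For every subject with both timepoints we compute the change (end minus
baseline) in a per-sample measure — the first principal coordinate of a
beta-diversity ordination, or a richness metric — and test, per stratum
(arm, or arm x sex), whether the mean change differs from zero with a
one-sample t test, Benjamini-Hochberg-corrected across the family of tests
run together.  The module also compares the *magnitude* of change between
arms (rank-sum on within-pair distances), estimates the between- vs
within-subject intraclass correlation by components of variance, and
correlates PC1 with collapsed taxon abundances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.stats as sps
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .core_io import CohortMetadata, FeatureTable
from .diversity import OrdinationResult

__all__ = [
    "IccResult",
    "paired_deltas",
    "orient_pc1",
    "one_sample_shift_tests",
    "magnitude_comparison",
    "icc",
    "pc_taxon_correlation",
]

logger = logging.getLogger(__name__)


def orient_pc1(res: OrdinationResult, table: FeatureTable) -> OrdinationResult:
    """Fix the arbitrary PCoA axis sign by a deterministic convention.

    The taxon whose relative abundance has the largest |Spearman
    correlation| with PC1 is made positively correlated; if that requires a
    flip, the PC1 coordinates are negated.  Makes per-subject deltas
    comparable across runs.
    """
    frac = table.relative_abundance()
    common = [s for s in res.sample_ids if s in frac.index]
    pc1 = res.pc1().loc[common].to_numpy()
    best, best_corr = None, 0.0
    for fid in frac.columns:
        x = frac.loc[common, fid].to_numpy()
        if np.ptp(x) == 0 or np.ptp(pc1) == 0:
            continue
        r = sps.spearmanr(pc1, x).statistic
        if np.isfinite(r) and abs(r) > abs(best_corr):
            best, best_corr = fid, r
    if best is not None and best_corr < 0:
        coords = res.coordinates.copy()
        coords["PC1"] = -coords["PC1"]
        return OrdinationResult(coords, res.eigenvalues, res.proportion_explained)
    return res


def paired_deltas(
    values: pd.Series | OrdinationResult,
    meta: CohortMetadata,
    axis: str = "PC1",
) -> pd.DataFrame:
    """Per-subject end-minus-baseline change in a per-sample measure.

    ``values`` is either a per-sample Series (e.g. a richness metric) or an
    :class:`OrdinationResult`, in which case ``axis`` selects the
    coordinate.  Subjects lacking either timepoint (or either value) are
    dropped with a logged count.  Returns one row per complete pair with
    columns ``subject_id, arm, sex, delta``.
    """
    if isinstance(values, OrdinationResult):
        values = values.coordinates[axis]
    rows = []
    dropped = 0
    info = meta.subject_info()
    for subj in meta.subjects():
        try:
            s_base = meta.sample_for(subj, "baseline")
            s_end = meta.sample_for(subj, "end")
        except KeyError:
            dropped += 1
            continue
        if s_base not in values.index or s_end not in values.index:
            dropped += 1
            continue
        rows.append(
            {
                "subject_id": subj,
                "arm": info.loc[subj, "arm"],
                "sex": info.loc[subj, "sex"],
                "delta": float(values[s_end]) - float(values[s_base]),
            }
        )
    if dropped:
        logger.info("paired_deltas: dropped %d incomplete pair(s)", dropped)
    if not rows:
        logger.warning("paired_deltas: no complete pairs")
        return pd.DataFrame(columns=["subject_id", "arm", "sex", "delta"])
    return pd.DataFrame(rows)


def one_sample_shift_tests(
    deltas: Mapping[str, pd.DataFrame] | pd.DataFrame,
    by_sex: bool = False,
) -> pd.DataFrame:
    """Two-sided one-sample t tests of mean delta per stratum, BH-corrected.

    ``deltas`` maps metric label to a :func:`paired_deltas` frame (a bare
    frame is treated as a single unnamed metric).  Strata are treatment arms,
    optionally split by sex.  The BH family is every (metric, stratum) row
    produced by this one call.  Zero-variance or n < 2 strata are flagged
    (``p`` is NaN) and excluded from the correction.
    """
    if isinstance(deltas, pd.DataFrame):
        deltas = {"value": deltas}
    rows = []
    for metric, df in deltas.items():
        group_cols = ["arm", "sex"] if by_sex else ["arm"]
        for keys, sub in df.groupby(group_cols, sort=True):
            keys = keys if isinstance(keys, tuple) else (keys,)
            d = sub["delta"].to_numpy(float)
            row = dict(zip(group_cols, keys))
            row.update(metric=metric, n=len(d), mean_delta=d.mean() if len(d) else np.nan)
            if len(d) < 2 or np.isclose(d.std(), 0.0):
                row.update(t=np.nan, p=np.nan, flag="degenerate")
            else:
                t, p = sps.ttest_1samp(d, 0.0)
                row.update(t=float(t), p=float(p), flag="")
            rows.append(row)
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "q"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    cols = ["metric"] + (["arm", "sex"] if by_sex else ["arm"]) + [
        "n", "mean_delta", "t", "p", "q", "flag"]
    return out[cols]


def magnitude_comparison(
    d: DistanceMatrix, meta: CohortMetadata
) -> tuple[float, float, pd.DataFrame]:
    """Compare arms on the size of each subject's baseline-to-end shift.

    The per-subject statistic is the beta-diversity distance between their
    two samples; arms are compared with a two-sided Wilcoxon rank-sum
    (Mann-Whitney U).  Returns ``(U, p, per_subject_frame)``.
    """
    info = meta.subject_info()
    rows = []
    for subj in meta.paired_subjects():
        s_b = meta.sample_for(subj, "baseline")
        s_e = meta.sample_for(subj, "end")
        if s_b not in d.ids or s_e not in d.ids:
            continue
        rows.append(
            {"subject_id": subj, "arm": info.loc[subj, "arm"],
             "distance": float(d[s_b, s_e])}
        )
    df = pd.DataFrame(rows)
    u_vals = df.loc[df["arm"] == "UDCA", "distance"]
    p_vals = df.loc[df["arm"] == "placebo", "distance"]
    if len(u_vals) == 0 or len(p_vals) == 0:
        raise ValueError("both arms need at least one complete pair")
    res = sps.mannwhitneyu(u_vals, p_vals, alternative="two-sided")
    return float(res.statistic), float(res.pvalue), df


@dataclass(frozen=True)
class IccResult:
    """Components-of-variance intraclass correlation for one metric."""

    metric: str
    sigma2_between: float
    sigma2_within: float

    @property
    def icc(self) -> float:
        tot = self.sigma2_between + self.sigma2_within
        return self.sigma2_between / tot if tot > 0 else 0.0


def icc(values: pd.Series, meta: CohortMetadata, metric: str = "value") -> IccResult:
    """One-way random-effects ANOVA estimator of the ICC (k = 2 per subject).

    ``sigma2_b = max(0, (MSB - MSW) / 2)``, ``sigma2_w = MSW``; negative
    between-subject components are truncated at zero so the ICC stays in
    [0, 1].  Only subjects with both timepoints contribute.
    """
    pairs = []
    for subj in meta.paired_subjects():
        s_b = meta.sample_for(subj, "baseline")
        s_e = meta.sample_for(subj, "end")
        if s_b in values.index and s_e in values.index:
            pairs.append((float(values[s_b]), float(values[s_e])))
    x = np.asarray(pairs, float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least two complete pairs")
    grand = x.mean()
    subj_means = x.mean(axis=1)
    msb = 2.0 * np.sum((subj_means - grand) ** 2) / (n - 1)
    msw = np.sum((x - subj_means[:, None]) ** 2) / n
    sigma2_b = max(0.0, (msb - msw) / 2.0)
    return IccResult(metric, sigma2_b, msw)


def pc_taxon_correlation(
    res: OrdinationResult, collapsed: FeatureTable
) -> pd.Series:
    """Spearman correlation of PC1 with each collapsed taxon's abundance.

    Computed on relative abundances across the samples shared by the
    ordination and the table, sorted by |correlation| descending.  Constant
    taxa are reported as NaN (correlation undefined).
    """
    frac = collapsed.relative_abundance()
    common = [s for s in res.sample_ids if s in frac.index]
    pc1 = res.pc1().loc[common].to_numpy()
    out = {}
    for taxon in frac.columns:
        x = frac.loc[common, taxon].to_numpy()
        if np.ptp(x) == 0:
            out[taxon] = np.nan
            continue
        out[taxon] = float(sps.spearmanr(pc1, x).statistic)
    s = pd.Series(out, name="spearman_rho")
    return s.reindex(s.abs().sort_values(ascending=False, kind="stable").index)
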