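"""ROI-level group comparisons and clinical-score correlations.

Desk-scale analog of a voxel-wise analysis: the 90 atlas regions are the
units. One-way ANOVA across the four groups per region (optionally on
covariate-adjusted values), two-sample pooled-t post-hoc contrasts against a
reference group restricted to ANOVA-significant regions, and per-region
Pearson correlations of uptake with a clinical score (FAQ) or with CSF
total-tau. Benjamini-Hochberg FDR is applied across the region family.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable, GROUPS
from .inference import fdr_bh
from .network import residualize

log = logging.getLogger(__name__)


def _group_values(cohort: CohortTable, adjust_covariates: bool = False):
    """Values (optionally residualized on age/sex/global uptake) per group."""
    values = cohort.values
    if adjust_covariates:
        values = residualize(values, cohort.meta("age"), cohort.meta("sex"),
                             cohort.global_uptake())
    groups = cohort.meta("group")
    present = [g for g in GROUPS if (groups == g).any()]
    return values, groups, present


def anova_regions(cohort: CohortTable, adjust_covariates: bool = False,
                  fdr_q: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA per region across the groups, BH-FDR across regions.

    Regions with zero variance inside every group are reported as degenerate
    and excluded from the FDR family.
    """
    values, groups, present = _group_values(cohort, adjust_covariates)
    if len(present) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    masks = {g: groups == g for g in present}
    for g, m in masks.items():
        if m.sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    names = cohort.atlas.names
    rows = []
    for j, region in enumerate(names):
        samples = [values[masks[g], j] for g in present]
        if all(s.std() == 0 for s in samples):
            rows.append({"region": region, "F": np.nan, "p": np.nan,
                         "degenerate": True})
            continue
        F, p = stats.f_oneway(*samples)
        row = {"region": region, "F": float(F), "p": float(p), "degenerate": False}
        for g, s in zip(present, samples):
            row[f"mean_{g}"] = float(s.mean())
        rows.append(row)
    out = pd.DataFrame(rows)
    ok = ~out["degenerate"]
    p_adj = np.full(len(out), np.nan)
    sig = np.zeros(len(out), dtype=bool)
    if ok.any():
        reject, adj = fdr_bh(out.loc[ok, "p"].to_numpy(), q=fdr_q)
        p_adj[ok.to_numpy()] = adj
        sig[ok.to_numpy()] = reject
    out["p_adj"] = p_adj
    out["significant"] = sig
    return out


def posthoc_contrasts(cohort: CohortTable, reference_group: str,
                      adjust_covariates: bool = False, fdr_q: float = 0.05,
                      restrict_to=None) -> dict[str, pd.DataFrame]:
    """Pooled two-sample t per region, each non-reference group vs reference.

    ``restrict_to`` limits the tested regions (by default the
    ANOVA-significant regions at the same FDR rate); BH-FDR is applied
    within each comparison.
    """
    values, groups, present = _group_values(cohort, adjust_covariates)
    if reference_group not in present:
        raise ValueError(f"reference group {reference_group!r} not present")
    if restrict_to is None:
        anova = anova_regions(cohort, adjust_covariates, fdr_q)
        restrict_to = anova.loc[anova["significant"], "region"].tolist()
    region_idx = [cohort.atlas.index(r) for r in restrict_to]
    ref_mask = groups == reference_group
    out: dict[str, pd.DataFrame] = {}
    for g in present:
        if g == reference_group:
            continue
        m = groups == g
        rows = []
        for j, region in zip(region_idx, restrict_to):
            a, b = values[m, j], values[ref_mask, j]
            t, p = stats.ttest_ind(a, b, equal_var=True)
            rows.append({"region": region, "t": float(t), "p": float(p),
                         f"mean_{g}": float(a.mean()),
                         f"mean_{reference_group}": float(b.mean())})
        df = pd.DataFrame(rows, columns=["region", "t", "p", f"mean_{g}",
                                         f"mean_{reference_group}"])
        if len(df):
            reject, adj = fdr_bh(df["p"].to_numpy(), q=fdr_q)
        else:
            reject, adj = np.zeros(0, bool), np.zeros(0)
        df["p_adj"] = adj
        df["significant"] = reject
        out[g] = df
    return out


def _pairwise_pearson(x: np.ndarray, score: np.ndarray, region: str) -> dict:
    ok = np.isfinite(x) & np.isfinite(score)
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"fewer than 3 complete pairs for region {region}")
    r, p = stats.pearsonr(x[ok], score[ok])
    return {"region": region, "r": float(r), "p": float(p), "n": n}


def correlate_with_score(cohort: CohortTable, regions, score_field: str,
                         group: str) -> pd.DataFrame:
    """Per-region Pearson r of uptake vs a clinical score within one group."""
    mask = cohort.meta("group") == group
    if mask.sum() < 3:
        raise ValueError(f"group {group!r} has fewer than 3 subjects")
    sub = cohort.subset(mask)
    score = sub.meta(score_field)
    complete = np.isfinite(score)
    if complete.sum() < mask.sum():
        log.info("dropping %d subject(s) with missing %s",
                 int(mask.sum() - complete.sum()), score_field)
    if np.nanstd(score) == 0:
        raise ValueError(f"{score_field} is constant in group {group!r}")
    rows = [_pairwise_pearson(sub.values[:, cohort.atlas.index(r)], score, r)
            for r in regions]
    return pd.DataFrame(rows)


def correlate_csf_pet(cohort: CohortTable, group: str) -> pd.DataFrame:
    """Pearson r of CSF T-Tau vs each region plus the global mean uptake."""
    mask = cohort.meta("group") == group
    sub = cohort.subset(mask)
    ttau = sub.meta("csf_ttau")
    if np.isfinite(ttau).sum() < 3:
        raise ValueError(f"fewer than 3 subjects with CSF T-Tau in {group!r}")
    if np.nanstd(ttau) == 0:
        raise ValueError(f"CSF T-Tau is constant in group {group!r}")
    rows = [_pairwise_pearson(sub.values[:, j], ttau, region)
            for j, region in enumerate(cohort.atlas.names)]
    rows.append(_pairwise_pearson(sub.global_uptake(), ttau, "GLOBAL_MEAN"))
    return pd.DataFrame(rows)
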