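"""Differential abundance, dendritic-localization calling and differential
3'UTR usage.

The count test is a negative-binomial Wald test (median-of-ratios size
factors, method-of-moments dispersions shrunk toward a mean-dispersion
trend) standing in, at the level of decision logic, for the DE tooling a
sequencing study would run. Localization calls combine three contrasts:

* dendrite-present: FDR(TRAP vs RNA in neuropil) < 0.05, LFC > 0, and
  LFC(Cre+ vs Cre-) > 0;
* dendrite-enriched: additionally FDR(neuropil vs cell-body TRAP) < 0.05
  and LFC > 0.

Differential 3'UTR usage is a beta-binomial likelihood-ratio test of the
isoform-vs-rest-of-gene proportion between conditions, with an optional
genotype x region interaction term.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_fdr, betabinom_lrt, estimate_dispersions, nb_glm_fit, size_factors

__all__ = [
    "nb_wald_test",
    "call_localization",
    "dendritic_localization_metric",
    "diff_utr_usage",
]

FDR_CUTOFF = 0.05


def _design(meta: pd.DataFrame, factor: str, level_test: str, level_ref: str,
            batch: str | None):
    """Intercept + contrast indicator (+ additive batch covariates)."""
    ind = (meta[factor] == level_test).astype(float).to_numpy()
    cols = [np.ones(len(meta)), ind]
    names = ["intercept", f"{factor}[{level_test}vs{level_ref}]"]
    if batch is not None:
        levels = sorted(meta[batch].unique())[1:]
        for lev in levels:
            cols.append((meta[batch] == lev).astype(float).to_numpy())
            names.append(f"{batch}[{lev}]")
    return np.column_stack(cols), names


def nb_wald_test(counts: pd.DataFrame, samples: pd.DataFrame,
                 contrast: tuple[str, str, str], batch: str | None = None,
                 sf: np.ndarray | None = None,
                 use_t: bool = False) -> pd.DataFrame:
    """Per-feature NB Wald test of ``contrast = (factor, test, ref)``.

    Returns a DiffResult frame with LFC (log2), SE, stat = LFC/SE, p and
    BH FDR. All-zero features get NA and are excluded from the BH
    denominator. Size factors default to median-of-ratios but can be
    supplied (e.g. all ones for pre-normalized counts). ``use_t`` refers
    the Wald statistic to a t distribution on the residual degrees of
    freedom instead of the standard normal.
    """
    factor, test, ref = contrast
    meta = samples.loc[samples[factor].isin([test, ref])]
    if min((meta[factor] == test).sum(), (meta[factor] == ref).sum()) < 2:
        raise ValueError("need >= 2 replicates per group")
    sub = counts[meta.index].to_numpy(dtype=float)
    if sf is None:
        sf = size_factors(sub)
    else:
        sf = np.asarray(sf, dtype=float)
    X, _ = _design(meta, factor, test, ref, batch)
    groups = meta[factor].to_numpy() if batch is None else (
        meta[factor].astype(str) + "/" + meta[batch].astype(str)).to_numpy()
    disp = estimate_dispersions(sub, sf, groups)
    offset = np.log(sf)
    n, p = X.shape
    df_resid = n - p

    lfc = np.full(len(sub), np.nan)
    se = np.full(len(sub), np.nan)
    for i in range(len(sub)):
        y = sub[i]
        if y.sum() == 0:
            continue
        beta, bse, _ = nb_glm_fit(y, X, offset, float(disp[i]))
        lfc[i] = beta[1] / np.log(2.0)
        se[i] = bse[1] / np.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = lfc / se
    if use_t and df_resid > 0:
        pval = 2.0 * sps.t.sf(np.abs(stat), df=df_resid)
    else:
        pval = 2.0 * sps.norm.sf(np.abs(stat))
    pval = np.where(np.isfinite(stat), pval, np.nan)
    return pd.DataFrame({
        "LFC": lfc, "SE": se, "stat": stat, "p": pval, "FDR": bh_fdr(pval),
    }, index=counts.index)


def call_localization(np_trap_vs_rna: pd.DataFrame,
                      cre_pos_vs_neg: pd.DataFrame,
                      np_vs_cb_trap: pd.DataFrame,
                      fdr: float = FDR_CUTOFF) -> pd.Series:
    """Classify genes as dendrite-enriched, dendrite-present or neither.

    Genes missing from any input table are classed ``neither``.
    """
    universe = np_trap_vs_rna.index
    a = np_trap_vs_rna.reindex(universe)
    b = cre_pos_vs_neg.reindex(universe)
    c = np_vs_cb_trap.reindex(universe)
    present = ((a["FDR"] < fdr) & (a["LFC"] > 0) & (b["LFC"] > 0)).fillna(False)
    enriched = present & ((c["FDR"] < fdr) & (c["LFC"] > 0)).fillna(False)
    out = pd.Series("neither", index=universe, name="localization")
    out[present] = "dendrite-present"
    out[enriched] = "dendrite-enriched"
    return out


def dendritic_localization_metric(np_vs_cb_trap: pd.DataFrame) -> pd.DataFrame:
    """Per-gene dendritic localization: the neuropil-vs-cell-body TRAP LFC,
    together with stat = LFC/SE for ranking and plotting."""
    return np_vs_cb_trap[["LFC", "stat"]].rename(
        columns={"LFC": "localization_lfc", "stat": "localization_stat"})


def diff_utr_usage(iso_counts: dict[str, pd.DataFrame], samples: pd.DataFrame,
                   condition: str = "compartment",
                   interaction_with: str | None = None) -> pd.DataFrame:
    """Beta-binomial test of differential isoform usage.

    ``iso_counts`` maps gene -> (isoform x sample) count frame. For each
    isoform of a multi-isoform gene, the count of that isoform out of the
    gene total is modelled on the logit scale; the likelihood-ratio test is
    on the condition coefficient, or on the condition x
    ``interaction_with`` interaction when requested. LFC is the log2 ratio
    of fitted usage proportions (condition on vs off). Samples where the
    gene total is zero are dropped for that gene; BH FDR is computed across
    all tested isoforms.
    """
    rows = []
    for gene, tab in iso_counts.items():
        if tab.shape[0] < 2:
            continue
        meta = samples.loc[tab.columns]
        cond_levels = sorted(meta[condition].unique())
        if len(cond_levels) != 2:
            raise ValueError(f"condition {condition!r} must have 2 levels")
        cond = (meta[condition] == cond_levels[1]).astype(float).to_numpy()
        cols = [np.ones(len(meta)), cond]
        test_col = 1
        if interaction_with is not None:
            other_levels = sorted(meta[interaction_with].unique())
            other = (meta[interaction_with] == other_levels[1]).astype(float).to_numpy()
            cols += [other, cond * other]
            test_col = 3
        X = np.column_stack(cols)
        totals = tab.sum(axis=0).to_numpy(dtype=float)
        for isoform, y in tab.iterrows():
            yv = y.to_numpy(dtype=float)
            beta, _, _, pval = betabinom_lrt(yv, totals, X, test_col)
            # usage log-ratio from pooled empirical proportions (with a
            # half-count continuity guard), not the shrunken model fit
            def pooled(mask):
                t = totals[mask].sum()
                return (yv[mask].sum() + 0.5) / (t + 1.0) if t > 0 else np.nan
            if interaction_with is None:
                p_on, p_off = pooled(cond == 1), pooled(cond == 0)
                lfc = np.log2(p_on / p_off) if p_off and np.isfinite(p_off) else np.nan
            else:
                p11, p10 = pooled((cond == 1) & (other == 1)), pooled((cond == 0) & (other == 1))
                p01, p00 = pooled((cond == 1) & (other == 0)), pooled((cond == 0) & (other == 0))
                lfc = np.log2((p11 / p10) / (p01 / p00))
            se = abs(lfc / sps.norm.isf(pval / 2)) if (
                np.isfinite(lfc) and 0 < pval < 1 and lfc != 0) else np.nan
            rows.append({"gene": gene, "isoform": isoform, "LFC": lfc,
                         "SE": se, "stat": lfc / se if se and np.isfinite(se) and se > 0 else np.nan,
                         "p": pval})
    out = pd.DataFrame(rows, columns=["gene", "isoform", "LFC", "SE", "stat", "p"])
    out["FDR"] = bh_fdr(out["p"].to_numpy()) if len(out) else []
    return out
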