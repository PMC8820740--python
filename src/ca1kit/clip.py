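"""Compartment-specific CLIP scores and two-rule dendritic target calling.

CLIP tags per gene are normalized first for transcript length and then for
sequencing depth (scaled to 10,000 tags) to give CLIP expression values
E_gr; a per-replicate ordinary least-squares fit of log10(E) on log10(TPM)
over well-detected genes defines the expected binding for a transcript of
that abundance, and the CLIP score is the log10 residual (observed minus
fitted). A gene is a dendritic target if it is reproducibly detected in
the neuropil (> 5 library-normalized tags per 10,000 in at least 3 of 5
replicates, no length term) OR its mean neuropil CLIP score exceeds 1.
"""

from __future__ import annotations

import logging
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

__all__ = [
    "normalize_clip",
    "detect_reproducible",
    "fit_clip_trap_model",
    "mean_clip_score",
    "call_dendritic_targets",
    "clip_score_table",
    "set_summary",
    "percent_round",
]

TAGS_PER = 10_000
REPRODUCIBLE_MIN_TAGS = 5.0   # normalized tags per 10,000, strict >
REPRODUCIBLE_K = 3
REPRODUCIBLE_N = 5
SCORE_CUTOFF = 1.0            # mean CLIP score, strict >
MIN_FIT_GENES = 10
FIT_TPM_MIN = 1.0
FIT_MIN_REPLICATES = 3


def normalize_clip(clip: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Length- and depth-normalized CLIP expression per gene and replicate.

    Adds ``E`` = (tags / length in kb) x (10^4 / library total) and
    ``tags_per_10k`` = tags x 10^4 / library total (no length term).
    Replicates with a zero library total are excluded and logged.
    """
    df = clip.copy()
    df["length_kb"] = lengths.reindex(df["gene"]).to_numpy() / 1000.0
    if df["length_kb"].isna().any():
        missing = df.loc[df["length_kb"].isna(), "gene"].unique()[:5]
        raise ValueError(f"missing transcript length for genes like {list(missing)}")
    totals = df.groupby(["compartment", "replicate"])["tags"].transform("sum")
    zero = totals == 0
    if zero.any():
        for comp, rep in df.loc[zero, ["compartment", "replicate"]].drop_duplicates().itertuples(index=False):
            log.warning("replicate %s/%s has zero library total; excluded", comp, rep)
        df = df.loc[~zero]
        totals = totals.loc[~zero]
    df["tags_per_10k"] = df["tags"] * TAGS_PER / totals
    df["E"] = (df["tags"] / df["length_kb"]) * TAGS_PER / totals
    return df.drop(columns="length_kb")


def detect_reproducible(norm: pd.DataFrame, compartment: str = "NP",
                        min_tags: float = REPRODUCIBLE_MIN_TAGS,
                        k: int = REPRODUCIBLE_K,
                        n: int = REPRODUCIBLE_N) -> pd.Series:
    """Rule A: > ``min_tags`` normalized tags per 10,000 (strict) in at
    least ``k`` of ``n`` replicates of the given compartment."""
    sub = norm.loc[norm["compartment"] == compartment]
    n_reps = sub["replicate"].nunique()
    if n_reps < k:
        raise ValueError(f"only {n_reps} replicates available; rule needs k={k}")
    if n_reps != n:
        log.warning("rule configured for %d replicates but %d present", n, n_reps)
    hits = (sub.assign(hit=sub["tags_per_10k"] > min_tags)
            .groupby("gene")["hit"].sum())
    return (hits >= k).rename("reproducible")


def fit_clip_trap_model(norm: pd.DataFrame, tpm: pd.Series, compartment: str,
                        replicate: int,
                        tpm_min: float = FIT_TPM_MIN,
                        min_replicates: int = FIT_MIN_REPLICATES,
                        min_fit_genes: int = MIN_FIT_GENES):
    """Per-replicate OLS of log10(E) on log10(TPM) and residual scores.

    The fit universe is genes with TPM > ``tpm_min`` and CLIP tags in at
    least ``min_replicates`` replicates of the compartment. Genes outside
    the universe still get a score when E > 0, using the fitted line.
    Returns (scores: Series, slope, intercept).
    """
    comp = norm.loc[norm["compartment"] == compartment]
    detected = (comp.loc[comp["tags"] > 0].groupby("gene")["replicate"].nunique()
                >= min_replicates)
    sub = comp.loc[comp["replicate"] == replicate].set_index("gene")
    t = tpm.reindex(sub.index)
    in_universe = (t > tpm_min) & detected.reindex(sub.index, fill_value=False) & (sub["E"] > 0)
    if int(in_universe.sum()) < min_fit_genes:
        raise ValueError(
            f"only {int(in_universe.sum())} genes in fit universe (< {min_fit_genes})")
    x = np.log10(t[in_universe].to_numpy(dtype=float))
    y = np.log10(sub.loc[in_universe, "E"].to_numpy(dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    scorable = (sub["E"] > 0) & (t > 0)
    scores = pd.Series(np.nan, index=sub.index, name="score")
    xs = np.log10(t[scorable].to_numpy(dtype=float))
    scores[scorable] = (np.log10(sub.loc[scorable, "E"].to_numpy(dtype=float))
                        - (slope * xs + intercept))
    return scores, float(slope), float(intercept)


def mean_clip_score(scores_by_rep: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean over replicates with defined scores, plus the count
    of contributing replicates. All-NA genes get NA."""
    return pd.DataFrame({
        "mean_score": scores_by_rep.mean(axis=1, skipna=True),
        "n_replicates": scores_by_rep.notna().sum(axis=1),
    })


def clip_score_table(clip: pd.DataFrame, tpm: pd.DataFrame, lengths: pd.Series,
                     **fit_kw) -> pd.DataFrame:
    """Per-gene score table for both compartments.

    Returns a frame indexed by gene with mean CLIP score and replicate
    count per compartment, the rule-A reproducibility flag (neuropil), and
    the dendritic-target call.
    """
    norm = normalize_clip(clip, lengths)
    out = {}
    for comp in norm["compartment"].unique():
        reps = sorted(norm.loc[norm["compartment"] == comp, "replicate"].unique())
        cols = {}
        for r in reps:
            scores, *_ = fit_clip_trap_model(norm, tpm[comp], comp, r, **fit_kw)
            cols[r] = scores
        m = mean_clip_score(pd.DataFrame(cols))
        out[f"mean_score_{comp}"] = m["mean_score"]
        out[f"n_replicates_{comp}"] = m["n_replicates"]
    table = pd.DataFrame(out)
    n_np = norm.loc[norm["compartment"] == "NP", "replicate"].nunique()
    repro = detect_reproducible(norm, "NP", n=max(n_np, REPRODUCIBLE_K))
    table["reproducible"] = repro.reindex(table.index, fill_value=False)
    table["score_gt1"] = table.get("mean_score_NP", pd.Series(np.nan, index=table.index)) > SCORE_CUTOFF
    table["dendritic_target"] = table["reproducible"] | table["score_gt1"]
    return table


def call_dendritic_targets(reproducible: pd.Series, mean_np_score: pd.Series,
                           score_cutoff: float = SCORE_CUTOFF) -> pd.DataFrame:
    """Two-rule dendritic target call: rule A (reproducible neuropil
    detection) OR rule B (mean neuropil CLIP score > ``score_cutoff``,
    strict). Reports per-rule provenance."""
    idx = reproducible.index.union(mean_np_score.index)
    a = reproducible.reindex(idx).fillna(False).astype(bool)
    b = (mean_np_score.reindex(idx) > score_cutoff).fillna(False)
    return pd.DataFrame({"rule_A": a, "rule_B": b, "dendritic_target": a | b})


def percent_round(num: float, den: float, decimals: int = 1) -> float:
    """Percent num/den rounded half-up to ``decimals`` places."""
    if den == 0:
        return float("nan")
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(100.0 * num / den).quantize(q, rounding=ROUND_HALF_UP))


def set_summary(sets: dict[str, set], universe: set | None = None) -> pd.DataFrame:
    """Pairwise overlap counts and rounded percentages between named gene
    sets, with a chi-squared enrichment test against the universe
    proportion when a universe is given."""
    names = list(sets)
    rows = []
    for a in names:
        for b in names:
            if a == b:
                continue
            A, B = sets[a], sets[b]
            inter = len(A & B)
            pct = percent_round(inter, len(A)) if len(A) else float("nan")
            row = {"set_a": a, "set_b": b, "n_a": len(A), "n_b": len(B),
                   "n_overlap": inter, "pct_of_a": pct}
            if universe is not None and len(A) and len(B):
                in_b = len(B & universe)
                table = np.array([[inter, len(A) - inter],
                                  [in_b - inter, len(universe) - len(A) - in_b + inter]])
                if (table >= 0).all() and table.sum() > 0:
                    chi2, p = sps.chi2_contingency(np.maximum(table, 0))[:2]
                    row["chi2"], row["chi2_p"] = float(chi2), float(p)
            rows.append(row)
    return pd.DataFrame(rows)
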