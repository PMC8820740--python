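"""Discovery of expressed 3'UTR isoforms from polyA-site peaks and splice
junctions.

The pipeline: filter polyA-site peaks (whole-cell tag/fraction rule or
compartment replicate-support rule), filter splice junctions (read count OR
gene-fraction rule), pair each kept polyA site with the acceptor of its
nearest upstream kept junction to form candidate final exons, require
near-complete base coverage in at least one experiment, remove candidates
overlapping other genes or UTRs, and classify the surviving multi-isoform
genes into tandem (3'UTR-APA) and CDS-truncating (UR-APA) events.

All genomic intervals are 0-based half-open; a polyA "position" is the
right edge of the last transcribed base on the plus strand and the left
edge on the minus strand.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

__all__ = [
    "filter_polya_sites",
    "filter_junctions",
    "pair_boundaries",
    "coverage_filter",
    "remove_ambiguous",
    "classify_apa",
    "discover_utrs",
]

MIN_TAGS = 10
MIN_TAG_FRACTION = 0.05
MIN_JUNCTION_READS = 10
MIN_JUNCTION_FRACTION = 0.10
MIN_COVERED_FRACTION = 0.80
MIN_REPLICATE_SUPPORT = 2


def filter_polya_sites(sites: pd.DataFrame, source: str,
                       min_tags: int = MIN_TAGS,
                       min_fraction: float = MIN_TAG_FRACTION,
                       min_replicates: int = MIN_REPLICATE_SUPPORT) -> pd.DataFrame:
    """Filter polyA-site peaks.

    Whole-cell peaks are kept iff they carry ``min_tags`` or more tags AND
    represent ``min_fraction`` or more of the gene's tags. Compartment
    peaks are kept iff they have tags in at least ``min_replicates``
    replicates. Output has one row per site, sorted by gene then position.
    """
    if source not in ("whole-cell", "compartment"):
        raise ValueError(f"unknown polyA source {source!r}")
    df = sites.copy()
    if (df["tags"] < 0).any():
        raise ValueError("negative tag counts")
    if source == "whole-cell":
        totals = df.groupby("gene")["tags"].transform("sum")
        frac = np.where(totals > 0, df["tags"] / totals, 0.0)
        keep = (df["tags"] >= min_tags) & (frac >= min_fraction)
        out = df.loc[keep].copy()
        out["fraction"] = frac[keep.to_numpy()]
    else:
        support = (df.loc[df["tags"] > 0]
                   .groupby(["gene", "position"])["replicate"].nunique())
        agg = (df.groupby(["gene", "strand", "position"], as_index=False)["tags"].sum())
        key = list(zip(agg["gene"], agg["position"]))
        agg["replicate_support"] = [int(support.get(k, 0)) for k in key]
        out = agg.loc[agg["replicate_support"] >= min_replicates].copy()
        totals = out.groupby("gene")["tags"].transform("sum")
        out["fraction"] = np.where(totals > 0, out["tags"] / totals, 0.0)
    out["source"] = source
    return out.sort_values(["gene", "position"], kind="mergesort").reset_index(drop=True)


def filter_junctions(junctions: pd.DataFrame,
                     min_reads: int = MIN_JUNCTION_READS,
                     min_fraction: float = MIN_JUNCTION_FRACTION) -> pd.DataFrame:
    """Keep junctions found in ``min_reads`` reads OR representing
    ``min_fraction`` of the gene's total junction reads (the denominator
    counts all junctions of the gene)."""
    df = junctions.copy()
    if (df["reads"] < 0).any():
        raise ValueError("negative junction read counts")
    totals = df.groupby("gene")["reads"].transform("sum")
    frac = np.where(totals > 0, df["reads"] / totals, 0.0)
    keep = (df["reads"] >= min_reads) | (frac >= min_fraction)
    out = df.loc[keep].copy()
    out["fraction"] = frac[keep.to_numpy()]
    return out.sort_values(["gene", "donor"], kind="mergesort").reset_index(drop=True)


def _stop_exon_start(model) -> int:
    """Transcript-order start of the stop-codon-containing exon."""
    for a, b in model.exons:
        if a <= model.stop_codon < b or model.stop_codon == b:
            return a if model.strand == "+" else b
    # stop codon annotated at an exon edge on the minus strand
    for a, b in model.exons:
        if a <= model.stop_codon <= b:
            return a if model.strand == "+" else b
    raise ValueError(f"stop codon outside exons for {model.gene_id}")


def pair_boundaries(sites: pd.DataFrame, junctions: pd.DataFrame,
                    models: dict | list) -> pd.DataFrame:
    """Pair each kept polyA site with the acceptor of the nearest upstream
    kept junction to define a candidate 3'UTR (final exon).

    Strand-aware: "upstream" is toward the 5' end of the transcript. When
    no kept junction lies upstream of the site, the 5' boundary falls back
    to the annotated start of the stop-codon-containing exon (covers
    single-exon 3'UTRs). Ties between equidistant acceptors are broken by
    read count, then by the 5'-most acceptor. Genes without a model are
    skipped and logged.
    """
    if not isinstance(models, dict):
        models = {m.gene_id: m for m in models}
    rows = []
    jby = dict(tuple(junctions.groupby("gene"))) if len(junctions) else {}
    for gene, gsites in sites.groupby("gene"):
        m = models.get(gene)
        if m is None:
            log.warning("no gene model for %s; skipped", gene)
            continue
        plus = m.strand == "+"
        gj = jby.get(gene)
        accs = gj["acceptor"].to_numpy() if gj is not None else np.array([])
        reads = gj["reads"].to_numpy() if gj is not None else np.array([])
        for _, srow in gsites.iterrows():
            p = int(srow["position"])
            if plus:
                ok = accs < p
            else:
                ok = accs > p
            five = None
            if ok.any():
                cand_a, cand_r = accs[ok], reads[ok]
                dist = (p - cand_a) if plus else (cand_a - p)
                best = dist == dist.min()
                if best.sum() > 1:  # tie: more reads, then 5'-most
                    rmax = cand_r[best].max()
                    best &= cand_r == rmax
                    tied = cand_a[best]
                    five = int(tied.min() if plus else tied.max())
                else:
                    five = int(cand_a[best][0])
            else:
                five = int(_stop_exon_start(m))
                if (plus and five >= p) or (not plus and five <= p):
                    log.warning("degenerate boundary for %s at %d; skipped", gene, p)
                    continue
            start, end = (five, p) if plus else (p, five)
            rows.append({"gene": gene, "strand": m.strand,
                         "utr_start": int(start), "utr_end": int(end),
                         "polya_position": p, "tags": srow.get("tags", np.nan)})
    out = pd.DataFrame(rows, columns=["gene", "strand", "utr_start", "utr_end",
                                      "polya_position", "tags"])
    return out.drop_duplicates(["gene", "utr_start", "utr_end"]).reset_index(drop=True)


def coverage_filter(utrs: pd.DataFrame, coverage: dict,
                    min_covered: float = MIN_COVERED_FRACTION) -> pd.DataFrame:
    """Keep candidate UTRs with >= ``min_covered`` covered-base fraction in
    at least one experiment (inclusive comparison).

    ``coverage`` maps experiment -> gene -> (offset, per-base array of
    covered indicators over the gene span).
    """
    frac_cols = {}
    keep = np.zeros(len(utrs), dtype=bool)
    best = np.zeros(len(utrs))
    for exp, genecov in coverage.items():
        fracs = np.full(len(utrs), np.nan)
        for i, row in enumerate(utrs.itertuples(index=False)):
            entry = genecov.get(row.gene)
            if entry is None:
                continue
            offset, arr = entry
            s, e = row.utr_start - offset, row.utr_end - offset
            if s < 0 or e > len(arr):
                raise ValueError(
                    f"coverage array for {row.gene} shorter than UTR [{row.utr_start},{row.utr_end})")
            fracs[i] = float(np.mean(arr[s:e] > 0))
        frac_cols[exp] = fracs
        with np.errstate(invalid="ignore"):
            keep |= fracs >= min_covered
        best = np.fmax(best, np.nan_to_num(fracs))
    out = utrs.loc[keep].copy()
    out["max_covered_fraction"] = best[keep]
    return out.reset_index(drop=True)


def remove_ambiguous(utrs: pd.DataFrame, models: dict | list,
                     same_strand_only: bool = True) -> pd.DataFrame:
    """Drop UTRs overlapping another gene's span or another gene's UTR, and
    all UTRs of "ambiguous" genes (genes whose annotated span overlaps
    another gene, by default on the same strand)."""
    if not isinstance(models, dict):
        models = {m.gene_id: m for m in models}
    tree = IntervalTree()
    for m in models.values():
        tree.addi(m.start, m.end, m)
    ambiguous = set()
    for m in models.values():
        for hit in tree.overlap(m.start, m.end):
            other = hit.data
            if other.gene_id != m.gene_id and (
                    not same_strand_only or other.strand == m.strand):
                ambiguous.add(m.gene_id)
    utr_tree = IntervalTree()
    for i, row in enumerate(utrs.itertuples(index=False)):
        utr_tree.addi(row.utr_start, row.utr_end, (i, row.gene))
    keep = []
    for i, row in enumerate(utrs.itertuples(index=False)):
        if row.gene in ambiguous:
            keep.append(False)
            continue
        bad = any(h.data.gene_id != row.gene
                  for h in tree.overlap(row.utr_start, row.utr_end))
        bad = bad or any(g != row.gene
                         for h in utr_tree.overlap(row.utr_start, row.utr_end)
                         for (_, g) in [h.data])
        keep.append(not bad)
    return utrs.loc[keep].reset_index(drop=True)


def classify_apa(utrs: pd.DataFrame, models: dict | list) -> pd.DataFrame:
    """Classify APA events for genes with >= 2 retained UTR isoforms.

    Sites in the terminal 3'UTR (downstream of the annotated stop codon)
    form tandem 3'UTR-APA events; sites upstream of the stop codon are
    UR-APA and flagged CDS-altering; genes with both kinds get type
    ``both``. Among terminal sites, the most stop-proximal is ``proximal``,
    the most distal ``distal``, and the rest ``internal``.
    """
    if not isinstance(models, dict):
        models = {m.gene_id: m for m in models}
    rows = []
    for gene, g in utrs.groupby("gene"):
        if len(g) < 2:
            continue
        m = models[gene]
        plus = m.strand == "+"
        pa = g["polya_position"].to_numpy()
        downstream = (pa > m.stop_codon) if plus else (pa < m.stop_codon)
        n_term = int(downstream.sum())
        has_tandem = n_term >= 2
        has_ur = int((~downstream).sum()) >= 1
        if has_tandem and has_ur:
            gtype = "both"
        elif has_ur:
            gtype = "UR-APA"
        else:
            gtype = "3'UTR-APA"
        dist = np.abs(pa - m.stop_codon).astype(float)
        dist[~downstream] = np.nan
        order = np.argsort(dist)
        classes = np.array([None] * len(g), dtype=object)
        if n_term >= 1:
            term_idx = order[:n_term]
            classes[term_idx] = "internal"
            classes[term_idx[0]] = "proximal"
            classes[term_idx[-1]] = "distal"
            if n_term == 1:
                classes[term_idx[0]] = "distal"
        for j, (_, row) in enumerate(g.iterrows()):
            rows.append({
                "gene": gene, "utr_start": row["utr_start"],
                "utr_end": row["utr_end"],
                "site_kind": "terminal" if downstream[j] else "upstream",
                "position_class": classes[j], "apa_type": gtype,
                "cds_altering": gtype in ("UR-APA", "both"),
            })
    return pd.DataFrame(rows, columns=["gene", "utr_start", "utr_end", "site_kind",
                                       "position_class", "apa_type", "cds_altering"])


def discover_utrs(polya_wholecell: pd.DataFrame,
                  polya_compartment: pd.DataFrame | None,
                  junctions: pd.DataFrame,
                  models: dict | list,
                  coverage: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full discovery pipeline; returns (retained UTRs, APA events).

    Junction tables with a per-sample ``sample`` column are aggregated over
    samples before filtering.
    """
    kept_sites = [filter_polya_sites(polya_wholecell, "whole-cell")]
    if polya_compartment is not None and len(polya_compartment):
        kept_sites.append(filter_polya_sites(polya_compartment, "compartment"))
    sites = (pd.concat(kept_sites, ignore_index=True)
             .drop_duplicates(["gene", "position"]))
    if "sample" in junctions.columns:
        junctions = (junctions.groupby(["gene", "donor", "acceptor"], as_index=False)
                     ["reads"].sum())
    juncs = filter_junctions(junctions)
    utrs = pair_boundaries(sites, juncs, models)
    utrs = coverage_filter(utrs, coverage)
    utrs = remove_ambiguous(utrs, models)
    events = classify_apa(utrs, models)
    return utrs, events
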