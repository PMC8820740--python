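"""Readers and writers for the standard interchange formats.

GTF parsing goes through gffutils; FASTA through Biopython; BED/TSV/CSV
tables through pandas. Gene sets use the GMT convention (set name,
description, then member genes, tab-separated).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GeneModel

__all__ = [
    "write_gtf", "read_gtf_models",
    "write_polya_bed", "read_polya_bed",
    "write_utr_bed12",
    "read_gmt", "write_gmt",
    "write_bedgraph", "read_bedgraph",
    "read_fasta", "write_fasta",
    "write_json", "read_json",
]


def write_gtf(models: list[GeneModel], path) -> None:
    """Write gene models as GTF (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.gene_id}.t1";'
            fh.write("\t".join([m.chrom, "ca1kit", "gene", str(m.start + 1),
                                str(m.end), ".", m.strand, ".", attrs]) + "\n")
            for a, b in m.exons:
                fh.write("\t".join([m.chrom, "ca1kit", "exon", str(a + 1),
                                    str(b), ".", m.strand, ".", attrs]) + "\n")
            fh.write("\t".join([m.chrom, "ca1kit", "stop_codon",
                                str(m.stop_codon + 1), str(m.stop_codon + 3),
                                ".", m.strand, ".", attrs]) + "\n")
            for p in m.polya_positions:
                fh.write("\t".join([m.chrom, "ca1kit", "polyA_site",
                                    str(p + 1), str(p + 1), ".", m.strand, ".",
                                    attrs]) + "\n")


def read_gtf_models(path) -> list[GeneModel]:
    """Read gene models written by :func:`write_gtf` back into memory
    (0-based half-open)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique",
                            disable_infer_genes=True,
                            disable_infer_transcripts=True)
    genes: dict[str, dict] = {}
    for feat in db.all_features():
        gid = feat.attributes["gene_id"][0]
        g = genes.setdefault(gid, {"exons": [], "polya": [], "stop": None,
                                   "chrom": feat.seqid, "strand": feat.strand,
                                   "start": None, "end": None})
        if feat.featuretype == "gene":
            g["start"], g["end"] = feat.start - 1, feat.end
        elif feat.featuretype == "exon":
            g["exons"].append((feat.start - 1, feat.end))
        elif feat.featuretype == "stop_codon":
            g["stop"] = feat.start - 1
        elif feat.featuretype == "polyA_site":
            g["polya"].append(feat.start - 1)
    out = []
    for gid, g in genes.items():
        out.append(GeneModel(gene_id=gid, chrom=g["chrom"], strand=g["strand"],
                             start=g["start"], end=g["end"],
                             exons=sorted(g["exons"]), stop_codon=g["stop"],
                             polya_positions=sorted(g["polya"])))
    return out


def write_polya_bed(sites: pd.DataFrame, path, chrom: str = "chrS") -> None:
    """polyA sites as BED6 with score = tag count."""
    df = pd.DataFrame({
        "chrom": chrom,
        "start": sites["position"],
        "end": sites["position"] + 1,
        "name": sites["gene"],
        "score": sites["tags"],
        "strand": sites["strand"],
    })
    df.to_csv(path, sep="\t", header=False, index=False)


def read_polya_bed(path, source: str = "whole-cell") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score", "strand"])
    return pd.DataFrame({"gene": df["name"], "strand": df["strand"],
                         "position": df["start"], "tags": df["score"],
                         "source": source})


def write_utr_bed12(utrs: pd.DataFrame, path, chrom: str = "chrS") -> None:
    rows = []
    for r in utrs.itertuples(index=False):
        size = r.utr_end - r.utr_start
        rows.append([chrom, r.utr_start, r.utr_end, f"{r.gene}_UTR",
                     0, r.strand, r.utr_start, r.utr_end, "0,0,0",
                     1, size, 0])
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_gmt(path) -> dict[str, set]:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: dict[str, set], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_bedgraph(coverage: dict, path, chrom: str = "chrS") -> None:
    """Per-base coverage of one experiment as bedGraph (runs of equal
    value); ``coverage`` maps gene -> (offset, per-base array)."""
    with open(path, "w") as fh:
        for gene in sorted(coverage):
            offset, arr = coverage[gene]
            arr = np.asarray(arr)
            edges = np.r_[0, np.nonzero(np.diff(arr))[0] + 1, len(arr)]
            for a, b in zip(edges[:-1], edges[1:]):
                fh.write(f"{chrom}\t{offset + a}\t{offset + b}\t{arr[a]:g}\n")


def read_bedgraph(path, models: list) -> dict:
    """Read a bedGraph back into gene -> (offset, per-base array) using the
    gene spans of ``models`` to assign intervals."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"])
    out = {m.gene_id: (m.start, np.zeros(m.end - m.start, dtype=np.float32))
           for m in models}
    spans = [(m.start, m.end, m.gene_id) for m in models]
    for r in df.itertuples(index=False):
        for s, e, gid in spans:
            if r.start >= s and r.end <= e:
                off, arr = out[gid]
                arr[r.start - off:r.end - off] = r.value
                break
    return out


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
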