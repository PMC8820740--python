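"""End-to-end orchestration: synthetic data -> UTR discovery ->
localization -> CLIP scores -> splicing/FISH/motif summaries -> report.

Every threshold used anywhere in the pipeline is a named key of
:class:`RunConfig` defaulting to the published value; the run manifest
echoes all of them together with the seed and output checksums, so a rerun
with the same manifest reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import clip as clipmod
from . import diffexp, fish, io, motif, simulate, splicing, utr

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "make_report"]

STAGES = ("simulate", "discover", "localize", "score", "fish", "motif")


@dataclass
class RunConfig:
    """Pipeline configuration. Unknown keys are rejected on load."""

    out_dir: str = "ca1kit_run"
    seed: int = 0
    stages: tuple = STAGES
    sim: dict = field(default_factory=dict)   # SimConfig overrides
    # published thresholds, all overridable
    polya_min_tags: int = utr.MIN_TAGS
    polya_min_fraction: float = utr.MIN_TAG_FRACTION
    junction_min_reads: int = utr.MIN_JUNCTION_READS
    junction_min_fraction: float = utr.MIN_JUNCTION_FRACTION
    min_covered_fraction: float = utr.MIN_COVERED_FRACTION
    fdr_cutoff: float = diffexp.FDR_CUTOFF
    dpsi_cutoff: float = splicing.DPSI_CUTOFF
    clip_min_tags_per_10k: float = clipmod.REPRODUCIBLE_MIN_TAGS
    clip_k_of_n: tuple = (clipmod.REPRODUCIBLE_K, clipmod.REPRODUCIBLE_N)
    clip_score_cutoff: float = clipmod.SCORE_CUTOFF
    neuropil_distance_um: float = fish.NEUROPIL_DISTANCE_UM
    fish_n_slices: int = fish.N_SLICES
    fish_poly_degree: int = fish.POLY_DEGREE
    fish_n_bins: int = 15
    fish_n_sample: int = 1000

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in d:
            d = {**d, "stages": tuple(d["stages"])}
        return cls(**d)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in dependency order and write outputs
    plus a manifest into ``cfg.out_dir``. Returns the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": cfg.seed, "stages": list(cfg.stages),
                "thresholds": {k: v for k, v in asdict(cfg).items()
                               if k not in ("sim", "stages", "out_dir")},
                "outputs": {}}
    sim_cfg = simulate.SimConfig(seed=cfg.seed, **cfg.sim)
    manifest["sim_config"] = sim_cfg.to_dict()

    data = None
    try:
        if "simulate" in cfg.stages:
            models, genes, isoforms = simulate.gen_gene_models(sim_cfg)
            data = simulate.gen_count_data(models, genes, isoforms, sim_cfg)
            data.clip = simulate.gen_clip_replicates(genes, data.tpm, sim_cfg)
            io.write_gtf(models, out / "models.gtf")
            data.counts.to_csv(out / "counts.tsv", sep="\t")
            data.samples.to_csv(out / "samples.tsv", sep="\t")
            data.tpm.to_csv(out / "tpm.tsv", sep="\t")
            data.junctions.to_csv(out / "junctions.tsv", sep="\t", index=False)
            io.write_polya_bed(data.polya_wholecell, out / "polya_wholecell.bed")
            data.clip.to_csv(out / "clip_tags.tsv", sep="\t", index=False)
            io.write_json({"genes": data.genes.reset_index().to_dict("records")},
                          out / "truth.json")

        if "discover" in cfg.stages:
            if data is None:
                raise FileNotFoundError(
                    "discover stage needs inputs: enable the simulate stage "
                    "or provide them")
            utrs, events = utr.discover_utrs(
                data.polya_wholecell, data.polya_compartment,
                data.junctions, data.models, data.coverage)
            io.write_utr_bed12(utrs, out / "utrs.bed12")
            events.to_csv(out / "apa_events.tsv", sep="\t", index=False)
            manifest["n_utrs"], manifest["n_apa_genes"] = (
                len(utrs), int(events["gene"].nunique()) if len(events) else 0)

        if "localize" in cfg.stages:
            if data is None:
                raise FileNotFoundError("localize stage needs simulated counts")
            s = data.samples
            wt = s[s.genotype == "WT"]
            np_sel = wt[(wt.compartment == "NP") & (wt.cre == "+")]
            d1 = diffexp.nb_wald_test(data.counts[np_sel.index], np_sel,
                                      ("assay", "TRAP", "RNA"))
            cre_sel = wt[(wt.assay == "TRAP") & (wt.compartment == "NP")]
            d2 = diffexp.nb_wald_test(data.counts[cre_sel.index], cre_sel,
                                      ("cre", "+", "-"))
            comp_sel = wt[(wt.assay == "TRAP") & (wt.cre == "+")]
            d3 = diffexp.nb_wald_test(data.counts[comp_sel.index], comp_sel,
                                      ("compartment", "NP", "CB"))
            calls = diffexp.call_localization(d1, d2, d3, fdr=cfg.fdr_cutoff)
            pd.concat([d1.add_prefix("trap_vs_rna_"),
                       d2.add_prefix("cre_"),
                       d3.add_prefix("np_vs_cb_"),
                       calls], axis=1).to_csv(out / "localization.tsv", sep="\t")
            manifest["n_dendrite_present"] = int((calls != "neither").sum())
            manifest["n_dendrite_enriched"] = int((calls == "dendrite-enriched").sum())

        if "score" in cfg.stages:
            if data is None or data.clip is None:
                raise FileNotFoundError("score stage needs CLIP tag tables")
            table = clipmod.clip_score_table(data.clip, data.tpm, data.lengths)
            table.to_csv(out / "clip_scores.tsv", sep="\t")
            manifest["n_dendritic_targets"] = int(table["dendritic_target"].sum())
            manifest["n_rule_A"] = int(table["reproducible"].sum())
            manifest["n_rule_B"] = int(table["score_gt1"].fillna(False).sum())

        if "fish" in cfg.stages:
            field_ = simulate.gen_fish_field(sim_cfg)
            curve = fish.estimate_boundary(field_.nuclei_um,
                                           n_slices=cfg.fish_n_slices,
                                           degree=cfg.fish_poly_degree,
                                           neuropil_above=field_.neuropil_above)
            dists = fish.spot_distances(field_.spots, curve)
            called, frac = fish.classify_spots(dists, cfg.neuropil_distance_um)
            called.to_csv(out / "fish_spots.csv", index=False)
            manifest["fish_neuropil_fraction"] = frac

        if "motif" in cfg.stages:
            rng = np.random.default_rng([cfg.seed, 99])
            seqs = {f"G{i:05d}": "".join(rng.choice(list("ACGU"), size=300))
                    for i in range(sim_cfg.n_genes)}
            flags = pd.Series({g: bool(motif.find_g4_motifs(s, g))
                               for g, s in seqs.items()})
            flags.rename("has_g4").to_csv(out / "g4_flags.tsv", sep="\t")
            manifest["n_g4_genes"] = int(flags.sum())
    except Exception as exc:  # halt with stage context; keep partial outputs
        manifest["failed"] = f"{type(exc).__name__}: {exc}"
        io.write_json(manifest, out / "manifest.json")
        raise

    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["outputs"][p.name] = _checksum(p)
    io.write_json(manifest, out / "manifest.json")
    return manifest


def make_report(manifest: dict) -> str:
    """Human-readable run summary from a manifest."""
    lines = ["ca1kit run report", "=" * 17, f"seed: {manifest.get('seed')}"]
    for key in ("n_utrs", "n_apa_genes", "n_dendrite_present",
                "n_dendrite_enriched", "n_dendritic_targets", "n_rule_A",
                "n_rule_B", "fish_neuropil_fraction", "n_g4_genes"):
        if key in manifest:
            v = manifest[key]
            lines.append(f"{key}: {v:.4f}" if isinstance(v, float) else f"{key}: {v}")
    if "n_rule_A" in manifest and "n_dendritic_targets" in manifest:
        a, b, u = manifest["n_rule_A"], manifest["n_rule_B"], manifest["n_dendritic_targets"]
        lines.append(f"rule overlap (A + B - union): {a + b - u}")
    return "\n".join(lines) + "\n"
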