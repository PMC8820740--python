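"""Synthetic data with known ground truth for the whole pipeline.

Emulates the data layers of a compartment-specific CA1 transcriptomics
study: gene models with alternative 3'UTR isoforms (tandem and intronic
polyA sites), overdispersed TRAP/RNA-seq count replicates per compartment
and genotype, polyA-site tag tables (PAPERCLIP-like), splice-junction read
tables mixed by isoform usage, CLIP tag counts correlated with abundance
plus spiked binding, and 2-D FISH spot fields above a curved cell-body
layer.

Every generator is a pure function of a :class:`SimConfig`; the seed fully
determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GeneModel",
    "SimData",
    "FishField",
    "gen_gene_models",
    "gen_count_data",
    "gen_clip_replicates",
    "gen_fish_field",
]

# library-size asymmetry observed between cell-body and neuropil CLIP
# libraries (746,827 vs 80,749 tags)
NEUROPIL_CB_CLIP_RATIO = 80749 / 746827


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the real experimental design: 4 TRAP replicates,
    5 CLIP replicates, 2 compartments (CB = cell bodies, NP = neuropil),
    2 genotypes, and a neuropil CLIP library roughly 10x smaller than the
    cell-body one.
    """

    n_genes: int = 200
    frac_multi_utr: float = 0.4
    frac_ur_apa: float = 0.25       # of multi-UTR genes: intronic-polyA only
    frac_both_apa: float = 0.10     # of multi-UTR genes: tandem + intronic
    frac_dendritic: float = 0.2
    frac_fmrp_bound: float = 0.1
    frac_localized_isoform: float = 0.5   # of multi-UTR genes
    n_trap_replicates: int = 4
    n_rna_replicates: int = 4
    n_clip_replicates: int = 5
    n_paperclip_replicates: int = 4
    include_ko: bool = False
    library_size_mean: float = 1.0        # relative depth multiplier
    nb_dispersion: float = 0.05
    expression_median: float = 100.0
    expression_sigma: float = 0.8         # log-normal sd of per-gene expression
    expression_floor: float = 30.0
    localization_lfc: float = 2.0         # log2, true dendritic enrichment
    usage_prox_cb: float = 0.7            # proximal-isoform usage in cell bodies
    usage_prox_np_localized: float = 0.3  # ... in neuropil for localized-isoform genes
    junction_rate: float = 0.3            # junction reads per gene count unit
    paperclip_scale: float = 5.0          # whole-cell tags per expression unit
    paperclip_np_scale: float = 1.0
    clip_enrichment_log10: float = 1.0
    clip_slope: float = 1.0
    clip_replicate_noise_sd: float = 0.15  # log10 log-normal replicate noise
    clip_cb_library: int = 150_000
    clip_np_cb_ratio: float = NEUROPIL_CB_CLIP_RATIO
    clip_bound_mode: Literal["top_tpm", "random"] = "top_tpm"
    # FISH field --------------------------------------------------------
    fish_boundary_coeffs: tuple = (40.0, 0.3, -0.004, 1.5e-5)  # µm, c0..c3
    fish_width_um: float = 135.0
    fish_height_um: float = 135.0
    um_per_px: float = 0.14
    fish_n_nuclei_px: int = 6000
    fish_layer_depth_um: float = 25.0
    fish_n_spots: int = 2000
    fish_neuropil_weight: float = 0.4
    fish_decay_um: float = 30.0
    spot_noise_sd: float = 0.5            # µm, added to spot coordinates
    neuropil_above: bool = True
    seed: int = 0

    def validate(self) -> None:
        counts = [self.n_genes, self.n_trap_replicates, self.n_rna_replicates,
                  self.n_clip_replicates, self.n_paperclip_replicates,
                  self.fish_n_nuclei_px, self.fish_n_spots]
        if any(c <= 0 for c in counts):
            raise ValueError("all counts in SimConfig must be > 0")
        for name in ("frac_multi_utr", "frac_ur_apa", "frac_both_apa",
                     "frac_dendritic", "frac_fmrp_bound",
                     "frac_localized_isoform", "fish_neuropil_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GeneModel:
    """A gene in 0-based half-open genomic coordinates."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list          # list of (start, end), genomic order
    stop_codon: int      # genomic coordinate of the translation stop
    polya_positions: list  # cleavage points (right edge on +, left edge on -)

    @property
    def final_exon(self):
        return self.exons[-1] if self.strand == "+" else self.exons[0]


@dataclass
class SimData:
    """Bundle of all synthetic inputs plus the ground truth."""

    config: SimConfig
    models: list
    genes: pd.DataFrame        # per-gene truth labels and expression propensity
    isoforms: pd.DataFrame     # per-isoform structure, kind and true usage
    counts: pd.DataFrame | None = None
    samples: pd.DataFrame | None = None
    tpm: pd.DataFrame | None = None
    lengths: pd.Series | None = None
    junctions: pd.DataFrame | None = None
    polya_wholecell: pd.DataFrame | None = None
    polya_compartment: pd.DataFrame | None = None
    coverage: dict | None = None
    clip: pd.DataFrame | None = None


@dataclass
class FishField:
    """One synthetic smFISH image: nuclei pixels, spots and the true layer."""

    spots: pd.DataFrame          # x_um, y_um, z_um, channel + truth columns
    nuclei_um: np.ndarray        # (n, 2) nuclei pixel centers in µm
    boundary_coeffs: np.ndarray  # true polynomial, ascending powers, µm
    um_per_px: float
    width_um: float
    height_um: float
    neuropil_above: bool


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), stage])


# ---------------------------------------------------------------------------
# gene models


def gen_gene_models(cfg: SimConfig):
    """Generate gene models and the per-isoform truth table.

    Genes are laid head-to-tail on one synthetic chromosome with gaps, half
    on each strand. Each gene has three coding exons and a final exon; a
    configured fraction carries a second tandem polyA site in the terminal
    3'UTR (3'UTR-APA), an intronic polyA site (UR-APA, CDS-truncating), or
    both.

    Returns ``(models, genes_truth, isoforms_truth)``.
    """
    cfg.validate()
    rng = _rng(cfg, 1)
    n = cfg.n_genes

    theta = cfg.expression_floor + rng.lognormal(
        np.log(cfg.expression_median), cfg.expression_sigma, size=n)
    dendritic = rng.random(n) < cfg.frac_dendritic
    multi = rng.random(n) < cfg.frac_multi_utr
    u = rng.random(n)
    kind_gene = np.where(~multi, "single",
                         np.where(u < cfg.frac_ur_apa, "ur",
                                  np.where(u < cfg.frac_ur_apa + cfg.frac_both_apa,
                                           "both", "tandem")))
    localized_iso = multi & (rng.random(n) < cfg.frac_localized_isoform)

    if cfg.clip_bound_mode == "top_tpm":
        k = int(round(cfg.frac_fmrp_bound * n))
        bound = np.zeros(n, dtype=bool)
        if k:
            bound[np.argsort(theta)[-k:]] = True
    else:
        bound = rng.random(n) < cfg.frac_fmrp_bound

    models: list[GeneModel] = []
    iso_rows = []
    pos = 1000
    gap = 1000
    for i in range(n):
        gid = f"G{i:05d}"
        strand = "+" if i % 2 == 0 else "-"
        e_len = (int(rng.integers(120, 200)), int(rng.integers(120, 200)))
        i_len = (int(rng.integers(250, 450)), int(rng.integers(250, 450)))
        utr5_cds = 150                               # CDS part of final exon
        d_prox = int(rng.integers(300, 600))         # stop -> proximal polyA
        d_dist = int(rng.integers(900, 2500))        # stop -> distal polyA
        d_intronic = int(rng.integers(100, 250))     # into intron 2

        # + strand template, transcript order left -> right
        e1 = (0, e_len[0])
        e2 = (e1[1] + i_len[0], e1[1] + i_len[0] + e_len[1])
        f0 = e2[1] + i_len[1]                        # final exon start
        stop = f0 + utr5_cds
        gk = kind_gene[i]
        tandem_sites = [stop + d_dist] if gk in ("single", "ur") else [stop + d_prox, stop + d_dist]
        intronic_site = e2[1] + d_intronic if gk in ("ur", "both") else None
        gene_len = stop + d_dist

        def fwd(x):
            return pos + x

        def rev(x):
            return pos + gene_len - x

        if strand == "+":
            exons = [(fwd(a), fwd(b)) for a, b in (e1, e2, (f0, gene_len))]
            stop_g = fwd(stop)
            polya = [fwd(s) for s in tandem_sites]
            intr_g = fwd(intronic_site) if intronic_site is not None else None
            final_start = fwd(f0)
            e2_acc = fwd(e2[0])   # acceptor of junction 1 in genomic coords
        else:
            exons = [(rev(b), rev(a)) for a, b in ((f0, gene_len), e2, e1)]
            stop_g = rev(stop)
            polya = [rev(s) for s in tandem_sites]
            intr_g = rev(intronic_site) if intronic_site is not None else None
            final_start = rev(f0)   # genomic right edge of final exon region
            e2_acc = rev(e2[0])

        all_polya = sorted(polya + ([intr_g] if intr_g is not None else []))
        models.append(GeneModel(
            gene_id=gid, chrom="chrS", strand=strand,
            start=pos, end=pos + gene_len,
            exons=exons, stop_codon=stop_g, polya_positions=all_polya))

        # ---- truth isoforms (candidate-UTR intervals, genomic half-open)
        def interval(five, three):
            return (min(five, three), max(five, three))

        iso_list = []
        for j, s in enumerate(tandem_sites):
            g3 = fwd(s) if strand == "+" else rev(s)
            iso_list.append(("tandem", interval(final_start, g3), s - stop))
        if intronic_site is not None:
            g3 = fwd(intronic_site) if strand == "+" else rev(intronic_site)
            iso_list.append(("intronic", interval(e2_acc, g3), None))

        n_iso = len(iso_list)
        if n_iso == 1:
            usage_cb = usage_np = [1.0]
        else:
            p = cfg.usage_prox_cb
            if n_iso == 2:
                usage_cb = [p, 1 - p]
            else:  # prox tandem, distal tandem, intronic
                usage_cb = [p * 0.8, (1 - p) * 0.8, 0.2]
            if localized_iso[i]:
                q = cfg.usage_prox_np_localized
                if n_iso == 2:
                    usage_np = [q, 1 - q]
                else:
                    usage_np = [q * 0.8, (1 - q) * 0.8, 0.2]
            else:
                usage_np = list(usage_cb)
        # order truth rows to match iso_list; tandem isoforms sorted
        # proximal->distal in transcript order already
        for j, (ikind, (a, b), ddist) in enumerate(iso_list):
            iso_rows.append({
                "gene_id": gid, "isoform": f"{gid}.i{j}", "kind": ikind,
                "utr_start": int(a), "utr_end": int(b), "strand": strand,
                "usage_cb": usage_cb[j], "usage_np": usage_np[j],
            })
        pos += gene_len + gap

    genes = pd.DataFrame({
        "gene_id": [m.gene_id for m in models],
        "theta": theta,
        "dendrite_enriched": dendritic,
        "fmrp_bound": bound,
        "localized_isoform": localized_iso,
        "apa_kind": kind_gene,
    }).set_index("gene_id")
    isoforms = pd.DataFrame(iso_rows)
    return models, genes, isoforms


# ---------------------------------------------------------------------------
# counts, junctions, polyA tags, coverage


def _nb_draw(rng, mean, dispersion):
    """Negative-binomial draw parametrized by mean and dispersion alpha
    (variance = mu + alpha mu^2); alpha=0 degenerates to Poisson."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + np.maximum(mean, 1e-12))
    out = rng.negative_binomial(r, p)
    return np.where(mean <= 0, 0, out)


def gen_count_data(models, genes, isoforms, cfg: SimConfig):
    """Generate count matrices, TPMs, junction tables, polyA tag tables and
    per-UTR base coverage, consistent with the gene-level truth.

    Counts follow NB(mean = library-scaled expression x isoform usage,
    dispersion = ``cfg.nb_dispersion``); junction reads are split between
    isoforms according to true usage.
    """
    rng = _rng(cfg, 2)
    gene_ids = genes.index.to_numpy()
    theta = genes["theta"].to_numpy()
    dend = genes["dendrite_enriched"].to_numpy()
    n = len(gene_ids)
    lfc = cfg.localization_lfc

    groups = [("TRAP", "NP", "+"), ("TRAP", "CB", "+"),
              ("RNA", "NP", "+"), ("TRAP", "NP", "-")]
    genotypes = ["WT", "KO"] if cfg.include_ko else ["WT"]
    sample_rows, cols = [], {}
    for gt in genotypes:
        for assay, comp, cre in groups:
            nrep = cfg.n_trap_replicates if assay == "TRAP" else cfg.n_rna_replicates
            for r in range(1, nrep + 1):
                name = f"{assay}_{comp}_cre{'pos' if cre == '+' else 'neg'}_{gt}_r{r}"
                # dendritic boost applies only to ribosome capture of CA1
                # material in the neuropil with Cre on
                boost = np.where(dend & (assay == "TRAP") & (comp == "NP") & (cre == "+"),
                                 2.0 ** lfc, 1.0)
                sf = cfg.library_size_mean * float(rng.uniform(0.7, 1.3))
                mu = sf * theta * boost
                cols[name] = _nb_draw(rng, mu, cfg.nb_dispersion)
                sample_rows.append({"sample": name, "assay": assay,
                                    "compartment": comp, "genotype": gt,
                                    "cre": cre, "batch": f"b{(r - 1) % 2 + 1}",
                                    "replicate": r})
    counts = pd.DataFrame(cols, index=gene_ids)
    samples = pd.DataFrame(sample_rows).set_index("sample")

    # transcript lengths: most-expressed (distal) isoform length
    lengths = {}
    for m in models:
        exonic = sum(b - a for a, b in m.exons)
        lengths[m.gene_id] = exonic
    lengths = pd.Series(lengths, name="length_nt")

    # TPM per compartment from TRAP counts (mean over Cre+ WT replicates)
    tpm_cols = {}
    for comp in ("NP", "CB"):
        sel = samples[(samples.assay == "TRAP") & (samples.compartment == comp)
                      & (samples.cre == "+") & (samples.genotype == "WT")].index
        rate = counts[sel].mean(axis=1) / lengths.reindex(gene_ids).to_numpy()
        tpm_cols[comp] = 1e6 * rate / rate.sum()
    tpm = pd.DataFrame(tpm_cols)

    # ---- junction reads -------------------------------------------------
    # junction J1 (exon1->exon2) is used by all isoforms; J2 (exon2->final
    # exon) only by non-truncated isoforms.
    iso = isoforms.set_index("gene_id")
    junc_rows = []
    usage_map = {"NP": "usage_np", "CB": "usage_cb"}
    trap_samples = samples[(samples.assay == "TRAP") & (samples.cre == "+")
                           & (samples.genotype == "WT")]
    for m in models:
        gi = iso.loc[[m.gene_id]]
        if m.strand == "+":
            j1 = (m.exons[0][1], m.exons[1][0])
            j2 = (m.exons[1][1], m.exons[2][0])
        else:
            j1 = (m.exons[2][0], m.exons[1][1])
            j2 = (m.exons[1][0], m.exons[0][1])
        for sname, srow in trap_samples.iterrows():
            ucol = usage_map[srow.compartment]
            frac_spliced = float(gi.loc[gi["kind"] != "intronic", ucol].sum())
            total = counts.at[m.gene_id, sname] * cfg.junction_rate
            r1 = _nb_draw(rng, total, cfg.nb_dispersion)
            r2 = rng.binomial(int(r1), min(frac_spliced, 1.0)) if r1 > 0 else 0
            junc_rows.append({"gene": m.gene_id, "donor": j1[0], "acceptor": j1[1],
                              "reads": int(r1), "sample": sname})
            junc_rows.append({"gene": m.gene_id, "donor": j2[0], "acceptor": j2[1],
                              "reads": int(r2), "sample": sname})
    junctions = pd.DataFrame(junc_rows)

    # ---- polyA tag tables ----------------------------------------------
    wc_rows, comp_rows = [], []
    for m in models:
        gi = iso.loc[[m.gene_id]]
        th = genes.at[m.gene_id, "theta"]
        for _, row in gi.iterrows():
            pa = row["utr_end"] if m.strand == "+" else row["utr_start"]
            wc_mean = cfg.paperclip_scale * th * row["usage_cb"]
            wc_tags = int(_nb_draw(rng, wc_mean, cfg.nb_dispersion))
            wc_rows.append({"gene": m.gene_id, "strand": m.strand,
                            "position": int(pa), "tags": wc_tags,
                            "source": "whole-cell"})
            for r in range(1, cfg.n_paperclip_replicates + 1):
                np_mean = cfg.paperclip_np_scale * th * row["usage_np"]
                comp_rows.append({"gene": m.gene_id, "strand": m.strand,
                                  "position": int(pa),
                                  "tags": int(_nb_draw(rng, np_mean, cfg.nb_dispersion)),
                                  "source": "compartment", "replicate": r})
    polya_wholecell = pd.DataFrame(wc_rows)
    polya_compartment = pd.DataFrame(comp_rows)

    # ---- per-base coverage (complete over expressed regions) -----------
    coverage = {}
    for sname in trap_samples.index:
        cov = {m.gene_id: (m.start, np.ones(m.end - m.start, dtype=np.float32))
               for m in models}
        coverage[sname] = cov

    return SimData(config=cfg, models=models, genes=genes, isoforms=isoforms,
                   counts=counts, samples=samples, tpm=tpm, lengths=lengths,
                   junctions=junctions, polya_wholecell=polya_wholecell,
                   polya_compartment=polya_compartment, coverage=coverage)


# ---------------------------------------------------------------------------
# CLIP replicates


def gen_clip_replicates(genes: pd.DataFrame, tpm: pd.DataFrame, cfg: SimConfig):
    """CLIP tag counts per gene, replicate and compartment.

    Expected log10 CLIP intensity is linear in log10(TPM) with a spiked
    additive offset (``clip_enrichment_log10``) on FMRP-bound genes and
    log-normal replicate noise; intensities are scaled to the configured
    library totals (neuropil libraries ~10x smaller than cell-body ones)
    and tag counts drawn Poisson. Genes with TPM = 0 get zero tags.
    """
    rng = _rng(cfg, 3)
    bound = genes["fmrp_bound"].to_numpy()
    rows = []
    libs = {"CB": float(cfg.clip_cb_library),
            "NP": float(cfg.clip_cb_library * cfg.clip_np_cb_ratio)}
    for comp in ("CB", "NP"):
        t = tpm[comp].reindex(genes.index).to_numpy()
        expressed = t > 0
        for r in range(1, cfg.n_clip_replicates + 1):
            eps = rng.normal(0.0, cfg.clip_replicate_noise_sd, size=len(t))
            log10r = (cfg.clip_slope * np.log10(np.where(expressed, t, 1.0))
                      + cfg.clip_enrichment_log10 * bound + eps)
            rel = np.where(expressed, 10.0 ** log10r, 0.0)
            lam = libs[comp] * rel / rel.sum()
            tags = rng.poisson(lam)
            rows.append(pd.DataFrame({
                "gene": genes.index, "compartment": comp, "replicate": r,
                "tags": tags}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# FISH field


def poly_eval(coeffs, x):
    """Evaluate a polynomial given ascending-power coefficients."""
    return np.polynomial.polynomial.polyval(np.asarray(x, dtype=float),
                                            np.asarray(coeffs, dtype=float))


def gen_fish_field(cfg: SimConfig) -> FishField:
    """One synthetic FISH image: nuclei pixels below (cell-body side of) a
    polynomial boundary and spots from a two-component mixture.

    Cell-body spots are uniform within the nuclear layer; neuropil spots sit
    at an Exp(``fish_decay_um``) distance beyond the boundary. Per-spot true
    component and true signed (vertical) distance are recorded.
    """
    cfg.validate()
    rng = _rng(cfg, 4)
    W, H = cfg.fish_width_um, cfg.fish_height_um
    coeffs = np.asarray(cfg.fish_boundary_coeffs, dtype=float)
    xs = np.linspace(0, W, 200)
    f = poly_eval(coeffs, xs)
    if f.min() < 0 or f.max() > H:
        raise ValueError("boundary curve leaves the image frame")
    sgn = 1.0 if cfg.neuropil_above else -1.0

    nx = rng.uniform(0, W, cfg.fish_n_nuclei_px)
    ny = poly_eval(coeffs, nx) - sgn * rng.uniform(0, cfg.fish_layer_depth_um,
                                                   cfg.fish_n_nuclei_px)
    # snap to the pixel grid, as a mask export would
    px = cfg.um_per_px
    nuclei = np.column_stack([np.round(nx / px) * px, np.round(ny / px) * px])

    nsp = cfg.fish_n_spots
    is_np = rng.random(nsp) < cfg.fish_neuropil_weight
    sx = rng.uniform(0, W, nsp)
    d = np.where(is_np,
                 rng.exponential(cfg.fish_decay_um, nsp),
                 -rng.uniform(0, cfg.fish_layer_depth_um, nsp))
    sy = poly_eval(coeffs, sx) + sgn * d + rng.normal(0, cfg.spot_noise_sd, nsp)
    true_d = sgn * (sy - poly_eval(coeffs, sx))
    spots = pd.DataFrame({
        "spot_id": [f"s{i:05d}" for i in range(nsp)],
        "x_um": sx, "y_um": np.clip(sy, 0, H),
        "z_um": rng.uniform(0, 5, nsp), "channel": "probeA",
        "true_component": np.where(is_np, "neuropil", "cell-body"),
        "true_distance_um": true_d,
        "true_compartment": np.where(true_d > 10.0, "neuropil", "cell-body"),
    })
    return FishField(spots=spots, nuclei_um=nuclei, boundary_coeffs=coeffs,
                     um_per_px=px, width_um=W, height_um=H,
                     neuropil_above=cfg.neuropil_above)
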