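import numpy as np
import pandas as pd
import pytest

from ca1kit.simulate import GeneModel, SimConfig, gen_count_data, gen_gene_models
from ca1kit.utr import (classify_apa, coverage_filter, discover_utrs,
                        filter_junctions, filter_polya_sites, pair_boundaries,
                        remove_ambiguous)


def make_model(gene="g1", strand="+", start=0):
    """Three-exon gene: exons [0,150) [400,550) [800,2500); stop at 950."""
    off = start
    return GeneModel(gene_id=gene, chrom="chrS", strand=strand, start=off,
                     end=off + 2500,
                     exons=[(off, off + 150), (off + 400, off + 550),
                            (off + 800, off + 2500)],
                     stop_codon=off + 950, polya_positions=[off + 2500])


class TestFilterPolyaSites:
    def test_tag_and_fraction_rules(self):
        sites = pd.DataFrame({
            "gene": ["g1", "g1", "g2", "g2"],
            "strand": ["+"] * 4,
            "position": [100, 200, 100, 200],
            "tags": [12, 88, 12, 988],
        })
        kept = filter_polya_sites(sites, "whole-cell")
        # 12/100 passes both rules; 12/1000 = 1.2% fails the fraction rule
        assert ("g1", 100) in set(zip(kept.gene, kept.position))
        assert ("g2", 100) not in set(zip(kept.gene, kept.position))

    def test_compartment_replicate_support(self):
        rows = []
        for rep, tags in enumerate([3, 2, 0, 0], start=1):
            rows.append({"gene": "g1", "strand": "+", "position": 50,
                         "tags": tags, "replicate": rep})
            rows.append({"gene": "g1", "strand": "+", "position": 99,
                         "tags": tags if rep == 1 else 0, "replicate": rep})
        kept = filter_polya_sites(pd.DataFrame(rows), "compartment")
        assert set(kept.position) == {50}  # 99 seen in only one replicate

    def test_matches_brute_force_on_random_tables(self, rng):
        genes = [f"g{i}" for i in range(40)]
        sites = pd.DataFrame({
            "gene": rng.choice(genes, 500),
            "strand": rng.choice(["+", "-"], 500),
            "position": rng.integers(0, 10_000, 500),
            "tags": rng.integers(0, 60, 500),
        }).drop_duplicates(["gene", "position"])
        kept = filter_polya_sites(sites, "whole-cell")
        kept_keys = set(zip(kept.gene, kept.position))
        totals = sites.groupby("gene")["tags"].sum().to_dict()
        expected = {(r.gene, r.position) for r in sites.itertuples()
                    if r.tags >= 10 and totals[r.gene] > 0
                    and r.tags / totals[r.gene] >= 0.05}
        assert kept_keys == expected

    def test_unknown_source_rejected(self):
        with pytest.raises(ValueError):
            filter_polya_sites(pd.DataFrame({"gene": [], "strand": [],
                                             "position": [], "tags": []}), "nuclear")


class TestFilterJunctions:
    def test_count_rule_and_fraction_rule_are_or(self):
        j = pd.DataFrame({
            "gene": ["g1", "g1", "g2", "g2"],
            "donor": [10, 30, 10, 30],
            "acceptor": [20, 40, 20, 40],
            "reads": [10, 990, 1, 7],
        })
        kept = filter_junctions(j)
        keys = set(zip(kept.gene, kept.donor))
        assert ("g1", 10) in keys          # 10 reads: count rule
        assert ("g2", 10) in keys          # 1/8 = 12.5%: fraction rule
        assert ("g2", 30) in keys

    def test_matches_brute_force(self, rng):
        genes = [f"g{i}" for i in range(30)]
        j = pd.DataFrame({
            "gene": rng.choice(genes, 300),
            "donor": rng.integers(0, 5000, 300),
            "acceptor": rng.integers(5000, 9000, 300),
            "reads": rng.integers(0, 40, 300),
        }).drop_duplicates(["gene", "donor", "acceptor"])
        kept = filter_junctions(j)
        totals = j.groupby("gene")["reads"].sum().to_dict()
        expected = {(r.gene, r.donor, r.acceptor) for r in j.itertuples()
                    if r.reads >= 10 or (totals[r.gene] > 0
                                         and r.reads / totals[r.gene] >= 0.10)}
        assert set(zip(kept.gene, kept.donor, kept.acceptor)) == expected

    def test_negative_reads_rejected(self):
        j = pd.DataFrame({"gene": ["g"], "donor": [0], "acceptor": [5],
                          "reads": [-1]})
        with pytest.raises(ValueError):
            filter_junctions(j)


class TestPairBoundaries:
    def test_single_pairing_plus_strand(self):
        m = make_model()
        sites = pd.DataFrame({"gene": ["g1"], "strand": ["+"],
                              "position": [1500], "tags": [50]})
        juncs = pd.DataFrame({"gene": ["g1"], "donor": [550],
                              "acceptor": [1000], "reads": [20]})
        utrs = pair_boundaries(sites, juncs, [m])
        assert utrs.iloc[0][["utr_start", "utr_end"]].tolist() == [1000, 1500]

    def test_nearest_upstream_junction_wins(self):
        m = make_model()
        sites = pd.DataFrame({"gene": ["g1"], "strand": ["+"],
                              "position": [2000], "tags": [50]})
        juncs = pd.DataFrame({"gene": ["g1", "g1"], "donor": [150, 550],
                              "acceptor": [400, 800], "reads": [20, 20]})
        utrs = pair_boundaries(sites, juncs, [m])
        assert len(utrs) == 1
        assert utrs.iloc[0]["utr_start"] == 800

    def test_fallback_to_stop_exon_start(self):
        m = make_model()
        sites = pd.DataFrame({"gene": ["g1"], "strand": ["+"],
                              "position": [2000], "tags": [50]})
        utrs = pair_boundaries(sites, pd.DataFrame(
            {"gene": [], "donor": [], "acceptor": [], "reads": []}), [m])
        assert utrs.iloc[0]["utr_start"] == 800  # start of stop-codon exon

    def test_matches_quadratic_oracle(self, rng):
        m = make_model()
        for _ in range(20):
            n_j, n_p = rng.integers(1, 6), rng.integers(1, 6)
            accs = np.sort(rng.choice(np.arange(200, 2400, 7), n_j, replace=False))
            juncs = pd.DataFrame({"gene": "g1", "donor": accs - 50,
                                  "acceptor": accs,
                                  "reads": rng.integers(1, 30, n_j)})
            pos = np.sort(rng.choice(np.arange(210, 2500, 11), n_p, replace=False))
            sites = pd.DataFrame({"gene": "g1", "strand": "+",
                                  "position": pos, "tags": 50})
            got = pair_boundaries(sites, juncs, [m])
            expected = set()
            for p in pos:
                ups = [a for a in accs if a < p]
                five = max(ups) if ups else 800
                if five < p:
                    expected.add((five, int(p)))
            assert set(zip(got.utr_start, got.utr_end)) == expected

    def test_strand_symmetry(self):
        # mirroring all coordinates around a pivot and flipping strand
        # must yield mirror-image boundaries
        L = 10_000
        m_plus = make_model("g1", "+")
        m_minus = GeneModel(
            gene_id="g1", chrom="chrS", strand="-",
            start=L - m_plus.end, end=L - m_plus.start,
            exons=[(L - b, L - a) for a, b in reversed(m_plus.exons)],
            stop_codon=L - m_plus.stop_codon,
            polya_positions=[L - p for p in m_plus.polya_positions])
        sites_p = pd.DataFrame({"gene": ["g1"], "strand": ["+"],
                                "position": [1500], "tags": [50]})
        juncs_p = pd.DataFrame({"gene": ["g1"], "donor": [550],
                                "acceptor": [1000], "reads": [20]})
        sites_m = sites_p.assign(position=L - sites_p.position, strand="-")
        juncs_m = juncs_p.assign(donor=L - juncs_p.donor,
                                 acceptor=L - juncs_p.acceptor)
        up = pair_boundaries(sites_p, juncs_p, [m_plus])
        um = pair_boundaries(sites_m, juncs_m, [m_minus])
        assert (L - up.utr_end.iloc[0], L - up.utr_start.iloc[0]) == \
            (um.utr_start.iloc[0], um.utr_end.iloc[0])


class TestCoverageFilter:
    def _utrs(self):
        return pd.DataFrame({"gene": ["g1"], "strand": ["+"],
                             "utr_start": [0], "utr_end": [100],
                             "polya_position": [100], "tags": [50]})

    def test_boundary_inclusive_at_80_percent(self):
        arr = np.zeros(100)
        arr[:80] = 1.0
        cov = {"e1": {"g1": (0, arr)}}
        assert len(coverage_filter(self._utrs(), cov)) == 1
        arr2 = arr.copy()
        arr2[79] = 0.0
        assert len(coverage_filter(self._utrs(), {"e1": {"g1": (0, arr2)}})) == 0

    def test_any_single_experiment_suffices(self):
        full = {"e1": {"g1": (0, np.zeros(100))},
                "e2": {"g1": (0, np.ones(100))}}
        assert len(coverage_filter(self._utrs(), full)) == 1

    def test_matches_base_counting_oracle(self, rng):
        utrs = pd.DataFrame({
            "gene": [f"g{i}" for i in range(30)], "strand": "+",
            "utr_start": 0, "utr_end": rng.integers(50, 200, 30),
            "polya_position": 0, "tags": 1})
        cov = {"e1": {f"g{i}": (0, (rng.random(200) < 0.85).astype(float))
                      for i in range(30)}}
        kept = coverage_filter(utrs, cov)
        expected = {r.gene for r in utrs.itertuples()
                    if np.mean(cov["e1"][r.gene][1][: r.utr_end] > 0) >= 0.8}
        assert set(kept.gene) == expected

    def test_short_array_rejected(self):
        with pytest.raises(ValueError):
            coverage_filter(self._utrs(), {"e1": {"g1": (0, np.ones(50))}})


class TestRemoveAmbiguous:
    def test_disjoint_genes_retained_overlapping_dropped(self):
        m1, m2 = make_model("g1"), make_model("g2", start=5000)
        utrs = pd.DataFrame({
            "gene": ["g1", "g2"], "strand": ["+", "+"],
            "utr_start": [800, 5800], "utr_end": [1500, 6500],
            "polya_position": [1500, 6500], "tags": [9, 9]})
        assert len(remove_ambiguous(utrs, [m1, m2])) == 2
        # a UTR running into the downstream gene is dropped
        utrs.loc[0, "utr_end"] = 5200
        kept = remove_ambiguous(utrs, [m1, m2])
        assert set(kept.gene) == {"g2"}

    def test_ambiguous_gene_dropped_entirely(self):
        m1, m2 = make_model("g1"), make_model("g2", start=1000)  # overlap
        utrs = pd.DataFrame({
            "gene": ["g1"], "strand": ["+"], "utr_start": [800],
            "utr_end": [900], "polya_position": [900], "tags": [9]})
        assert len(remove_ambiguous(utrs, [m1, m2])) == 0

    def test_matches_quadratic_overlap_oracle(self, rng):
        models = [make_model(f"g{i}", start=int(s))
                  for i, s in enumerate(np.cumsum(rng.integers(2600, 4000, 12)))]
        spans = {m.gene_id: (m.start, m.end) for m in models}
        utrs = pd.DataFrame({
            "gene": [m.gene_id for m in models], "strand": "+",
            "utr_start": [m.start + 800 for m in models],
            "utr_end": [m.start + 800 + int(rng.integers(200, 4000))
                        for m in models],
            "polya_position": 0, "tags": 1})
        kept = remove_ambiguous(utrs, models)
        expected = set()
        for r in utrs.itertuples():
            clash = False
            for g, (s, e) in spans.items():
                if g != r.gene and r.utr_start < e and s < r.utr_end:
                    clash = True
            for r2 in utrs.itertuples():
                if r2.gene != r.gene and r.utr_start < r2.utr_end \
                        and r2.utr_start < r.utr_end:
                    clash = True
            if not clash:
                expected.add(r.gene)
        assert set(kept.gene) == expected


class TestClassifyApa:
    def test_two_terminal_sites(self):
        m = make_model()
        utrs = pd.DataFrame({
            "gene": "g1", "strand": "+", "utr_start": 800,
            "utr_end": [1400, 2400], "polya_position": [1400, 2400],
            "tags": 9})
        ev = classify_apa(utrs, [m])
        assert (ev.apa_type == "3'UTR-APA").all()
        assert not ev.cds_altering.any()
        assert set(ev.position_class) == {"proximal", "distal"}

    def test_intronic_site_is_cds_altering(self):
        m = make_model()
        utrs = pd.DataFrame({
            "gene": "g1", "strand": "+", "utr_start": [550, 800],
            "utr_end": [700, 2400], "polya_position": [700, 2400],
            "tags": 9})
        ev = classify_apa(utrs, [m])
        assert (ev.apa_type == "UR-APA").all()
        assert ev.cds_altering.all()
        assert (ev.loc[ev.site_kind == "upstream", "position_class"].isna()).all()

    def test_three_terminal_sites_middle_is_internal(self):
        m = make_model()
        utrs = pd.DataFrame({
            "gene": "g1", "strand": "+", "utr_start": 800,
            "utr_end": [1200, 1800, 2400], "polya_position": [1200, 1800, 2400],
            "tags": 9})
        ev = classify_apa(utrs, [m]).set_index("utr_end")
        assert ev.loc[1200, "position_class"] == "proximal"
        assert ev.loc[1800, "position_class"] == "internal"
        assert ev.loc[2400, "position_class"] == "distal"

    def test_single_isoform_gene_yields_no_event(self):
        m = make_model()
        utrs = pd.DataFrame({
            "gene": ["g1"], "strand": ["+"], "utr_start": [800],
            "utr_end": [2400], "polya_position": [2400], "tags": [9]})
        assert len(classify_apa(utrs, [m])) == 0


class TestFullDiscovery:
    def test_recovery_and_idempotence_on_synthetic_data(self, sim200):
        utrs, events = discover_utrs(
            sim200.polya_wholecell, sim200.polya_compartment,
            sim200.junctions, sim200.models, sim200.coverage)
        truth = set(zip(sim200.isoforms.gene_id, sim200.isoforms.utr_start,
                        sim200.isoforms.utr_end))
        found = set(zip(utrs.gene, utrs.utr_start, utrs.utr_end))
        recovery = len(truth & found) / len(truth)
        assert recovery >= 0.95
        # every retained UTR passes the filters when re-checked
        sites = pd.DataFrame({
            "gene": utrs.gene, "strand": utrs.strand,
            "position": utrs.polya_position, "tags": utrs.tags})
        models = {m.gene_id: m for m in sim200.models}
        refiltered = coverage_filter(utrs, sim200.coverage)
        assert len(refiltered) == len(utrs)
        assert len(remove_ambiguous(utrs, models)) == len(utrs)
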