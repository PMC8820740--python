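import numpy as np
import pandas as pd
import pytest

from ca1kit.clip import (call_dendritic_targets, clip_score_table,
                         detect_reproducible, fit_clip_trap_model,
                         mean_clip_score, normalize_clip, percent_round,
                         set_summary)


def clip_frame(tags_by_gene_rep, compartment="NP"):
    rows = []
    for gene, tags in tags_by_gene_rep.items():
        for rep, t in enumerate(tags, start=1):
            rows.append({"gene": gene, "compartment": compartment,
                         "replicate": rep, "tags": t})
    return pd.DataFrame(rows)


class TestNormalizeClip:
    def test_single_gene_whole_library(self):
        df = clip_frame({"g1": [50]})
        lengths = pd.Series({"g1": 1000})
        out = normalize_clip(df, lengths)
        assert out.tags_per_10k.iloc[0] == pytest.approx(10_000)
        assert out.E.iloc[0] == pytest.approx(10_000)  # length 1 kb

    def test_depth_scale_invariance(self):
        lengths = pd.Series({"g1": 2000, "g2": 500})
        a = normalize_clip(clip_frame({"g1": [30], "g2": [70]}), lengths)
        b = normalize_clip(clip_frame({"g1": [60], "g2": [140]}), lengths)
        np.testing.assert_allclose(a.E.to_numpy(), b.E.to_numpy())
        np.testing.assert_allclose(a.tags_per_10k.to_numpy(),
                                   b.tags_per_10k.to_numpy())

    def test_matches_two_step_oracle(self, rng):
        genes = [f"g{i}" for i in range(40)]
        lengths = pd.Series(rng.integers(500, 8000, 40), index=genes)
        df = clip_frame({g: rng.integers(0, 100, 3) for g in genes})
        out = normalize_clip(df, lengths)
        for r in out.itertuples():
            lib = df.loc[(df.replicate == r.replicate), "tags"].sum()
            expected = (r.tags / (lengths[r.gene] / 1000)) * 10_000 / lib
            assert r.E == pytest.approx(expected)

    def test_zero_library_excluded(self):
        df = clip_frame({"g1": [0, 10], "g2": [0, 5]})
        out = normalize_clip(df, pd.Series({"g1": 1000, "g2": 1000}))
        assert set(out.replicate) == {2}


class TestDetectReproducible:
    def test_three_of_five_rule_and_strictness(self):
        df = clip_frame({"hit": [6, 6, 6, 0, 0], "edge": [5, 5, 5, 5, 5]})
        # make library totals equal across replicates so per-10k is exact
        lengths = pd.Series({"hit": 1000, "edge": 1000, "fill": 1000})
        fill = clip_frame({"fill": [9989, 9989, 9989, 9995, 9995]})
        norm = normalize_clip(pd.concat([df, fill]), lengths)
        flags = detect_reproducible(norm, "NP")
        assert bool(flags["hit"]) is True
        assert bool(flags["edge"]) is False  # strict > 5

    def test_matches_counting_oracle(self, rng):
        genes = [f"g{i}" for i in range(60)]
        df = clip_frame({g: rng.integers(0, 40, 5) for g in genes})
        lengths = pd.Series(1000, index=genes)
        norm = normalize_clip(df, lengths)
        flags = detect_reproducible(norm, "NP")
        for g in genes:
            sub = norm[norm.gene == g]
            expected = int((sub.tags_per_10k > 5).sum()) >= 3
            assert bool(flags[g]) == expected

    def test_too_few_replicates_rejected(self):
        norm = normalize_clip(clip_frame({"g": [5, 5]}), pd.Series({"g": 1000}))
        with pytest.raises(ValueError):
            detect_reproducible(norm, "NP")


class TestFitClipTrapModel:
    def _norm(self, E_by_gene, tpm):
        # craft tag counts so that E comes out as requested (length 1 kb)
        genes = list(E_by_gene)
        rows = []
        for rep in (1, 2, 3):
            for g in genes:
                rows.append({"gene": g, "compartment": "NP", "replicate": rep,
                             "tags": E_by_gene[g]})
        df = pd.DataFrame(rows)
        return normalize_clip(df, pd.Series(1000, index=genes))

    def test_perfect_loglinear_relation_gives_zero_scores(self):
        tpm = pd.Series({f"g{i}": 10.0 * (i + 1) for i in range(12)})
        norm = self._norm({g: int(t * 5) for g, t in tpm.items()}, tpm)
        scores, slope, intercept = fit_clip_trap_model(norm, tpm, "NP", 1)
        assert slope == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(scores.to_numpy(), 0.0, atol=1e-9)

    def test_location_equivariance(self):
        tpm = pd.Series({f"g{i}": 10.0 * (i + 1) for i in range(12)})
        base = {g: int(t * 5) for g, t in tpm.items()}
        shifted = {g: v * 10 for g, v in base.items()}  # +1 in log10(E)
        s1, _, i1 = fit_clip_trap_model(self._norm(base, tpm), tpm, "NP", 1)
        s2, _, i2 = fit_clip_trap_model(self._norm(shifted, tpm), tpm, "NP", 1)
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-9)

    def test_small_universe_refused(self):
        tpm = pd.Series({f"g{i}": 10.0 for i in range(5)})
        norm = self._norm({g: 10 for g in tpm.index}, tpm)
        with pytest.raises(ValueError):
            fit_clip_trap_model(norm, tpm, "NP", 1)


class TestMeanClipScore:
    def test_plain_mean_and_na_exclusion(self):
        scores = pd.DataFrame({1: [1.0, 2.0], 2: [1.0, np.nan], 3: [1.0, 0.0]},
                              index=["a", "b"])
        m = mean_clip_score(scores)
        assert m.loc["a", "mean_score"] == pytest.approx(1.0)
        assert m.loc["b", "mean_score"] == pytest.approx(1.0)
        assert m.loc["b", "n_replicates"] == 2

    def test_matches_brute_force(self, rng):
        arr = rng.normal(size=(30, 5))
        arr[rng.random((30, 5)) < 0.2] = np.nan
        df = pd.DataFrame(arr)
        m = mean_clip_score(df)
        for i in range(30):
            vals = arr[i][np.isfinite(arr[i])]
            if len(vals):
                assert m.mean_score.iloc[i] == pytest.approx(vals.mean())
            else:
                assert np.isnan(m.mean_score.iloc[i])


class TestCallTargets:
    def test_or_semantics_and_strict_threshold(self):
        rep = pd.Series({"a": True, "b": False, "c": False})
        score = pd.Series({"a": 0.2, "b": 1.0, "c": 1.2})
        out = call_dendritic_targets(rep, score)
        assert bool(out.loc["a", "dendritic_target"])      # rule A alone
        assert not bool(out.loc["b", "dendritic_target"])  # 1.0 not > 1
        assert bool(out.loc["c", "dendritic_target"])

    def test_union_accounting(self, rng):
        genes = [f"g{i}" for i in range(100)]
        rep = pd.Series(rng.random(100) < 0.3, index=genes)
        score = pd.Series(rng.normal(0.5, 0.7, 100), index=genes)
        out = call_dendritic_targets(rep, score)
        n_a, n_b = int(out.rule_A.sum()), int(out.rule_B.sum())
        n_ab = int((out.rule_A & out.rule_B).sum())
        assert int(out.dendritic_target.sum()) == n_a + n_b - n_ab


class TestSetSummary:
    def test_published_overlap_percentages(self):
        targets = {f"t{i}" for i in range(383)}
        enriched = set(list(targets)[:233]) | {f"e{i}" for i in range(900)}
        present = set(list(targets)[:293]) | {f"p{i}" for i in range(1700)}
        out = set_summary({"targets": targets, "enriched": enriched,
                           "present": present})
        row = out[(out.set_a == "targets") & (out.set_b == "enriched")].iloc[0]
        assert row.pct_of_a == 60.8
        row = out[(out.set_a == "targets") & (out.set_b == "present")].iloc[0]
        assert row.pct_of_a == 76.5

    def test_subset_is_100_percent(self):
        out = set_summary({"a": {"x", "y"}, "b": {"x", "y", "z"}})
        assert out[(out.set_a == "a")].pct_of_a.iloc[0] == 100.0

    def test_rounding_half_up(self):
        assert percent_round(1, 16) == 6.3   # 6.25 rounds up
        assert percent_round(233, 383) == 60.8
        assert percent_round(0, 0) != percent_round(0, 0)  # NaN

    def test_chi2_reported_against_universe(self):
        universe = {f"g{i}" for i in range(1000)}
        a = {f"g{i}" for i in range(100)}
        b = {f"g{i}" for i in range(50, 550)}
        out = set_summary({"a": a, "b": b}, universe=universe)
        assert out.chi2_p.notna().all()


class TestScoreTableInvariants:
    def test_length_unit_switch_leaves_target_calls_unchanged(self, rng):
        genes = [f"g{i}" for i in range(120)]
        tpm_vals = rng.lognormal(3, 1, 120)
        tpm = pd.DataFrame({"NP": tpm_vals, "CB": tpm_vals}, index=genes)
        rows = []
        for comp in ("NP", "CB"):
            for rep in range(1, 6):
                tags = rng.poisson(tpm_vals * 2)
                for g, t in zip(genes, tags):
                    rows.append({"gene": g, "compartment": comp,
                                 "replicate": rep, "tags": t})
        clip = pd.DataFrame(rows)
        lengths_nt = pd.Series(rng.integers(500, 9000, 120), index=genes)
        t1 = clip_score_table(clip, tpm, lengths_nt)
        t2 = clip_score_table(clip, tpm, lengths_nt / 1000.0)
        pd.testing.assert_series_equal(t1.dendritic_target, t2.dendritic_target)
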