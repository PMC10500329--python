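"""TMM normalization, differential calling, consensus filter, HSP panels,
profiles, and strategy classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from antheat import expression, simulate
from antheat.expression import CountMatrix


def _matrix(mat, n_hs=None):
    mat = np.asarray(mat)
    n = mat.shape[1]
    n_hs = n_hs if n_hs is not None else n // 2
    samples = [f"HS_{i}" for i in range(n_hs)] + [f"NHS_{i}" for i in range(n - n_hs)]
    return CountMatrix(
        counts=pd.DataFrame(mat, index=[f"t{i}" for i in range(mat.shape[0])],
                            columns=samples),
        conditions=pd.Series(["HS"] * n_hs + ["NHS"] * (n - n_hs), index=samples),
    )


def _naive_tmm_factor(obs, ref, lib_obs, lib_ref):
    """Direct recomputation of one sample's trimmed weighted mean (oracle)."""
    keep = (obs > 0) & (ref > 0)
    p_obs, p_ref = obs[keep] / lib_obs, ref[keep] / lib_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    var = (lib_obs - obs[keep]) / (lib_obs * obs[keep]) + (
        lib_ref - ref[keep]) / (lib_ref * ref[keep])
    n = m.size
    lo_m = int(np.floor(n * 0.3)) + 1
    lo_a = int(np.floor(n * 0.05)) + 1
    rm, ra = stats.rankdata(m), stats.rankdata(a)
    sel = (rm >= lo_m) & (rm <= n + 1 - lo_m) & (ra >= lo_a) & (ra <= n + 1 - lo_a)
    return 2.0 ** (np.sum(m[sel] / var[sel]) / np.sum(1.0 / var[sel]))


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        col = np.array([5, 10, 200, 3, 80])
        nf = expression.tmm_factors(pd.DataFrame({"a": col, "b": col, "c": col}))
        assert np.allclose(nf.factors, 1.0)

    def test_pure_depth_scaling_gives_unit_factors(self):
        col = np.array([5, 10, 200, 3, 80])
        nf = expression.tmm_factors(pd.DataFrame({"a": col, "b": 3 * col}))
        assert np.allclose(nf.factors, 1.0)

    def test_matches_naive_oracle_on_random_matrix(self):
        rng = np.random.default_rng(99)
        mu = rng.lognormal(4, 1.5, 400)
        mat = np.column_stack(
            [rng.negative_binomial(10, 10 / (10 + mu * f)) for f in (1, 1.3, 0.75, 1.1)]
        )
        df = pd.DataFrame(mat, columns=list("abcd"))
        nf = expression.tmm_factors(df)
        lib = mat.sum(axis=0)
        f75 = np.array([np.quantile(mat[:, j], 0.75) / lib[j] for j in range(4)])
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
        raw = np.ones(4)
        for j in range(4):
            if j != ref:
                raw[j] = _naive_tmm_factor(mat[:, j].astype(float),
                                           mat[:, ref].astype(float),
                                           lib[j], lib[ref])
        raw /= np.exp(np.mean(np.log(raw)))
        assert np.allclose(nf.factors.to_numpy(), raw, atol=1e-10)

    def test_matches_bioconductor_reference_values(self):
        """Frozen cross-check against edgeR::calcNormFactors (TMM) computed
        on this exact seeded matrix."""
        rng = np.random.default_rng(2024)
        mu = rng.lognormal(4, 1.5, 300)
        mat = np.column_stack(
            [rng.negative_binomial(10, 10 / (10 + mu * f))
             for f in (1.0, 1.2, 0.8, 1.1, 0.9, 1.3)]
        )
        nf = expression.tmm_factors(pd.DataFrame(mat, columns=[f"s{i}" for i in range(6)]))
        edger = [0.952330, 1.030966, 1.057588, 0.956827, 1.045597, 0.962618]
        assert np.allclose(nf.factors.to_numpy(), edger, atol=1e-6)

    def test_invariant_to_row_and_column_order(self, toy_counts):
        df = toy_counts.counts
        nf = expression.tmm_factors(df)
        rng = np.random.default_rng(1)
        rows = rng.permutation(df.index)
        cols = rng.permutation(df.columns)
        nf2 = expression.tmm_factors(df.loc[rows, cols])
        assert np.allclose(nf.factors[cols].to_numpy(), nf2.factors.to_numpy(),
                           atol=1e-12)

    def test_disjoint_sample_raises(self):
        df = pd.DataFrame({"a": [5, 0, 9, 0], "b": [4, 0, 7, 0], "c": [0, 3, 0, 8]})
        with pytest.raises(ValueError, match="c"):
            expression.tmm_factors(df)


class TestNormalize:
    def test_cpm_arithmetic(self):
        df = pd.DataFrame({"a": [100, 999900], "b": [100, 999900]})
        nf = expression.tmm_factors(df)
        norm = expression.normalize_tmm(df, nf)
        assert norm.iloc[0, 0] == pytest.approx(100.0)

    def test_global_doubling_is_invariant(self, toy_counts):
        df = toy_counts.counts
        n1 = expression.normalize_tmm(df, expression.tmm_factors(df))
        n2 = expression.normalize_tmm(2 * df, expression.tmm_factors(2 * df))
        assert np.allclose(n1.to_numpy(), n2.to_numpy())

    def test_column_sums_are_one_million_for_unit_factors(self):
        col = np.array([5, 10, 200, 3, 80])
        df = pd.DataFrame({"a": col, "b": col})
        norm = expression.normalize_tmm(df, expression.tmm_factors(df))
        assert np.allclose(norm.sum(axis=0), 1e6)

    def test_missing_factor_raises(self, toy_counts):
        nf = expression.tmm_factors(toy_counts.counts.iloc[:, :4])
        with pytest.raises(ValueError):
            expression.normalize_tmm(toy_counts.counts, nf)


class TestBHFDR:
    def test_step_up_values(self):
        assert np.allclose(expression.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_equal_and_singleton(self):
        assert np.allclose(expression.bh_fdr([0.2, 0.2, 0.2, 0.2]), 0.2)
        assert np.allclose(expression.bh_fdr([0.07]), [0.07])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            expression.bh_fdr([0.5, 1.2])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        p = rng.uniform(size=200)
        assert np.allclose(expression.bh_fdr(p),
                           multipletests(p, method="fdr_bh")[1])


class TestDETest:
    def test_all_zero_transcript(self):
        mat = np.zeros((3, 8), dtype=int)
        mat[0] = [50, 60, 55, 45, 52, 58, 49, 51]
        mat[2] = [400, 420, 390, 410, 100, 95, 105, 99]
        tab = expression.de_test(_matrix(mat)).set_index("transcript_id")
        assert tab.loc["t1", "log2fc"] == 0.0
        assert tab.loc["t1", "pvalue"] == 1.0

    def test_fourfold_change_low_noise(self):
        """HS mean 400 vs NHS mean 100 at tiny dispersion: log2FC -> 2."""
        rng = np.random.default_rng(3)
        base = rng.lognormal(5, 0.5, 300)
        n = 1.0 / 1e-6
        hs = np.column_stack([rng.negative_binomial(n, n / (n + base)) for _ in range(4)])
        nhs = hs.copy()
        gene_hs = np.array([rng.negative_binomial(n, n / (n + 400)) for _ in range(4)])
        gene_nhs = np.array([rng.negative_binomial(n, n / (n + 100)) for _ in range(4)])
        mat = np.vstack([np.concatenate([gene_hs, gene_nhs])[None, :],
                         np.hstack([hs, nhs])])
        tab = expression.de_test(_matrix(mat)).set_index("transcript_id")
        assert tab.loc["t0", "log2fc"] == pytest.approx(2.0, abs=0.05)
        assert tab.loc["t0", "fdr"] < 1e-6

    def test_null_pvalues_are_uniform(self):
        """Without true effects the caller's p-values pass a KS uniformity
        check over 2000 null genes."""
        spec = simulate.SpeciesSimSpec("x", 45, 1.5, 2000, 1000, 0.5, 0.2,
                                       "reactive", 0, 0.0)
        cats, _ = simulate.simulate_transcriptomes([spec], 1500, 5)
        cm, _ = simulate.simulate_counts(spec, cats["x"], 4, 13)
        p = expression.de_test(cm)["pvalue"].to_numpy()
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestConsensus:
    def _table(self, fcs, fdrs, caller):
        return pd.DataFrame(
            {
                "transcript_id": [f"t{i}" for i in range(len(fcs))],
                "log2fc": fcs,
                "pvalue": fdrs,
                "fdr": fdrs,
                "caller": caller,
            }
        )

    def test_threshold_rules(self):
        a = self._table([2.5, 2.1, 2.5], [1e-4, 5e-4, 1e-6], "A")
        b = self._table([1.4, 2.3, -2.5], [1e-4, 9e-4, 1e-6], "B")
        det = expression.consensus_det(a, b)
        # t0: mean |fc| 1.95 < 2 -> out; t1: in, up; t2: sign conflict -> out
        assert det.transcripts == ["t1"]
        assert det.direction["t1"] == "up_HS"

    def test_self_consensus_with_open_cutoffs(self):
        t = self._table([1.5, -0.7, 0.0, 3.0], [0.9, 0.5, 0.1, 0.2], "A")
        det = expression.consensus_det(t, t, fc_cut=0.0, fdr_cut=1.0)
        assert set(det.transcripts) == {"t0", "t1", "t3"}
        assert det.direction["t1"] == "down_HS"

    def test_partial_table_overlap_is_counted(self):
        a = self._table([2.5], [1e-6], "A")
        b = pd.concat([a.assign(caller="B"),
                       self._table([2.2], [1e-6], "B").assign(transcript_id="u9")])
        det = expression.consensus_det(a, b)
        assert det.n_only_one_table == 1


class TestConsensusRecovery:
    def test_recovers_induced_genes_with_fdr_control(self):
        """Reactive species, 2000 transcripts, 50 stress genes at |log2FC|=3:
        over 20 replicate simulations the two-caller consensus recovers >= 90%
        of the induced genes with a pooled false-discovery proportion <= 5%."""
        spec = simulate.SpeciesSimSpec("x", 45, 1.5, 2000, 1000, 0.5, 0.2,
                                       "reactive", 50, 3.0)
        cats, _ = simulate.simulate_transcriptomes([spec], 1500, 11)
        tp = fp = fn = 0
        for ss in np.random.SeedSequence(11).spawn(20):
            cm, truth = simulate.simulate_counts(spec, cats["x"], 4, ss)
            det = expression.consensus_det(
                expression.de_test(cm), expression.de_test_logcpm(cm)
            )
            true_set = set(truth.index[truth["true_de"]])
            called = set(det.transcripts)
            tp += len(called & true_set)
            fp += len(called - true_set)
            fn += len(true_set - called)
        assert tp / (tp + fn) >= 0.9
        assert fp / max(tp + fp, 1) <= 0.05


class TestHSPPanel:
    def test_substring_matching(self):
        ann = pd.Series({"a": "heat shock protein 70 cognate 4",
                         "b": "HSPA8 homolog", "c": "hsp 90 beta"})
        norm = pd.DataFrame(np.ones((3, 2)), index=list("abc"), columns=["s1", "s2"])
        panel = expression.find_hsp_transcripts(ann, norm)
        assert panel.members["HSP70"] == ["a"]
        assert panel.members["HSP90"] == ["c"]

    def test_top_isoform_is_argmax_of_mean_expression(self):
        tids = [f"h{i}" for i in range(5)]
        ann = pd.Series({t: f"hsp70 isoform {t}" for t in tids})
        rng = np.random.default_rng(21)
        norm = pd.DataFrame(rng.uniform(0, 100, (5, 4)), index=tids,
                            columns=[f"s{i}" for i in range(4)])
        panel = expression.find_hsp_transcripts(ann, norm)
        assert panel.top_isoform["HSP70"] == norm.mean(axis=1).idxmax()

    def test_no_match_warns(self):
        ann = pd.Series({"a": "actin"})
        norm = pd.DataFrame([[1.0]], index=["a"], columns=["s"])
        with pytest.warns(UserWarning):
            panel = expression.find_hsp_transcripts(ann, norm)
        assert panel.top_isoform["HSP70"] is None


class TestProfilesAndStrategies:
    @pytest.mark.parametrize(
        "det,size,pct,profile",
        [
            (53, 38726, 0.14, "weak"),
            (54, 44525, 0.12, "weak"),
            (253, 41912, 0.60, "medium"),
            (698, 45701, 1.53, "medium"),
            (4991, 62416, 8.00, "strong"),
            (10778, 84784, 12.71, "strong"),
        ],
    )
    def test_profile_classification(self, det, size, pct, profile):
        res = expression.classify_profile(det, size)
        assert round(res.det_fraction, 2) == pct
        assert res.profile == profile

    @pytest.mark.parametrize(
        "profile,habitat,hsp,width,expected",
        [
            ("weak", "desert", {"HSP70": False, "HSP90": False}, 2.0, "constitutive"),
            ("medium", "desert", {"HSP70": True, "HSP90": False}, 6.0, "reactive"),
            ("strong", "temperate", {"HSP70": True, "HSP90": True}, 2.0,
             "temperate_like"),
            ("strong", "desert", {"HSP70": False, "HSP90": False}, 2.0,
             "unclassified"),
        ],
    )
    def test_strategy_rules(self, profile, habitat, hsp, width, expected):
        prof = expression.ResponseProfile("sp", 10, 1000, 1.0, profile)
        call = expression.call_strategy(prof, habitat, hsp, width)
        assert call.strategy == expected
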