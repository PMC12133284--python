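"""Pearson metric, secondary-structure and SASA stratification, reports."""

import warnings

import numpy as np
import pandas as pd
import pytest

import indelnet as dn
from indelnet.core_io import MutantKey, ProteinAnnotation
from indelnet.evaluate import SASA_STRATA


def _annotation(ss: str, ratios=None) -> ProteinAnnotation:
    L = len(ss)
    volume = np.full(L, 100.0)
    if ratios is None:
        ratios = np.linspace(0.1, 0.9, L)
    df = pd.DataFrame(
        {"aa": ["A"] * L, "ss": list(ss), "sasa": np.asarray(ratios) * volume,
         "volume": volume},
        index=pd.Index(range(1, L + 1), name="index"),
    )
    return ProteinAnnotation(protein_id="toy", residues=df)


class TestPearson:
    def test_identity_is_one(self):
        x = np.arange(10.0)
        assert dn.pearson(x, x) == pytest.approx(1.0)

    def test_negative_affine_is_minus_one(self):
        x = np.arange(10.0)
        assert dn.pearson(x, -2 * x + 3) == pytest.approx(-1.0)

    def test_matches_closed_form_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        mx, my = x.mean(), y.mean()
        cov = ((x - mx) * (y - my)).mean()
        expected = cov / (x.std() * y.std())
        assert dn.pearson(x, y) == pytest.approx(expected, abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=50), rng.normal(size=50)
        r = dn.pearson(x, y)
        assert dn.pearson(3.5 * x + 2, y) == pytest.approx(r, abs=1e-12)
        assert dn.pearson(x, 0.1 * y - 7) == pytest.approx(r, abs=1e-12)

    def test_zero_variance_warns_and_returns_nan(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            r = dn.pearson(np.ones(5), np.arange(5.0))
        assert np.isnan(r)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            dn.pearson([1.0], [2.0])


class TestSSCategory:
    @pytest.mark.parametrize(
        "p1,p2,helix,sheet",
        [
            (13, 20, False, False),  # both on C -> neither
            (1, 10, True, True),     # H and E
            (1, 20, True, False),    # H and C
            (10, 20, False, True),   # E and C
            (1, 2, True, False),     # both H
        ],
    )
    def test_at_least_one_rule(self, p1, p2, helix, sheet):
        ann = _annotation("HH" + "E" * 10 + "C" * 18)
        cat = dn.ss_category(MutantKey(p1, p2, "A", "A"), ann)
        assert (cat.helix, cat.sheet) == (helix, sheet)
        assert cat.neither == (not helix and not sheet)


class TestSASAPercentiles:
    def test_hand_computed_interpolation(self):
        """Ratios (0,1,2): linear interpolation gives 0.66 and 1.32."""
        ann = _annotation("CCC", ratios=[0.0, 1.0, 2.0])
        p33, p66 = dn.sasa_percentiles(ann)
        assert p33 == pytest.approx(0.66)
        assert p66 == pytest.approx(1.32)

    def test_degenerate_all_equal(self):
        ann = _annotation("CCCC", ratios=[0.5] * 4)
        p33, p66 = dn.sasa_percentiles(ann)
        assert p33 == p66 == 0.5
        # everything is medium -> the only SASA stratum is "other"
        assert dn.sasa_category(MutantKey(1, 3, "A", "A"), ann, (p33, p66)) == "other"

    def test_permutation_invariant(self):
        rng = np.random.default_rng(4)
        ratios = rng.uniform(0.1, 0.9, size=30)
        a = dn.sasa_percentiles(_annotation("C" * 30, ratios=ratios))
        b = dn.sasa_percentiles(_annotation("C" * 30, ratios=ratios[rng.permutation(30)]))
        assert a == pytest.approx(b)


class TestSASACategory:
    @pytest.fixture
    def ann(self):
        return _annotation("C" * 9, ratios=[0.1, 0.1, 0.1, 0.5, 0.5, 0.5, 0.9, 0.9, 0.9])

    def test_both_low(self, ann):
        cuts = dn.sasa_percentiles(ann)
        assert dn.sasa_category(MutantKey(1, 3, "A", "A"), ann, cuts) == "low_low"

    def test_both_high(self, ann):
        cuts = dn.sasa_percentiles(ann)
        assert dn.sasa_category(MutantKey(7, 9, "A", "A"), ann, cuts) == "high_high"

    @pytest.mark.parametrize("p1,p2", [(1, 9), (1, 5), (4, 8), (4, 6)])
    def test_mixed_is_other(self, ann, p1, p2):
        cuts = dn.sasa_percentiles(ann)
        assert dn.sasa_category(MutantKey(p1, p2, "A", "A"), ann, cuts) == "other"

    def test_vectorized_labels_match_scalar(self, small_benchmark):
        ann, _, raw = small_benchmark
        keys = raw.key_frame().head(200)
        cats = dn.categorize_keys(keys, ann)
        cuts = dn.sasa_percentiles(ann)
        for i, row in keys.iterrows():
            key = MutantKey(row.p1, row.p2, row.a1, row.a2)
            assert cats.loc[i, "sasa"] == dn.sasa_category(key, ann, cuts)
            sc = dn.ss_category(key, ann)
            assert cats.loc[i, "helix"] == sc.helix
            assert cats.loc[i, "sheet"] == sc.sheet
            assert cats.loc[i, "neither"] == sc.neither


class TestStratumAlgebra:
    def test_ss_cover_and_neither_disjoint(self, small_benchmark):
        ann, _, raw = small_benchmark
        cats = dn.categorize_keys(raw.key_frame(), ann)
        covered = cats["helix"] | cats["sheet"] | cats["neither"]
        assert covered.all()
        assert not (cats["neither"] & (cats["helix"] | cats["sheet"])).any()

    def test_sasa_partition(self, small_benchmark):
        ann, _, raw = small_benchmark
        cats = dn.categorize_keys(raw.key_frame(), ann)
        counts = cats["sasa"].value_counts()
        assert counts.sum() == len(cats)
        assert set(counts.index) <= set(SASA_STRATA)


class TestEvaluateReport:
    @pytest.fixture(scope="class")
    def perfect_setup(self, normalized_small, small_splits, small_benchmark):
        """A dataset whose targets are the model's own predictions, so every
        correlation is exactly 1."""
        ann, _, _ = small_benchmark
        dataset, _ = normalized_small
        state = dn.initialize(
            dn.ModelConfig(position_vocab=40, embedding_dim=8), seed=3
        )
        preds = dn.predict(state, dataset.key_frame())
        df = dataset.key_frame()
        for j, s in enumerate(state.score_names):
            df[s] = preds[:, j]
        perfect = dn.MutantDataset(scores=df, normalized=True)
        return state, perfect, ann

    def test_perfect_predictions_give_r_one(self, perfect_setup, small_splits):
        state, perfect, ann = perfect_setup
        report = dn.evaluate(state, perfect, small_splits, ann)
        assert (report["r"].dropna() > 0.999999).all()

    def test_report_schema(self, perfect_setup, small_splits):
        state, perfect, ann = perfect_setup
        report = dn.evaluate(state, perfect, small_splits, ann)
        overall = report[report["stratum"] == "all"]
        assert set(overall["split"]) == {"train", "val", "test1", "test2", "test3"}
        for split in set(overall["split"]):
            assert list(overall[overall["split"] == split]["score"]) == list(
                dn.RETAINED_SCORES
            )
        strata = set(report.loc[report["split"] == "test1", "stratum"])
        assert {"all", "helix", "sheet", "neither", "low_low", "high_high", "other"} <= strata

    def test_stratified_r_matches_subset_oracle(
        self, normalized_small, small_splits, small_benchmark
    ):
        """Per-stratum r equals recomputing Pearson on independently
        re-derived stratum subsets."""
        ann, _, _ = small_benchmark
        dataset, _ = normalized_small
        state = dn.initialize(dn.ModelConfig(position_vocab=40, embedding_dim=8), seed=7)
        report = dn.evaluate(state, dataset, small_splits, ann)
        keys = small_splits.test1
        merged = keys.merge(dataset.scores, on=["p1", "p2", "a1", "a2"])
        preds = dn.predict(state, keys)
        cats = dn.categorize_keys(keys, ann)
        for stratum, mask in [
            ("sheet", cats["sheet"].to_numpy()),
            ("low_low", (cats["sasa"] == "low_low").to_numpy()),
        ]:
            if mask.sum() < 2:
                continue
            for score in ("fa_atr", "ref"):
                j = list(state.score_names).index(score)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    expected = dn.pearson(
                        preds[mask, j], merged.loc[mask, score].to_numpy()
                    )
                got = report[
                    (report["split"] == "test1")
                    & (report["stratum"] == stratum)
                    & (report["score"] == score)
                ]["r"].iloc[0]
                assert got == pytest.approx(expected, abs=1e-12, nan_ok=True)
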