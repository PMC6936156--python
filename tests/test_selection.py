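import numpy as np
import pandas as pd
import pytest

from peis import (
    DataError,
    align_pairs,
    finalize_scores,
    find_neighbors,
    influence_ratio,
    score_all_sites,
    select_f_and_t,
    select_top,
    select_ttest_only,
    simulate_cohort,
)


def make_annotation(positions, chrom="chr1"):
    if isinstance(positions, dict):
        items = list(positions.items())
    else:
        items = [(f"cg{i}", p) for i, p in enumerate(positions)]
    return pd.DataFrame(
        {
            "chromosome": [chrom if not isinstance(p, tuple) else p[0] for _, p in items],
            "position": [p if not isinstance(p, tuple) else p[1] for _, p in items],
        },
        index=pd.Index([s for s, _ in items], name="site_id"),
    )


def make_signals(scores: dict, signs: dict | None = None) -> pd.DataFrame:
    ids = list(scores)
    s = np.array([scores[i] for i in ids], dtype=float)
    return pd.DataFrame(
        {
            "score": s,
            "sign": [signs[i] if signs else (1 if scores[i] >= 0 else -1) for i in ids],
            "testable": ~np.isnan(s),
        },
        index=pd.Index(ids, name="site_id"),
    )


class TestInfluenceRatio:
    @pytest.mark.parametrize("d, expected", [(500, 0.5), (1, 0.999), (999, 0.001)])
    def test_linear_decay(self, d, expected):
        assert influence_ratio(d) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("d", [0, -5, 1000, 1500])
    def test_outside_strict_window_errors(self, d):
        with pytest.raises(ValueError):
            influence_ratio(d)

    def test_strictly_decreasing_over_window(self):
        ds = np.arange(1, 1000)
        alphas = np.array([influence_ratio(d) for d in ds])
        assert np.all(np.diff(alphas) < 0)
        assert np.all((alphas > 0) & (alphas < 1))


class TestFindNeighbors:
    def test_distance_arithmetic_and_window(self):
        annot = make_annotation({"focal": 5000, "a": 4600, "b": 5300, "c": 6100})
        hits = find_neighbors(annot, "focal")
        assert [(h.neighbor_site_id, h.distance) for h in hits] == [("b", 300), ("a", 400)]
        assert hits[0].alpha == pytest.approx(0.7)

    def test_lonely_chromosome_has_no_neighbors(self):
        annot = make_annotation({"focal": ("chr1", 5000), "other": ("chr2", 5100)})
        assert find_neighbors(annot, "focal") == []

    def test_equidistant_tie_broken_by_position(self):
        annot = make_annotation({"focal": 5000, "lo": 4800, "hi": 5200})
        hits = find_neighbors(annot, "focal")
        assert [h.neighbor_site_id for h in hits] == ["lo", "hi"]
        assert all(h.distance == 200 for h in hits)

    def test_unannotated_site_errors(self):
        annot = make_annotation({"a": 100})
        with pytest.raises(DataError, match="ghost"):
            find_neighbors(annot, "ghost")

    def test_eligible_restriction(self):
        annot = make_annotation({"focal": 5000, "a": 5100, "b": 5250, "c": 5400})
        hits = find_neighbors(annot, "focal", eligible={"b", "c"})
        assert [h.neighbor_site_id for h in hits] == ["b", "c"]


class TestFinalizeScores:
    def test_two_neighbor_hand_example(self):
        annot = make_annotation({"i": 10_000, "n1": 10_100, "n2": 10_400})
        signals = make_signals({"i": 10.0, "n1": 2.0, "n2": 5.0})
        final = finalize_scores(signals, annot)
        # f = 10 + 0.9*2 + 0.6*5 = 14.8
        assert final.loc["i", "final_score"] == pytest.approx(14.8, abs=1e-12)
        assert final.loc["i", "n_neighbors"] == 2

    def test_isolated_site_keeps_base_score(self):
        annot = make_annotation({"i": 10_000, "far": 50_000})
        final = finalize_scores(make_signals({"i": 7.0, "far": 3.0}), annot)
        assert final.loc["i", "final_score"] == 7.0

    def test_hypo_neighbor_contributes_negatively(self):
        annot = make_annotation({"i": 10_000, "n": 10_500})
        final = finalize_scores(make_signals({"i": 10.0, "n": -6.0}), annot)
        # f = 10 + 0.5 * (-6) = 7
        assert final.loc["i", "final_score"] == pytest.approx(7.0, abs=1e-12)

    def test_site_at_exactly_window_distance_excluded(self):
        annot = make_annotation({"i": 10_000, "edge": 11_000})
        final = finalize_scores(make_signals({"i": 4.0, "edge": 9.0}), annot)
        assert final.loc["i", "final_score"] == 4.0
        assert final.loc["i", "n_neighbors"] == 0

    def test_untestable_sites_neither_scored_nor_donating(self):
        annot = make_annotation({"i": 10_000, "dead": 10_200, "ok": 10_600})
        signals = make_signals({"i": 5.0, "dead": np.nan, "ok": 2.0})
        final = finalize_scores(signals, annot)
        assert "dead" not in final.index
        # only `ok` (d = 600) contributes: 5 + 0.4*2
        assert final.loc["i", "final_score"] == pytest.approx(5.8, abs=1e-12)

    def test_all_in_window_mode_sums_every_neighbor(self):
        annot = make_annotation({"i": 10_000, "a": 10_100, "b": 10_300, "c": 10_600})
        signals = make_signals({"i": 1.0, "a": 1.0, "b": 1.0, "c": 1.0})
        two = finalize_scores(signals, annot)
        allw = finalize_scores(signals, annot, neighbor_mode="all_in_window")
        assert two.loc["i", "n_neighbors"] == 2
        assert allw.loc["i", "n_neighbors"] == 3
        assert allw.loc["i", "final_score"] == pytest.approx(1 + 0.9 + 0.7 + 0.4)

    def test_clustered_site_outranks_equal_isolated_site(self):
        annot = make_annotation({"iso": 100_000, "clu": 200_000, "buddy": 200_300})
        signals = make_signals({"iso": 8.0, "clu": 8.0, "buddy": 8.0})
        final = finalize_scores(signals, annot)
        assert abs(final.loc["clu", "final_score"]) > abs(final.loc["iso", "final_score"])

    def test_matches_brute_force_all_pairs_oracle(self, rng):
        n = 200
        chroms = rng.choice(["chr1", "chr2"], n)
        positions = rng.integers(1, 60_000, n)
        ids = [f"cg{i}" for i in range(n)]
        annot = pd.DataFrame(
            {"chromosome": chroms, "position": positions},
            index=pd.Index(ids, name="site_id"),
        )
        scores = rng.normal(0, 5, n)
        scores[rng.uniform(size=n) < 0.2] = np.nan  # untestable
        signals = make_signals(dict(zip(ids, scores)))

        final = finalize_scores(signals, annot)

        testable = signals["testable"]
        for sid in final.index:
            c, p = annot.loc[sid, "chromosome"], annot.loc[sid, "position"]
            cands = []
            for other in annot.index:
                if other == sid or not testable[other]:
                    continue
                if annot.loc[other, "chromosome"] != c:
                    continue
                d = abs(int(annot.loc[other, "position"]) - int(p))
                if 0 < d < 1000:
                    cands.append((d, int(annot.loc[other, "position"]), other))
            cands.sort()
            expected = signals.loc[sid, "score"] + sum(
                (1 - d / 1000) * signals.loc[other, "score"]
                for d, _, other in cands[:2]
            )
            assert final.loc[sid, "final_score"] == expected


class TestSelectTop:
    @pytest.fixture()
    def final(self, rng):
        n = 50
        return pd.DataFrame(
            {
                "chromosome": rng.choice(["chr1", "chr2"], n),
                "position": rng.integers(1, 10_000, n),
                "final_score": rng.normal(0, 5, n),
                "sign": rng.choice([1, -1], n),
            },
            index=pd.Index([f"cg{i}" for i in range(n)], name="site_id"),
        )

    def test_size_is_min_k_n(self, final):
        assert len(select_top(final, k=10)) == 10
        assert len(select_top(final, k=1000)) == 50

    def test_absolute_ranking_keeps_hypo_sites(self, final):
        final.loc[:, "final_score"] = np.linspace(-10, 5, len(final))
        final.loc[:, "sign"] = np.where(final["final_score"] > 0, 1, -1)
        top = select_top(final, k=5)
        assert (top["direction"] == "hypo").all()  # the -10..-8 magnitudes win

    def test_signed_ranking_orders_descending(self, final):
        top = select_top(final, k=10, ranking="signed")
        assert (np.diff(top["score"]) <= 0).all()

    def test_tie_broken_by_genomic_coordinate(self):
        final = pd.DataFrame(
            {
                "chromosome": ["chr2", "chr1", "chr1"],
                "position": [100, 900, 200],
                "final_score": [3.0, -3.0, 3.0],
                "sign": [1, -1, 1],
            },
            index=pd.Index(["x", "y", "z"], name="site_id"),
        )
        top = select_top(final, k=3)
        assert list(top.index) == ["z", "y", "x"]

    def test_invalid_k_errors(self, final):
        with pytest.raises(ValueError):
            select_top(final, k=0)

    def test_direction_from_base_sign(self, final):
        top = select_top(final, k=50)
        assert (top["direction"] == np.where(final.loc[top.index, "sign"] > 0,
                                             "hyper", "hypo")).all()


@pytest.fixture(scope="module")
def cohort():
    return simulate_cohort(
        n_patients=15, n_sites=800, n_informative_hyper=60,
        n_informative_hypo=60, seed=23,
    )


@pytest.fixture(scope="module")
def paired(cohort):
    return align_pairs(cohort.beta, cohort.design)


class TestBaselineSelectors:
    def test_smallest_p_ranked_first(self, cohort, paired):
        top = select_ttest_only(paired, cohort.annotation, k=100)
        assert (np.diff(top["score"]) >= 0).all()  # score column = p_mean
        signals = score_all_sites(paired)
        assert top["score"].iloc[0] == signals["p_mean"].min()

    def test_k_equal_n_returns_all_usable(self, cohort, paired):
        signals = score_all_sites(paired)
        n_usable = signals["p_mean"].notna().sum()
        top = select_ttest_only(paired, cohort.annotation, k=len(signals))
        assert len(top) == n_usable

    def test_f_filter_excludes_failing_sites(self, cohort, paired):
        signals = score_all_sites(paired)
        top = select_f_and_t(paired, cohort.annotation, k=10_000, p_threshold=0.05)
        assert (signals.loc[top.index, "p_var"] < 0.05).all()

    def test_threshold_one_reduces_to_ttest_only(self, cohort, paired):
        a = select_ttest_only(paired, cohort.annotation, k=100)
        b = select_f_and_t(paired, cohort.annotation, k=100, p_threshold=1.1)
        assert list(a.index) == list(b.index)

    def test_no_survivors_errors(self, cohort, paired):
        with pytest.raises(DataError):
            select_f_and_t(paired, cohort.annotation, k=10, p_threshold=1e-300)
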