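import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from pathprints.sras import (
    Signature,
    differential_signature,
    intersect_signatures,
    kaplan_meier_curves,
    logrank_test,
    permutation_background,
    read_signature,
    sras_score,
    stratify_two_groups,
    write_signature,
)
from conftest import random_ternary_prints


def hand_logrank(times_a, events_a, times_b, events_b):
    """Independent oracle: the textbook hypergeometric tally, explicit loops."""
    records = [(t, e, "A") for t, e in zip(times_a, events_a)] + [
        (t, e, "B") for t, e in zip(times_b, events_b)
    ]
    event_times = sorted({t for t, e, _ in records if e == 1})
    o_a = e_a = v = 0.0
    for t in event_times:
        n = sum(1 for tt, _, _ in records if tt >= t)
        n_a = sum(1 for tt, _, g in records if tt >= t and g == "A")
        d = sum(1 for tt, ee, _ in records if tt == t and ee == 1)
        d_a = sum(1 for tt, ee, g in records if tt == t and ee == 1 and g == "A")
        o_a += d_a
        e_a += d * n_a / n
        if n > 1:
            v += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    stat = (o_a - e_a) ** 2 / v
    return stat, float(chi2.sf(stat, 1))


def _grouped_prints(lsc, hsc, prog):
    """Prints whose per-group columns are constant copies of the given vectors."""
    cols, groups = {}, {}
    for name, vec in (("leukemic_stem", lsc), ("normal_stem", hsc), ("progenitor", prog)):
        for i in range(4):
            sid = f"{name}_{i}"
            cols[sid] = vec
            groups[sid] = name
    prints = pd.DataFrame(cols, index=[f"PW{i}" for i in range(len(lsc))]).astype(int)
    return prints, pd.Series(groups)


class TestDifferentialSignature:
    def test_rule_application(self):
        # per pathway (LSC, HSC, progenitor) consensus:
        # PW0 (+1,+1,0) -> included +1; PW1 (+1,-1,0) -> stem disagreement;
        # PW2 (+1,+1,+1) -> not differential; PW3 (-1,-1,+1) -> included -1
        prints, groups = _grouped_prints(
            lsc=[1, 1, 1, -1], hsc=[1, -1, 1, -1], prog=[0, 0, 1, 1]
        )
        sig = differential_signature(prints, groups, t_cons=0.75)
        assert sig.pathways == ["PW0", "PW3"]
        assert sig.signs == [1, -1]

    def test_symmetric_in_stem_groups(self):
        prints, groups = _grouped_prints(
            lsc=[1, 0, -1, 1], hsc=[1, 1, -1, 0], prog=[0, 1, 0, 0]
        )
        swapped = groups.map(
            {"leukemic_stem": "normal_stem", "normal_stem": "leukemic_stem",
             "progenitor": "progenitor"}
        )
        a = differential_signature(prints, groups)
        b = differential_signature(prints, swapped)
        assert a.pathways == b.pathways and a.signs == b.signs

    def test_empty_result_warns_not_errors(self):
        prints, groups = _grouped_prints(lsc=[1, 0], hsc=[0, 1], prog=[0, 0])
        with pytest.warns(UserWarning, match="empty"):
            sig = differential_signature(prints, groups)
        assert len(sig) == 0

    def test_missing_group_rejected(self):
        prints, groups = _grouped_prints(lsc=[1], hsc=[1], prog=[0])
        bad = groups[groups != "progenitor"]
        with pytest.raises(ValueError, match="progenitor"):
            differential_signature(prints[bad.index], bad)


class TestIntersectSignatures:
    def test_common_pathways_with_matching_signs(self):
        a = Signature(["P1", "P2"], [1, -1])
        b = Signature(["P2", "P3"], [-1, 1])
        out = intersect_signatures(a, b)
        assert out.pathways == ["P2"] and out.signs == [-1]

    def test_sign_conflict_excluded(self):
        a = Signature(["P1"], [1])
        b = Signature(["P1"], [-1])
        assert len(intersect_signatures(a, b)) == 0

    def test_idempotent(self):
        a = Signature(["P1", "P2", "P3"], [1, -1, 1])
        out = intersect_signatures(a, a)
        assert out.pathways == a.pathways and out.signs == a.signs


class TestSrasScore:
    def _vec(self, vals):
        return pd.Series(vals, index=[f"PW{i}" for i in range(len(vals))])

    def test_plain_sum(self):
        sig = Signature([f"PW{i}" for i in range(4)], [1, 1, 1, 1])
        assert sras_score(self._vec([1, 1, 0, -1]), sig) == 1

    def test_zero_vector_scores_zero(self):
        sig = Signature(["PW0", "PW1"], [1, -1])
        assert sras_score(self._vec([0, 0]), sig) == 0

    def test_bounds_attained(self):
        sig = Signature([f"PW{i}" for i in range(3)], [1, 1, 1])
        assert sras_score(self._vec([1, 1, 1]), sig) == 3
        assert sras_score(self._vec([-1, -1, -1]), sig) == -3

    def test_additive_over_disjoint_signatures(self):
        v = self._vec([1, -1, 0, 1, 1])
        a = Signature(["PW0", "PW1"], [1, 1])
        b = Signature(["PW3", "PW4"], [1, -1])
        ab = Signature(a.pathways + b.pathways, a.signs + b.signs)
        assert sras_score(v, ab) == sras_score(v, a) + sras_score(v, b)

    def test_sign_weighted_variant(self):
        sig = Signature(["PW0", "PW1"], [1, -1])
        assert sras_score(self._vec([1, -1]), sig, sign_weighted=True) == 2

    def test_matrix_input_gives_per_sample_series(self):
        prints = pd.DataFrame({"s1": [1, 1], "s2": [-1, 0]}, index=["PW0", "PW1"])
        sig = Signature(["PW0", "PW1"], [1, 1])
        out = sras_score(prints, sig)
        assert out.to_dict() == {"s1": 2, "s2": -1}

    def test_missing_pathway_rejected(self):
        sig = Signature(["PWX"], [1])
        with pytest.raises(ValueError, match="PWX"):
            sras_score(self._vec([1]), sig)


def brute_force_two_means(vals):
    """Oracle: evaluate every positional split of the sorted vector."""
    order = np.argsort(vals, kind="mergesort")
    x = np.asarray(vals, dtype=float)[order]
    best_k, best_wss = None, np.inf
    for k in range(1, len(x)):
        lo, hi = x[:k], x[k:]
        wss = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if wss < best_wss - 1e-12:
            best_wss, best_k = wss, k
    labels = np.empty(len(x), dtype=object)
    labels[order[:best_k]] = "low"
    labels[order[best_k:]] = "high"
    return labels


class TestStratifyTwoGroups:
    def test_obvious_optimum(self):
        s = pd.Series([0, 0, 0, 4, 4, 4], index=list("abcdef"))
        out = stratify_two_groups(s)
        assert (out[["a", "b", "c"]] == "low").all()
        assert (out[["d", "e", "f"]] == "high").all()

    def test_matches_exhaustive_oracle_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            vals = rng.integers(-8, 9, size=n)
            if np.unique(vals).size < 2:
                continue
            s = pd.Series(vals, index=[f"s{i}" for i in range(n)])
            got = stratify_two_groups(s).to_numpy()
            expected = brute_force_two_means(vals)
            assert (got == expected).all()

    def test_high_group_has_larger_mean(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            vals = rng.normal(size=15)
            s = pd.Series(vals, index=[f"s{i}" for i in range(15)])
            out = stratify_two_groups(s)
            assert s[out == "high"].mean() > s[out == "low"].mean()

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            stratify_two_groups(pd.Series([2, 2, 2]))


def _surv(ids, times, events):
    return pd.DataFrame({"sample_id": ids, "time": times, "event": events})


class TestLogrank:
    def test_identical_groups_give_null_result(self):
        surv = _surv([f"s{i}" for i in range(6)], [1, 2, 3, 1, 2, 3], [1, 1, 0, 1, 1, 0])
        groups = pd.Series(
            ["high"] * 3 + ["low"] * 3, index=[f"s{i}" for i in range(6)]
        )
        res = logrank_test(groups, surv)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hand_hypergeometric_tally(self):
        # group A (high) dies at 1,2,3; group B (low) at 4,5,6 -- all events
        stat, p = hand_logrank([1, 2, 3], [1, 1, 1], [4, 5, 6], [1, 1, 1])
        assert stat == pytest.approx(5.0516605, abs=1e-6)  # frozen from the tally
        surv = _surv(["a1", "a2", "a3", "b1", "b2", "b3"], [1, 2, 3, 4, 5, 6], [1] * 6)
        groups = pd.Series(["high"] * 3 + ["low"] * 3, index=surv["sample_id"])
        res = logrank_test(groups, surv)
        assert res.statistic == pytest.approx(stat, rel=1e-9)
        assert res.p_value == pytest.approx(p, rel=1e-9)

    def test_invariant_under_label_swap(self):
        surv = _surv([f"s{i}" for i in range(8)], [1, 3, 2, 8, 5, 4, 9, 7],
                     [1, 1, 0, 1, 1, 1, 0, 1])
        g = pd.Series(["high", "low"] * 4, index=surv["sample_id"])
        swapped = g.map({"high": "low", "low": "high"})
        assert logrank_test(g, surv).p_value == pytest.approx(
            logrank_test(swapped, surv).p_value
        )

    def test_zero_events_rejected(self):
        surv = _surv(["a", "b"], [1, 2], [0, 0])
        g = pd.Series(["high", "low"], index=["a", "b"])
        with pytest.raises(ValueError, match="events"):
            logrank_test(g, surv)

    def test_km_curves_start_at_one_and_decrease(self):
        surv = _surv([f"s{i}" for i in range(6)], [1, 2, 3, 4, 5, 6], [1] * 6)
        g = pd.Series(["high"] * 3 + ["low"] * 3, index=surv["sample_id"])
        km = kaplan_meier_curves(g, surv)
        for _, grp in km.groupby("group"):
            vals = grp.sort_values("time")["survival"].to_numpy()
            assert vals[0] == 1.0
            assert (np.diff(vals) <= 1e-12).all()


class TestPermutationBackground:
    def test_bit_identical_under_fixed_seed(self):
        rng = np.random.default_rng(31)
        prints = random_ternary_prints(rng, 30, 40)
        from pathprints.synthetic import make_survival

        surv = make_survival(prints.iloc[:5].sum(axis=0), beta=0.0, seed=1)
        a = permutation_background(prints, surv, sig_size=5, n_perm=10, seed=2)
        b = permutation_background(prints, surv, sig_size=5, n_perm=10, seed=2)
        assert np.array_equal(a.p_values, b.p_values)
        assert a.n_skipped == b.n_skipped

    def test_degenerate_permutations_skipped_and_counted(self):
        # all-zero prints make every permutation score constant -> all skipped
        prints = pd.DataFrame(
            0, index=[f"PW{i}" for i in range(10)], columns=[f"s{i}" for i in range(20)]
        )
        surv = _surv([f"s{i}" for i in range(20)], np.arange(1.0, 21.0), [1] * 20)
        res = permutation_background(prints, surv, sig_size=3, n_perm=5, seed=0)
        assert res.n_skipped == 5
        assert len(res.p_values) == 0

    def test_oversized_signature_rejected(self):
        prints = pd.DataFrame(
            1, index=["PW0"], columns=["s0", "s1"]
        )
        with pytest.raises(ValueError, match="sig_size"):
            permutation_background(prints, _surv(["s0", "s1"], [1, 2], [1, 1]), sig_size=2)


class TestSignatureIO:
    def test_round_trip(self, tmp_path):
        sig = Signature(["P1", "P2", "P3"], [1, -1, 1])
        write_signature(sig, tmp_path / "sig.tsv")
        back = read_signature(tmp_path / "sig.tsv")
        assert back.pathways == sig.pathways and back.signs == sig.signs
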