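import numpy as np
import pandas as pd
import pytest

from senescan.gating import (
    Gate,
    GatingError,
    apply_gates,
    area_by_gate,
    percent_positive,
    singlet_gate_bf,
    singlet_gate_dapi,
    summarize_percent,
    threshold_from_control,
    two_sample_test,
)


def _table(**cols):
    n = len(next(iter(cols.values())))
    cols.setdefault("cell_id", [f"c{i}" for i in range(n)])
    cols.setdefault("sample_id", ["s"] * n)
    return pd.DataFrame(cols)


class TestControlThreshold:
    def test_quantile_cutoff_linear_interpolation(self):
        """Control 1..100 at q=0.99 'above' puts the cutoff at 99.01 and
        marks ~1% of its own values positive."""
        g = threshold_from_control(np.arange(1.0, 101.0), "above", 0.99)
        assert g.cutoff == pytest.approx(99.01)
        assert np.mean(np.arange(1.0, 101.0) > g.cutoff) == pytest.approx(0.01)

    def test_symmetric_distribution_symmetric_capture(self, rng):
        vals = rng.normal(0, 1, 2001)
        vals = np.concatenate([vals, -vals])  # exactly symmetric
        lo = threshold_from_control(vals, "below", 0.05)
        hi = threshold_from_control(vals, "above", 0.95)
        assert np.mean(vals < lo.cutoff) == pytest.approx(np.mean(vals > hi.cutoff))

    def test_default_quantiles_by_direction(self, rng):
        vals = rng.normal(0, 1, 500)
        assert threshold_from_control(vals, "below").cutoff == pytest.approx(
            np.quantile(vals, 0.01)
        )
        assert threshold_from_control(vals, "above").cutoff == pytest.approx(
            np.quantile(vals, 0.99)
        )

    def test_shifted_population_falls_below_cutoff(self, rng):
        """A population shifted -5 sigma from the control is almost entirely
        below the 1% control cutoff."""
        control = rng.normal(0, 1, 1000)
        shifted = rng.normal(-5, 1, 1000)
        g = threshold_from_control(control, "below", 0.01)
        assert np.mean(shifted < g.cutoff) >= 0.95

    def test_requires_enough_finite_controls(self):
        with pytest.raises(GatingError, match="50"):
            threshold_from_control(np.arange(10.0), "above")
        with pytest.raises(GatingError, match="finite"):
            threshold_from_control([np.nan] * 60, "above")


class TestApplyGates:
    def test_simple_threshold_membership_count(self):
        t = _table(x=[1.0] * 9 + [100.0])
        res = apply_gates(t, [Gate("g", "threshold", feature="x", direction="below", cutoff=50)])
        assert res.membership["g"].sum() == 9

    def test_boolean_truth_table(self):
        """SA+ AND NOT HMGB1+ over the four marker combinations."""
        t = _table(sa=[1.0, 1.0, 0.0, 0.0], h=[1.0, 0.0, 1.0, 0.0])
        gates = [
            Gate("sa_pos", "threshold", feature="sa", direction="above", cutoff=0.5),
            Gate("h_pos", "threshold", feature="h", direction="above", cutoff=0.5),
            Gate("h_neg", "boolean", op="NOT", gates=("h_pos",)),
            Gate("senescent", "boolean", op="AND", gates=("sa_pos", "h_neg")),
        ]
        res = apply_gates(t, gates)
        assert res.membership["senescent"].tolist() == [False, True, False, False]

    def test_random_tree_matches_bruteforce(self, rng):
        """Vectorized evaluation equals a per-cell interpreter on a random
        gate tree."""
        n = 200
        t = _table(
            a=rng.normal(size=n), b=rng.normal(size=n), c=rng.uniform(0, 1, n)
        )
        gates = [
            Gate("g0", "threshold", feature="a", direction="above", cutoff=0.0),
            Gate("g1", "interval", parent="g0", feature="b", lo=-1.0, hi=1.0),
            Gate("g2", "rect2d", feature_x="a", feature_y="c", box=(-0.5, 2.0, 0.2, 0.9)),
            Gate("g3", "boolean", op="OR", gates=("g1", "g2")),
            Gate("g4", "boolean", parent="g0", op="AND", gates=("g3", "g2")),
            Gate("g5", "boolean", op="NOT", gates=("g4",)),
        ]
        res = apply_gates(t, gates)

        def brute(row):
            out = {}
            out["g0"] = row.a > 0.0
            out["g1"] = out["g0"] and (-1.0 <= row.b <= 1.0)
            out["g2"] = (-0.5 <= row.a <= 2.0) and (0.2 <= row.c <= 0.9)
            out["g3"] = out["g1"] or out["g2"]
            out["g4"] = out["g0"] and (out["g3"] and out["g2"])
            out["g5"] = not out["g4"]
            return out

        for i, row in enumerate(t.itertuples()):
            expect = brute(row)
            for g in expect:
                assert bool(res.membership[g].iloc[i]) == expect[g], (i, g)

    def test_hierarchy_containment_invariant(self, rng):
        n = 300
        t = _table(a=rng.normal(size=n), b=rng.normal(size=n))
        gates = [
            Gate("p", "threshold", feature="a", direction="above", cutoff=-0.5),
            Gate("c1", "threshold", parent="p", feature="b", direction="below", cutoff=0.3),
            Gate("c2", "boolean", parent="c1", op="NOT", gates=("p",)),
        ]
        res = apply_gates(t, gates)
        assert not (res.membership["c1"] & ~res.membership["p"]).any()
        assert not (res.membership["c2"] & ~res.membership["c1"]).any()

    def test_missing_features_fall_into_ungated_tally(self):
        t = _table(x=[1.0, np.nan, 3.0, np.nan])
        res = apply_gates(t, [Gate("g", "threshold", feature="x", direction="above", cutoff=0.0)])
        assert res.membership["g"].tolist() == [True, False, True, False]
        assert res.ungated["g"] == 2

    def test_invalid_trees_rejected_before_evaluation(self):
        t = _table(x=[1.0])
        with pytest.raises(GatingError, match="unknown feature"):
            apply_gates(t, [Gate("g", "threshold", feature="nope", direction="above", cutoff=0)])
        with pytest.raises(GatingError, match="not defined earlier"):
            apply_gates(t, [Gate("g", "threshold", parent="later", feature="x",
                                 direction="above", cutoff=0)])
        with pytest.raises(GatingError, match="references undefined"):
            apply_gates(t, [Gate("g", "boolean", op="AND", gates=("ghost",))])
        with pytest.raises(GatingError, match="duplicate"):
            apply_gates(t, [Gate("g", "threshold", feature="x", direction="above", cutoff=0)] * 2)


class TestSingletGates:
    def test_bf_gate_excludes_elongated_doublet_and_giant_debris(self):
        t = _table(
            area_um2=[200.0, 380.0, 9000.0],
            aspect_ratio=[0.95, 0.45, 0.9],  # single disk, tangent doublet, blob
        )
        res = apply_gates(t, [singlet_gate_bf()])
        assert res.membership["singlets"].tolist() == [True, False, False]

    def test_dapi_gate_excludes_double_intensity(self):
        rng = np.random.default_rng(0)
        area = rng.normal(100, 5, 50)
        inten = rng.normal(1e4, 500, 50)
        area[:3], inten[:3] = 200.0, 2.1e4  # doublets: 2x area and intensity
        t = _table(dapi_area_um2=area, dapi_intensity=inten)
        res = apply_gates(t, [singlet_gate_dapi(t)])
        assert res.membership["singlets"].tolist()[:3] == [False, False, False]
        assert res.membership["singlets"].iloc[3:].all()

    def test_anucleate_record_not_gated(self):
        t = _table(dapi_area_um2=[100.0, np.nan], dapi_intensity=[1e4, np.nan])
        res = apply_gates(t, [singlet_gate_dapi(t)])
        assert res.membership["singlets"].tolist() == [True, False]
        assert res.ungated["singlets"] == 1


class TestPopulationStats:
    def test_percent_positive_per_sample(self):
        t = _table(x=[1.0] * 9 + [0.0] + [0.0] * 5, sample_id=["a"] * 10 + ["b"] * 5)
        res = apply_gates(t, [Gate("g", "threshold", feature="x", direction="above", cutoff=0.5)])
        out = percent_positive(res, "g").set_index("sample_id")
        assert out.loc["a", "percent"] == pytest.approx(90.0)
        assert out.loc["b", "percent"] == pytest.approx(0.0)

    def test_sum_rule_positive_plus_negative_is_100(self):
        rng = np.random.default_rng(3)
        t = _table(x=rng.normal(size=50))
        gates = [
            Gate("pos", "threshold", feature="x", direction="above", cutoff=0.1),
            Gate("neg", "boolean", op="NOT", gates=("pos",)),
        ]
        res = apply_gates(t, gates)
        p = percent_positive(res, "pos")["percent"][0]
        n = percent_positive(res, "neg")["percent"][0]
        assert p + n == 100.0

    def test_mean_sem_across_samples(self):
        per_sample = pd.DataFrame({"percent": [80.0, 90.0, 100.0]})
        mean, sem = summarize_percent(per_sample)
        assert mean == pytest.approx(90.0)
        assert sem == pytest.approx(5.7735, abs=1e-4)

    def test_area_by_gate_recovers_injected_shift(self):
        t = _table(
            x=[1.0] * 10 + [0.0] * 10,
            area_um2=[200.0] * 10 + [100.0] * 10,
        )
        res = apply_gates(t, [Gate("g", "threshold", feature="x", direction="above", cutoff=0.5)])
        inside, outside = area_by_gate(t, res, "g")
        assert inside.mean_area_um2 == pytest.approx(200.0)
        assert outside.mean_area_um2 == pytest.approx(100.0)
        assert inside.sem == pytest.approx(0.0)

    def test_area_by_gate_empty_gate_errors(self):
        t = _table(x=[0.0, 0.0], area_um2=[1.0, 2.0])
        res = apply_gates(t, [Gate("g", "threshold", feature="x", direction="above", cutoff=1.0)])
        with pytest.raises(GatingError, match="inside"):
            area_by_gate(t, res, "g")


class TestTwoSampleTest:
    def test_identical_groups_t_zero_p_one(self):
        t, p = two_sample_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_closed_form_value(self):
        t, p = two_sample_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert t == pytest.approx(-1.224744871, abs=1e-6)

    def test_swapping_groups_flips_sign_only(self):
        a, b = [1.0, 5.0, 2.0, 4.0], [3.0, 7.0, 6.0]
        t1, p1 = two_sample_test(a, b)
        t2, p2 = two_sample_test(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_small_groups_rejected(self):
        with pytest.raises(GatingError):
            two_sample_test([1.0], [1.0, 2.0])
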