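"""Density-valley thresholds, gate geometry, classification trees."""

import numpy as np
import pandas as pd
import pytest

from ctcgate.core import (
    LABEL_CTC_STANDARD,
    LABEL_CTC_STRICT,
    LABEL_MYELOID_FP,
    LABEL_WBC,
    ConfigurationError,
    EventTable,
    InsufficientDataError,
    ValidationError,
)
from ctcgate.gating import (
    Gate,
    GatingStrategy,
    ThresholdSet,
    apply_gate,
    classify_standard,
    classify_strict,
    derive_threshold,
    derive_thresholds,
    run_strategy,
)
from ctcgate.synthetic import make_scenario, sample_events

from conftest import make_two_pop_scenario


def events_from(values: dict, sample_id="t") -> EventTable:
    n = len(next(iter(values.values())))
    df = pd.DataFrame({"event_id": np.arange(1, n + 1)})
    base = {"hoechst": 3000.0, "cd45": 10.0, "cd11b": 10.0, "pck": 10.0,
            "pdl1": 10.0, "isotype": 10.0, "capture": 10.0}
    for ch, v in base.items():
        df[ch] = values.get(ch, np.full(n, v))
    return EventTable(sample_id=sample_id, capture_antibody="EpCAM", data=df)


class TestDeriveThreshold:
    def test_cutoff_between_two_point_masses(self):
        values = np.r_[np.ones(100), np.full(100, 10.0)]
        res = derive_threshold(values)
        assert res.ok
        assert 1.0 < res.cutoff < 10.0

    def test_lognormal_mixture_cutoff_and_misclassification(self, rng):
        n = 5000
        labels = rng.random(n) < 0.5
        sig = np.log(1.6)
        values = np.where(labels, 2000.0, 20.0) * np.exp(sig * rng.standard_normal(n))
        res = derive_threshold(values)
        assert res.ok
        assert 100 <= res.cutoff <= 400
        predicted = values >= res.cutoff
        assert (predicted != labels).mean() < 0.01

    def test_unimodal_returns_no_valley(self, rng):
        values = 100.0 * np.exp(0.5 * rng.standard_normal(2000))
        res = derive_threshold(values)
        assert res.status == "no_valley"
        assert res.cutoff is None

    def test_too_few_values_rejected(self):
        with pytest.raises(InsufficientDataError):
            derive_threshold(np.ones(49))

    def test_one_decade_separation_misclassifies_below_2pct(self, rng):
        # planted two-population property at a single decade of separation
        n = 4000
        labels = rng.random(n) < 0.4
        values = np.where(labels, 500.0, 50.0) * np.exp(
            np.log(1.5) * rng.standard_normal(n))
        res = derive_threshold(values)
        assert res.ok
        assert ((values >= res.cutoff) != labels).mean() < 0.02


class TestApplyGate:
    def test_rectangle_boundary_is_inside(self):
        ev = events_from({"cd45": np.array([10.0, 10.1]),
                          "pck": np.array([10.0, 5.0])})
        gate = Gate("box", "cd45", (0, 10, 0, 10), y_axis="pck",
                    kind="rectangle")
        np.testing.assert_array_equal(apply_gate(ev, gate), [True, False])

    def test_threshold_polarity(self):
        ev = events_from({"cd45": np.array([5.0, 7.0, 9.0])})
        gate = Gate("cd45+", "cd45", ("ge", 7.0))
        np.testing.assert_array_equal(apply_gate(ev, gate),
                                      [False, True, True])
        np.testing.assert_array_equal(
            apply_gate(ev, Gate("cd45-", "cd45", ("ge", 7.0), mode="exclude")),
            [True, False, False])

    def test_polygon_matches_ray_casting_oracle(self, rng):
        def ray_cast(poly, px, py):
            inside = False
            n = len(poly)
            for i in range(n):
                x1, y1 = poly[i]
                x2, y2 = poly[(i + 1) % n]
                if (y1 > py) != (y2 > py):
                    xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
                    if px < xint:
                        inside = not inside
            return inside

        for _ in range(5):
            # random star-shaped (hence simple) polygon
            angles = np.sort(rng.uniform(0, 2 * np.pi, size=7))
            radii = rng.uniform(2, 10, size=7)
            poly = [(5 + r * np.cos(a), 5 + r * np.sin(a))
                    for r, a in zip(radii, angles)]
            x = rng.uniform(-6, 16, size=1000)
            y = rng.uniform(-6, 16, size=1000)
            ev = events_from({"cd45": x, "pck": y})
            gate = Gate("poly", "cd45", tuple(poly), y_axis="pck",
                        kind="polygon")
            got = apply_gate(ev, gate)
            expected = np.array([ray_cast(poly, xi, yi) for xi, yi in zip(x, y)])
            assert (got == expected).all()

    def test_missing_axis_rejected(self):
        ev = events_from({"cd45": np.array([1.0])})
        with pytest.raises(ValidationError):
            apply_gate(ev, Gate("bad", "nonexistent", ("ge", 1.0)))

    def test_self_intersecting_polygon_rejected(self):
        bowtie = ((0, 0), (2, 2), (2, 0), (0, 2))
        with pytest.raises(ValidationError):
            Gate("bow", "cd45", bowtie, y_axis="pck", kind="polygon")


THR = ThresholdSet(cutoffs={"pck": 50.0, "cd45": 500.0, "cd11b": 100.0})


class TestClassification:
    @pytest.mark.parametrize("pck,cd45,cd11b,std,strict", [
        (400, 10, 10, LABEL_CTC_STANDARD, LABEL_CTC_STRICT),
        (400, 10, 900, LABEL_CTC_STANDARD, LABEL_MYELOID_FP),
        (400, 900, 10, LABEL_WBC, LABEL_WBC),
        (10, 10, 10, "OTHER", "OTHER"),
    ])
    def test_classification_tree(self, pck, cd45, cd11b, std, strict):
        ev = events_from({"pck": np.array([float(pck)]),
                          "cd45": np.array([float(cd45)]),
                          "cd11b": np.array([float(cd11b)])})
        assert classify_standard(ev, THR).iloc[0] == std
        assert classify_strict(ev, THR).iloc[0] == strict

    def test_missing_cutoff_raises_configuration_error(self):
        ev = events_from({"pck": np.array([1.0])})
        with pytest.raises(ConfigurationError):
            classify_standard(ev, ThresholdSet(cutoffs={"pck": 50.0}))

    def test_strict_subset_of_standard_and_exact_decomposition(self, rng):
        n = 2000
        ev = events_from({
            "pck": np.exp(rng.uniform(0, 7, n)),
            "cd45": np.exp(rng.uniform(0, 8, n)),
            "cd11b": np.exp(rng.uniform(0, 8, n)),
        })
        std = classify_standard(ev, THR).to_numpy()
        strict = classify_strict(ev, THR).to_numpy()
        std_set = std == LABEL_CTC_STANDARD
        strict_set = strict == LABEL_CTC_STRICT
        fp_set = strict == LABEL_MYELOID_FP
        assert (strict_set <= std_set).all()           # strict subset
        assert ((strict_set | fp_set) == std_set).all()  # exact partition

    def test_raising_cd11b_cutoff_grows_strict_set(self, rng):
        n = 1000
        ev = events_from({
            "pck": np.full(n, 400.0),
            "cd45": np.full(n, 10.0),
            "cd11b": np.exp(rng.uniform(0, 8, n)),
        })
        sizes = []
        for cut in (10.0, 100.0, 1000.0):
            thr = ThresholdSet(cutoffs={"pck": 50.0, "cd45": 500.0,
                                        "cd11b": cut})
            sizes.append((classify_strict(ev, thr) == LABEL_CTC_STRICT).sum())
        assert sizes[0] <= sizes[1] <= sizes[2]

    def test_fig3_standard_pool_mixes_ctc_and_myeloid(self):
        sc = make_scenario("fig3_falsepos", seed=2, n_cells=2000,
                           capture_antibody="EpCAM")[0]
        ev, _ = sample_events(sc)
        thr = derive_thresholds(ev, ["pck", "cd45", "cd11b"])
        std = classify_standard(ev, thr)
        in_pool = ev.data.loc[(std == LABEL_CTC_STANDARD).to_numpy(),
                              "truth_class"]
        assert {"CTC", "MYELOID"} <= set(in_pool.unique())
        # strict classification recovers planted labels with >= 95% agreement
        strict = classify_strict(ev, thr).to_numpy()
        truth = ev.data["truth_class"].to_numpy()
        expected = np.select(
            [truth == "WBC", truth == "MYELOID", truth == "CTC"],
            [LABEL_WBC, LABEL_MYELOID_FP, LABEL_CTC_STRICT], default="OTHER")
        # myeloid cells are CD45-low, not CD45-negative: they sit below the
        # CD45 cutoff, so their expected strict label is MYELOID_FP
        assert (strict == expected).mean() >= 0.95


class TestRunStrategy:
    def test_include_all_gate_retains_everything(self, rng):
        ev = events_from({"cd45": np.exp(rng.uniform(0, 8, 100))})
        strat = GatingStrategy(
            gates=[Gate("all", "cd45", ("ge", 0.0))],
            exclude_labels=["excluded"], retained_label="kept")
        out, audit = run_strategy(ev, strat)
        assert (out.data["label"] == "kept").all()
        assert (audit["excluded_by"] == "").all()

    def test_sequential_exclusion_matches_planted_fractions(self):
        from scipy.stats import binom
        sc = make_scenario("fig2d_capture", seed=8, n_cells=2000,
                           capture_antibody="Vim")[0]
        ev, _ = sample_events(sc)
        thr = derive_thresholds(ev, ["cd45", "cd11b"])
        strat = GatingStrategy(
            gates=[Gate("cd45-excl", "cd45", ("ge", thr["cd45"]), mode="exclude"),
                   Gate("cd11b-excl", "cd11b", ("ge", thr["cd11b"]), mode="exclude")],
            exclude_labels=[LABEL_WBC, LABEL_MYELOID_FP])
        out, audit = run_strategy(ev, strat)
        retained = (out.data["label"] == LABEL_CTC_STANDARD).mean()
        planted = 1.0 - sc.planted["class_fractions"]["WBC"] \
            - sc.planted["class_fractions"]["MYELOID"]
        lo, hi = binom.interval(0.99, len(ev), planted)
        assert lo / len(ev) <= retained <= hi / len(ev)
        # audit records the first excluding gate per event
        excluded = audit.loc[audit["label"] == LABEL_WBC, "excluded_by"]
        assert (excluded == "cd45-excl").all()

    def test_disjoint_exclusions_commute(self, rng):
        ev = events_from({
            "cd45": np.exp(rng.uniform(0, 8, 500)),
            "cd11b": np.exp(rng.uniform(0, 8, 500)),
        })
        g1 = Gate("a", "cd45", ("ge", 1000.0), mode="exclude")
        g2 = Gate("b", "cd11b", ("ge", 1000.0), mode="exclude")
        out12, _ = run_strategy(ev, GatingStrategy([g1, g2], ["x", "y"]))
        out21, _ = run_strategy(ev, GatingStrategy([g2, g1], ["y", "x"]))
        kept12 = out12.data.loc[out12.data.label == LABEL_CTC_STANDARD, "event_id"]
        kept21 = out21.data.loc[out21.data.label == LABEL_CTC_STANDARD, "event_id"]
        assert set(kept12) == set(kept21)

    def test_empty_strategy_rejected(self):
        with pytest.raises(ValidationError):
            GatingStrategy(gates=[], exclude_labels=[])


class TestThresholdSet:
    def test_uniform_application_records_provenance(self):
        sc1 = make_two_pop_scenario(seed=1, n_cells=2000)
        ev, _ = sample_events(sc1)
        thr = derive_thresholds(ev, ["pck"])
        assert thr.source_sample == "twopop"
        assert "pck" in thr

    def test_manual_override(self):
        sc1 = make_two_pop_scenario(seed=1, n_cells=200)
        ev, _ = sample_events(sc1)
        thr = derive_thresholds(ev, ["pck", "cd45"], manual={"cd45": 123.0})
        assert thr["cd45"] == 123.0

    def test_invalid_cutoffs_rejected(self):
        with pytest.raises(ValidationError):
            ThresholdSet(cutoffs={"cd45": -1.0})
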