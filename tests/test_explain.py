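"""Attributions (additivity, exhaustive-Shapley oracle), prompts, reports."""

import itertools
import math
import warnings

import numpy as np
import pytest

from beatguard.explain import (
    Attribution,
    build_prompt,
    global_importance,
    render_report,
    shap_attributions,
    template_generator,
)
from beatguard.model import Hyperparams, LabeledFeatures, train

ADD_TOL = 1e-6


# ---------------------------------------------------------------------------
# exhaustive path-dependent Shapley oracle
# ---------------------------------------------------------------------------

def _tree_expectation(node, subset, x):
    """Conditional expectation of one tree given the features in ``subset``
    take their values from ``x`` (cover-weighted path descent)."""
    if "leaf_value" in node:
        return node["leaf_value"]
    f = node["split_feature"]
    left, right = node["left_child"], node["right_child"]
    if f in subset:
        go_left = x[f] <= node["threshold"]
        return _tree_expectation(left if go_left else right, subset, x)
    cl = left.get("internal_count", left.get("leaf_count"))
    cr = right.get("internal_count", right.get("leaf_count"))
    el = _tree_expectation(left, subset, x)
    er = _tree_expectation(right, subset, x)
    return (cl * el + cr * er) / (cl + cr)


def _model_expectation(dump, subset, x):
    return sum(
        _tree_expectation(t["tree_structure"], subset, x)
        for t in dump["tree_info"]
    )


def _exhaustive_shapley(dump, x, n_features):
    """Direct subset enumeration of the Shapley formula over tree-path
    conditional expectations (the path-dependent convention)."""
    feats = list(range(n_features))
    phi = np.zeros(n_features)
    m = n_features
    for i in feats:
        rest = [f for f in feats if f != i]
        for k in range(len(rest) + 1):
            for subset in itertools.combinations(rest, k):
                weight = (math.factorial(k) * math.factorial(m - k - 1)
                          / math.factorial(m))
                gain = (_model_expectation(dump, set(subset) | {i}, x)
                        - _model_expectation(dump, set(subset), x))
                phi[i] += weight * gain
    return phi


def _toy_bundle(n_features=4, depth=3, n_trees=2, seed=0, n=80):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_features))
    y = ["pos" if (x[0] + 0.5 * x[1] > 0) else "neg" for x in X]
    feats = LabeledFeatures(X, y, [f"f{i}" for i in range(n_features)])
    hp = Hyperparams(n_estimators=n_trees, max_depth=depth,
                     num_leaves=2**depth, learning_rate=0.3,
                     subsample=1.0, colsample_bytree=1.0, seed=0)
    return train(feats, hp, apply_smote=False,
                 extra_params={"min_data_in_leaf": 2, "min_data_in_bin": 1}), X


class TestShap:
    def test_matches_exhaustive_shapley_on_small_trees(self):
        bundle, X = _toy_bundle()
        booster = bundle.booster()
        dump = booster.dump_model()
        for row in X[:10]:
            contrib = booster.predict(row.reshape(1, -1),
                                      pred_contrib=True)[0]
            ref = _exhaustive_shapley(dump, row, 4)
            np.testing.assert_allclose(contrib[:4], ref, atol=1e-9)

    def test_additivity_holds_for_1000_random_vectors(self, two_class_data):
        bundle = two_class_data["bundle"]
        rng = np.random.default_rng(0)
        lo = np.nanmin(two_class_data["X"], axis=0)
        hi = np.nanmax(two_class_data["X"], axis=0)
        for _ in range(1000):
            x = rng.uniform(lo, hi)
            a = shap_attributions(bundle, x)
            assert abs(a.base_value + a.contributions.sum() - a.margin) \
                < ADD_TOL

    def test_constant_model_all_zero_contributions(self):
        X = np.tile(np.array([1.0, 2.0, 3.0]), (40, 1))
        y = ["a"] * 25 + ["b"] * 15
        feats = LabeledFeatures(X, y, ["f0", "f1", "f2"])
        bundle = train(feats, Hyperparams(n_estimators=5, seed=0),
                       apply_smote=False)
        a = shap_attributions(bundle, np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(a.contributions, 0.0, atol=1e-12)
        assert abs(a.base_value - a.margin) < ADD_TOL

    def test_attribution_validates_additivity(self):
        with pytest.raises(ValueError, match="additivity"):
            Attribution(base_value=0.0, contributions=np.array([1.0]),
                        margin=5.0, feature_values=np.array([0.0]),
                        feature_names=["f0"], label="a", confidence=0.9)


class TestGlobalImportance:
    def test_hand_arithmetic(self):
        atts = [
            Attribution(0.0, np.array([1.0, -2.0]), -1.0,
                        np.zeros(2), ["f0", "f1"], "a", 0.9),
            Attribution(0.0, np.array([3.0, 0.0]), 3.0,
                        np.zeros(2), ["f0", "f1"], "a", 0.9),
        ]
        ranked = global_importance(atts)
        assert ranked == [("f0", 2.0), ("f1", 1.0)]

    def test_single_attribution_equals_absolutes(self):
        a = Attribution(0.5, np.array([-0.2, 0.1]), 0.4,
                        np.zeros(2), ["f0", "f1"], "a", 0.8)
        assert global_importance([a]) == [("f0", pytest.approx(0.2)),
                                          ("f1", pytest.approx(0.1))]

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            global_importance([])


def _attribution(drivers):
    names = list(drivers)
    vals = np.array([v for v, _ in drivers.values()])
    shaps = np.array([s for _, s in drivers.values()])
    return Attribution(
        base_value=-1.0, contributions=shaps,
        margin=-1.0 + shaps.sum(), feature_values=vals,
        feature_names=names, label="anomaly", confidence=0.92,
    )


class TestPrompt:
    def test_k_zero_prompt_has_no_drivers(self):
        a = _attribution({"qrs_duration": (162.0, 2.1)})
        p = build_prompt(a, k=0)
        assert p.drivers == []
        assert "anomaly" in p.render()
        assert "92%" in p.render()

    def test_drivers_sorted_by_absolute_shap(self):
        a = _attribution({
            "qrs_duration": (162.0, 2.1),
            "t_amplitude": (-0.19, -1.3),
            "rr_pre": (640.0, 0.4),
        })
        p = build_prompt(a, k=2)
        assert [d.feature for d in p.drivers] == ["qrs_duration",
                                                  "t_amplitude"]
        assert p.drivers[0].direction == "+"
        assert p.drivers[1].direction == "-"

    def test_prompt_byte_identical_across_calls(self):
        a = _attribution({"qrs_duration": (162.0, 2.1),
                          "t_amplitude": (-0.19, -1.3)})
        assert build_prompt(a, 5).render() == build_prompt(a, 5).render()

    def test_case_study_drivers_named(self):
        """Wide-QRS + inverted-T anomaly evidence surfaces both drivers."""
        a = _attribution({"qrs_duration": (162.0, 2.4),
                          "t_amplitude": (-0.19, -1.1),
                          "sdnn": (12.0, 0.2)})
        text = render_report(build_prompt(a, 3))
        assert "qrs_duration" in text and "162" in text
        assert "t_amplitude" in text and "-0.19" in text


class TestReport:
    def test_template_sections_in_order(self):
        a = _attribution({"qrs_duration": (84.0, -1.9),
                          "rr_pre": (780.0, -0.8),
                          "t_amplitude": (0.41, -0.7)})
        text = render_report(build_prompt(a, 3))
        order = [text.index(s) for s in
                 ("PREDICTION SUMMARY", "KEY DRIVERS", "INTERPRETATION",
                  "CAUTION/LIMITATIONS")]
        assert order == sorted(order)
        # every driver named (normal-beat case-study trio)
        for name in ("qrs_duration", "rr_pre", "t_amplitude"):
            assert name in text

    def test_driver_sentences_count_and_determinism(self):
        a = _attribution({"qrs_duration": (162.0, 2.1),
                          "t_amplitude": (-0.19, -1.3)})
        p = build_prompt(a, 2)
        t1, t2 = render_report(p), render_report(p)
        assert t1 == t2
        lines = [l for l in t1.splitlines() if l[:2] in ("1.", "2.", "3.")]
        assert len(lines) == 2

    def test_template_grounding_no_foreign_feature_names(self,
                                                         two_class_data):
        from beatguard.features import FEATURE_NAMES

        bundle = two_class_data["bundle"]
        x = two_class_data["X"][two_class_data["test_idx"][0]]
        a = shap_attributions(bundle, x)
        p = build_prompt(a, 5)
        text = render_report(p)
        named = {d.feature for d in p.drivers}
        for feature in FEATURE_NAMES:
            if feature in named:
                continue
            # a foreign feature may only appear as a substring of a named
            # driver (e.g. "std" inside "dwt_std_d2")
            if any(feature in n for n in named):
                continue
            assert feature not in text

    def test_external_generator_failure_falls_back(self):
        a = _attribution({"qrs_duration": (162.0, 2.1)})
        p = build_prompt(a, 1)

        def broken(prompt):
            raise RuntimeError("model endpoint unreachable")

        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            text = render_report(p, broken)
        assert text == template_generator(p)
        assert any("falling back" in str(w.message) for w in caught)

    def test_external_generator_used_when_healthy(self):
        a = _attribution({"qrs_duration": (162.0, 2.1)})
        p = build_prompt(a, 1)
        assert render_report(p, lambda pr: "CUSTOM") == "CUSTOM"
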