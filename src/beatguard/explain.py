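"""Additive explanations and clinician-facing report generation.

Attributions are exact path-dependent TreeSHAP values computed by the tree
ensemble itself, so the additivity identity holds to numerical precision:
the base value plus the per-feature contributions equals the prediction
margin (log-odds) of the explained class.

A deterministic prompt document carries the evidence — prediction summary,
base value, top-K drivers ranked by |SHAP| — into a report generator.  The
shipped generator is a fill-in template (four fixed sections: prediction
summary, key drivers, interpretation, caution/limitations) that mentions
every driver and nothing outside the prompt's evidence; any external text
generator can be injected instead and falls back to the template on
failure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .features import FeatureVector
from .io import ModelBundle
from .model import predict_proba

ADDITIVITY_TOL = 1e-6


@dataclass
class Attribution:
    """Base value plus per-feature contributions for one prediction."""

    base_value: float
    contributions: np.ndarray
    margin: float
    feature_values: np.ndarray
    feature_names: list[str]
    label: str
    confidence: float

    def __post_init__(self) -> None:
        self.contributions = np.asarray(self.contributions, dtype=float)
        self.feature_values = np.asarray(self.feature_values, dtype=float)
        gap = abs(self.base_value + self.contributions.sum() - self.margin)
        if gap > 1e-4:
            raise ValueError(
                f"attribution violates additivity (gap {gap:.2e})"
            )


def shap_attributions(bundle: ModelBundle,
                      vector: FeatureVector | np.ndarray) -> Attribution:
    """Exact TreeSHAP attribution for the predicted class of one input."""
    if isinstance(vector, FeatureVector):
        x = np.where(vector.mask, np.nan, vector.values)
    else:
        x = np.asarray(vector, dtype=float)
    if x.size != len(bundle.feature_names):
        raise ValueError(
            f"expected {len(bundle.feature_names)} features, got {x.size}"
        )
    medians = np.asarray(bundle.metadata.get(
        "medians", np.zeros(x.size)), dtype=float)
    x_filled = np.where(np.isnan(x), medians, x).reshape(1, -1)

    probs = predict_proba(bundle, x_filled)[0]
    k = int(np.argmax(probs))
    label, confidence = bundle.classes[k], float(probs[k])

    booster = bundle.booster()
    contrib = booster.predict(x_filled, pred_contrib=True)[0]
    raw = booster.predict(x_filled, raw_score=True)[0]
    n = len(bundle.feature_names)
    if contrib.size == n + 1:  # binary: contributions are for class 1
        phi, base = contrib[:n], float(contrib[n])
        margin = float(np.atleast_1d(raw)[0])
        if k == 0:
            phi, base, margin = -phi, -base, -margin
    else:  # multiclass: one (n+1)-block per class
        block = contrib.reshape(len(bundle.classes), n + 1)[k]
        phi, base = block[:n], float(block[n])
        margin = float(np.atleast_1d(raw)[k])
    return Attribution(
        base_value=base,
        contributions=phi,
        margin=margin,
        feature_values=x_filled[0],
        feature_names=list(bundle.feature_names),
        label=label,
        confidence=confidence,
    )


def global_importance(attributions: list[Attribution]
                      ) -> list[tuple[str, float]]:
    """Mean |SHAP| per feature, descending; ties keep canonical order."""
    if not attributions:
        raise ValueError("global importance needs at least one attribution")
    names = attributions[0].feature_names
    phi = np.stack([a.contributions for a in attributions])
    means = np.mean(np.abs(phi), axis=0)
    order = sorted(range(len(names)), key=lambda i: (-means[i], i))
    return [(names[i], float(means[i])) for i in order]


@dataclass
class Driver:
    feature: str
    value: float
    shap: float

    @property
    def direction(self) -> str:
        return "+" if self.shap >= 0 else "-"


INSTRUCTION_BLOCK = (
    "Write a clinician-facing report with exactly four sections in this "
    "order: prediction summary, key drivers, interpretation, "
    "caution/limitations. Ground every statement in the evidence listed "
    "above; use only the listed features and values and do not add "
    "unsupported diagnoses."
)


@dataclass
class PromptDoc:
    """Deterministic evidence document fed to the report generator."""

    label: str
    confidence: float
    base_value: float
    drivers: list[Driver] = field(default_factory=list)
    instructions: str = INSTRUCTION_BLOCK

    def render(self) -> str:
        lines = [
            f"Prediction: {self.label} "
            f"(confidence {round(self.confidence * 100):d}%)",
            f"Base value: {self.base_value:+.4f}",
            "Top drivers (|SHAP| descending):",
        ]
        for d in self.drivers:
            lines.append(
                f"  - {d.feature}: value={d.value:.4f} "
                f"shap={d.shap:+.4f} direction={d.direction}"
            )
        lines += ["", self.instructions]
        return "\n".join(lines)


def build_prompt(attribution: Attribution, k: int = 5) -> PromptDoc:
    """Top-K drivers by |SHAP|, ties broken by canonical feature order."""
    if k < 0:
        raise ValueError("K must be non-negative")
    order = sorted(
        range(len(attribution.feature_names)),
        key=lambda i: (-abs(attribution.contributions[i]), i),
    )[: min(k, len(attribution.feature_names))]
    drivers = [
        Driver(
            feature=attribution.feature_names[i],
            value=float(attribution.feature_values[i]),
            shap=float(attribution.contributions[i]),
        )
        for i in order
    ]
    return PromptDoc(
        label=attribution.label,
        confidence=attribution.confidence,
        base_value=attribution.base_value,
        drivers=drivers,
    )


def template_generator(prompt: PromptDoc) -> str:
    """Deterministic fill-in report; evidence-only by construction."""
    pct = round(prompt.confidence * 100)
    lines = [
        "PREDICTION SUMMARY",
        f"The model classified this beat as {prompt.label} "
        f"with {pct}% confidence.",
        "",
        "KEY DRIVERS",
    ]
    if prompt.drivers:
        for rank, d in enumerate(prompt.drivers, 1):
            push = ("pushed the prediction toward this decision"
                    if d.shap >= 0 else
                    "pushed the prediction away from this decision")
            lines.append(
                f"{rank}. {d.feature} = {d.value:.4f} "
                f"(SHAP {d.shap:+.4f}) {push}."
            )
    else:
        lines.append("No individual feature drivers were requested.")
    lines += [
        "",
        "INTERPRETATION",
        f"Starting from a base value of {prompt.base_value:+.4f}, the "
        "listed measurements jointly account for the model's output; the "
        "drivers above are ranked by the magnitude of their contribution.",
        "",
        "CAUTION/LIMITATIONS",
        "This report is generated automatically from model attributions "
        "and the measured feature values only. It is decision support, "
        "not a diagnosis; clinical correlation is required.",
    ]
    return "\n".join(lines)


def render_report(prompt: PromptDoc,
                  generator: Callable[[PromptDoc], str] | None = None
                  ) -> str:
    """Render the four-section report; external generators fall back to
    the template on failure (with a warning)."""
    if generator is None:
        return template_generator(prompt)
    try:
        return generator(prompt)
    except Exception as exc:  # noqa: BLE001 - any generator failure
        warnings.warn(
            f"external report generator failed ({exc}); "
            "falling back to the built-in template",
            RuntimeWarning,
            stacklevel=2,
        )
        return template_generator(prompt)
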