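"""Probability-to-category calling guide with accuracy annotation.

The prediction models emit per-category probabilities; casework reporting
needs a single categorical call.  Eye colour is called as the most probable
category and annotated with an empirical accuracy drawn from
probability-binned test-set performance.  Hair colour combines the most
probable colour category with the light/dark shade probability into the
field's combined labels ("Light Blond", "Dark Blond/Brown", "Black/Dark
Brown", ...), each mapped to the test-set accuracy of that label family.

The bundled guide configuration reproduces every published call and
accuracy for the 26-sample skeletal series; see ``data/calling_guide.yaml``
for which bin edges are data-constrained and which are conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .model import PredictionDecision, ProbabilityVector
from .panel import _data_path


class CallingConfigError(ValueError):
    pass


class GuideError(RuntimeError):
    """A probability fell outside every configured rule (table not exhaustive)."""


@dataclass(frozen=True)
class HairRule:
    quantity: str            # "p" (argmax probability) or "light" (shade)
    lo: float
    hi: float
    label: str


@dataclass
class HairDecisionTable:
    """Ordered rules per argmax category; intervals are half-open (lo, hi]."""

    rules: dict[str, list[HairRule]]

    def label(self, category: str, p: float, light: float) -> str:
        if category not in self.rules:
            raise GuideError(f"no hair rules for argmax category {category!r}")
        for rule in self.rules[category]:
            value = p if rule.quantity == "p" else light
            if rule.lo < value <= rule.hi or (value == 0.0 and rule.lo == 0.0):
                return rule.label
        raise GuideError(
            f"hair decision table not exhaustive: category={category}, p={p}, light={light}"
        )


@dataclass
class AccuracyLookup:
    """Accuracy annotations: hair by combined label, eye by (category,
    probability bin).  Accuracies in percent, half-open bins [lo, hi)."""

    hair_by_label: dict[str, float]
    eye_bins: dict[str, list[tuple[float, float, float]]]

    def hair(self, label: str) -> float:
        try:
            return self.hair_by_label[label]
        except KeyError:
            raise GuideError(f"no hair accuracy configured for label {label!r}") from None

    def eye(self, category: str, probability: float) -> float:
        for lo, hi, acc in self.eye_bins.get(category, ()):
            if lo <= probability < hi:
                return acc
        raise GuideError(f"no eye accuracy bin for {category!r} at p={probability}")


@dataclass
class EyeCall:
    label: str
    probability: float
    accuracy: float
    tie: bool = False


@dataclass
class HairCall:
    label: str
    category: str
    probability: float
    light: float
    accuracy: float
    tie: bool = False


@dataclass
class PhenotypeReport:
    """Final per-sample report row: calls, accuracies and caveats.

    Refused tasks carry ``None`` calls and render as "-" in tabular output.
    """

    sample_id: str
    eye: EyeCall | None
    hair: HairCall | None
    caveats: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


DEFAULT_EYE_DARKNESS = ("brown", "intermediate", "blue")
DEFAULT_HAIR_DARKNESS = ("black", "brown", "red", "blond")


def load_calling_config(
    path: str | Path | None = None,
) -> tuple[HairDecisionTable, AccuracyLookup, dict[str, tuple[str, ...]]]:
    """Load the decision table and accuracy lookups (bundled default if no
    path), validating that accuracies are in (0, 100] and, per category,
    non-decreasing in probability."""
    if path is None:
        path = _data_path("calling_guide.yaml")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)

    rules = {
        cat: [HairRule(**r) for r in rs] for cat, rs in cfg["hair_rules"].items()
    }
    table = HairDecisionTable(rules)

    hair_acc = {str(k): float(v) for k, v in cfg["hair_accuracy"].items()}
    eye_bins = {
        cat: [(float(b["lo"]), float(b["hi"]), float(b["accuracy"])) for b in bins]
        for cat, bins in cfg["eye_accuracy"].items()
    }
    for label, acc in hair_acc.items():
        if not 0 < acc <= 100:
            raise CallingConfigError(f"hair accuracy for {label!r} outside (0, 100]")
    for cat, bins in eye_bins.items():
        ordered = sorted(bins, key=lambda b: b[0])
        accs = [b[2] for b in ordered]
        if any(not 0 < a <= 100 for a in accs):
            raise CallingConfigError(f"eye accuracy for {cat!r} outside (0, 100]")
        if accs != sorted(accs):
            raise CallingConfigError(f"eye accuracies for {cat!r} not non-decreasing in probability")

    darkness = {
        "eye": tuple(cfg.get("eye_darkness_order", DEFAULT_EYE_DARKNESS)),
        "hair": tuple(cfg.get("hair_darkness_order", DEFAULT_HAIR_DARKNESS)),
    }
    return table, lookup_from(hair_acc, eye_bins), darkness


def lookup_from(hair_acc: dict[str, float], eye_bins) -> AccuracyLookup:
    return AccuracyLookup(hair_by_label=hair_acc, eye_bins=eye_bins)


def _argmax_with_ties(
    probs: dict[str, float], darkness: Sequence[str]
) -> tuple[str, float, bool]:
    """Most probable category; exact ties go to the darker category."""
    top = max(probs.values())
    tied = [c for c, v in probs.items() if v == top]
    if len(tied) == 1:
        return tied[0], top, False
    winner = min(tied, key=lambda c: darkness.index(c) if c in darkness else len(darkness))
    return winner, top, True


def call_eye(
    pv: ProbabilityVector,
    lookup: AccuracyLookup,
    darkness: Sequence[str] = DEFAULT_EYE_DARKNESS,
) -> EyeCall:
    """Call eye colour as the argmax category with its binned accuracy."""
    if pv.task != "eye":
        raise CallingConfigError(f"call_eye needs an eye vector, got {pv.task!r}")
    cat, p, tie = _argmax_with_ties(pv.probs, darkness)
    return EyeCall(label=cat.capitalize(), probability=p, accuracy=lookup.eye(cat, p), tie=tie)


def call_hair(
    p_hair: ProbabilityVector,
    p_shade: ProbabilityVector,
    table: HairDecisionTable,
    lookup: AccuracyLookup,
    darkness: Sequence[str] = DEFAULT_HAIR_DARKNESS,
) -> HairCall:
    """Combine hair category and shade probabilities into the final label."""
    if p_hair.task != "hair" or p_shade.task != "shade":
        raise CallingConfigError("call_hair needs a hair vector and a shade vector")
    cat, p, tie = _argmax_with_ties(p_hair.probs, darkness)
    light = p_shade["light"]
    label = table.label(cat, p, light)
    return HairCall(
        label=label, category=cat, probability=p, light=light,
        accuracy=lookup.hair(label), tie=tie,
    )


def build_report(
    sample_id: str,
    decision: PredictionDecision,
    eye: EyeCall | None,
    hair: HairCall | None,
    flags: Sequence[str] = (),
) -> PhenotypeReport:
    """Assemble the final report row, checking call/policy consistency."""
    if eye is not None and not decision.eye_allowed:
        raise CallingConfigError(f"{sample_id}: eye call supplied but policy refused eye prediction")
    if hair is not None and not decision.hair_allowed:
        raise CallingConfigError(f"{sample_id}: hair call supplied but policy refused hair prediction")
    return PhenotypeReport(
        sample_id=sample_id, eye=eye, hair=hair,
        caveats=list(decision.caveats), flags=list(flags),
    )


__all__ = [
    "HairRule",
    "HairDecisionTable",
    "AccuracyLookup",
    "EyeCall",
    "HairCall",
    "PhenotypeReport",
    "CallingConfigError",
    "GuideError",
    "load_calling_config",
    "call_eye",
    "call_hair",
    "build_report",
]
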