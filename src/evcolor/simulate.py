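"""Synthetic reference panels and degraded low-template replicate profiles.

The prediction models in this package are trained on genotype/phenotype
reference panels that are not publicly distributable; this module generates
statistical stand-ins with the structure the analysis assumes, so fitting,
policy, consensus and calling are all testable offline:

* reference panels: genotypes in Hardy-Weinberg proportions at configurable
  European-like effect-allele frequencies, with phenotype categories drawn
  from configurable "true" multinomial-logit models (defaults encode the
  dominant blue/brown effect of rs12913832, the darkening effect of
  rs16891982, and near-complete penetrance of the rare *MC1R* red-hair
  variants);

* degraded replicates: per-allele drop-out whose probability follows a
  logistic curve in template DNA mass (midpoint 60 pg — the approximate
  threshold above which drop-out is not expected), scaled per marker so the
  *MC1R* insertion probe is the most fragile and rs4959270 second, plus
  rare drop-in of a foreign allele at a low relative signal.

All generators are reproducible from an explicit seed.  The drop-out curve
shape and the drop-in rate are self-consistency devices for testing, not
estimates of any particular laboratory process.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .model import MLRModel, ModelSpec, default_spec
from .panel import (
    AlleleCall,
    ConsensusProfile,
    ConsensusStatus,
    MarkerDef,
    ReplicateProfile,
    model_markers,
    write_genotype_table,
)


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# true models


def _coef_row(marker_ids: Sequence[str], values: Mapping[str, float]) -> list[float]:
    return [values.get(mid, 0.0) for mid in marker_ids]


def default_true_models(panel: Sequence[MarkerDef]) -> dict[str, MLRModel]:
    """Hand-set generating models for the three tasks.

    Effect sizes are per effect-allele copy on the log-odds scale against
    the darkest (reference) category.  They encode the qualitative genetics
    of European pigmentation — a strong blue-eye effect of the *HERC2*
    variant, darkening by the *SLC45A2* substitution, high-penetrance
    *MC1R* red-hair alleles — at magnitudes chosen so that synthetic panels
    show realistic category mixtures; they are not published coefficients.
    """
    eye_spec = default_spec("eye", panel)
    blue = {
        "rs16891982": -1.2, "rs12203592": -0.5, "rs1800407": 0.8,
        "rs12913832": 3.0, "rs12896399": 0.3, "rs1393350": 0.3,
    }
    intermediate = {
        "rs16891982": -0.5, "rs12203592": -0.2, "rs1800407": 0.6,
        "rs12913832": 1.1, "rs12896399": 0.15, "rs1393350": 0.15,
    }
    eye = MLRModel(
        eye_spec,
        intercepts=np.array([-4.4, -2.8]),
        coefficients=np.array(
            [_coef_row(eye_spec.marker_ids, blue), _coef_row(eye_spec.marker_ids, intermediate)]
        ),
        provenance="synthetic-true-model",
    )

    hair_spec = default_spec("hair", panel)
    red_pen = {m.marker_id: 2.8 for m in panel if m.red_penetrant}
    red_weak = {"rs885479": 1.0, "rs1805005": 1.0, "rs2228479": 1.0, "rs1110400": 1.0}
    blond = {
        "rs12913832": 1.2, "rs16891982": -1.8, "rs12821256": 0.6, "rs4959270": 0.5,
        "rs1042602": 0.4, "rs12203592": 0.6, "rs683": -0.4, "rs2402130": 0.3,
    }
    brown = {"rs12913832": 0.4, "rs16891982": -1.2, "rs12203592": 0.3, "rs683": -0.1}
    red = {**red_pen, **red_weak}
    hair = MLRModel(
        hair_spec,
        intercepts=np.array([0.3, 0.8, -6.5]),
        coefficients=np.array(
            [
                _coef_row(hair_spec.marker_ids, blond),
                _coef_row(hair_spec.marker_ids, brown),
                _coef_row(hair_spec.marker_ids, red),
            ]
        ),
        provenance="synthetic-true-model",
    )

    shade_spec = default_spec("shade", panel)
    light = {
        "rs12913832": 1.5, "rs16891982": -1.6, "rs12203592": 0.5,
        "rs1042602": 0.3, "rs12821256": 0.4, "rs4959270": 0.3,
    }
    shade = MLRModel(
        shade_spec,
        intercepts=np.array([-0.8]),
        coefficients=np.array([_coef_row(shade_spec.marker_ids, light)]),
        provenance="synthetic-true-model",
    )
    return {"eye": eye, "hair": hair, "shade": shade}


# ---------------------------------------------------------------------------
# reference panels


@dataclass
class PanelSimConfig:
    n_individuals: int
    allele_freqs: dict[str, float]
    true_models: dict[str, MLRModel]
    seed: int

    def __post_init__(self) -> None:
        for mid, f in self.allele_freqs.items():
            if not 0.0 < f < 1.0:
                raise SimulationError(f"degenerate effect-allele frequency for {mid}: {f}")
        for task in ("eye", "hair", "shade"):
            if task not in self.true_models:
                raise SimulationError(f"true_models must cover {task!r}")


@dataclass
class ReferencePanel:
    """Simulated genotype/phenotype panel: one dosage column per panel
    marker (assay order), one label per individual per task."""

    marker_ids: list[str]
    dosages: np.ndarray                 # (n, 24) effect-allele counts
    labels: dict[str, list[str]]

    def task_dosages(self, spec: ModelSpec) -> np.ndarray:
        idx = [self.marker_ids.index(mid) for mid in spec.marker_ids]
        return self.dosages[:, idx]


def default_sim_config(
    panel: Sequence[MarkerDef], n_individuals: int = 5000, seed: int = 1
) -> PanelSimConfig:
    return PanelSimConfig(
        n_individuals=n_individuals,
        allele_freqs={m.marker_id: m.effect_allele_freq for m in panel},
        true_models=default_true_models(panel),
        seed=seed,
    )


def simulate_reference_panel(
    config: PanelSimConfig, panel: Sequence[MarkerDef]
) -> ReferencePanel:
    """Draw a genotype/phenotype panel: per-marker Hardy-Weinberg genotypes
    (dosage ~ Binomial(2, f)), then per-task category labels sampled from
    the true models' probabilities given the dosages."""
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    marker_ids = [m.marker_id for m in panel]
    dosages = np.empty((n, len(panel)), dtype=float)
    for j, m in enumerate(panel):
        dosages[:, j] = rng.binomial(2, config.allele_freqs[m.marker_id], size=n)

    ref = ReferencePanel(marker_ids, dosages, labels={})
    for task in ("eye", "hair", "shade"):
        model = config.true_models[task]
        probs = model.probabilities(ref.task_dosages(model.spec))
        cum = np.cumsum(probs, axis=1)
        u = rng.random(n)
        idx = (u[:, None] > cum).sum(axis=1)
        cats = model.spec.categories
        ref.labels[task] = [cats[i] for i in idx]
    return ref


# ---------------------------------------------------------------------------
# degradation


@dataclass
class DegradationParams:
    template_pg: float
    dropout_midpoint_pg: float = 60.0
    #: Chosen so per-allele drop-out is ~0.8% at 120 pg and >90% at 10 pg
    #: for a baseline-sensitivity marker.
    dropout_steepness: float = 0.08
    sensitivity: dict[str, float] = field(default_factory=dict)
    dropin_rate: float = 0.002
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.template_pg <= 0:
            raise SimulationError("template_pg must be positive")
        if self.n_replicates < 1:
            raise SimulationError("n_replicates must be >= 1")
        if not 0.0 <= self.dropin_rate <= 1.0:
            raise SimulationError("dropin_rate must be a probability")


def dropout_probability(marker: MarkerDef, params: DegradationParams) -> float:
    """Per-allele drop-out probability: logistic in template mass, scaled by
    the marker's fragility weight, capped at 1."""
    base = float(expit((params.dropout_midpoint_pg - params.template_pg) * params.dropout_steepness))
    sens = params.sensitivity.get(marker.marker_id, marker.dropout_sensitivity)
    return min(1.0, base * sens)


def simulate_degraded_replicates(
    truth: ConsensusProfile,
    panel: Sequence[MarkerDef],
    params: DegradationParams,
) -> list[ReplicateProfile]:
    """Generate replicate typings of a complete true profile under
    low-template artifacts.

    Each allele drops out independently with :func:`dropout_probability`;
    a heterozygote losing one allele appears homozygous, losing both gives
    a missing call.  With probability ``dropin_rate`` per locus per
    replicate, a foreign allele is added at a low relative signal
    (uniform on [0.02, 0.09], mostly below the 0.05 detection threshold),
    provided the call is not already a clean heterozygote.
    """
    for m in panel:
        if truth.calls[m.marker_id].is_missing:
            raise SimulationError(f"truth profile has missing call at {m.marker_id}")
    rng = np.random.default_rng(params.seed)
    reps: list[ReplicateProfile] = []
    for rep_i in range(1, params.n_replicates + 1):
        calls: dict[str, AlleleCall] = {}
        for m in panel:
            true_alleles = truth.calls[m.marker_id].alleles
            p_drop = dropout_probability(m, params)
            survivors = [a for a in true_alleles if rng.random() >= p_drop]
            distinct = sorted(set(survivors), key=m.alleles.index)
            signal: float | None = None
            if rng.random() < params.dropin_rate and len(distinct) < 2:
                foreign = [a for a in m.alleles if a not in distinct]
                add = foreign[rng.integers(len(foreign))]
                distinct = sorted(distinct + [add], key=m.alleles.index)
                signal = float(rng.uniform(0.02, 0.09))
            if not distinct:
                calls[m.marker_id] = AlleleCall(m.marker_id)
            elif len(distinct) == 1:
                calls[m.marker_id] = AlleleCall(m.marker_id, (distinct[0], distinct[0]), signal)
            else:
                calls[m.marker_id] = AlleleCall(m.marker_id, tuple(distinct), signal)
        reps.append(
            ReplicateProfile(truth.sample_id, rep_i, calls, template_pg=params.template_pg)
        )
    return reps


# ---------------------------------------------------------------------------
# end-to-end case sets


def dosage_to_calls(
    dosage_row: np.ndarray, panel: Sequence[MarkerDef]
) -> dict[str, AlleleCall]:
    calls = {}
    for m, d in zip(panel, dosage_row):
        other = next(a for a in m.alleles if a != m.effect_allele)
        geno = {0: (other, other), 1: None, 2: (m.effect_allele, m.effect_allele)}[int(d)]
        if geno is None:
            geno = tuple(sorted((other, m.effect_allele), key=m.alleles.index))
        calls[m.marker_id] = AlleleCall(m.marker_id, geno)
    return calls


def true_profile(sample_id: str, dosage_row: np.ndarray, panel: Sequence[MarkerDef]) -> ConsensusProfile:
    calls = dosage_to_calls(dosage_row, panel)
    status = {m.marker_id: ConsensusStatus.CONSISTENT for m in panel}
    return ConsensusProfile(sample_id, calls, status, n_replicates=1)


def generate_case_set(
    n_cases: int,
    panel: Sequence[MarkerDef],
    templates: Sequence[float],
    seed: int,
    genotypes_path: str | Path,
    truth_path: str | Path,
    *,
    true_models: dict[str, MLRModel] | None = None,
    n_replicates: int = 2,
    dropin_rate: float = 0.002,
) -> None:
    """Write a replicate genotype TSV plus a hidden truth table.

    Each case draws Hardy-Weinberg genotypes, true-model argmax phenotypes,
    a template amount cycling through ``templates``, and ``n_replicates``
    degraded replicate typings.  Output is deterministic given the seed.
    """
    if true_models is None:
        true_models = default_true_models(panel)
    rng = np.random.default_rng(seed)
    freqs = {m.marker_id: m.effect_allele_freq for m in panel}
    profiles: list[ReplicateProfile] = []
    truth_rows: list[str] = []
    header = ["sample_id", "template_pg"] + [m.marker_id for m in panel] + [
        "true_eye", "true_hair", "true_shade",
    ]
    for i in range(n_cases):
        sid = f"C{i + 1:04d}"
        dosage = np.array([rng.binomial(2, freqs[m.marker_id]) for m in panel], dtype=float)
        truth = true_profile(sid, dosage, panel)
        labels = {}
        for task in ("eye", "hair", "shade"):
            model = true_models[task]
            idx = [[m.marker_id for m in panel].index(mid) for mid in model.spec.marker_ids]
            p = model.probabilities(dosage[idx])
            labels[task] = model.spec.categories[int(np.argmax(p))]
        template = float(templates[i % len(templates)])
        params = DegradationParams(
            template_pg=template, dropin_rate=dropin_rate,
            n_replicates=n_replicates, seed=int(rng.integers(2**31)),
        )
        profiles.extend(simulate_degraded_replicates(truth, panel, params))
        from .panel import format_genotype  # local to avoid cycle at import time

        truth_rows.append(
            "\t".join(
                [sid, f"{template:g}"]
                + [format_genotype(truth.calls[m.marker_id]) for m in panel]
                + [labels["eye"], labels["hair"], labels["shade"]]
            )
        )
    write_genotype_table(profiles, genotypes_path, panel)
    with open(truth_path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        fh.write("\n".join(truth_rows) + "\n")


__all__ = [
    "SimulationError",
    "PanelSimConfig",
    "ReferencePanel",
    "DegradationParams",
    "default_true_models",
    "default_sim_config",
    "simulate_reference_panel",
    "dropout_probability",
    "simulate_degraded_replicates",
    "dosage_to_calls",
    "true_profile",
    "generate_case_set",
]
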