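"""Multinomial logistic prediction of eye colour, hair colour and hair
shade from effect-allele dosages.

Three independent regressions are used: eye colour (blue / intermediate /
brown, 6 markers), hair colour (blond / brown / red / black, 22 markers)
and hair shade (light / dark, the same 22 markers).  Each is a standard
reference-category multinomial logit,

    p_k(x) = exp(a_k + b_k . x) / (1 + sum_j exp(a_j + b_j . x)),

with the reference category taking the normalizing remainder.  The
originally published coefficient values are not reproduced here; models are
either fitted to (synthetic) reference panels or loaded from plain-text
coefficient files, so published coefficients can be dropped in without code
changes.

Fitting maximizes the multinomial log-likelihood with a small ridge penalty
on the slope coefficients (intercepts unpenalized) by damped Newton
iteration.  The penalty stabilizes rare-variant columns — several *MC1R*
red-hair variants segregate at frequencies of a few per thousand — and
guards against complete separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .panel import ConsensusProfile, MarkerDef, model_markers

RIDGE_DEFAULT = 1e-4
GRAD_TOL = 1e-8
MAX_ITER = 200

TASK_CATEGORIES = {
    "eye": ("blue", "intermediate", "brown"),
    "hair": ("blond", "brown", "red", "black"),
    "shade": ("light", "dark"),
}

#: MC1R variants with high penetrance for red hair; if one of these is
#: missing while hair colour is still predicted, red hair cannot be excluded.
RED_PENETRANT_MARKERS = frozenset(
    {"N29insA", "rs11547464", "rs1805006", "rs1805007", "rs1805008", "rs1805009", "Y152OCH"}
)


class ModelError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


class PolicyRefusalError(RuntimeError):
    """Raised when a prediction is requested for a task the policy refused."""

    def __init__(self, task: str, caveats: Sequence[str]):
        super().__init__(f"{task} prediction refused by missing-marker policy: {'; '.join(caveats)}")
        self.task = task
        self.caveats = list(caveats)


@dataclass(frozen=True)
class ModelSpec:
    task: str
    categories: tuple[str, ...]
    reference_category: str
    marker_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        expected = {"eye": 3, "hair": 4, "shade": 2}
        if self.task not in expected:
            raise ModelError(f"unknown task {self.task!r}")
        if len(self.categories) != expected[self.task]:
            raise ModelError(
                f"{self.task} model needs {expected[self.task]} categories, got {len(self.categories)}"
            )
        if self.reference_category not in self.categories:
            raise ModelError("reference_category must be one of the categories")

    @property
    def nonreference(self) -> tuple[str, ...]:
        return tuple(c for c in self.categories if c != self.reference_category)


def default_spec(task: str, panel: Sequence[MarkerDef]) -> ModelSpec:
    """Standard spec for a task: canonical categories, darkest category as
    reference, task marker subset in assay order."""
    cats = TASK_CATEGORIES[task]
    return ModelSpec(
        task=task,
        categories=cats,
        reference_category=cats[-1],
        marker_ids=tuple(m.marker_id for m in model_markers(panel, task)),
    )


@dataclass(frozen=True)
class ProbabilityVector:
    """Normalized category probabilities for one task."""

    task: str
    probs: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.probs.values())
        if not np.isclose(total, 1.0, atol=0.011):
            raise ModelError(f"{self.task} probabilities sum to {total:.4f}, not 1")

    def argmax(self) -> str:
        return max(self.probs, key=self.probs.get)

    def __getitem__(self, category: str) -> float:
        return self.probs[category]


@dataclass
class MLRModel:
    """Reference-category multinomial logit for one prediction task.

    ``intercepts`` has one entry per non-reference category;
    ``coefficients`` is (n_categories - 1, n_markers), rows in
    ``spec.nonreference`` order, columns in ``spec.marker_ids`` order.
    """

    spec: ModelSpec
    intercepts: np.ndarray
    coefficients: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        self.coefficients = np.atleast_2d(np.asarray(self.coefficients, dtype=float))
        k = len(self.spec.categories) - 1
        if self.intercepts.shape != (k,):
            raise ModelError(f"expected {k} intercepts, got {self.intercepts.shape}")
        if self.coefficients.shape != (k, len(self.spec.marker_ids)):
            raise ModelError(
                f"coefficient shape {self.coefficients.shape} != "
                f"({k}, {len(self.spec.marker_ids)})"
            )

    def probabilities(self, dosages: np.ndarray) -> np.ndarray:
        """Category probabilities (in ``spec.categories`` order) for one
        dosage vector or an (n, m) dosage matrix."""
        x = np.atleast_2d(np.asarray(dosages, dtype=float))
        eta = x @ self.coefficients.T + self.intercepts  # (n, K-1)
        full = np.concatenate([eta, np.zeros((x.shape[0], 1))], axis=1)
        full -= full.max(axis=1, keepdims=True)
        expd = np.exp(full)
        p_aug = expd / expd.sum(axis=1, keepdims=True)
        # reorder from (nonreference..., reference) into categories order
        order = list(self.spec.nonreference) + [self.spec.reference_category]
        out = np.empty_like(p_aug)
        for j, cat in enumerate(self.spec.categories):
            out[:, j] = p_aug[:, order.index(cat)]
        return out if np.asarray(dosages).ndim > 1 else out[0]


@dataclass
class PredictionDecision:
    """Outcome of the missing-marker policy for one consensus profile."""

    eye_allowed: bool
    hair_allowed: bool
    shade_allowed: bool
    caveats: list[str] = field(default_factory=list)
    imputed_markers: list[str] = field(default_factory=list)

    def allows(self, task: str) -> bool:
        return {"eye": self.eye_allowed, "hair": self.hair_allowed, "shade": self.shade_allowed}[task]


# ---------------------------------------------------------------------------
# fitting


def _design(x: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(x.shape[0]), x])


def _nll_grad_hess(theta: np.ndarray, xd: np.ndarray, y_idx: np.ndarray,
                   k: int, ridge: float, want_hess: bool):
    """Penalized negative log-likelihood, gradient and (optionally) Hessian.

    ``theta`` is (k, p) with column 0 the intercept; the reference category
    has an implicit zero row.  ``y_idx`` codes the reference category as k.
    """
    n, p = xd.shape
    eta = xd @ theta.T                             # (n, k)
    full = np.column_stack([eta, np.zeros(n)])
    shift = full.max(axis=1, keepdims=True)
    logz = shift[:, 0] + np.log(np.exp(full - shift).sum(axis=1))
    ll = full[np.arange(n), y_idx] - logz
    pen_mask = np.ones(p)
    pen_mask[0] = 0.0                              # intercept unpenalized
    nll = -ll.sum() + 0.5 * ridge * float((theta**2 * pen_mask).sum())

    probs = np.exp(full - logz[:, None])           # (n, k+1)
    indic = np.zeros((n, k))
    sel = y_idx < k
    indic[np.arange(n)[sel], y_idx[sel]] = 1.0
    resid = probs[:, :k] - indic                   # (n, k)
    grad = resid.T @ xd + ridge * theta * pen_mask

    if not want_hess:
        return nll, grad, None

    hess = np.empty((k * p, k * p))
    for a in range(k):
        for b in range(a, k):
            w = probs[:, a] * ((a == b) - probs[:, b])
            block = (xd * w[:, None]).T @ xd
            hess[a * p:(a + 1) * p, b * p:(b + 1) * p] = block
            if b != a:
                hess[b * p:(b + 1) * p, a * p:(a + 1) * p] = block
    hess += ridge * np.diag(np.tile(pen_mask, k))
    return nll, grad, hess


def fit_mlr(
    dosages: np.ndarray,
    labels: Sequence[str],
    spec: ModelSpec,
    *,
    ridge: float = RIDGE_DEFAULT,
    tol: float = GRAD_TOL,
    max_iter: int = MAX_ITER,
    provenance: str = "fitted",
) -> MLRModel:
    """Fit the multinomial logit by damped Newton iteration.

    Deterministic given data and options.  Raises :class:`ModelError` if a
    spec category is absent from the training labels, and
    :class:`ConvergenceError` if the gradient does not reach ``tol`` within
    ``max_iter`` iterations (with unpenalized fits this typically signals
    complete separation; refit with ridge > 0).
    """
    x = np.asarray(dosages, dtype=float)
    if x.ndim != 2 or x.shape[1] != len(spec.marker_ids):
        raise ModelError(f"dosage matrix must be (n, {len(spec.marker_ids)})")
    labels = list(labels)
    observed = set(labels)
    for cat in spec.categories:
        if cat not in observed:
            raise ModelError(f"category {cat!r} absent from training data")

    nonref = spec.nonreference
    cat_index = {c: i for i, c in enumerate(nonref)}
    k = len(nonref)
    y_idx = np.array([cat_index.get(lab, k) for lab in labels])
    xd = _design(x)
    p = xd.shape[1]

    theta = np.zeros((k, p))
    nll, grad, _ = _nll_grad_hess(theta, xd, y_idx, k, ridge, want_hess=False)
    converged = False
    for _ in range(max_iter):
        if np.abs(grad).max() < tol:
            converged = True
            break
        _, _, hess = _nll_grad_hess(theta, xd, y_idx, k, ridge, want_hess=True)
        try:
            step = np.linalg.solve(hess, grad.ravel()).reshape(k, p)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad.ravel(), rcond=None)[0].reshape(k, p)
        # damped step: halve until the objective decreases
        scale = 1.0
        for _ in range(40):
            cand = theta - scale * step
            cand_nll, cand_grad, _ = _nll_grad_hess(cand, xd, y_idx, k, ridge, want_hess=False)
            if cand_nll <= nll + 1e-12:
                theta, nll, grad = cand, cand_nll, cand_grad
                break
            scale *= 0.5
        else:
            break
    else:
        if np.abs(grad).max() < tol:
            converged = True
    if not converged and np.abs(grad).max() >= tol:
        hint = " (possible complete separation; refit with ridge > 0)" if ridge == 0 else ""
        raise ConvergenceError(
            f"Newton did not converge: max|grad| = {np.abs(grad).max():.3e}{hint}"
        )
    if ridge == 0 and nll < 1e-3:
        # the unpenalized likelihood attains its supremum only under complete
        # separation, where the MLE is at infinity
        raise ConvergenceError(
            "training data are completely separated and the unpenalized "
            "likelihood has no finite maximum; refit with ridge > 0"
        )

    return MLRModel(
        spec=spec,
        intercepts=theta[:, 0].copy(),
        coefficients=theta[:, 1:].copy(),
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# prediction and policy


def predict_proba(
    model: MLRModel,
    dosages: np.ndarray,
    decision: PredictionDecision | None = None,
) -> ProbabilityVector:
    """Category probabilities for one dosage vector.

    If a policy ``decision`` is supplied and refuses the model's task, a
    :class:`PolicyRefusalError` carrying the policy caveats is raised;
    masked dosages must already have been resolved by the policy.
    """
    if decision is not None and not decision.allows(model.spec.task):
        raise PolicyRefusalError(model.spec.task, decision.caveats)
    p = model.probabilities(np.asarray(dosages, dtype=float))
    return ProbabilityVector(model.spec.task, dict(zip(model.spec.categories, p.tolist())))


def missing_marker_policy(
    profile: ConsensusProfile, panel: Sequence[MarkerDef]
) -> PredictionDecision:
    """Decide which predictions a partially missing profile supports.

    Eye colour requires all six eye-model markers.  Hair colour and shade
    tolerate at most one missing hair-model marker, imputed as dosage 0
    (no effect alleles) with a caveat; with two or more missing the
    prediction is refused.  If the missing-but-tolerated marker is the
    *MC1R* insertion or another high-penetrance red-hair variant, the
    prediction additionally carries the caveat that red hair cannot be
    excluded, since a single untyped high-penetrance variant can hide a
    red-hair genotype.
    """
    missing = {mid for mid, call in profile.calls.items() if call.is_missing}
    eye_ids = {m.marker_id for m in model_markers(panel, "eye")}
    hair_ids = [m.marker_id for m in model_markers(panel, "hair")]
    red_ids = {m.marker_id for m in panel if m.red_penetrant} or RED_PENETRANT_MARKERS

    caveats: list[str] = []
    imputed: list[str] = []

    eye_missing = sorted(missing & eye_ids)
    eye_allowed = not eye_missing
    if eye_missing:
        caveats.append(f"eye prediction refused: missing eye-model markers {', '.join(eye_missing)}")

    hair_missing = sorted(m for m in hair_ids if m in missing)
    if len(hair_missing) == 0:
        hair_allowed = True
    elif len(hair_missing) == 1:
        hair_allowed = True
        imputed = hair_missing
        caveats.append(f"hair prediction with {hair_missing[0]} missing, imputed as dosage 0")
        if hair_missing[0] in red_ids:
            caveats.append("red hair cannot be excluded")
    else:
        hair_allowed = False
        caveats.append(
            f"hair prediction refused: missing genotypes at {len(hair_missing)} "
            f"DNA variants ({', '.join(hair_missing)})"
        )

    return PredictionDecision(
        eye_allowed=eye_allowed,
        hair_allowed=hair_allowed,
        shade_allowed=hair_allowed,
        caveats=caveats,
        imputed_markers=imputed,
    )


def resolve_dosages(
    dosages: np.ndarray,
    mask: np.ndarray,
    *,
    strategy: str = "zero",
    panel_by_id: dict[str, MarkerDef] | None = None,
    marker_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Fill masked (missing) dosages for a policy-tolerated prediction.

    ``zero`` imputes no effect alleles (conservative default);
    ``frequency`` imputes the Hardy-Weinberg expectation 2f from the panel's
    configured effect-allele frequency.
    """
    out = np.asarray(dosages, dtype=float).copy()
    if not mask.any():
        return out
    if strategy == "zero":
        out[mask] = 0.0
    elif strategy == "frequency":
        if panel_by_id is None or marker_ids is None:
            raise ModelError("frequency imputation needs panel_by_id and marker_ids")
        for j in np.flatnonzero(mask):
            out[j] = 2.0 * panel_by_id[marker_ids[j]].effect_allele_freq
    else:
        raise ModelError(f"unknown imputation strategy {strategy!r}")
    return out


# ---------------------------------------------------------------------------
# plain-text model files (bit-exact round trip)


def save_model(model: MLRModel, path: str | Path) -> None:
    """Write a coefficient file: header lines (key: value), then one
    ``coef <category> <marker|_intercept> <value>`` line per parameter,
    with values in full hex float precision for bit-exact reload."""
    with open(path, "w") as fh:
        fh.write(f"task: {model.spec.task}\n")
        fh.write(f"categories: {','.join(model.spec.categories)}\n")
        fh.write(f"reference: {model.spec.reference_category}\n")
        fh.write(f"markers: {','.join(model.spec.marker_ids)}\n")
        fh.write(f"provenance: {model.provenance}\n")
        for i, cat in enumerate(model.spec.nonreference):
            v = model.intercepts[i]
            fh.write(f"coef\t{cat}\t_intercept\t{v!r}\t{float(v).hex()}\n")
            for j, mid in enumerate(model.spec.marker_ids):
                v = model.coefficients[i, j]
                fh.write(f"coef\t{cat}\t{mid}\t{v!r}\t{float(v).hex()}\n")


def load_model(path: str | Path) -> MLRModel:
    header: dict[str, str] = {}
    coefs: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith("coef\t"):
                _, cat, mid, _dec, hexv = line.split("\t")
                coefs[(cat, mid)] = float.fromhex(hexv)
            else:
                key, _, val = line.partition(":")
                header[key.strip()] = val.strip()
    spec = ModelSpec(
        task=header["task"],
        categories=tuple(header["categories"].split(",")),
        reference_category=header["reference"],
        marker_ids=tuple(header["markers"].split(",")),
    )
    k = len(spec.nonreference)
    intercepts = np.array([coefs[(c, "_intercept")] for c in spec.nonreference])
    coefficients = np.array(
        [[coefs[(c, mid)] for mid in spec.marker_ids] for c in spec.nonreference]
    ).reshape(k, len(spec.marker_ids))
    return MLRModel(spec, intercepts, coefficients, provenance=header.get("provenance", ""))


__all__ = [
    "TASK_CATEGORIES",
    "RED_PENETRANT_MARKERS",
    "RIDGE_DEFAULT",
    "ModelSpec",
    "MLRModel",
    "ProbabilityVector",
    "PredictionDecision",
    "ModelError",
    "ConvergenceError",
    "PolicyRefusalError",
    "default_spec",
    "fit_mlr",
    "predict_proba",
    "missing_marker_policy",
    "resolve_dosages",
    "save_model",
    "load_model",
]
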