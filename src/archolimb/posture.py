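"""Two-class linear discriminant analysis for bipedal vs quadrupedal
posture, with a repeated-training-set voting harness.

The classifier is pooled-covariance LDA implemented from its formulas:
with class means μ₀, μ₁ and pooled covariance Σ, the weight vector is
w = Σ⁻¹(μ₁ − μ₀), the score s(x) = wᵀx − wᵀ(μ₀ + μ₁)/2, and x is labelled
class 1 (bipedal) iff s(x) + log(π₁/π₀) > 0.  The posterior follows from
the equal-covariance Gaussian model: P(1|x) = σ(s(x) + log(π₁/π₀)).

The voting harness mirrors the repeated-training-set procedure used for
archosauriform posture prediction: one LDA is fitted per training set and
the target taxon is classified by each, tallying bipedal votes (the
published composition of those training sets lives in external data, so
the harness accepts any list of sets and the synthetic-data module ships a
generator emulating the structure).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger("archolimb")

__all__ = [
    "FeatureRecord",
    "LDAModel",
    "DEFAULT_FEATURES",
    "feature_matrix",
    "fit_lda",
    "predict",
    "vote_over_trainings",
    "BIPEDAL",
    "QUADRUPEDAL",
]

BIPEDAL = "bipedal"
QUADRUPEDAL = "quadrupedal"

#: default feature spec: log10 body mass, GA-normalized COM, limb ratio
DEFAULT_FEATURES = ("log10_mass", "com_ga", "limb_ratio")


@dataclass
class FeatureRecord:
    """Per-taxon morphometric features for posture classification."""

    taxon: str
    body_mass_kg: float
    com_dimensionless: float
    forelimb_m: float
    hindlimb_m: float
    posture: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.com_dimensionless):
            raise ValueError(f"{self.taxon!r}: GA-normalized COM must be finite")
        if self.body_mass_kg <= 0 or self.forelimb_m <= 0 or self.hindlimb_m <= 0:
            raise ValueError(f"{self.taxon!r}: mass and limb lengths must be positive")

    def features(self, spec=DEFAULT_FEATURES) -> np.ndarray:
        vals = {
            "log10_mass": np.log10(self.body_mass_kg),
            "mass": self.body_mass_kg,
            "com_ga": self.com_dimensionless,
            "limb_ratio": self.forelimb_m / self.hindlimb_m,
            "forelimb": self.forelimb_m,
            "hindlimb": self.hindlimb_m,
        }
        try:
            return np.array([vals[f] for f in spec], dtype=float)
        except KeyError as exc:
            raise ValueError(f"unknown feature {exc.args[0]!r}") from exc


def feature_matrix(records, spec=DEFAULT_FEATURES) -> np.ndarray:
    return np.stack([r.features(spec) for r in records])


@dataclass
class LDAModel:
    """Fitted pooled-covariance LDA (class 0 quadrupedal, class 1 bipedal)."""

    mu0: np.ndarray
    mu1: np.ndarray
    sigma: np.ndarray
    weights: np.ndarray
    intercept: float
    priors: tuple
    spec: tuple = DEFAULT_FEATURES

    def score(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float).reshape(-1)
        if x.shape != self.weights.shape:
            raise ValueError(
                f"feature dimension mismatch: got {x.shape[0]}, "
                f"model expects {self.weights.shape[0]}"
            )
        return float(self.weights @ x - self.intercept)


def fit_lda(records, spec=DEFAULT_FEATURES, ridge: float = 0.0,
            priors=None) -> LDAModel:
    """Fit pooled-covariance LDA to labelled records.

    *priors* is None (class frequencies), "equal", or a (π₀, π₁) pair.
    *ridge* adds ridge·I to the pooled covariance; a singular covariance
    with ridge 0 raises an error advising a ridge.  Each class needs at
    least two records.
    """
    X0 = [r.features(spec) for r in records if r.posture == QUADRUPEDAL]
    X1 = [r.features(spec) for r in records if r.posture == BIPEDAL]
    if len(X0) < 2 or len(X1) < 2:
        raise ValueError(
            f"need >= 2 records per class, got {len(X0)} quadrupedal / "
            f"{len(X1)} bipedal"
        )
    X0, X1 = np.stack(X0), np.stack(X1)
    if not (np.isfinite(X0).all() and np.isfinite(X1).all()):
        raise ValueError("features contain non-finite values")
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    n0, n1 = len(X0), len(X1)
    scatter = (X0 - mu0).T @ (X0 - mu0) + (X1 - mu1).T @ (X1 - mu1)
    sigma = scatter / (n0 + n1 - 2) + ridge * np.eye(X0.shape[1])
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "pooled covariance is singular; pass ridge > 0 to regularize"
        ) from exc
    diff = mu1 - mu0
    w = np.linalg.solve(chol.T, np.linalg.solve(chol, diff))
    intercept = float(w @ (mu0 + mu1) / 2.0)
    if priors is None:
        pri = (n0 / (n0 + n1), n1 / (n0 + n1))
    elif priors == "equal":
        pri = (0.5, 0.5)
    else:
        p0, p1 = float(priors[0]), float(priors[1])
        if not np.isclose(p0 + p1, 1.0):
            raise ValueError("priors must sum to 1")
        pri = (p0, p1)
    return LDAModel(mu0=mu0, mu1=mu1, sigma=sigma, weights=w,
                    intercept=intercept, priors=pri, spec=tuple(spec))


def predict(model: LDAModel, record) -> tuple:
    """(label, posterior probability of bipedal) for one record or vector."""
    x = record.features(model.spec) if isinstance(record, FeatureRecord) else record
    s = model.score(x) + np.log(model.priors[1] / model.priors[0])
    posterior = float(1.0 / (1.0 + np.exp(-s)))
    return (BIPEDAL if s > 0 else QUADRUPEDAL), posterior


def vote_over_trainings(training_sets, target, spec=DEFAULT_FEATURES,
                        ridge: float = 0.0, priors=None,
                        strict: bool = False) -> dict:
    """Fit one LDA per training set and tally bipedal votes for *target*.

    An unfittable set is recorded as an abstention with a logged reason
    (or raises in strict mode).  Returns votes, the number of sets, and
    the per-set posteriors (None for abstentions).
    """
    if len(training_sets) == 0:
        raise ValueError("need at least one training set")
    votes = 0
    posteriors = []
    abstentions = []
    for i, records in enumerate(training_sets):
        try:
            model = fit_lda(records, spec=spec, ridge=ridge, priors=priors)
        except ValueError as exc:
            if strict:
                raise
            log.warning("training set %d abstains: %s", i, exc)
            posteriors.append(None)
            abstentions.append((i, str(exc)))
            continue
        label, post = predict(model, target)
        posteriors.append(post)
        votes += label == BIPEDAL
    return {
        "bipedal_votes": votes,
        "n_sets": len(training_sets),
        "posteriors": posteriors,
        "abstentions": abstentions,
    }
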