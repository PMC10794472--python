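"""Group statistics and linear-discriminant classification.

Implements one-way ANOVA with Bonferroni-adjusted pairwise t tests per
feature, Fisher LDA (pooled within-class covariance, optional shrinkage
toward its diagonal), projection onto the first two discriminants,
nearest-class prediction under the pooled metric, confusion-matrix
reporting, 95% confidence ellipses for score scatters, and the end-to-end
four-family benchmark.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import scipy.linalg
import scipy.stats

from .baselines import (
    DEFAULT_FD_BAND,
    arma_features,
    frequency_domain_features,
    time_domain_features,
)
from .modal import FeatureVector, ModalExtractionError, extract_ss_features
from .signal import PASignal
from .subspace import IdentificationError
from .synthetic import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "GroupComparison",
    "LDAModel",
    "ClassificationReport",
    "EllipseSpec",
    "anova_bonferroni",
    "fit_lda",
    "transform_lda",
    "predict",
    "confusion_and_accuracy",
    "confidence_ellipse",
    "run_benchmark",
    "features_to_matrix",
    "FAMILIES",
]

FAMILIES = ("TD", "FD", "ARMA", "SS")


@dataclass
class GroupComparison:
    """ANOVA + Bonferroni post hoc result for one feature."""

    parameter_name: str
    anova_F: float
    anova_p: float
    pairwise: dict[tuple[str, str], dict]  # {'p_raw', 'p_adj', 'stars'}


@dataclass
class LDAModel:
    class_labels: list[str]
    class_means: np.ndarray  # k x p
    pooled_covariance: np.ndarray  # p x p (after shrinkage, if any)
    priors: np.ndarray  # k
    discriminant_basis: np.ndarray  # p x d, columns ordered by eigenvalue
    feature_names: list[str]
    shrinkage: float = 0.0


@dataclass
class ClassificationReport:
    class_labels: list[str]
    confusion: np.ndarray  # rows = true, columns = predicted
    accuracy: float  # percent
    per_class_recall: dict[str, float]
    meta: dict = field(default_factory=dict)


@dataclass
class EllipseSpec:
    center: np.ndarray
    semi_axes: np.ndarray
    rotation: float  # radians, angle of the leading eigenvector
    level: float = 0.95


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def anova_bonferroni(
    values_by_class: Mapping[str, Sequence[float]],
    parameter_name: str = "",
) -> GroupComparison:
    """One-way ANOVA across classes plus Bonferroni-adjusted pairwise
    pooled-variance t tests (m = number of class pairs)."""
    labels = sorted(values_by_class)
    groups = [np.asarray(values_by_class[lbl], dtype=float) for lbl in labels]
    if len(groups) < 2:
        raise ValueError("need at least 2 classes")
    if any(g.size < 2 for g in groups):
        raise ValueError("each class needs at least 2 values")
    allv = np.concatenate(groups)
    if np.var(allv) == 0:
        raise ValueError("zero total variance: ANOVA undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # identical groups give F = 0 with a warning
        F, p = scipy.stats.f_oneway(*groups)
    if not np.isfinite(F):
        F, p = 0.0, 1.0
    pairs = list(itertools.combinations(labels, 2))
    m = len(pairs)
    pairwise = {}
    for la, lb in pairs:
        a = np.asarray(values_by_class[la], dtype=float)
        b = np.asarray(values_by_class[lb], dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p_raw = scipy.stats.ttest_ind(a, b, equal_var=True)
        if not np.isfinite(p_raw):
            p_raw = 1.0
        p_adj = min(1.0, m * float(p_raw))
        pairwise[(la, lb)] = {"p_raw": float(p_raw), "p_adj": p_adj,
                              "stars": _stars(p_adj)}
    return GroupComparison(parameter_name=parameter_name, anova_F=float(F),
                           anova_p=float(p), pairwise=pairwise)


def features_to_matrix(
    features: Sequence[FeatureVector],
) -> tuple[np.ndarray, list[str], list[str]]:
    """Stack feature vectors into (X, labels, feature_names); the name order
    is taken from the first vector."""
    if not features:
        raise ValueError("empty feature list")
    names = list(features[0].values)
    X = np.array([[fv.values[n] for n in names] for fv in features], dtype=float)
    labels = [fv.label for fv in features]
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    return X, labels, names


def fit_lda(
    X: np.ndarray,
    labels: Sequence[str],
    feature_names: Optional[Sequence[str]] = None,
    shrinkage: Optional[float] = None,
) -> LDAModel:
    """Fisher LDA from the eigen-decomposition of pooled-within vs between
    scatter.

    ``shrinkage`` in [0, 1] mixes the pooled covariance toward its diagonal;
    ``None`` enables a default of 0.1 whenever any class has fewer than
    twice as many samples as features (tiny classes make the pooled estimate
    noisy), else 0.
    """
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    if X.ndim != 2 or X.shape[0] != len(labels):
        raise ValueError("X rows must match labels")
    class_labels = sorted(set(labels))
    if len(class_labels) < 2:
        raise ValueError("need at least 2 classes")
    n, p = X.shape
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(p)]
    counts = np.array([labels.count(c) for c in class_labels])
    if np.any(counts < 2):
        raise ValueError("each class needs at least 2 samples")
    if shrinkage is None:
        shrinkage = 0.1 if np.min(counts) < 2 * p else 0.0

    means = np.vstack([X[[l == c for l in labels]].mean(axis=0) for c in class_labels])
    grand = X.mean(axis=0)
    Sw = np.zeros((p, p))
    for c, mu in zip(class_labels, means):
        Xi = X[[l == c for l in labels]] - mu
        Sw += Xi.T @ Xi
    Sw /= n - len(class_labels)
    if shrinkage > 0:
        Sw = (1.0 - shrinkage) * Sw + shrinkage * np.diag(np.diag(Sw))
    Sb = np.zeros((p, p))
    for cnt, mu in zip(counts, means):
        d = (mu - grand).reshape(-1, 1)
        Sb += cnt * (d @ d.T)
    Sb /= n

    try:
        evals, evecs = scipy.linalg.eigh(Sb, Sw)
    except scipy.linalg.LinAlgError as exc:
        raise ValueError(
            "pooled covariance is singular; refit with shrinkage > 0"
        ) from exc
    order = np.argsort(evals)[::-1]
    d = min(len(class_labels) - 1, p)
    W = evecs[:, order[:d]]
    # deterministic sign: largest-magnitude loading positive
    for k in range(W.shape[1]):
        idx = np.argmax(np.abs(W[:, k]))
        if W[idx, k] < 0:
            W[:, k] = -W[:, k]

    return LDAModel(
        class_labels=class_labels,
        class_means=means,
        pooled_covariance=Sw,
        priors=counts / n,
        discriminant_basis=W,
        feature_names=list(feature_names),
        shrinkage=float(shrinkage),
    )


def transform_lda(
    model: LDAModel,
    X: np.ndarray,
    feature_names: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Project samples onto the first two discriminants (LD1, LD2)."""
    if feature_names is not None and list(feature_names) != model.feature_names:
        raise ValueError(
            f"feature-name mismatch: model expects {model.feature_names}, "
            f"got {list(feature_names)}"
        )
    W = model.discriminant_basis
    if W.shape[1] < 2:
        raise ValueError("model has fewer than 2 discriminants")
    return np.asarray(X, dtype=float) @ W[:, :2]


def predict(
    model: LDAModel,
    X: np.ndarray,
    feature_names: Optional[Sequence[str]] = None,
) -> list[str]:
    """Nearest class under the pooled-covariance Mahalanobis metric plus log
    prior; ties break to the lexicographically first class."""
    if feature_names is not None and list(feature_names) != model.feature_names:
        raise ValueError("feature-name mismatch")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Sinv = np.linalg.pinv(model.pooled_covariance)
    scores = np.empty((X.shape[0], len(model.class_labels)))
    for k, mu in enumerate(model.class_means):
        d = X - mu
        scores[:, k] = -0.5 * np.einsum("ij,jk,ik->i", d, Sinv, d) + np.log(
            model.priors[k]
        )
    # class_labels is sorted, and argmax keeps the first maximum -> lexicographic ties
    return [model.class_labels[k] for k in np.argmax(scores, axis=1)]


def confusion_and_accuracy(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    class_labels: Optional[Sequence[str]] = None,
) -> ClassificationReport:
    """Counts matrix (rows = true, columns = predicted) and accuracy in percent."""
    t = list(true_labels)
    pr = list(predicted_labels)
    if len(t) != len(pr) or not t:
        raise ValueError("label sequences must have equal nonzero length")
    if class_labels is None:
        class_labels = sorted(set(t) | set(pr))
    else:
        class_labels = list(class_labels)
        unknown = (set(t) | set(pr)) - set(class_labels)
        if unknown:
            raise ValueError(f"labels outside the class set: {sorted(unknown)}")
    idx = {c: k for k, c in enumerate(class_labels)}
    cm = np.zeros((len(class_labels), len(class_labels)), dtype=int)
    for a, b in zip(t, pr):
        cm[idx[a], idx[b]] += 1
    accuracy = 100.0 * np.trace(cm) / cm.sum()
    recall = {}
    for c in class_labels:
        row = cm[idx[c]]
        recall[c] = 100.0 * row[idx[c]] / row.sum() if row.sum() else float("nan")
    return ClassificationReport(
        class_labels=class_labels, confusion=cm, accuracy=float(accuracy),
        per_class_recall=recall,
    )


def confidence_ellipse(scores: np.ndarray, level: float = 0.95) -> EllipseSpec:
    """Gaussian confidence ellipse of 2-D scores (chi-square scaling, 2 dof)."""
    S = np.asarray(scores, dtype=float)
    if S.ndim != 2 or S.shape[1] != 2 or S.shape[0] < 3:
        raise ValueError("need at least 3 two-dimensional points")
    center = S.mean(axis=0)
    cov = np.cov(S.T)
    evals, evecs = np.linalg.eigh(cov)
    if np.any(evals <= 0):
        raise ValueError("degenerate covariance: ellipse undefined")
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    scale = np.sqrt(scipy.stats.chi2.ppf(level, df=2))
    rotation = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return EllipseSpec(center=center, semi_axes=np.sqrt(evals) * scale,
                       rotation=rotation, level=level)


# ---------------------------------------------------------------------------
# end-to-end benchmark

_EXTRACTORS: dict[str, Callable] = {}


def _extract_family(
    family: str,
    signals: Iterable[PASignal],
    id_prefix: str,
    fd_band: tuple[float, float],
    arma_order: tuple[int, int],
    ss_options: dict,
) -> list[FeatureVector]:
    out = []
    for k, sig in enumerate(signals):
        sid = f"{id_prefix}{k:03d}"
        try:
            if family == "TD":
                out.append(time_domain_features(sig, sample_id=sid))
            elif family == "FD":
                out.append(frequency_domain_features(sig, band=fd_band, sample_id=sid))
            elif family == "ARMA":
                p, q = arma_order
                out.append(arma_features(sig, p=p, q=q, sample_id=sid))
            elif family == "SS":
                out.append(extract_ss_features(sig, sample_id=sid, **ss_options))
            else:
                raise ValueError(f"unknown family {family!r}")
        except (ModalExtractionError, IdentificationError, ValueError) as exc:
            logger.warning("sample %s excluded from family %s: %s", sid, family, exc)
    return out


def run_benchmark(
    config: SimulationConfig,
    families: Sequence[str] = FAMILIES,
    split_spec: str = "holdout20",
    n_test_per_class: int = 4,
    fd_band: tuple[float, float] = DEFAULT_FD_BAND,
    arma_order: tuple[int, int] = (2, 2),
    ss_options: Optional[dict] = None,
    shrinkage: Optional[float] = None,
) -> dict:
    """Simulate, extract all feature families, fit LDA per family, and report.

    ``split_spec``:
      * ``"holdout20"`` — training set from the class table, plus a freshly
        simulated stratified test set (``n_test_per_class`` per class).
      * ``"resubstitution"`` — train and test on the same simulated set
        (reports are flagged accordingly).
    """
    ss_options = dict(ss_options or {})
    train_signals = simulate_dataset(config)
    if split_spec == "holdout20":
        from dataclasses import replace as _replace

        test_cfg = _replace(config, seed=config.seed + 10_000)
        test_signals = simulate_dataset(
            test_cfg, n_samples_override=[n_test_per_class] * len(config.classes)
        )
    elif split_spec == "resubstitution":
        test_signals = train_signals
    else:
        raise ValueError(f"unknown split_spec {split_spec!r}")

    results: dict = {"split_spec": split_spec, "seed": config.seed, "families": {}}
    for family in families:
        train_fv = _extract_family(family, train_signals, "train", fd_band,
                                   arma_order, ss_options)
        test_fv = _extract_family(family, test_signals, "test", fd_band,
                                  arma_order, ss_options)
        if not train_fv or not test_fv:
            logger.warning("family %s excluded: no usable samples", family)
            continue
        n_train_classes = len({fv.label for fv in train_fv})
        if n_train_classes < 2:
            logger.warning("family %s excluded: fewer than 2 classes survived", family)
            continue
        Xtr, ytr, names = features_to_matrix(train_fv)
        Xte, yte, _ = features_to_matrix(test_fv)
        model = fit_lda(Xtr, ytr, feature_names=names, shrinkage=shrinkage)
        pred = predict(model, Xte)
        report = confusion_and_accuracy(yte, pred, class_labels=model.class_labels)
        report.meta["split_spec"] = split_spec
        report.meta["n_excluded_train"] = len(train_signals) - len(train_fv)
        report.meta["n_excluded_test"] = len(test_signals) - len(test_fv)
        scores = transform_lda(model, Xtr)
        ellipses = {}
        for c in model.class_labels:
            pts = scores[[l == c for l in ytr]]
            if pts.shape[0] >= 3:
                try:
                    ellipses[c] = confidence_ellipse(pts)
                except ValueError:
                    pass
        results["families"][family] = {
            "report": report,
            "lda": model,
            "train_features": train_fv,
            "test_features": test_fv,
            "train_scores": scores,
            "train_labels": ytr,
            "ellipses": ellipses,
        }

    # per-parameter group statistics on the SS family (when present)
    if "SS" in results["families"]:
        fvs = results["families"]["SS"]["train_features"]
        comparisons = {}
        for pname in ("alpha", "omega_n", "c1", "c2"):
            by_class: dict[str, list[float]] = {}
            for fv in fvs:
                by_class.setdefault(fv.label, []).append(fv.values[pname])
            try:
                comparisons[pname] = anova_bonferroni(by_class, parameter_name=pname)
            except ValueError as exc:
                logger.warning("ANOVA skipped for %s: %s", pname, exc)
        results["group_comparisons"] = comparisons
        # per-class NRMSE of the state-space refit
        nrmse_by_class: dict[str, list[float]] = {}
        for fv in fvs:
            if fv.meta.get("nrmse") is not None:
                nrmse_by_class.setdefault(fv.label, []).append(fv.meta["nrmse"])
        results["nrmse_by_class"] = {
            c: float(np.mean(v)) for c, v in sorted(nrmse_by_class.items())
        }
    return results
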