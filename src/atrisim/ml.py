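"""Endpoint classification, permutation importance and Shapley attribution.

Binary arrhythmia endpoints (induced at the LAA analogue, induced at the
roof analogue, induced at either, terminated within the tracking window) are
related to the electrolyte inputs with seeded classifiers: logistic
regression, random forest or gradient boosting (random forest is the default
reporting classifier). A guard requires at least two samples of each class.

The reported score is the coefficient of determination computed on the
predicted class-1 probability against the 0/1 labels; accuracy and AUROC are
reported alongside for transparency.

Feature attribution:

* permutation importance — mean and sd of the score drop over ``n``
  per-column permutations (default 100);
* exact Shapley values — full subset enumeration over the <= 5 features,
  with the value of a coalition defined as the expected model output when
  the complementary features are marginalised over a background sample
  (interventional Shapley). Additivity (local accuracy) holds exactly:
  for every row, base value + sum of Shapley values = predicted probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .ionic import DomainError

__all__ = [
    "ENDPOINT_NAMES", "FeatureTable", "GuardError", "ClassifierReport",
    "train_classifier", "permutation_importance", "shapley_summary",
    "AttributionReport", "attribution_report",
]

ENDPOINT_NAMES = ("induced_LAA", "induced_AR", "induced_any", "terminated")
BASE_FEATURES = ("Ko", "Nao", "Cao")
AUGMENTED_FEATURES = BASE_FEATURES + ("fibrosis_fraction", "surface_area")


class GuardError(ValueError):
    """Endpoint does not have >= 2 samples of each class."""


@dataclass
class FeatureTable:
    """Rows = (substrate x electrolyte set); features + binary endpoints.

    ``augmented`` mode adds the fibrosis fraction and atrial surface area to
    the three electrolyte features (cohort-level training).
    """

    df: pd.DataFrame
    augmented: bool = False

    def __post_init__(self) -> None:
        feats = self.feature_names
        missing = [c for c in feats if c not in self.df.columns]
        if missing:
            raise DomainError(f"missing feature columns {missing}")
        if self.df[list(feats)].isna().any().any():
            raise DomainError("feature table contains missing values")

    @property
    def feature_names(self) -> tuple:
        return AUGMENTED_FEATURES if self.augmented else BASE_FEATURES

    def X(self) -> np.ndarray:
        return self.df[list(self.feature_names)].to_numpy(dtype=float)

    def y(self, endpoint: str) -> np.ndarray:
        if endpoint not in self.df.columns:
            raise DomainError(f"unknown endpoint {endpoint}")
        return self.df[endpoint].to_numpy(dtype=float).astype(int)


@dataclass
class ClassifierReport:
    endpoint: str
    kind: str
    r2: float
    accuracy: float
    auroc: float
    n: int


def _proba(clf, X) -> np.ndarray:
    return clf.predict_proba(np.asarray(X, dtype=float))[:, 1]


def _score(clf, X, y) -> float:
    """R^2 of predicted class-1 probability against the binary labels."""
    from sklearn.metrics import r2_score
    return float(r2_score(y, _proba(clf, X)))


def train_classifier(table: FeatureTable, endpoint: str,
                     kind: str = "random_forest", seed: int = 0):
    """Fit a seeded classifier; returns ``(clf, ClassifierReport)``.

    Raises :class:`GuardError` unless both classes have >= 2 samples.
    """
    from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import accuracy_score, roc_auc_score

    X, y = table.X(), table.y(endpoint)
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise GuardError(
            f"endpoint {endpoint}: class counts {counts.tolist()} "
            "(need >= 2 each); endpoint skipped")

    if kind == "logit":
        clf = LogisticRegression(max_iter=2000, random_state=seed)
    elif kind == "random_forest":
        clf = RandomForestClassifier(n_estimators=200, random_state=seed)
    elif kind == "gradient_boost":
        clf = GradientBoostingClassifier(random_state=seed)
    else:
        raise DomainError(f"unknown classifier kind {kind!r}")
    clf.fit(X, y)
    p = _proba(clf, X)
    rep = ClassifierReport(
        endpoint=endpoint, kind=kind, r2=_score(clf, X, y),
        accuracy=float(accuracy_score(y, p > 0.5)),
        auroc=float(roc_auc_score(y, p)), n=len(y))
    return clf, rep


def permutation_importance(clf, table: FeatureTable, endpoint: str,
                           n_permutations: int = 100, seed: int = 0):
    """Per-feature score drop under column permutation (mean, sd over n).

    Returns a DataFrame indexed by feature with columns ``mean`` and ``sd``.
    """
    rng = np.random.default_rng(seed)
    X, y = table.X(), table.y(endpoint)
    base = _score(clf, X, y)
    names = table.feature_names
    drops = np.empty((len(names), n_permutations))
    for fi in range(len(names)):
        for r in range(n_permutations):
            Xp = X.copy()
            Xp[:, fi] = Xp[rng.permutation(len(y)), fi]
            drops[fi, r] = base - _score(clf, Xp, y)
    return pd.DataFrame({"mean": drops.mean(axis=1), "sd": drops.std(axis=1)},
                        index=list(names))


# ---------------------------------------------------------------------------
# Exact Shapley values by subset enumeration
# ---------------------------------------------------------------------------

def _coalition_values(clf, x: np.ndarray, background: np.ndarray) -> dict:
    """v(S) = E_b[f(x_S, b_~S)] for every coalition S (bitmask keyed)."""
    d = x.size
    nb = background.shape[0]
    values = {}
    for m in range(1 << d):
        Xs = background.copy()
        for fi in range(d):
            if m >> fi & 1:
                Xs[:, fi] = x[fi]
        values[m] = float(np.mean(_proba(clf, Xs)))
    return values


def shapley_values(clf, X: np.ndarray, background: np.ndarray | None = None,
                   max_features: int = 12) -> tuple:
    """Exact interventional Shapley values of the class-1 probability.

    Returns ``(phi (n, d), base_value)`` with
    ``base + phi.sum(axis=1) == predict_proba[:, 1]`` exactly (local
    accuracy), by the efficiency property of the Shapley value. Cost is
    O(2^d) model evaluations per row; guarded to ``max_features``.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if d > max_features:
        raise DomainError(f"{d} features; exact enumeration capped at {max_features}")
    if background is None:
        background = X
    background = np.asarray(background, dtype=float)

    # Shapley kernel weights per coalition size
    w = {s: 1.0 / (d * comb(d - 1, s)) for s in range(d)}

    phi = np.zeros((n, d))
    base = float(np.mean(_proba(clf, background)))
    for r in range(n):
        v = _coalition_values(clf, X[r], background)
        for fi in range(d):
            others = [k for k in range(d) if k != fi]
            for s in range(d):
                for S in combinations(others, s):
                    m = 0
                    for k in S:
                        m |= 1 << k
                    phi[r, fi] += w[s] * (v[m | (1 << fi)] - v[m])
    return phi, base


def shapley_summary(clf, table: FeatureTable,
                    background: np.ndarray | None = None) -> pd.DataFrame:
    """Per-row, per-feature Shapley values as a long-format DataFrame
    (columns ``feature``, ``value``, ``row``) ready for violin plots."""
    if not hasattr(clf, "predict_proba"):
        raise DomainError("classifier must expose predict_proba")
    X = table.X()
    phi, base = shapley_values(clf, X, background)
    names = table.feature_names
    rows = [{"row": r, "feature": names[fi], "value": phi[r, fi]}
            for r in range(X.shape[0]) for fi in range(len(names))]
    out = pd.DataFrame(rows)
    out.attrs["base_value"] = base
    return out


@dataclass
class AttributionReport:
    """Combined importance + Shapley report for one endpoint."""

    endpoint: str
    classifier_kind: str
    r2: float
    n_permutations: int
    importance: pd.DataFrame            # per-feature mean/sd
    shapley: pd.DataFrame               # long format
    base_value: float
    meta: dict = field(default_factory=dict)


def attribution_report(table: FeatureTable, endpoint: str,
                       kind: str = "random_forest", seed: int = 0,
                       n_permutations: int = 100) -> AttributionReport:
    """Train, score and attribute one endpoint end to end."""
    clf, rep = train_classifier(table, endpoint, kind=kind, seed=seed)
    imp = permutation_importance(clf, table, endpoint,
                                 n_permutations=n_permutations, seed=seed)
    shap_df = shapley_summary(clf, table)
    return AttributionReport(
        endpoint=endpoint, classifier_kind=kind, r2=rep.r2,
        n_permutations=n_permutations, importance=imp, shapley=shap_df,
        base_value=shap_df.attrs["base_value"],
        meta={"accuracy": rep.accuracy, "auroc": rep.auroc, "n": rep.n})


def violin_plot(report: AttributionReport, path) -> None:
    """Shapley violin plot (one violin per feature), saved to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    feats = report.importance.index.tolist()
    data = [report.shapley.loc[report.shapley.feature == f, "value"].to_numpy()
            for f in feats]
    fig, ax = plt.subplots(figsize=(1.5 * len(feats) + 2, 4))
    ax.violinplot(data, showmeans=True)
    ax.set_xticks(range(1, len(feats) + 1), feats)
    ax.set_ylabel("Shapley value")
    ax.set_title(f"{report.endpoint} ({report.classifier_kind})")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
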