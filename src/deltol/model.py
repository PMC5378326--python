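"""Classifiers of deletion tolerance and their cross-validated evaluation.

Two learners predict whether a deletion is tolerated from structural
predictors (RSA, WCN, secondary structure, mean design score): a
maximum-likelihood logistic regression and a soft-margin SVM with an RBF
kernel (cost C = 1, kernel width gamma = 1/d with d the number of encoded
predictor columns).  Performance is measured by the pooled-ROC
cross-validated AUC: each round of k-fold cross-validation pools the
out-of-fold scores of all rows into one ROC curve, and the round is
repeated with independent random partitions to give a mean AUC and its
standard error.

The user-facing surface follows the model/results idiom::

    model = ToleranceModel(table, predictors=("rsa", "wcn"), learner="logistic")
    res = model.fit()           # full-data fit: coefficients, in-sample AUC
    cv = model.cross_validate(CVConfig(k=10, repetitions=100, seed=7))
    print(cv.summary())
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from sklearn.metrics import roc_curve
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationWarning,
)

from .exceptions import (
    DegenerateLabelError,
    EncodingError,
    UndefinedAUCError,
)

logger = logging.getLogger(__name__)

#: Canonical predictor names, in canonical order.
PREDICTORS = ("rsa", "wcn", "ss", "mean_score")

_DISPLAY = {"rsa": "RSA", "wcn": "WCN", "ss": "SS", "mean_score": "Mean Score"}

SS_LEVELS = ("helix", "loop", "sheet")  # alphabetical; helix = reference


@dataclass(frozen=True)
class ModelSpec:
    """A predictor subset plus the learner used to fit it."""

    predictors: tuple[str, ...]
    learner: str = "logistic"

    def __post_init__(self) -> None:
        if not self.predictors:
            raise ValueError("predictor set must be non-empty")
        unknown = set(self.predictors) - set(PREDICTORS)
        if unknown:
            raise ValueError(f"unknown predictors: {sorted(unknown)}")
        if self.learner not in ("logistic", "svm_rbf"):
            raise ValueError(f"unknown learner {self.learner!r}")
        # canonical order, no duplicates
        canonical = tuple(p for p in PREDICTORS if p in self.predictors)
        object.__setattr__(self, "predictors", canonical)

    @property
    def name(self) -> str:
        return " + ".join(_DISPLAY[p] for p in self.predictors)


def enumerate_model_specs(learner: str = "logistic") -> list[ModelSpec]:
    """All 15 non-empty predictor subsets, ordered by size then lexically."""
    subsets = []
    for size in range(1, len(PREDICTORS) + 1):
        for combo in itertools.combinations(PREDICTORS, size):
            subsets.append(combo)
    subsets.sort(key=lambda c: (len(c), tuple(sorted(c))))
    return [ModelSpec(predictors=c, learner=learner) for c in subsets]


@dataclass
class EncodedDesign:
    """Numeric design matrix, column names and 0/1 label vector (1=tolerated)."""

    X: np.ndarray
    columns: list[str]
    y: np.ndarray
    index: np.ndarray

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def encode_design(
    table: pd.DataFrame,
    spec: ModelSpec,
    drop_ss_reference: Optional[bool] = None,
) -> EncodedDesign:
    """Encode a feature table for one model specification.

    Continuous predictors are copied as-is.  Secondary structure expands to
    indicator columns; for the logistic learner the reference level
    (``helix``, alphabetically first) is dropped to keep the design full
    rank, while the SVM keeps all three indicators.

    Raises
    ------
    EncodingError
        If any required column has missing values (rows are listed).
    """
    if drop_ss_reference is None:
        drop_ss_reference = spec.learner == "logistic"
    needed = [p if p != "ss" else "ss" for p in spec.predictors]
    cols: list[np.ndarray] = []
    names: list[str] = []
    for p in spec.predictors:
        if p == "ss":
            levels = SS_LEVELS[1:] if drop_ss_reference else SS_LEVELS
            for level in levels:
                cols.append((table["ss"] == level).to_numpy(dtype=float))
                names.append(f"ss_{level}")
        else:
            vals = table[p].to_numpy(dtype=float)
            cols.append(vals)
            names.append(p)
    X = np.column_stack(cols)
    bad = np.argwhere(~np.isfinite(X))
    if bad.size:
        rows = sorted({int(r) for r, _ in bad})
        ids = (
            table["mutant_id"].iloc[rows].tolist()
            if "mutant_id" in table.columns
            else rows
        )
        raise EncodingError(
            f"missing/non-finite values in columns {needed} for rows {ids}"
        )
    y = table["functional"].to_numpy(dtype=int)
    return EncodedDesign(
        X=X, columns=names, y=y, index=np.asarray(table.index)
    )


# ---------------------------------------------------------------------------
# learners


@dataclass
class LogisticFit:
    """A maximum-likelihood logit fit: coefficients, SEs, fitted scores."""

    params: pd.Series
    bse: pd.Series
    fitted: np.ndarray  # in-sample predicted P(tolerated)
    separation: bool
    _sm_result: object = field(repr=False, default=None)

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xc = sm.add_constant(X, has_constant="add")
        eta = Xc @ self.params.to_numpy()
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))


def fit_logistic(design: EncodedDesign) -> LogisticFit:
    """Maximum-likelihood logistic regression (binomial GLM with logit link).

    Complete separation is detected and logged; the fit at the iteration
    cap is still returned so cross-validation never aborts mid-round.
    """
    _require_both_classes(design.y)
    if len(design.y) < 2:
        raise DegenerateLabelError("need at least 2 rows")
    Xc = sm.add_constant(design.X, has_constant="add")
    model = sm.Logit(design.y, Xc)
    model.raise_on_perfect_prediction = False
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        with np.errstate(all="ignore"):
            try:
                result = model.fit(
                    disp=0, maxiter=100, warn_convergence=False
                )
            except np.linalg.LinAlgError:
                # singular Hessian (e.g. a constant indicator column in a
                # small training fold): fall back to a gradient method
                logger.info(
                    "Newton step hit a singular Hessian; refitting with BFGS"
                )
                result = model.fit(
                    method="bfgs", disp=0, maxiter=200,
                    warn_convergence=False,
                )
    for w in caught:
        if issubclass(w.category, PerfectSeparationWarning):
            separation = True
    if separation:
        logger.warning(
            "complete separation detected in logistic fit; "
            "coefficients taken at the iteration cap"
        )
    names = ["const"] + list(design.columns)
    with np.errstate(over="ignore"):
        fitted = np.asarray(result.predict(Xc))
    return LogisticFit(
        params=pd.Series(result.params, index=names),
        bse=pd.Series(result.bse, index=names),
        fitted=fitted,
        separation=separation,
        _sm_result=result,
    )


@dataclass
class SVMFit:
    """A fitted RBF-kernel SVM plus its training-fold standardization."""

    scaler: StandardScaler
    svc: SVC
    gamma: float
    fitted: np.ndarray  # in-sample decision values (positive => tolerated)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svc.decision_function(self.scaler.transform(X))


def fit_svm_rbf(
    design: EncodedDesign, C: float = 1.0, gamma: Optional[float] = None
) -> SVMFit:
    """Soft-margin RBF-kernel SVM with gamma defaulting to 1/d.

    ``d`` is the number of encoded predictor columns.  Features are
    standardized (zero mean, unit variance) using training statistics
    before fitting; the ranking score is the signed decision value.
    """
    _require_both_classes(design.y)
    if gamma is None:
        gamma = 1.0 / design.n_features
    scaler = StandardScaler().fit(design.X)
    svc = SVC(C=C, kernel="rbf", gamma=gamma)
    Xs = scaler.transform(design.X)
    svc.fit(Xs, design.y)
    return SVMFit(
        scaler=scaler,
        svc=svc,
        gamma=gamma,
        fitted=svc.decision_function(Xs),
    )


def _require_both_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise DegenerateLabelError(
            "both tolerated and non-tolerated labels are required"
        )


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass
class ROCResult:
    """An ROC curve (thresholds, FPR, TPR) and its trapezoidal AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """ROC curve over all score thresholds and its area.

    Scores must be oriented so that larger means more likely tolerated.
    The trapezoidal AUC equals the tie-corrected rank statistic
    P(s+ > s-) + 0.5 P(s+ = s-).

    Raises
    ------
    UndefinedAUCError
        If only one class is present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise UndefinedAUCError("AUC undefined with a single class")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVConfig:
    """Repeated k-fold configuration (defaults: 10 folds, 100 repetitions)."""

    k: int = 10
    repetitions: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


def kfold_partition(
    n: int, k: int, rng: int | np.random.Generator
) -> list[np.ndarray]:
    """Random partition of ``range(n)`` into k folds of near-equal size."""
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    perm = rng.permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


def _oof_scores(
    design: EncodedDesign,
    partition: Sequence[np.ndarray],
    learner: str,
    C: float,
    gamma: Optional[float],
) -> np.ndarray:
    n = len(design.y)
    out = np.full(n, np.nan)
    for fold in partition:
        mask = np.zeros(n, dtype=bool)
        mask[fold] = True
        train = EncodedDesign(
            X=design.X[~mask],
            columns=design.columns,
            y=design.y[~mask],
            index=design.index[~mask],
        )
        if learner == "logistic":
            fit = fit_logistic(train)
        else:
            fit = fit_svm_rbf(train, C=C, gamma=gamma)
        out[mask] = fit.predict(design.X[mask])
    return out


def _partition_is_degenerate(
    y: np.ndarray, partition: Sequence[np.ndarray]
) -> bool:
    n = len(y)
    for fold in partition:
        mask = np.zeros(n, dtype=bool)
        mask[fold] = True
        if len(np.unique(y[~mask])) < 2:
            return True
    return False


def pooled_cv_predictions(
    table: pd.DataFrame,
    spec: ModelSpec,
    partition: Sequence[np.ndarray],
    C: float = 1.0,
    gamma: Optional[float] = None,
) -> np.ndarray:
    """Out-of-fold score for every row: fold f scored by a model trained
    on the complement of f.  Logistic scores are probabilities, SVM scores
    signed decision values.

    Raises
    ------
    DegenerateLabelError
        If some training complement contains a single class.
    """
    design = encode_design(table, spec)
    if _partition_is_degenerate(design.y, partition):
        raise DegenerateLabelError(
            "a training fold-complement contains a single class"
        )
    return _oof_scores(design, partition, spec.learner, C, gamma)


@dataclass
class CVSummary:
    """Repetition-wise pooled AUCs of one model spec, with mean and SE."""

    spec: ModelSpec
    repetition_aucs: np.ndarray
    n_redraws: int = 0

    def __post_init__(self) -> None:
        self.repetition_aucs = np.asarray(self.repetition_aucs, dtype=float)

    @property
    def repetitions(self) -> int:
        return len(self.repetition_aucs)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.repetition_aucs))

    @property
    def se_auc(self) -> float:
        if self.repetitions < 2:
            return float("nan")
        return float(
            np.std(self.repetition_aucs, ddof=1) / np.sqrt(self.repetitions)
        )

    def summary(self) -> str:
        return (
            f"{self.spec.name} [{self.spec.learner}]: "
            f"mean CV AUC = {self.mean_auc:.3f} +/- {self.se_auc:.4f} "
            f"({self.repetitions} repetitions of 10-fold CV)"
        )


def repeated_cv_auc(
    table: pd.DataFrame,
    spec: ModelSpec,
    cv: CVConfig,
    C: float = 1.0,
    gamma: Optional[float] = None,
    max_redraws: int = 100,
) -> CVSummary:
    """Repeated k-fold pooled-ROC AUC for one model spec.

    Repetition ``r`` draws an independent random partition from
    ``cv.seed + r``; partitions leaving a single-class training set are
    re-drawn (logged).  Returns the per-repetition AUCs with their mean
    and standard error (sd across repetitions / sqrt(repetitions)).
    """
    design = encode_design(table, spec)
    _require_both_classes(design.y)
    n = len(design.y)
    aucs = np.empty(cv.repetitions)
    n_redraws = 0
    for r in range(cv.repetitions):
        rng = np.random.default_rng(cv.seed + r)
        partition = kfold_partition(n, cv.k, rng)
        redraw = 0
        while _partition_is_degenerate(design.y, partition):
            redraw += 1
            if redraw > max_redraws:
                raise DegenerateLabelError(
                    "could not draw a partition with two-class training sets"
                )
            partition = kfold_partition(n, cv.k, rng)
        if redraw:
            logger.info(
                "repetition %d: re-drew partition %d time(s) to avoid a "
                "single-class training fold", r, redraw,
            )
            n_redraws += redraw
        scores = _oof_scores(design, partition, spec.learner, C, gamma)
        aucs[r] = roc_auc(scores, design.y).auc
    return CVSummary(spec=spec, repetition_aucs=aucs, n_redraws=n_redraws)


def full_fit_auc(
    table: pd.DataFrame,
    spec: ModelSpec,
    C: float = 1.0,
    gamma: Optional[float] = None,
) -> float:
    """In-sample AUC of a model fitted to the entire dataset ("Model AUC")."""
    design = encode_design(table, spec)
    if spec.learner == "logistic":
        fit = fit_logistic(design)
    else:
        fit = fit_svm_rbf(design, C=C, gamma=gamma)
    return roc_auc(fit.fitted, design.y).auc


def compare_models(
    a: CVSummary, b: CVSummary, paired: bool = False
) -> tuple[float, float]:
    """t-test on two repetition-AUC lists (Welch by default).

    ``paired=True`` runs a paired t-test instead, appropriate when the two
    summaries were computed with shared partition seeds.
    """
    xa, xb = a.repetition_aucs, b.repetition_aucs
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("need >= 2 repetition AUCs per model")
    if paired:
        if len(xa) != len(xb):
            raise ValueError("paired comparison needs equal-length AUC lists")
        diffs = xa - xb
        if np.all(diffs == 0):
            return 0.0, 1.0
        t, p = scipy.stats.ttest_rel(xa, xb)
    else:
        if np.std(xa) == 0 and np.std(xb) == 0:
            if np.mean(xa) == np.mean(xb):
                return 0.0, 1.0
            return float(np.inf) * np.sign(np.mean(xa) - np.mean(xb)), 0.0
        t, p = scipy.stats.ttest_ind(xa, xb, equal_var=False)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# model/results front end


class ToleranceModel:
    """Deletion-tolerance classifier over a feature table.

    Parameters
    ----------
    table : pandas.DataFrame
        Feature table with columns ``rsa, wcn, ss, mean_score, functional``
        (only the columns named in ``predictors`` need be complete).
    predictors : sequence of str
        Subset of ``("rsa", "wcn", "ss", "mean_score")``.
    learner : str
        ``"logistic"`` or ``"svm_rbf"``.
    C, gamma : float
        SVM cost and kernel width; ``gamma=None`` means 1/d.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        predictors: Sequence[str] = PREDICTORS,
        learner: str = "logistic",
        C: float = 1.0,
        gamma: Optional[float] = None,
    ) -> None:
        self.table = table.reset_index(drop=True)
        self.spec = ModelSpec(predictors=tuple(predictors), learner=learner)
        self.C = C
        self.gamma = gamma

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, **kwargs) -> "ToleranceModel":
        return cls(table, **kwargs)

    def fit(self) -> "ToleranceResults":
        """Fit on all rows; returns coefficients (logistic) and in-sample AUC."""
        design = encode_design(self.table, self.spec)
        if self.spec.learner == "logistic":
            fit = fit_logistic(design)
        else:
            fit = fit_svm_rbf(design, C=self.C, gamma=self.gamma)
        roc = roc_auc(fit.fitted, design.y)
        return ToleranceResults(model=self, design=design, fit=fit, roc=roc)

    def cross_validate(self, cv: Optional[CVConfig] = None) -> CVSummary:
        """Repeated k-fold pooled-ROC AUC under this model's spec."""
        if cv is None:
            cv = CVConfig()
        return repeated_cv_auc(
            self.table, self.spec, cv, C=self.C, gamma=self.gamma
        )


class ToleranceResults:
    """Results of a full-data fit: parameters, scores, ROC and summary table."""

    def __init__(self, model, design, fit, roc) -> None:
        self.model = model
        self.design = design
        self._fit = fit
        self.roc = roc

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    @property
    def auc(self) -> float:
        """In-sample ("Model") AUC."""
        return self.roc.auc

    @property
    def params(self) -> Optional[pd.Series]:
        return getattr(self._fit, "params", None)

    @property
    def bse(self) -> Optional[pd.Series]:
        return getattr(self._fit, "bse", None)

    @property
    def fittedvalues(self) -> np.ndarray:
        """In-sample ranking scores (probabilities or decision values)."""
        return self._fit.fitted

    def predict(self, table: Optional[pd.DataFrame] = None) -> np.ndarray:
        """Ranking scores for new rows (or the training rows by default)."""
        if table is None:
            return self.fittedvalues
        design = encode_design(
            table.reset_index(drop=True), self.spec,
            drop_ss_reference=self.spec.learner == "logistic",
        )
        return self._fit.predict(design.X)

    def summary(self) -> str:
        lines = [
            f"Deletion-tolerance model: {self.spec.name}",
            f"Learner: {self.spec.learner}   n = {len(self.design.y)}   "
            f"Model AUC = {self.auc:.3f}",
        ]
        if self.params is not None:
            tbl = pd.DataFrame({"coef": self.params, "std err": self.bse})
            lines.append(tbl.to_string(float_format=lambda v: f"{v:10.4f}"))
            if getattr(self._fit, "separation", False):
                lines.append(
                    "warning: complete separation detected; coefficients "
                    "taken at the iteration cap"
                )
        else:
            lines.append(
                f"RBF-SVM: C = {self.model.C}, gamma = {self._fit.gamma:.4f} "
                f"(1/d), support vectors = {len(self._fit.svc.support_)}"
            )
        return "\n".join(lines)


def evaluate_models(
    table: pd.DataFrame,
    learner: str,
    cv: CVConfig,
    C: float = 1.0,
    gamma: Optional[float] = None,
    return_summaries: bool = False,
):
    """Score all 15 predictor subsets for one learner.

    Returns a table with columns ``model, model_auc, mean_cv_auc,
    se_cv_auc`` sorted by descending mean cross-validated AUC — the same
    layout as the headline model-comparison tables of the analysis.  With
    ``return_summaries=True`` also returns the per-spec :class:`CVSummary`
    objects keyed by model name (for pairwise comparisons).
    """
    rows = []
    summaries: dict[str, CVSummary] = {}
    for spec in enumerate_model_specs(learner):
        summary = repeated_cv_auc(table, spec, cv, C=C, gamma=gamma)
        summaries[spec.name] = summary
        rows.append(
            {
                "model": spec.name,
                "model_auc": full_fit_auc(table, spec, C=C, gamma=gamma),
                "mean_cv_auc": summary.mean_auc,
                "se_cv_auc": summary.se_auc,
            }
        )
    df = pd.DataFrame(rows).sort_values(
        "mean_cv_auc", ascending=False, ignore_index=True
    )
    if return_summaries:
        return df, summaries
    return df
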