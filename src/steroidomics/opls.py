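"""OPLS discriminant model with VIP selection and an LLR probability link.

Orthogonal projections to latent structures (OPLS) regresses a group code
(+1 patient / -1 control) on the standardized steroidomic predictors,
splitting predictor variability into a single component predictive of the
response and a single component orthogonal to it:

    X = Tp Pp' + To Po' + E        (predictors)
    y = Tp c  + f                  (response)

The orthogonal component absorbs the strong shared variation of steroids in
the same pathway, which would otherwise contaminate the predictive weights
of ordinary single-component PLS.  With the orthogonal structure removed,
the predictive weights of OPLS coincide with those of one-component PLS.

The fitted linear prediction is mapped to a log-likelihood ratio of class
membership by a one-dimensional equal-variance Gaussian discriminant on the
predictive score, so that the training decision point maps to LLR 0 and
probability = exp(LLR)/(1+exp(LLR)).  Model reduction uses variable
importance in projection (VIP, mean squared value 1); multivariate
homogeneity is screened with Hotelling's T-squared on the score pair; the
explained response variability is cross-validated with venetian-blind
folds (default 7).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = [
    "OplsModel",
    "ClassificationReport",
    "fit_opls",
    "vip_scores",
    "select_predictors",
    "hotelling_screen",
    "cross_validated_explained",
    "predict_llr",
    "wald_ci",
    "classification_report",
    "model_summary",
]

_MIN_PER_GROUP = 6


def _coerce_y(y) -> np.ndarray:
    arr = np.asarray(y)
    if arr.dtype.kind in "OUS":
        out = np.where(arr == "patient", 1.0, -1.0)
        if not set(np.unique(arr)) <= {"patient", "control"}:
            raise ValueError("labels must be 'patient' or 'control'")
        return out
    out = arr.astype(float)
    if not set(np.unique(out)) <= {-1.0, 1.0}:
        raise ValueError("numeric y must be coded +1 (patient) / -1 (control)")
    return out


@dataclass
class OplsModel:
    """Fitted OPLS model (1 predictive + up to 1 orthogonal component)."""

    variables: tuple[str, ...]
    w: np.ndarray                 # predictive weights, unit norm
    Pp: np.ndarray                # predictive loadings (X side)
    c: float                      # response loading (y side)
    w_ortho: np.ndarray | None    # orthogonal weights, unit norm (None if absent)
    Po: np.ndarray | None         # orthogonal loadings
    Tp: np.ndarray                # predictive scores (training subjects)
    To: np.ndarray                # orthogonal scores (zeros if absent)
    E: np.ndarray                 # predictor residuals
    F_res: np.ndarray             # response residuals
    y_mean: float
    llr_scale: float              # a in llr = a * (yhat - decision point)
    llr_offset: float             # the decision point on the yhat scale
    b: np.ndarray                 # llr = X @ b + b0
    b0: float
    loading_R: np.ndarray         # corr(X_j, Tp)
    vip: np.ndarray
    explained_fit: float          # % of response SS explained in fit
    explained_cv: float | None = None
    # training data retained for refits (selection, outlier removal)
    X_train: np.ndarray = field(default=None, repr=False)
    y_train: np.ndarray = field(default=None, repr=False)

    def _project(self, X: np.ndarray) -> np.ndarray:
        """Predictive score of new observations (orthogonal part removed)."""
        if self.w_ortho is not None:
            to = X @ self.w_ortho
            X = X - np.outer(to, self.Po)
        return X @ self.w

    def predict_yhat(self, X: np.ndarray) -> np.ndarray:
        return self._project(X) * self.c + self.y_mean


def fit_opls(X, y, n_ortho: int = 1) -> OplsModel:
    """Fit the OPLS model on standardized predictors.

    Parameters
    ----------
    X : DataFrame or array, subjects x variables, standardized.
    y : group labels ("patient"/"control") or +1/-1 codes.
    n_ortho : number of orthogonal components; this implementation is fixed
        at one predictive + at most one orthogonal component, so only 0 or 1
        is accepted.
    """
    if n_ortho not in (0, 1):
        raise ValueError("component counts are fixed at 1 predictive + 1 orthogonal")
    if isinstance(X, pd.DataFrame):
        variables = tuple(str(c) for c in X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        variables = tuple(f"x{j}" for j in range(Xm.shape[1]))
    yv = _coerce_y(y)
    if np.ptp(yv) == 0:
        raise ValueError("response is constant; need both groups")
    n_pat = int(np.sum(yv > 0))
    n_ctl = int(np.sum(yv < 0))
    if min(n_pat, n_ctl) < _MIN_PER_GROUP:
        raise ValueError(f"need at least {_MIN_PER_GROUP} subjects per group")
    if not np.all(np.isfinite(Xm)):
        raise ValueError("predictor matrix must be finite (no missing values)")
    y_mean = float(np.mean(yv))
    yc = yv - y_mean

    w1 = Xm.T @ yc
    nw1 = np.linalg.norm(w1)
    if nw1 == 0:
        raise ValueError("predictors are uncorrelated with the response (rank issue)")
    w1 = w1 / nw1
    t1 = Xm @ w1
    p1 = Xm.T @ t1 / (t1 @ t1)

    w_ortho = None
    Po = None
    To = np.zeros_like(yv)
    Xf = Xm
    if n_ortho == 1:
        wo = p1 - (w1 @ p1) * w1
        nwo = np.linalg.norm(wo)
        if nwo > 1e-10 * max(np.linalg.norm(p1), 1.0):
            wo = wo / nwo
            to = Xm @ wo
            po = Xm.T @ to / (to @ to)
            Xf = Xm - np.outer(to, po)
            w_ortho, Po, To = wo, po, to

    w = Xf.T @ yc
    w = w / np.linalg.norm(w)
    Tp = Xf @ w
    Pp = Xf.T @ Tp / (Tp @ Tp)
    c = float(yc @ Tp / (Tp @ Tp))

    # orient the predictive direction so patients score positive
    if np.mean(Tp[yv > 0]) < np.mean(Tp[yv < 0]):
        w, Tp, Pp, c = -w, -Tp, -Pp, -c

    yhat = Tp * c + y_mean
    F_res = yv - yhat
    E = Xf - np.outer(Tp, Pp)
    ss_tot = float(np.sum(yc**2))
    explained_fit = 100.0 * (1.0 - float(np.sum(F_res**2)) / ss_tot)

    # LLR link: equal-variance Gaussian discriminant on the fitted yhat
    mu1 = float(np.mean(yhat[yv > 0]))
    mu0 = float(np.mean(yhat[yv < 0]))
    s2 = (
        float(np.sum((yhat[yv > 0] - mu1) ** 2) + np.sum((yhat[yv < 0] - mu0) ** 2))
        / max(n_pat + n_ctl - 2, 1)
    )
    s2 = max(s2, 1e-12)
    llr_scale = (mu1 - mu0) / s2
    llr_offset = (mu1 + mu0) / 2.0

    # equivalent multiple-regression coefficients on the llr scale
    b_y = c * (w - (w_ortho * (Po @ w) if w_ortho is not None else 0.0))
    b = llr_scale * b_y
    b0 = llr_scale * (y_mean - llr_offset)

    sdT = np.std(Tp)
    sdX = np.std(Xm, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        loading_R = (Xm - Xm.mean(axis=0)).T @ (Tp - Tp.mean()) / (
            Xm.shape[0] * np.where(sdX > 0, sdX, np.nan) * (sdT if sdT > 0 else np.nan)
        )
    loading_R = np.clip(np.nan_to_num(loading_R), -1.0, 1.0)

    vip = np.sqrt(len(variables)) * np.abs(w)  # ||w|| == 1

    return OplsModel(
        variables=variables,
        w=w,
        Pp=Pp,
        c=c,
        w_ortho=w_ortho,
        Po=Po,
        Tp=Tp,
        To=To,
        E=E,
        F_res=F_res,
        y_mean=y_mean,
        llr_scale=llr_scale,
        llr_offset=llr_offset,
        b=b,
        b0=b0,
        loading_R=loading_R,
        vip=vip,
        explained_fit=explained_fit,
        X_train=Xm,
        y_train=yv,
    )


def vip_scores(model: OplsModel) -> np.ndarray:
    """Variable importance in projection over the predictive component.

    With one predictive component and unit-norm weights this reduces to
    sqrt(p) * |w_j|; the mean of the squared VIPs is exactly 1.
    """
    return model.vip.copy()


def select_predictors(
    model: OplsModel, threshold: float = 1.0, rounds: int = 1
) -> tuple[OplsModel, tuple[str, ...]]:
    """Drop variables with VIP below ``threshold``, then refit once.

    A single elimination round is the default; a second round (re-applying
    the cut to the refitted VIPs) is the permitted maximum.  More rounds
    would keep shaving the panel indefinitely, because VIPs are
    renormalized to mean square 1 on every refit.  Returns the refitted
    model and the kept variable names.
    """
    if not 1 <= rounds <= 2:
        raise ValueError("at most two elimination rounds are supported")
    if threshold <= 0:
        return model, model.variables
    current = model
    for _ in range(rounds):
        keep = current.vip >= threshold
        if keep.all():
            break
        if not keep.any():
            raise ValueError(
                "threshold eliminates every predictor; lower the VIP threshold"
            )
        names = tuple(v for v, k in zip(current.variables, keep) if k)
        Xk = pd.DataFrame(current.X_train[:, keep], columns=names)
        current = fit_opls(Xk, current.y_train)
    return current, current.variables


def hotelling_screen(model: OplsModel, level: float = 0.95) -> np.ndarray:
    """Inlier flags from Hotelling's T-squared on the (Tp, To) score pair.

    The T-squared of each subject's score pair is compared with the
    F-distribution ellipse at ``level``; True marks inliers.  ``level = 1``
    flags nothing.
    """
    scores = [model.Tp]
    if model.w_ortho is not None:
        scores.append(model.To)
    S = np.column_stack(scores)
    n, k = S.shape
    if n < 10:
        raise ValueError("need at least 10 subjects for the homogeneity screen")
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    var = np.var(S, axis=0, ddof=1)
    t2 = np.sum(S**2 / var, axis=1)
    if level == 1.0:
        return np.ones(n, dtype=bool)
    limit = k * (n - 1) * (n + 1) / (n * (n - k)) * stats.f.ppf(level, k, n - k)
    return t2 <= limit


def _venetian_folds(n: int, folds: int, offset: int = 0) -> np.ndarray:
    return (np.arange(n) + offset) % folds


def cross_validated_explained(X, y, folds: int = 7, n_ortho: int = 1) -> float:
    """Cross-validated % of response variability explained (Q2 x 100).

    Venetian-blind assignment (every ``folds``-th subject shares a fold);
    each fold is predicted from a model fitted on the remainder and the
    PRESS is referenced to the total response sum of squares.  If some
    training split would lose a class the assignment is deterministically
    reshuffled once; a second failure raises.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    Xm = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    yv = _coerce_y(y)
    n = len(yv)
    assign = _venetian_folds(n, folds)

    def _valid(a: np.ndarray) -> bool:
        for f in range(folds):
            tr = yv[a != f]
            if tr.size == 0 or np.ptp(tr) == 0 or np.min(
                [np.sum(tr > 0), np.sum(tr < 0)]
            ) < _MIN_PER_GROUP:
                return False
        return True

    if not _valid(assign):
        perm = np.random.default_rng(0).permutation(n)
        assign = np.empty(n, dtype=int)
        assign[perm] = np.arange(n) % folds
        if not _valid(assign):
            raise ValueError("cannot build folds retaining both classes")
    press = 0.0
    for f in range(folds):
        tr = assign != f
        sub = fit_opls(Xm[tr], yv[tr], n_ortho=n_ortho)
        pred = sub.predict_yhat(Xm[~tr])
        press += float(np.sum((yv[~tr] - pred) ** 2))
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    return 100.0 * (1.0 - press / ss_tot)


def predict_llr(model: OplsModel, X_new):
    """LLR, probability and predicted label for new observations.

    ``X_new`` must carry the model's variables (DataFrame columns are
    aligned by name).  probability = exp(llr) / (1 + exp(llr)); the label is
    "patient" iff probability > 0.5.
    """
    if isinstance(X_new, pd.DataFrame):
        lookup = {str(c): c for c in X_new.columns}
        missing = [v for v in model.variables if v not in lookup]
        if missing:
            raise KeyError(f"missing model variables: {missing}")
        Xm = X_new[[lookup[v] for v in model.variables]].to_numpy(dtype=float)
    else:
        Xm = np.atleast_2d(np.asarray(X_new, dtype=float))
        if Xm.shape[1] != len(model.variables):
            raise ValueError(
                f"expected {len(model.variables)} variables, got {Xm.shape[1]}"
            )
    yhat = model.predict_yhat(Xm)
    llr = model.llr_scale * (yhat - model.llr_offset)
    prob = expit(llr)
    labels = np.where(prob > 0.5, "patient", "control")
    return llr, prob, labels


def wald_ci(p_hat: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wald confidence interval for a proportion, clipped to [0, 1]."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= p_hat <= 1:
        raise ValueError("p_hat must be in [0, 1]")
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(p_hat * (1.0 - p_hat) / n)
    return (max(0.0, p_hat - half), min(1.0, p_hat + half))


@dataclass
class ClassificationReport:
    """Per-subject predictions and in-sample operating characteristics."""

    llr: np.ndarray
    probability: np.ndarray
    predicted: np.ndarray
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    n_cases: int
    n_controls: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "llr": self.llr,
                "probability": self.probability,
                "predicted": self.predicted,
            }
        )


def classification_report(model: OplsModel, X, y) -> ClassificationReport:
    """In-sample sensitivity/specificity with 95% Wald intervals."""
    yv = _coerce_y(y)
    llr, prob, labels = predict_llr(model, X)
    pred_pat = labels == "patient"
    cases = yv > 0
    n_cases = int(cases.sum())
    n_controls = int((~cases).sum())
    sens = float(np.sum(pred_pat & cases)) / n_cases
    spec = float(np.sum(~pred_pat & ~cases)) / n_controls
    return ClassificationReport(
        llr=llr,
        probability=prob,
        predicted=labels,
        sensitivity=sens,
        sensitivity_ci=wald_ci(sens, n_cases),
        specificity=spec,
        specificity_ci=wald_ci(spec, n_controls),
        n_cases=n_cases,
        n_controls=n_controls,
    )


def model_summary(model: OplsModel, folds: int = 7) -> pd.DataFrame:
    """Per-variable summary: component loading (as correlation with the
    predictive score), a jackknife t statistic over the cross-validation
    folds, the equivalent regression coefficient and the VIP."""
    Xm, yv = model.X_train, model.y_train
    n = len(yv)
    assign = _venetian_folds(n, folds)
    thetas = []
    for f in range(folds):
        tr = assign != f
        if np.ptp(yv[tr]) == 0:
            continue
        try:
            sub = fit_opls(
                pd.DataFrame(Xm[tr], columns=list(model.variables)), yv[tr]
            )
            thetas.append(sub.loading_R)
        except ValueError:
            continue
    t_stat = np.full(len(model.variables), np.nan)
    if len(thetas) >= 2:
        th = np.vstack(thetas)
        kf = th.shape[0]
        se = np.sqrt((kf - 1) / kf * np.sum((th - th.mean(axis=0)) ** 2, axis=0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_stat = np.where(se > 0, model.loading_R / se, np.nan)
    return pd.DataFrame(
        {
            "variable": list(model.variables),
            "loading_R": model.loading_R,
            "t_statistic": t_stat,
            "coefficient": model.b,
            "vip": model.vip,
        }
    )
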