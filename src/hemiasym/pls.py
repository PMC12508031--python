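"""Partial least squares prediction engine.

Network × epoch feature matrices (9 major networks × 17 epochs = 153
predictors) feed two-block PLS regression models that predict hemispheric
asymmetry from bilateral amplitude, or task accuracy from either measure.
Component count is chosen by within-sample k-fold cross-validation and
robustness is assessed by two-fold cross-cohort validation between
matched discovery and replication halves, with Bonferroni-corrected
predicted-versus-observed correlation heatmaps.

The latent components admit network-level scores

    PC_{i,n} = Σ_j A_{i,j} · ω_{i,j,n}

where A_{i,j} is the (cohort-mean or per-subject) value for network i and
epoch j and ω_{i,j,n} the loading of that predictor on component n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .networks import NetworkEpochMatrix
from .vocab import EPOCHS, MAJOR_NETWORKS

DEFAULT_N_COMPONENTS = 12


def build_feature_matrix(
    matrix: NetworkEpochMatrix,
    networks=MAJOR_NETWORKS,
    epochs=EPOCHS,
) -> pd.DataFrame:
    """Subjects × (network, epoch) predictor matrix in fixed column order.

    Columns are ordered network-major, epoch-minor.  With the default 9
    major networks and 17 epochs this yields the 153-column predictor
    block; the three minor networks (ORA, VMM, PMM) are excluded for
    their small size and diffuse activation.
    """
    networks = list(networks)
    epochs = list(epochs)
    missing_k = [k for k in networks if k not in matrix.networks]
    missing_e = [e for e in epochs if e not in matrix.epochs]
    if missing_k or missing_e:
        raise ValueError(
            f"matrix is missing networks {missing_k} and/or epochs {missing_e}"
        )
    cols = pd.MultiIndex.from_product([networks, epochs], names=["network", "epoch"])
    return matrix.values.loc[:, cols]


@dataclass
class PLSModel:
    """A fitted two-block PLS regression model.

    Wraps a NIPALS PLS regression with training-set centering and
    unit-variance scaling of every predictor and response column.  The
    ``loadings_tensor`` reshapes the X-loadings to (network, epoch,
    component) for Eq-style component scores; it exists only when the
    feature columns carry a (network, epoch) MultiIndex.
    """

    estimator: PLSRegression
    n_components: int
    feature_columns: pd.Index
    response_columns: pd.Index
    training_ids: list = field(default_factory=list)

    @property
    def x_weights(self) -> np.ndarray:
        return self.estimator.x_weights_

    @property
    def x_loadings(self) -> np.ndarray:
        return self.estimator.x_loadings_

    @property
    def y_loadings(self) -> np.ndarray:
        return self.estimator.y_loadings_

    @property
    def x_scores(self) -> np.ndarray:
        return self.estimator.x_scores_

    @property
    def explained_variance_x(self) -> np.ndarray:
        """Fraction of (standardized) predictor variance per component.

        Component a explains ||t_a||²·||p_a||² of the Frobenius norm of
        the standardized training X, whose total is (n−1)·n_features.
        """
        T = self.estimator.x_scores_
        P = self.estimator.x_loadings_
        n, n_features = T.shape[0], len(self.feature_columns)
        per = np.einsum("ij,ij->j", T, T) * np.einsum("ij,ij->j", P, P)
        return per / ((n - 1) * n_features)

    @property
    def cumulative_explained_variance_x(self) -> np.ndarray:
        return np.cumsum(self.explained_variance_x)

    @property
    def loadings_tensor(self) -> np.ndarray:
        """ω_{i,j,n}: X-loadings as (network, epoch, component)."""
        if not isinstance(self.feature_columns, pd.MultiIndex):
            raise ValueError("feature columns carry no (network, epoch) structure")
        n_networks = len(self.feature_columns.get_level_values(0).unique())
        n_epochs = len(self.feature_columns.get_level_values(1).unique())
        return self.x_loadings.reshape(n_networks, n_epochs, self.n_components)

    def _check_features(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if not X.columns.equals(self.feature_columns):
                raise ValueError("feature columns do not match the training layout")
            return X.to_numpy(float)
        return np.asarray(X, float)

    def predict(self, X) -> np.ndarray:
        return self.estimator.predict(self._check_features(X))

    def transform(self, X) -> np.ndarray:
        """Per-subject latent component scores (subjects × components)."""
        return self.estimator.transform(self._check_features(X))


def fit_pls(X, Y, n_components: int = DEFAULT_N_COMPONENTS) -> PLSModel:
    """Fit a PLS regression of Y on X with centered, unit-scaled columns.

    Deterministic for fixed inputs.  ``n_components`` must not exceed the
    feasible rank min(n_samples − 1, n_features).
    """
    X_arr = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    Y_arr = Y.to_numpy(float) if isinstance(Y, pd.DataFrame) else np.asarray(Y, float)
    if Y_arr.ndim == 1:
        Y_arr = Y_arr[:, None]
    if X_arr.shape[0] != Y_arr.shape[0]:
        raise ValueError("X and Y must share rows")
    cap = min(X_arr.shape[0] - 1, X_arr.shape[1])
    if not 1 <= n_components <= cap:
        raise ValueError(
            f"n_components={n_components} exceeds the feasible rank {cap}"
        )
    est = PLSRegression(n_components=n_components, scale=True, max_iter=2000)
    est.fit(X_arr, Y_arr)
    return PLSModel(
        estimator=est,
        n_components=n_components,
        feature_columns=X.columns if isinstance(X, pd.DataFrame) else pd.RangeIndex(X_arr.shape[1]),
        response_columns=Y.columns if isinstance(Y, pd.DataFrame) else pd.RangeIndex(Y_arr.shape[1]),
        training_ids=list(X.index) if isinstance(X, pd.DataFrame) else list(range(X_arr.shape[0])),
    )


def select_components_cv(
    X,
    Y,
    k: int = 10,
    max_components: int = DEFAULT_N_COMPONENTS,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Choose the component count by seeded k-fold cross-validation.

    Returns ``(n_components, curve)`` where ``curve`` has the mean
    held-out squared error per candidate count and the chosen count
    minimizes it (smallest count on ties).
    """
    X_arr = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    Y_arr = Y.to_numpy(float) if isinstance(Y, pd.DataFrame) else np.asarray(Y, float)
    if Y_arr.ndim == 1:
        Y_arr = Y_arr[:, None]
    n = X_arr.shape[0]
    if k > n:
        raise ValueError(f"k={k} folds exceed n={n} rows")
    max_components = min(max_components, X_arr.shape[1], n - max(2, n // k) - 1)
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(kf.split(X_arr))
    errors = np.zeros((max_components, k))
    for a in range(1, max_components + 1):
        for fi, (tr, te) in enumerate(folds):
            est = PLSRegression(n_components=a, scale=True, max_iter=2000)
            est.fit(X_arr[tr], Y_arr[tr])
            pred = est.predict(X_arr[te])
            errors[a - 1, fi] = np.mean((pred - Y_arr[te]) ** 2)
    curve = pd.DataFrame(
        {"n_components": np.arange(1, max_components + 1), "cv_mse": errors.mean(axis=1)}
    )
    chosen = int(curve.loc[curve["cv_mse"].idxmin(), "n_components"])
    return chosen, curve


@dataclass
class HeatmapResult:
    """Predicted-vs-observed correlations for one model on one cohort.

    ``r``/``p`` are Series per response variable; ``mask`` flags
    significance after Bonferroni over the response family (p < α/m).
    ``mask_uncorrected`` applies the display threshold p < α directly.
    """

    r: pd.Series
    p: pd.Series
    mask: pd.Series
    role: str  # {"train", "test"}
    alpha: float = 0.05
    family_size: int = 0

    @property
    def mask_uncorrected(self) -> pd.Series:
        return self.p < self.alpha

    @property
    def mean_r(self) -> float:
        return float(self.r.mean())


def predicted_vs_observed(
    model: PLSModel, X, Y, role: str, alpha: float = 0.05,
    family_size: int | None = None,
) -> HeatmapResult:
    """Correlate model predictions with observations per response variable."""
    Y_arr = Y.to_numpy(float) if isinstance(Y, pd.DataFrame) else np.asarray(Y, float)
    if Y_arr.ndim == 1:
        Y_arr = Y_arr[:, None]
    pred = model.predict(X)
    cols = Y.columns if isinstance(Y, pd.DataFrame) else model.response_columns
    rs, ps = [], []
    for j in range(Y_arr.shape[1]):
        if np.std(Y_arr[:, j]) == 0 or np.std(pred[:, j]) == 0:
            rs.append(np.nan)
            ps.append(np.nan)
            continue
        r, p = stats.pearsonr(pred[:, j], Y_arr[:, j])
        rs.append(r)
        ps.append(p)
    r = pd.Series(rs, index=cols, name="r")
    p = pd.Series(ps, index=cols, name="p")
    m = family_size if family_size is not None else len(cols)
    mask = p < alpha / m
    return HeatmapResult(r=r, p=p, mask=mask, role=role, alpha=alpha, family_size=m)


def cross_cohort_validate(
    X_discovery,
    Y_discovery,
    X_replication,
    Y_replication,
    n_components: int = DEFAULT_N_COMPONENTS,
    select_by_cv: bool = False,
    k: int = 10,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Two-fold cross-cohort validation of a PLS prediction.

    Trains on the discovery cohort and evaluates on the replication
    cohort, then reverses the roles.  Cohorts must be disjoint.  Returns
    a dict with per-direction model, train and test heatmap results.
    """
    if isinstance(X_discovery, pd.DataFrame) and isinstance(X_replication, pd.DataFrame):
        overlap = set(X_discovery.index) & set(X_replication.index)
        if overlap:
            raise ValueError(f"cohorts overlap on subjects: {sorted(overlap)[:5]}")
        if not X_discovery.columns.equals(X_replication.columns):
            raise ValueError("cohorts must share an identical feature layout")
    out = {}
    pairs = {
        "discovery_to_replication": (X_discovery, Y_discovery, X_replication, Y_replication),
        "replication_to_discovery": (X_replication, Y_replication, X_discovery, Y_discovery),
    }
    for direction, (Xtr, Ytr, Xte, Yte) in pairs.items():
        ncomp = n_components
        if select_by_cv:
            ncomp, _ = select_components_cv(
                Xtr, Ytr, k=k, max_components=n_components, seed=seed
            )
        model = fit_pls(Xtr, Ytr, n_components=ncomp)
        out[direction] = {
            "model": model,
            "train": predicted_vs_observed(model, Xtr, Ytr, role="train", alpha=alpha),
            "test": predicted_vs_observed(model, Xte, Yte, role="test", alpha=alpha),
        }
    return out


def component_scores(A, model: PLSModel, weights: str = "loadings"):
    """Network-level component scores PC_{i,n} = Σ_j A_{i,j} ω_{i,j,n}.

    ``A`` may be a network × epoch DataFrame of cohort-mean values
    (returns a networks × components DataFrame) or a
    :class:`NetworkEpochMatrix` of per-subject values (returns an array
    of shape (subjects, networks, components)).  ``weights`` selects the
    ω definition: the X-loadings (default) or the X-weights.
    """
    omega = model.loadings_tensor if weights == "loadings" else (
        model.x_weights.reshape(model.loadings_tensor.shape)
    )
    nets = list(model.feature_columns.get_level_values(0).unique())
    epochs = list(model.feature_columns.get_level_values(1).unique())
    ncomp = model.n_components
    if isinstance(A, NetworkEpochMatrix):
        arr = build_feature_matrix(A, networks=nets, epochs=epochs).to_numpy(float)
        arr = arr.reshape(arr.shape[0], len(nets), len(epochs))
        return np.einsum("sij,ijn->sin", arr, omega)
    A_tbl = A.reindex(index=nets, columns=epochs)
    if A_tbl.isna().any().any():
        raise ValueError("A's network/epoch axes do not match the model's features")
    scores = np.einsum("ij,ijn->in", A_tbl.to_numpy(float), omega)
    return pd.DataFrame(scores, index=nets, columns=[f"PC{n+1}" for n in range(ncomp)])


def score_covariate_effects(scores: np.ndarray, subjects: pd.DataFrame) -> pd.DataFrame:
    """Sex and age effects on per-subject component scores.

    Per component: two-sample t-test of male versus female scores and the
    Pearson correlation of scores with age, both with two-sided p-values.
    """
    scores = np.asarray(scores, float)
    if scores.ndim != 2 or scores.shape[0] != len(subjects):
        raise ValueError("scores must be subjects × components, aligned with the table")
    male = (subjects["sex"] == "M").to_numpy()
    female = (subjects["sex"] == "F").to_numpy()
    if not male.any() or not female.any():
        raise ValueError("both sex groups must be nonempty")
    age = subjects["age"].to_numpy(float)
    rows = []
    for n in range(scores.shape[1]):
        s = scores[:, n]
        t_sex, p_sex = stats.ttest_ind(s[male], s[female])
        r_age, p_age = stats.pearsonr(s, age)
        rows.append(
            {
                "component": n + 1,
                "t_sex_MvsF": t_sex,
                "p_sex": p_sex,
                "r_age": r_age,
                "p_age": p_age,
            }
        )
    return pd.DataFrame(rows).set_index("component")
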