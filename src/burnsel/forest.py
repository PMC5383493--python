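"""Random-forest classifier wrapper for the used/available analysis.

Two interchangeable engines sit behind one sklearn-style estimator:

``engine="cart"`` (default)
    A bagging loop over :class:`sklearn.tree.DecisionTreeClassifier`
    with per-tree bootstrap weights.  Because the bootstrap membership of
    every tree is held in-repo, the estimator can report the classical
    out-of-bag (OOB) error, per-class OOB errors, and Breiman-style OOB
    permutation importances (mean decrease in per-tree OOB accuracy when
    one predictor is permuted) -- the importance measure the R
    ``randomForest`` tradition reports as MeanDecreaseAccuracy.

``engine="hist"``
    LightGBM in random-forest boosting mode.  Histogram split finding
    makes fits roughly an order of magnitude faster, which matters for
    permutation-significance simulations; per-tree bags are not exposed
    there, so the accuracy estimate comes from an internal stratified
    validation split and importances from split gain.

Both engines are deterministic under a fixed ``random_state``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

__all__ = ["UsedAvailableForest"]


class UsedAvailableForest(BaseEstimator, ClassifierMixin):
    """Binary random-forest classifier with OOB accuracy accounting.

    Parameters
    ----------
    n_trees : int
        Number of bootstrap trees (the study design uses 4,000; tests and
        simulations reduce this through configuration).
    engine : {"cart", "hist"}
        Tree backend, see module docstring.
    max_features : str or int
        Features considered per split ("sqrt" follows forest convention).
    valid_fraction : float
        Internal validation share used for the accuracy estimate when
        ``engine="hist"``.
    random_state : int
        Seed for bootstraps, tree randomness, and importance permutations.

    Attributes
    ----------
    classes_ : ndarray
        The two class labels (available=0, used=1).
    oob_error_ : float
        Estimated classification error (OOB for cart, validation for hist).
    class_errors_ : dict
        Per-class error rates on the same basis.
    feature_names_ : list of str
        Column names seen during fit.
    """

    def __init__(
        self,
        n_trees: int = 4000,
        engine: str = "cart",
        max_features="sqrt",
        valid_fraction: float = 0.3,
        random_state: int = 0,
    ):
        self.n_trees = n_trees
        self.engine = engine
        self.max_features = max_features
        self.valid_fraction = valid_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _validate_Xy(self, X, y):
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            self.feature_names_ = list(X.columns)
            X = X.to_numpy()
        else:
            X = np.asarray(X)
            self.feature_names_ = [f"x{i}" for i in range(X.shape[1])]
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("response has a single class; need used and available rows")
        if len(classes) > 2:
            raise ValueError("response must be binary (used=1 / available=0)")
        self.classes_ = classes
        return np.ascontiguousarray(X, dtype=np.float32), y

    def fit(self, X, y):
        if self.engine == "cart":
            return self._fit_cart(*self._validate_Xy(X, y))
        if self.engine == "hist":
            return self._fit_hist(*self._validate_Xy(X, y))
        raise ValueError(f"unknown engine {self.engine!r}")

    # -- cart engine ---------------------------------------------------
    def _fit_cart(self, X, y):
        n = len(y)
        rng = np.random.default_rng(self.random_state)
        y01 = (y == self.classes_[1]).astype(np.int8)
        trees, oob_masks = [], []
        votes = np.zeros((n, 2))
        counts = np.zeros(n)
        for _ in range(self.n_trees):
            idx = rng.integers(0, n, n)
            sw = np.bincount(idx, minlength=n).astype(np.float64)
            tree = DecisionTreeClassifier(
                max_features=self.max_features,
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(X, y01, sample_weight=sw, check_input=False)
            oob = sw == 0
            if oob.any():
                proba = tree.predict_proba(X[oob], check_input=False)
                votes[oob] += self._expand_proba(proba, tree)
                counts[oob] += 1
            trees.append(tree)
            oob_masks.append(oob)
        self._trees = trees
        self._oob_masks = oob_masks
        self._X_fit, self._y01_fit = X, y01
        seen = counts > 0
        oob_pred = votes.argmax(axis=1)
        self.oob_decision_counts_ = votes
        self.oob_error_ = float((oob_pred[seen] != y01[seen]).mean())
        self.class_errors_ = {
            int(cls): float((oob_pred[seen & (y01 == k)] != k).mean())
            for k, cls in enumerate(self.classes_)
        }
        self._perm_rng_seed = int(np.random.default_rng(self.random_state).integers(2**31 - 1))
        self.importances_ = None  # computed lazily
        return self

    @staticmethod
    def _expand_proba(proba, tree):
        # a tree trained on a bootstrap holding one class predicts a
        # single column; expand to the (0, 1) layout
        if proba.shape[1] == 2:
            return proba
        out = np.zeros((len(proba), 2))
        out[:, int(tree.classes_[0])] = proba[:, 0]
        return out

    def oob_permutation_importances(self) -> np.ndarray:
        """Mean per-tree decrease in OOB accuracy when a column is permuted.

        Negative raw values are reported as-is; the model-improvement
        ratio downstream floors them at zero.
        """
        check_is_fitted(self, "oob_error_")
        if self.engine != "cart":
            raise ValueError("OOB permutation importances need engine='cart'")
        if self.importances_ is not None:
            return self.importances_
        X, y01 = self._X_fit, self._y01_fit
        p = X.shape[1]
        rng = np.random.default_rng(self._perm_rng_seed)
        drops = np.zeros(p)
        n_used = 0
        for tree, oob in zip(self._trees, self._oob_masks):
            m = int(oob.sum())
            if m == 0:
                continue
            n_used += 1
            Xo = X[oob]
            yo = y01[oob]
            base_acc = (tree.predict(Xo, check_input=False) == yo).mean()
            for j in range(p):
                Xp = Xo.copy()
                Xp[:, j] = Xo[rng.permutation(m), j]
                acc = (tree.predict(Xp, check_input=False) == yo).mean()
                drops[j] += base_acc - acc
        self.importances_ = drops / max(n_used, 1)
        return self.importances_

    # -- hist engine ---------------------------------------------------
    def _fit_hist(self, X, y):
        import lightgbm as lgb
        from sklearn.model_selection import train_test_split

        y01 = (y == self.classes_[1]).astype(np.int8)
        n_feat = X.shape[1]
        if self.max_features == "sqrt":
            feat_frac = max(np.sqrt(n_feat) / n_feat, 1.0 / n_feat)
        elif self.max_features in (None, "all"):
            feat_frac = 1.0
        else:
            feat_frac = max(float(self.max_features) / n_feat, 1.0 / n_feat)
        idx_tr, idx_va = train_test_split(
            np.arange(len(y01)),
            test_size=self.valid_fraction,
            random_state=self.random_state % (2**32 - 1),
            stratify=y01,
        )
        model = lgb.LGBMClassifier(
            boosting_type="rf",
            n_estimators=self.n_trees,
            bagging_freq=1,
            bagging_fraction=0.632,
            feature_fraction=min(max(feat_frac, 0.05), 0.9999),
            num_leaves=96,
            n_jobs=1,
            deterministic=True,
            random_state=self.random_state % (2**31 - 1),
            verbose=-1,
        )
        model.fit(X[idx_tr], y01[idx_tr])
        self._lgbm = model
        pred = (model.booster_.predict(X[idx_va]) > 0.5).astype(np.int8)
        yv = y01[idx_va]
        self.oob_error_ = float((pred != yv).mean())
        self.class_errors_ = {
            int(cls): float((pred[yv == k] != k).mean()) if (yv == k).any() else float("nan")
            for k, cls in enumerate(self.classes_)
        }
        gains = model.booster_.feature_importance(importance_type="gain")
        self.importances_ = np.asarray(gains, dtype=float)
        return self

    # ------------------------------------------------------------------
    def importances(self) -> np.ndarray:
        """Variable importances on the engine's native scale."""
        check_is_fitted(self, "oob_error_")
        if self.engine == "cart":
            return self.oob_permutation_importances()
        return self.importances_

    def predict_proba(self, X):
        check_is_fitted(self, "oob_error_")
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            X = X.to_numpy()
        X = np.ascontiguousarray(X, dtype=np.float32)
        if self.engine == "hist":
            p1 = self._lgbm.booster_.predict(X)
            return np.column_stack((1.0 - p1, p1))
        acc = np.zeros((len(X), 2))
        for tree in self._trees:
            acc += self._expand_proba(tree.predict_proba(X, check_input=False), tree)
        return acc / len(self._trees)

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[(proba[:, 1] > 0.5).astype(int)]

    def score(self, X, y):
        return float((self.predict(X) == np.asarray(y)).mean())

    @property
    def oob_accuracy_(self) -> float:
        return 1.0 - self.oob_error_
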