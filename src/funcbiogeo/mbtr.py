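"""Multivariate boosted tree regression (MBTR) with vector-valued leaves.

Gradient boosting in which every regression tree predicts the full
response vector jointly: a single split partition is chosen for all
response dimensions at once, which lets correlated responses share
structure (small-sample regularisation) and conserves the correlation
structure between responses. Under squared-error loss the hessian of the
loss is the identity, so the optimal leaf value is simply the mean
residual vector of the leaf's samples, and the split gain is the joint
sum-of-squares reduction

    gain = ||sum_L r||^2 / n_L + ||sum_R r||^2 / n_R - ||sum r||^2 / n

summed over response dimensions. Candidate thresholds per feature are
the interior evenly-spaced empirical quantiles of the node's samples.
Fitting is fully deterministic; gain ties break to the lowest feature
index, then the lowest threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["MBTRHyperparams", "TreeNode", "BoostedEnsemble", "fit_tree", "fit_mbtr", "predict"]


@dataclass(frozen=True)
class MBTRHyperparams:
    """Boosting hyperparameters.

    Defaults mirror the validated study configuration: squared-error
    loss, learning rate 5e-3, at least 30 observations per terminal
    leaf, 10 candidate quantiles per split.
    """

    learning_rate: float = 5e-3
    min_leaf: int = 30
    n_quantiles: int = 10
    max_rounds: int = 2000
    max_depth: int = 6
    loss: str = "mse"
    early_stop_patience: int | None = None
    global_quantiles: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must lie in (0, 1]")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if self.n_quantiles < 2:
            raise ValueError("n_quantiles must be >= 2")
        if self.loss != "mse":
            raise ValueError("only the squared-error loss ('mse') is implemented")


@dataclass
class TreeNode:
    """A node of a multivariate regression tree.

    Internal nodes carry (split_feature, split_value, gain) and two
    children; leaves carry the mean residual vector ``leaf_value`` over
    the full response dimension. Samples with feature <= split_value go
    left.
    """

    split_feature: int | None = None
    split_value: float = np.nan
    split_gain: float = 0.0
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    leaf_value: np.ndarray | None = None

    @property
    def is_leaf(self) -> bool:
        return self.split_feature is None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.is_leaf:
            return np.tile(self.leaf_value, (X.shape[0], 1))
        out = np.empty((X.shape[0], self._dim()), dtype=float)
        mask = X[:, self.split_feature] <= self.split_value
        if mask.any():
            out[mask] = self.left.predict(X[mask])
        if (~mask).any():
            out[~mask] = self.right.predict(X[~mask])
        return out

    def _dim(self) -> int:
        node = self
        while not node.is_leaf:
            node = node.left
        return node.leaf_value.size

    def walk(self):
        """Yield every node (pre-order)."""
        yield self
        if not self.is_leaf:
            yield from self.left.walk()
            yield from self.right.walk()


def _candidate_thresholds(x: np.ndarray, n_quantiles: int) -> np.ndarray:
    qs = np.arange(1, n_quantiles + 1) / (n_quantiles + 1)
    return np.unique(np.quantile(x, qs))


def _best_split(
    X: np.ndarray, R: np.ndarray, hp: MBTRHyperparams, candidates: list[np.ndarray] | None
) -> tuple[int, float, float] | None:
    """Scan all (feature, quantile threshold) pairs for the max joint gain."""
    n = X.shape[0]
    total = R.sum(axis=0)
    parent = np.dot(total, total) / n
    best: tuple[int, float, float] | None = None
    for f in range(X.shape[1]):
        x = X[:, f]
        thresholds = (
            candidates[f] if candidates is not None else _candidate_thresholds(x, hp.n_quantiles)
        )
        if thresholds.size == 0:
            continue
        order = np.argsort(x, kind="stable")
        xs = x[order]
        prefix = np.cumsum(R[order], axis=0)  # prefix[i] = sum of first i+1 residual vectors
        n_left = np.searchsorted(xs, thresholds, side="right")
        valid = (n_left >= hp.min_leaf) & (n - n_left >= hp.min_leaf)
        for t, nl in zip(thresholds[valid], n_left[valid]):
            left_sum = prefix[nl - 1]
            right_sum = total - left_sum
            gain = (
                np.dot(left_sum, left_sum) / nl
                + np.dot(right_sum, right_sum) / (n - nl)
                - parent
            )
            if best is None or gain > best[2] + 1e-15:
                best = (f, float(t), float(gain))
    if best is None or best[2] <= 1e-12:
        return None
    return best


def fit_tree(
    X: np.ndarray,
    residuals: np.ndarray,
    hp: MBTRHyperparams,
    _depth: int = 0,
    _candidates: list[np.ndarray] | None = None,
) -> TreeNode:
    """Fit one multivariate regression tree to the current residuals.

    Recursion stops at ``max_depth``, when no split leaves ``min_leaf``
    samples on both sides, or when no candidate split reduces the joint
    squared error.
    """
    X = np.asarray(X, dtype=float)
    residuals = np.asarray(residuals, dtype=float)
    if residuals.ndim == 1:
        residuals = residuals[:, None]
    if X.shape[0] != residuals.shape[0]:
        raise ValueError("X and residuals disagree on the number of samples")

    if _depth == 0 and hp.global_quantiles:
        _candidates = [_candidate_thresholds(X[:, f], hp.n_quantiles) for f in range(X.shape[1])]

    leaf = TreeNode(leaf_value=residuals.mean(axis=0))
    if _depth >= hp.max_depth or X.shape[0] < 2 * hp.min_leaf:
        return leaf
    split = _best_split(X, residuals, hp, _candidates)
    if split is None:
        return leaf
    f, t, gain = split
    mask = X[:, f] <= t
    return TreeNode(
        split_feature=f,
        split_value=t,
        split_gain=gain,
        left=fit_tree(X[mask], residuals[mask], hp, _depth + 1, _candidates),
        right=fit_tree(X[~mask], residuals[~mask], hp, _depth + 1, _candidates),
    )


@dataclass
class BoostedEnsemble:
    """A fitted MBTR: base prediction plus shrunken trees.

    Prediction after r rounds is
    ``base_prediction + learning_rate * sum_{i<=r} tree_i(X)``.
    """

    trees: list[TreeNode]
    base_prediction: np.ndarray
    hyperparams: MBTRHyperparams
    train_loss: list[float] = field(default_factory=list)
    test_loss: list[float] = field(default_factory=list)
    feature_names: list[str] | None = None
    response_names: list[str] | None = None
    n_features: int | None = None

    @property
    def n_rounds(self) -> int:
        return len(self.trees)

    @property
    def best_rounds(self) -> int:
        """Boosting rounds minimizing the held-out loss (all, if none)."""
        if self.test_loss:
            return int(np.argmin(self.test_loss)) + 1
        return self.n_rounds

    def to_json(self) -> str:
        def encode(node: TreeNode):
            if node.is_leaf:
                return {"leaf": node.leaf_value.tolist()}
            return {
                "f": node.split_feature,
                "t": node.split_value,
                "g": node.split_gain,
                "l": encode(node.left),
                "r": encode(node.right),
            }

        return json.dumps(
            {
                "base_prediction": self.base_prediction.tolist(),
                "hyperparams": self.hyperparams.__dict__,
                "train_loss": self.train_loss,
                "test_loss": self.test_loss,
                "feature_names": self.feature_names,
                "response_names": self.response_names,
                "n_features": self.n_features,
                "trees": [encode(t) for t in self.trees],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "BoostedEnsemble":
        def decode(d) -> TreeNode:
            if "leaf" in d:
                return TreeNode(leaf_value=np.asarray(d["leaf"], dtype=float))
            return TreeNode(
                split_feature=d["f"],
                split_value=d["t"],
                split_gain=d["g"],
                left=decode(d["l"]),
                right=decode(d["r"]),
            )

        d = json.loads(text)
        return cls(
            trees=[decode(t) for t in d["trees"]],
            base_prediction=np.asarray(d["base_prediction"], dtype=float),
            hyperparams=MBTRHyperparams(**d["hyperparams"]),
            train_loss=d["train_loss"],
            test_loss=d["test_loss"],
            feature_names=d["feature_names"],
            response_names=d["response_names"],
            n_features=d.get("n_features"),
        )


def _mse(Y: np.ndarray, P: np.ndarray) -> float:
    return float(np.mean((Y - P) ** 2))


def fit_mbtr(
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_test: np.ndarray | None = None,
    Y_test: np.ndarray | None = None,
    hp: MBTRHyperparams = MBTRHyperparams(),
    feature_names: list[str] | None = None,
    response_names: list[str] | None = None,
) -> BoostedEnsemble:
    """Fit the boosted ensemble by sequential residual fitting.

    Each round fits one multivariate tree to the residuals of the
    running prediction and advances the prediction by ``learning_rate``
    times the tree's output; train (and, when a test set is given, test)
    mean squared error pooled over all response dimensions is recorded
    per round. Stops early when no tree can improve, or — with
    ``early_stop_patience`` set — when the test loss has not improved
    for that many rounds.
    """
    X_train = np.asarray(X_train, dtype=float)
    Y_train = np.asarray(Y_train, dtype=float)
    if Y_train.ndim == 1:
        Y_train = Y_train[:, None]
    if not (np.isfinite(X_train).all() and np.isfinite(Y_train).all()):
        raise ValueError("non-finite values in training data")
    has_test = X_test is not None and Y_test is not None
    if has_test:
        X_test = np.asarray(X_test, dtype=float)
        Y_test = np.asarray(Y_test, dtype=float)
        if Y_test.ndim == 1:
            Y_test = Y_test[:, None]
        if X_test.shape[1] != X_train.shape[1] or Y_test.shape[1] != Y_train.shape[1]:
            raise ValueError("train/test feature or response dimensions differ")
        if not (np.isfinite(X_test).all() and np.isfinite(Y_test).all()):
            raise ValueError("non-finite values in test data")

    base = Y_train.mean(axis=0)
    pred = np.tile(base, (X_train.shape[0], 1))
    pred_test = np.tile(base, (X_test.shape[0], 1)) if has_test else None

    ens = BoostedEnsemble(
        trees=[],
        base_prediction=base,
        hyperparams=hp,
        feature_names=feature_names,
        response_names=response_names,
        n_features=X_train.shape[1],
    )
    best_test = np.inf
    stall = 0
    for _ in range(hp.max_rounds):
        resid = Y_train - pred
        tree = fit_tree(X_train, resid, hp)
        if tree.is_leaf and np.allclose(tree.leaf_value, 0.0, atol=1e-14):
            break  # nothing left to learn
        pred = pred + hp.learning_rate * tree.predict(X_train)
        ens.trees.append(tree)
        ens.train_loss.append(_mse(Y_train, pred))
        if has_test:
            pred_test = pred_test + hp.learning_rate * tree.predict(X_test)
            loss = _mse(Y_test, pred_test)
            ens.test_loss.append(loss)
            if hp.early_stop_patience is not None:
                if loss < best_test - 1e-15:
                    best_test, stall = loss, 0
                else:
                    stall += 1
                    if stall >= hp.early_stop_patience:
                        break
    return ens


def predict(ensemble: BoostedEnsemble, X: np.ndarray, n_rounds: int | None = None) -> np.ndarray:
    """Predict responses using the first ``n_rounds`` trees.

    Defaults to the round count minimizing the recorded test loss
    (all trees when none was recorded).
    """
    X = np.asarray(X, dtype=float)
    expected = ensemble.n_features if ensemble.n_features is not None else _n_features(ensemble.trees)
    if expected is not None and X.shape[1] != expected:
        raise ValueError(f"feature count mismatch: got {X.shape[1]}, expected {expected}")
    if n_rounds is None:
        n_rounds = ensemble.best_rounds
    if n_rounds > len(ensemble.trees):
        raise ValueError("n_rounds exceeds the number of fitted trees")
    out = np.tile(ensemble.base_prediction, (X.shape[0], 1))
    for tree in ensemble.trees[:n_rounds]:
        out = out + ensemble.hyperparams.learning_rate * tree.predict(X)
    return out


def _n_features(trees: list[TreeNode]) -> int | None:
    mx = -1
    for t in trees:
        for node in t.walk():
            if not node.is_leaf:
                mx = max(mx, node.split_feature)
    return mx + 1 if mx >= 0 else None
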