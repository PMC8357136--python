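"""Registry of age-prediction learners.

All thirteen learners compared in the original protocol are reachable by
name for both tasks where they apply; the default is the gradient-boosted
tree ensemble (XGBoost), which is what the pipeline exercises.  Tree
learners are pinned to a single thread so repeated runs with the same
seed are bit-reproducible.

``logistic``, ``lda`` and ``naive_bayes`` are discrete-label models; for
the regression task they treat the training ages as class labels and
predict one of them, which is how they were benchmarked historically.
"""

from __future__ import annotations

import inspect

from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    AdaBoostClassifier,
    AdaBoostRegressor,
    BaggingClassifier,
    BaggingRegressor,
    ExtraTreesClassifier,
    ExtraTreesRegressor,
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.linear_model import (
    ARDRegression,
    HuberRegressor,
    LinearRegression,
    LogisticRegression,
)
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from xgboost import XGBClassifier, XGBRegressor

from .datasets import ConfigError

__all__ = ["DEFAULT_MODEL", "make_model", "available_models"]

DEFAULT_MODEL = "xgboost"

_REGRESSORS = {
    "xgboost": lambda: XGBRegressor(n_jobs=1, verbosity=0),
    "gradient_boosting": GradientBoostingRegressor,
    "adaboost": AdaBoostRegressor,
    "bagging": BaggingRegressor,
    "random_forest": lambda: RandomForestRegressor(n_jobs=1),
    "extra_trees": lambda: ExtraTreesRegressor(n_jobs=1),
    "knn": KNeighborsRegressor,
    "logistic": lambda: LogisticRegression(max_iter=1000),
    "lda": LinearDiscriminantAnalysis,
    "naive_bayes": GaussianNB,
    "linear": LinearRegression,
    "huber": lambda: HuberRegressor(max_iter=1000),
    "ard": ARDRegression,
}

_CLASSIFIERS = {
    "xgboost": lambda: XGBClassifier(n_jobs=1, verbosity=0, eval_metric="mlogloss"),
    "gradient_boosting": GradientBoostingClassifier,
    "adaboost": AdaBoostClassifier,
    "bagging": BaggingClassifier,
    "random_forest": lambda: RandomForestClassifier(n_jobs=1),
    "extra_trees": lambda: ExtraTreesClassifier(n_jobs=1),
    "knn": KNeighborsClassifier,
    "logistic": lambda: LogisticRegression(max_iter=1000),
    "lda": LinearDiscriminantAnalysis,
    "naive_bayes": GaussianNB,
}


def available_models(task: str = "regression") -> list[str]:
    return sorted(_REGRESSORS if task == "regression" else _CLASSIFIERS)


def make_model(name: str, task: str, seed: int | None = None, **params):
    """Instantiate a named learner with library defaults plus ``params``.

    ``seed`` is forwarded as ``random_state`` when the learner accepts
    one; deterministic learners ignore it.
    """
    registry = {"regression": _REGRESSORS, "classification": _CLASSIFIERS}.get(task)
    if registry is None:
        raise ConfigError(f"task must be 'regression' or 'classification', got {task!r}")
    factory = registry.get(name)
    if factory is None:
        raise ConfigError(
            f"unknown model {name!r} for {task}; available: {', '.join(sorted(registry))}"
        )
    model = factory()
    accepted = inspect.signature(type(model).__init__).parameters
    if seed is not None and "random_state" in accepted:
        params = {"random_state": int(seed), **params}
    if params:
        model.set_params(**params)
    return model
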