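"""Classifier adapters and tuning grids.

The evaluation harness is classifier-agnostic: any object with ``fit(X, y)``
and ``predict(X)`` works.  Three named adapters are shipped — a
nearest-neighbor model, a tree ensemble and a linear max-margin model — with
their default hyper-parameter grids.  Grids are ordered simplest first, so
argmax-with-first-wins tie-breaking prefers the most parsimonious setting
(fewest neighbors, smallest mtry/ntree, smallest cost).
"""

from __future__ import annotations

from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .errors import ParameterError

DEFAULT_GRIDS: dict[str, list[dict]] = {
    "knn": [{"n_neighbors": n} for n in range(1, 10)],
    "random_forest": [
        {"mtry": m, "ntree": t}
        for m in (5, 7, 9, 10, 11, 13, 15, 17)
        for t in (500, 1000, 1500, 2000, 2500, 3000)
    ],
    "svm": [{"cost": c} for c in (0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 1, 5, 10, 50)],
}


def make_classifier(name: str, params: dict, random_state: int | None = None):
    """Build an unfitted classifier from an adapter name and grid point."""
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=params["n_neighbors"])
    if name == "random_forest":
        return RandomForestClassifier(
            max_features=params["mtry"],
            n_estimators=params["ntree"],
            random_state=random_state,
        )
    if name == "svm":
        return SVC(kernel="linear", C=params["cost"])
    raise ParameterError(f"unknown classifier {name!r}; available: {sorted(DEFAULT_GRIDS)}")


def default_grid(name: str) -> list[dict]:
    try:
        return [dict(p) for p in DEFAULT_GRIDS[name]]
    except KeyError:
        raise ParameterError(f"no default grid for classifier {name!r}") from None
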