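"""Principal-component reduction of standardized microenvironment vectors.

Vectors are centered and projected onto the leading principal components
(default 80) before coarse clustering; component loadings can then be
inspected to explain what separates clusters in the reduced space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
from sklearn.decomposition import PCA

from .microenv import MicroenvironmentSet

DEFAULT_N_COMPONENTS = 80


@dataclass
class PCAModel:
    """Fitted PCA: data mean, orthonormal component rows (decreasing
    explained variance), and the per-component explained variance.

    Component signs are fixed by making each row's largest-magnitude
    loading positive, so fits are fully deterministic.
    """

    mean: np.ndarray
    components: np.ndarray
    explained_variance: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "mean": self.mean.tolist(),
                    "components": self.components.tolist(),
                    "explained_variance": self.explained_variance.tolist(),
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "PCAModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            mean=np.array(d["mean"]),
            components=np.array(d["components"]),
            explained_variance=np.array(d["explained_variance"]),
        )


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Flip each component so its largest-|loading| entry is positive."""
    idx = np.argmax(np.abs(components), axis=1)
    signs = np.sign(components[np.arange(len(idx)), idx])
    signs[signs == 0] = 1.0
    return components * signs[:, None]


def fit_pca(ms: MicroenvironmentSet, n_components: int = DEFAULT_N_COMPONENTS) -> PCAModel:
    """Fit PCA on a standardized set.

    ``n_components`` must lie in [1, min(n_sites - 1, D)].  Population
    variance convention is used so explained variances sum to the total
    population variance of the data.
    """
    if ms.space_tag != "standardized":
        raise ValueError(f"fit_pca expects standardized space, got {ms.space_tag!r}")
    limit = min(ms.n_sites - 1, ms.n_features)
    if not 1 <= n_components <= limit:
        raise ValueError(f"n_components must be in [1, {limit}], got {n_components}")
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(ms.features)
    # population variance: sklearn divides by n-1
    scale = (ms.n_sites - 1) / ms.n_sites
    return PCAModel(
        mean=pca.mean_,
        components=_fix_signs(pca.components_),
        explained_variance=pca.explained_variance_ * scale,
    )


def transform(model: PCAModel, ms: MicroenvironmentSet) -> MicroenvironmentSet:
    """Project a set onto the model's components; returns a reduced-space set."""
    if ms.n_features != model.components.shape[1]:
        raise ValueError(
            f"dimension mismatch: set has D={ms.n_features}, "
            f"model expects D={model.components.shape[1]}"
        )
    scores = (ms.features - model.mean) @ model.components.T
    return replace(
        ms,
        features=scores,
        feature_names=[f"PC{i + 1}" for i in range(model.n_components)],
        space_tag="reduced",
    )


def top_loadings(model: PCAModel, component: int, n: int,
                 feature_names=None) -> list[tuple[str, float]]:
    """The n features with largest |loading| on one component.

    Sorted by |loading| descending; ties broken by feature index.  ``n``
    larger than D returns all D features.
    """
    if component >= model.n_components:
        raise ValueError(f"component {component} out of range")
    row = model.components[component]
    names = list(feature_names) if feature_names is not None else [
        f"f{i}" for i in range(len(row))
    ]
    order = sorted(range(len(row)), key=lambda i: (-abs(row[i]), i))
    return [(names[i], float(row[i])) for i in order[: min(n, len(row))]]
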