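"""Composite aneurysm-morphology index (MAAI) via principal components.

Aneurysm size descriptors are strongly collinear, so the outcome models
use a single composite: variables are standardized to zero mean / unit SD,
the correlation matrix is eigen-decomposed, and the first eigenvector
defines the index.  The loading sign is anchored so that larger aneurysms
get larger scores, which makes a negative occlusion-model coefficient read
directly as "smaller aneurysms occlude more often".

Correlation (not covariance) PCA is used because the descriptors mix
linear (mm) and volumetric (mm^3) scales.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MAAIModel", "fit_maai", "maai_score",
           "DEFAULT_MAAI_VARIABLES", "FIVE_VARIABLE_SET"]

#: default descriptor set: the four size variables of the composite
DEFAULT_MAAI_VARIABLES = ("width", "depth", "neck_max", "neck_min")
#: optional extended set including the aneurysm volume
FIVE_VARIABLE_SET = ("width", "depth", "neck_max", "neck_min", "volume")


@dataclass
class MAAIModel:
    variable_names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray          # unit-norm first eigenvector
    explained_fraction: float     # lambda_1 / sum(lambda)
    anchor: str                   # variable whose loading is fixed >= 0
    n_fit: int
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "variable_names": list(self.variable_names),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_fraction": self.explained_fraction,
            "anchor": self.anchor,
            "n_fit": self.n_fit,
            "warnings": self.warnings,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "MAAIModel":
        with open(path) as fh:
            p = json.load(fh)
        return cls(
            variable_names=tuple(p["variable_names"]),
            means=np.asarray(p["means"], dtype=float),
            sds=np.asarray(p["sds"], dtype=float),
            loadings=np.asarray(p["loadings"], dtype=float),
            explained_fraction=float(p["explained_fraction"]),
            anchor=p["anchor"],
            n_fit=int(p["n_fit"]),
            warnings=list(p.get("warnings", [])),
        )


def _as_matrix(records, variables) -> np.ndarray:
    if isinstance(records, pd.DataFrame):
        missing = [v for v in variables if v not in records.columns]
        if missing:
            raise ValueError(f"records missing variable(s) {missing}")
        return records[list(variables)].to_numpy(dtype=float)
    # sequence of AneurysmMorphology-like objects
    try:
        return np.array([[float(getattr(r, v)) for v in variables] for r in records])
    except AttributeError as exc:
        raise ValueError(f"record missing variable: {exc}") from exc


def fit_maai(records, variables=DEFAULT_MAAI_VARIABLES) -> MAAIModel:
    """Fit the morphology index on a sample of aneurysm records.

    ``records`` is a DataFrame or a sequence of objects exposing the named
    variables.  Requires at least 3 records and no zero-variance variable
    (raises, naming it).  If there are fewer records than variables, the
    fit proceeds but carries a warning in its metadata.
    """
    variables = tuple(variables)
    X = _as_matrix(records, variables)
    n, p = X.shape
    if n < 3:
        raise ValueError(f"need at least 3 records to fit MAAI, got {n}")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        raise ValueError(f"zero-variance variable {variables[zero[0]]!r}")
    warn: list[str] = []
    if n < p:
        warn.append(f"fewer records ({n}) than variables ({p}); loadings unstable")
    Z = (X - means) / sds
    corr = (Z.T @ Z) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    loadings = eigvecs[:, 0]
    # sign convention: non-negative loading on the largest-variance variable
    anchor_idx = int(np.argmax(sds**2))
    if loadings[anchor_idx] < 0:
        loadings = -loadings
    explained = float(eigvals[0] / eigvals.sum())
    return MAAIModel(
        variable_names=variables, means=means, sds=sds,
        loadings=loadings, explained_fraction=explained,
        anchor=variables[anchor_idx], n_fit=n, warnings=warn,
    )


def maai_score(model: MAAIModel, record):
    """Score one record (object/Series/dict) or a DataFrame of records.

    The score is the dot product of the loadings with the standardized
    variables; records at the fitting means score exactly 0.
    """
    if isinstance(record, pd.DataFrame):
        X = _as_matrix(record, model.variable_names)
    elif isinstance(record, (dict, pd.Series)):
        try:
            X = np.array([[float(record[v]) for v in model.variable_names]])
        except KeyError as exc:
            raise ValueError(f"record missing variable {exc}") from exc
    else:
        X = _as_matrix([record], model.variable_names)
    z = (X - model.means) / model.sds
    scores = z @ model.loadings
    return scores if scores.shape[0] > 1 else float(scores[0])
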