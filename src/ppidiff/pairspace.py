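"""Protein-level feature normalization and pair difference vectors.

Each protein is a point in descriptor space; a protein pair is represented
by the per-feature difference of the two (min-max rescaled) descriptor
vectors.  The default pair representation is the absolute difference:
interaction is a symmetric relation and the ordering of ids in a pair table
is arbitrary, so the design matrix should not depend on it.  The signed
difference is retained behind ``mode="signed"``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .seq_io import LabeledPair

logger = logging.getLogger(__name__)

Mode = Literal["signed", "absolute"]


class SchemaError(ValueError):
    """Feature schemas of two stages do not match."""


@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature min/max over a stated reference protein set."""

    feature_names: tuple[str, ...]
    z_min: np.ndarray
    z_max: np.ndarray
    reference_set_id: str = ""

    def __post_init__(self) -> None:
        if np.any(self.z_min > self.z_max):
            raise ValueError("z_min must be <= z_max per feature")

    @property
    def degenerate(self) -> np.ndarray:
        """Boolean mask of features with z_max == z_min (no spread)."""
        return self.z_min == self.z_max

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_names": list(self.feature_names),
                "z_min": self.z_min.tolist(),
                "z_max": self.z_max.tolist(),
                "reference_set_id": self.reference_set_id,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "NormalizationParams":
        d = json.loads(text)
        return cls(
            tuple(d["feature_names"]),
            np.asarray(d["z_min"], dtype=float),
            np.asarray(d["z_max"], dtype=float),
            d.get("reference_set_id", ""),
        )


def fit_normalization(
    matrix: pd.DataFrame, reference_set_id: str = ""
) -> NormalizationParams:
    """Record each feature's min and max over a protein set.

    Features with zero spread are flagged degenerate (see
    :attr:`NormalizationParams.degenerate`); they map to 0 on application
    and are dropped when building a design matrix.
    """
    if matrix.shape[0] == 0:
        raise ValueError("cannot fit normalization on an empty protein set")
    values = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("feature matrix contains non-finite values")
    params = NormalizationParams(
        tuple(matrix.columns),
        values.min(axis=0),
        values.max(axis=0),
        reference_set_id,
    )
    n_deg = int(params.degenerate.sum())
    if n_deg:
        logger.info("%d degenerate (constant) features flagged", n_deg)
    return params


def apply_normalization(
    matrix: pd.DataFrame, params: NormalizationParams
) -> pd.DataFrame:
    """Min-max rescale features to [0, 1]: ``(z - z_min) / (z_max - z_min)``.

    Values outside the fitted range (possible when params come from a
    training subset) are clipped to [0, 1]; degenerate features map to 0.
    """
    if tuple(matrix.columns) != params.feature_names:
        raise SchemaError("feature schema does not match normalization params")
    values = matrix.to_numpy(dtype=float)
    span = params.z_max - params.z_min
    safe_span = np.where(span == 0, 1.0, span)
    scaled = (values - params.z_min) / safe_span
    scaled[:, params.degenerate] = 0.0
    np.clip(scaled, 0.0, 1.0, out=scaled)
    return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns)


def pair_difference(
    vec_a: pd.Series | np.ndarray,
    vec_b: pd.Series | np.ndarray,
    mode: Mode = "absolute",
) -> np.ndarray:
    """Per-feature difference of two descriptor vectors.

    ``signed`` returns ``A - B``; ``absolute`` returns ``|A - B|`` and is
    symmetric under swapping the two proteins.
    """
    if isinstance(vec_a, pd.Series) and isinstance(vec_b, pd.Series):
        if tuple(vec_a.index) != tuple(vec_b.index):
            raise SchemaError("pair members have different feature schemas")
    a = np.asarray(vec_a, dtype=float)
    b = np.asarray(vec_b, dtype=float)
    if a.shape != b.shape:
        raise SchemaError("pair members have different feature counts")
    diff = a - b
    return np.abs(diff) if mode == "absolute" else diff


def build_design_matrix(
    pairs: Sequence[LabeledPair],
    features: pd.DataFrame,
    mode: Mode = "absolute",
    drop_degenerate: bool = True,
) -> pd.DataFrame:
    """One difference-vector row per pair, with ``id_a``/``id_b``/``label``.

    *features* should already be normalized.  Constant (degenerate) columns
    are dropped with their names logged; pairs referencing proteins absent
    from *features* are dropped and logged.
    """
    cols = features.columns
    if drop_degenerate:
        values = features.to_numpy(dtype=float)
        degenerate = values.min(axis=0) == values.max(axis=0)
        if degenerate.any():
            logger.info(
                "dropping %d degenerate features: %s",
                int(degenerate.sum()),
                list(cols[degenerate][:10]),
            )
            features = features.loc[:, ~degenerate]
            cols = features.columns
    index = {pid: i for i, pid in enumerate(features.index)}
    values = features.to_numpy(dtype=float)

    rows, meta = [], []
    dropped = 0
    for p in pairs:
        ia, ib = index.get(p.id_a), index.get(p.id_b)
        if ia is None or ib is None:
            dropped += 1
            continue
        diff = values[ia] - values[ib]
        if mode == "absolute":
            diff = np.abs(diff)
        rows.append(diff)
        meta.append((p.id_a, p.id_b, p.label))
    if dropped:
        logger.info("dropped %d pairs lacking feature vectors", dropped)
    data = pd.DataFrame(
        np.asarray(rows).reshape(len(rows), len(cols)), columns=cols
    )
    head = pd.DataFrame(meta, columns=["id_a", "id_b", "label"])
    return pd.concat([head, data], axis=1)


def split_design_matrix(design: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Split a design matrix into (feature frame X, label array y)."""
    y = design["label"].to_numpy(dtype=int)
    X = design.drop(columns=["id_a", "id_b", "label"])
    return X, y


class MinMaxNormalizer(BaseEstimator, TransformerMixin):
    """Sklearn-style wrapper around :func:`fit_normalization`.

    Fitted attributes: ``params_`` (:class:`NormalizationParams`),
    ``degenerate_mask_``.  ``transform`` clips out-of-range values to
    [0, 1] and maps degenerate features to 0.
    """

    def __init__(self, reference_set_id: str = ""):
        self.reference_set_id = reference_set_id

    def fit(self, X: pd.DataFrame, y=None) -> "MinMaxNormalizer":
        self.params_ = fit_normalization(X, self.reference_set_id)
        self.degenerate_mask_ = self.params_.degenerate
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "params_")
        return apply_normalization(X, self.params_)


class PairDifferenceTransformer(BaseEstimator, TransformerMixin):
    """Build pair difference rows from a normalized protein feature matrix.

    ``transform(pairs)`` returns the design matrix of
    :func:`build_design_matrix` for the feature matrix given at
    construction.
    """

    def __init__(self, features: pd.DataFrame, mode: Mode = "absolute"):
        self.features = features
        self.mode = mode

    def fit(self, X: Iterable[LabeledPair], y=None):
        return self

    def transform(self, X: Sequence[LabeledPair]) -> pd.DataFrame:
        return build_design_matrix(list(X), self.features, self.mode)
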