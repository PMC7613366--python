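"""Min-max scaling and the stratified 70/30 train/test split.

Every variable (reflectance channel, spectral index, concentration) is
linearly rescaled to [0, 1] over its fitted range, N = (x - x_min) /
(x_max - x_min), and the transform is invertible so errors can be
reported back in original units (mg/kg dry weight).  Scalers are fitted
on the training set only by default; fitting before the split is
available for protocols that scale the pooled data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MinMaxScaler", "fit_transform_minmax", "SplitSpec", "split_train_test"]


class MinMaxScaler:
    """Per-variable min-max scaler with exact inversion.

    Constant variables (x_max == x_min) map to all zeros with a warning
    rather than dividing by zero; their inverse maps back to x_min.
    """

    def __init__(self):
        self.x_min = None
        self.x_max = None
        self.columns = None

    @property
    def fitted(self) -> bool:
        return self.x_min is not None

    def fit(self, values) -> "MinMaxScaler":
        arr, self.columns = _as_2d(values)
        if arr.shape[0] < 2:
            raise ValueError("need at least 2 rows to fit a min-max scaler")
        self.x_min = np.nanmin(arr, axis=0)
        self.x_max = np.nanmax(arr, axis=0)
        if np.any(self.x_max == self.x_min):
            n_const = int(np.sum(self.x_max == self.x_min))
            warnings.warn(
                f"{n_const} constant variable(s): scaled values set to 0",
                stacklevel=2,
            )
        return self

    def transform(self, values):
        self._check_fitted()
        arr, cols = _as_2d(values)
        rng = self.x_max - self.x_min
        safe = np.where(rng == 0, 1.0, rng)
        out = (arr - self.x_min) / safe
        out[:, rng == 0] = 0.0
        return _like_input(values, out, cols)

    def fit_transform(self, values):
        return self.fit(values).transform(values)

    def invert(self, scaled):
        self._check_fitted()
        arr, cols = _as_2d(scaled)
        out = self.x_min + arr * (self.x_max - self.x_min)
        return _like_input(scaled, out, cols)

    @property
    def range_(self) -> np.ndarray:
        self._check_fitted()
        return self.x_max - self.x_min

    def to_json(self) -> str:
        self._check_fitted()
        return json.dumps({
            "columns": list(self.columns) if self.columns is not None else None,
            "x_min": self.x_min.tolist(),
            "x_max": self.x_max.tolist(),
        })

    @classmethod
    def from_json(cls, payload: str) -> "MinMaxScaler":
        data = json.loads(payload)
        scaler = cls()
        scaler.columns = data["columns"]
        scaler.x_min = np.asarray(data["x_min"], float)
        scaler.x_max = np.asarray(data["x_max"], float)
        return scaler

    def _check_fitted(self):
        if not self.fitted:
            raise ValueError("scaler is not fitted")


def _as_2d(values):
    if isinstance(values, pd.DataFrame):
        return values.to_numpy(float), list(values.columns)
    if isinstance(values, pd.Series):
        return values.to_numpy(float).reshape(-1, 1), [values.name]
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        return arr.reshape(-1, 1), None
    return arr, None


def _like_input(template, arr, cols):
    if isinstance(template, pd.DataFrame):
        return pd.DataFrame(arr, index=template.index, columns=template.columns)
    if isinstance(template, pd.Series):
        return pd.Series(arr[:, 0], index=template.index, name=template.name)
    if np.asarray(template).ndim == 1:
        return arr[:, 0]
    return arr


def fit_transform_minmax(values):
    """Fit a scaler and return (scaler, scaled values)."""
    scaler = MinMaxScaler()
    return scaler, scaler.fit_transform(values)


@dataclass(frozen=True)
class SplitSpec:
    """Random train/test partition: 70/30 by default, stratified, seeded."""

    train_fraction: float = 0.7
    seed: int = 0
    stratify: bool = True

    def __post_init__(self):
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")


def split_train_test(sample_ids, spec: SplitSpec,
                     strata=None) -> tuple[list, list]:
    """Deterministic stratified split with train size = round(f * n).

    Per-stratum train counts are allocated by largest remainder so the
    global train size is exactly round(train_fraction * n).  Strata with
    fewer than 2 members trigger an unstratified fallback with a warning.
    """
    sample_ids = list(sample_ids)
    n = len(sample_ids)
    if n < 3:
        raise ValueError("need at least 3 samples to split")
    if len(set(sample_ids)) != n:
        raise ValueError("sample_ids must be unique")
    n_train = int(round(spec.train_fraction * n))
    rng = np.random.default_rng(spec.seed)

    use_strata = spec.stratify and strata is not None
    if use_strata:
        strata = list(strata)
        if len(strata) != n:
            raise ValueError("strata length must match sample_ids")
        counts = pd.Series(strata).value_counts()
        if (counts < 2).any():
            warnings.warn(
                "stratum with fewer than 2 samples: falling back to an "
                "unstratified split", stacklevel=2)
            use_strata = False

    if not use_strata:
        perm = rng.permutation(n)
        train_idx = set(perm[:n_train].tolist())
        train = [sample_ids[i] for i in sorted(train_idx)]
        test = [s for i, s in enumerate(sample_ids) if i not in train_idx]
        return train, test

    groups: dict = {}
    for i, s in enumerate(strata):
        groups.setdefault(s, []).append(i)
    keys = sorted(groups, key=str)
    quotas = np.array([spec.train_fraction * len(groups[k]) for k in keys])
    base = np.floor(quotas).astype(int)
    short = n_train - base.sum()
    remainder_order = np.argsort(-(quotas - base), kind="stable")
    for j in remainder_order[:short]:
        base[j] += 1
    train_idx = set()
    for k, take in zip(keys, base):
        idx = np.array(groups[k])
        perm = rng.permutation(len(idx))
        train_idx.update(idx[perm[:take]].tolist())
    train = [sample_ids[i] for i in range(n) if i in train_idx]
    test = [sample_ids[i] for i in range(n) if i not in train_idx]
    return train, test
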