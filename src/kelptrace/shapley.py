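"""Shapley-value attribution for the trained classifier.

A feature's Shapley value phi_i averages its marginal contribution
v(S u {i}) - v(S) over all subsets S of the remaining features, weighted by
|S|!(|F|-|S|-1)!/|F|!.  The coalition value v(S) is realized without
retraining, by background masking (the interventional expectation): features
in S keep the explained sample's values, features outside S are replaced by
background values — either each background row in turn with the model
outputs averaged (sample-average mode) or the single background mean vector.
v(empty set) is then the model's mean output over the background, the "base
value" that anchors a force plot, and v(F) = f(x), so the efficiency axiom
base + sum_i phi_i = f(x) holds.

Two estimators are provided: exact enumeration over all 2^|F| coalitions
(the oracle; refuses more than 15 active features) and antithetic
permutation sampling (the full-width workhorse; unbiased, with a
proportional residual correction so additivity holds exactly and the raw
residual reported).  Attribution operates on softmax probabilities in
standardized input units; a logit-space option is available.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations, permutations
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = ["Background", "Explanation", "ShapleyExplainer",
           "value_function", "shapley_exact", "shapley_permutation",
           "global_importance", "local_explanation"]

_MAX_EXACT = 15


@dataclass
class Background:
    """Reference samples defining "feature absent" and the base value."""

    samples: np.ndarray  # (n_background, n_features), standardized units
    summary_mode: str = "sample-average"  # or "mean-vector"

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.shape[0] == 0:
            raise ValueError("background must be non-empty")
        if self.summary_mode not in ("sample-average", "mean-vector"):
            raise ValueError(f"unknown summary mode {self.summary_mode!r}")

    @property
    def reference_rows(self) -> np.ndarray:
        if self.summary_mode == "mean-vector":
            return self.samples.mean(axis=0, keepdims=True)
        return self.samples


@dataclass
class Explanation:
    """Shapley attributions for a batch of samples.

    phi has shape (n_samples, n_features, n_classes) in model-output
    (probability) units; base_values is the per-class value of the empty
    coalition; additivity_residual stores, per (sample, class), the raw
    |f(x) - base - sum_i phi_i| before any correction.
    """

    phi: np.ndarray
    base_values: np.ndarray
    outputs: np.ndarray  # f(x) per sample, (n_samples, n_classes)
    additivity_residual: np.ndarray
    feature_ids: list[str]
    method: dict = field(default_factory=dict)

    def write(self, table_path: str | Path, header_path: str | Path,
              sample_ids: Sequence[str] | None = None) -> None:
        n, d, C = self.phi.shape
        sample_ids = list(sample_ids) if sample_ids is not None else \
            [f"S{i:03d}" for i in range(n)]
        rows = [
            {"sample_id": sample_ids[i], "class": c,
             "feature_id": self.feature_ids[j],
             "phi": self.phi[i, j, c]}
            for i in range(n) for c in range(C) for j in range(d)
        ]
        pd.DataFrame(rows).to_csv(table_path, sep="\t", index=False,
                                  float_format="%.17g")
        with open(header_path, "w", encoding="utf-8") as fh:
            json.dump({
                "method": self.method,
                "base_values": self.base_values.tolist(),
                "max_additivity_residual": float(
                    self.additivity_residual.max()),
            }, fh, indent=1)


def _combine(x: np.ndarray, refs: np.ndarray, in_s: np.ndarray) -> np.ndarray:
    """Masked inputs: x where in_s, each reference row elsewhere."""
    return np.where(in_s[None, :], x[None, :], refs)


def value_function(predict: Callable[[np.ndarray], np.ndarray],
                   x: np.ndarray, S: Sequence[int],
                   background: Background) -> np.ndarray:
    """Coalition value v(S): expected model output with S fixed to x."""
    x = np.asarray(x, dtype=float)
    d = x.shape[0]
    S = np.asarray(sorted(set(int(i) for i in S)), dtype=int)
    if S.size and (S.min() < 0 or S.max() >= d):
        raise IndexError(f"feature index out of range 0..{d - 1}")
    in_s = np.zeros(d, dtype=bool)
    in_s[S] = True
    refs = background.reference_rows
    return np.asarray(predict(_combine(x, refs, in_s))).mean(axis=0)


class ShapleyExplainer:
    """Explain a probabilistic classifier with Shapley values.

    Parameters
    ----------
    predict : callable
        Batched model function mapping (n, d) arrays to (n, C) outputs
        (e.g. ``clf.predict_proba``).
    background : Background or ndarray
        Reference data in the model's input units (conventionally the
        standardized training set).
    method : "permutation" or "exact"
    n_permutations : int
        Antithetic pairs drawn per explained sample (each pair is a random
        feature ordering plus its reverse).
    random_state : int or None
    batch_rows : int
        Chunk size for model calls, bounding peak memory.
    """

    def __init__(self, predict: Callable, background, *,
                 method: str = "permutation", n_permutations: int = 16,
                 random_state: int | None = None, batch_rows: int = 4096):
        if method not in ("permutation", "exact"):
            raise ValueError(f"unknown method {method!r}")
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        self.predict = predict
        self.background = (background if isinstance(background, Background)
                           else Background(background))
        self.method = method
        self.n_permutations = n_permutations
        self.random_state = random_state
        self.batch_rows = batch_rows

    # -------------------------------------------------------------- #

    def _predict_chunked(self, X: np.ndarray) -> np.ndarray:
        outs = [self.predict(X[i:i + self.batch_rows])
                for i in range(0, X.shape[0], self.batch_rows)]
        return np.vstack(outs)

    def base_values(self) -> np.ndarray:
        """v(empty set): mean model output over the background reference.

        In sample-average mode this is the mean prediction over the
        background (training) samples; in mean-vector mode it is the model
        output at the background mean.
        """
        return self._predict_chunked(
            self.background.reference_rows).mean(axis=0)

    def explain(self, X: np.ndarray,
                feature_ids: Sequence[str] | None = None,
                active_features: Sequence[int] | None = None) -> Explanation:
        """Shapley values for each row of X.

        ``active_features`` restricts the game to a subset of features; the
        rest are permanently held at background (treated as absent from F).
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n, d = X.shape
        active = (np.arange(d) if active_features is None
                  else np.asarray(sorted(set(active_features)), dtype=int))
        if feature_ids is None:
            feature_ids = [f"x{j}" for j in range(d)]

        base = self.base_values()
        C = base.shape[0]
        phi = np.zeros((n, d, C))
        outputs = np.zeros((n, C))
        residual = np.zeros((n, C))
        rng = np.random.default_rng(self.random_state)
        for i in range(n):
            if self.method == "exact":
                phi_i, out_i = self._exact_one(X[i], active, base)
                phi[i, active] = phi_i
                outputs[i] = out_i
                residual[i] = np.abs(out_i - base - phi[i].sum(axis=0))
            else:
                phi_i, out_i, res_i = self._permutation_one(
                    X[i], active, base, rng)
                phi[i, active] = phi_i
                outputs[i] = out_i
                residual[i] = res_i
        return Explanation(
            phi=phi, base_values=base, outputs=outputs,
            additivity_residual=residual, feature_ids=list(feature_ids),
            method={
                "estimator": self.method,
                "n_permutations": (None if self.method == "exact"
                                   else self.n_permutations),
                "seed": self.random_state,
                "background_mode": self.background.summary_mode,
                "n_background": int(self.background.samples.shape[0]),
                "n_active_features": int(active.size),
            },
        )

    # -------------------------------------------------------------- #

    def _coalition_values(self, x: np.ndarray, active: np.ndarray,
                          masks: np.ndarray) -> np.ndarray:
        """v(S) for many coalitions at once.

        masks: (n_coalitions, m) booleans over the active features.
        Returns (n_coalitions, C).
        """
        refs = self.background.reference_rows
        r = refs.shape[0]
        full = np.zeros((masks.shape[0], x.shape[0]), dtype=bool)
        full[:, active] = masks
        # rows: coalition-major, background-minor
        tiled = np.repeat(full, r, axis=0)
        stacked = np.where(tiled, x[None, :], np.tile(refs, (masks.shape[0], 1)))
        out = self._predict_chunked(stacked)
        C = out.shape[1]
        return out.reshape(masks.shape[0], r, C).mean(axis=1)

    def _exact_one(self, x, active, base):
        m = active.size
        if m > _MAX_EXACT:
            raise ValueError(
                f"exact enumeration limited to {_MAX_EXACT} active features "
                f"(got {m}); use method='permutation'"
            )
        subsets = []
        index = {}
        for size in range(m + 1):
            for S in combinations(range(m), size):
                index[S] = len(subsets)
                subsets.append(S)
        masks = np.zeros((len(subsets), m), dtype=bool)
        for t, S in enumerate(subsets):
            masks[t, list(S)] = True
        values = self._coalition_values(x, active, masks)  # (2^m, C)

        fact = [math.factorial(t) for t in range(m + 1)]
        phi = np.zeros((m, values.shape[1]))
        for S in index:
            vS = values[index[S]]
            w = fact[len(S)] * fact[m - len(S) - 1] / fact[m]
            in_S = set(S)
            for i in range(m):
                if i in in_S:
                    continue
                Si = tuple(sorted(in_S | {i}))
                phi[i] += w * (values[index[Si]] - vS)
        out = values[index[tuple(range(m))]]
        return phi, out

    def _permutation_one(self, x, active, base, rng):
        m = active.size
        C = base.shape[0]
        acc = np.zeros((m, C))
        n_orderings = 0
        for _ in range(self.n_permutations):
            perm = rng.permutation(m)
            for ordering in (perm, perm[::-1]):  # antithetic pair
                masks = np.zeros((m + 1, m), dtype=bool)
                for t in range(1, m + 1):
                    masks[t] = masks[t - 1]
                    masks[t, ordering[t - 1]] = True
                values = self._coalition_values(x, active, masks)
                acc[ordering] += values[1:] - values[:-1]
                n_orderings += 1
        phi = acc / n_orderings
        out = self._value_full(x)
        raw = out - base - phi.sum(axis=0)
        # proportional residual correction: additivity exactly, by |phi| share
        abs_sum = np.abs(phi).sum(axis=0)
        for c in range(C):
            if abs_sum[c] > 0:
                phi[:, c] += raw[c] * np.abs(phi[:, c]) / abs_sum[c]
            elif m > 0:
                phi[:, c] += raw[c] / m
        return phi, out, np.abs(raw)

    def _value_full(self, x):
        return np.asarray(self.predict(x[None, :]))[0]


# ------------------------------------------------------------------ #
# functional wrappers


def shapley_exact(predict, x, background, *, active_features=None,
                  feature_ids=None) -> Explanation:
    """Exact Shapley values by coalition enumeration (<= 15 features)."""
    return ShapleyExplainer(predict, background, method="exact").explain(
        np.atleast_2d(x), feature_ids=feature_ids,
        active_features=active_features)


def shapley_permutation(predict, x, background, *, n_perm=16, seed=None,
                        active_features=None, feature_ids=None) -> Explanation:
    """Antithetic permutation-sampling Shapley estimate."""
    return ShapleyExplainer(
        predict, background, method="permutation", n_permutations=n_perm,
        random_state=seed,
    ).explain(np.atleast_2d(x), feature_ids=feature_ids,
              active_features=active_features)


def exhaustive_permutation_reference(predict, x, background,
                                     active_features=None) -> np.ndarray:
    """Average marginal contributions over all |F|! orderings (tiny F only).

    Deduplicated full enumeration; equals the exact Shapley value.  Kept as
    an independent cross-check route.
    """
    x = np.asarray(x, dtype=float)
    background = (background if isinstance(background, Background)
                  else Background(background))
    d = x.shape[0]
    active = (np.arange(d) if active_features is None
              else np.asarray(sorted(set(active_features)), dtype=int))
    m = active.size
    if m > 6:
        raise ValueError("full enumeration reference limited to 6 features")
    expl = ShapleyExplainer(predict, background, method="exact")
    acc = None
    count = 0
    for ordering in set(permutations(range(m))):
        masks = np.zeros((m + 1, m), dtype=bool)
        for t in range(1, m + 1):
            masks[t] = masks[t - 1]
            masks[t, ordering[t - 1]] = True
        values = expl._coalition_values(x, active, masks)
        contrib = np.zeros((m, values.shape[1]))
        contrib[list(ordering)] = values[1:] - values[:-1]
        acc = contrib if acc is None else acc + contrib
        count += 1
    return acc / count


def global_importance(expl: Explanation, top_k: int | None = None
                      ) -> pd.DataFrame:
    """Mean |phi| per feature: per class and stacked across classes.

    Returns a DataFrame sorted by stacked importance (descending; ties keep
    feature order), one row per feature.
    """
    mean_abs = np.abs(expl.phi).mean(axis=0)  # (d, C)
    df = pd.DataFrame(
        mean_abs,
        columns=[f"mean_abs_shap_class{c}" for c in range(mean_abs.shape[1])],
    )
    df.insert(0, "feature_id", expl.feature_ids)
    df["stacked_importance"] = mean_abs.sum(axis=1)
    df = df.sort_values("stacked_importance", ascending=False,
                        kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df.head(top_k) if top_k else df


def local_explanation(expl: Explanation, sample_index: int,
                      class_index: int) -> dict:
    """Force-plot record for one (sample, class): base value, signed
    contributions sorted by |phi|, and the model output."""
    phi = expl.phi[sample_index, :, class_index]
    order = np.argsort(-np.abs(phi), kind="stable")
    return {
        "base_value": float(expl.base_values[class_index]),
        "output": float(expl.outputs[sample_index, class_index]),
        "contributions": [
            {"feature_id": expl.feature_ids[j], "phi": float(phi[j])}
            for j in order
        ],
    }
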