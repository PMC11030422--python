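"""SCPF-fragment pair attributes and the trainable logistic match score.

Whether a fragment feature belongs to a precursor SCPF is decided from
three attributes:

* ``norm_intensity_rank`` — the fragment's intensity rank within the
  candidate list ``L`` (decreasing intensity, rank 1 = most intense)
  divided by ``|L|``;
* ``norm_cycle_number`` — cycles in which the fragment is observed divided
  by cycles in which the SCPF is observed (may exceed 1);
* ``shared_xic`` — the area shared by the two unit-area, linearly
  interpolated elution profiles, in ``[0, 1]``.

A logistic regression model maps the attribute vector to a match
probability.  Training data are labeled from identified proteoforms:
a pair is positive when the fragment mass matches a b- or y-ion mass of
the SCPF's proteoform within a ppm tolerance.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .feature_model import SCPF, FragmentFeature

logger = logging.getLogger(__name__)

__all__ = [
    "ATTRIBUTE_NAMES",
    "PairAttributes",
    "ScoredPair",
    "PairModel",
    "shared_xic",
    "intensity_rank_map",
    "compute_attributes",
    "build_pair_table",
    "label_pairs",
    "train_model",
    "score_pair",
]

ATTRIBUTE_NAMES = ("norm_intensity_rank", "norm_cycle_number", "shared_xic")


@dataclass(frozen=True)
class PairAttributes:
    norm_intensity_rank: float  # in (0, 1]
    norm_cycle_number: float  # >= 0, uncapped
    shared_xic: float  # in [0, 1]

    def __post_init__(self) -> None:
        if not 0 < self.norm_intensity_rank <= 1:
            raise ValueError("norm_intensity_rank must be in (0, 1]")
        if self.norm_cycle_number < 0:
            raise ValueError("norm_cycle_number must be non-negative")
        if not 0 <= self.shared_xic <= 1:
            raise ValueError("shared_xic must be in [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.norm_intensity_rank, self.norm_cycle_number, self.shared_xic]
        )


@dataclass
class ScoredPair:
    scpf_id: str
    fragment_id: str
    attributes: PairAttributes
    score: float | None = None
    label: int | None = None  # 1 positive, 0 negative, None unlabeled


# ---------------------------------------------------------------------------
# shared XIC


def _profile_breakpoints(xic: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear elution profile of an XIC in cycle coordinates.

    The profile passes through ``(i, a_i)`` for every cycle of the support
    span and falls to zero half a cycle beyond the first and last observed
    cycles.  A single-cycle feature thus becomes a unit-base triangle, so
    unit-area normalization is always defined.
    """
    x = np.asarray(xic, dtype=float)
    nz = np.flatnonzero(x > 0)
    if nz.size == 0:
        raise ValueError("empty feature: XIC has no positive entry")
    s, e = int(nz[0]), int(nz[-1])
    xs = np.concatenate(([s + 0.5], np.arange(s, e + 1) + 1.0, [e + 1.5]))
    ys = np.concatenate(([0.0], x[s : e + 1], [0.0]))
    return xs, ys


def shared_xic(a: np.ndarray, b: np.ndarray) -> float:
    """Shared area under the two unit-area interpolated XIC profiles.

    Both elution profiles are linearly interpolated, scaled to unit area,
    and the area under their pointwise minimum is returned.  Because both
    normalized profiles are piecewise linear, the minimum is integrated
    exactly on the union of their breakpoints plus the segment crossing
    points.  Symmetric, bounded in ``[0, 1]``, and 1 exactly when the
    normalized profiles coincide.
    """
    xa, ya = _profile_breakpoints(a)
    xb, yb = _profile_breakpoints(b)
    xs = np.union1d(xa, xb)
    fa = np.interp(xs, xa, ya)  # 0 outside support (edge values are 0)
    fb = np.interp(xs, xb, yb)
    fa /= np.trapezoid(fa, xs)
    fb /= np.trapezoid(fb, xs)
    # insert the points where the two normalized profiles cross
    d = fa - fb
    sign_change = d[:-1] * d[1:] < 0
    if np.any(sign_change):
        i = np.flatnonzero(sign_change)
        xc = xs[i] + d[i] * (xs[i + 1] - xs[i]) / (d[i] - d[i + 1])
        grid = np.sort(np.concatenate([xs, xc]))
        fa = np.interp(grid, xs, fa)
        fb = np.interp(grid, xs, fb)
    else:
        grid = xs
    area = float(np.trapezoid(np.minimum(fa, fb), grid))
    return min(1.0, max(0.0, area))


# ---------------------------------------------------------------------------
# attributes


def intensity_rank_map(candidates: Sequence[FragmentFeature]) -> dict[str, int]:
    """Rank (1 = most intense) of each fragment in the candidate list ``L``.

    Ties are broken by ascending mass then feature id so the ranks are a
    permutation of ``1..|L|``.
    """
    order = sorted(
        candidates, key=lambda f: (-f.total_intensity, f.mono_mass, f.feature_id)
    )
    return {f.feature_id: r for r, f in enumerate(order, start=1)}


def compute_attributes(
    scpf: SCPF,
    fragment: FragmentFeature,
    candidates: Sequence[FragmentFeature],
    rank_map: Mapping[str, int] | None = None,
) -> PairAttributes:
    """The three match attributes for one (SCPF, fragment) pair.

    ``candidates`` is the round-1 survivor list ``L``; ``rank_map`` may be
    passed to reuse the ranking across the pairs of one SCPF.
    """
    if rank_map is None:
        rank_map = intensity_rank_map(candidates)
    if fragment.feature_id not in rank_map:
        raise ValueError(f"fragment {fragment.feature_id} not in candidate list L")
    c = scpf.num_cycles
    if c < 1:
        raise ValueError("SCPF observed in no cycle")
    return PairAttributes(
        norm_intensity_rank=rank_map[fragment.feature_id] / len(rank_map),
        norm_cycle_number=fragment.num_cycles / c,
        shared_xic=shared_xic(scpf.xic, fragment.xic),
    )


def build_pair_table(
    scpfs: Sequence[SCPF],
    fragments: Sequence[FragmentFeature],
    t: int = 3,
) -> pd.DataFrame:
    """Attribute table of all (SCPF, fragment) pairs passing the round-1 gate.

    Pairs are formed per isolation window with the apex-distance cutoff
    ``min{t, floor(c/2)}`` and no greedy consumption, so a fragment may
    pair with several SCPFs — the pairing used to assemble training data.
    """
    from .pseudo_spectrum import round1_filter  # local import: avoids a cycle

    frag_by_window: dict[int, list[FragmentFeature]] = {}
    for f in fragments:
        frag_by_window.setdefault(f.window_index, []).append(f)
    rows: list[dict] = []
    for s in scpfs:
        if s.window_index is None:
            continue
        L = round1_filter(s, frag_by_window.get(s.window_index, []), t)
        if not L:
            continue
        rank_map = intensity_rank_map(L)
        for f in L:
            a = compute_attributes(s, f, L, rank_map)
            rows.append(
                {
                    "scpf_id": s.feature_id,
                    "proteoform_feature_id": s.proteoform_feature_id,
                    "fragment_id": f.feature_id,
                    "fragment_mass": f.mono_mass,
                    "norm_intensity_rank": a.norm_intensity_rank,
                    "norm_cycle_number": a.norm_cycle_number,
                    "shared_xic": a.shared_xic,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "scpf_id",
            "proteoform_feature_id",
            "fragment_id",
            "fragment_mass",
            *ATTRIBUTE_NAMES,
        ],
    )


# ---------------------------------------------------------------------------
# labeling


def matches_ladder(mass: float, ladder: np.ndarray, ppm_tol: float) -> bool:
    """True when ``mass`` is within ``ppm_tol`` of some theoretical b/y mass."""
    if ladder.size == 0:
        return False
    i = int(np.searchsorted(ladder, mass))
    for j in (i - 1, i):
        if 0 <= j < ladder.size and abs(mass - ladder[j]) <= ppm_tol * 1e-6 * ladder[j]:
            return True
    return False


def label_pairs(
    pairs: pd.DataFrame,
    catalog: Mapping[str, np.ndarray],
    ppm_tol: float = 10.0,
) -> pd.DataFrame:
    """Label pairs positive when the fragment mass matches a catalog b/y mass.

    ``pairs`` needs columns ``proteoform_feature_id`` and ``fragment_mass``;
    ``catalog`` maps proteoform ids to sorted neutral b/y mass arrays.
    Pairs whose SCPF has no catalog entry are dropped with a warning.
    A fragment may legitimately appear in pairs with several SCPFs.
    """
    known = pairs["proteoform_feature_id"].isin(catalog.keys())
    if not known.all():
        warnings.warn(
            f"dropping {int((~known).sum())} pairs without a catalog proteoform",
            stacklevel=2,
        )
    out = pairs.loc[known].copy()
    ladders = {pfid: np.sort(np.asarray(m, dtype=float)) for pfid, m in catalog.items()}
    out["label"] = [
        int(matches_ladder(m, ladders[pfid], ppm_tol))
        for pfid, m in zip(out["proteoform_feature_id"], out["fragment_mass"])
    ]
    return out


# ---------------------------------------------------------------------------
# model


@dataclass
class PairModel:
    """Logistic pair-scoring model: ``P(match) = logistic(w.x + b)``."""

    weights: np.ndarray  # one weight per attribute
    intercept: float
    attribute_names: tuple[str, ...] = ATTRIBUTE_NAMES
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.attribute_names),):
            raise ValueError("one weight per attribute required")

    def score_matrix(self, X: np.ndarray) -> np.ndarray:
        z = np.asarray(X, dtype=float) @ self.weights + self.intercept
        return 1.0 / (1.0 + np.exp(-z))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "weights": [repr(float(w)) for w in self.weights],
                    "intercept": repr(float(self.intercept)),
                    "attribute_names": list(self.attribute_names),
                    "training_meta": self.training_meta,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PairModel":
        d = json.loads(Path(path).read_text())
        return cls(
            np.array([float(w) for w in d["weights"]]),
            float(d["intercept"]),
            tuple(d["attribute_names"]),
            d.get("training_meta", {}),
        )


def train_model(
    labeled: pd.DataFrame,
    split_ratio: float = 0.7,
    seed: int = 0,
    max_iter: int = 5000,
) -> PairModel:
    """Fit the logistic model on a random train/validation split.

    The labeled pair table is split ``split_ratio : 1 - split_ratio``
    (default 70:30); the maximum-likelihood fit (no regularization, no
    standardization — the attributes are already normalized ratios) is
    evaluated on the held-out part.  Balanced accuracy (0.5 threshold) and
    ROC-AUC land in ``training_meta``.  Deterministic given (data, seed).
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import balanced_accuracy_score, roc_auc_score
    from sklearn.model_selection import train_test_split

    X = labeled[list(ATTRIBUTE_NAMES)].to_numpy(dtype=float)
    y = labeled["label"].to_numpy(dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    X_tr, X_va, y_tr, y_va = train_test_split(
        X, y, train_size=split_ratio, random_state=seed
    )
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=max_iter)
    clf.fit(X_tr, y_tr)
    model = PairModel(clf.coef_[0].copy(), float(clf.intercept_[0]))
    p_va = model.score_matrix(X_va)
    model.training_meta = {
        "split_ratio": split_ratio,
        "seed": seed,
        "n_train": int(len(y_tr)),
        "n_validation": int(len(y_va)),
        "balanced_accuracy": float(balanced_accuracy_score(y_va, p_va > 0.5)),
        "auc": float(roc_auc_score(y_va, p_va)),
    }
    logger.info(
        "trained pair model: balanced accuracy %.4f, AUC %.4f (n=%d)",
        model.training_meta["balanced_accuracy"],
        model.training_meta["auc"],
        len(y),
    )
    return model


def score_pair(model: PairModel, attributes: PairAttributes) -> float:
    """Closed-form logistic score ``1 / (1 + exp(-(w.x + b)))``."""
    return float(model.score_matrix(attributes.as_array()[None, :])[0])
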