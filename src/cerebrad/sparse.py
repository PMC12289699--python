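"""Sparse-representation classification (SRC) with orthogonal matching pursuit.

The classifier represents a test feature vector ``f`` as a sparse linear
combination of the normalized training columns ``F = [f_1^1 .. f_m^1,
f_1^2 .. f_n^2]`` by solving

    beta_hat = argmin_beta ||f - F beta||_2^2 + gamma ||beta||_0

with a greedy orthogonal matching pursuit (OMP), then computes per-class
reconstruction residuals r_c(f) = ||f - F delta_c(beta_hat)||_2, where
delta_c zeroes every coefficient not belonging to class c, and assigns the
class with the smallest residual.  The l0 penalty is realized operationally
through the OMP sparsity cap and residual tolerance; gamma (default 0.01) is
carried as metadata.

Feature screening reuses the same pursuit: the +/-1 class-indicator vector is
sparse-coded against the transposed training matrix (each feature is a
dictionary atom over subjects), and features are ranked by absolute
coefficient magnitude accumulated over resampled repetitions.

The model/results surface follows the usual statistical-modelling shape:
``SparseRepresentationClassifier(X, y, ...).fit()`` returns ``SRCResults``
with prediction, decision scores and a text summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Normalizer",
    "SparseCode",
    "SparseDictionary",
    "ClassDecision",
    "omp_solve",
    "screen_features",
    "SparseRepresentationClassifier",
    "SRCResults",
]

SCALE_FLOOR = 1e-8
SCORE_EPS = 1e-12


class Normalizer:
    """Per-feature z-scoring learned on training rows and reused on test rows."""

    def __init__(self) -> None:
        self.center_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Normalizer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("normalizer needs >= 2 training rows")
        self.center_ = X.mean(axis=0)
        self.scale_ = np.maximum(X.std(axis=0), SCALE_FLOOR)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.center_ is None:
            raise RuntimeError("normalizer not fitted")
        return (np.asarray(X, dtype=float) - self.center_) / self.scale_

    def to_dict(self) -> dict:
        return {"center": self.center_.tolist(), "scale": self.scale_.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Normalizer":
        out = cls()
        out.center_ = np.asarray(d["center"], dtype=float)
        out.scale_ = np.asarray(d["scale"], dtype=float)
        return out


@dataclass
class SparseCode:
    """A greedy sparse code: coefficients, support, and the final residual."""

    beta_hat: np.ndarray
    support: np.ndarray
    residual_norm: float
    gamma: float = 0.01
    max_atoms: int = 30


@dataclass
class ClassDecision:
    """Per-class residuals, the argmin class, and a continuous ROC score.

    ``score = (r1 - r2) / (r1 + r2 + eps)``: positive means class 2 is the
    better reconstruction.  Exact ties predict class 1 (logged by callers).
    """

    residuals: tuple[float, float]
    predicted: int
    score: float


def omp_solve(
    F: np.ndarray,
    f: np.ndarray,
    max_atoms: int | None = None,
    tol: float = 1e-6,
    gamma: float = 0.01,
) -> SparseCode:
    """Orthogonal matching pursuit for ``f ~ F beta`` with unit-norm columns.

    Iteratively adds the column most correlated with the current residual and
    re-solves least squares on the support; stops when the support reaches
    ``max_atoms`` (default ``min(30, n_columns)``), the residual norm falls
    below ``tol``, or no column correlates with the residual.

    A zero-norm ``f`` returns the all-zero code with residual 0.
    """
    F = np.asarray(F, dtype=float)
    f = np.asarray(f, dtype=float).ravel()
    if F.shape[0] != f.shape[0]:
        raise ValueError(f"dimension mismatch: F has {F.shape[0]} rows, f has {f.shape[0]}")
    n_cols = F.shape[1]
    if max_atoms is None:
        max_atoms = min(30, n_cols)
    max_atoms = min(max_atoms, n_cols, F.shape[0])

    beta = np.zeros(n_cols)
    fnorm = float(np.linalg.norm(f))
    if fnorm == 0.0:
        return SparseCode(beta, np.array([], dtype=int), 0.0, gamma, max_atoms)

    support: list[int] = []
    residual = f.copy()
    coef = np.array([])
    for _ in range(max_atoms):
        corr = F.T @ residual
        corr[support] = 0.0
        j = int(np.argmax(np.abs(corr)))
        if abs(corr[j]) < 1e-12:
            break
        support.append(j)
        Fs = F[:, support]
        coef, *_ = np.linalg.lstsq(Fs, f, rcond=None)
        residual = f - Fs @ coef
        if np.linalg.norm(residual) <= tol:
            break

    sup = np.asarray(support, dtype=int)
    beta[sup] = coef
    return SparseCode(beta, sup, float(np.linalg.norm(residual)), gamma, max_atoms)


@dataclass
class SparseDictionary:
    """Normalized training columns with class labels and the screening state.

    ``F`` is feature-dimension x (m + n); columns have unit Euclidean norm.
    ``column_classes`` holds 1 or 2 per column.
    """

    F: np.ndarray
    column_classes: np.ndarray
    normalizer: Normalizer
    selected_features: np.ndarray
    column_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        m = int(np.sum(self.column_classes == 1))
        n = int(np.sum(self.column_classes == 2))
        if m < 1 or n < 1:
            raise ValueError("dictionary needs at least one column of each class")

    def save(self, out_dir: str | Path, settings: dict | None = None) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.F).to_csv(out_dir / "dictionary.csv", index=False)
        pd.DataFrame(
            {"column_id": self.column_ids or range(self.F.shape[1]),
             "class": self.column_classes}
        ).to_csv(out_dir / "columns.csv", index=False)
        (out_dir / "normalizer.json").write_text(json.dumps(self.normalizer.to_dict()))
        (out_dir / "selected_features.json").write_text(
            json.dumps([int(i) for i in self.selected_features])
        )
        (out_dir / "settings.json").write_text(json.dumps(settings or {}, indent=2))

    @classmethod
    def load(cls, in_dir: str | Path) -> "SparseDictionary":
        in_dir = Path(in_dir)
        F = pd.read_csv(in_dir / "dictionary.csv").to_numpy(dtype=float)
        cols = pd.read_csv(in_dir / "columns.csv")
        normalizer = Normalizer.from_dict(json.loads((in_dir / "normalizer.json").read_text()))
        selected = np.asarray(json.loads((in_dir / "selected_features.json").read_text()), dtype=int)
        return cls(F, cols["class"].to_numpy(), normalizer, selected,
                   tuple(cols["column_id"].astype(str)))


def _unit_columns(A: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(A, axis=0)
    norms = np.where(norms < SCALE_FLOOR, 1.0, norms)
    return A / norms


def screen_features(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 100,
    n_repeats: int = 10,
    subsample: float = 0.8,
    max_atoms: int | None = None,
    tol: float = 1e-6,
    seed: int = 0,
) -> np.ndarray:
    """Sparse-representation feature screening; returns top-``k`` column indices.

    The +/-1 class indicator is sparse-coded (OMP) against the transposed,
    z-scored, unit-normalized training matrix; over ``n_repeats`` stratified
    row subsamples the absolute coefficients are accumulated and features are
    ranked by the total (ties broken by absolute label correlation, then
    index).  Deterministic for a given seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    n, p = X.shape
    if not 1 <= k <= p:
        raise ValueError(f"k must be in [1, {p}], got {k}")
    if k == p:
        return np.arange(p)

    target = np.where(y == np.unique(y)[-1], 1.0, -1.0)
    rng = np.random.default_rng(seed)
    scores = np.zeros(p)
    for _ in range(n_repeats):
        idx = _stratified_subsample(target, subsample, rng)
        Xs = X[idx]
        Z = Xs - Xs.mean(axis=0)
        sd = np.maximum(Xs.std(axis=0), SCALE_FLOOR)
        D = _unit_columns(Z / sd)
        code = omp_solve(D, target[idx], max_atoms=max_atoms, tol=tol)
        scores += np.abs(code.beta_hat)

    Zf = X - X.mean(axis=0)
    denom = np.linalg.norm(Zf, axis=0) * np.linalg.norm(target - target.mean())
    denom = np.where(denom < SCALE_FLOOR, 1.0, denom)
    tiebreak = np.abs(Zf.T @ (target - target.mean())) / denom
    order = np.lexsort((np.arange(p), -tiebreak, -scores))
    return np.sort(order[:k])


def _stratified_subsample(target: np.ndarray, frac: float, rng: np.random.Generator):
    idx: list[int] = []
    for cls in np.unique(target):
        members = np.nonzero(target == cls)[0]
        take = max(2, int(round(frac * members.size)))
        take = min(take, members.size)
        idx.extend(rng.choice(members, size=take, replace=False))
    return np.sort(np.asarray(idx))


def classify(dic: SparseDictionary, f: np.ndarray, max_atoms: int | None = None,
             tol: float = 1e-6, gamma: float = 0.01) -> ClassDecision:
    """SRC decision for one normalized, screened test vector."""
    f = np.asarray(f, dtype=float).ravel()
    if f.shape[0] != dic.F.shape[0]:
        raise ValueError(
            f"dimension mismatch: expected {dic.F.shape[0]} features, got {f.shape[0]}"
        )
    code = omp_solve(dic.F, f, max_atoms=max_atoms, tol=tol, gamma=gamma)
    residuals = []
    for cls in (1, 2):
        beta_c = np.where(dic.column_classes == cls, code.beta_hat, 0.0)
        residuals.append(float(np.linalg.norm(f - dic.F @ beta_c)))
    r1, r2 = residuals
    predicted = 1 if r1 <= r2 else 2
    score = (r1 - r2) / (r1 + r2 + SCORE_EPS)
    return ClassDecision(residuals=(r1, r2), predicted=predicted, score=score)


@dataclass
class SRCSettings:
    """Operative knobs of screening and the OMP solver.

    ``dictionary_offset`` shifts every z-scored feature to a common positive
    baseline (in training-s.d. units) before unit-normalizing the dictionary
    columns.  Residual-based sparse-representation classification needs
    positively correlated class columns (as raw image or radiomics vectors
    are); pure z-scoring makes the two class means antipodal, and signed OMP
    coefficients then reconstruct a test vector equally well from either
    class, collapsing the residual contrast to chance.
    """

    n_selected: int = 100
    max_atoms: int = 30
    tol: float = 1e-6
    gamma: float = 0.01
    screen_repeats: int = 10
    screen_subsample: float = 0.8
    dictionary_offset: float = 4.0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


class SparseRepresentationClassifier:
    """Binary SRC model over a subjects x features matrix.

    Parameters
    ----------
    X : array-like, subjects x features
    y : array-like of two distinct labels; ``classes[0]`` maps to class 1
        and ``classes[1]`` to class 2.
    """

    def __init__(
        self,
        X,
        y,
        classes: Sequence | None = None,
        feature_names: Sequence[str] | None = None,
        settings: SRCSettings | None = None,
        seed: int = 0,
    ) -> None:
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y).ravel()
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X must be subjects x features matching y")
        self.classes = tuple(classes) if classes is not None else tuple(np.unique(self.y))
        if len(self.classes) != 2:
            raise ValueError(f"binary classifier needs exactly 2 classes, got {self.classes}")
        self.feature_names = tuple(feature_names) if feature_names is not None else None
        self.settings = settings or SRCSettings()
        self.seed = seed

    @classmethod
    def from_feature_matrix(cls, fm, positive, negative, settings=None, seed: int = 0):
        """Build from a FeatureMatrix; ``negative`` maps to class 1, ``positive`` to class 2."""
        sub, ybin = fm.task_subset(positive, negative)
        labels = np.where(ybin.to_numpy() == 1, "positive", "negative")
        names = ["|".join(map(str, c)) for c in sub.values.columns]
        return cls(sub.values.to_numpy(), labels, classes=("negative", "positive"),
                   feature_names=names, settings=settings, seed=seed)

    def fit(self) -> "SRCResults":
        """Normalize, screen, and assemble the sparse dictionary."""
        s = self.settings
        normalizer = Normalizer().fit(self.X)
        Z = normalizer.transform(self.X)
        ybin = np.where(self.y == self.classes[1], 1, 0)
        if ybin.sum() == 0 or ybin.sum() == ybin.size:
            raise ValueError("training data must contain both classes")
        k = min(s.n_selected, self.X.shape[1])
        selected = screen_features(
            self.X, ybin, k=k, n_repeats=s.screen_repeats,
            subsample=s.screen_subsample, max_atoms=s.max_atoms, tol=s.tol,
            seed=self.seed,
        )
        # class-1 columns first, then class-2, as F = [f^1 ..., f^2 ...]
        order = np.concatenate([np.nonzero(ybin == 0)[0], np.nonzero(ybin == 1)[0]])
        F = _unit_columns(Z[order][:, selected].T + s.dictionary_offset)
        dic = SparseDictionary(
            F=F,
            column_classes=np.where(ybin[order] == 1, 2, 1),
            normalizer=normalizer,
            selected_features=selected,
            column_ids=tuple(str(i) for i in order),
        )
        return SRCResults(self, dic)


class SRCResults:
    """Fitted SRC: the dictionary plus prediction and reporting methods."""

    def __init__(self, model: SparseRepresentationClassifier, dictionary: SparseDictionary):
        self.model = model
        self.dictionary = dictionary
        self.n_ties_ = 0

    @property
    def selected_feature_names(self) -> tuple[str, ...]:
        names = self.model.feature_names
        sel = self.dictionary.selected_features
        if names is None:
            return tuple(str(i) for i in sel)
        return tuple(names[i] for i in sel)

    def decide(self, X) -> pd.DataFrame:
        """Residuals, score, and predicted label per test row."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.model.X.shape[1]:
            raise ValueError(
                f"dimension mismatch: expected {self.model.X.shape[1]} features, got {X.shape[1]}"
            )
        s = self.model.settings
        Z = (
            self.dictionary.normalizer.transform(X)[:, self.dictionary.selected_features]
            + s.dictionary_offset
        )
        rows = []
        for f in Z:
            d = classify(self.dictionary, f, max_atoms=s.max_atoms, tol=s.tol, gamma=s.gamma)
            if d.residuals[0] == d.residuals[1]:
                self.n_ties_ += 1
            rows.append(
                {
                    "residual_1": d.residuals[0],
                    "residual_2": d.residuals[1],
                    "score": d.score,
                    "predicted": self.model.classes[d.predicted - 1],
                }
            )
        return pd.DataFrame(rows)

    def predict(self, X) -> np.ndarray:
        return self.decide(X)["predicted"].to_numpy()

    def summary(self) -> str:
        m = self.model
        counts = {c: int(np.sum(m.y == c)) for c in m.classes}
        lines = [
            "Sparse representation classifier (OMP)",
            "=" * 46,
            f"training subjects:   {m.X.shape[0]}  "
            f"({m.classes[0]}: {counts[m.classes[0]]}, {m.classes[1]}: {counts[m.classes[1]]})",
            f"features available:  {m.X.shape[1]}",
            f"features selected:   {len(self.dictionary.selected_features)}",
            f"max atoms / tol:     {m.settings.max_atoms} / {m.settings.tol:g}",
            f"gamma (metadata):    {m.settings.gamma}",
            "top selected features:",
        ]
        for name in self.selected_feature_names[:10]:
            lines.append(f"  {name}")
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> None:
        self.dictionary.save(out_dir, settings={
            **self.model.settings.to_dict(),
            "classes": list(map(str, self.model.classes)),
            "seed": self.model.seed,
        })
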