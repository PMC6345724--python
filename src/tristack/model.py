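"""Sequence + stacking feature encoding and epsilon-SVR affinity models.

gcPBM probes (fixed-length genomic sequences with fluorescence intensities)
are encoded as a 4K one-hot block — slot order A, T, G, C per position, so
"A" is 1 0 0 0 and "C" is 0 0 0 1 — optionally followed by the K-2
sliding-window stacking free energies (the "1mer+dgs" feature set; for
K = 36 the widths are 144 and 178). A linear epsilon-SVR is trained to
predict ln(intensity), and performance is estimated with nested k-fold
cross-validation: an inner CV picks (C, epsilon) on each outer training
fold, the model is refit and scored by Pearson correlation on the held-out
fold, so no probe is ever predicted by a model that saw it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.svm import LinearSVR

from ._util import check_acgt
from .energy import DinucleotideTable
from .profile import stacking_profile

__all__ = [
    "BASE_SLOT_ORDER",
    "ProbeSet",
    "FeatureMatrix",
    "CvResult",
    "DEFAULT_C_GRID",
    "DEFAULT_EPSILON_GRID",
    "encode_1mer",
    "encode_features",
    "train_svr",
    "nested_cv",
    "pearson",
    "read_gcpbm",
    "write_gcpbm",
]

#: One-hot slot order per position. Deliberately A, T, G, C (not
#: alphabetical) — the convention the binding-affinity matrices use.
BASE_SLOT_ORDER = "ATGC"

DEFAULT_C_GRID = tuple(2.0**e for e in range(-5, 6, 2))  # 2^-5 .. 2^5
DEFAULT_EPSILON_GRID = (0.01, 0.1, 0.5)


@dataclass(frozen=True)
class ProbeSet:
    """Fixed-length probes with positive fluorescence intensities."""

    sequences: tuple[str, ...]
    intensities: np.ndarray
    name: str = "probes"

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.intensities):
            raise ValueError("sequences and intensities differ in length")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"heterogeneous probe lengths {sorted(lengths)}")
        if np.any(np.asarray(self.intensities) <= 0):
            raise ValueError("intensities must be positive (ln must be defined)")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def probe_length(self) -> int:
        return len(self.sequences[0])


@dataclass
class FeatureMatrix:
    X: np.ndarray  # (n, 4K) or (n, 4K + K-2)
    y: np.ndarray  # ln(intensity)
    mode: str  # "1mer" or "1mer+dgs"
    n_1mer: int
    n_stack: int
    scaling: str = "none"  # record of column scaling applied to X

    @property
    def stack_slice(self) -> slice:
        return slice(self.n_1mer, self.n_1mer + self.n_stack)


def encode_1mer(seq: str) -> np.ndarray:
    """Binary vector of length 4K, one indicator per position and base."""
    s = check_acgt(seq, what="probe")
    out = np.zeros(4 * len(s))
    for i, b in enumerate(s):
        out[4 * i + BASE_SLOT_ORDER.index(b)] = 1.0
    return out


def encode_features(
    probes: ProbeSet, table: DinucleotideTable | None, mode: str = "1mer"
) -> FeatureMatrix:
    """Encode a probe set as a feature matrix with response ln(intensity)."""
    if mode not in ("1mer", "1mer+dgs"):
        raise ValueError(f"unknown feature mode {mode!r}")
    k = probes.probe_length
    onehot = np.array([encode_1mer(s) for s in probes.sequences])
    if mode == "1mer+dgs":
        if table is None:
            raise ValueError("1mer+dgs mode needs a dinucleotide table")
        stack = np.array(
            [stacking_profile(s, table).values for s in probes.sequences]
        )
        X = np.hstack([onehot, stack])
        n_stack = k - 2
    else:
        X = onehot
        n_stack = 0
    return FeatureMatrix(
        X=X,
        y=np.log(np.asarray(probes.intensities, dtype=float)),
        mode=mode,
        n_1mer=4 * k,
        n_stack=n_stack,
    )


def pearson(pred, obs) -> float:
    """Product-moment correlation; errors out on zero variance."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if pred.std() == 0.0 or obs.std() == 0.0:
        raise ValueError("Pearson correlation undefined for zero variance")
    return float(np.corrcoef(pred, obs)[0, 1])


def _safe_pcc(pred, obs) -> float:
    """PCC for model scoring: a constant prediction scores 0."""
    pred = np.asarray(pred, dtype=float)
    if pred.std() == 0.0:
        return 0.0
    return pearson(pred, obs)


class StackingSvr:
    """Linear epsilon-SVR over encoded features.

    Stacking (kcal/mol) columns are min-max scaled to [0, 1] with
    statistics from the data seen by :meth:`fit`, putting them on the same
    footing as the one-hot indicators without leaking test information.
    """

    def __init__(
        self,
        C: float = 1.0,
        epsilon: float = 0.1,
        stack_slice: slice = slice(0, 0),
        scale_stacking: bool = True,
        random_state: int = 0,
        max_iter: int = 1000,
        tol: float = 1e-3,
    ):
        if C <= 0 or epsilon < 0:
            raise ValueError("require C > 0 and epsilon >= 0")
        self.C = C
        self.epsilon = epsilon
        self.stack_slice = stack_slice
        self.scale_stacking = scale_stacking
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol
        self._svr: LinearSVR | None = None
        self._const: float | None = None
        self._y_center: float = 0.0
        self._lo: np.ndarray | None = None
        self._span: np.ndarray | None = None

    def _transform(self, X: np.ndarray) -> np.ndarray:
        if self._lo is None:
            return X
        X = X.copy()
        block = X[:, self.stack_slice]
        X[:, self.stack_slice] = (block - self._lo) / self._span
        return X

    def fit(self, X: np.ndarray, y: np.ndarray) -> "StackingSvr":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(X) < 2:
            raise ValueError("need at least 2 training rows")
        if self.scale_stacking and self.stack_slice.stop > self.stack_slice.start:
            block = X[:, self.stack_slice]
            self._lo = block.min(axis=0)
            span = block.max(axis=0) - self._lo
            span[span == 0.0] = 1.0
            self._span = span
        if y.std() == 0.0:
            warnings.warn("degenerate response (zero variance): constant predictor")
            self._const = float(y[0])
            return self
        # Centering the response keeps the (regularized) intercept small
        # and the dual coordinate-descent solver well behaved.
        self._y_center = float(y.mean())
        self._svr = LinearSVR(
            C=self.C,
            epsilon=self.epsilon,
            loss="epsilon_insensitive",
            max_iter=self.max_iter,
            tol=self.tol,
            random_state=self.random_state,
        )
        with warnings.catch_warnings():
            from sklearn.exceptions import ConvergenceWarning

            warnings.simplefilter("ignore", ConvergenceWarning)
            self._svr.fit(self._transform(X), y - self._y_center)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self._const is not None:
            return np.full(len(X), self._const)
        if self._svr is None:
            raise RuntimeError("predictor is not fitted")
        return self._svr.predict(self._transform(X)) + self._y_center


def train_svr(
    fm: FeatureMatrix,
    hyper: tuple[float, float] = (1.0, 0.1),
    scale_stacking: bool = True,
    random_state: int = 0,
) -> StackingSvr:
    """Fit a linear epsilon-SVR on a whole feature matrix."""
    C, epsilon = hyper
    model = StackingSvr(
        C=C,
        epsilon=epsilon,
        stack_slice=fm.stack_slice,
        scale_stacking=scale_stacking,
        random_state=random_state,
    )
    return model.fit(fm.X, fm.y)


@dataclass
class CvResult:
    per_fold_pcc: list[float]
    chosen_hyperparameters: list[dict]
    n_features: int
    fold_seed: int
    mode: str
    fold_test_indices: list[np.ndarray] = field(repr=False, default_factory=list)

    @property
    def mean_pcc(self) -> float:
        return float(np.mean(self.per_fold_pcc))

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "per_fold_pcc": self.per_fold_pcc,
            "mean_pcc": self.mean_pcc,
            "chosen_hyperparameters": self.chosen_hyperparameters,
            "n_features": self.n_features,
            "fold_seed": self.fold_seed,
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        return path


def nested_cv(
    probes: ProbeSet,
    table: DinucleotideTable | None,
    mode: str = "1mer+dgs",
    folds: int = 10,
    grid: tuple | None = None,
    seed: int = 0,
    inner_folds: int = 5,
    scale_stacking: bool = True,
) -> CvResult:
    """Nested cross-validation of the affinity model.

    ``grid`` is (C values, epsilon values); defaults to the libsvm-style
    C in 2^-5..2^5 (step 2^2) by epsilon in {0.01, 0.1, 0.5}. Fold
    assignment is a seeded shuffle, so a run is a pure function of
    (probes, mode, folds, grid, seed).
    """
    if folds > len(probes):
        raise ValueError(f"folds={folds} exceeds {len(probes)} probes")
    c_grid, eps_grid = grid if grid is not None else (
        DEFAULT_C_GRID,
        DEFAULT_EPSILON_GRID,
    )
    if not c_grid or not eps_grid:
        raise ValueError("empty hyperparameter grid")
    fm = encode_features(probes, table, mode)
    outer = KFold(n_splits=folds, shuffle=True, random_state=seed)
    per_fold: list[float] = []
    chosen: list[dict] = []
    test_idx_per_fold: list[np.ndarray] = []
    for fold_i, (train_idx, test_idx) in enumerate(outer.split(fm.X)):
        inner = KFold(
            n_splits=inner_folds, shuffle=True, random_state=seed + 1 + fold_i
        )
        best = None
        for C in c_grid:
            for eps in eps_grid:
                scores = []
                for in_tr, in_val in inner.split(train_idx):
                    tr = train_idx[in_tr]
                    val = train_idx[in_val]
                    m = StackingSvr(
                        C, eps, fm.stack_slice, scale_stacking, random_state=seed
                    ).fit(fm.X[tr], fm.y[tr])
                    scores.append(_safe_pcc(m.predict(fm.X[val]), fm.y[val]))
                mean_score = float(np.mean(scores))
                # strict > keeps the first grid point on ties (deterministic)
                if best is None or mean_score > best[0]:
                    best = (mean_score, C, eps)
        _, C, eps = best
        final = StackingSvr(
            C, eps, fm.stack_slice, scale_stacking, random_state=seed
        ).fit(fm.X[train_idx], fm.y[train_idx])
        per_fold.append(_safe_pcc(final.predict(fm.X[test_idx]), fm.y[test_idx]))
        chosen.append({"C": C, "epsilon": eps, "inner_mean_pcc": best[0]})
        test_idx_per_fold.append(test_idx)
    return CvResult(
        per_fold_pcc=per_fold,
        chosen_hyperparameters=chosen,
        n_features=fm.X.shape[1],
        fold_seed=seed,
        mode=mode,
        fold_test_indices=test_idx_per_fold,
    )


def read_gcpbm(path: str | Path, name: str | None = None) -> ProbeSet:
    """Read a gcPBM-style TSV: columns sequence, signal (header optional).

    Non-positive or non-numeric signal rows are dropped with a logged
    count; heterogeneous sequence lengths are an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 tab-separated columns")
    first = str(df.iloc[0, 1])
    try:
        float(first)
    except ValueError:  # header row
        df = df.iloc[1:]
    seqs = df.iloc[:, 0].astype(str).str.upper().tolist()
    signals = pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy()
    keep = np.isfinite(signals) & (signals > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        import logging

        logging.getLogger(__name__).info(
            "%s: dropped %d rows with unusable signal", path, n_dropped
        )
    return ProbeSet(
        sequences=tuple(s for s, k in zip(seqs, keep) if k),
        intensities=signals[keep],
        name=name or path.stem,
    )


def write_gcpbm(probes: ProbeSet, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as out:
        out.write("sequence\tsignal\n")
        for s, v in zip(probes.sequences, probes.intensities):
            out.write(f"{s}\t{float(v)!r}\n")
    return path
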