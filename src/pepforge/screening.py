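"""Sequence-encoded affinity screening.

Conjoint Triad featurization (7 physicochemical classes, 343 triad bins),
peptide/target pair encoding, seeded 80:20 splitting, a uniform harness over
four regressor kinds, shared regression metrics, and top-K ranking of mutant
libraries by predicted affinity (lower = stronger binding).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .design import MutantLibrary, validate_sequence
from .errors import DataError, SequenceError

#: the 7 standard Conjoint-Triad amino-acid classes
TRIAD_CLASSES = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")

_CLASS_OF = {aa: idx for idx, group in enumerate(TRIAD_CLASSES) for aa in group}

N_BINS = 7 ** 3  # 343


@dataclass(frozen=True)
class AffinityRecord:
    peptide_seq: str
    target_seq: str
    affinity: float  # free-energy-like; lower = stronger

    def __post_init__(self):
        validate_sequence(self.peptide_seq)
        validate_sequence(self.target_seq)
        if not np.isfinite(self.affinity):
            raise ValueError("affinity must be finite")


@dataclass
class ModelConfig:
    kind: str = "ridge"  # random_forest | ridge | gradient_boosting | xgboost
    n_estimators: int = 100
    alpha: float = 1.0
    random_state: int = 42

    KINDS = ("random_forest", "ridge", "gradient_boosting", "xgboost")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown model kind '{self.kind}'")


@dataclass
class SplitMetrics:
    r2: float
    mse: float
    mae: float
    pearson: float


@dataclass
class MetricsReport:
    train: Optional[SplitMetrics] = None
    test: Optional[SplitMetrics] = None


@dataclass
class RankedList:
    k: int
    rows: list[tuple[str, str, float]] = field(default_factory=list)
    # rows: (variant name, sequence, predicted affinity), ascending

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows,
                            columns=["Peptide", "Sequence", "Predicted Value"])


def conjoint_triad(seq: str, normalization: str = "frequency") -> np.ndarray:
    """343-bin triad vector: every overlapping length-3 window increments
    bin c1*49 + c2*7 + c3 where c_i is the residue's class index.

    ``normalization`` is ``"count"`` (raw window counts, sums to L-2) or
    ``"frequency"`` (counts / (L-2), sums to 1).
    """
    validate_sequence(seq)
    if len(seq) < 3:
        raise SequenceError(f"sequence too short to encode (need >= 3): '{seq}'")
    if normalization not in ("count", "frequency"):
        raise ValueError(f"unknown normalization '{normalization}'")
    classes = np.array([_CLASS_OF[aa] for aa in seq], dtype=int)
    bins = np.zeros(N_BINS)
    idx = classes[:-2] * 49 + classes[1:-1] * 7 + classes[2:]
    np.add.at(bins, idx, 1.0)
    if normalization == "frequency":
        bins /= len(seq) - 2
    return bins


def encode_pair(peptide: str, target: str,
                normalization: str = "frequency") -> np.ndarray:
    """686-value concatenation [triad(peptide) || triad(target)]."""
    return np.concatenate([conjoint_triad(peptide, normalization),
                           conjoint_triad(target, normalization)])


def split_dataset(records: Sequence[AffinityRecord], train_fraction: float = 0.8,
                  seed: int = 0):
    """Seeded shuffle split; |train| = round(train_fraction * n)."""
    records = list(records)
    if len(records) < 5:
        raise DataError(f"need at least 5 records to split, got {len(records)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n_train = int(round(train_fraction * len(records)))
    train = [records[i] for i in order[:n_train]]
    test = [records[i] for i in order[n_train:]]
    return train, test


def features_and_targets(records: Sequence[AffinityRecord],
                         normalization: str = "frequency"):
    X = np.array([encode_pair(r.peptide_seq, r.target_seq, normalization)
                  for r in records])
    y = np.array([r.affinity for r in records])
    return X, y


def _build_estimator(cfg: ModelConfig):
    if cfg.kind == "ridge":
        from sklearn.linear_model import Ridge
        return Ridge(alpha=cfg.alpha)
    if cfg.kind == "random_forest":
        from sklearn.ensemble import RandomForestRegressor
        return RandomForestRegressor(n_estimators=cfg.n_estimators,
                                     random_state=cfg.random_state)
    if cfg.kind == "gradient_boosting":
        from sklearn.ensemble import GradientBoostingRegressor
        return GradientBoostingRegressor(n_estimators=cfg.n_estimators,
                                         random_state=cfg.random_state)
    # xgboost: optional dependency; fall back to a sklearn boosted ensemble
    try:
        from xgboost import XGBRegressor
        return XGBRegressor(n_estimators=cfg.n_estimators,
                            random_state=cfg.random_state)
    except ImportError:
        warnings.warn(
            "xgboost is not installed; using sklearn GradientBoostingRegressor "
            "as the boosted-tree backend for kind='xgboost'"
        )
        from sklearn.ensemble import GradientBoostingRegressor
        return GradientBoostingRegressor(n_estimators=cfg.n_estimators,
                                         random_state=cfg.random_state)


def train_model(cfg: ModelConfig, X: np.ndarray, y: np.ndarray):
    """Fit the configured regressor; returns the fitted estimator."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per target value")
    if len(y) < 2:
        raise DataError("need at least 2 training records")
    if np.ptp(y) == 0:
        warnings.warn("constant training targets; model will predict a constant")
    model = _build_estimator(cfg)
    model.fit(X, y)
    return model


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> SplitMetrics:
    """Shared metric routine: R^2, MSE, MAE, Pearson correlation."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size == 0:
        raise DataError("empty evaluation set")
    resid = y_true - y_pred
    mse = float(np.mean(resid**2))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        warnings.warn("zero-variance targets: R^2 undefined (NaN)")
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        pearson = float("nan")
    else:
        pearson = float(np.corrcoef(y_true, y_pred)[0, 1])
    return SplitMetrics(r2=r2, mse=mse, mae=mae, pearson=pearson)


def evaluate(model, X_test, y_test, X_train=None, y_train=None) -> MetricsReport:
    """Metrics on the test split (and the train split when provided)."""
    report = MetricsReport()
    report.test = compute_metrics(y_test, model.predict(np.asarray(X_test)))
    if X_train is not None and y_train is not None:
        report.train = compute_metrics(y_train, model.predict(np.asarray(X_train)))
    return report


def rank_variants(model, library: MutantLibrary, target: str, k: int,
                  normalization: str = "frequency") -> RankedList:
    """Predict affinity for every library variant paired with ``target`` and
    return the ``k`` best (most negative first; ties keep library order)."""
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if not library.variants:
        raise DataError("empty mutant library")
    X = np.array([encode_pair(v.sequence, target, normalization)
                  for v in library.variants])
    preds = model.predict(X)
    order = np.argsort(preds, kind="stable")
    rows = [(library.variants[i].name, library.variants[i].sequence,
             float(preds[i])) for i in order[:k]]
    return RankedList(k=k, rows=rows)


def read_affinity_csv(path) -> list[AffinityRecord]:
    """Load an affinity table (columns peptide_seq, target_seq, affinity)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"peptide_seq", "target_seq", "affinity"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"affinity table missing column(s): {sorted(missing)}")
    return [AffinityRecord(str(r.peptide_seq), str(r.target_seq), float(r.affinity))
            for r in df.itertuples(index=False)]
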