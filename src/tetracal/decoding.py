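"""Cross-validated position decoding from windowed population activity.

Each decoded sample uses the activity of the previous N (default 5) 100-ms
bins of every neuron.  Data are split into contiguous temporal folds
(default 10); each fold is held out once and predicted by a decoder trained
on the rest.  The chance level repeats the whole procedure on targets that
were flipped in time and circularly shifted by at least 2000 bins.  The
reference decoder is deterministic ridge regression on flattened windows; a
feedforward MLP and an LSTM (requires torch) are available as alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .preprocess import AlignedDataset

__all__ = [
    "DecodingResult", "build_windows", "contiguous_folds", "crossval_decode",
    "chance_level", "compare_region_subsets",
]


@dataclass
class DecodingResult:
    fold_errors: list                       # per fold: per-bin Euclidean error (cm)
    fold_medians: np.ndarray                # median error per fold
    predictions: list                       # per fold: predicted xy
    true_positions: list                    # per fold: true xy
    decoder: str
    subset: str = "all"
    is_chance: bool = False

    @property
    def mean_of_medians(self) -> float:
        return float(np.mean(self.fold_medians))

    @property
    def sem_of_medians(self) -> float:
        return float(np.std(self.fold_medians, ddof=1) / np.sqrt(len(self.fold_medians)))


def build_windows(binned_activity: np.ndarray, positions: np.ndarray,
                  n_window: int = 5,
                  valid_mask: np.ndarray | None = None
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sliding-window design matrix and targets.

    Sample t uses activity bins [t-N+1 .. t] (flattened window x neurons);
    the first N-1 bins are dropped.  Samples whose window or target touches
    an invalid bin are removed.  Returns (X, y, sample_bins).
    """
    A = np.atleast_2d(np.asarray(binned_activity, float))
    positions = np.asarray(positions, float)
    n_neurons, n_bins = A.shape
    if n_window < 1:
        raise ValueError("window must be >= 1 bin")
    if n_bins < n_window:
        raise ValueError("fewer bins than the window length")
    idx = np.arange(n_window - 1, n_bins)
    # windows[t] = A[:, t-N+1 .. t] -> flatten time-major
    win = np.stack([A[:, t - n_window + 1: t + 1].T.ravel() for t in idx])
    y = positions[idx]
    if valid_mask is not None:
        vm = np.asarray(valid_mask, bool)
        ok = np.array([vm[t - n_window + 1: t + 1].all() for t in idx])
    else:
        ok = np.isfinite(y).all(axis=1)
    return win[ok], y[ok], idx[ok]


def contiguous_folds(n_samples: int, n_folds: int = 10) -> list[np.ndarray]:
    """Equal contiguous temporal blocks (no shuffled-bin leakage)."""
    return np.array_split(np.arange(n_samples), n_folds)


# ---------------------------------------------------------------------------
# Decoders
# ---------------------------------------------------------------------------

class _RidgeFold:
    """Per-fold ridge factorization, reusable across target shuffles."""

    def __init__(self, X_train: np.ndarray, alpha: float):
        self.X = X_train
        self.xm = X_train.mean(axis=0)
        Xc = X_train - self.xm
        G = Xc.T @ Xc
        G[np.diag_indices_from(G)] += alpha
        self.cho = cho_factor(G)

    def solve(self, y_train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ym = y_train.mean(axis=0)
        b = (self.X - self.xm).T @ (y_train - ym)
        return cho_solve(self.cho, b), ym

    def predict(self, X_test: np.ndarray, W: np.ndarray, ym: np.ndarray) -> np.ndarray:
        return (X_test - self.xm) @ W + ym


def _fit_predict(decoder: str, X_tr, y_tr, X_te, rng, alpha: float,
                 fold_solver: _RidgeFold | None = None) -> np.ndarray:
    if decoder == "ridge":
        solver = fold_solver or _RidgeFold(X_tr, alpha)
        W, ym = solver.solve(y_tr)
        return solver.predict(X_te, W, ym)
    if decoder == "mlp":
        from sklearn.neural_network import MLPRegressor
        mdl = MLPRegressor(hidden_layer_sizes=(64,), max_iter=300,
                           random_state=int(rng.integers(2**31 - 1)))
        mdl.fit(X_tr, y_tr)
        return mdl.predict(X_te)
    if decoder == "lstm":
        return _lstm_fit_predict(X_tr, y_tr, X_te, rng)
    raise ValueError(f"unknown decoder {decoder!r}")


def _lstm_fit_predict(X_tr, y_tr, X_te, rng, units: int = 200,
                      dropout: float = 0.25, epochs: int = 10):
    """Recurrent decoder (units=200, dropout=0.25, 10 epochs); optional,
    needs torch."""
    try:
        import torch
        from torch import nn
    except ImportError as e:  # pragma: no cover - torch not in the base stack
        raise ImportError("decoder 'lstm' requires torch; use 'ridge' or 'mlp'") from e
    torch.manual_seed(int(rng.integers(2**31 - 1)))

    def reshape(X):  # flattened windows back to (samples, time, neurons)
        n_feat = X.shape[1]
        return torch.tensor(X, dtype=torch.float32).reshape(len(X), -1, n_feat // _LSTM_STEPS[0])

    net = nn.Sequential()
    lstm = nn.LSTM(input_size=X_tr.shape[1] // _LSTM_STEPS[0], hidden_size=units,
                   batch_first=True, dropout=0.0)
    head = nn.Sequential(nn.Dropout(dropout), nn.Linear(units, 2))
    opt = torch.optim.Adam(list(lstm.parameters()) + list(head.parameters()), lr=1e-3)
    Xt, yt = reshape(X_tr), torch.tensor(y_tr, dtype=torch.float32)
    for _ in range(epochs):
        opt.zero_grad()
        out, _ = lstm(Xt)
        loss = nn.functional.mse_loss(head(out[:, -1]), yt)
        loss.backward()
        opt.step()
    with torch.no_grad():
        out, _ = lstm(reshape(X_te))
        return head(out[:, -1]).numpy()


_LSTM_STEPS = [5]  # window length used to unflatten LSTM inputs


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def crossval_decode(X: np.ndarray, y: np.ndarray,
                    decoder: str = "ridge", n_folds: int = 10,
                    rng: np.random.Generator | None = None,
                    alpha: float = 1.0, n_window: int = 5,
                    subset: str = "all",
                    _solvers: list | None = None,
                    is_chance: bool = False) -> DecodingResult:
    """Hold out each contiguous fold once; report per-bin Euclidean errors."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if len(X) < n_folds * (n_window + 1):
        raise ValueError("too few samples for the requested fold count")
    rng = rng or np.random.default_rng(0)
    _LSTM_STEPS[0] = n_window
    folds = contiguous_folds(len(X), n_folds)
    errors, medians, preds, trues = [], [], [], []
    for fi, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(X)), test_idx)
        solver = _solvers[fi] if _solvers is not None else None
        pred = _fit_predict(decoder, X[train_idx], y[train_idx], X[test_idx],
                            rng, alpha, solver)
        err = np.linalg.norm(pred - y[test_idx], axis=1)
        errors.append(err)
        medians.append(np.median(err))
        preds.append(pred)
        trues.append(y[test_idx])
    return DecodingResult(errors, np.asarray(medians), preds, trues,
                          decoder, subset, is_chance)


def _ridge_solvers(X: np.ndarray, n_folds: int, alpha: float) -> list[_RidgeFold]:
    folds = contiguous_folds(len(X), n_folds)
    out = []
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(len(X)), test_idx)
        out.append(_RidgeFold(X[train_idx], alpha))
    return out


def chance_level(X: np.ndarray, y: np.ndarray, rng: np.random.Generator,
                 decoder: str = "ridge", n_folds: int = 10,
                 min_shift: int = 2000, n_reps: int = 5,
                 alpha: float = 1.0, n_window: int = 5,
                 subset: str = "all") -> DecodingResult:
    """Chance-level decoding: flip targets in time, cycle-shift by a random
    offset of at least `min_shift` bins, and re-run the full CV; repeated
    `n_reps` times and pooled."""
    if min_shift < 2000:
        raise ValueError("minimum cycle shift is 2000 frames")
    n = len(y)
    if n <= 2 * min_shift:
        raise ValueError("session too short for the required cycle shift")
    solvers = _ridge_solvers(X, n_folds, alpha) if decoder == "ridge" else None
    errors, medians, preds, trues = [], [], [], []
    for _ in range(n_reps):
        shift = int(rng.integers(min_shift, n - min_shift))
        y_sh = np.roll(y[::-1], shift, axis=0)
        res = crossval_decode(X, y_sh, decoder, n_folds, rng, alpha, n_window,
                              subset, _solvers=solvers, is_chance=True)
        errors += res.fold_errors
        medians += list(res.fold_medians)
        preds += res.predictions
        trues += res.true_positions
    return DecodingResult(errors, np.asarray(medians), preds, trues,
                          decoder, subset, is_chance=True)


def compare_region_subsets(dataset: AlignedDataset, rng: np.random.Generator,
                           subsets: dict | None = None,
                           decoder: str = "ridge", n_folds: int = 10,
                           n_window: int = 5, alpha: float = 1.0,
                           min_shift: int = 2000, n_chance_reps: int = 5,
                           with_chance: bool = True
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Decode from each region subset (default: every single region plus the
    pooled set) and compare.

    Returns (fold_table, summary): fold_table has one row per subset x fold
    (plus pooled chance rows); summary carries per-subset median-of-medians,
    a Mann-Whitney test of fold medians against that subset's chance level,
    and a Wilcoxon signed-rank test pairing each single-region subset's fold
    medians with the pooled subset's.
    """
    regions = list(pd.unique(dataset.region_labels))
    if subsets is None:
        subsets = {r: [r] for r in regions}
        subsets["all"] = regions
    results: dict[str, DecodingResult] = {}
    chances: dict[str, DecodingResult] = {}
    rows = []
    for name, regs in subsets.items():
        idx = np.nonzero(np.isin(dataset.region_labels, regs))[0]
        if idx.size == 0:
            raise ValueError(f"subset {name!r} selects no neurons")
        sub = dataset.subset_neurons(idx)
        X, y, _ = build_windows(sub.binned_activity, sub.bin_positions,
                                n_window, sub.valid_mask)
        res = crossval_decode(X, y, decoder, n_folds, rng, alpha, n_window,
                              subset=name)
        results[name] = res
        for fi, m in enumerate(res.fold_medians):
            rows.append({"subset": name, "fold": fi, "median_error_cm": m,
                         "chance": False})
        if with_chance:
            ch = chance_level(X, y, rng, decoder, n_folds, min_shift,
                              n_chance_reps, alpha, n_window, subset=name)
            chances[name] = ch
            for fi, m in enumerate(ch.fold_medians):
                rows.append({"subset": name, "fold": fi, "median_error_cm": m,
                             "chance": True})
    summary = []
    pooled = results.get("all")
    for name, res in results.items():
        row = {"subset": name,
               "median_error_cm": res.mean_of_medians,
               "sem_cm": res.sem_of_medians}
        if with_chance:
            u = stats.mannwhitneyu(res.fold_medians, chances[name].fold_medians,
                                   alternative="less")
            row["chance_median_cm"] = chances[name].mean_of_medians
            row["p_vs_chance"] = float(u.pvalue)
        if pooled is not None and name != "all":
            w = stats.wilcoxon(results[name].fold_medians, pooled.fold_medians)
            row["p_vs_pooled"] = float(w.pvalue)
        summary.append(row)
    return pd.DataFrame(rows), pd.DataFrame(summary)
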