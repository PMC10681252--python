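"""Totonou / non-totonou brain-state decoding from in-ear EEG.

The decoding pipeline, per participant, in fixed order::

    segment -> fft_power -> noise_screen -> standardize -> balance
            -> split -> pca -> lambda_cv -> fit -> test

* **Features** — the rest recording is band-passed 2-45 Hz and cut into
  4-s segments; for each of three signals (left ear, right ear, and the
  time-domain difference L-R) the spectral power on a 0.5 Hz grid from
  4.0 to 40.0 Hz (73 steps) is computed by summing periodogram bins, for
  3 x 73 = 219 features per segment.  Pre-sauna segments are labelled
  ``non_totonou``; all post-set segments ``totonou``.
* **Noise screen** — per participant, a segment's noise score is its
  total broadband power over the feature grid; segments scoring more
  than 2 SD above that participant's mean are excluded.
* **Standardisation** — per-column z-scoring within participant.  By
  default the scaler is fit on training rows only and applied to test
  rows (no leakage); a ``"global"`` mode fitting on all rows is kept for
  comparison.
* **Classifier** — PCA to at most 150 components (fit on training rows
  only), then an L1-penalised linear discriminant: for two balanced
  classes coded y = ±1 the LDA direction coincides with the
  least-squares regression direction, so the sparse discriminant is fit
  as a lasso on PCA scores.  The penalty λ is chosen by 10-fold
  cross-validation on the training data (lowest misclassification; ties
  resolved toward the larger, sparser λ) and the final weights are refit
  on all training rows.
* **Evaluation** — stratified 90/10 train/test splits; because a single
  split is high-variance, accuracy is averaged over 20 seeded splits by
  default (a single-split mode is available via ``n_splits=1``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.decomposition import PCA
from sklearn.linear_model import lasso_path
from sklearn.model_selection import StratifiedKFold, train_test_split

from .errors import DataFormatError, InsufficientDataError, ParameterError
from .preprocess import bandpass, segment
from .spectral import power_spectrum
from . import stats as group_stats

#: Feature frequency grid: 0.5 Hz steps over [4, 40] Hz inclusive.
FEATURE_FREQS = np.round(np.arange(4.0, 40.0 + 1e-9, 0.5), 1)
SIGNALS = ("L", "R", "L-R")

#: Decoder-path band pass (Hz).  Wider than the 2-30 Hz band-power path
#: so the 30-40 Hz features carry signal.
DECODER_FILTER_HZ = (2.0, 45.0)

DECODER_SEGMENT_S = 4.0

#: Fixed pipeline order, recorded on every fitted model.
PIPELINE_STEPS = ("segment", "fft_power", "noise_screen", "standardize",
                  "balance", "split", "pca", "lambda_cv", "fit", "test")

CLASS_NAMES = {0: "non_totonou", 1: "totonou"}


@dataclass
class FeatureMatrix:
    """Per-segment spectral features with class and participant labels.

    ``X`` has shape ``(n_segments, 219)``; ``y`` is 1 for totonou and 0
    for non-totonou rows.
    """

    X: np.ndarray
    y: np.ndarray
    participant_id: np.ndarray
    stage: np.ndarray
    feature_names: list

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    def participants(self):
        return list(pd.unique(self.participant_id))

    def for_participant(self, pid) -> "FeatureMatrix":
        m = self.participant_id == pid
        return FeatureMatrix(self.X[m], self.y[m], self.participant_id[m],
                             self.stage[m], self.feature_names)

    def subset(self, idx) -> "FeatureMatrix":
        return FeatureMatrix(self.X[idx], self.y[idx],
                             self.participant_id[idx], self.stage[idx],
                             self.feature_names)


def build_features(sessions, segment_s: float = DECODER_SEGMENT_S,
                   filter_hz=DECODER_FILTER_HZ) -> FeatureMatrix:
    """Spectral feature matrix from labelled in-ear rest sessions.

    ``sessions`` yields ``(SessionLabel, ContinuousRecording)``.  The
    difference signal is formed in the time domain before the Fourier
    transform; 0.5 Hz features are sums of the constituent periodogram
    bins (bin centred at f covers [f, f + 0.5) Hz).
    """
    X_rows, y_rows, pid_rows, stage_rows = [], [], [], []
    for label, rec in sessions:
        rec.require_channels(("L", "R"))
        filtered = bandpass(rec, *filter_hz)
        left = filtered.channel("L")
        right = filtered.channel("R")
        stack = np.vstack([left, right, left - right])
        from .core import ContinuousRecording
        rec3 = ContinuousRecording(stack, filtered.rate_hz, SIGNALS)
        segs = segment(rec3, segment_s)
        spec = power_spectrum(segs)
        # map periodogram bins onto the 0.5 Hz grid
        bin_idx = [np.flatnonzero((spec.freqs_hz >= f) &
                                  (spec.freqs_hz < f + 0.5))
                   for f in FEATURE_FREQS]
        feats = np.concatenate(
            [np.stack([spec.power[:, c, idx].sum(axis=1)
                       for idx in bin_idx], axis=1)
             for c in range(3)], axis=1)  # (n_seg, 3*73)
        X_rows.append(feats)
        y_rows.append(np.full(feats.shape[0],
                              1 if label.decoder_class == "totonou" else 0))
        pid_rows.append(np.full(feats.shape[0], label.participant_id,
                                dtype=object))
        stage_rows.append(np.full(feats.shape[0], label.stage, dtype=object))
    if not X_rows:
        raise InsufficientDataError("no sessions supplied")
    names = [f"{sig}_{f:.1f}" for sig in SIGNALS for f in FEATURE_FREQS]
    return FeatureMatrix(
        X=np.concatenate(X_rows), y=np.concatenate(y_rows),
        participant_id=np.concatenate(pid_rows),
        stage=np.concatenate(stage_rows), feature_names=names)


def noise_screen(features: FeatureMatrix, k_sd: float = 2.0):
    """Exclude unusually high-power segments per participant.

    A segment's noise score is its total power across the feature grid;
    segments with score above ``mean + k_sd * SD`` of their participant's
    scores are excluded.  Zero-variance score sets keep everything.

    Returns ``(kept FeatureMatrix, exclusion log DataFrame)``.
    """
    keep = np.ones(features.n_rows, dtype=bool)
    log_rows = []
    scores = features.X.sum(axis=1)
    for pid in features.participants():
        m = features.participant_id == pid
        if int(m.sum()) < 3:
            raise InsufficientDataError(
                f"participant {pid} has fewer than 3 segments to screen"
            )
        s = scores[m]
        sd = s.std(ddof=1)
        if sd == 0:
            continue
        thr = s.mean() + k_sd * sd
        bad = m & (scores > thr)
        keep[bad] = False
        for i in np.flatnonzero(bad):
            log_rows.append({"participant": pid, "row": int(i),
                             "score": float(scores[i]),
                             "threshold": float(thr)})
    log = pd.DataFrame(log_rows, columns=["participant", "row", "score",
                                          "threshold"])
    return features.subset(keep), log


def _balance_indices(y, rng) -> np.ndarray:
    """Indices subsampling the majority class to the minority count."""
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ParameterError("both classes must be present to balance")
    minority = classes[np.argmin(counts)]
    n_min = counts.min()
    keep = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        if c != minority and len(idx) > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(idx)
    return np.sort(np.concatenate(keep))


def balance_classes(features: FeatureMatrix, seed: int = 0) -> FeatureMatrix:
    """Subsample the majority class within each participant.

    The totonou class (three post sets vs one pre set) is randomly
    subsampled without replacement to the non-totonou count; rows of the
    output are a subset of the input (no duplication).
    """
    rng = np.random.default_rng(seed)
    keep = []
    for pid in features.participants():
        idx = np.flatnonzero(features.participant_id == pid)
        keep.append(idx[_balance_indices(features.y[idx], rng)])
    return features.subset(np.sort(np.concatenate(keep)))


@dataclass
class DecoderModel:
    """A fitted per-participant decoder.

    Holds the standardisation parameters, PCA basis, selected λ and the
    sparse discriminant weights; :meth:`predict` replays the pipeline on
    new feature rows.
    """

    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    pca_mean: np.ndarray
    pca_components: np.ndarray  # (n_components, n_features)
    lambda_: float
    coef: np.ndarray            # (n_components,)
    intercept: float
    lambda_grid: np.ndarray
    cv_error: np.ndarray
    train_fraction: float = 0.9
    pipeline: tuple = PIPELINE_STEPS

    @property
    def n_nonzero_weights(self) -> int:
        return int(np.sum(self.coef != 0))

    def decision_function(self, X, standardized: bool = False) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if not standardized:
            X = (X - self.scaler_mean) / self.scaler_scale
        Z = (X - self.pca_mean) @ self.pca_components.T
        return Z @ self.coef + self.intercept

    def predict(self, X, standardized: bool = False) -> np.ndarray:
        """Predict class labels (1 = totonou) for raw feature rows."""
        return (self.decision_function(X, standardized) >= 0).astype(int)


def fit_decoder(X, y, n_components: int = 150, folds: int = 10,
                lambda_grid=None, seed: int = 0) -> DecoderModel:
    """Fit the PCA + sparse-discriminant classifier on (standardised)
    training rows.

    λ is chosen to minimise mean 10-fold cross-validated
    misclassification on the training data; ties resolve toward the
    larger (sparser) λ.  The final weights are refit on all training
    rows at the chosen λ.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ParameterError("training set must contain exactly two classes")
    counts = {c: int(np.sum(y == c)) for c in classes}
    if min(counts.values()) < folds:
        raise InsufficientDataError(
            f"need at least {folds} training rows per class for "
            f"{folds}-fold cross-validation; have {counts}"
        )
    ypm = np.where(y == classes.max(), 1.0, -1.0)

    n, d = X.shape
    ncomp = int(min(n_components, d, n - 1))
    pca = PCA(n_components=ncomp, svd_solver="full")
    Z = pca.fit_transform(X)

    if lambda_grid is None:
        lam_max = float(np.max(np.abs(Z.T @ (ypm - ypm.mean()))) / n)
        if lam_max <= 0:
            lam_max = 1.0
        lambda_grid = np.geomspace(lam_max, lam_max * 1e-3, 50)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    errs = np.zeros((folds, len(lambda_grid)))
    for k, (tr, te) in enumerate(skf.split(Z, y)):
        mu = Z[tr].mean(axis=0)
        yb = ypm[tr].mean()
        alphas, coefs, _ = lasso_path(Z[tr] - mu, ypm[tr] - yb,
                                      alphas=lambda_grid, max_iter=5000)
        pred = (Z[te] - mu) @ coefs + yb          # (n_te, n_alphas)
        hard = np.where(pred >= 0, 1.0, -1.0)
        errs[k] = (hard != ypm[te, None]).mean(axis=0)
    mean_err = errs.mean(axis=0)
    best = int(np.argmin(mean_err))  # grid is descending: first = sparsest
    lam = float(lambda_grid[best])

    mu = Z.mean(axis=0)
    yb = ypm.mean()
    _, coefs, _ = lasso_path(Z - mu, ypm - yb, alphas=[lam], max_iter=5000)
    coef = coefs[:, 0]
    intercept = float(yb - mu @ coef)

    return DecoderModel(
        scaler_mean=np.zeros(d), scaler_scale=np.ones(d),
        pca_mean=pca.mean_, pca_components=pca.components_,
        lambda_=lam, coef=coef, intercept=intercept,
        lambda_grid=lambda_grid, cv_error=mean_err,
    )


def decode_split(X, y, train_idx, test_idx, standardize_mode: str = "train",
                 n_components: int = 150, folds: int = 10, lambda_grid=None,
                 seed: int = 0):
    """Standardise, fit and test the decoder on an explicit split.

    With ``standardize_mode="train"`` (default) the per-column mean/SD
    are computed from training rows only; ``"global"`` uses all rows
    (the leakage-prone variant, kept for comparison).  Returns
    ``(DecoderModel, test accuracy)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    test_idx = np.asarray(test_idx)
    for c in np.unique(y):
        if np.sum(y[test_idx] == c) < 1:
            raise InsufficientDataError(
                f"test split has no rows of class {c}"
            )
    if standardize_mode == "train":
        ref = X[train_idx]
    elif standardize_mode == "global":
        ref = X
    else:
        raise ParameterError("standardize_mode must be 'train' or 'global'")
    mean = ref.mean(axis=0)
    scale = ref.std(axis=0)
    scale[scale == 0] = 1.0

    Xs = (X[train_idx] - mean) / scale
    model = fit_decoder(Xs, y[train_idx], n_components=n_components,
                        folds=folds, lambda_grid=lambda_grid, seed=seed)
    model.scaler_mean = mean
    model.scaler_scale = scale
    acc = float(np.mean(model.predict(X[test_idx]) == y[test_idx]))
    return model, acc


@dataclass
class ParticipantDecoding:
    """Held-out decoding performance for one participant."""

    participant_id: str
    accuracies: np.ndarray       # one per split, fraction correct
    n_segments: int
    n_balanced: int
    lambda_selected: float       # from the last split's model
    n_nonzero_weights: int

    @property
    def mean_accuracy_pct(self) -> float:
        return float(self.accuracies.mean() * 100)

    @property
    def sd_accuracy_pct(self) -> float:
        return float(self.accuracies.std(ddof=1) * 100) \
            if len(self.accuracies) > 1 else 0.0


def evaluate_participant(features: FeatureMatrix, participant_id=None,
                         train_fraction: float = 0.9, n_splits: int = 20,
                         seed: int = 0, standardize_mode: str = "train",
                         n_components: int = 150, folds: int = 10) -> ParticipantDecoding:
    """Held-out accuracy for one participant's decoder.

    Each split re-balances the classes, draws a stratified
    ``train_fraction`` / ``1 - train_fraction`` split, fits within the
    training rows only, and scores the held-out rows.
    """
    fm = features if participant_id is None \
        else features.for_participant(participant_id)
    pid = participant_id if participant_id is not None \
        else (fm.participants()[0] if fm.n_rows else "?")
    if fm.n_rows == 0:
        raise InsufficientDataError(f"no rows for participant {pid}")
    accs = []
    model = None
    n_bal = 0
    for s in range(n_splits):
        rs = (1000003 * (seed + 1) + s) % (2 ** 31 - 1)
        rng = np.random.default_rng(rs)
        bal = _balance_indices(fm.y, rng)
        Xb, yb = fm.X[bal], fm.y[bal]
        n_bal = len(bal)
        idx = np.arange(len(yb))
        tr, te = train_test_split(idx, test_size=1 - train_fraction,
                                  stratify=yb, random_state=rs % (2 ** 31))
        model, acc = decode_split(Xb, yb, tr, te,
                                  standardize_mode=standardize_mode,
                                  n_components=n_components, folds=folds,
                                  seed=rs % (2 ** 31))
        accs.append(acc)
    return ParticipantDecoding(
        participant_id=str(pid), accuracies=np.asarray(accs),
        n_segments=fm.n_rows, n_balanced=n_bal,
        lambda_selected=model.lambda_, n_nonzero_weights=model.n_nonzero_weights)


@dataclass
class CohortDecoding:
    """Per-participant accuracies plus the group-level summary."""

    per_participant: pd.DataFrame
    group_mean_pct: float
    group_sd_pct: float
    t_vs_chance: group_stats.TTestResult

    def summary(self) -> pd.DataFrame:
        out = self.per_participant.copy()
        out.loc[len(out)] = {
            "participant": "GROUP", "n_segments": out["n_segments"].sum(),
            "lambda": np.nan, "n_nonzero_weights": np.nan,
            "accuracy_mean_pct": self.group_mean_pct,
            "accuracy_sd_pct": self.group_sd_pct,
        }
        return out


def evaluate_cohort(features: FeatureMatrix, train_fraction: float = 0.9,
                    n_splits: int = 20, seed: int = 0,
                    standardize_mode: str = "train",
                    n_components: int = 150, folds: int = 10) -> CohortDecoding:
    """Per-participant decoders plus the group mean/SD and a one-sample
    t-test of the participant accuracies against chance (50 %)."""
    rows = []
    means = []
    for j, pid in enumerate(features.participants()):
        res = evaluate_participant(
            features, pid, train_fraction=train_fraction, n_splits=n_splits,
            seed=seed + 7919 * j, standardize_mode=standardize_mode,
            n_components=n_components, folds=folds)
        rows.append({
            "participant": pid, "n_segments": res.n_segments,
            "lambda": res.lambda_selected,
            "n_nonzero_weights": res.n_nonzero_weights,
            "accuracy_mean_pct": res.mean_accuracy_pct,
            "accuracy_sd_pct": res.sd_accuracy_pct,
        })
        means.append(res.mean_accuracy_pct)
    means = np.asarray(means)
    t = group_stats.one_sample_t(means, 50.0) if len(means) >= 2 else None
    return CohortDecoding(
        per_participant=pd.DataFrame(rows),
        group_mean_pct=float(means.mean()),
        group_sd_pct=float(means.std(ddof=1)) if len(means) > 1 else 0.0,
        t_vs_chance=t,
    )
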