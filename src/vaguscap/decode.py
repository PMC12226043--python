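"""Gaussian naive Bayes decoding of immune state from vagal firing rates.

Each second of a recording is assigned to one of three classes — baseline,
post-first-injection, post-second-injection — from the vector of per-unit
firing rates smoothed with a 30-point Gaussian-weighted moving average.
Training and decoding are performed within one mouse; the per-timepoint
class posteriors and the per-class probability of correct assignment (mean
posterior mass on the true class) are the primary outputs.
"""
from __future__ import annotations

import numpy as np

from .types import CLASS_ORDER, DecodeResult, DecoderModel, FeatureSeries, RateSeries

__all__ = [
    "gaussian_kernel",
    "build_features",
    "split_train_test",
    "train_nb",
    "decode",
    "decode_mouse",
]


def gaussian_kernel(n_points: int = 30, sigma: float | None = None) -> np.ndarray:
    """Unit-sum Gaussian weights for the moving-average filter.

    The default sigma of n/6 puts the kernel support at ±3 sigma.
    """
    if sigma is None:
        sigma = n_points / 6.0
    x = np.arange(n_points) - (n_points - 1) / 2.0
    w = np.exp(-0.5 * (x / sigma) ** 2)
    return w / w.sum()


def _smooth(series: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Convolve with a unit-sum kernel, renormalizing over the valid
    support at the edges (no artificial zero-padding bias)."""
    num = np.convolve(series, kernel, mode="same")
    den = np.convolve(np.ones_like(series), kernel, mode="same")
    return num / den


def build_features(series: list[RateSeries], window: int = 30) -> FeatureSeries:
    """Smoothed per-second rate features with true class labels.

    All units must share the same 1-s bin grid; labels come from the
    session plan's injection times.
    """
    if not series:
        raise ValueError("need at least one unit")
    edges0 = series[0].bin_edges
    for s in series[1:]:
        if len(s.bin_edges) != len(edges0) or not np.allclose(s.bin_edges, edges0):
            raise ValueError("all units must share the same time grid")
    kernel = gaussian_kernel(window)
    feats = np.column_stack([_smooth(s.rates, kernel) for s in series])
    centers = series[0].bin_centers
    return FeatureSeries(
        timepoints=centers,
        features=feats,
        labels=series[0].plan.period_of(centers),
        unit_ids=tuple(s.unit_id for s in series),
    )


def split_train_test(
    features: FeatureSeries, train_frac: float = 0.5, seed: int = 0,
) -> tuple[FeatureSeries, FeatureSeries]:
    """Pseudo-random class-stratified split into training and test subsets."""
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(int(seed))
    n = len(features.timepoints)
    train_mask = np.zeros(n, dtype=bool)
    for cls in np.unique(features.labels):
        idx = np.flatnonzero(features.labels == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 timepoints")
        n_train = int(round(train_frac * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)  # both subsets keep the class
        train_mask[rng.choice(idx, size=n_train, replace=False)] = True

    def subset(mask: np.ndarray) -> FeatureSeries:
        return FeatureSeries(
            timepoints=features.timepoints[mask],
            features=features.features[mask],
            labels=features.labels[mask],
            unit_ids=features.unit_ids,
        )

    return subset(train_mask), subset(~train_mask)


def train_nb(train: FeatureSeries, var_floor_frac: float = 1e-6) -> DecoderModel:
    """Fit per-class feature means/variances and empirical class priors.

    Variances are floored at ``var_floor_frac`` times the global feature
    variance (with an absolute fallback for all-constant features) to keep
    log-likelihoods finite.
    """
    present = set(np.unique(train.labels))
    if present != set(CLASS_ORDER):
        missing = set(CLASS_ORDER) - present
        raise ValueError(f"training data is missing class(es): {sorted(missing)}")
    X = train.features
    global_var = float(X.var(axis=0).max())
    floor = max(var_floor_frac * global_var, 1e-12)
    means, variances, priors = [], [], []
    for cls in CLASS_ORDER:
        sel = train.labels == cls
        Xc = X[sel]
        means.append(Xc.mean(axis=0))
        variances.append(np.maximum(Xc.var(axis=0), floor))
        priors.append(sel.mean())
    return DecoderModel(
        classes=CLASS_ORDER,
        means=np.stack(means),
        variances=np.stack(variances),
        priors=np.asarray(priors),
    )


def decode(model: DecoderModel, test: FeatureSeries) -> DecodeResult:
    """Posterior class probabilities for every test timepoint.

    Posteriors are computed in log space and normalized; the decoded class
    is the argmax (ties resolved toward the earlier class in the fixed
    order BL < C1 < C2).  The per-class probability of correct assignment
    is the mean posterior mass on the true class over that class's test
    timepoints; a hard per-class accuracy is reported alongside.
    """
    X = test.features
    if X.shape[1] != model.means.shape[1]:
        raise ValueError(
            f"feature dimensionality {X.shape[1]} does not match the model "
            f"({model.means.shape[1]})"
        )
    log_post = np.empty((X.shape[0], len(model.classes)))
    for k in range(len(model.classes)):
        mu, var = model.means[k], model.variances[k]
        ll = -0.5 * np.sum(
            np.log(2.0 * np.pi * var) + (X - mu) ** 2 / var, axis=1
        )
        log_post[:, k] = ll + np.log(model.priors[k])
    log_post -= log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post)
    post /= post.sum(axis=1, keepdims=True)
    decoded_idx = np.argmax(post, axis=1)  # argmax takes the earliest tie
    decoded = np.asarray(model.classes)[decoded_idx]

    cls_idx = {c: k for k, c in enumerate(model.classes)}
    correct_prob: dict[str, float] = {}
    accuracy: dict[str, float] = {}
    confusion = np.zeros((len(model.classes), len(model.classes)), dtype=int)
    for cls in model.classes:
        sel = test.labels == cls
        if sel.any():
            correct_prob[cls] = float(post[sel, cls_idx[cls]].mean())
            accuracy[cls] = float(np.mean(decoded[sel] == cls))
            for k, other in enumerate(model.classes):
                confusion[cls_idx[cls], k] = int(np.sum(decoded[sel] == other))
        else:
            correct_prob[cls] = float("nan")
            accuracy[cls] = float("nan")
    return DecodeResult(
        timepoints=test.timepoints,
        posteriors=post,
        decoded=decoded,
        truth=test.labels,
        classes=model.classes,
        class_correct_prob=correct_prob,
        class_accuracy=accuracy,
        confusion=confusion,
    )


def decode_mouse(
    series: list[RateSeries],
    train_frac: float = 0.5,
    seed: int = 0,
    window: int = 30,
) -> DecodeResult:
    """Full per-mouse decoding chain: features -> split -> train -> decode."""
    features = build_features(series, window=window)
    train, test = split_train_test(features, train_frac=train_frac, seed=seed)
    model = train_nb(train)
    return decode(model, test)
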