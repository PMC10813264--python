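"""Level 3 (feed-forward) — risk-averse statistical template matching.

Eighteen optic-flow-pattern neurons each store a statistical template of the
opponent-motion feature vector for one direction (left/right) and one
10-frame temporal window of the 90-frame action (9 windows x 2 directions).
The instantaneous feed-forward evidence G_i(t) for neuron i factorizes into

    G_i = (window match) x (direction posterior),

where the window match is the neuron's risk-averse diagonal-Gaussian
log-likelihood score — the log-likelihood minus a risk-aversion penalty
proportional to the template's log-dispersion (high-variance templates are
distrusted) — affinely rescaled per neuron onto a fixed evidence range, and
the direction posterior is a logistic function of the log-likelihood
*ratio* between the window's two direction templates, scaled by the
window's typical margin and a global difficulty temperature.  The match
factor carries the temporal selectivity (when in the action the pattern
occurs); the posterior factor carries the left/right discrimination and is
graded in the deviation angle.

The exact functional form of the original classifier is reconstructed here
as the minimal model consistent with its descriptors — descriptive (fit by
moments), risk-averse (dispersion-penalized), Bayesian (class-conditional
Gaussian likelihoods and their posterior ratio); the contracts guaranteed
are monotonicity in the likelihood at fixed dispersion and exact left/right
symmetry for mirror-symmetric training data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DIRECTIONS = ("right", "left")
N_WINDOWS = 9
N_TEMPLATES = 18


@dataclass(frozen=True)
class TemplateConfig:
    lambda_risk: float = 0.5  # risk-aversion weight on the dispersion penalty
    var_floor: float = 1e-4   # lower bound on per-detector template variance
    #: affine rescaling target range of the evidence
    evidence_range: tuple[float, float] = (0.0, 1.0)
    #: raw-score percentiles (over the training set) mapped onto the range
    calibration_pct: tuple[float, float] = (5.0, 95.0)


def _other(direction: str) -> str:
    return "left" if direction == "right" else "right"


def window_of_pair(pair_index: int) -> int:
    """Temporal window (0..8) of a frame pair.

    Pair ``k`` (0-based) is the flow from frame k+1 to k+2 (1-based frames);
    window j covers target frames 10j+1 .. 10j+10, so the first window holds
    9 pairs and the rest 10.
    """
    return min((pair_index + 1) // 10, N_WINDOWS - 1)


def template_index(direction: str, window: int) -> int:
    """Neuron index of (direction, window): right -> 0..8, left -> 9..17."""
    return DIRECTIONS.index(direction) * N_WINDOWS + window


@dataclass
class TemplateBank:
    """18 diagonal-Gaussian templates plus the evidence rescaling map.

    The affine evidence map is per neuron (G_i = clip(scale_i * raw_i +
    offset_i)): each neuron's matched-window raw-score distribution over the
    training set is mapped onto the configured evidence range, so that all
    temporal windows drive the downstream dynamics in comparable units
    (a per-neuron gain normalization).
    """

    means: np.ndarray      # (18, n_features)
    variances: np.ndarray  # (18, n_features), floored
    config: TemplateConfig
    scale: np.ndarray | float = 1.0
    offset: np.ndarray | float = 0.0
    #: per-window typical |log-likelihood-ratio| over the training set
    margin_scale: np.ndarray | None = None
    #: global difficulty temperature of the direction posterior (>1 =
    #: flatter posteriors = harder discrimination); calibrated by the
    #: observer model
    posterior_temp: float = 1.0
    training_meta: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def raw_score(self, features: np.ndarray) -> np.ndarray:
        """Unscaled risk-averse log-likelihood of features under each
        template: -(1/2) sum (x-mu)^2/s^2 - (1+lambda)/2 sum log s^2.

        ``features``: (..., n_features) -> scores (..., 18).
        """
        x = np.asarray(features, dtype=float)
        if x.shape[-1] != self.n_features:
            raise ValueError(
                f"feature dimension {x.shape[-1]} does not match the bank's "
                f"{self.n_features}")
        diff = x[..., None, :] - self.means  # (..., 18, nf)
        maha = np.sum(diff * diff / self.variances, axis=-1)
        logdet = np.sum(np.log(self.variances), axis=-1)  # (18,)
        lam = self.config.lambda_risk
        return -0.5 * maha - 0.5 * (1.0 + lam) * logdet

    def window_match(self, raw: np.ndarray) -> np.ndarray:
        """Per-neuron match level: raw scores affinely rescaled and clipped
        onto the evidence range."""
        lo, hi = self.config.evidence_range
        return np.clip(self.scale * raw + self.offset, lo, hi)

    def direction_posterior(self, raw: np.ndarray) -> np.ndarray:
        """P(right | feature, window) for each of the 9 windows,
        shape (..., 9): logistic in the rightward log-likelihood ratio."""
        from scipy.special import expit

        margins = raw[..., :N_WINDOWS] - raw[..., N_WINDOWS:]
        if self.margin_scale is None:
            return expit(margins / self.posterior_temp)
        return expit(margins / (self.posterior_temp * self.margin_scale))

    def evidence(self, features: np.ndarray) -> np.ndarray:
        """Evidence G in the configured range; shape (..., 18).

        G = window match x direction posterior.  The match factor is shared
        between a window's two direction templates (their average level):
        the temporal gating population is direction-agnostic, and *all*
        left/right information is carried by the graded posterior, whose
        sharpness the difficulty temperature controls.
        """
        raw = self.raw_score(features)
        match = self.window_match(raw)
        common = 0.5 * (match[..., :N_WINDOWS] + match[..., N_WINDOWS:])
        p_right = self.direction_posterior(raw)
        g = np.empty_like(match)
        g[..., :N_WINDOWS] = common * p_right
        g[..., N_WINDOWS:] = common * (1.0 - p_right)
        return g


def fit_templates(feature_sequences, labels,
                  config: TemplateConfig | None = None) -> TemplateBank:
    """Fit the 18 templates from labeled opponent-feature sequences.

    ``feature_sequences``: iterable of (n_pairs, n_features) arrays (one per
    training kick, n_pairs = 89); ``labels``: matching 'left'/'right'
    direction labels.  Per (direction, window) the template is the pooled
    mean and diagonal variance of the feature vectors across the window's
    frame pairs and across all sequences of that direction.  The evidence
    rescaling is calibrated on the training set itself: the configured
    percentiles of raw matched-window scores map onto the evidence range.
    Deterministic and invariant to the order of the training sequences.
    """
    config = config or TemplateConfig()
    seqs = [np.asarray(f, dtype=float) for f in feature_sequences]
    labels = list(labels)
    if len(seqs) != len(labels):
        raise ValueError("feature_sequences and labels length mismatch")
    for d in DIRECTIONS:
        if sum(1 for l in labels if l == d) < 2:
            raise ValueError(f"need at least 2 training sequences per "
                             f"direction (missing {d!r})")
    n_feat = seqs[0].shape[1]
    n_pairs = seqs[0].shape[0]
    win = np.array([window_of_pair(k) for k in range(n_pairs)])

    means = np.zeros((N_TEMPLATES, n_feat))
    variances = np.full((N_TEMPLATES, n_feat), config.var_floor)
    for d in DIRECTIONS:
        pooled = [s for s, l in zip(seqs, labels) if l == d]
        stack = np.stack(pooled)  # (n_seq, n_pairs, n_feat)
        for j in range(N_WINDOWS):
            i = template_index(d, j)
            samples = stack[:, win == j, :].reshape(-1, n_feat)
            means[i] = samples.mean(axis=0)
            variances[i] = np.maximum(samples.var(axis=0), config.var_floor)

    bank = TemplateBank(means, variances, config,
                        training_meta={"n_sequences": len(seqs),
                                       "n_features": n_feat})
    # per-neuron affine calibration on matched-window raw scores
    raws = [[] for _ in range(N_TEMPLATES)]
    for s, l in zip(seqs, labels):
        r = bank.raw_score(s)  # (n_pairs, 18)
        for j in range(N_WINDOWS):
            i = template_index(l, j)
            raws[i].append(r[win == j, i])
    lo, hi = config.evidence_range
    scale = np.ones(N_TEMPLATES)
    offset = np.zeros(N_TEMPLATES)
    for i in range(N_TEMPLATES):
        p_lo, p_hi = np.percentile(np.concatenate(raws[i]),
                                   config.calibration_pct)
        if p_hi - p_lo > 0:
            scale[i] = (hi - lo) / (p_hi - p_lo)
            offset[i] = lo - scale[i] * p_lo
    bank.scale, bank.offset = scale, offset
    # per-window margin scale: typical |log-likelihood ratio| between the
    # two direction templates on matched-window training frames
    margins = [[] for _ in range(N_WINDOWS)]
    for s, l in zip(seqs, labels):
        r = bank.raw_score(s)
        for j in range(N_WINDOWS):
            m = r[win == j, template_index(l, j)] \
                - r[win == j, template_index(_other(l), j)]
            margins[j].append(np.abs(m))
    bank.margin_scale = np.array(
        [max(float(np.median(np.concatenate(m))), 1e-12) for m in margins])
    return bank


def evidence(feature: np.ndarray, bank: TemplateBank,
             frame_index: int | None = None) -> np.ndarray:
    """Evidence G_i for one feature vector (all 18 templates evaluated)."""
    return bank.evidence(feature)


def evidence_stream(features: np.ndarray, bank: TemplateBank) -> np.ndarray:
    """(n_pairs, 18) evidence time series for one sequence's features.

    Sequence-aware: each window's direction posterior is a sequential
    Bayesian estimate — the running mean of the window's log-likelihood-
    ratio margins *weighted by the window's match level*, so that margins
    count only while the window's pattern is actually present in the
    stimulus.  Before the window plays, its posterior is flat (0.5); while
    it plays, evidence accumulates; afterwards the accumulated estimate is
    retained (the neuron remembers its direction verdict), so the drive to
    the decision layer integrates direction information across the whole
    action seen so far and single-frame margin spikes are suppressed.
    """
    features = np.asarray(features, dtype=float)
    raw = bank.raw_score(features)                    # (n_pairs, 18)
    margins = raw[:, :N_WINDOWS] - raw[:, N_WINDOWS:]
    match = bank.window_match(raw)
    common = 0.5 * (match[:, :N_WINDOWS] + match[:, N_WINDOWS:])
    w_sum = np.cumsum(common, axis=0)
    acc = np.cumsum(common * margins, axis=0) / np.maximum(w_sum, 1e-12)
    acc[w_sum <= 1e-12] = 0.0
    scale = bank.posterior_temp * (bank.margin_scale
                                   if bank.margin_scale is not None else 1.0)
    from scipy.special import expit

    p_right = expit(acc / scale)
    g = np.empty_like(match)
    g[:, :N_WINDOWS] = common * p_right
    g[:, N_WINDOWS:] = common * (1.0 - p_right)
    return g


def classify(features: np.ndarray, bank: TemplateBank) -> str:
    """Direction whose matched-window evidence sum is largest."""
    n_pairs = features.shape[0]
    win = np.array([window_of_pair(k) for k in range(n_pairs)])
    g = bank.evidence(features)  # (n_pairs, 18)
    totals = {}
    for d in DIRECTIONS:
        idx = np.array([template_index(d, j) for j in win])
        totals[d] = float(g[np.arange(n_pairs), idx].sum())
    return max(totals, key=totals.get)


@dataclass
class CVReport:
    fold_accuracies: list
    mean: float
    sd: float
    folds: list  # list of test-index arrays


def crossvalidate(feature_sequences, labels, k: int = 5, seed: int = 0,
                  config: TemplateConfig | None = None) -> CVReport:
    """Stratified k-fold direction-classification cross-validation.

    Folds partition the sequences; each fold's bank is fit on the remaining
    folds and scored by argmax of summed matched-window evidence.
    """
    seqs = [np.asarray(f, dtype=float) for f in feature_sequences]
    labels = np.asarray(labels)
    n = len(seqs)
    rng = np.random.default_rng(seed)
    # stratified assignment: shuffle within each class, deal round-robin
    fold_of = np.empty(n, dtype=int)
    for d in DIRECTIONS:
        idx = np.flatnonzero(labels == d)
        idx = idx[rng.permutation(len(idx))]
        fold_of[idx] = np.arange(len(idx)) % k
    folds = [np.flatnonzero(fold_of == f) for f in range(k)]
    accs = []
    for f, test_idx in enumerate(folds):
        train_idx = np.flatnonzero(fold_of != f)
        train_labels = labels[train_idx]
        if len(set(labels[test_idx])) < 2 or len(set(train_labels)) < 2:
            raise ValueError(f"fold {f} does not contain both classes")
        bank = fit_templates([seqs[i] for i in train_idx], train_labels,
                             config)
        pred = [classify(seqs[i], bank) for i in test_idx]
        accs.append(float(np.mean(pred == labels[test_idx])))
    return CVReport(accs, float(np.mean(accs)), float(np.std(accs)), folds)
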