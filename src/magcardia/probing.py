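"""Task probes, fine-tuning protocol, patient-stratified CV and metrics.

A shallow head — dropout (0.2), a 64-unit fully connected layer with
swish activation, and a sigmoid output neuron — is attached to the
pretrained encoder.  Each cross-validation fold trains the head alone for
a warm-up phase with the encoder frozen, then optimises encoder and head
jointly, minimising class-frequency-weighted binary cross-entropy with
Adam.  Folds are assigned at the patient level (stratified), so no
patient's segments ever span train and validation.  Segment scores are
averaged per patient and patient-level AUC, sensitivity, specificity,
accuracy, precision and F1 are reported as fold means with 95% t-interval
confidence bounds.

The supervised baseline trains the identical encoder-head architecture
end-to-end from random initialisation, without pretraining or warm-up
freezing, for the same total number of epochs.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import nn
from .encoder_ssl import EncoderConfig, MCGEncoder, PretrainResult
from .preprocess import Segment


# ---------------------------------------------------------------------------
# probe head
# ---------------------------------------------------------------------------

def swish(x: np.ndarray) -> np.ndarray:
    return x * nn.sigmoid(x)


class Swish:
    def __init__(self):
        self._x = None

    def params(self):
        return []

    def forward(self, x, train=True):
        if train:
            self._x = x
        return x * nn.sigmoid(x)

    def backward(self, dy):
        s = nn.sigmoid(self._x)
        dx = dy * (s * (1.0 + self._x * (1.0 - s)))
        self._x = None
        return dx


class _ScaleNorm:
    """Per-sample rescaling e -> sqrt(D) * e / ||e||.

    SSL embeddings arrive at an arbitrary, often large, scale; the cosine
    objective only constrains their directions.  Normalising the scale
    keeps the head and the joint fine-tuning well conditioned regardless of
    how the encoder was initialised or pretrained."""

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, e, train=True):
        d = np.sqrt(e.shape[1]).astype(nn.DTYPE)
        norms = np.maximum(np.linalg.norm(e, axis=1, keepdims=True),
                           np.finfo(nn.DTYPE).tiny)
        y = d * e / norms
        if train:
            self._cache = (y / d, norms, d)
        return y

    def backward(self, dy):
        u, norms, d = self._cache  # u = e / ||e||
        self._cache = None
        return d * (dy - u * (dy * u).sum(axis=1, keepdims=True)) / norms


class ProbeHead:
    """scale-norm -> dropout(0.2) -> Linear(D, 64) -> swish -> Linear(64, 1)."""

    def __init__(self, embed_dim: int, rng: np.random.Generator,
                 hidden: int = 64, dropout: float = 0.2,
                 normalize_input: bool = True):
        if embed_dim < 1:
            raise ValueError("embed_dim must be >= 1")
        self.norm = _ScaleNorm() if normalize_input else None
        self.drop = nn.Dropout(dropout)
        self.lin1 = nn.Linear(embed_dim, hidden, rng)
        self.act = Swish()
        self.lin2 = nn.Linear(hidden, 1, rng)

    def params(self):
        return self.lin1.params() + self.lin2.params()

    def forward(self, e, train=True, rng=None):
        h = self.norm.forward(e, train) if self.norm is not None else e
        h = self.drop.forward(h, train, rng)
        h = self.act.forward(self.lin1.forward(h, train), train)
        return self.lin2.forward(h, train)[:, 0]

    def backward(self, dlogit):
        d = self.lin2.backward(dlogit[:, None])
        d = self.lin1.backward(self.act.backward(d))
        d = self.drop.backward(d)
        return self.norm.backward(d) if self.norm is not None else d

    def predict(self, e):
        return nn.sigmoid(self.forward(e, train=False))


def weighted_bce_with_logits(logits: np.ndarray, y: np.ndarray,
                             w: np.ndarray, return_grad: bool = False):
    """Mean-with-weights binary cross-entropy: sum(w_i l_i) / sum(w_i)."""
    logits = np.asarray(logits, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    # log(1 + e^-|x|) + max(x,0) - x*y  is the stable per-sample BCE
    per = np.log1p(np.exp(-np.abs(logits))) + np.maximum(logits, 0) - logits * y
    wsum = w.sum()
    loss = float((w * per).sum() / wsum)
    if not return_grad:
        return loss
    p = nn.sigmoid(logits)
    grad = (w * (p - y) / wsum).astype(nn.DTYPE)
    return loss, grad


def class_weights(y: np.ndarray) -> np.ndarray:
    """Per-sample weights inversely proportional to class frequency."""
    y = np.asarray(y)
    n = y.size
    w = np.empty(n, dtype=float)
    for cls in (0, 1):
        n_c = int((y == cls).sum())
        if n_c == 0:
            raise ValueError("both classes must be present")
        w[y == cls] = n / (2.0 * n_c)
    return w


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

def stratified_patient_folds(patient_labels: dict[str, int], k: int = 5,
                             seed: int = 0) -> dict[str, int]:
    """Patient-level stratified fold assignment, patient_id -> fold index."""
    pids = sorted(patient_labels)
    y = np.array([patient_labels[p] for p in pids])
    for cls in (0, 1):
        if int((y == cls).sum()) < k:
            raise ValueError(
                f"class {cls} has fewer than k={k} patients; cannot stratify")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment: dict[str, int] = {}
    for fold, (_, val_idx) in enumerate(skf.split(np.zeros_like(y), y)):
        for i in val_idx:
            assignment[pids[i]] = fold
    return assignment


def audit_fold_assignment(assignment: dict[str, int], segments: list[Segment],
                          k: int) -> None:
    """Raise if any patient leaks across folds or a segment's patient is
    missing from the assignment."""
    seen: dict[str, int] = {}
    for seg in segments:
        if seg.patient_id not in assignment:
            raise ValueError(f"patient {seg.patient_id} has no fold")
        f = assignment[seg.patient_id]
        if not 0 <= f < k:
            raise ValueError(f"fold index {f} out of range")
        if seen.setdefault(seg.patient_id, f) != f:
            raise ValueError(f"patient {seg.patient_id} assigned to multiple folds")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def aggregate_patient(scores: np.ndarray, patient_ids: list[str],
                      how: str = "mean") -> tuple[list[str], np.ndarray]:
    """Pool segment scores per patient (arithmetic mean by default)."""
    agg = np.mean if how == "mean" else np.median
    pids = sorted(set(patient_ids))
    pid_arr = np.asarray(patient_ids)
    scores = np.asarray(scores)
    return pids, np.array([float(agg(scores[pid_arr == p])) for p in pids])


def compute_metrics(scores: np.ndarray, labels: np.ndarray,
                    threshold: float = 0.5) -> dict[str, float]:
    """Patient-level AUC (rank statistic, ties get half credit) plus
    thresholded operating-point metrics."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if len(set(y)) < 2:
        raise ValueError("AUC undefined with a single class")
    auc = float(roc_auc_score(y, s))
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    prec = tp / (tp + fp) if tp + fp else float("nan")
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else float("nan")
    return {"auc": auc, "sensitivity": sens, "specificity": spec,
            "accuracy": (tp + tn) / y.size, "precision": prec, "f1": f1}


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Operating point maximising sensitivity + specificity - 1; meant to be
    computed on *training* scores to avoid validation leakage."""
    from sklearn.metrics import roc_curve
    fpr, tpr, thresholds = roc_curve(labels, scores)
    return float(thresholds[np.argmax(tpr - fpr)])


def bootstrap_auc_ci(scores: np.ndarray, labels: np.ndarray,
                     n_resamples: int = 1000, level: float = 0.95,
                     seed: int = 0) -> tuple[float, float, float]:
    """Patient-bootstrap percentile interval for the AUC."""
    rng = np.random.default_rng(seed)
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    point = float(roc_auc_score(labels, scores))
    n = labels.size
    vals = []
    while len(vals) < n_resamples:
        idx = rng.integers(0, n, n)
        if len(set(labels[idx])) < 2:
            continue
        vals.append(roc_auc_score(labels[idx], scores[idx]))
    lo, hi = np.quantile(vals, [0.5 - level / 2, 0.5 + level / 2])
    return point, float(lo), float(hi)


def pooled_vessel_metrics(results: list["ProbeResult"],
                          threshold: float = 0.5) -> dict[str, float]:
    """Micro-average across vessel probes: pool every (patient, vessel)
    prediction and score the pooled set."""
    scores, labels = [], []
    for res in results:
        for fold in res.folds:
            scores.extend(fold.patient_scores.tolist())
            labels.extend(fold.patient_labels.tolist())
    return compute_metrics(np.array(scores), np.array(labels), threshold)


def fold_ci(values: list[float], level: float = 0.95) -> tuple[float, float, float]:
    """Mean and two-sided t-interval across folds."""
    v = np.asarray(values, dtype=float)
    mean = float(v.mean())
    if v.size < 2:
        return mean, float("nan"), float("nan")
    half = stats.t.ppf(0.5 + level / 2, v.size - 1) * v.std(ddof=1) / np.sqrt(v.size)
    return mean, mean - half, mean + half


# ---------------------------------------------------------------------------
# fine-tuning / baseline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FinetuneConfig:
    warmup_epochs: int = 5
    joint_epochs: int = 30
    batch_size: int = 16
    head_lr: float = 1e-3
    joint_lr: float = 1e-3
    # optional discriminative fine-tuning: during joint optimisation of a
    # *pretrained* encoder it moves at joint_lr * encoder_lr_scale; the
    # supervised baseline always trains everything at joint_lr
    encoder_lr_scale: float = 1.0
    seed: int = 0
    aggregate: str = "mean"
    threshold: float = 0.5


@dataclass
class FoldOutcome:
    fold: int
    metrics: dict[str, float]
    patient_ids: list[str]
    patient_scores: np.ndarray
    patient_labels: np.ndarray
    segment_scores: np.ndarray
    val_segments: list[Segment]
    encoder: MCGEncoder
    head: ProbeHead


@dataclass
class ProbeResult:
    task: str
    folds: list[FoldOutcome]
    summary: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.folds and not self.summary:
            keys = self.folds[0].metrics
            self.summary = {k: fold_ci([f.metrics[k] for f in self.folds])
                            for k in keys}

    @property
    def mean_auc(self) -> float:
        return self.summary["auc"][0]


def _train_one_fold(encoder: MCGEncoder, head: ProbeHead,
                    train_segs: list[Segment], task: str, cfg: FinetuneConfig,
                    rng: np.random.Generator, freeze_warmup: bool) -> None:
    from .encoder_ssl import encode_segments

    x = np.stack([s.signal for s in train_segs]).astype(nn.DTYPE)
    y = np.array([s.labels[task] for s in train_segs], dtype=float)
    if len(set(y)) < 2:
        raise ValueError("training fold contains a single class")
    w = class_weights(y)
    n = len(train_segs)

    if freeze_warmup and cfg.warmup_epochs > 0:
        # encoder frozen: embeddings computed once, head trained alone
        before = encoder.checksum()
        emb = encode_segments(encoder, train_segs)
        opt = nn.Adam(head.params(), lr=cfg.head_lr)
        for _ in range(cfg.warmup_epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                logits = head.forward(emb[idx], train=True, rng=rng)
                _, dlogit = weighted_bce_with_logits(logits, y[idx], w[idx],
                                                     return_grad=True)
                opt.zero_grad()
                head.backward(dlogit)
                opt.step()
        assert encoder.checksum() == before, "encoder changed during warm-up"

    enc_lr = cfg.joint_lr * (cfg.encoder_lr_scale if freeze_warmup else 1.0)
    opt_enc = nn.Adam(encoder.params(), lr=enc_lr)
    opt_head = nn.Adam(head.params(), lr=cfg.joint_lr)
    total = cfg.joint_epochs if freeze_warmup else cfg.warmup_epochs + cfg.joint_epochs
    for _ in range(total):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            emb = encoder.forward(x[idx], train=True)
            logits = head.forward(emb, train=True, rng=rng)
            _, dlogit = weighted_bce_with_logits(logits, y[idx], w[idx],
                                                 return_grad=True)
            opt_enc.zero_grad()
            opt_head.zero_grad()
            encoder.backward(head.backward(dlogit))
            opt_enc.step()
            opt_head.step()


def _evaluate_fold(fold: int, encoder: MCGEncoder, head: ProbeHead,
                   val_segs: list[Segment], task: str,
                   cfg: FinetuneConfig) -> FoldOutcome:
    from .encoder_ssl import encode_segments

    emb = encode_segments(encoder, val_segs)
    seg_scores = head.predict(emb)
    pids, pat_scores = aggregate_patient(
        seg_scores, [s.patient_id for s in val_segs], cfg.aggregate)
    label_of = {s.patient_id: s.labels[task] for s in val_segs}
    pat_labels = np.array([label_of[p] for p in pids])
    metrics = compute_metrics(pat_scores, pat_labels, cfg.threshold)
    return FoldOutcome(fold, metrics, pids, pat_scores, pat_labels,
                       seg_scores, val_segs, encoder, head)


def _run_cv(segments: list[Segment], task: str, folds: dict[str, int],
            cfg: FinetuneConfig, make_encoder, freeze_warmup: bool) -> ProbeResult:
    k = max(folds.values()) + 1
    audit_fold_assignment(folds, segments, k)
    outcomes = []
    ss = np.random.SeedSequence(cfg.seed)
    for fold, child in enumerate(ss.spawn(k)):
        rng = np.random.default_rng(child)
        train_segs = [s for s in segments if folds[s.patient_id] != fold]
        val_segs = [s for s in segments if folds[s.patient_id] == fold]
        if not val_segs:
            continue
        encoder, head = make_encoder(rng)
        _train_one_fold(encoder, head, train_segs, task, cfg, rng, freeze_warmup)
        outcomes.append(_evaluate_fold(fold, encoder, head, val_segs, task, cfg))
    return ProbeResult(task=task, folds=outcomes)


def finetune_probe(pretrained: PretrainResult, segments: list[Segment],
                   task: str, folds: dict[str, int],
                   cfg: FinetuneConfig = FinetuneConfig()) -> ProbeResult:
    """Warm-up (encoder frozen) then joint fine-tuning, per fold."""
    def make(rng):
        encoder = MCGEncoder(pretrained.encoder_config, rng)
        encoder.set_state(pretrained.encoder.get_state())
        head = ProbeHead(pretrained.encoder_config.embed_dim, rng)
        return encoder, head

    return _run_cv(segments, task, folds, cfg, make, freeze_warmup=True)


def train_supervised_baseline(enc_cfg: EncoderConfig, segments: list[Segment],
                              task: str, folds: dict[str, int],
                              cfg: FinetuneConfig = FinetuneConfig()) -> ProbeResult:
    """Same architecture trained end-to-end from random init, no freeze."""
    def make(rng):
        return MCGEncoder(enc_cfg, rng), ProbeHead(enc_cfg.embed_dim, rng)

    return _run_cv(segments, task, folds, cfg, make, freeze_warmup=False)


def patient_labels_from_segments(segments: list[Segment], task: str) -> dict[str, int]:
    labels: dict[str, int] = {}
    for s in segments:
        y = int(s.labels[task])
        if labels.setdefault(s.patient_id, y) != y:
            raise ValueError(f"inconsistent labels for patient {s.patient_id}")
    return labels


def permute_patient_labels(segments: list[Segment], task: str,
                           seed: int) -> list[Segment]:
    """Deep-copied segments with task labels permuted across patients —
    the no-signal control for leakage checks."""
    labels = patient_labels_from_segments(segments, task)
    pids = sorted(labels)
    rng = np.random.default_rng(seed)
    permuted = dict(zip(pids, rng.permutation([labels[p] for p in pids])))
    out = []
    for s in segments:
        s2 = copy.copy(s)
        s2.labels = dict(s.labels)
        s2.labels[task] = int(permuted[s.patient_id])
        out.append(s2)
    return out
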